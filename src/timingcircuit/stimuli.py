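"""Stimulus-train generation for all task protocols.

A :class:`StimulusTrain` is an ordered list of flash onsets (ms) with a common
pulse duration.  Generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "StimulusTrain",
    "make_isochronous",
    "make_tracking_blocks",
    "make_perturbation",
    "make_sync_cont",
    "TRACKING_ISI_CHOICES",
    "SYNC_CONT_ISI_GRID",
]

#: Random-block ISI values of the tracking protocol (discrete uniform).
TRACKING_ISI_CHOICES = (600.0, 700.0, 800.0, 900.0)

#: Five-point ISI grid of the synchronization/continuation protocol
#: (evenly spaced between the stated minimum 550 ms and maximum 817 ms).
SYNC_CONT_ISI_GRID = (550.0, 617.0, 683.0, 750.0, 817.0)


@dataclass
class StimulusTrain:
    """Ordered stimulus onsets (ms) plus pulse duration and provenance."""

    onsets: np.ndarray
    pulse_dur: float = 10.0
    protocol_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if len(self.onsets) and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    @property
    def isis(self) -> np.ndarray:
        """Inter-stimulus intervals, ``ISI_n = m_{n+1} - m_n``."""
        return np.diff(self.onsets)

    def __len__(self) -> int:
        return len(self.onsets)

    def write_tsv(self, path) -> None:
        """Headered two-column table (onset_ms, duration_ms)."""
        lines = ["onset_ms\tduration_ms"]
        lines += [f"{t:.6g}\t{self.pulse_dur:.6g}" for t in self.onsets]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read_tsv(cls, path) -> "StimulusTrain":
        text = Path(path).read_text().strip().splitlines()
        header = text[0].split("\t")
        if header != ["onset_ms", "duration_ms"]:
            raise ValueError(f"malformed event-table header: {header!r}")
        onsets, durs = [], []
        for line in text[1:]:
            o, d = line.split("\t")
            onsets.append(float(o))
            durs.append(float(d))
        pulse = durs[0] if durs else 10.0
        return cls(onsets=np.asarray(onsets), pulse_dur=pulse)


def make_isochronous(isi: float, n: int, start: float = 750.0,
                     pulse_dur: float = 10.0) -> StimulusTrain:
    """``n`` equally spaced onsets starting at ``start``."""
    if isi <= 0:
        raise ValueError("isi must be positive")
    if n < 1:
        raise ValueError("need at least one onset")
    onsets = start + np.arange(n) * float(isi)
    return StimulusTrain(onsets, pulse_dur,
                         {"protocol": "isochronous", "isi": isi, "n": n, "start": start})


def make_tracking_blocks(seed, start: float = 750.0, n_blocks: int = 5,
                         block_len: int = 20, initial_isi: float = 800.0,
                         choices=TRACKING_ISI_CHOICES) -> StimulusTrain:
    """ISI tracking protocol: a fixed warm-up block followed by random blocks.

    Block 1 holds ``block_len`` consecutive ``initial_isi`` intervals; each
    later block's ISI is drawn from the discrete uniform ``choices`` grid
    (independent draws, repeats allowed).  Defaults give 5 blocks x 20 ISIs =
    100 intervals.
    """
    rng = np.random.default_rng(seed)
    isis = [initial_isi] * block_len
    block_isis = [initial_isi]
    for _ in range(n_blocks - 1):
        isi = float(rng.choice(choices))
        block_isis.append(isi)
        isis += [isi] * block_len
    onsets = start + np.concatenate([[0.0], np.cumsum(isis)])
    return StimulusTrain(
        onsets, 10.0,
        {"protocol": "tracking", "block_isis": block_isis, "seed": seed,
         "block_len": block_len, "n_intervals": len(isis)},
    )


def make_perturbation(kind: str, start: float = 750.0, n_pre: int = 30,
                      n_post: int = 15) -> StimulusTrain:
    """Perturbed metronome trains (deterministic).

    ``step``: 30 ISIs at 800 ms then 1000 ms thereafter.
    ``phase_shift``: 30 ISIs at 500 ms, one 600 ms ISI, then 500 ms (all
    later onsets shifted +100 ms relative to the original grid).
    ``jitter``: 30 ISIs at 500 ms, then 600 ms and 400 ms, then 500 ms
    (one delayed stimulus; later onsets back in phase).
    """
    if kind == "step":
        isis = [800.0] * n_pre + [1000.0] * n_post
    elif kind == "phase_shift":
        isis = [500.0] * n_pre + [600.0] + [500.0] * (n_post - 1)
    elif kind == "jitter":
        isis = [500.0] * n_pre + [600.0, 400.0] + [500.0] * (n_post - 2)
    else:
        raise ValueError(f"unknown perturbation kind: {kind!r}")
    onsets = start + np.concatenate([[0.0], np.cumsum(isis)])
    return StimulusTrain(
        onsets, 10.0,
        {"protocol": f"perturbation:{kind}", "n_pre": n_pre, "n_post": n_post},
    )


def make_sync_cont(isi: Optional[float] = None, seed=None, start: float = 750.0,
                   n_flashes: int = 3, n_continuation: int = 17,
                   grid=SYNC_CONT_ISI_GRID) -> tuple[StimulusTrain, int]:
    """Synchronization/continuation trial: ``n_flashes`` flashes at one ISI.

    If ``isi`` is None it is drawn uniformly from the five-point ``grid``.
    Returns the train and the number of continuation productions the model is
    allowed after the final flash.
    """
    if isi is None:
        rng = np.random.default_rng(seed)
        isi = float(rng.choice(grid))
    onsets = start + np.arange(n_flashes) * float(isi)
    train = StimulusTrain(
        onsets, 10.0,
        {"protocol": "sync_cont", "isi": isi, "n_flashes": n_flashes,
         "n_continuation": n_continuation},
    )
    return train, n_continuation
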