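"""Instrument-trace container shared by the simulator, generators and fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "CHANNELS"]

CHANNELS = ("mant", "fret", "pbp", "quench")


@dataclass
class Trace:
    """One instrument channel's signal versus time.

    ``signal`` is in relative-fluorescence units for the optical channels
    (mant, fret, pbp) and in % uncleaved GTP for the quench channel.
    ``time`` is in seconds and must be strictly increasing.
    """

    channel: str
    time: np.ndarray
    signal: np.ndarray
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int | None = None
    construct_label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(
                f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have the same shape")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def __len__(self) -> int:
        return self.time.size

    def window(self, t_min: float = -np.inf, t_max: float = np.inf) -> "Trace":
        """Return the sub-trace with t_min <= t <= t_max."""
        m = (self.time >= t_min) & (self.time <= t_max)
        return Trace(self.channel, self.time[m], self.signal[m],
                     self.noise_sd, self.n_replicates, self.seed,
                     self.construct_label, dict(self.meta))
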