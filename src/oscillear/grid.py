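"""Time grids and trajectory containers shared by every integrator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SimGrid:
    """Uniform time discretisation: ``t_start``, ``t_end``, step ``dt``.

    The number of steps must come out to an integer (within round-off);
    every fixed-step integrator in the package runs on such a grid, which is
    what makes runs bit-reproducible.
    """

    t_start: float
    t_end: float
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        n = (self.t_end - self.t_start) / self.dt
        if abs(n - round(n)) > 1e-6 * max(1.0, n):
            raise ValueError(
                f"(t_end - t_start)/dt = {n} is not an integer number of steps"
            )
        if round(n) < 1:
            raise ValueError("grid must contain at least one step")

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    @property
    def n_samples(self) -> int:
        return self.n_steps + 1

    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_samples)

    def refined(self, factor: int = 2) -> "SimGrid":
        """Same span with ``dt`` divided by ``factor`` (convergence checks)."""
        return SimGrid(self.t_start, self.t_end, self.dt / factor)


@dataclass
class Trajectory:
    """Time-indexed state history with named channels.

    Channels are real (displacement ``x``, velocity ``xdot``) or complex
    (amplitude ``z``).  For multi-unit systems a channel holds a 2-D array of
    shape ``(n_samples, n_units)``.  ``unit`` labels the time unit the model
    was integrated in (each model runs in its own
    natural units).
    """

    t: np.ndarray
    channels: dict[str, np.ndarray]
    unit: str = "1"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.channels.items():
            if arr.shape[0] != self.t.shape[0]:
                raise ValueError(
                    f"channel {name!r} has {arr.shape[0]} samples, "
                    f"time axis has {self.t.shape[0]}"
                )
            if not np.all(np.isfinite(self.t)):
                raise ValueError("non-finite time samples")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, t_lo: float, t_hi: float) -> "Trajectory":
        """Sub-trajectory with t in [t_lo, t_hi]."""
        mask = (self.t >= t_lo - 1e-12) & (self.t <= t_hi + 1e-12)
        return Trajectory(
            self.t[mask],
            {k: v[mask] for k, v in self.channels.items()},
            unit=self.unit,
            meta=dict(self.meta),
        )

    def tail(self, fraction: float) -> "Trajectory":
        """Final ``fraction`` of the trajectory (amplitude read-outs)."""
        if not 0 < fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        i0 = int(np.floor(self.t.shape[0] * (1 - fraction)))
        i0 = min(i0, self.t.shape[0] - 2)
        return Trajectory(
            self.t[i0:],
            {k: v[i0:] for k, v in self.channels.items()},
            unit=self.unit,
            meta=dict(self.meta),
        )
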