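"""A bidirectionally coupled Hopf pair: basilar-membrane and organ-of-Corti
units that are each damped in isolation but form a global oscillator when
coupled strongly enough.

Dynamics (complex amplitudes, real parts are the displacements):

    ż_bm = z_bm(α_bm + i2πf) + c12 z_oc
    ż_oc = z_oc(α_oc + i2πf + β|z_oc|²) + c21 z_bm

With α_bm, α_oc < 0 both units decay when uncoupled; the linearised pair
acquires an eigenvalue with non-negative real part at the critical symmetric
coupling c* = √(α_bm·α_oc), and above it the saturating nonlinearity
(β < 0) stops the growth on a limit cycle near frequency f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DivergenceError
from .grid import SimGrid, Trajectory

__all__ = [
    "HopfPairParams",
    "simulate_pair",
    "pair_threshold",
    "pair_eigenvalues",
    "classify_pair_run",
]


@dataclass(frozen=True)
class HopfPairParams:
    f: float
    alpha_bm: float
    alpha_oc: float
    beta_nl: float
    c12: float
    c21: float

    def __post_init__(self) -> None:
        if self.f <= 0:
            raise ValueError("f must be > 0")


def pair_eigenvalues(params: HopfPairParams) -> np.ndarray:
    """Eigenvalues of the linearised (small-amplitude) coupling matrix."""
    m = np.array(
        [
            [params.alpha_bm + 2j * math.pi * params.f, params.c12],
            [params.c21, params.alpha_oc + 2j * math.pi * params.f],
        ],
        dtype=complex,
    )
    return np.linalg.eigvals(m)


def pair_threshold(params: HopfPairParams) -> float:
    """Smallest symmetric coupling c = c12 = c21 > 0 destabilising the pair.

    For real symmetric coupling the eigenvalue real parts are
    (α_bm+α_oc)/2 ± √(((α_bm−α_oc)/2)² + c²), which first touches zero at
    c* = √(α_bm·α_oc).  Requires both units passive (α < 0); otherwise the
    pair is already unstable at c = 0.
    """
    a1, a2 = params.alpha_bm, params.alpha_oc
    if a1 >= 0 or a2 >= 0:
        raise ValueError("already unstable at c=0: both alphas must be < 0")
    return math.sqrt(a1 * a2)


def simulate_pair(
    params: HopfPairParams,
    z_bm0: complex,
    z_oc0: complex,
    grid: SimGrid,
    unit: str = "1",
) -> Trajectory:
    """Fixed-step RK4 integration; channels ``z_bm`` and ``z_oc``."""
    iw = 2j * math.pi * params.f
    a1 = params.alpha_bm + iw
    a2 = params.alpha_oc + iw
    be = params.beta_nl
    c12, c21 = params.c12, params.c21
    n = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    limit = 1e6 * max(1.0, abs(z_bm0), abs(z_oc0))
    zb = np.empty(n + 1, dtype=complex)
    zo = np.empty(n + 1, dtype=complex)
    b, o = complex(z_bm0), complex(z_oc0)
    zb[0], zo[0] = b, o

    def rhs(b, o):
        return (a1 * b + c12 * o,
                (a2 + be * (o.real * o.real + o.imag * o.imag)) * o + c21 * b)

    for i in range(n):
        kb1, ko1 = rhs(b, o)
        kb2, ko2 = rhs(b + half * kb1, o + half * ko1)
        kb3, ko3 = rhs(b + half * kb2, o + half * ko2)
        kb4, ko4 = rhs(b + dt * kb3, o + dt * ko3)
        b = b + dt / 6.0 * (kb1 + 2.0 * (kb2 + kb3) + kb4)
        o = o + dt / 6.0 * (ko1 + 2.0 * (ko2 + ko3) + ko4)
        if not (math.isfinite(b.real) and math.isfinite(o.real)) or \
                abs(b) > limit or abs(o) > limit:
            raise DivergenceError(
                f"hopf pair diverged at step {i + 1} "
                f"(t = {grid.t_start + (i + 1) * dt:g})",
                step=i + 1, time=grid.t_start + (i + 1) * dt,
            )
        zb[i + 1], zo[i + 1] = b, o
    return Trajectory(grid.times(), {"z_bm": zb, "z_oc": zo}, unit=unit,
                      meta={"model": "hopf-pair"})


def classify_pair_run(
    traj: Trajectory, dead_band: float = 1e-4
) -> tuple[str, float]:
    """Growth/decay verdict from the log|z_bm| envelope over the last half.

    A line is fitted to log|z_bm|; slope sign with a ±dead_band decides
    between 'growing', 'decaying' and 'steady'.
    """
    mag = np.abs(traj["z_bm"])
    n = mag.size
    seg = np.maximum(mag[n // 2:], 1e-300)
    t = traj.dt * np.arange(seg.size)
    slope = float(np.polyfit(t, np.log(seg), 1)[0])
    if abs(slope) <= dead_band:
        return "steady", slope
    return ("growing" if slope > 0 else "decaying"), slope
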