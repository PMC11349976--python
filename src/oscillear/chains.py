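"""Nearest-neighbour-coupled oscillator chains for the lizard ear.

Two chain families model a papilla of hair-cell bundles:

* a complex Hopf chain, ż_j = (iω_j + ε_j)z_j − B|z_j|²z_j
  + (d_R + i·d_I)(z_{j+1} − 2z_j + z_{j−1}), with complex nearest-neighbour
  coupling strength d_R + i·d_I applied through the discrete Laplacian;
* a Van der Pol chain in the first-order (Liénard) form
  ẋ_n = μ_n(y_n − x_n³/3 + α_n x_n + coupling), ẏ_n = −(2πf_n)²x_n/μ_n,
  which eliminates to ẍ_n + μ_n(−α_n + x_n²)ẋ_n + (2πf_n)²x_n = 0 per unit,
  with either elastic (γ_el, displacement-stencil inside the ẋ bracket) or
  viscous (γ_vis, velocity-stencil on the acceleration) coupling.

With a monotone frequency gradient and sufficient coupling, units lock into
frequency plateaus — the model's picture of a single SOAE as a cluster of
frequency-locked oscillators.  ``detect_plateaus`` measures that clustering.

The neighbour stencil is the standard second difference
(z_{j+1} − 2z_j + z_{j−1}); free ends (one-sided stencil) by
default, so the coupling term sums to zero over the chain, with a periodic
option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError
from .grid import SimGrid, Trajectory
from .signals import dominant_frequency

__all__ = [
    "HopfChainParams",
    "VdPChainParams",
    "PlateauReport",
    "simulate_hopf_chain",
    "simulate_vdp_chain",
    "detect_plateaus",
]


def _laplacian(z: np.ndarray, boundary: str) -> np.ndarray:
    lap = np.empty_like(z)
    lap[1:-1] = z[2:] - 2.0 * z[1:-1] + z[:-2]
    if boundary == "free":
        lap[0] = z[1] - z[0]
        lap[-1] = z[-2] - z[-1]
    elif boundary == "periodic":
        lap[0] = z[1] - 2.0 * z[0] + z[-1]
        lap[-1] = z[0] - 2.0 * z[-1] + z[-2]
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    return lap


@dataclass(frozen=True)
class HopfChainParams:
    """Per-unit ω_j, ε_j; shared nonlinearity B; coupling d_R + i·d_I."""

    omega_j: np.ndarray
    epsilon_j: np.ndarray
    B: float = 1.0
    dR: float = 0.0
    dI: float = 0.0
    boundary: str = "free"

    def __post_init__(self) -> None:
        om = np.asarray(self.omega_j, dtype=float)
        ep = np.asarray(self.epsilon_j, dtype=float)
        object.__setattr__(self, "omega_j", om)
        object.__setattr__(self, "epsilon_j", ep)
        if om.size < 2:
            raise ValueError("chain needs n >= 2 units")
        if om.shape != ep.shape:
            raise ValueError("omega_j and epsilon_j must have the same length")
        if np.any(om <= 0):
            raise ValueError("all omega_j must be > 0")

    @property
    def n(self) -> int:
        return int(self.omega_j.size)


@dataclass(frozen=True)
class VdPChainParams:
    """Per-unit μ_n, α_n, f_n; at most one of γ_el, γ_vis nonzero per run."""

    mu_n: np.ndarray
    alpha_n: np.ndarray
    f_n: np.ndarray
    gamma_el: float = 0.0
    gamma_vis: float = 0.0
    boundary: str = "free"

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu_n, dtype=float)
        al = np.asarray(self.alpha_n, dtype=float)
        fn = np.asarray(self.f_n, dtype=float)
        object.__setattr__(self, "mu_n", mu)
        object.__setattr__(self, "alpha_n", al)
        object.__setattr__(self, "f_n", fn)
        if mu.size < 2:
            raise ValueError("chain needs n >= 2 units")
        if not (mu.shape == al.shape == fn.shape):
            raise ValueError("per-unit parameter arrays must share a length")
        if self.gamma_el != 0.0 and self.gamma_vis != 0.0:
            raise ValueError(
                "use at most one of gamma_el, gamma_vis per run "
                "(the coupling modes are investigated separately)"
            )

    @property
    def n(self) -> int:
        return int(self.mu_n.size)


@dataclass
class PlateauReport:
    """Per-unit dominant frequencies and the detected frequency plateaus."""

    frequencies: np.ndarray
    plateaus: list[tuple[int, int, float]]
    silent_units: list[int] = field(default_factory=list)

    @property
    def plateau_count(self) -> int:
        return len(self.plateaus)


def simulate_hopf_chain(
    params: HopfChainParams,
    z0: np.ndarray,
    grid: SimGrid,
    unit: str = "1",
) -> Trajectory:
    """Vectorised RK4 over all units; channel ``z`` of shape (samples, n)."""
    z0 = np.asarray(z0, dtype=complex)
    if z0.shape != (params.n,):
        raise ValueError("z0 must provide one complex amplitude per unit")
    lin = 1j * params.omega_j + params.epsilon_j
    B = params.B
    d = params.dR + 1j * params.dI
    boundary = params.boundary
    n_steps = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    limit = 1e6 * max(1.0, float(np.max(np.abs(z0))))
    out = np.empty((n_steps + 1, params.n), dtype=complex)
    z = z0.copy()
    out[0] = z

    def rhs(z):
        return lin * z - B * (z.real ** 2 + z.imag ** 2) * z \
            + d * _laplacian(z, boundary)

    for i in range(n_steps):
        k1 = rhs(z)
        k2 = rhs(z + half * k1)
        k3 = rhs(z + half * k2)
        k4 = rhs(z + dt * k3)
        z = z + dt / 6.0 * (k1 + 2.0 * (k2 + k3) + k4)
        peak = float(np.max(np.abs(z)))
        if not np.isfinite(peak) or peak > limit:
            j = int(np.argmax(np.abs(z)))
            raise DivergenceError(
                f"hopf chain unit {j} diverged at step {i + 1}",
                step=i + 1, time=grid.t_start + (i + 1) * dt, element=j,
            )
        out[i + 1] = z
    return Trajectory(grid.times(), {"z": out}, unit=unit,
                      meta={"model": "hopf-chain"})


def simulate_vdp_chain(
    params: VdPChainParams,
    x0: np.ndarray,
    y0: np.ndarray,
    grid: SimGrid,
    unit: str = "1",
) -> Trajectory:
    """Van der Pol chain in Liénard coordinates; channels ``x`` and ``y``."""
    x0 = np.asarray(x0, dtype=float)
    y0 = np.asarray(y0, dtype=float)
    if x0.shape != (params.n,) or y0.shape != (params.n,):
        raise ValueError("x0 and y0 must provide one value per unit")
    mu = params.mu_n
    al = params.alpha_n
    om2 = (2.0 * np.pi * params.f_n) ** 2
    g_el = params.gamma_el
    g_vis = params.gamma_vis
    boundary = params.boundary
    n_steps = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    limit = 1e6 * max(1.0, float(np.max(np.abs(x0))))
    xs = np.empty((n_steps + 1, params.n))
    ys = np.empty((n_steps + 1, params.n))
    x, y = x0.copy(), y0.copy()
    xs[0], ys[0] = x, y

    def rhs(x, y):
        bracket = y - x ** 3 / 3.0 + al * x
        if g_el != 0.0:
            bracket = bracket + g_el * _laplacian(x, boundary)
        xdot = mu * bracket
        ydot = -om2 / mu * x
        if g_vis != 0.0:
            # viscous stencil acts on velocities in the acceleration
            # equation; in Liénard coordinates that means feeding
            # γ_vis·Δ²(ẋ)/μ into ẏ.
            ydot = ydot + g_vis * _laplacian(xdot, boundary) / mu
        return xdot, ydot

    for i in range(n_steps):
        kx1, ky1 = rhs(x, y)
        kx2, ky2 = rhs(x + half * kx1, y + half * ky1)
        kx3, ky3 = rhs(x + half * kx2, y + half * ky2)
        kx4, ky4 = rhs(x + dt * kx3, y + dt * ky3)
        x = x + dt / 6.0 * (kx1 + 2.0 * (kx2 + kx3) + kx4)
        y = y + dt / 6.0 * (ky1 + 2.0 * (ky2 + ky3) + ky4)
        peak = float(np.max(np.abs(x)))
        if not np.isfinite(peak) or peak > limit:
            j = int(np.argmax(np.abs(x)))
            raise DivergenceError(
                f"vdp chain unit {j} diverged at step {i + 1}",
                step=i + 1, time=grid.t_start + (i + 1) * dt, element=j,
            )
        xs[i + 1], ys[i + 1] = x, y
    return Trajectory(grid.times(), {"x": xs, "y": ys}, unit=unit,
                      meta={"model": "vdp-chain"})


def detect_plateaus(
    traj: Trajectory,
    rel_tol: float = 0.01,
    channel: str | None = None,
    tail_fraction: float = 0.5,
    silence_floor: float = 1e-9,
) -> PlateauReport:
    """Per-unit dominant frequencies and greedy plateau merging.

    The dominant frequency of each unit is measured on the late-time window;
    adjacent units whose frequencies agree with the running plateau mean
    within ``rel_tol`` are merged.  Silent units get frequency NaN, are
    excluded from plateaus and reported separately.  The trajectory must be
    long enough for ≥ 20 cycles of the slowest unit.
    """
    if channel is None:
        channel = "x" if "x" in traj.channels else "z"
    data = traj.channels[channel]
    if np.iscomplexobj(data):
        data = data.real
    if data.ndim != 2:
        raise ValueError("detect_plateaus expects a multi-unit trajectory")
    tail = traj.tail(tail_fraction)
    seg = tail.channels[channel]
    if np.iscomplexobj(seg):
        seg = seg.real
    dt = traj.dt
    n = data.shape[1]
    freqs = np.full(n, np.nan)
    silent: list[int] = []
    for j in range(n):
        col = seg[:, j]
        if np.max(np.abs(col - col.mean())) < silence_floor:
            silent.append(j)
            continue
        freqs[j] = dominant_frequency(col, dt)
    active = freqs[np.isfinite(freqs) & (freqs > 0)]
    if active.size:
        fmin = active.min()
        if tail.duration * fmin < 20:
            raise ValueError(
                "late-time window too short: need >= 20 cycles of the "
                f"slowest unit ({fmin:g})"
            )
    plateaus: list[tuple[int, int, float]] = []
    start = None
    acc: list[float] = []
    for j in range(n):
        f = freqs[j]
        if not np.isfinite(f) or f <= 0:
            if start is not None:
                plateaus.append((start, j - 1, float(np.mean(acc))))
                start, acc = None, []
            continue
        if start is None:
            start, acc = j, [f]
        elif abs(f - np.mean(acc)) <= rel_tol * np.mean(acc):
            acc.append(f)
        else:
            plateaus.append((start, j - 1, float(np.mean(acc))))
            start, acc = j, [f]
    if start is not None:
        plateaus.append((start, n - 1, float(np.mean(acc))))
    return PlateauReport(freqs, plateaus, silent)
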