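"""Single-unit oscillator models of SOAE generators.

Five families, each integrated in the unit system its parameters are
defined in:

* Van der Pol  — ``x'' + ω(−α + βx²)x' + ω²x = F(t)``: negative damping for
  small displacement (if α > 0), positive for large, yielding a stable limit
  cycle of amplitude ≈ 2√(α/β) in the weakly nonlinear regime.
* Van der Pol–Duffing — the same damping with hardening stiffness
  ``ω²(λ + μx²)x``, so oscillation frequency grows with amplitude for μ > 0.
* Delayed-stiffness Van der Pol — part of the restoring force is applied with
  a delay, ``ω²(x(t) + κ x(t−Δt))``; the delay can flip the oscillator
  between active and passive.
* Anti-damped Van der Pol — damping ``ω(α + βx² − γ/⟨x²⟩)x'``, where ⟨x²⟩ is
  the squared amplitude averaged over a slow time scale; the γ term injects
  energy when the oscillation is weak, giving fast recovery after
  suppression.
* Hopf normal form — ``ż = (iω₀ + ε)z − |z|²z``: self-oscillating with
  |z| → √ε for ε > 0, damped for ε < 0.

All integrators are fixed-step 4th-order Runge–Kutta (bit-reproducible, and
the natural history buffer for the delayed model).  An optional external
drive force supports noise driving and entrainment probes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import DivergenceError
from .grid import SimGrid, Trajectory

__all__ = [
    "VdPParams",
    "DuffingParams",
    "DelayVdPParams",
    "AntiDampParams",
    "HopfParams",
    "damping_profile",
    "simulate_vdp",
    "simulate_duffing",
    "simulate_delay_vdp",
    "simulate_antidamp",
    "simulate_hopf",
    "steady_amplitude",
    "hopf_radius_exact",
    "delay_vdp_growth_rate",
]

# ---------------------------------------------------------------------------
# parameter records


@dataclass(frozen=True)
class VdPParams:
    """ω: angular frequency; α: linear undamping; β: amplitude limiter."""

    omega: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class DuffingParams:
    """Van der Pol damping plus hardening stiffness ω²(λ + μx²)x."""

    omega: float
    alpha: float
    beta: float
    lam: float
    mu: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.lam <= 0:
            raise ValueError("lam must be > 0 for the cases exercised")


@dataclass(frozen=True)
class DelayVdPParams:
    """Delayed-stiffness weight κ and delay Δt on the restoring force."""

    omega: float
    alpha: float
    beta: float
    kappa_d: float
    delta_t: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.delta_t < 0:
            raise ValueError("delta_t must be >= 0")


@dataclass(frozen=True)
class AntiDampParams:
    """γ/⟨x²⟩ anti-damping with slow averaging time constant tau_avg.

    In this model's sign convention the linear damping is +α (an
    ordinary damped oscillator for α > 0); only the γ term injects energy.
    """

    omega: float
    alpha: float
    beta: float
    gamma_ad: float
    tau_avg: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.gamma_ad < 0:
            raise ValueError("gamma_ad must be >= 0")
        if self.tau_avg <= 0:
            raise ValueError("tau_avg must be > 0")


@dataclass(frozen=True)
class HopfParams:
    """Natural angular frequency ω₀ and control parameter ε."""

    omega0: float
    epsilon: float

    def __post_init__(self) -> None:
        if self.omega0 <= 0:
            raise ValueError("omega0 must be > 0")


# ---------------------------------------------------------------------------
# helpers

Drive = Callable[[float], float] | Sequence[float] | np.ndarray | None


def _half_step_drive(drive: Drive, grid: SimGrid) -> np.ndarray | None:
    """Resolve a drive to samples on the half-step grid (2·n_steps + 1).

    RK4 stages fall exactly on half steps, so a pre-sampled drive avoids any
    per-step interpolation and keeps runs bit-reproducible.
    """
    if drive is None:
        return None
    n = 2 * grid.n_steps + 1
    if callable(drive):
        h = grid.dt / 2.0
        return np.asarray(
            [drive(grid.t_start + i * h) for i in range(n)], dtype=float
        )
    arr = np.asarray(drive, dtype=float)
    if arr.shape != (n,):
        raise ValueError(
            f"sampled drive must have 2*n_steps+1 = {n} samples on the "
            f"half-step grid, got {arr.shape}"
        )
    return arr


def _guard(x: float, limit: float, step: int, t: float, model: str) -> None:
    if not math.isfinite(x) or abs(x) > limit:
        raise DivergenceError(
            f"{model}: |x| exceeded divergence guard {limit:g} "
            f"at step {step} (t = {t:g})",
            step=step,
            time=t,
        )


_GUARD_FACTOR = 1e6  # |x| > 1e6 × max(1, |x0|) aborts


# ---------------------------------------------------------------------------
# operations


def damping_profile(params: VdPParams, x: float | np.ndarray):
    """Displacement-dependent damping −α + βx² (even in x)."""
    return -params.alpha + params.beta * np.square(x)


def simulate_vdp(
    params: VdPParams,
    x0: float,
    v0: float,
    grid: SimGrid,
    drive: Drive = None,
    unit: str = "1",
) -> Trajectory:
    """Integrate the Van der Pol oscillator; channels ``x`` and ``xdot``."""
    d = _half_step_drive(drive, grid)
    om, al, be = params.omega, params.alpha, params.beta
    return _integrate_second_order(
        lambda x, v, f: -om * (-al + be * x * x) * v - om * om * x + f,
        x0, v0, grid, d, "vdp", unit,
    )


def simulate_duffing(
    params: DuffingParams,
    x0: float,
    v0: float,
    grid: SimGrid,
    drive: Drive = None,
    unit: str = "1",
) -> Trajectory:
    """Van der Pol–Duffing oscillator with hardening stiffness."""
    d = _half_step_drive(drive, grid)
    om, al, be = params.omega, params.alpha, params.beta
    lam, mu = params.lam, params.mu
    om2 = om * om
    return _integrate_second_order(
        lambda x, v, f: -om * (-al + be * x * x) * v
        - om2 * (lam + mu * x * x) * x + f,
        x0, v0, grid, d, "duffing", unit,
    )


def _integrate_second_order(acc, x0, v0, grid, drive, model, unit):
    """Scalar RK4 for x'' = acc(x, x', F(t)); drive on half steps."""
    n = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    limit = _GUARD_FACTOR * max(1.0, abs(x0))
    xs = np.empty(n + 1)
    vs = np.empty(n + 1)
    x, v = float(x0), float(v0)
    xs[0], vs[0] = x, v
    have_drive = drive is not None
    f0 = fm = f1 = 0.0
    for i in range(n):
        if have_drive:
            j = 2 * i
            f0, fm, f1 = drive[j], drive[j + 1], drive[j + 2]
        a1 = acc(x, v, f0)
        x2 = x + half * v
        v2 = v + half * a1
        a2 = acc(x2, v2, fm)
        x3 = x + half * v2
        v3 = v + half * a2
        a3 = acc(x3, v3, fm)
        x4 = x + dt * v3
        v4 = v + dt * a3
        a4 = acc(x4, v4, f1)
        x += dt / 6.0 * (v + 2.0 * (v2 + v3) + v4)
        v += dt / 6.0 * (a1 + 2.0 * (a2 + a3) + a4)
        _guard(x, limit, i + 1, grid.t_start + (i + 1) * dt, model)
        xs[i + 1], vs[i + 1] = x, v
    return Trajectory(grid.times(), {"x": xs, "xdot": vs}, unit=unit,
                      meta={"model": model})


def simulate_delay_vdp(
    params: DelayVdPParams,
    history_x: float,
    history_v: float,
    grid: SimGrid,
    drive: Drive = None,
    unit: str = "1",
) -> Trajectory:
    """Delayed-stiffness Van der Pol with constant pre-history.

    ``history_x`` is the constant value of x(t) for t ≤ t_start (the delayed
    stiffness term reads it); ``history_v`` only sets the initial velocity.
    For Δt = 0 this reduces exactly to a plain oscillator with stiffness
    ω²(1 + κ).  The delayed value is obtained by linear interpolation into
    the stored trajectory, so Δt need not be a multiple of dt (but must be
    ≥ dt, or 0, so stage look-backs stay inside the computed history).
    """
    om, al, be = params.omega, params.alpha, params.beta
    kap, lag = params.kappa_d, params.delta_t
    om2 = om * om
    if lag == 0.0:
        d = _half_step_drive(drive, grid)
        return _integrate_second_order(
            lambda x, v, f: -om * (-al + be * x * x) * v
            - om2 * (x + kap * x) + f,
            history_x, history_v, grid, d, "delay-vdp", unit,
        )
    dt = grid.dt
    if lag < dt:
        raise ValueError(
            f"delta_t = {lag} shorter than dt = {dt}: refine the grid so the "
            "delayed value lies inside the stored history"
        )
    d = _half_step_drive(drive, grid)
    n = grid.n_steps
    half = dt / 2.0
    t0 = grid.t_start
    limit = _GUARD_FACTOR * max(1.0, abs(history_x))
    xs = np.empty(n + 1)
    vs = np.empty(n + 1)
    x, v = float(history_x), float(history_v)
    xs[0], vs[0] = x, v

    def delayed(t: float, cur: int) -> float:
        s = t - lag
        if s <= t0:
            return history_x
        u = (s - t0) / dt
        i = int(u)
        if i >= cur:
            return xs[cur]
        frac = u - i
        return xs[i] + frac * (xs[i + 1] - xs[i])

    have_drive = d is not None
    f0 = fm = f1 = 0.0
    for i in range(n):
        t = t0 + i * dt
        if have_drive:
            j = 2 * i
            f0, fm, f1 = d[j], d[j + 1], d[j + 2]
        xd0 = delayed(t, i)
        xdm = delayed(t + half, i)
        xd1 = delayed(t + dt, i)

        a1 = -om * (-al + be * x * x) * v - om2 * (x + kap * xd0) + f0
        x2 = x + half * v
        v2 = v + half * a1
        a2 = -om * (-al + be * x2 * x2) * v2 - om2 * (x2 + kap * xdm) + fm
        x3 = x + half * v2
        v3 = v + half * a2
        a3 = -om * (-al + be * x3 * x3) * v3 - om2 * (x3 + kap * xdm) + fm
        x4 = x + dt * v3
        v4 = v + dt * a3
        a4 = -om * (-al + be * x4 * x4) * v4 - om2 * (x4 + kap * xd1) + f1
        x += dt / 6.0 * (v + 2.0 * (v2 + v3) + v4)
        v += dt / 6.0 * (a1 + 2.0 * (a2 + a3) + a4)
        _guard(x, limit, i + 1, t + dt, "delay-vdp")
        xs[i + 1], vs[i + 1] = x, v
    return Trajectory(grid.times(), {"x": xs, "xdot": vs}, unit=unit,
                      meta={"model": "delay-vdp"})


def simulate_antidamp(
    params: AntiDampParams,
    x0: float,
    v0: float,
    msq0: float,
    grid: SimGrid,
    drive: Drive = None,
    msq_floor: float = 1e-12,
    unit: str = "1",
) -> Trajectory:
    """Anti-damped Van der Pol with ⟨x²⟩ kept as an exponential moving
    average of x² with time constant ``tau_avg``.

    ``msq0`` must be > 0 (the γ/⟨x²⟩ term is singular at zero).  If the
    average ever falls below ``msq_floor`` it is clamped there and a warning
    is recorded, not an abort: a cold start is a legitimate use.
    Channels: ``x``, ``xdot``, ``msq``.
    """
    if msq0 <= 0:
        raise ValueError("msq0 must be > 0 (gamma/<x^2> is singular at 0)")
    d = _half_step_drive(drive, grid)
    om, al, be = params.omega, params.alpha, params.beta
    gam, tau = params.gamma_ad, params.tau_avg
    om2 = om * om
    n = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    limit = _GUARD_FACTOR * max(1.0, abs(x0))
    xs = np.empty(n + 1)
    vs = np.empty(n + 1)
    ms = np.empty(n + 1)
    x, v, m = float(x0), float(v0), float(msq0)
    xs[0], vs[0], ms[0] = x, v, m
    clamped = False
    have_drive = d is not None
    f0 = fm = f1 = 0.0

    def rates(x, v, m, f):
        meff = m if m > msq_floor else msq_floor
        a = -om * (al + be * x * x - gam / meff) * v - om2 * x + f
        dm = (x * x - m) / tau
        return a, dm

    for i in range(n):
        if have_drive:
            j = 2 * i
            f0, fm, f1 = d[j], d[j + 1], d[j + 2]
        a1, q1 = rates(x, v, m, f0)
        x2, v2, m2 = x + half * v, v + half * a1, m + half * q1
        a2, q2 = rates(x2, v2, m2, fm)
        x3, v3, m3 = x + half * v2, v + half * a2, m + half * q2
        a3, q3 = rates(x3, v3, m3, fm)
        x4, v4, m4 = x + dt * v3, v + dt * a3, m + dt * q3
        a4, q4 = rates(x4, v4, m4, f1)
        x += dt / 6.0 * (v + 2.0 * (v2 + v3) + v4)
        v += dt / 6.0 * (a1 + 2.0 * (a2 + a3) + a4)
        m += dt / 6.0 * (q1 + 2.0 * (q2 + q3) + q4)
        if m < msq_floor:
            m = msq_floor
            clamped = True
        _guard(x, limit, i + 1, grid.t_start + (i + 1) * dt, "antidamp")
        xs[i + 1], vs[i + 1], ms[i + 1] = x, v, m
    if clamped:
        warnings.warn(
            "antidamp: <x^2> hit the floor "
            f"{msq_floor:g} and was clamped", RuntimeWarning, stacklevel=2,
        )
    return Trajectory(
        grid.times(), {"x": xs, "xdot": vs, "msq": ms}, unit=unit,
        meta={"model": "antidamp", "msq_clamped": clamped},
    )


def simulate_hopf(
    params: HopfParams,
    z0: complex,
    grid: SimGrid,
    drive: Drive = None,
    unit: str = "1",
) -> Trajectory:
    """Hopf normal form ż = (iω₀ + ε)z − |z|²z; complex channel ``z``."""
    d = _half_step_drive(drive, grid)
    lin = 1j * params.omega0 + params.epsilon
    n = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    limit = _GUARD_FACTOR * max(1.0, abs(z0))
    zs = np.empty(n + 1, dtype=complex)
    z = complex(z0)
    zs[0] = z
    have_drive = d is not None
    f0 = fm = f1 = 0.0

    def rhs(z, f):
        return lin * z - (z.real * z.real + z.imag * z.imag) * z + f

    for i in range(n):
        if have_drive:
            j = 2 * i
            f0, fm, f1 = d[j], d[j + 1], d[j + 2]
        k1 = rhs(z, f0)
        k2 = rhs(z + half * k1, fm)
        k3 = rhs(z + half * k2, fm)
        k4 = rhs(z + dt * k3, f1)
        z = z + dt / 6.0 * (k1 + 2.0 * (k2 + k3) + k4)
        _guard(abs(z), limit, i + 1, grid.t_start + (i + 1) * dt, "hopf")
        zs[i + 1] = z
    return Trajectory(grid.times(), {"z": zs}, unit=unit,
                      meta={"model": "hopf"})


def hopf_radius_exact(
    epsilon: float, r0: float, t: np.ndarray | float
) -> np.ndarray | float:
    """Closed-form |z(t)| for the radial equation ṙ = εr − r³.

    r(t)² = ε r0² e^{2εt} / (ε + r0²(e^{2εt} − 1)) for ε ≠ 0; the ε → 0
    limit is r0/√(1 + 2r0²t).
    """
    t = np.asarray(t, dtype=float)
    if r0 == 0:
        return np.zeros_like(t)
    if epsilon == 0:
        return r0 / np.sqrt(1.0 + 2.0 * r0 * r0 * t)
    e2 = np.exp(2.0 * epsilon * t)
    return np.sqrt(epsilon * r0 * r0 * e2 /
                   (epsilon + r0 * r0 * (e2 - 1.0)))


def steady_amplitude(
    traj: Trajectory,
    window_fraction: float = 0.2,
    channel: str | None = None,
) -> float:
    """Half the peak-to-peak excursion over the final window.

    Robust for non-sinusoidal steady signals, unlike RMS×√2.  Returns 0 for
    an identically zero signal.  Raises if the window is shorter than one
    period of the dominant frequency (the estimate would alias the envelope).
    Complex channels are read through their real part.
    """
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    if channel is None:
        channel = "x" if "x" in traj.channels else next(iter(traj.channels))
    data = traj.channels[channel]
    if np.iscomplexobj(data):
        data = data.real
    if data.ndim != 1:
        raise ValueError("steady_amplitude needs a single-unit channel")
    tail = traj.tail(window_fraction)
    seg = tail.channels[channel]
    if np.iscomplexobj(seg):
        seg = seg.real
    if not np.any(data != 0):
        return 0.0
    from .signals import dominant_frequency  # local: avoids import cycle

    f = dominant_frequency(seg, traj.dt)
    span = tail.duration
    if f > 0 and span < 1.0 / f:
        raise ValueError(
            f"window ({span:g}) shorter than one period of the dominant "
            f"frequency ({1.0 / f:g})"
        )
    return 0.5 * float(seg.max() - seg.min())


def delay_vdp_growth_rate(params: DelayVdPParams) -> float:
    """Largest Re(s) over roots of the linearised delayed oscillator.

    The small-amplitude dynamics obey the quasipolynomial
    ``s² + ω(−α)s + ω²(1 + κ e^{−sΔt}) = 0``; a root with positive real
    part means the delayed oscillator is active (self-sustaining), all roots
    in the left half-plane mean it is passive.  Roots are located by Newton
    iteration from a grid of starting points; only the rightmost matters.
    """
    om, al = params.omega, params.alpha
    kap, lag = params.kappa_d, params.delta_t
    om2 = om * om

    def _exp(s: complex) -> complex:
        # Newton iterates can wander far left; cap the exponent to avoid
        # overflow (such iterates are discarded by the residual check).
        w = -s * lag
        if w.real > 300.0:
            w = complex(300.0, w.imag)
        return np.exp(w)

    def f(s: complex) -> complex:
        return s * s - om * al * s + om2 * (1.0 + kap * _exp(s))

    def fp(s: complex) -> complex:
        return 2.0 * s - om * al - om2 * kap * lag * _exp(s)

    best = -np.inf
    re_grid = np.linspace(-3.0 * om, 1.5 * om, 10)
    im_grid = np.linspace(0.0, 4.0 * om, 24)
    for re0 in re_grid:
        for im0 in im_grid:
            s = complex(re0, im0)
            for _ in range(60):
                d = fp(s)
                if d == 0:
                    break
                step = f(s) / d
                s -= step
                if abs(step) < 1e-12 * max(1.0, abs(s)):
                    break
            if abs(f(s)) < 1e-8 * om2 and s.real > best:
                best = s.real
    return float(best)
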