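"""The fluid-filled-box cochlea: a middle-ear oscillator plus an array of
micromechanical elements coupled through incompressible fluid pressure.

The model is a one-dimensional duct holding ``n`` elements.  Element 1 is a
damped harmonic oscillator standing for the middle ear and eardrum; elements
2…n are tuned sections of the cochlear partition with natural frequencies
decreasing exponentially from base to apex.  The fluid couples them through

    p(t) = a · F⁻¹ · ẍ(t)

where F is the discrete second-difference operator of the duct with a
stapes-side row tied to the middle-ear acceleration and a pressure-release
(Dirichlet) apical boundary, and the single constant ``a`` absorbs fluid
density, duct height and element spacing.  Because the pressure depends on
the instantaneous accelerations, which themselves depend on the pressure,
every step solves the implicit linear system exactly: the state-independent
operator S = (I − a·M⁻¹·K·F⁻¹)⁻¹ is factorised once, and accelerations are
S·M⁻¹·(local forces).

Two element mechanics are available:

* Van der Pol sections — ẍ_j + ω_j(−α_j + β_j x_j²)ẋ_j + ω_j²x_j = κ p_j.
  One element given α > 0 becomes a self-sustaining local oscillator; the
  wave it launches reflects at the stapes and forms a standing wave whose
  pressure at the base drives the middle ear: an SOAE.
* Two-mass (basilar-membrane + tectorial-membrane) elements with a
  tanh-saturating active feedback of gain γ₀ on the relative motion of the
  two masses.  Larger γ₀ means less damping; a single γ₀ irregularity in an
  otherwise uniform (and individually stable) array can make the whole box
  a global oscillator.

Sign convention for F: interior rows are (1, −2, 1)/h², which with a > 0
makes the fluid load the partition inertially (pressure opposes
acceleration); the opposite sign would feed energy into a fully passive box.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import DivergenceError
from .grid import SimGrid, Trajectory

__all__ = [
    "BoxConfig",
    "FluidMatrix",
    "VdPElementSpec",
    "NKElementSpec",
    "BoxHistory",
    "build_frequency_map",
    "natural_frequency",
    "build_fluid_matrix",
    "fluid_pressure",
    "saturation_gamma",
    "simulate_vdp_box",
    "simulate_nk_box",
    "apply_irregularity",
    "standing_wave_profile",
    "damping_sweep",
    "vdp_box_growth_rate",
    "nk_box_growth_rate",
    "nk_element_growth_rate",
    "nk_place_maps",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class BoxConfig:
    """Geometry, fluid constant, middle ear and integration grid.

    Frequencies are in the unit system the run is integrated in: cycles per
    time unit of ``grid`` (kHz with a millisecond grid, Hz with a second
    grid).  ``omega1`` is the middle-ear angular frequency in rad per time
    unit.
    """

    n: int = 351
    a: float = 0.2
    kappa: float = 1.0
    d1: float = 0.1
    omega1: float = 2.0 * np.pi          # 1 kHz on a millisecond grid
    f_base: float = 10.0
    f_apex: float = 0.14
    grid: SimGrid = field(default_factory=lambda: SimGrid(0.0, 50.0, 0.005))
    unit: str = "ms"
    basal_weight: float = 1.0
    duct_length: float = 100.0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not self.f_base > self.f_apex > 0:
            raise ValueError("need f_base > f_apex > 0")


def build_frequency_map(n: int, f_base: float, f_apex: float) -> np.ndarray:
    """Natural angular frequencies ω_j for elements j = 2…n.

    ω_j = 2π·f_base·(f_apex/f_base)^((j−2)/(n−2)), strictly decreasing from
    base to apex.  Returns an array of length n−1; entry ``j−2`` belongs to
    element j (1-based numbering, element 1 being the middle ear).
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if f_apex >= f_base:
        raise ValueError("f_apex must be < f_base")
    j = np.arange(2, n + 1)
    return 2.0 * np.pi * f_base * (f_apex / f_base) ** ((j - 2) / (n - 2))


def natural_frequency(n: int, f_base: float, f_apex: float, j: int) -> float:
    """Natural frequency (cycles per time unit) of element j = 2…n."""
    if not 2 <= j <= n:
        raise ValueError(f"element index {j} outside 2..{n}")
    return f_base * (f_apex / f_base) ** ((j - 2) / (n - 2))


# ---------------------------------------------------------------------------
# fluid coupling


@dataclass
class FluidMatrix:
    """The n×n operator F with its cached inverse: p = a·F⁻¹·ẍ."""

    F: np.ndarray
    F_inv: np.ndarray
    h: float

    @property
    def n(self) -> int:
        return self.F.shape[0]


def build_fluid_matrix(config: BoxConfig) -> FluidMatrix:
    """Second-difference duct operator with stapes and pressure-release ends.

    Interior rows (1, −2, 1)/h² on a duct of length ``duct_length``
    (h = duct_length/(n−1)); the duct length sets how much travelling-wave
    phase accumulates between the stapes and a given place, hence the
    number of standing-wave nodes the box can hold.  The
    basal row is the one-sided difference (p₂ − p₁)·w_b/h² tying the basal
    pressure gradient to the middle-ear acceleration; the apical row uses a
    Dirichlet ghost (p = 0 beyond element n).  All physical constants are
    folded into the single pressure parameter ``a``.
    """
    n = config.n
    h = config.duct_length / (n - 1)
    s = 1.0 / (h * h)
    F = np.zeros((n, n))
    for i in range(1, n - 1):
        F[i, i - 1] = s
        F[i, i] = -2.0 * s
        F[i, i + 1] = s
    F[0, 0] = -config.basal_weight * s
    F[0, 1] = config.basal_weight * s
    F[n - 1, n - 2] = s
    F[n - 1, n - 1] = -2.0 * s        # Dirichlet ghost beyond the apex
    try:
        F_inv = np.linalg.inv(F)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("fluid matrix singular: bad boundary rows") from exc
    return FluidMatrix(F, F_inv, h)


def fluid_pressure(fm: FluidMatrix, a: float, xddot: np.ndarray) -> np.ndarray:
    """Exact linear solve p = a·F⁻¹·ẍ (bitwise deterministic)."""
    xddot = np.asarray(xddot, dtype=float)
    if xddot.shape != (fm.n,):
        raise ValueError(f"need {fm.n} accelerations, got {xddot.shape}")
    if not np.all(np.isfinite(xddot)):
        raise ValueError("non-finite accelerations")
    return a * (fm.F_inv @ xddot)


# ---------------------------------------------------------------------------
# element specifications


@dataclass(frozen=True)
class VdPElementSpec:
    """Per-element damping-profile parameters for elements 2…n.

    Defaults reproduce the single-active-oscillator configuration: β_j = 20
    everywhere, α_j = −0.1 (passive) except α₂₀₀ = +0.1 (active).
    """

    alpha_j: np.ndarray
    beta_j: np.ndarray

    def __post_init__(self) -> None:
        al = np.asarray(self.alpha_j, dtype=float)
        be = np.asarray(self.beta_j, dtype=float)
        object.__setattr__(self, "alpha_j", al)
        object.__setattr__(self, "beta_j", be)
        if al.shape != be.shape or al.ndim != 1:
            raise ValueError("alpha_j and beta_j must be 1-D of equal length")

    @classmethod
    def uniform(
        cls, n: int, alpha: float = -0.1, beta: float = 20.0,
        active_element: int | None = 200, active_alpha: float = 0.1,
    ) -> "VdPElementSpec":
        al = np.full(n - 1, alpha)
        be = np.full(n - 1, beta)
        if active_element is not None:
            al[active_element - 2] = active_alpha
        return cls(al, be)


def saturation_gamma(rel_x, rel_v, alpha_sat: float, beta_sat: float):
    """Saturating feedback gain γ[α, β] = 1 − tanh((α/α_sat)² + (β/β_sat)²).

    Equals 1 at rest, decreases monotonically with |relative displacement|
    and |relative velocity|, and tends to 0 for large excursions — the
    compressive nonlinearity of the cochlear amplifier.
    """
    return 1.0 - np.tanh(
        np.square(np.asarray(rel_x) / alpha_sat)
        + np.square(np.asarray(rel_v) / beta_sat)
    )


@dataclass(frozen=True)
class NKElementSpec:
    """Two-mass element family: BM mass m1, TM mass m2, four spring/damper
    pairs per element, per-element feedback gain scale γ₀ and the
    saturation scales of the nonlinearity.

    Arrays hold elements 2…n (length n−1).  With γ₀ = 0 every element is a
    passive two-mass resonator.
    """

    m1: float
    m2: float
    k1: np.ndarray
    c1: np.ndarray
    k2: np.ndarray
    c2: np.ndarray
    k3: np.ndarray
    c3: np.ndarray
    k4: np.ndarray
    c4: np.ndarray
    gamma0: np.ndarray
    g: float = 1.0
    alpha_sat: float = 2e-5
    beta_sat: float = 0.1

    def __post_init__(self) -> None:
        for name in ("k1", "c1", "k2", "c2", "k3", "c3", "k4", "c4",
                     "gamma0"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("masses must be > 0")
        if self.alpha_sat <= 0 or self.beta_sat <= 0:
            raise ValueError("saturation scales must be > 0")
        shape = self.k1.shape
        for name in ("c1", "k2", "c2", "k3", "c3", "k4", "c4", "gamma0"):
            if getattr(self, name).shape != shape:
                raise ValueError("all per-element arrays must share a length")

    def with_gamma0(self, gamma0: np.ndarray) -> "NKElementSpec":
        return dataclasses.replace(self, gamma0=np.asarray(gamma0, float))


def nk_place_maps(
    n: int = 351,
    f_base: float = 10_000.0,
    f_apex: float = 140.0,
    m1: float = 0.044,
    m2: float = 0.0073,
    gamma0: float | np.ndarray = 0.5,
    zeta1: float = 0.22,
    zeta2: float = 0.14,
    zeta3: float = 0.04,
    zeta4: float = 0.1,
    base_taper_end: float = 0.25,
    base_taper_depth: float = 0.5,
    apex_taper_start: float = 0.9,
    apex_taper_depth: float = 0.75,
    r2: float = 0.5,
    lam3: float = 0.12,
    lam4: float = 0.35,
    alpha_sat: float = 2e-5,
    beta_sat: float = 0.1,
) -> NKElementSpec:
    """Smooth exponential stiffness/damping place-maps for two-mass elements.

    Every spring and damper scales with the local place frequency so that
    the passive (γ₀ = 0) element resonance at element j tracks the
    place-frequency map: k1 = m1ω², c1 = 2ζ₁m1ω for the BM branch; the TM
    branch resonates at r₂·ω (detuning the second mass below the local
    characteristic frequency is what lets a stable element amplify
    travelling waves); k3, c3 couple the masses; k4, c4 set the scale of
    the active feedback force, so γ₀·c4 undamps the BM.  The shape
    constants are repository defaults chosen so that an isolated element is
    stable up to γ₀ ≈ 1 and strongly unstable at γ₀ = 2.
    """
    om = build_frequency_map(n, f_base, f_apex)  # rad per time unit
    u = np.arange(n - 1) / (n - 2)               # 0 at base, 1 at apex
    # feedback-force gain profile: flat through the mid-region, rolled off
    # toward both ends.  Without the rolls the stapes and pressure-release
    # boundaries support edge modes that destabilise before any physical
    # standing-wave mode between an irregularity and the stapes.
    def _smoothstep(t):
        t = np.clip(t, 0.0, 1.0)
        return t * t * t * (t * (6.0 * t - 15.0) + 10.0)

    base = _smoothstep(u / base_taper_end)
    apex = _smoothstep((1.0 - u) / (1.0 - apex_taper_start))
    profile = (1.0 - base_taper_depth * (1.0 - base)) \
        * (1.0 - apex_taper_depth * (1.0 - apex))
    zeta4_j = zeta4 * profile
    lam4_j = lam4 * profile
    spec = NKElementSpec(
        m1=m1,
        m2=m2,
        k1=m1 * om ** 2,
        c1=2.0 * zeta1 * m1 * om,
        k2=m2 * (r2 * om) ** 2,
        c2=2.0 * zeta2 * m2 * (r2 * om),
        k3=lam3 * m2 * om ** 2,
        c3=2.0 * zeta3 * m2 * om,
        k4=lam4_j * m1 * om ** 2,
        c4=2.0 * zeta4_j * m1 * om,
        gamma0=np.full(n - 1, gamma0) if np.isscalar(gamma0) else gamma0,
        alpha_sat=alpha_sat,
        beta_sat=beta_sat,
    )
    return spec


def apply_irregularity(spec, element: int, delta: float, n: int | None = None):
    """Copy of the spec with a single-element offset (a pure function).

    For a two-mass spec the offset goes on γ₀; for a Van der Pol spec it
    goes on α.  ``element`` uses 1-based numbering (2…n).
    """
    size = spec.gamma0.size if isinstance(spec, NKElementSpec) \
        else spec.alpha_j.size
    n_total = size + 1
    if not 2 <= element <= n_total:
        raise ValueError(f"element {element} outside 2..{n_total}")
    idx = element - 2
    if isinstance(spec, NKElementSpec):
        g = spec.gamma0.copy()
        g[idx] += delta
        return dataclasses.replace(spec, gamma0=g)
    if isinstance(spec, VdPElementSpec):
        al = spec.alpha_j.copy()
        al[idx] += delta
        return dataclasses.replace(spec, alpha_j=al)
    raise TypeError(f"unsupported spec type {type(spec)!r}")


# ---------------------------------------------------------------------------
# history container


@dataclass
class BoxHistory:
    """Stored output of a box run.

    Full-resolution time axis ``t`` carries the middle-ear displacement
    ``x1`` and the monitored element's displacement ``x_monitor``; the
    decimated axis ``t_dec`` carries the full state (x, v, and y, vy for
    two-mass runs) plus the pressure field, so the pressure identity
    p = a·F⁻¹·ẍ can be re-verified sample by sample.
    """

    t: np.ndarray
    x1: np.ndarray
    x_monitor: np.ndarray
    monitor_element: int
    t_dec: np.ndarray
    x_dec: np.ndarray
    v_dec: np.ndarray
    p_dec: np.ndarray
    unit: str
    meta: dict = field(default_factory=dict)
    y_dec: np.ndarray | None = None
    vy_dec: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.x_dec.shape[1]

    def x1_trajectory(self) -> Trajectory:
        return Trajectory(self.t, {"x": self.x1}, unit=self.unit,
                          meta=dict(self.meta))

    def monitor_trajectory(self) -> Trajectory:
        return Trajectory(self.t, {"x": self.x_monitor}, unit=self.unit,
                          meta=dict(self.meta))


# ---------------------------------------------------------------------------
# Van der Pol box


def _vdp_local_force(x, v, cfg_consts, out):
    d1om1, om1sq, om_e, om2_e, al_e, be_e = cfg_consts
    out[0] = -d1om1 * v[0] - om1sq * x[0]
    xe = x[1:]
    out[1:] = -om_e * (-al_e + be_e * xe * xe) * v[1:] - om2_e * xe
    return out


def simulate_vdp_box(
    config: BoxConfig,
    spec: VdPElementSpec | None = None,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    decimate: int = 10,
    monitor_element: int | None = None,
    guard_limit: float = 1e6,
) -> BoxHistory:
    """Co-integrate the n-element Van der Pol box.

    Default initial state is all zeros except ẋ₂₀₀(0) = 0.01 (a small
    velocity kick at the active element).  The implicit pressure coupling is solved exactly each stage via
    the cached operator S = (I − a·K·F⁻¹)⁻¹.
    """
    n = config.n
    if spec is None:
        spec = VdPElementSpec.uniform(n)
    if spec.alpha_j.size != n - 1:
        raise ValueError(f"spec arrays must have length n-1 = {n - 1}")
    om_e = build_frequency_map(n, config.f_base, config.f_apex)
    om2_e = om_e ** 2
    fm = build_fluid_matrix(config)
    K = np.full(n, config.kappa)
    K[0] = 1.0                      # middle ear takes p_1 directly
    S = np.linalg.inv(np.eye(n) - config.a * (K[:, None] * fm.F_inv))
    consts = (config.d1 * config.omega1, config.omega1 ** 2,
              om_e, om2_e, spec.alpha_j, spec.beta_j)

    grid = config.grid
    n_steps = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    if monitor_element is None:
        monitor_element = 200 if n >= 200 else n
    mon = monitor_element - 1
    if x0 is None:
        x0 = np.zeros(n)
    if v0 is None:
        # default initial state: everything quiescent except a small
        # velocity kick at the monitored (active) element
        v0 = np.zeros(n)
        v0[mon] = 0.01
    x = np.asarray(x0, dtype=float).copy()
    v = np.asarray(v0, dtype=float).copy()

    limit = guard_limit * max(1.0, float(np.max(np.abs(x))))
    t_full = grid.times()
    x1_rec = np.empty(n_steps + 1)
    mon_rec = np.empty(n_steps + 1)
    n_dec = n_steps // decimate + 1
    x_dec = np.empty((n_dec, n))
    v_dec = np.empty((n_dec, n))
    p_dec = np.empty((n_dec, n))
    t_dec = np.empty(n_dec)
    scratch = np.empty(n)

    def acc(x, v):
        return S @ _vdp_local_force(x, v, consts, scratch)

    idec = 0
    for i in range(n_steps + 1):
        if i % decimate == 0 and idec < n_dec:
            a_now = acc(x, v)
            x_dec[idec] = x
            v_dec[idec] = v
            p_dec[idec] = config.a * (fm.F_inv @ a_now)
            t_dec[idec] = t_full[i]
            idec += 1
        x1_rec[i] = x[0]
        mon_rec[i] = x[mon]
        if i == n_steps:
            break
        a1 = acc(x, v)
        x2 = x + half * v
        v2 = v + half * a1
        a2 = acc(x2, v2)
        x3 = x + half * v2
        v3 = v + half * a2
        a3 = acc(x3, v3)
        x4 = x + dt * v3
        v4 = v + dt * a3
        a4 = acc(x4, v4)
        x = x + dt / 6.0 * (v + 2.0 * (v2 + v3) + v4)
        v = v + dt / 6.0 * (a1 + 2.0 * (a2 + a3) + a4)
        peak = float(np.max(np.abs(x)))
        if not np.isfinite(peak) or peak > limit:
            j = int(np.argmax(np.abs(x))) + 1
            raise DivergenceError(
                f"vdp box element {j} diverged at step {i + 1} "
                f"(t = {t_full[i] + dt:g} {config.unit})",
                step=i + 1, time=float(t_full[i] + dt), element=j,
            )
    return BoxHistory(
        t=t_full, x1=x1_rec, x_monitor=mon_rec,
        monitor_element=monitor_element,
        t_dec=t_dec[:idec], x_dec=x_dec[:idec], v_dec=v_dec[:idec],
        p_dec=p_dec[:idec], unit=config.unit,
        meta={"variant": "vdp", "config": config, "spec": spec},
    )


# ---------------------------------------------------------------------------
# two-mass (BM + TM) box


def _nk_coeffs(spec: NKElementSpec, dx, dv):
    """State-dependent coefficient arrays a11..a14 (a21..a24 are constant).

    dx, dv are the relative displacement x−y and velocity ẋ−ẏ.  a14 pairs
    k4 with the feedback term, mirroring a13's c4.
    """
    gam = saturation_gamma(dx, dv, spec.alpha_sat, spec.beta_sat)
    gg = spec.gamma0 * gam
    a11 = spec.g * gg * spec.c4 - (spec.c1 + spec.c3)
    a12 = spec.g * gg * spec.k4 - (spec.k1 + spec.k3)
    a13 = spec.c3 - gg * spec.c4
    a14 = spec.k3 - gg * spec.k4
    return a11, a12, a13, a14


def simulate_nk_box(
    config: BoxConfig,
    spec: NKElementSpec,
    x0: np.ndarray | None = None,
    v0: np.ndarray | None = None,
    y0: np.ndarray | None = None,
    vy0: np.ndarray | None = None,
    kick: float = 1e-4,
    kick_element: int = 200,
    decimate: int = 10,
    monitor_element: int | None = None,
    guard_limit: float = 1e6,
) -> BoxHistory:
    """Co-integrate the box of two-mass elements.

    Default initial state is all zeros except ẏ at ``kick_element``
    (``kick`` = 10⁻⁴ for the single-active-element run; 0.1 for the
    irregularity run).  Coefficients a11…a14 are refreshed every stage from
    the instantaneous relative motion through the saturating gain; the
    implicit fluid coupling uses the cached S = (I − a·M⁻¹·F⁻¹)⁻¹.
    """
    n = config.n
    if spec.k1.size != n - 1:
        raise ValueError(f"spec arrays must have length n-1 = {n - 1}")
    fm = build_fluid_matrix(config)
    minv = np.full(n, 1.0 / spec.m1)
    minv[0] = 1.0                       # middle-ear unit mass
    S = np.linalg.inv(np.eye(n) - config.a * (minv[:, None] * fm.F_inv))
    SM = S * minv[None, :]              # S @ diag(minv)

    grid = config.grid
    n_steps = grid.n_steps
    dt = grid.dt
    half = dt / 2.0
    x = np.zeros(n) if x0 is None else np.asarray(x0, float).copy()
    v = np.zeros(n) if v0 is None else np.asarray(v0, float).copy()
    y = np.zeros(n - 1) if y0 is None else np.asarray(y0, float).copy()
    vy = np.zeros(n - 1) if vy0 is None else np.asarray(vy0, float).copy()
    if y0 is None and vy0 is None and x0 is None and v0 is None:
        vy[kick_element - 2] = kick
    if monitor_element is None:
        monitor_element = kick_element if n >= kick_element else n
    mon = monitor_element - 1

    d1om1 = config.d1 * config.omega1
    om1sq = config.omega1 ** 2
    a21, a22 = spec.c3, spec.k3
    a23, a24 = -(spec.c2 + spec.c3), -(spec.k2 + spec.k3)
    m2 = spec.m2

    limit = guard_limit * max(1.0, float(np.max(np.abs(x))), 1.0)
    t_full = grid.times()
    x1_rec = np.empty(n_steps + 1)
    mon_rec = np.empty(n_steps + 1)
    n_dec = n_steps // decimate + 1
    x_dec = np.empty((n_dec, n))
    v_dec = np.empty((n_dec, n))
    y_dec = np.empty((n_dec, n - 1))
    vy_dec = np.empty((n_dec, n - 1))
    p_dec = np.empty((n_dec, n))
    t_dec = np.empty(n_dec)

    def rates(x, v, y, vy):
        xe, ve = x[1:], v[1:]
        a11, a12, a13, a14 = _nk_coeffs(spec, xe - y, ve - vy)
        r = np.empty(n)
        r[0] = -d1om1 * v[0] - om1sq * x[0]
        r[1:] = a11 * ve + a12 * xe + a13 * vy + a14 * y
        accx = SM @ r
        accy = (a21 * ve + a22 * xe + a23 * vy + a24 * y) / m2
        return accx, accy

    idec = 0
    for i in range(n_steps + 1):
        if i % decimate == 0 and idec < n_dec:
            accx, _ = rates(x, v, y, vy)
            x_dec[idec] = x
            v_dec[idec] = v
            y_dec[idec] = y
            vy_dec[idec] = vy
            p_dec[idec] = config.a * (fm.F_inv @ accx)
            t_dec[idec] = t_full[i]
            idec += 1
        x1_rec[i] = x[0]
        mon_rec[i] = x[mon]
        if i == n_steps:
            break
        ax1, ay1 = rates(x, v, y, vy)
        x2, v2 = x + half * v, v + half * ax1
        y2, vy2 = y + half * vy, vy + half * ay1
        ax2, ay2 = rates(x2, v2, y2, vy2)
        x3, v3 = x + half * v2, v + half * ax2
        y3, vy3 = y + half * vy2, vy + half * ay2
        ax3, ay3 = rates(x3, v3, y3, vy3)
        x4, v4 = x + dt * v3, v + dt * ax3
        y4, vy4 = y + dt * vy3, vy + dt * ay3
        ax4, ay4 = rates(x4, v4, y4, vy4)
        x = x + dt / 6.0 * (v + 2.0 * (v2 + v3) + v4)
        v = v + dt / 6.0 * (ax1 + 2.0 * (ax2 + ax3) + ax4)
        y = y + dt / 6.0 * (vy + 2.0 * (vy2 + vy3) + vy4)
        vy = vy + dt / 6.0 * (ay1 + 2.0 * (ay2 + ay3) + ay4)
        peak = float(np.max(np.abs(x)))
        if not np.isfinite(peak) or peak > limit:
            j = int(np.argmax(np.abs(x))) + 1
            raise DivergenceError(
                f"two-mass box element {j} diverged at step {i + 1} "
                f"(t = {t_full[i] + dt:g} {config.unit})",
                step=i + 1, time=float(t_full[i] + dt), element=j,
            )
    return BoxHistory(
        t=t_full, x1=x1_rec, x_monitor=mon_rec,
        monitor_element=monitor_element,
        t_dec=t_dec[:idec], x_dec=x_dec[:idec], v_dec=v_dec[:idec],
        p_dec=p_dec[:idec], y_dec=y_dec[:idec], vy_dec=vy_dec[:idec],
        unit=config.unit,
        meta={"variant": "nk", "config": config, "spec": spec},
    )


# ---------------------------------------------------------------------------
# linear stability (small-amplitude growth rates)


def vdp_box_growth_rate(config: BoxConfig,
                        spec: VdPElementSpec | None = None) -> float:
    """Largest eigenvalue real part of the linearised Van der Pol box."""
    n = config.n
    if spec is None:
        spec = VdPElementSpec.uniform(n)
    om_e = build_frequency_map(n, config.f_base, config.f_apex)
    fm = build_fluid_matrix(config)
    K = np.full(n, config.kappa)
    K[0] = 1.0
    S = np.linalg.inv(np.eye(n) - config.a * (K[:, None] * fm.F_inv))
    dvv = np.empty(n)
    dvx = np.empty(n)
    dvv[0] = -config.d1 * config.omega1
    dvx[0] = -config.omega1 ** 2
    dvv[1:] = om_e * spec.alpha_j          # linearised damping −ω(−α)
    dvx[1:] = -om_e ** 2
    A = np.zeros((2 * n, 2 * n))
    A[:n, n:] = np.eye(n)
    A[n:, :n] = S * dvx[None, :]
    A[n:, n:] = S * dvv[None, :]
    return float(np.linalg.eigvals(A).real.max())


def nk_element_growth_rate(spec: NKElementSpec, element: int,
                           gamma0: float | None = None) -> float:
    """Largest eigenvalue real part of one isolated two-mass element.

    Small-amplitude limit (γ = 1).  ``gamma0`` overrides the stored value.
    """
    i = element - 2
    g0 = spec.gamma0[i] if gamma0 is None else gamma0
    c1, c3, c4 = spec.c1[i], spec.c3[i], spec.c4[i]
    k1, k3, k4 = spec.k1[i], spec.k3[i], spec.k4[i]
    c2, k2 = spec.c2[i], spec.k2[i]
    m1, m2, g = spec.m1, spec.m2, spec.g
    a11 = g * g0 * c4 - (c1 + c3)
    a12 = g * g0 * k4 - (k1 + k3)
    a13 = c3 - g0 * c4
    a14 = k3 - g0 * k4
    A = np.array([
        [0.0, 1.0, 0.0, 0.0],
        [a12 / m1, a11 / m1, a14 / m1, a13 / m1],
        [0.0, 0.0, 0.0, 1.0],
        [k3 / m2, c3 / m2, -(k2 + k3) / m2, -(c2 + c3) / m2],
    ])
    return float(np.linalg.eigvals(A).real.max())


def nk_box_growth_rate(config: BoxConfig, spec: NKElementSpec) -> float:
    """Largest eigenvalue real part of the full linearised two-mass box.

    The state is [x, ẋ, y, ẏ] with the fluid coupling folded in through S;
    this locates the collective instability without a time-domain run.
    """
    n = config.n
    fm = build_fluid_matrix(config)
    minv = np.full(n, 1.0 / spec.m1)
    minv[0] = 1.0
    S = np.linalg.inv(np.eye(n) - config.a * (minv[:, None] * fm.F_inv))
    SM = S * minv[None, :]
    g0 = spec.gamma0
    a11 = spec.g * g0 * spec.c4 - (spec.c1 + spec.c3)
    a12 = spec.g * g0 * spec.k4 - (spec.k1 + spec.k3)
    a13 = spec.c3 - g0 * spec.c4
    a14 = spec.k3 - g0 * spec.k4
    m2 = spec.m2
    ne = n - 1
    dim = 2 * n + 2 * ne
    A = np.zeros((dim, dim))
    ix, iv, iy, ivy = 0, n, 2 * n, 2 * n + ne
    A[ix:ix + n, iv:iv + n] = np.eye(n)
    # force vector r as linear map of state, then accx = SM @ r
    Rx = np.zeros((n, dim))
    Rx[0, ix] = -config.omega1 ** 2
    Rx[0, iv] = -config.d1 * config.omega1
    rows = np.arange(1, n)
    Rx[rows, ix + rows] = a12
    Rx[rows, iv + rows] = a11
    Rx[rows, iy + rows - 1] = a14
    Rx[rows, ivy + rows - 1] = a13
    A[iv:iv + n, :] = SM @ Rx
    A[iy:iy + ne, ivy:ivy + ne] = np.eye(ne)
    erows = np.arange(ne)
    A[ivy + erows, ix + 1 + erows] = spec.k3 / m2
    A[ivy + erows, iv + 1 + erows] = spec.c3 / m2
    A[ivy + erows, iy + erows] = -(spec.k2 + spec.k3) / m2
    A[ivy + erows, ivy + erows] = -(spec.c2 + spec.c3) / m2
    return float(np.linalg.eigvals(A).real.max())


# ---------------------------------------------------------------------------
# readouts


def standing_wave_profile(
    history: BoxHistory,
    window: tuple[float, float],
    node_fraction: float = 0.5,
    flank: int = 15,
) -> tuple[np.ndarray, list[int]]:
    """Per-element maximum |x_j| over the window, plus standing-wave nodes.

    Nodes are sharp interior local minima of the profile between element 1
    and the monitored (active/irregular) element: a local minimum counts
    when its value is below ``node_fraction`` of both flanking local maxima
    (searched within ``flank`` elements), which keeps the criterion
    scale-free on a profile that rises steeply toward the source.  Returns
    (profile, node elements) with the profile indexed 0-based (entry j−1
    for element j).
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    mask = (history.t_dec >= lo) & (history.t_dec <= hi)
    if mask.sum() < 4:
        raise ValueError("window holds too few stored samples")
    seg = history.x_dec[mask]
    profile = np.max(np.abs(seg), axis=0)
    mon = history.monitor_element - 1
    span = profile[: mon + 1]
    if np.all(span == 0):
        return profile, []
    floor = 1e-3 * span.max()            # ignore numerical-noise minima
    nodes: list[int] = []
    for i in range(1, mon):
        if not (span[i] < span[i - 1] and span[i] < span[i + 1]):
            continue
        left = span[max(0, i - flank): i].max()
        right = span[i + 1: min(mon + 1, i + 1 + flank)].max()
        if min(left, right) > floor and span[i] < node_fraction * min(left,
                                                                      right):
            nodes.append(i + 1)          # back to 1-based element numbering
    return profile, nodes


def damping_sweep(
    config: BoxConfig,
    sweep_values: np.ndarray,
    variant: str = "vdp",
    base_spec=None,
    active_element: int = 200,
    active_value: float | None = None,
    window_fraction: float = 0.2,
    kick: float = 1e-4,
    decimate: int = 10,
) -> list[dict]:
    """Steady middle-ear amplitude versus the passive elements' (un)damping.

    For the Van der Pol box the swept parameter is the passive α_j (active
    element's α held at +0.1 unless overridden); for the two-mass box it is
    the passive γ₀ (active element's γ₀ held at 2.0).  Each sweep point runs
    a full simulation; unstable points are recorded as such, not aborted
    sweep-wide.  Returns one record per value with steady amplitude,
    sinusoidality and stability flags.
    """
    from .oscillators import steady_amplitude
    from .signals import sinusoidality

    results = []
    for val in np.asarray(sweep_values, dtype=float):
        n = config.n
        try:
            if variant == "vdp":
                av = 0.1 if active_value is None else active_value
                spec = VdPElementSpec.uniform(
                    n, alpha=val, active_element=active_element,
                    active_alpha=av,
                )
                hist = simulate_vdp_box(config, spec, decimate=decimate,
                                        monitor_element=active_element)
            elif variant == "nk":
                av = 2.0 if active_value is None else active_value
                spec = (base_spec if base_spec is not None
                        else nk_place_maps(n))
                g = np.full(n - 1, val)
                g[active_element - 2] = av
                spec = spec.with_gamma0(g)
                hist = simulate_nk_box(config, spec, kick=kick,
                                       kick_element=active_element,
                                       decimate=decimate,
                                       monitor_element=active_element)
            else:
                raise ValueError(f"unknown variant {variant!r}")
        except DivergenceError as exc:
            results.append({
                "value": float(val), "stable": False, "amplitude": np.nan,
                "sinusoidality": np.nan, "error": str(exc),
            })
            continue
        traj = hist.x1_trajectory()
        amp = steady_amplitude(traj, window_fraction)
        tail = traj.tail(window_fraction)
        try:
            sin_idx = sinusoidality(tail["x"], traj.dt)
        except Exception:
            sin_idx = np.nan
        results.append({
            "value": float(val), "stable": True, "amplitude": float(amp),
            "sinusoidality": float(sin_idx),
        })
    return results
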