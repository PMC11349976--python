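"""Seeded generators for the random inputs of the SOAE models.

Three families:

* noise drives — white Gaussian force series, and narrow-band noise
  (white noise through a zero-phase Butterworth band-pass of stated centre
  frequency and width) used to drive an oscillator the way internal
  physiological noise drives an emission generator;
* multiplicative Gaussian roughness — per-element parameter perturbation
  base·(1 + ε·N(0,1)), the standard recipe for cochlear irregularity;
* Ornstein–Uhlenbeck spatial fields — spatially correlated imperfection
  profiles ε(x) with mean-reversion speed θ and volatility σ, sampled with
  the exact Gaussian transition kernel so the statistics are
  grid-independent (stationary variance σ²/(2θ), lag-1 autocorrelation
  e^(−θΔx)).

Every generator is a pure function of (spec, seed): identical seeds give
bitwise-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .grid import SimGrid

__all__ = [
    "NoiseSpec",
    "RoughnessSpec",
    "generate_noise",
    "ou_field",
    "roughen",
]


@dataclass(frozen=True)
class NoiseSpec:
    """kind 'white' or 'narrowband'; bandwidth defaults to 0.5·f0."""

    kind: str
    f0: float = 1.0
    bandwidth: float | None = None
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("white", "narrowband"):
            raise ValueError("kind must be 'white' or 'narrowband'")
        if self.kind == "narrowband":
            bw = self.bandwidth if self.bandwidth is not None else 0.5 * self.f0
            if not 0 < bw < 2 * self.f0:
                raise ValueError("bandwidth must be in (0, 2·f0)")
            object.__setattr__(self, "bandwidth", bw)


@dataclass(frozen=True)
class RoughnessSpec:
    """mode 'gaussian_multiplicative' (scale epsilon) or 'ou_field'
    (mean reversion theta, volatility sigma)."""

    mode: str
    epsilon: float = 0.0
    theta: float = 0.008
    sigma: float = 1.0
    seed: int = 0
    clamp_floor: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("gaussian_multiplicative", "ou_field"):
            raise ValueError(
                "mode must be 'gaussian_multiplicative' or 'ou_field'"
            )
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.mode == "ou_field" and self.theta <= 0:
            raise ValueError("theta must be > 0 for an OU field")


def generate_noise(
    spec: NoiseSpec, grid: SimGrid, half_step: bool = False
) -> np.ndarray:
    """Sampled noise force series on the grid (deterministic per seed).

    With ``half_step=True`` the series is sampled at dt/2 so it can feed the
    RK4 drive hook of the oscillator integrators directly.
    """
    n = 2 * grid.n_steps + 1 if half_step else grid.n_samples
    dt = grid.dt / 2.0 if half_step else grid.dt
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(n)
    if spec.kind == "white" or spec.amplitude == 0.0:
        return spec.amplitude * white
    lo = spec.f0 - spec.bandwidth / 2.0
    hi = spec.f0 + spec.bandwidth / 2.0
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=1.0 / dt, output="sos")
    shaped = sps.sosfiltfilt(sos, white)
    # rescale so the stated amplitude is the RMS of the delivered force
    rms = shaped.std()
    if rms > 0:
        shaped = shaped / rms
    return spec.amplitude * shaped


def ou_field(
    theta: float, sigma: float, n: int, seed: int, dx: float = 1.0,
    x0: float | None = None,
) -> np.ndarray:
    """Ornstein–Uhlenbeck imperfection series by exact discretisation.

    x_{k+1} = x_k e^(−θΔx) + √(σ²(1 − e^(−2θΔx))/(2θ))·ξ_k, ξ ~ N(0,1).
    Zero-mean target; ``x0`` defaults to a draw from the stationary law so
    the whole series is stationary.  σ = 0 decays deterministically to 0.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    decay = np.exp(-theta * dx)
    stat_var = sigma * sigma / (2.0 * theta)
    step_sd = np.sqrt(stat_var * (1.0 - decay * decay))
    out = np.empty(n)
    if x0 is None:
        out[0] = rng.normal(0.0, np.sqrt(stat_var)) if sigma > 0 else 0.0
    else:
        out[0] = x0
    noise = rng.standard_normal(n - 1)
    for k in range(n - 1):
        out[k + 1] = out[k] * decay + step_sd * noise[k]
    return out


def roughen(base: np.ndarray, spec: RoughnessSpec) -> np.ndarray:
    """Perturb per-element base values with the chosen roughness model.

    gaussian_multiplicative: base·(1 + ε·N(0,1)) elementwise;
    ou_field: base·(1 + field) with the OU series of matching length.
    Pure function of (base, spec): the seed fixes the draw.  If perturbation
    flips the sign of any base value a warning is issued; an optional
    ``clamp_floor`` (fraction of |base|) clips the result away from zero.
    """
    base = np.asarray(base, dtype=float)
    if not np.all(np.isfinite(base)):
        raise ValueError("base values must be finite")
    if spec.mode == "gaussian_multiplicative":
        rng = np.random.default_rng(spec.seed)
        factor = 1.0 + spec.epsilon * rng.standard_normal(base.shape)
    else:
        field = ou_field(spec.theta, spec.sigma, base.size, spec.seed)
        factor = 1.0 + field.reshape(base.shape)
    out = base * factor
    flipped = np.sign(out) != np.sign(base)
    flipped &= base != 0
    if np.any(flipped):
        warnings.warn(
            f"roughness flipped the sign of {int(flipped.sum())} element(s)",
            RuntimeWarning, stacklevel=2,
        )
        if spec.clamp_floor is not None:
            floor = spec.clamp_floor * np.abs(base)
            out = np.where(flipped, np.sign(base) * floor, out)
    return out
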