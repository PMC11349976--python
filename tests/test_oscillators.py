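"""Single-oscillator models against closed-form and brute-force oracles."""

import numpy as np
import pytest

from oscillear.errors import DivergenceError
from oscillear.grid import SimGrid
from oscillear.oscillators import (
    AntiDampParams,
    DelayVdPParams,
    DuffingParams,
    HopfParams,
    VdPParams,
    damping_profile,
    delay_vdp_growth_rate,
    hopf_radius_exact,
    simulate_antidamp,
    simulate_delay_vdp,
    simulate_duffing,
    simulate_hopf,
    simulate_vdp,
    steady_amplitude,
)
from oscillear.signals import dominant_frequency

TWO_PI = 2.0 * np.pi


# ---------------------------------------------------------------------------
# damping profile


@pytest.mark.parametrize("alpha,beta,x,expected", [
    (1.0, 4.0, 0.0, -1.0),
    (1.0, 4.0, 0.5, 0.0),        # root at sqrt(alpha/beta)
    (-0.05, 1.0, 0.0, 0.05),
])
def test_damping_profile_values(alpha, beta, x, expected):
    p = VdPParams(TWO_PI, alpha, beta)
    assert damping_profile(p, x) == pytest.approx(expected, abs=1e-12)


def test_damping_profile_even_in_x():
    p = VdPParams(TWO_PI, 0.3, 7.0)
    x = np.linspace(-2, 2, 41)
    np.testing.assert_allclose(damping_profile(p, x),
                               damping_profile(p, -x))


# ---------------------------------------------------------------------------
# Van der Pol


def test_vdp_sustained_amplitude_near_one(unit_grid):
    """Strong undamping (alpha=1, beta=4): permanent oscillation whose
    amplitude slightly exceeds the weakly-nonlinear estimate 2*sqrt(a/b)=1."""
    traj = simulate_vdp(VdPParams(TWO_PI, 1.0, 4.0), 0.001, 0.0, unit_grid)
    amp = steady_amplitude(traj, 0.2)
    assert 1.0 < amp < 1.06


def test_vdp_weak_nonlinearity_amplitude_and_frequency():
    grid = SimGrid(0.0, 200.0, 0.002)
    traj = simulate_vdp(VdPParams(TWO_PI, 0.1, 20.0), 0.001, 0.0, grid)
    amp = steady_amplitude(traj, 0.2)
    assert amp == pytest.approx(2 * np.sqrt(0.1 / 20.0), rel=0.02)
    tail = traj.tail(0.25)
    f = dominant_frequency(tail["x"], grid.dt)
    assert f == pytest.approx(1.0, rel=0.01)


def test_vdp_positive_damping_decays(unit_grid):
    traj = simulate_vdp(VdPParams(TWO_PI, -0.05, 1.0), 1.0, 0.0, unit_grid)
    x = traj["x"]
    early = np.abs(x[: x.size // 4]).max()
    late = np.abs(x[-x.size // 4:]).max()
    assert late < 0.05 * early


def test_vdp_zero_initial_state_stays_zero(unit_grid):
    traj = simulate_vdp(VdPParams(TWO_PI, 1.0, 4.0), 0.0, 0.0, unit_grid)
    assert np.all(traj["x"] == 0.0)
    assert np.all(traj["xdot"] == 0.0)


@pytest.mark.parametrize("model", ["vdp", "duffing", "delay"])
def test_sign_symmetry(model, unit_grid):
    """All models are odd-symmetric: negating the initial state negates
    the whole trajectory."""
    if model == "vdp":
        run = lambda s: simulate_vdp(  # noqa: E731
            VdPParams(TWO_PI, 0.5, 2.0), s * 0.3, s * 0.1, unit_grid)
    elif model == "duffing":
        run = lambda s: simulate_duffing(  # noqa: E731
            DuffingParams(TWO_PI, 0.5, 2.0, 1.0, 0.5), s * 0.3, s * 0.1,
            unit_grid)
    else:
        run = lambda s: simulate_delay_vdp(  # noqa: E731
            DelayVdPParams(TWO_PI, -0.2, 3.0, 0.3, 0.25), s * 0.0, s * 0.2,
            unit_grid)
    plus, minus = run(1.0), run(-1.0)
    np.testing.assert_allclose(plus["x"], -minus["x"], atol=1e-12)


def test_grid_refinement_convergence():
    """Halving dt changes the steady amplitude by well under 0.1%."""
    for alpha, beta in [(1.0, 4.0), (0.1, 20.0)]:
        p = VdPParams(TWO_PI, alpha, beta)
        g1 = SimGrid(0.0, 60.0, 0.005)
        a1 = steady_amplitude(simulate_vdp(p, 0.001, 0.0, g1), 0.2)
        a2 = steady_amplitude(simulate_vdp(p, 0.001, 0.0, g1.refined()), 0.2)
        assert abs(a2 - a1) / a1 < 1e-3


def test_divergence_guard_reports_step():
    # a Duffing oscillator with negative stiffness runs away
    p = DuffingParams(TWO_PI, 0.0, 0.0, 1.0, -5.0)
    with pytest.raises(DivergenceError) as err:
        simulate_duffing(p, 2.0, 0.0, SimGrid(0.0, 20.0, 0.005))
    assert err.value.step is not None


# ---------------------------------------------------------------------------
# steady_amplitude


def test_steady_amplitude_pure_sine():
    t = np.arange(0, 30, 0.01)
    from oscillear.grid import Trajectory

    traj = Trajectory(t, {"x": 2.0 * np.sin(TWO_PI * t)})
    assert steady_amplitude(traj, 0.5) == pytest.approx(2.0, rel=1e-3)


def test_steady_amplitude_zero_signal():
    from oscillear.grid import Trajectory

    t = np.arange(0, 10, 0.01)
    traj = Trajectory(t, {"x": np.zeros_like(t)})
    assert steady_amplitude(traj, 0.5) == 0.0


def test_steady_amplitude_window_too_short():
    from oscillear.grid import Trajectory

    t = np.arange(0, 100, 0.01)
    traj = Trajectory(t, {"x": np.sin(2 * np.pi * 0.02 * t)})  # 50-unit period
    with pytest.raises(ValueError, match="window"):
        steady_amplitude(traj, 0.2)  # 20-unit window < one period


def test_steady_amplitude_decayed_run_near_zero(unit_grid):
    traj = simulate_vdp(VdPParams(TWO_PI, -0.5, 1.0), 1.0, 0.0, unit_grid)
    assert steady_amplitude(traj, 0.2) < 1e-6


# ---------------------------------------------------------------------------
# Duffing


def test_duffing_mu_zero_reduces_to_vdp(unit_grid):
    d = simulate_duffing(DuffingParams(TWO_PI, 0.5, 2.0, 1.0, 0.0),
                         0.3, 0.0, unit_grid)
    v = simulate_vdp(VdPParams(TWO_PI, 0.5, 2.0), 0.3, 0.0, unit_grid)
    np.testing.assert_allclose(d["x"], v["x"], atol=1e-10)


def test_duffing_hardening_frequency_grows_with_amplitude():
    """With mu > 0 and the printed (slowly decaying) configuration, the
    early large-amplitude window oscillates faster than the late one."""
    p = DuffingParams(TWO_PI, -0.05, 1.0, 1.0, 5.0)
    grid = SimGrid(0.0, 60.0, 0.002)
    traj = simulate_duffing(p, 1.0, 0.0, grid)
    x = traj["x"]
    n = x.size
    f_early = dominant_frequency(x[: n // 3], grid.dt)
    f_late = dominant_frequency(x[-n // 3:], grid.dt)
    assert f_early > f_late * 1.02


def test_duffing_small_amplitude_frequency_is_linear_resonance():
    p = DuffingParams(TWO_PI, -0.05, 1.0, 1.44, 5.0)   # omega*sqrt(lam)=1.2
    grid = SimGrid(0.0, 80.0, 0.002)
    traj = simulate_duffing(p, 1e-3, 0.0, grid)
    f = dominant_frequency(traj["x"][: traj.t.size // 2], grid.dt)
    assert f == pytest.approx(1.2, rel=0.01)


# ---------------------------------------------------------------------------
# delayed stiffness


def test_delay_zero_matches_boosted_stiffness(unit_grid):
    """Delta_t = 0 must reduce to a plain oscillator with stiffness
    omega^2(1+kappa): decaying oscillation near frequency sqrt(1.3)."""
    p = DelayVdPParams(TWO_PI, -0.2, 3.0, 0.3, 0.0)
    traj = simulate_delay_vdp(p, 0.0, 0.2, unit_grid)
    f = dominant_frequency(traj["x"][: traj.t.size // 2], unit_grid.dt)
    assert f == pytest.approx(np.sqrt(1.3), rel=0.01)
    # and the envelope decays (positive damping 0.2*omega)
    x = traj["x"]
    assert np.abs(x[-2000:]).max() < 1e-3 * np.abs(x[:2000]).max()


def test_delay_zero_history_stays_zero(unit_grid):
    p = DelayVdPParams(TWO_PI, -0.2, 3.0, 0.3, 0.5)
    traj = simulate_delay_vdp(p, 0.0, 0.0, unit_grid)
    assert np.all(traj["x"] == 0.0)


def test_delay_growth_rate_oracle_brackets_flip():
    """The quasipolynomial oracle finds both signs across delay values
    (delay can switch the oscillator between passive and active)."""
    rates = {lag: delay_vdp_growth_rate(
        DelayVdPParams(TWO_PI, -0.2, 3.0, 0.3, lag))
        for lag in (0.05, 0.3, 0.7)}
    assert rates[0.05] < 0 < rates[0.3]
    assert rates[0.7] < 0


def test_delay_simulation_matches_oracle_sign():
    for lag, expect_growth in [(0.1, False), (0.3, True), (0.6, False)]:
        p = DelayVdPParams(TWO_PI, -0.2, 3.0, 0.3, lag)
        traj = simulate_delay_vdp(p, 0.0, 0.001, SimGrid(0.0, 40.0, 0.005))
        x = traj["x"]
        grew = np.abs(x[-1000:]).max() > 3 * np.abs(x[1000:2000]).max()
        assert grew == expect_growth, f"lag={lag}"


def test_delay_shorter_than_dt_rejected():
    p = DelayVdPParams(TWO_PI, -0.2, 3.0, 0.3, 0.001)
    with pytest.raises(ValueError, match="delta_t"):
        simulate_delay_vdp(p, 0.0, 0.2, SimGrid(0.0, 10.0, 0.005))


# ---------------------------------------------------------------------------
# anti-damped oscillator


def test_antidamp_gamma_zero_is_damped_vdp(unit_grid):
    """gamma=0 removes the anti-damping term: damping omega(alpha+beta x^2)
    is positive everywhere and the motion decays like the matching
    Van der Pol run."""
    a = simulate_antidamp(AntiDampParams(TWO_PI, 0.1, 1.0, 0.0, 10.0),
                          1.0, 0.0, 0.5, unit_grid)
    v = simulate_vdp(VdPParams(TWO_PI, -0.1, 1.0), 1.0, 0.0, unit_grid)
    np.testing.assert_allclose(a["x"], v["x"], atol=1e-10)


def test_antidamp_frozen_average_equals_shifted_vdp():
    """With <x^2> effectively frozen at c (huge averaging time), the model
    is a Van der Pol with linear undamping gamma/c - alpha."""
    gamma, c, alpha = 0.2, 0.5, 0.1
    grid = SimGrid(0.0, 20.0, 0.002)
    a = simulate_antidamp(AntiDampParams(TWO_PI, alpha, 1.0, gamma, 1e9),
                          0.3, 0.0, c, grid)
    v = simulate_vdp(VdPParams(TWO_PI, gamma / c - alpha, 1.0), 0.3, 0.0,
                     grid)
    np.testing.assert_allclose(a["x"], v["x"], atol=1e-6)


def test_antidamp_reaches_steady_limit_cycle():
    """For gamma > 0 the solution approaches a steady limit cycle on which
    the cycle-averaged net damping vanishes."""
    p = AntiDampParams(TWO_PI, 0.05, 0.5, 0.05, 10.0)
    grid = SimGrid(0.0, 300.0, 0.005)
    traj = simulate_antidamp(p, 0.1, 0.0, 0.01, grid)
    x, v, m = traj["x"], traj["xdot"], traj["msq"]
    n = x.size
    seg = slice(n - 20000, n)
    # energy balance: <(alpha + beta x^2 - gamma/<x^2>) * xdot^2> ~ 0
    net = np.mean((p.alpha + p.beta * x[seg] ** 2
                   - p.gamma_ad / m[seg]) * v[seg] ** 2)
    scale = np.mean(np.abs(p.alpha) * v[seg] ** 2)
    assert abs(net) < 0.05 * scale
    # amplitude stable over the last quarter
    a1 = np.abs(x[-30000:-15000]).max()
    a2 = np.abs(x[-15000:]).max()
    assert a2 == pytest.approx(a1, rel=0.02)


def test_antidamp_rejects_zero_initial_average(unit_grid):
    p = AntiDampParams(TWO_PI, 0.1, 1.0, 0.1, 10.0)
    with pytest.raises(ValueError, match="msq0"):
        simulate_antidamp(p, 0.1, 0.0, 0.0, unit_grid)


def test_antidamp_floor_clamp_warns():
    p = AntiDampParams(TWO_PI, 0.5, 1.0, 0.0, 0.05)
    with pytest.warns(RuntimeWarning, match="floor"):
        simulate_antidamp(p, 1e-9, 0.0, 1e-10, SimGrid(0.0, 20.0, 0.005),
                          msq_floor=1e-12)


# ---------------------------------------------------------------------------
# Hopf


def test_hopf_supercritical_radius(fine_grid):
    traj = simulate_hopf(HopfParams(TWO_PI, 5.0), 0.1 + 0j, fine_grid)
    assert abs(traj["z"][-1]) == pytest.approx(np.sqrt(5.0), abs=1e-3)


def test_hopf_subcritical_decays(fine_grid):
    traj = simulate_hopf(HopfParams(TWO_PI, -0.2), 1.0 + 0j, fine_grid)
    mag = np.abs(traj["z"])
    assert mag[-1] < 0.05 * mag[0]
    assert np.all(np.diff(mag) <= 1e-12)     # spirals monotonically down


def test_hopf_zero_stays_zero(fine_grid):
    traj = simulate_hopf(HopfParams(TWO_PI, 5.0), 0.0 + 0j, fine_grid)
    assert np.all(traj["z"] == 0.0)


@pytest.mark.parametrize("epsilon,r0", [(5.0, 0.1), (-0.2, 1.0), (1.0, 2.0),
                                        (0.5, 0.01)])
def test_hopf_matches_radial_closed_form(epsilon, r0):
    """|z(t)| follows r(t) = sqrt(eps r0^2 e^{2 eps t} /
    (eps + r0^2(e^{2 eps t} - 1))) for the whole trajectory."""
    grid = SimGrid(0.0, 10.0, 0.001)
    traj = simulate_hopf(HopfParams(TWO_PI, epsilon), r0 + 0j, grid)
    exact = hopf_radius_exact(epsilon, r0, traj.t)
    np.testing.assert_allclose(np.abs(traj["z"]), exact, atol=1e-7)


def test_hopf_real_part_is_pure_sine_when_active():
    grid = SimGrid(0.0, 60.0, 0.002)
    traj = simulate_hopf(HopfParams(TWO_PI, 5.0), 0.1 + 0j, grid)
    from oscillear.signals import sinusoidality

    tail = traj.tail(0.5)
    assert sinusoidality(tail["z"].real, grid.dt) > 0.98


# ---------------------------------------------------------------------------
# passive-decay invariant across models


def test_passive_models_do_not_gain_energy(unit_grid):
    """With every energy-injecting term disabled, signal energy over
    successive cycles is non-increasing after the first cycle."""
    runs = {
        "vdp": simulate_vdp(VdPParams(TWO_PI, -0.3, 1.0), 1.0, 0.0,
                            unit_grid)["x"],
        "hopf": simulate_hopf(HopfParams(TWO_PI, -0.5), 1.0 + 0j,
                              unit_grid)["z"].real,
        "antidamp": simulate_antidamp(
            AntiDampParams(TWO_PI, 0.3, 1.0, 0.0, 10.0), 1.0, 0.0, 0.5,
            unit_grid)["x"],
    }
    per = int(round(1.0 / unit_grid.dt))
    for name, x in runs.items():
        m = x.size // per
        energy = (x[: m * per].reshape(m, per) ** 2).sum(axis=1)
        assert np.all(np.diff(energy[1:]) <= 1e-9 * energy[1]), name
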