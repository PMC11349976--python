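"""Fluid-filled-box cochlea: fluid operator, element mechanics, readouts.

Unit tests run on a reduced box (n = 61) so each simulation takes well
under a second; the full 351-element runs of the printed configurations
live in the acceptance suite.
"""

import dataclasses

import numpy as np
import pytest

from oscillear.box import (
    BoxConfig,
    NKElementSpec,
    VdPElementSpec,
    apply_irregularity,
    build_fluid_matrix,
    build_frequency_map,
    damping_sweep,
    fluid_pressure,
    natural_frequency,
    nk_box_growth_rate,
    nk_element_growth_rate,
    nk_place_maps,
    saturation_gamma,
    simulate_nk_box,
    simulate_vdp_box,
    standing_wave_profile,
    vdp_box_growth_rate,
)
from oscillear.errors import DivergenceError
from oscillear.grid import SimGrid
from oscillear.signals import classify_self_sustaining, dominant_frequency


def small_config(**kw):
    defaults = dict(n=61, grid=SimGrid(0.0, 60.0, 0.005))
    defaults.update(kw)
    return BoxConfig(**defaults)


def small_spec(n=61, active=40):
    return VdPElementSpec.uniform(n, active_element=active)


# ---------------------------------------------------------------------------
# place-frequency map


def test_frequency_map_endpoints_and_interior():
    om = build_frequency_map(351, 10.0, 0.14)
    assert om[0] == pytest.approx(2 * np.pi * 10.0)
    assert om[-1] == pytest.approx(2 * np.pi * 0.14)
    assert natural_frequency(351, 10.0, 0.14, 200) == pytest.approx(0.9,
                                                                    abs=0.02)
    assert np.all(np.diff(om) < 0)


def test_frequency_map_rejects_inverted_endpoints():
    with pytest.raises(ValueError):
        build_frequency_map(351, 0.14, 10.0)


# ---------------------------------------------------------------------------
# fluid operator


def test_fluid_pressure_zero_for_zero_acceleration():
    fm = build_fluid_matrix(small_config())
    p = fluid_pressure(fm, 0.2, np.zeros(61))
    assert np.all(p == 0.0)


def test_fluid_pressure_uniform_acceleration_is_quadratic():
    """Uniform acceleration solves the 1-D Poisson problem: the pressure
    profile is quadratic in position with curvature equal to a."""
    cfg = small_config()
    fm = build_fluid_matrix(cfg)
    p = fluid_pressure(fm, cfg.a, np.ones(cfg.n))
    pos = fm.h * np.arange(cfg.n)
    coef = np.polyfit(pos, p, 2)
    fit = np.polyval(coef, pos)
    assert np.max(np.abs(p - fit)) < 1e-8 * np.max(np.abs(p))
    assert 2 * coef[0] == pytest.approx(cfg.a, rel=1e-6)


def test_fluid_pressure_linear_in_a():
    cfg = small_config()
    fm = build_fluid_matrix(cfg)
    rng = np.random.default_rng(0)
    acc = rng.standard_normal(cfg.n)
    np.testing.assert_allclose(fluid_pressure(fm, 0.4, acc),
                               2.0 * fluid_pressure(fm, 0.2, acc))


def test_fluid_pressure_long_range_and_smooth():
    """A localized acceleration produces a pressure profile that spans the
    duct smoothly (long-range coupling, no oscillatory kernel)."""
    cfg = small_config()
    fm = build_fluid_matrix(cfg)
    acc = np.zeros(cfg.n)
    acc[30] = 1.0
    p = fluid_pressure(fm, cfg.a, acc)
    assert np.min(np.abs(p[:30])) > 0.1 * np.abs(p[30])
    # monotone from the flat basal plateau to the pressure-release apex
    assert np.all(np.diff(p) >= -1e-9 * np.abs(p).max())


def test_fluid_pressure_input_validation():
    fm = build_fluid_matrix(small_config())
    with pytest.raises(ValueError, match="non-finite"):
        fluid_pressure(fm, 0.2, np.full(61, np.nan))
    with pytest.raises(ValueError, match="accelerations"):
        fluid_pressure(fm, 0.2, np.zeros(10))


# ---------------------------------------------------------------------------
# saturating feedback gain


def test_saturation_gamma_reference_points():
    assert saturation_gamma(0.0, 0.0, 2e-5, 0.1) == 1.0
    assert saturation_gamma(2e-5, 0.0, 2e-5, 0.1) == pytest.approx(
        1.0 - np.tanh(1.0))
    assert saturation_gamma(2e-4, 1.0, 2e-5, 0.1) == pytest.approx(0.0,
                                                                   abs=1e-6)


def test_saturation_gamma_monotone_in_excursion():
    xs = np.linspace(0, 1e-4, 50)
    vals = saturation_gamma(xs, 0.0, 2e-5, 0.1)
    assert np.all(np.diff(vals) <= 0)
    assert vals[1] < vals[0]


# ---------------------------------------------------------------------------
# irregularity injection


def test_apply_irregularity_notch_values():
    spec = nk_place_maps(351, gamma0=0.65)
    notched = apply_irregularity(spec, 200, -0.15)
    assert notched.gamma0[198] == pytest.approx(0.5)
    assert spec.gamma0[198] == pytest.approx(0.65)     # pure function
    same = apply_irregularity(spec, 200, 0.0)
    np.testing.assert_array_equal(same.gamma0, spec.gamma0)


def test_apply_irregularity_vdp_and_range_check():
    spec = VdPElementSpec.uniform(61, active_element=None)
    out = apply_irregularity(spec, 40, 0.2)
    assert out.alpha_j[38] == pytest.approx(0.1)
    with pytest.raises(ValueError, match="outside"):
        apply_irregularity(spec, 1, 0.1)
    with pytest.raises(ValueError, match="outside"):
        apply_irregularity(spec, 62, 0.1)


# ---------------------------------------------------------------------------
# Van der Pol box dynamics


def test_passive_zero_init_stays_zero():
    cfg = small_config(grid=SimGrid(0.0, 10.0, 0.005))
    spec = VdPElementSpec.uniform(61, active_element=None)
    hist = simulate_vdp_box(cfg, spec, v0=np.zeros(61))
    assert np.all(hist.x1 == 0.0)
    assert np.all(hist.x_dec == 0.0)
    assert np.all(hist.p_dec == 0.0)


def test_passive_kicked_box_decays():
    """A fully passive box rings down: the fluid mass-loading slows the
    decay well below the in-vacuo damping rate, but the envelope shrinks
    steadily and the linearised spectrum is strictly stable."""
    cfg = small_config(grid=SimGrid(0.0, 150.0, 0.005))
    spec = VdPElementSpec.uniform(61, active_element=None)
    v0 = np.zeros(61)
    v0[39] = 0.01
    hist = simulate_vdp_box(cfg, spec, v0=v0, monitor_element=40)
    from oscillear.signals import bandpass

    # ringing at the kicked element's own frequency dies out quickly; the
    # residual is a near-marginal very-low-frequency fluid sloshing mode
    f40 = natural_frequency(61, 10.0, 0.14, 40)
    x = bandpass(hist.x_monitor, cfg.grid.dt, f40, 0.5 * f40)
    q = x.size // 4
    assert np.abs(x[-q:]).max() < 0.05 * np.abs(x[:q]).max()
    assert vdp_box_growth_rate(cfg, spec) < 0


def test_active_element_drives_middle_ear_at_its_frequency():
    """The SOAE frequency read at the middle ear equals the frequency at
    the active element (within 1%): something on the partition vibrates at
    the emission frequency."""
    cfg = small_config()
    hist = simulate_vdp_box(cfg, small_spec(), monitor_element=40)
    dt = cfg.grid.dt
    f1 = dominant_frequency(hist.x1[-6000:], dt)
    f_el = dominant_frequency(hist.x_monitor[-6000:], dt)
    assert f1 == pytest.approx(f_el, rel=0.01)
    assert vdp_box_growth_rate(cfg, small_spec()) > 0


def test_emission_frequency_tracks_active_place():
    """Moving the active element basally raises the emission frequency."""
    cfg = small_config()
    freqs = []
    for el in (30, 40, 50):
        hist = simulate_vdp_box(cfg, small_spec(active=el),
                                v0=None if el == 40 else _kick(61, el),
                                monitor_element=el)
        freqs.append(dominant_frequency(hist.x1[-6000:], cfg.grid.dt))
    assert freqs[0] > freqs[1] > freqs[2]


def _kick(n, el, size=0.01):
    v0 = np.zeros(n)
    v0[el - 1] = size
    return v0


def test_pressure_identity_holds_at_stored_samples():
    """Recomputing p = a F^-1 xdd from the stored state reproduces the
    stored pressures to round-off."""
    cfg = small_config()
    spec = small_spec()
    hist = simulate_vdp_box(cfg, spec, monitor_element=40)
    fm = build_fluid_matrix(cfg)
    om_e = build_frequency_map(cfg.n, cfg.f_base, cfg.f_apex)
    K = np.full(cfg.n, cfg.kappa)
    K[0] = 1.0
    S = np.linalg.inv(np.eye(cfg.n) - cfg.a * (K[:, None] * fm.F_inv))
    for i in (0, len(hist.t_dec) // 2, len(hist.t_dec) - 1):
        x, v = hist.x_dec[i], hist.v_dec[i]
        r = np.empty(cfg.n)
        r[0] = -cfg.d1 * cfg.omega1 * v[0] - cfg.omega1 ** 2 * x[0]
        r[1:] = -om_e * (-spec.alpha_j + spec.beta_j * x[1:] ** 2) * v[1:] \
            - om_e ** 2 * x[1:]
        p = fluid_pressure(fm, cfg.a, S @ r)
        np.testing.assert_allclose(p, hist.p_dec[i], atol=1e-14)


def test_divergence_guard_reports_element():
    cfg = small_config(grid=SimGrid(0.0, 30.0, 0.005))
    with pytest.raises(DivergenceError) as err:
        simulate_vdp_box(cfg, small_spec(), guard_limit=1e-3,
                         monitor_element=40)
    assert err.value.element is not None
    assert err.value.step is not None


def test_standing_wave_profile_degenerate_inputs():
    cfg = small_config(grid=SimGrid(0.0, 10.0, 0.005))
    spec = VdPElementSpec.uniform(61, active_element=None)
    hist = simulate_vdp_box(cfg, spec, v0=np.zeros(61))
    profile, nodes = standing_wave_profile(hist, (5.0, 10.0))
    assert np.all(profile == 0.0)
    assert nodes == []
    with pytest.raises(ValueError, match="window"):
        standing_wave_profile(hist, (10.0, 5.0))


def test_uncoupled_single_element_has_no_nodes():
    """With fluid coupling switched off (a -> 0) the active element rings
    alone: single-element peak, no interference nodes."""
    cfg = small_config(a=1e-12)
    hist = simulate_vdp_box(cfg, small_spec(), monitor_element=40)
    profile, nodes = standing_wave_profile(hist, (40.0, 60.0))
    assert nodes == []
    assert int(np.argmax(profile)) == 39


def test_vdp_box_grid_refinement():
    cfg = small_config(grid=SimGrid(0.0, 50.0, 0.005))
    from oscillear.oscillators import steady_amplitude

    a1 = steady_amplitude(
        simulate_vdp_box(cfg, small_spec(),
                         monitor_element=40).x1_trajectory(), 0.2)
    cfg2 = dataclasses.replace(cfg, grid=SimGrid(0.0, 50.0, 0.0025))
    a2 = steady_amplitude(
        simulate_vdp_box(cfg2, small_spec(),
                         monitor_element=40).x1_trajectory(), 0.2)
    assert abs(a2 - a1) / a1 < 0.01


def test_damping_sweep_baseline_consistency():
    """A sweep of one value equal to the baseline gives the baseline run."""
    cfg = small_config(grid=SimGrid(0.0, 50.0, 0.005))
    res = damping_sweep(cfg, [-0.1], variant="vdp", active_element=40)
    hist = simulate_vdp_box(cfg, small_spec(), monitor_element=40)
    from oscillear.oscillators import steady_amplitude

    assert res[0]["amplitude"] == pytest.approx(
        steady_amplitude(hist.x1_trajectory(), 0.2), rel=1e-12)
    assert res[0]["stable"]


# ---------------------------------------------------------------------------
# two-mass element family


def test_nk_place_maps_shapes_and_positivity():
    spec = nk_place_maps(61)
    for name in ("k1", "c1", "k2", "c2", "k3", "c3", "k4", "c4"):
        arr = getattr(spec, name)
        assert arr.shape == (60,)
        assert np.all(arr > 0)


def test_nk_passive_resonance_tracks_place_map():
    """With gamma0 = 0 the element's driven BM response peaks near the
    place-map frequency."""
    n = 61
    spec = nk_place_maps(n, f_base=10.0, f_apex=0.14)
    om = build_frequency_map(n, 10.0, 0.14)
    for el in (10, 30, 50):
        i = el - 2
        m1, m2 = spec.m1, spec.m2
        k13 = spec.k1[i] + spec.k3[i]
        c13 = spec.c1[i] + spec.c3[i]
        w_scan = om[i] * np.linspace(0.5, 1.5, 301)
        s = 1j * w_scan
        H_tm = (spec.c3[i] * s + spec.k3[i]) / (
            m2 * s ** 2 + (spec.c2[i] + spec.c3[i]) * s
            + spec.k2[i] + spec.k3[i])
        D = m1 * s ** 2 + c13 * s + k13 \
            - (spec.c3[i] * s + spec.k3[i]) * H_tm
        peak = w_scan[int(np.argmax(1.0 / np.abs(D)))]
        assert peak == pytest.approx(om[i], rel=0.15)


def test_nk_element_stability_vs_gamma0():
    """gamma0 = 0 (and moderate gamma0) leaves every element passive; the
    single-active-element value 2.0 destabilises the mid-array element it
    is applied to."""
    spec = nk_place_maps(351)
    for el in (2, 100, 200, 350):
        assert nk_element_growth_rate(spec, el, 0.0) < 0
        assert nk_element_growth_rate(spec, el, 1.0) < 0
    assert nk_element_growth_rate(spec, 200, 2.0) > 0


def test_nk_divergence_guard_reports_cleanly():
    n = 61
    spec = nk_place_maps(n, f_base=10.0, f_apex=0.14)
    cfg = small_config(omega1=2 * np.pi, f_base=10.0, f_apex=0.14,
                       grid=SimGrid(0.0, 30.0, 0.005))
    with pytest.raises(DivergenceError) as err:
        simulate_nk_box(cfg, spec, kick=1e-4, kick_element=40,
                        guard_limit=1e-10)
    assert err.value.element is not None
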