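"""Preset loading and runnable pipelines behind the command-line interface.

Every command resolves its inputs to a flat ``params`` dict, executes
through :func:`dispatch`, and writes outputs plus a manifest.  Re-running
``dispatch`` with the same params reproduces every output bitwise, which is
what the manifest machinery verifies.
"""

from __future__ import annotations

import dataclasses
import importlib.resources as resources
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import box as boxmod
from . import chains, oscillators, pairs, signals, stochastic
from .grid import SimGrid, Trajectory

__all__ = [
    "load_preset",
    "dispatch",
    "run_osc",
    "run_pair",
    "run_lizard",
    "run_box",
    "run_noise",
    "run_roughness",
    "run_fig2",
    "box_setup",
]


def load_preset(name: str) -> dict:
    """Load a named preset YAML shipped with the package."""
    ref = resources.files("oscillear") / "presets" / f"{name}.yaml"
    if not ref.is_file():
        raise ValueError(f"unknown preset {name!r}")
    return yaml.safe_load(ref.read_text())


def _write_csv(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format="%.17g")


def _traj_frame(traj: Trajectory) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"t": traj.t}
    for name, arr in traj.channels.items():
        if arr.ndim == 1:
            if np.iscomplexobj(arr):
                cols[f"re_{name}"] = arr.real
                cols[f"im_{name}"] = arr.imag
            else:
                cols[name] = arr
        else:
            for j in range(arr.shape[1]):
                col = arr[:, j]
                if np.iscomplexobj(col):
                    cols[f"re_{name}{j + 1}"] = col.real
                    cols[f"im_{name}{j + 1}"] = col.imag
                else:
                    cols[f"{name}{j + 1}"] = col
    return pd.DataFrame(cols)


def _summary_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=float) + "\n")


# ---------------------------------------------------------------------------
# single oscillators


def run_osc(params: dict) -> list[str]:
    model = params["model"]
    grid = SimGrid(params.get("t_start", 0.0), params["t_end"], params["dt"])
    p = params.get("params", {})
    x0 = params.get("x0", 0.0)
    v0 = params.get("v0", 0.0)
    drive = None
    if params.get("probe_freq") is not None:
        f_p = params["probe_freq"]
        a_p = params.get("probe_amplitude", 0.0)
        import math

        drive = lambda t: a_p * math.sin(2 * math.pi * f_p * t)  # noqa: E731
    if model == "vdp":
        traj = oscillators.simulate_vdp(
            oscillators.VdPParams(p["omega"], p["alpha"], p["beta"]),
            x0, v0, grid, drive=drive)
    elif model == "duffing":
        traj = oscillators.simulate_duffing(
            oscillators.DuffingParams(p["omega"], p["alpha"], p["beta"],
                                      p["lam"], p["mu"]),
            x0, v0, grid, drive=drive)
    elif model == "delay-vdp":
        traj = oscillators.simulate_delay_vdp(
            oscillators.DelayVdPParams(p["omega"], p["alpha"], p["beta"],
                                       p["kappa_d"], p["delta_t"]),
            x0, v0, grid, drive=drive)
    elif model == "antidamp":
        traj = oscillators.simulate_antidamp(
            oscillators.AntiDampParams(p["omega"], p["alpha"], p["beta"],
                                       p["gamma_ad"], p["tau_avg"]),
            x0, v0, params.get("msq0", 1e-3), grid, drive=drive)
    elif model == "hopf":
        traj = oscillators.simulate_hopf(
            oscillators.HopfParams(p["omega0"], p["epsilon"]),
            complex(x0, v0), grid, drive=drive)
    else:
        raise ValueError(f"unknown model {model!r}")
    outputs = []
    if params.get("out"):
        _write_csv(params["out"], _traj_frame(traj))
        outputs.append(params["out"])
    if params.get("summary"):
        s = signals.summarise(traj,
                              probe_frequency=params.get("probe_freq"))
        _summary_json(params["summary"], {
            "model": model,
            "params": p,
            "steady_amplitude": s.steady_amplitude,
            "dominant_frequency_hz": s.dominant_frequency,
            "self_sustaining": s.self_sustaining,
            "classification": s.classification,
            "sinusoidality": s.sinusoidality,
            "entrainment": s.entrainment,
        })
        outputs.append(params["summary"])
    return outputs


# ---------------------------------------------------------------------------
# coupled pair


def run_pair(params: dict) -> list[str]:
    preset = load_preset("pair")
    merged = {**preset, **{k: v for k, v in params.items() if v is not None}}
    c12 = merged.get("c12", merged.get("c"))
    c21 = merged.get("c21", merged.get("c"))
    hp = pairs.HopfPairParams(
        f=merged["f"], alpha_bm=merged["alpha_bm"],
        alpha_oc=merged["alpha_oc"], beta_nl=merged["beta"],
        c12=c12, c21=c21,
    )
    grid = SimGrid(0.0, merged["t_end"], merged["dt"])
    zb0 = complex(*merged["z_bm0"]) if isinstance(merged["z_bm0"], list) \
        else complex(merged["z_bm0"])
    zo0 = complex(*merged["z_oc0"]) if isinstance(merged["z_oc0"], list) \
        else complex(merged["z_oc0"])
    traj = pairs.simulate_pair(hp, zb0, zo0, grid)
    outputs = []
    if params.get("out"):
        _write_csv(params["out"], _traj_frame(traj))
        outputs.append(params["out"])
    if params.get("summary"):
        label, slope = pairs.classify_pair_run(traj)
        f_bm = signals.dominant_frequency(
            traj["z_bm"].real[traj.t.size // 2:], traj.dt)
        _summary_json(params["summary"], {
            "c12": c12, "c21": c21,
            "threshold_c": pairs.pair_threshold(hp),
            "classification": label,
            "envelope_slope": slope,
            "dominant_frequency": f_bm,
        })
        outputs.append(params["summary"])
    return outputs


# ---------------------------------------------------------------------------
# lizard-ear chains


def _freq_map(kind_spec: str, n: int) -> np.ndarray:
    kind, f1, f2 = kind_spec.split(":")
    f1, f2 = float(f1), float(f2)
    if kind == "lin":
        return np.linspace(f1, f2, n)
    if kind == "geom":
        return f1 * (f2 / f1) ** (np.arange(n) / (n - 1))
    raise ValueError(f"unknown frequency map {kind!r}")


def run_lizard(params: dict) -> list[str]:
    n = params["n"]
    freqs = _freq_map(params.get("freq_map", "lin:1.0:2.0"), n)
    grid = SimGrid(0.0, params["t_end"], params["dt"])
    rng = np.random.default_rng(params.get("seed", 0))
    if params.get("chain", "hopf") == "hopf":
        cp = chains.HopfChainParams(
            omega_j=2 * np.pi * freqs,
            epsilon_j=np.full(n, params.get("eps", 1.0)),
            B=params.get("B", 1.0),
            dR=params.get("dr", 0.0), dI=params.get("di", 0.0),
        )
        z0 = 0.01 * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
        traj = chains.simulate_hopf_chain(cp, z0, grid)
        channel = "z"
    else:
        cp = chains.VdPChainParams(
            mu_n=np.full(n, params.get("mu", 1.0)),
            alpha_n=np.full(n, params.get("alpha", 1.0)),
            f_n=freqs,
            gamma_el=params.get("gamma_el", 0.0),
            gamma_vis=params.get("gamma_vis", 0.0),
        )
        x0 = 0.01 * rng.standard_normal(n)
        y0 = 0.01 * rng.standard_normal(n)
        traj = chains.simulate_vdp_chain(cp, x0, y0, grid)
        channel = "x"
    outputs = []
    if params.get("out"):
        _write_csv(params["out"], _traj_frame(traj))
        outputs.append(params["out"])
    if params.get("plateaus"):
        rep = chains.detect_plateaus(traj, params.get("rel_tol", 0.01),
                                     channel=channel)
        _summary_json(params["plateaus"], {
            "frequencies": [None if not np.isfinite(f) else float(f)
                            for f in rep.frequencies],
            "plateaus": [
                {"start": s + 1, "end": e + 1, "frequency": f}
                for s, e, f in rep.plateaus
            ],
            "plateau_count": rep.plateau_count,
            "silent_units": [j + 1 for j in rep.silent_units],
        })
        outputs.append(params["plateaus"])
    return outputs


# ---------------------------------------------------------------------------
# fluid-box presets


def box_setup(preset: dict):
    """Build (BoxConfig, element spec, kick info) from a preset dict."""
    variant = preset["variant"]
    n = preset["n"]
    grid = SimGrid(0.0, preset["t_end"], preset["dt"])
    if variant == "vdp":
        cfg = boxmod.BoxConfig(
            n=n, a=preset["a"], kappa=preset.get("kappa", 1.0),
            d1=preset["d1"],
            omega1=2 * np.pi * preset["f1_khz"],
            f_base=preset["f_base"], f_apex=preset["f_apex"],
            grid=grid, unit=preset.get("unit", "ms"),
            duct_length=preset.get("duct_length", 100.0),
        )
        spec = boxmod.VdPElementSpec.uniform(
            n, alpha=preset["alpha"], beta=preset["beta"],
            active_element=preset.get("active_element"),
            active_alpha=preset.get("active_alpha", 0.1),
        )
        return cfg, spec, {"kick": preset.get("kick", 0.01),
                           "kick_element": preset.get("active_element", 200)}
    if variant == "nk":
        cfg = boxmod.BoxConfig(
            n=n, a=preset["a"], d1=preset["d1"],
            omega1=2 * np.pi * preset["f1_hz"],
            f_base=preset["f_base"], f_apex=preset["f_apex"],
            grid=grid, unit=preset.get("unit", "s"),
            duct_length=preset.get("duct_length", 100.0),
        )
        spec = boxmod.nk_place_maps(
            n, f_base=preset["f_base"], f_apex=preset["f_apex"],
            m1=preset["m1"], m2=preset["m2"],
            gamma0=preset["gamma0"],
            alpha_sat=preset["alpha_sat"], beta_sat=preset["beta_sat"],
        )
        if preset.get("active_element") is not None:
            g = spec.gamma0.copy()
            g[preset["active_element"] - 2] = preset["active_gamma0"]
            spec = spec.with_gamma0(g)
            kick_el = preset["active_element"]
        elif preset.get("notch_element") is not None:
            spec = boxmod.apply_irregularity(
                spec, preset["notch_element"], preset["notch_delta"])
            kick_el = preset["notch_element"]
        else:
            kick_el = 200
        return cfg, spec, {"kick": preset.get("kick", 1e-4),
                           "kick_element": kick_el}
    raise ValueError(f"unknown box variant {variant!r}")


def run_box(params: dict) -> list[str]:
    preset = load_preset(params["preset"])
    for key, val in params.get("overrides", {}).items():
        if key not in preset:
            raise ValueError(f"unknown preset key {key!r}")
        preset[key] = type(preset[key])(val) if preset[key] is not None \
            else val
    if params.get("t_end"):
        preset["t_end"] = params["t_end"]
    if params.get("dt"):
        preset["dt"] = params["dt"]
    cfg, spec, kick = box_setup(preset)
    if preset["variant"] == "vdp":
        v0 = np.zeros(cfg.n)
        v0[kick["kick_element"] - 1] = kick["kick"]
        hist = boxmod.simulate_vdp_box(
            cfg, spec, v0=v0, decimate=preset.get("decimate", 10),
            monitor_element=kick["kick_element"])
    else:
        hist = boxmod.simulate_nk_box(
            cfg, spec, kick=kick["kick"],
            kick_element=kick["kick_element"],
            decimate=preset.get("decimate", 10),
            monitor_element=kick["kick_element"])
    outputs = []
    if params.get("out"):
        frame = pd.DataFrame({"t": hist.t, "x1": hist.x1,
                              f"x{hist.monitor_element}": hist.x_monitor})
        _write_csv(params["out"], frame)
        outputs.append(params["out"])
    t_end = preset["t_end"]
    window = (0.8 * t_end, t_end)
    profile, nodes = boxmod.standing_wave_profile(hist, window)
    if params.get("profile"):
        _write_csv(params["profile"], pd.DataFrame({
            "element": np.arange(1, cfg.n + 1),
            "max_abs_x": profile,
        }))
        outputs.append(params["profile"])
    if params.get("summary"):
        dt = preset["dt"]
        half = hist.x1[hist.x1.size // 2:]
        try:
            label, slope = signals.classify_self_sustaining(hist.x1, dt)
        except ValueError:
            label, slope = "indeterminate", float("nan")
        f1 = signals.dominant_frequency(half, dt)
        try:
            amp = oscillators.steady_amplitude(hist.x1_trajectory(), 0.2)
        except ValueError:       # run too short for a full-period window
            amp = float("nan")
        _summary_json(params["summary"], {
            "preset": preset["name"],
            "emission_frequency_hz": f1 * (1e3 if preset.get("unit") == "ms"
                                           else 1.0),
            "emission_frequency_per_unit_time": f1,
            "x1_steady_amplitude": amp,
            "self_sustaining": label == "self-sustaining",
            "classification": label,
            "envelope_slope_per_unit_time": slope,
            "nodes": nodes,
        })
        outputs.append(params["summary"])
    return outputs


# ---------------------------------------------------------------------------
# stochastic inputs


def run_noise(params: dict) -> list[str]:
    spec = stochastic.NoiseSpec(
        kind=params.get("kind", "narrowband"),
        f0=params.get("f0", 1.0),
        bandwidth=params.get("bw"),
        amplitude=params.get("amplitude", 1.0),
        seed=params.get("seed", 0),
    )
    grid = SimGrid(0.0, params["t_end"], params["dt"])
    series = stochastic.generate_noise(spec, grid)
    _write_csv(params["out"], pd.DataFrame({"t": grid.times(),
                                            "force": series}))
    return [params["out"]]


def run_roughness(params: dict) -> list[str]:
    mode = params.get("mode", "ou")
    n = params["n"]
    if mode in ("ou", "ou_field"):
        field = stochastic.ou_field(params.get("theta", 0.008),
                                    params.get("sigma", 1.0), n,
                                    params.get("seed", 0))
    else:
        spec = stochastic.RoughnessSpec(
            mode="gaussian_multiplicative",
            epsilon=params.get("epsilon", 0.0), seed=params.get("seed", 0))
        field = stochastic.roughen(np.ones(n), spec) - 1.0
    _write_csv(params["out"], pd.DataFrame({"index": np.arange(n),
                                            "epsilon": field}))
    return [params["out"]]


# ---------------------------------------------------------------------------
# noise-driven oscillator statistics (the bimodality pipeline)


def run_fig2(params: dict) -> dict:
    """Noise-driven Van der Pol histogram pipeline.

    Returns a dict with the spectrum, both band verdicts and, when
    ``out_dir`` is in params, writes signal/spectrum/histogram CSVs plus a
    summary JSON.  The emission band must show a double-peaked amplitude
    distribution with a minimum near zero; a noise-only band a single
    zero-centred mode.
    """
    preset = load_preset("fig2")
    merged = {**preset, **{k: v for k, v in params.items() if v is not None}}
    seed = merged.get("seed", 7)
    om, al, be = merged["omega"], merged["alpha"], merged["beta"]
    vp = oscillators.VdPParams(om, al, be)
    dt = merged["dt"]
    # self-calibrate the fundamental from a short undriven run
    warm = oscillators.simulate_vdp(vp, merged["x0"], merged["v0"],
                                    SimGrid(0.0, 200.0, dt))
    f0 = signals.dominant_frequency(warm["x"][warm.t.size // 2:], dt)
    grid = SimGrid(0.0, merged["t_end"], dt)
    drive = stochastic.generate_noise(
        stochastic.NoiseSpec("narrowband", f0=f0,
                             bandwidth=merged["bandwidth_factor"] * f0,
                             amplitude=merged["drive_amplitude"],
                             seed=seed),
        grid, half_step=True)
    traj = oscillators.simulate_vdp(vp, merged["x0"], merged["v0"], grid,
                                    drive=drive)
    rng = np.random.default_rng(seed + 1)
    x = traj["x"] + merged["white_amplitude"] * rng.standard_normal(
        traj.t.size)
    spec = signals.amplitude_spectrum(x, dt)
    width = merged["filter_width_factor"] * f0
    # the strongest spectral peak away from the emission line but inside
    # the driven region (harmonics of the oscillator live at k·f0 and must
    # not be mistaken for noise peaks)
    bw = merged["bandwidth_factor"] * f0
    mask = (np.abs(spec.frequency - f0) > 2 * width) \
        & (spec.frequency > f0 - bw) \
        & (spec.frequency < f0 + bw)
    idx = int(np.argmax(np.where(mask, spec.amplitude, 0.0)))
    f_noise = float(spec.frequency[idx])
    emission_band = signals.bandpass(x, dt, f0, width)
    noise_band = signals.bandpass(x, dt, f_noise, width)
    hist_em = signals.amplitude_histogram(emission_band)
    hist_no = signals.amplitude_histogram(noise_band)
    result = {
        "f0": f0,
        "f_noise": f_noise,
        "emission_modes": hist_em.mode_count,
        "noise_modes": hist_no.mode_count,
        "emission_bimodal": hist_em.bimodal,
        "peak_to_floor_db": 20 * np.log10(
            1.0 / max(spec.amplitude[idx], 1e-12)),
        "histograms": {"emission": hist_em, "noise": hist_no},
        "signal": x,
        "dt": dt,
    }
    out_dir = params.get("out_dir")
    outputs: list[str] = []
    if out_dir:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(out / "signal.csv",
                   pd.DataFrame({"t": traj.t, "x": x}))
        _write_csv(out / "spectrum.csv",
                   pd.DataFrame({"frequency": spec.frequency,
                                 "amplitude": spec.amplitude}))
        for tag, h in (("emission", hist_em), ("noise", hist_no)):
            _write_csv(out / f"hist_{tag}.csv", pd.DataFrame({
                "bin_left": h.bin_edges[:-1],
                "bin_right": h.bin_edges[1:],
                "count": h.counts,
            }))
        _summary_json(out / "summary.json", {
            "f0": f0, "f_noise": f_noise,
            "emission_modes": hist_em.mode_count,
            "noise_modes": hist_no.mode_count,
            "emission_bimodal": bool(hist_em.bimodal),
            "peak_to_floor_db": result["peak_to_floor_db"],
            "seed": seed,
        })
        outputs = [str(out / p) for p in
                   ("signal.csv", "spectrum.csv", "hist_emission.csv",
                    "hist_noise.csv", "summary.json")]
    result["outputs"] = outputs
    return result


# ---------------------------------------------------------------------------
# dispatcher (manifest re-runs go through here)

_RUNNERS = {
    "osc": run_osc,
    "pair": run_pair,
    "lizard": run_lizard,
    "box": run_box,
    "noise": run_noise,
    "roughness": run_roughness,
    "fig2": lambda p: run_fig2(p)["outputs"],
}


def dispatch(command: str, params: dict) -> list[str]:
    """Execute a named command with resolved params; returns output paths."""
    if command not in _RUNNERS:
        raise ValueError(f"unknown command {command!r}")
    out = _RUNNERS[command](params)
    return list(out)
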