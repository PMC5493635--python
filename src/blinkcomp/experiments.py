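"""Experiment configs, presets, report writing and fixture generation.

An :class:`ExperimentConfig` fully describes a synthetic study: the
scene (emitters, pixel grid, PSF), blinking kinetics, noise, and which
analysis to run.  A config plus a master seed reproduces every output
bit-for-bit.  The master seed fans out to fixed sub-streams (blinking,
noise, analysis) through ``numpy.random.SeedSequence(master_seed,
spawn_key)`` so the consumers of randomness are decoupled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .components import component_report, component_set
from .kinetics import BlinkParams, emission_stats, simulate_photon_counts
from .metrics import (diagonal_profile, fwhm, inflection_point,
                      magnitude_curve, min_max_ratio)
from .musical import (count_peaks, eigenimages, pseudospectrum,
                      split_subspaces, subspaces_from_factor)
from .optics import (EmitterSet, PixelGrid, PSFModel, build_system_matrix,
                     mean_image)
from .sofi import sofi2, sofi_component_check
from .stacks import add_poisson_noise, simulate_stack, write_stack_tiff

__all__ = ["ExperimentConfig", "PRESETS", "preset_config", "run_experiment",
           "generate_fixture"]

log = logging.getLogger("blinkcomp")

_ANALYSES = ("simulate", "components", "metrics", "musical", "sofi",
             "blinkstats")


class ConfigError(ValueError):
    """Invalid experiment configuration; lists the offending keys."""


@dataclass(frozen=True)
class ExperimentConfig:
    name: str
    analysis: str
    psf: dict = field(default_factory=lambda: {
        "kind": "airy1d", "rayleigh_radius_nm": 222.0})
    grid: dict = field(default_factory=lambda: {
        "n_pixels": 10, "pixel_size_nm": 100.0})
    emitters: dict = field(default_factory=lambda: {
        "count": 2, "delta_y_nm": 100.0})
    blink: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    musical: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    n_frames: int = 500
    master_seed: int = 0

    _KNOWN = {"name", "analysis", "psf", "grid", "emitters", "blink",
              "noise", "musical", "metrics", "n_frames", "master_seed"}

    def __post_init__(self) -> None:
        if self.analysis not in _ANALYSES:
            raise ConfigError(f"analysis must be one of {_ANALYSES}, "
                              f"got {self.analysis!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        unknown = set(d) - cls._KNOWN
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"name", "analysis"} - set(d)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    # ---- constructors of model objects ------------------------------------
    def psf_model(self) -> PSFModel:
        return PSFModel(**self.psf)

    def emitter_set(self) -> EmitterSet:
        if "positions_nm" in self.emitters:
            return EmitterSet(tuple(self.emitters["positions_nm"]))
        return EmitterSet.uniform(int(self.emitters.get("count", 2)),
                                  float(self.emitters.get("delta_y_nm", 100.0)))

    def pixel_grid(self) -> PixelGrid:
        g = self.grid
        if "half_span_nm" in g:  # ideal or sliding grid
            if g.get("pixel_size_nm", 0.0):
                return PixelGrid.sliding(g["half_span_nm"], g["pixel_size_nm"],
                                         g.get("step_nm", 2.0))
            return PixelGrid.ideal(g["half_span_nm"], g.get("step_nm", 1.0))
        return PixelGrid.camera(int(g["n_pixels"]), float(g["pixel_size_nm"]))

    def blink_params(self) -> BlinkParams:
        return BlinkParams(n_frames=self.n_frames, **self.blink)


# ---------------------------------------------------------------------------
# presets (study conditions of the worked examples)
# ---------------------------------------------------------------------------

PRESETS: dict = {
    # ideal camera, two emitters 100 nm apart
    "example1": {
        "name": "example1", "analysis": "components",
        "grid": {"half_span_nm": 700.0, "step_nm": 1.0},
        "emitters": {"count": 2, "delta_y_nm": 100.0},
    },
    # practical camera: 10 pixels of 100 nm
    "example2": {
        "name": "example2", "analysis": "components",
        "grid": {"n_pixels": 10, "pixel_size_nm": 100.0},
        "emitters": {"count": 2, "delta_y_nm": 100.0},
    },
    # small simulated stack for tests and demos
    "two_emitters_100nm": {
        "name": "two_emitters_100nm", "analysis": "simulate",
        "grid": {"n_pixels": 10, "pixel_size_nm": 100.0},
        "emitters": {"count": 2, "delta_y_nm": 100.0},
        "blink": {"tau_max_b": 10.0, "tau_max_d": 10.0,
                  "emission_rate": 40.0, "frame_time": 10.0},
        "n_frames": 500,
    },
    "eight_emitters_10nm": {
        "name": "eight_emitters_10nm", "analysis": "musical",
        "grid": {"n_pixels": 40, "pixel_size_nm": 100.0},
        "emitters": {"count": 8, "delta_y_nm": 10.0},
        "musical": {"alpha": 1.0, "s0_policy": "rank", "rank": 8,
                    "test_step_nm": 1.0, "use_factor": True},
    },
    "eight_emitters_100nm_snr20": {
        "name": "eight_emitters_100nm_snr20", "analysis": "musical",
        "grid": {"n_pixels": 40, "pixel_size_nm": 100.0},
        "emitters": {"count": 8, "delta_y_nm": 100.0},
        "noise": {"peak_snr": 20.0, "apply_to": "G"},
        "musical": {"alpha": 1.0, "s0_policy": "rank", "rank": 8,
                    "test_step_nm": 1.0},
    },
    # quantum-dot photon statistics at T = 10 ms across time-scale ratios
    "blinkstats_T10ms": {
        "name": "blinkstats_T10ms", "analysis": "blinkstats",
        "blink": {"tau_max_b": 10.0, "tau_max_d": 10.0,
                  "emission_rate": 40.0, "frame_time": 10.0},
        "metrics": {"ratio_sweep": [1e-2, 1.0, 100.0], "n_emitters": 4},
        "n_frames": 10000,
    },
    # magnitude sweep on sliding 100-nm pixels
    "magnitude_sweep": {
        "name": "magnitude_sweep", "analysis": "metrics",
        "grid": {"half_span_nm": 700.0, "pixel_size_nm": 100.0,
                 "step_nm": 2.0},
        "metrics": {"delta_y_min": 10.0, "delta_y_max": 400.0,
                    "delta_y_step": 2.0},
    },
}


def preset_config(name: str, seed: int | None = None) -> ExperimentConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    d = dict(PRESETS[name])
    if seed is not None:
        d["master_seed"] = int(seed)
    return ExperimentConfig.from_dict(d)


# ---------------------------------------------------------------------------
# running experiments
# ---------------------------------------------------------------------------

def _seed_for(config: ExperimentConfig, stream: str) -> np.random.SeedSequence:
    offsets = {"blink": 1, "noise": 2, "musical": 3}
    return np.random.SeedSequence(config.master_seed,
                                  spawn_key=(offsets[stream],))


def _matrix_csv(path: Path, C: np.ndarray, coords: np.ndarray) -> None:
    df = pd.DataFrame(C, index=np.round(coords, 6), columns=np.round(coords, 6))
    df.to_csv(path, index_label="r_nm")


def _noisy_G(config, sm, seeds):
    noise = config.noise
    if noise.get("peak_snr") and noise.get("apply_to", "G") == "G":
        return sm.with_G(add_poisson_noise(sm.G, noise["peak_snr"], seeds))
    return sm


def run_experiment(config: ExperimentConfig, out_dir) -> dict:
    """Run the configured analysis and write its report bundle.

    Writes a TIFF stack when one is simulated, CSV tables for matrices
    and curves, a JSON summary embedding the config digest/seed/version,
    and a plain-text log.  Returns the summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "experiment.log")
    log.addHandler(handler)
    try:
        summary = {"name": config.name, "analysis": config.analysis,
                   "config_digest": config.digest(),
                   "master_seed": config.master_seed,
                   "blinkcomp_version": __version__,
                   "numpy_version": np.__version__}
        log.info("running %s (%s), seed %d", config.name, config.analysis,
                 config.master_seed)
        runner = {
            "simulate": _run_simulate,
            "components": _run_components,
            "metrics": _run_metrics,
            "musical": _run_musical,
            "sofi": _run_sofi,
            "blinkstats": _run_blinkstats,
        }[config.analysis]
        summary.update(runner(config, out))
        config.to_yaml(out / "config.yaml")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
        return summary
    finally:
        log.removeHandler(handler)
        handler.close()


def _simulate_core(config: ExperimentConfig):
    psf, grid = config.psf_model(), config.pixel_grid()
    sm = build_system_matrix(config.emitter_set(), grid, psf)
    counts = simulate_photon_counts(config.blink_params(),
                                    sm.M, _seed_for(config, "blink"))
    stack = simulate_stack(sm, counts)
    noise = config.noise
    if noise.get("peak_snr") and noise.get("apply_to", "I") == "I":
        noisy = add_poisson_noise(stack.I, noise["peak_snr"],
                                  _seed_for(config, "noise"))
        stack = type(stack)(noisy, stack.frame_time, "simulated",
                            stack.pixel_size_nm)
    return sm, counts, stack


def _run_simulate(config, out: Path) -> dict:
    sm, counts, stack = _simulate_core(config)
    write_stack_tiff(out / "stack.tiff", stack)
    pd.DataFrame(counts.S).to_csv(out / "photon_counts.csv", index=False)
    mu, sigma, ratio = emission_stats(counts)
    return {"N": sm.N, "M": sm.M, "K": stack.K,
            "mu": mu, "sigma": sigma, "mu2_over_sigma2": ratio}


def _run_components(config, out: Path) -> dict:
    psf, grid = config.psf_model(), config.pixel_grid()
    sm = build_system_matrix(config.emitter_set(), grid, psf)
    sm = _noisy_G(config, sm, _seed_for(config, "noise"))
    mu, sigma = config.blink.get("mu", 1.0), config.blink.get("sigma", 1.0)
    cs = component_set(sm, config.n_frames, mu, sigma)
    coords = grid.centers
    for name, C in (("C1", cs.C1), ("C2", cs.C2), ("C3", cs.C3),
                    ("C2minusC3", None if cs.C3 is None else cs.C2 - cs.C3)):
        if C is not None:
            _matrix_csv(out / f"{name}.csv", C, coords)
    profiles = {"mean_image": mean_image(sm),
                "diag_C1": diagonal_profile(cs.C1),
                "diag_C2": diagonal_profile(cs.C2)}
    if cs.C3 is not None:
        profiles["diag_C3"] = diagonal_profile(cs.C3)
        profiles["diag_C2minusC3"] = diagonal_profile(cs.C2 - cs.C3)
    pd.DataFrame({"r_nm": coords, **profiles}).to_csv(
        out / "profiles.csv", index=False)
    rep = component_report(cs)
    prof = profiles["mean_image"]
    try:
        rep["fwhm_mean_image_nm"] = fwhm(prof, coords)
    except ValueError:
        pass
    rep["R_mean_image"] = min_max_ratio(prof, coords)
    return rep


def _run_metrics(config, out: Path) -> dict:
    psf, grid = config.psf_model(), config.pixel_grid()
    m = config.metrics
    dys = np.arange(m.get("delta_y_min", 10.0),
                    m.get("delta_y_max", 400.0) + 1e-9,
                    m.get("delta_y_step", 2.0))
    noise_snr = config.noise.get("peak_snr")
    n_real = int(config.noise.get("n_realizations", 100)) if noise_snr else 1
    summary = {"delta_y_nm": [float(dys[0]), float(dys[-1])],
               "inflection_points_nm": {}}
    frames = {}
    for mid in ("meanimg", "C1", "C2", "C3", "C2minusC3"):
        curve = magnitude_curve(dys, mid, grid, psf,
                                noise_peak_snr=noise_snr,
                                n_realizations=n_real,
                                rng_seed=_seed_for(config, "noise")
                                .generate_state(1)[0] if noise_snr else None)
        frames[mid] = curve.values
        if curve.sd is not None:
            frames[mid + "_sd"] = curve.sd
        if mid != "C2minusC3":
            x = inflection_point(curve)
            summary["inflection_points_nm"][mid] = x
    pd.DataFrame({"delta_y_nm": dys, **frames}).to_csv(
        out / "magnitude_curves.csv", index=False)
    return summary


def _run_musical(config, out: Path) -> dict:
    psf, grid = config.psf_model(), config.pixel_grid()
    emitters = config.emitter_set()
    sm = build_system_matrix(emitters, grid, psf, normalize_columns=True)
    sm = _noisy_G(config, sm, _seed_for(config, "noise"))
    mconf = config.musical
    alpha = float(mconf.get("alpha", 1.0))
    step = float(mconf.get("test_step_nm", 1.0))
    lo, hi = grid.span
    test = np.arange(lo, hi + step / 2, step)
    from .components import compute_components
    C1, C2, C3 = compute_components(sm)
    results = {}
    curves = {"r_nm": test}
    span = np.abs(emitters.positions).max() + (emitters.delta_y or 100.0)
    for name, C in (("C1", C1), ("C2", C2), ("C3", C3)):
        if C is None:
            continue
        if name == "C1":
            sub = split_subspaces(eigenimages(C), "rank", rank=1)
        elif mconf.get("use_factor"):
            sub = split_subspaces(subspaces_from_factor(sm), "rank",
                                  rank=int(mconf.get("rank", sm.M)))
        elif mconf.get("s0_policy", "eigengap") == "rank":
            sub = split_subspaces(eigenimages(C), "rank",
                                  rank=int(mconf.get("rank", sm.M)))
        elif mconf.get("s0_policy") == "fixed":
            sub = split_subspaces(eigenimages(C), "fixed",
                                  s0=float(mconf["s0"]))
        else:
            sub = split_subspaces(eigenimages(C), "eigengap")
        ps = pseudospectrum(sub, psf, grid, test, alpha=alpha)
        n, peaks = count_peaks(ps, float(mconf.get("min_rel_height", 0.05)),
                               window=(-span, span))
        curves[f"f_{name}"] = ps.f
        curves[f"dps_{name}"] = ps.dps
        curves[f"dpn_{name}"] = ps.dpn
        results[name] = {"n_peaks": n, "peaks_nm": peaks.tolist(),
                         "n_signal": sub.n_signal}
    pd.DataFrame(curves).to_csv(out / "pseudospectra.csv", index=False)
    return {"alpha": alpha, "peak_window_nm": float(span),
            "per_matrix": results}


def _run_sofi(config, out: Path) -> dict:
    sm, counts, stack = _simulate_core(config)
    mu, sigma, _ = emission_stats(counts)
    img = sofi2(stack, int(config.metrics.get("kappa", 0)))
    pd.DataFrame({"r_nm": sm.grid.centers, "sofi2": img.F}).to_csv(
        out / "sofi2.csv", index=False)
    chk = sofi_component_check(sm, mu, sigma, stack)
    return {k: v for k, v in chk.items() if np.isscalar(v)}


def _run_blinkstats(config, out: Path) -> dict:
    m = config.metrics
    ratios = m.get("ratio_sweep", [1e-2, 1.0, 100.0])
    n_emit = int(m.get("n_emitters", 4))
    base = config.blink_params()
    rows = []
    ss = _seed_for(config, "blink")
    for i, ratio in enumerate(ratios):
        params = BlinkParams(
            tau_max_b=base.tau_max_b, tau_max_d=base.tau_max_b / ratio,
            powerlaw_exponent=base.powerlaw_exponent,
            tau_min_frac=base.tau_min_frac,
            emission_rate=base.emission_rate, frame_time=base.frame_time,
            n_frames=base.n_frames)
        counts = simulate_photon_counts(params, n_emit, ss.spawn(1)[0])
        mu, sigma, r = emission_stats(counts)
        rows.append({"tau_ratio": ratio, "mu": mu, "sigma": sigma,
                     "mu2_over_sigma2": r})
    pd.DataFrame(rows).to_csv(out / "blink_stats.csv", index=False)
    return {"frame_time_ms": base.frame_time, "n_frames": base.n_frames,
            "table": rows}


def generate_fixture(preset: str, seed: int, out_dir) -> dict:
    """Write a small deterministic fixture bundle for a named preset."""
    config = preset_config(preset, seed)
    return run_experiment(config, out_dir)
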