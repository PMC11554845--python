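"""Study orchestration: prior sampling -> ensemble simulation -> PCE -> Sobol'.

A study draws parameter sets from the uniform prior box, runs the multiscale
model for each (proximal 1D solve plus structured-tree beds), collects a
fixed-shape vector of quantities of interest per sample, fits Legendre
polynomial-chaos surrogates pointwise, and reports uncertainty bands,
validation error and (generalized) Sobol' indices.  Per-sample results are
cached on disk keyed by a hash of the parameter vector and the relevant
configuration, so interrupted studies resume without recomputation and
reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distal import pressure_spectrum, propagate_pathway
from .network import MaterialParameters, ProximalNetwork, default_network, load_network
from .pce import (
    ParameterPrior,
    fit_ols,
    generalized_sobol,
    moments,
    sample_prior,
    sobol_indices,
    validation_mse,
)
from .qoi import WAVE_TYPES, cyclic_stretch, proximal_wss, wave_intensity
from .solver import ConvergenceError, SolverConfig, SolverError, run_simulation
from .structured_tree import (
    SpectralGrid,
    TreeParameters,
    generate_tree_index,
    grand_admittance,
)
from .waveforms import la_pressure, mpa_inflow, read_waveform

__all__ = ["StudyConfig", "SampleResult", "simulate_sample", "run_ensemble", "run_study"]

PARAM_NAMES = ("K_A", "K_ST", "K_V", "alpha", "beta", "lrr_A", "lrr_V", "r_min")


@dataclass
class StudyConfig:
    """Everything needed to reproduce a study end to end."""

    network: str = "default"  # or a network CSV path
    # synthetic waveform parameters (ignored when *_file given)
    T: float = 0.85
    stroke_volume: float = 70.0
    systolic_fraction: float = 0.4
    backflow_fraction: float = 0.02
    p_base: float = 8.0
    a_amp: float = 3.0
    v_amp: float = 2.0
    inflow_file: str | None = None
    la_file: str | None = None
    # solver / spectral resolution
    dx: float = 0.125
    dt_target: float = 1.04e-4
    n_modes: int = 512
    max_cycles: int = 80
    convergence_tol: float = 1.0
    # experiment design
    N_train: int = 2000
    N_val: int = 100
    order: int = 4
    seed: int = 0
    design: str = "random"
    # quantities of interest
    qoi_vessels: tuple[str, ...] = ("MPA", "LPA", "RPA", "LIV", "LSV", "RIV", "RSV")
    distal_bed: str = "RIA D1"
    n_profile: int = 21
    n_qoi_t: int = 64
    out_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "qoi_vessels" in raw:
            raw["qoi_vessels"] = tuple(raw["qoi_vessels"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["qoi_vessels"] = list(d["qoi_vessels"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    # -- derived objects --------------------------------------------------
    def load_network(self, materials: MaterialParameters | None = None) -> ProximalNetwork:
        if self.network == "default":
            return default_network(materials)
        return load_network(self.network, materials=materials)

    def waveforms(self):
        if self.inflow_file:
            inflow = read_waveform(self.inflow_file, "flow")
        else:
            inflow = mpa_inflow(
                self.T, self.stroke_volume, self.systolic_fraction, self.backflow_fraction
            )
        if self.la_file:
            la = read_waveform(self.la_file, "pressure")
        else:
            la = la_pressure(self.T, self.p_base, self.a_amp, self.v_amp)
        return inflow, la

    def solver_config(self) -> SolverConfig:
        return SolverConfig(
            dx=self.dx,
            dt_target=self.dt_target,
            max_cycles=self.max_cycles,
            convergence_tol=self.convergence_tol,
        )

    def _cache_key_fields(self) -> dict:
        d = asdict(self)
        for k in ("N_train", "N_val", "order", "seed", "design", "out_dir"):
            d.pop(k)
        d["qoi_vessels"] = list(d["qoi_vessels"])
        return d


SampleResult = dict[str, np.ndarray]


def _theta_dict(theta: np.ndarray) -> dict[str, float]:
    return dict(zip(PARAM_NAMES, np.asarray(theta, dtype=float)))


def build_beds(
    network: ProximalNetwork,
    theta: dict[str, float],
    grid: SpectralGrid,
    keep_subtrees_for: str | None = None,
) -> dict:
    """One two-sided bed per terminal artery-vein pair."""
    beds = {}
    for a, v in network.terminal_pairs:
        params = TreeParameters(
            alpha=theta["alpha"],
            beta=theta["beta"],
            lrr_A=theta["lrr_A"],
            lrr_V=theta["lrr_V"],
            r_min=theta["r_min"],
            K_ST=theta["K_ST"],
            root_radius=network[a].radius,
        )
        beds[a] = grand_admittance(
            generate_tree_index(params),
            params,
            grid,
            venous_root_radius=network[v].radius,
            rho=network.materials.rho,
            keep_subtrees=(a == keep_subtrees_for),
        )
    return beds


def simulate_field(theta: np.ndarray, config: StudyConfig):
    """Run one multiscale simulation; returns (field, beds, network)."""
    th = _theta_dict(theta)
    mats = MaterialParameters(K_A=th["K_A"], K_V=th["K_V"])
    network = config.load_network(mats)
    inflow, la = config.waveforms()
    grid = SpectralGrid(inflow.T, config.n_modes)
    beds = build_beds(network, th, grid, keep_subtrees_for=config.distal_bed)
    field = run_simulation(network, beds, inflow, la, config.solver_config())
    return field, beds, network


def simulate_sample(theta: np.ndarray, config: StudyConfig) -> SampleResult:
    """Run the full multiscale model for one parameter vector.

    Returns a flat dict of fixed-shape arrays: decimated midpoint time
    series (p/q/wss) for the configured vessels, per-vessel cyclic stretch
    and mean flow, WIA energies, and distal pathway profiles of the chosen
    bed pooled onto a normalized distance-from-termination grid.
    """
    th = _theta_dict(theta)
    mats = MaterialParameters(K_A=th["K_A"], K_V=th["K_V"])
    field, beds, network = simulate_field(theta, config)

    out: SampleResult = {"theta": np.asarray(theta, dtype=float)}
    stride = max(1, field.n_steps // config.n_qoi_t)
    for vn in config.qoi_vessels:
        out[f"p:{vn}"] = field.midpoint(vn, "p")[::stride]
        out[f"q:{vn}"] = field.midpoint(vn, "q")[::stride]
        out[f"wss:{vn}"] = proximal_wss(field, vn)[::stride]
        wia = wave_intensity(field, vn)
        out[f"wia:{vn}"] = np.array([wia.energies[w] for w in WAVE_TYPES])
    names = field.names
    out["vessel_cs"] = np.array([cyclic_stretch(field, n) for n in names])
    out["vessel_mean_q"] = np.array(
        [field.midpoint(n, "q").mean() for n in names]
    )
    out["vessel_mean_p"] = np.array(
        [field.midpoint(n, "p").mean() for n in names]
    )
    out["n_cycles"] = np.array([field.n_cycles], dtype=float)

    # distal pathways of the chosen bed
    bed_art = config.distal_bed
    bed_vein = dict(network.terminal_pairs)[bed_art]
    SA = pressure_spectrum(field.end(bed_art, "p", "L"), config.n_modes)
    SV = pressure_spectrum(field.end(bed_vein, "p", "0"), config.n_modes)
    ngrid = np.linspace(0.0, 1.0, config.n_profile)
    endpoints = {}
    for pw in ("alpha", "beta"):
        prof = propagate_pathway(beds[bed_art], SA, SV, pw, rho=mats.rho)
        for side in ("arterial", "venous"):
            for col in ("mean_p_dyncm2", "mean_q_cm3s", "wss_dyncm2", "cs"):
                key = f"distal:{pw}:{side}:{col}"
                out[key] = prof.on_normalized_grid(ngrid, col, side)
        art = prof.side("arterial")
        endpoints[f"{pw}_root_wss"] = art["wss_dyncm2"].iloc[0]
        endpoints[f"{pw}_term_wss"] = art["wss_dyncm2"].iloc[-1]
    out["distal_endpoint_wss"] = np.array(
        [endpoints[k] for k in ("alpha_root_wss", "alpha_term_wss", "beta_root_wss", "beta_term_wss")]
    )
    return out


def _sample_key(theta: np.ndarray, config: StudyConfig) -> str:
    payload = json.dumps(
        {"theta": [f"{v:.12e}" for v in theta], "config": config._cache_key_fields()},
        sort_keys=True,
    )
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def run_ensemble(
    thetas: np.ndarray,
    config: StudyConfig,
    cache_dir: str | Path | None = None,
    progress: bool = False,
) -> tuple[list[SampleResult | None], list[str]]:
    """Simulate each row of ``thetas``; failures yield None plus a message."""
    results: list[SampleResult | None] = []
    errors: list[str] = []
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    it = range(thetas.shape[0])
    if progress:
        from tqdm import tqdm

        it = tqdm(it, desc="ensemble")
    for k in it:
        theta = thetas[k]
        fp = cache / f"{_sample_key(theta, config)}.npz" if cache else None
        if fp is not None and fp.exists():
            with np.load(fp, allow_pickle=False) as z:
                results.append({k2: z[k2] for k2 in z.files})
            errors.append("")
            continue
        try:
            res = simulate_sample(theta, config)
        except (SolverError, ConvergenceError, ValueError) as err:
            results.append(None)
            errors.append(f"sample {k}: {err}")
            continue
        results.append(res)
        errors.append("")
        if fp is not None:
            np.savez_compressed(fp, **res)
    failed = [e for e in errors if e]
    if thetas.shape[0] and len(failed) / thetas.shape[0] > 0.02:
        warnings.warn(
            f"{len(failed)}/{thetas.shape[0]} ensemble samples failed; "
            "they are excluded from regression",
            stacklevel=2,
        )
    return results, errors


def stack_outputs(results: list[SampleResult | None]) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Stack per-sample dicts into (key -> (N_ok, n_out)) plus the success mask."""
    ok = np.array([r is not None for r in results])
    good = [r for r in results if r is not None]
    if not good:
        raise RuntimeError("no successful ensemble samples")
    keys = [k for k in good[0] if k != "theta"]
    return {k: np.stack([np.atleast_1d(r[k]) for r in good]) for k in keys}, ok


def run_study(config: StudyConfig) -> Path:
    """Execute the full pipeline and write artifacts into ``config.out_dir``.

    Stages: prior sampling (train + validation), ensemble simulation with
    caching, pointwise PCE fits per quantity of interest, uncertainty bands
    (mean +- SD), validation MSE, and generalized Sobol' indices.  A JSON
    manifest records seeds, sizes, failures and stage hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prior = ParameterPrior()
    thetas, xi = sample_prior(prior, config.N_train + config.N_val, config.seed, config.design)
    results, errors = run_ensemble(thetas, config, cache_dir=out / "cache", progress=True)
    outputs, ok = stack_outputs(results)
    xi_ok = xi[ok]
    n_ok = int(ok.sum())
    n_val = min(config.N_val, max(0, n_ok - max(config.N_train // 2, 1)))
    xi_tr, xi_va = (xi_ok[: n_ok - n_val], xi_ok[n_ok - n_val :]) if n_val else (xi_ok, None)

    band_rows, sobol_rows, mse_rows = [], [], []
    for key, Z in outputs.items():
        if key == "n_cycles":
            continue
        Ztr = Z[: n_ok - n_val] if n_val else Z
        try:
            surr = fit_ols(xi_tr, Ztr, config.order, prior=prior, seed=config.seed, canonical=True)
        except (ValueError, np.linalg.LinAlgError) as err:
            warnings.warn(f"PCE fit skipped for '{key}': {err}", stacklevel=2)
            continue
        mean, var = moments(surr)
        sd = np.sqrt(var)
        for t in range(mean.size):
            band_rows.append((key, t, mean[t], sd[t]))
        if n_val:
            _, mse = validation_mse(surr, xi_va, Z[n_ok - n_val :], canonical=True)
            mse_rows.append((key, mse))
        rep = sobol_indices(surr)
        if np.any(rep.valid):
            v = var.copy()
            v[~rep.valid] = 0.0
            for i, nm in enumerate(prior.names):
                s1 = np.nan_to_num(rep.S1[i])
                st = np.nan_to_num(rep.ST[i])
                gs1 = generalized_sobol(s1, v) if mean.size > 1 else float(s1[0])
                gst = generalized_sobol(st, v) if mean.size > 1 else float(st[0])
                sobol_rows.append((key, nm, "", "GS1", float(gs1)))
                sobol_rows.append((key, nm, "", "GST", float(gst)))
            for (i, j), s2 in rep.S2.items():
                s2 = np.nan_to_num(s2)
                gs2 = generalized_sobol(s2, v) if mean.size > 1 else float(s2[0])
                sobol_rows.append((key, prior.names[i], prior.names[j], "GS2", float(gs2)))

    pd.DataFrame(band_rows, columns=["qoi", "point", "mean", "sd"]).to_csv(
        out / "uncertainty_bands.csv", index=False
    )
    pd.DataFrame(sobol_rows, columns=["qoi", "param1", "param2", "index_type", "value"]).to_csv(
        out / "sobol_indices.csv", index=False
    )
    pd.DataFrame(mse_rows, columns=["qoi", "mse"]).to_csv(
        out / "validation_mse.csv", index=False
    )

    # plain ensemble summaries (no emulator) for the scalar QoIs
    summary = {}
    for key in ("vessel_cs", "vessel_mean_q", "vessel_mean_p", "distal_endpoint_wss"):
        Z = outputs[key]
        summary[key] = {
            "mean": Z.mean(axis=0).tolist(),
            "sd": Z.std(axis=0, ddof=1).tolist() if Z.shape[0] > 1 else [0.0] * Z.shape[1],
        }
    with open(out / "ensemble_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)

    manifest = {
        "seed": config.seed,
        "design": config.design,
        "N_train": config.N_train,
        "N_val": config.N_val,
        "order": config.order,
        "n_failed": sum(1 for e in errors if e),
        "failures": [e for e in errors if e],
        "config_hash": hashlib.sha1(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return out
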