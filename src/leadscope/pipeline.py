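"""End-to-end pipeline runs over synthetic data, with validated config.

``run_pipeline`` wires the stages together in dependency order: generate a
synthetic analog library and screen it against the template; generate and
fit every titration-style assay (dose-response, MST, thermal melt pair,
pH titration); generate a planted trajectory and map its epitopes; compute
and calibrate a membrane permeability.  The stage summary is collated into
one machine-readable JSON document.

Configuration is a nested mapping mirroring :data:`DEFAULT_CONFIG`;
unknown keys are rejected by name, and the effective (merged) config is
echoed to the run log together with the tool version, a config hash and
per-stage wall times.  Results are deterministic under a fixed seed (the
log, which carries timings, is not part of the summary).
"""

from __future__ import annotations

import copy
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from . import assay_fits, epitope_mapper, permeability, shape_screen, synthetic_data

__all__ = ["DEFAULT_CONFIG", "ConfigError", "validate_config", "run_pipeline"]


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": ["screen", "fits", "epitope", "permeability"],
    "screen": {
        "n_library": 8,
        "n_starts": 6,
        "thresholds": [1.5, 1.4, 1.3, 1.2, 1.0],
        "max_mw": 400.0,
    },
    "fits": {
        "ic50_uM": 33.0,
        "kd_uM": 39.0,
        "target_conc_nM": 100.0,
        "tm_apo_C": 74.5,
        "delta_tm_C": -1.6,
        "pka": 6.69,
        "noise": {"dose_sd": 0.03, "mst_sd": 0.2, "melt_sd": 0.005,
                  "pka_sd": 0.005},
    },
    "epitope": {
        "n_frames": 400,
        "fractions": [0.132, 0.101],
        "cutoff_angstrom": 4.0,
        "min_residues": 5,
        "grid_spacing": 1.0,
        "cut_distance": 0.7,
    },
    "permeability": {
        "diffusivity_cm2_s": 1e-5,
        "temperature_K": 300.0,
        "barrier_height_kcal": 5.0,
        "well_depth_kcal": 1.5,
    },
}


class ConfigError(ValueError):
    """A pipeline configuration contains unknown or invalid keys."""


def validate_config(user: dict | None, defaults: dict | None = None) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys by name."""
    defaults = copy.deepcopy(DEFAULT_CONFIG if defaults is None else defaults)
    if user is None:
        return defaults

    def merge(base: dict, override: dict, path: str) -> dict:
        for key, value in override.items():
            full = f"{path}.{key}" if path else str(key)
            if key not in base:
                raise ConfigError(f"unknown configuration key: {full!r}")
            if isinstance(base[key], dict) and isinstance(value, dict):
                merge(base[key], value, full)
            else:
                base[key] = value
        return base

    return merge(defaults, user, "")


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, outdir: str | Path = "run",
                 seed: int | None = None) -> dict:
    """Run the configured stages and write per-stage outputs plus a summary.

    Returns the summary dict; writes ``summary.json`` and ``run.log`` under
    ``outdir``.  A stage failure raises after logging the stage name;
    partial outputs are retained.
    """
    config = validate_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [
        f"leadscope {__version__}",
        f"config_hash {_config_hash(config)}",
        "config " + json.dumps(config, sort_keys=True),
    ]
    root = np.random.SeedSequence(config["seed"])
    stage_seeds = {name: int(child.generate_state(1)[0] % (2 ** 31))
                   for name, child in zip(
                       ["screen", "fits", "epitope", "permeability"],
                       root.spawn(4))}
    summary: dict = {"version": __version__, "seed": config["seed"],
                     "config_hash": _config_hash(config)}
    try:
        for stage in config["stages"]:
            t0 = time.perf_counter()
            runner = _STAGES[stage]
            summary[stage] = runner(config, stage_seeds[stage], outdir)
            log_lines.append(f"stage {stage} ok "
                             f"{time.perf_counter() - t0:.2f}s")
    except Exception as exc:
        log_lines.append(f"stage {stage} FAILED: {exc}")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        raise
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_screen(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["screen"]
    template = synthetic_data.example_template()
    library, _ = synthetic_data.gen_molecule_library(
        template, n=cfg["n_library"], seed=seed,
        out_sdf=outdir / "library.sdf")
    library = [m for m in library
               if m.molecular_weight < cfg["max_mw"]] or library
    report = shape_screen.screen_library(
        template, library, thresholds=cfg["thresholds"],
        n_starts=cfg["n_starts"], seed=seed)
    rows = [{"id": name, "shape_tanimoto": r.shape_tanimoto,
             "color_tanimoto": r.color_tanimoto, "combo": r.combo,
             "rank": i + 1}
            for i, (name, r) in enumerate(report.ranked)]
    (outdir / "screen_report.json").write_text(
        json.dumps({"ranked": rows, "census": {str(k): v for k, v in
                                               report.census.items()}},
                   indent=2) + "\n")
    return {
        "n_scored": len(rows),
        "top_combo": rows[0]["combo"] if rows else None,
        "census": {str(k): v for k, v in sorted(report.census.items(),
                                                reverse=True)},
    }


def _stage_fits(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["fits"]
    noise = cfg["noise"]
    ss = np.random.SeedSequence(seed)
    seeds = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(5)]

    dose, _ = synthetic_data.gen_dose_response(
        ic50=cfg["ic50_uM"], noise_sd=noise["dose_sd"], seed=seeds[0],
        out=outdir / "dose_response.csv")
    ic50_fit = assay_fits.fit_ic50(assay_fits.TitrationSeries(
        dose.iloc[:, 0].to_numpy(), dose.iloc[:, 1:].to_numpy()))

    mst, _ = synthetic_data.gen_mst_titration(
        kd=cfg["kd_uM"], target_conc_nM=cfg["target_conc_nM"],
        noise_sd=noise["mst_sd"], seed=seeds[1], out=outdir / "mst.csv")
    kd_fit = assay_fits.fit_mst_kd(
        assay_fits.TitrationSeries(mst.iloc[:, 0].to_numpy(),
                                   mst.iloc[:, 1:].to_numpy()),
        target_conc_nM=cfg["target_conc_nM"])

    apo, _ = synthetic_data.gen_melting_curve(
        tm=cfg["tm_apo_C"], noise_sd=noise["melt_sd"], seed=seeds[2],
        out=outdir / "melt_apo.csv")
    cplx, _ = synthetic_data.gen_melting_curve(
        tm=cfg["tm_apo_C"] + cfg["delta_tm_C"], noise_sd=noise["melt_sd"],
        seed=seeds[3], out=outdir / "melt_complex.csv")
    tm_apo = assay_fits.compute_tm(apo["temperature_C"], apo["F330"], apo["F350"])
    tm_cplx = assay_fits.compute_tm(cplx["temperature_C"], cplx["F330"], cplx["F350"])

    ph, _ = synthetic_data.gen_ph_titration(
        pka=cfg["pka"], noise_sd=noise["pka_sd"], seed=seeds[4],
        out=outdir / "ph_titration.csv")
    pka_fit = assay_fits.fit_pka(assay_fits.TitrationSeries(
        ph["pH"].to_numpy(), ph["shift_ppm"].to_numpy()))

    return {
        "ic50_uM": ic50_fit.ic50,
        "ic50_class": assay_fits.classify_activity(ic50_fit),
        "kd_app_uM": kd_fit.kd_app,
        "tm_apo_C": tm_apo.tm,
        "tm_complex_C": tm_cplx.tm,
        "delta_tm_C": assay_fits.delta_tm(tm_apo, tm_cplx),
        "pka": pka_fit.pka,
        "protonated_fraction_ph7_5": assay_fits.protonated_fraction(
            pka_fit.pka, 7.5),
    }


def _stage_epitope(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["epitope"]
    traj, manifest = synthetic_data.gen_trajectory(
        n_frames=cfg["n_frames"],
        epitope_specs=None if cfg["fractions"] == [0.132, 0.101] else [
            ([("A", i) for i in range(5, 10)], cfg["fractions"][0]),
            ([("C", i) for i in range(10, 15)], cfg["fractions"][1]),
        ],
        seed=seed, out_pdb=outdir / "trajectory.pdb")
    fps = epitope_mapper.trajectory_fingerprints(
        traj, cutoff=cfg["cutoff_angstrom"])
    bound = epitope_mapper.filter_bound_frames(
        fps, min_residues=cfg["min_residues"])
    bound_fps = [fps[i] for i in bound]
    clusters = epitope_mapper.cluster_fingerprints(
        bound_fps, cut=cfg["cut_distance"])
    report = epitope_mapper.epitope_report(traj.n_frames, bound_fps, clusters)
    grid = epitope_mapper.density_grid(traj, bound,
                                       spacing=cfg["grid_spacing"])
    epitope_mapper.write_dx(grid, outdir / "density.dx")
    return {
        "n_bound_frames": len(bound),
        "n_clusters": len(report.clusters),
        "occupancies_pct": [c.occupancy_pct for c in report.clusters],
        "planted_occupancies_pct": [e["occupancy_pct"]
                                    for e in manifest["epitopes"]],
        "grid_total_counts": grid.total,
    }


def _stage_permeability(config: dict, seed: int, outdir: Path) -> dict:
    cfg = config["permeability"]
    pmf_df, _ = synthetic_data.gen_pmf_profile(
        barrier_height=cfg["barrier_height_kcal"],
        well_depth=cfg["well_depth_kcal"], seed=seed,
        out=outdir / "pmf.csv")
    profile = permeability.PMFProfile(pmf_df["z_angstrom"].to_numpy(),
                                      pmf_df["dG_kcal_mol"].to_numpy(),
                                      temperature=cfg["temperature_K"])
    log_pmf = permeability.peff_from_pmf(
        profile, diffusivity=cfg["diffusivity_cm2_s"])
    model = permeability.fit_calibration(
        list(permeability.LEAD_COMPOUND_CALIBRATION.values()))
    result = permeability.apply_calibration(model, log_pmf)
    return {
        "log_peff_pmf": result.log_peff_pmf,
        "log_peff_pampa": result.log_peff_pampa,
        "peff_cm_s": result.peff,
        "class": result.permeability_class,
        "calibration_slope": model.slope,
        "calibration_intercept": model.intercept,
    }


_STAGES = {
    "screen": _stage_screen,
    "fits": _stage_fits,
    "epitope": _stage_epitope,
    "permeability": _stage_permeability,
}
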