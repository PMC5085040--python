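"""End-to-end analysis driver.

Runs the full inference chain on a study dataset (measured or synthetic):
per-condition censored-gamma moments, kinetic-structure selection,
temperature-law selection, shared-shape and RNA-polymerase-constrained
comparisons, parametric-bootstrap goodness of fit, and the pre/post-commit
reconciliation.  Produces CSV reports plus a machine-readable
``summary.json`` stamped with seeds and schema version.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .commit import lineweaver_burk_split, postcommit_assignments, read_activity, reconcile_split
from .gof import parametric_bootstrap
from .inference import ModelStructure, fit_censored_gamma
from .io import SCHEMA_VERSION, StudyDataset, read_rnap_profile, read_study, write_study
from .selection import select_structure
from .simulate import ObservationDesign, generate_study
from .temperature import TemperatureLaw, fit_rnap_constrained, \
    fit_shared_shape, select_temperature_model

log = logging.getLogger("txinit")

DEFAULT_STAGES = ["moments", "select", "fit_temperature", "gof"]


def _structure_from_config(cfg) -> ModelStructure:
    return ModelStructure(int(cfg.get("n_steps", 1)), bool(cfg.get("switching", True)))


def law_from_config(cfg) -> TemperatureLaw:
    entries = {}
    for name, e in cfg.items():
        coefs = tuple(float(c) for c in e["coefficients"])
        entries[name] = (int(e.get("order", 0)), coefs)
    return TemperatureLaw(entries)


def simulate_from_config(cfg, seed: int) -> StudyDataset:
    design = ObservationDesign(
        movie_length=float(cfg.get("movie_length", 7200.0)),
        sampling_interval=float(cfg.get("sampling_interval", 60.0)),
        n_cells=int(cfg.get("n_cells", 100)),
    )
    schemes = {name: law_from_config(laws) for name, laws in cfg["schemes"].items()}
    temperatures = [float(t) for t in cfg.get("temperatures", [24, 30, 37, 41])]
    conditions, intervals = generate_study(design, schemes, temperatures, seed=seed)
    return StudyDataset(conditions, intervals,
                        provenance={"generator_seed": seed, "schema_version": SCHEMA_VERSION})


def run_pipeline(config: dict, output_dir) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    Any stage failure is logged and downstream stages are skipped; the
    summary then carries an ``error`` key.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    n_starts = int(config.get("n_starts", 10))
    stages = list(config.get("stages", DEFAULT_STAGES))
    rng = np.random.default_rng(seed)
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "txinit_version": __version__,
        "seed": seed,
        "stages": stages,
    }

    if "simulate" in config:
        dataset = simulate_from_config(config["simulate"], seed)
        write_study(dataset, out / "conditions.csv", out / "intervals.csv")
    elif "input" in config:
        dataset = read_study(config["input"]["conditions"], config["input"]["intervals"])
    else:
        raise ValueError("config needs either a 'simulate' or an 'input' section")
    if "promoter_filter" in config:
        wanted = config["promoter_filter"]
        known = set(dataset.conditions.get("promoter", pd.Series(dtype=str)))
        if wanted not in known:
            raise ValueError(f"unknown promoter filter {wanted!r}; known: {sorted(known)}")
        keep = dataset.conditions[dataset.conditions["promoter"] == wanted]
        dataset = StudyDataset(keep,
                               dataset.intervals[dataset.intervals["condition_id"]
                                                 .isin(keep["condition_id"])],
                               dataset.provenance)
    summary["n_conditions"] = int(len(dataset.conditions))
    summary["n_intervals"] = int(len(dataset.intervals))

    structure = _structure_from_config(config.get("structure", {}))
    try:
        if "moments" in stages:
            rows = []
            for cid in dataset.conditions["condition_id"]:
                recs = dataset.records_for(cid)
                if not len(recs):
                    continue
                fit, mom = fit_censored_gamma(recs, seed=int(rng.integers(2**31)))
                rows.append({"condition_id": cid, "n_exact": fit.n_exact,
                             "n_censored": fit.n_censored, "mean_s": mom.mean,
                             "sd_s": mom.sd, "cv": mom.cv,
                             "median_to_mean": mom.median_to_mean})
            pd.DataFrame(rows).to_csv(out / "moments.csv", index=False)
            summary["moments"] = rows

        if "select" in stages:
            reports = []
            for cid in dataset.conditions["condition_id"]:
                recs = dataset.records_for(cid)
                if not len(recs):
                    continue
                comp = select_structure(recs, n_starts=n_starts,
                                        seed=int(rng.integers(2**31)))
                frame = comp.to_frame()
                frame.insert(0, "condition_id", cid)
                reports.append(frame)
                log.info("condition %s: best structure %s (dBIC %.3g)", cid,
                         comp.candidates[comp.best][0], comp.delta_bic_second_best or 0.0)
            if reports:
                pd.concat(reports, ignore_index=True).to_csv(
                    out / "selection_report.csv", index=False)
                summary["structure_selection"] = [
                    {"condition_id": r["condition_id"].iloc[0],
                     "best": r["structure"].iloc[0],
                     "delta_bic": float(r["delta_BIC"].iloc[1]) if len(r) > 1 else None}
                    for r in reports
                ]

        best_temp_fit = None
        if "fit_temperature" in stages:
            by_T = dataset.by_temperature()
            if len(by_T) >= 2:
                comp = select_temperature_model(by_T, structure, n_starts=n_starts,
                                                seed=int(rng.integers(2**31)))
                comp.to_frame().to_csv(out / "temperature_selection.csv", index=False)
                best_temp_fit = comp.best_fit
                law = best_temp_fit.extra.get("law")
                if law is not None:
                    from .io import write_laws
                    write_laws(law, out / "laws.csv")
                summary["temperature_selection"] = {
                    "best": best_temp_fit.model_spec,
                    "delta_bic": comp.delta_bic_second_best,
                    "delta_bic_lb": comp.delta_bic_lb,
                    "evidence": comp.evidence,
                }

        if "shared_shape" in stages and "scheme" in dataset.conditions.columns:
            by_scheme = {}
            for scheme, sub in dataset.conditions.groupby("scheme"):
                by_scheme[scheme] = dataset.by_temperature(sub["condition_id"])
            if len(by_scheme) >= 2:
                fit = fit_shared_shape(by_scheme, structure, n_starts=n_starts,
                                       seed=int(rng.integers(2**31)))
                summary["shared_shape"] = {
                    "loglik": fit.loglik,
                    "scales": fit.extra["scales"],
                    "converged": fit.converged,
                }

        if "rnap" in stages and "rnap_profile" in config:
            profile = read_rnap_profile(config["rnap_profile"])
            fit = fit_rnap_constrained(dataset.by_temperature(), profile, structure,
                                       n_starts=n_starts, seed=int(rng.integers(2**31)))
            summary["rnap_constrained"] = {
                "loglik": fit.loglik,
                "k1_tilde": float(np.exp(fit.estimates[0])),
                "converged": fit.converged,
            }

        if "gof" in stages:
            # the bootstrap needs a single kinetic model: fit the configured
            # structure to the pooled records
            from .inference import fit_model
            gof_fit = fit_model(dataset.intervals, structure, n_starts=n_starts,
                                seed=int(rng.integers(2**31)))
            gof = parametric_bootstrap(
                dataset.intervals, gof_fit,
                rounds=int(config.get("gof_rounds", 1000)),
                seed=int(rng.integers(2**31)),
            )
            gof_report = {"p_fraction": gof.p_fraction, "rounds": gof.rounds,
                          "seed": gof.seed, "empirical_loglik": gof.empirical_loglik,
                          "schema_version": SCHEMA_VERSION}
            (out / "gof.json").write_text(json.dumps(gof_report, indent=2))
            summary["gof"] = gof_report

        if "split" in stages and "activity" in config:
            split = lineweaver_burk_split(read_activity(config["activity"]))
            summary["commit_split"] = split
            if "step_durations" in config:
                shares = postcommit_assignments(config["step_durations"])
                summary["commit_split"]["assignments"] = list(shares)
                summary["commit_split"]["reconciliation"] = reconcile_split(shares, split)
    except Exception as exc:  # noqa: BLE001 - stage failures are reported, not hidden
        log.error("pipeline stage failed: %s", exc)
        summary["error"] = str(exc)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
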