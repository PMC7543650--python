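"""End-to-end orchestration: simulate -> score -> fit -> select -> peb -> classify.

Every stage writes its outputs into the run directory and records itself in
``manifest.json`` (package version, derived per-stage seeds, configuration
hash), so a rerun with the same configuration reproduces all outputs
byte-identically.  A stage failure halts the run with the stage name while
preserving the outputs of completed stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__, cmc_forward as cmc, io
from .behavior_scoring import score_cohort, signed_rank_vs_zero
from .density_classifier import classify_parameter
from .dcm_inversion import fit_dcm
from .model_selection import bms_fixed_effects
from .peb_group import (
    build_design_matrix,
    compare_model_fits_by_group,
    run_peb,
    threshold_parameters,
)
from .synthetic_data import (
    CohortConfig,
    default_group_truth,
    generate_behavior_cohort,
    generate_csd_dataset,
    generate_subject_parameters,
)

__all__ = ["default_config", "run_pipeline"]


def default_config() -> dict:
    """Full-cohort default: 21 HV + 4 SC, all four architectures."""
    return {
        "seed": 0,
        "n_hv": 21,
        "n_sc": 4,
        "models": [1, 2, 3, 4],
        "noise_level": 0.1,
        "max_iter": 128,
        "pp_threshold": 0.95,
        "classifier_threshold": 0.95,
        "behavior": {
            "HV": {"d_mean": -0.297, "d_sd": 0.44},
            "SC": {"d_mean": -0.083, "d_sd": 0.32},
        },
    }


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute all stages into ``out_dir``; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = default_config()
    cfg.update(config or {})
    seed = int(cfg["seed"])
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }
    stage = "init"
    try:
        # --- simulate + score behavior -----------------------------------
        stage = "behavior"
        tables = []
        for gi, grp in enumerate(("HV", "SC")):
            n = cfg["n_hv"] if grp == "HV" else cfg["n_sc"]
            if n == 0:
                continue
            b = cfg["behavior"][grp]
            cc = CohortConfig(
                group=grp, n_subjects=n, d_mean=b["d_mean"], d_sd=b["d_sd"],
                seed=seed + 11 * (gi + 1),
            )
            tables.extend(generate_behavior_cohort(cc))
        io.write_behavior_csv(tables, out / "behavior.csv")
        scores = score_cohort(tables)
        scores.to_csv(out / "dscores.csv", index=False)
        groups_of = {
            str(t["subject_id"].iloc[0]): str(t["group"].iloc[0]) for t in tables
        }
        tests = {}
        for grp in ("HV", "SC"):
            d = scores[
                scores["subject_id"].map(groups_of) == grp
            ]["D"].tolist()
            if len(d) >= 5:
                tests[grp] = asdict(signed_rank_vs_zero(d))
        io.write_json(tests, out / "group_tests.json")
        manifest["stages"]["behavior"] = {
            "seed": seed + 11, "outputs": ["behavior.csv", "dscores.csv",
                                          "group_tests.json"],
        }

        # --- subject parameters and cross-spectra ------------------------
        stage = "simulate_csd"
        truth = default_group_truth()
        subjects = generate_subject_parameters(
            truth, cfg["n_hv"], cfg["n_sc"], seed=seed + 101
        )
        datasets = generate_csd_dataset(
            subjects, noise_level=cfg["noise_level"], seed=seed + 202
        )
        io.write_csd_h5(
            datasets,
            [s.subject_id for s in subjects],
            [s.group for s in subjects],
            out / "csd.h5",
            seed=seed + 202,
        )
        manifest["stages"]["simulate_csd"] = {
            "seed": seed + 202, "outputs": ["csd.h5"],
        }

        # --- first-level inversion per model -----------------------------
        stage = "fit"
        specs = {m.model_id: m for m in cmc.build_model_space()}
        posteriors = {}  # model -> {sid: Posterior}
        for mid in cfg["models"]:
            mdir = out / f"fits_model{mid}"
            mdir.mkdir(exist_ok=True)
            posteriors[mid] = {}
            for s, ds in zip(subjects, datasets):
                post = fit_dcm(
                    ds, specs[mid], max_iter=cfg["max_iter"],
                    subject_id=s.subject_id,
                )
                posteriors[mid][s.subject_id] = post
                io.write_posterior_json(post, mdir / f"{s.subject_id}.json")
        manifest["stages"]["fit"] = {
            "models": list(cfg["models"]),
            "outputs": [f"fits_model{m}" for m in cfg["models"]],
        }

        # --- model selection ---------------------------------------------
        stage = "select"
        bms = bms_fixed_effects(
            {m: {sid: p.F for sid, p in per.items()}
             for m, per in posteriors.items()}
        )
        io.write_json(
            {
                "summed_F": bms.summed_F,
                "winner": bms.winner,
                "tied_models": bms.tied_models,
                "relative_log_evidence": bms.relative_log_evidence,
            },
            out / "bms.json",
        )
        winner = bms.winner if bms.winner is not None else bms.tied_models[0]
        manifest["stages"]["select"] = {"winner": winner, "outputs": ["bms.json"]}

        # --- second-level PEB --------------------------------------------
        stage = "peb"
        win_posts = [posteriors[winner][s.subject_id] for s in subjects]
        X = build_design_matrix([s.group for s in subjects])
        fields = [
            n for n in cmc.parameter_names(specs[winner])
            if n.startswith(("F:", "B:", "Mod:"))
        ]
        peb = run_peb(win_posts, X, fields)
        hits = threshold_parameters(peb, cfg["pp_threshold"])
        fit_cmp = compare_model_fits_by_group(
            [p.fit_correlations["mean"] for p in win_posts],
            [s.group for s in subjects],
        )
        io.write_json(
            {
                "parameters": peb.parameters,
                "covariates": peb.covariates,
                "Ep": peb.Ep,
                "Vp": peb.Vp,
                "Pp": peb.Pp,
                "between_subject_sd": peb.between_subject_sd,
                "thresholded": hits,
                "fit_comparison": fit_cmp,
            },
            out / "peb.json",
        )
        manifest["stages"]["peb"] = {"outputs": ["peb.json"]}

        # --- density classification --------------------------------------
        stage = "classify"
        if cfg["n_sc"] == 0:
            manifest["stages"]["classify"] = {
                "skipped": "no SC subjects in cohort"
            }
        else:
            params = [h[0] for h in hits["group"]] or list(
                dict.fromkeys(truth.parameters[-3:])
            )
            reports = {}
            hv_posts = [
                posteriors[winner][s.subject_id]
                for s in subjects if s.group == "HV"
            ]
            sc_posts = [
                posteriors[winner][s.subject_id]
                for s in subjects if s.group == "SC"
            ]
            for pname in params:
                rep = classify_parameter(
                    pname,
                    [p.get(pname) for p in hv_posts],
                    [p.variance(pname) for p in hv_posts],
                    [p.get(pname) for p in sc_posts],
                    [p.variance(pname) for p in sc_posts],
                    threshold=cfg["classifier_threshold"],
                )
                reports[pname] = asdict(rep)
            io.write_json(reports, out / "classifier.json")
            with open(out / "classifier.tsv", "w") as fh:
                fh.write("parameter\tmean_sensitivity\tspecificity\n")
                for pname, rep in reports.items():
                    fh.write(
                        f"{pname}\t{rep['mean_sensitivity']:.0f}"
                        f"\t{rep['specificity']:.1f}\n"
                    )
            manifest["stages"]["classify"] = {
                "parameters": params,
                "outputs": ["classifier.json", "classifier.tsv"],
            }
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(err).__name__}: {err}"
        io.write_json(manifest, out / "manifest.json")
        raise
    io.write_json(manifest, out / "manifest.json")
    return manifest
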