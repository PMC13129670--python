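"""End-to-end orchestration of the four workflow phases.

A single YAML config drives: (1) pre-processing — reading or simulating the
measurement tables, encoding statuses, filtering to the minimum number of
time points; (2) predictive model definition — fitting (or selecting) the
functional clustering model; (3) model abstraction — classifying new
trajectories against the frozen model; (4) post-processing — survival,
concordance and landmark analyses.  Every output directory carries a run
manifest (config echo, seed, input digests, version, per-phase timings) so
a report can always be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import classify_cohort, entropy_vs_length_table
from .clustering import (
    discriminant_functions,
    fdb_index,
    fit_fcm,
    save_model,
    select_model,
)
from .data import filter_cohort, read_cohort, write_cohort
from .simulate import default_archetypes, default_config, generate_cohort, generate_survival
from .survival import (
    GroupMerge,
    SurvivalRecord,
    cox_hr,
    km_estimate,
    landmark_analysis,
    logrank_test,
)

__all__ = ["WorkflowError", "load_config", "run_workflow"]


class WorkflowError(RuntimeError):
    """A phase failed or the config is inconsistent; the message names it."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise WorkflowError("config: top level must be a mapping")
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _classification_frame(results, G) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"patient_id": r.patient_id}
        row.update({f"p{k + 1}": r.memberships[k] for k in range(G)})
        row["entropy_bits"] = r.entropy_bits
        row["label"] = r.label
        row["n_timepoints"] = r.n_timepoints
        rows.append(row)
    return pd.DataFrame(rows)


def run_workflow(config_path, output_dir: Optional[str] = None) -> dict:
    """Execute the configured phases; returns the run manifest.

    Outputs (model JSON, classification/entropy/discriminant CSVs, survival
    tables, manifest) are written under the config's ``output_dir`` unless
    overridden.  Identical (config, seed, inputs) yield identical outputs.
    """
    config_path = Path(config_path)
    cfg = load_config(config_path)
    seed = int(cfg.get("seed", 0))
    out = Path(output_dir or cfg.get("output_dir", "mrdflow_out"))
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "config_path": str(config_path),
        "inputs": {},
        "timings_s": {},
        "status": "running",
        "phases": [],
    }

    def _phase(name):
        manifest["phases"].append(name)
        return time.perf_counter()

    try:
        # ---- phase 1: pre-processing (read or simulate) -------------------
        t0 = _phase("preprocess")
        pre = cfg.get("preprocess", {})
        min_tp = int(pre.get("min_timepoints", 3))
        if "simulate" in cfg:
            sim = cfg["simulate"] or {}
            config = default_config(
                seed=seed, **{k: v for k, v in sim.items() if k != "separation"}
            )
            specs = default_archetypes()
            cohort, labels = generate_cohort(specs, config)
            cohort.clinical = generate_survival(labels, specs, config)
            write_cohort(
                cohort, out / "measurements.csv", out / "clinical.csv"
            )
            pd.DataFrame(
                {"patient_id": cohort.patient_ids()[: len(labels)],
                 "true_archetype": [specs[int(k)].name for k in labels]}
            ).to_csv(out / "truth.csv", index=False)
        elif "inputs" in cfg:
            inputs = cfg["inputs"]
            if "measurements" not in inputs:
                raise WorkflowError("config: inputs.measurements is required")
            mpath = Path(inputs["measurements"])
            cpath = inputs.get("clinical")
            manifest["inputs"]["measurements"] = _digest(mpath)
            if cpath:
                manifest["inputs"]["clinical"] = _digest(Path(cpath))
            cohort = read_cohort(mpath, cpath)
        else:
            raise WorkflowError("config: need either a 'simulate' or an 'inputs' block")
        cohort = filter_cohort(cohort, min_tp)
        if len(cohort) == 0:
            raise WorkflowError("preprocess: no trajectory survived filtering")
        manifest["n_trajectories"] = len(cohort)
        manifest["timings_s"]["preprocess"] = round(time.perf_counter() - t0, 3)

        # ---- phase 2: predictive model definition -------------------------
        t0 = _phase("fit")
        fit_cfg = cfg.get("fit", {})
        if "select" in cfg:
            sel = cfg["select"]
            p_star, G_star, h_star, diag = select_model(
                cohort,
                p_grid=sel.get("p_grid", [4, 5, 6]),
                G_grid=sel.get("G_grid", [1, 2, 3, 4, 5]),
                h_rule=sel.get("h_rule"),
                seed=seed,
                n_starts=int(fit_cfg.get("n_starts", 5)),
            )
            manifest["selection"] = {
                "p": p_star, "G": G_star, "h": h_star,
                "cv_loglik": {str(k): v for k, v in diag["cv_loglik"].items()},
                "fdb": {str(k): v for k, v in diag["fdb"].items()},
            }
        else:
            p_star = int(fit_cfg.get("p", 5))
            G_star = int(fit_cfg.get("G", 4))
            h_star = fit_cfg.get("h")
        fit = fit_fcm(
            cohort,
            G=G_star,
            p=p_star,
            h=h_star,
            n_starts=int(fit_cfg.get("n_starts", 10)),
            seed=seed,
        )
        model = fit.model
        save_model(
            model, out / "model.json",
            meta={"seed": seed, "p": p_star, "G": G_star,
                  "n_trajectories": len(cohort), "loglik": fit.loglik},
        )
        if model.G >= 2:
            manifest["fdb"] = fdb_index(fit, cohort)
            t_max = max(float(t.times.max()) for t in cohort.trajectories)
            grid = np.linspace(0.0, t_max, 200)
            D = discriminant_functions(model, grid)
            ddf = pd.DataFrame(
                {"time_months": grid,
                 **{f"discriminant_{j + 1}": D[:, j] for j in range(D.shape[1])}}
            )
            ddf.to_csv(out / "discriminant_curves.csv", index=False)
        manifest["loglik"] = fit.loglik
        manifest["converged"] = bool(fit.converged)
        manifest["cluster_sizes"] = np.bincount(
            fit.assignments, minlength=model.G
        ).tolist()
        manifest["timings_s"]["fit"] = round(time.perf_counter() - t0, 3)

        # ---- phase 3: model abstraction (classification) ------------------
        t0 = _phase("classify")
        cls_cfg = cfg.get("classify", {})
        new_path = cfg.get("inputs", {}).get("classify_measurements")
        if new_path:
            manifest["inputs"]["classify_measurements"] = _digest(Path(new_path))
            targets = filter_cohort(read_cohort(new_path), min_tp).trajectories
        else:
            targets = cohort.trajectories  # classify the training cohort
        results = classify_cohort(
            model,
            targets,
            cutoff=float(cls_cfg.get("cutoff", 0.6)),
            entropy_max=float(cls_cfg.get("entropy_max", 1.0)),
            min_timepoints=min_tp,
        )
        cdf = _classification_frame(results, model.G)
        cdf.to_csv(out / "classification.csv", index=False)
        ent_df, ent_summary = entropy_vs_length_table(results)
        ent_df.to_csv(out / "entropy.csv", index=False)
        manifest["entropy_summary"] = ent_summary
        manifest["timings_s"]["classify"] = round(time.perf_counter() - t0, 3)

        # ---- phase 4: post-processing (survival / landmark) ----------------
        surv_cfg = cfg.get("survival", {})
        if surv_cfg.get("enabled", bool(cohort.clinical)):
            t0 = _phase("survival")
            if not cohort.clinical:
                raise WorkflowError(
                    "config: survival requested but no clinical table was "
                    "provided (inputs.clinical)"
                )
            merge_map = surv_cfg.get("merge")
            merge = (
                GroupMerge({int(k): str(v) for k, v in merge_map.items()})
                if merge_map
                else GroupMerge(
                    {k: ("FAVORABLE" if k < model.G / 2 else "UNFAVORABLE")
                     for k in range(model.G)}
                )
            )
            label_by_pid = {r.patient_id: r.label for r in results if r.assigned}
            records = [
                SurvivalRecord(pid, rec.ttp_months, rec.event, merge(label_by_pid[pid]))
                for pid, rec in cohort.clinical.items()
                if pid in label_by_pid
            ]
            rows = []
            for group in sorted({r.group for r in records}):
                km = km_estimate([r for r in records if r.group == group])
                rows.append(
                    {"group": group, "n": km.n, "events": km.n_events,
                     "median_ttp_months": km.median if np.isfinite(km.median) else "NOT_REACHED"}
                )
            pd.DataFrame(rows).to_csv(out / "survival_groups.csv", index=False)
            stat, p = logrank_test(records)
            hr, ci, hr_p = cox_hr(records, reference="FAVORABLE")
            with open(out / "survival.json", "w") as fh:
                json.dump(
                    {"logrank_statistic": stat, "logrank_p": p,
                     "hr_unfavorable": hr, "hr_ci95": list(ci), "hr_p": hr_p},
                    fh, indent=1,
                )
            manifest["survival"] = {"logrank_p": p, "hr_unfavorable": hr}
            manifest["timings_s"]["survival"] = round(time.perf_counter() - t0, 3)

            lm_cfg = cfg.get("landmark", {})
            if lm_cfg.get("landmarks"):
                t0 = _phase("landmark")
                lm = landmark_analysis(
                    model, cohort,
                    landmarks=[float(x) for x in lm_cfg["landmarks"]],
                    min_timepoints=min_tp, merge=merge,
                )
                lrows = [
                    {"landmark": r.landmark, "evaluable": r.evaluable,
                     "n_at_risk": len(r.records), "logrank_p": r.logrank_p,
                     "reason": r.reason}
                    for r in lm
                ]
                pd.DataFrame(lrows).to_csv(out / "landmark.csv", index=False)
                manifest["timings_s"]["landmark"] = round(time.perf_counter() - t0, 3)

        manifest["status"] = "ok"
    except WorkflowError:
        manifest["status"] = f"failed in phase {manifest['phases'][-1] if manifest['phases'] else 'config'}"
        _write_manifest(manifest, out)
        raise
    except Exception as e:  # keep partial outputs, name the failing phase
        phase = manifest["phases"][-1] if manifest["phases"] else "config"
        manifest["status"] = f"failed in phase {phase}"
        _write_manifest(manifest, out)
        raise WorkflowError(f"phase {phase} failed: {e}") from e

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
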