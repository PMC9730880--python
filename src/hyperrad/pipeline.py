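"""End-to-end orchestration: simulate -> label -> model -> survival.

``run_pipeline`` executes the stages for which inputs are available (or
generates the deterministic worked-example cohort), writes every artifact
plus a manifest into a run directory, and is bit-identical on rerun for the
deterministic stages.  ``report`` renders the artifacts as a plain-text
summary.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig
from .hyperprogression import classify_cohort, cohort_rates
from .modeling import nested_cv_evaluate
from .survival import hazard_ratio, km_estimate, landmark_filter, logrank_test
from .synthetic import build_figure2_fixture

__all__ = ["run_pipeline", "report", "survival_summary"]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def survival_summary(patients: pd.DataFrame, statuses: pd.DataFrame,
                     landmark_months: float = 3.0) -> dict:
    """Landmark KM medians, log-rank p and HRs vs the non-progressing group."""
    df = patients.merge(statuses[["patient_id", "status"]], on="patient_id")
    df = df.rename(columns={"os_months": "time"})[["time", "event", "status"]]
    lm = landmark_filter(df, landmark_months)
    out: dict = {"landmark_months": landmark_months, "groups": {}}
    for status, sub in lm.groupby("status"):
        km = km_estimate(sub)
        out["groups"][status] = {
            "n": int(len(sub)),
            "median_os_months": (km.median if km.median_reached
                                 else "not reached"),
        }
    ref = lm[lm["status"] == "nPD"]
    for status in ("PD-nHPD", "PD-HPD"):
        sub = lm[lm["status"] == status]
        if len(sub) == 0 or len(ref) == 0 or (sub["event"].sum() +
                                              ref["event"].sum()) == 0:
            continue
        hr = hazard_ratio(sub, ref)
        stat, p = logrank_test(sub, ref)
        out["groups"][status].update({
            "hr_vs_npd": hr.hr, "hr_ci": [hr.ci_low, hr.ci_high],
            "logrank_p_vs_npd": p,
        })
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run all configured stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "inputs": {}}
    t0 = time.time()

    # --- inputs: load or simulate -----------------------------------------
    if config.lesions_csv:
        lesions_path = Path(config.lesions_csv)
        if not lesions_path.exists():
            raise FileNotFoundError(
                f"config key 'lesions_csv': no such file {lesions_path}")
        lesions = pd.read_csv(lesions_path)
        manifest["inputs"]["lesions_csv"] = _sha256(lesions_path)
        patients = None
        if config.patients_csv:
            ppath = Path(config.patients_csv)
            if not ppath.exists():
                raise FileNotFoundError(
                    f"config key 'patients_csv': no such file {ppath}")
            patients = pd.read_csv(ppath)
            manifest["inputs"]["patients_csv"] = _sha256(ppath)
    else:
        patients, lesions = build_figure2_fixture()
        lesions.to_csv(out / "lesions.csv", index=False)
        patients.to_csv(out / "patients.csv", index=False)
        manifest["stages"]["simulate"] = {"source": "figure2_fixture"}

    # --- hyperprogression labeling ----------------------------------------
    try:
        assessments, statuses = classify_cohort(lesions)
    except Exception as exc:
        raise RuntimeError(f"stage 'hpl' failed: {exc}") from exc
    assessments.to_csv(out / "assessments.csv", index=False)
    statuses.to_csv(out / "patients_status.csv", index=False)
    rates = cohort_rates(assessments, statuses)
    (out / "rates.json").write_text(json.dumps(rates, indent=2))
    manifest["stages"]["hpl"] = {"n_lesions": rates["n_lesions"],
                                 "n_patients": rates["n_patients"]}

    # --- survival ----------------------------------------------------------
    if patients is not None and "os_months" in patients.columns:
        try:
            surv = survival_summary(patients, statuses, config.landmark_months)
        except Exception as exc:
            raise RuntimeError(f"stage 'survival' failed: {exc}") from exc
        (out / "survival.json").write_text(json.dumps(surv, indent=2))
        manifest["stages"]["survival"] = {"landmark": config.landmark_months}

    # --- modeling (only when a feature table is supplied) -------------------
    if config.features_csv:
        fpath = Path(config.features_csv)
        if not fpath.exists():
            raise FileNotFoundError(
                f"config key 'features_csv': no such file {fpath}")
        table = pd.read_csv(fpath)
        manifest["inputs"]["features_csv"] = _sha256(fpath)
        results = {}
        for modality in config.modalities:
            try:
                res = nested_cv_evaluate(
                    table, modality, seed=config.seed,
                    k_outer=config.outer_folds, n_iter=config.n_search,
                    repeats=config.inner_repeats, k_inner=config.inner_folds,
                    tau_threshold=config.tau_threshold)
            except Exception as exc:
                raise RuntimeError(
                    f"stage 'model' ({modality}) failed: {exc}") from exc
            results[modality] = res.to_dict()
        (out / "cv_results.json").write_text(json.dumps(results, indent=2))
        manifest["stages"]["model"] = {"modalities": config.modalities}

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    config.to_yaml(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run = Path(run_dir)
    missing = [f for f in ("rates.json", "manifest.json")
               if not (run / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run, missing: {missing}")
    lines = [f"Run summary: {run}"]
    r = json.loads((run / "rates.json").read_text())
    lines += [
        "",
        "Lesion-level rates",
        f"  progressing lesions : {r['n_pd_lesions']}/{r['n_lesions']}"
        f" ({r['lesion_pd_rate_pct']:.1f}%)",
        f"  HPL overall         : {r['n_hpl_lesions']}/{r['n_lesions']}"
        f" ({r['hpl_rate_overall_pct']:.1f}%)",
        f"  HPL among PD        : {r['n_hpl_lesions']}/{r['n_pd_lesions']}"
        f" ({r['hpl_rate_among_pd_pct']:.1f}%)",
        "Patient-level rates",
        f"  PD patients         : {r['n_pd_patients']}/{r['n_patients']}"
        f" ({r['patient_pd_rate_pct']:.1f}%)",
        f"  PD-HPD among PD     : {r['n_pd_hpd_patients']}/{r['n_pd_patients']}"
        f" ({r['pd_hpd_among_pd_pct']:.1f}%)",
        f"  PD-HPD overall      : {r['n_pd_hpd_patients']}/{r['n_patients']}"
        f" ({r['pd_hpd_overall_pct']:.1f}%)",
    ]
    if (run / "survival.json").exists():
        s = json.loads((run / "survival.json").read_text())
        lines += ["", f"Survival (landmark {s['landmark_months']} months)"]
        for grp, info in s["groups"].items():
            line = f"  {grp:8s} n={info['n']:3d} median OS: " \
                   f"{info['median_os_months']}"
            if "hr_vs_npd" in info:
                line += (f"  HR vs nPD: {info['hr_vs_npd']:.2f} "
                         f"({info['hr_ci'][0]:.2f}-{info['hr_ci'][1]:.2f})")
            lines.append(line)
    if (run / "cv_results.json").exists():
        cv = json.loads((run / "cv_results.json").read_text())
        lines += ["", "HPL models (nested CV)"]
        for modality, res in cv.items():
            folds = ", ".join(f"{a:.3f}" for a in res["outer_fold_aucs"])
            lines.append(f"  {modality:5s} test AUC {res['auc_mean']:.3f} "
                         f"+/- {res['auc_sd']:.3f}  folds: [{folds}]")
    return "\n".join(lines)
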