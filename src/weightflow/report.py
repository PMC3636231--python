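"""Pipeline orchestration: simulate -> qc -> cohort -> features -> analyze,
with flow accounting, structured logging, and a plain-text summary report.

Each stage reads and writes headered CSVs/JSON in the output directory, so
any stage can also be run standalone from files.  When the run includes
simulated ground truth, the manual-review step is emulated by two synthetic
reviewers who label each flagged entry according to the truth with a small
independent flip probability, and disagreements are resolved to the truth -
this exercises the agreement statistics and keeps the pipeline end-to-end
runnable without human input.  On real data, reviewer labels are supplied
as a CSV instead.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .config import PipelineConfig
from .cohort import (FlowLedger, build_cohort, fraction_documenting_regain,
                     stratify_by_span)
from .features import (BINARY_FLAGS, CATEGORICAL_PREDICTORS, assemble_totals,
                       build_features)
from .qc import (apply_baseline_exclusions, drop_confirmed_errors,
                 filter_sensitivity, resolve_reviews, run_all_filters)
from .regression import fit_stepwise, fit_univariable_adjusted, screen_confounders
from .simulate import simulate_dataset

log = logging.getLogger("weightflow")

STAGES = ["simulate", "qc", "cohort", "features", "analyze", "report"]

CONFOUNDER_CANDIDATES = ["baseline_bmi", "age", "sex", "reg_source",
                         "region", "weight_entry_span"]


def simulated_review_labels(flagged_entry_ids, truth_entry_ids, seed: int,
                            flip_p: float):
    """Two synthetic reviewers labelling flags against ground truth.

    Each reviewer independently mislabels an entry with probability
    ``flip_p``; the consensus for discordant entries is the ground truth.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 911]))
    truth_ids = set(truth_entry_ids)
    flagged = sorted(flagged_entry_ids)
    rows = []
    for reviewer in ("R1", "R2"):
        flips = rng.random(len(flagged)) < flip_p
        for entry_id, flip in zip(flagged, flips):
            truly_bad = entry_id in truth_ids
            verdict = "erroneous" if (truly_bad != flip) else "valid"
            rows.append((entry_id, reviewer, verdict))
    labels = pd.DataFrame(rows, columns=["entry_id", "reviewer_id", "verdict"])
    consensus = pd.DataFrame({
        "entry_id": flagged,
        "verdict": ["erroneous" if e in truth_ids else "valid"
                    for e in flagged]})
    return labels, consensus


def _stage_simulate(config: PipelineConfig, out: Path) -> dict:
    if config.in_dir is not None:
        ind = Path(config.in_dir)
        data = {
            "members": wio.read_members(ind / "members.csv"),
            "weights": wio.read_weights(ind / "weights.csv"),
            "logins": wio.read_logins(ind / "logins.csv"),
            "usage": wio.read_usage(ind / "usage.csv"),
            "entry_truth": None,
        }
        gt = ind / "ground_truth.csv"
        if gt.exists():
            data["entry_truth"] = wio.read_ground_truth(gt)
        log.info("stage=load in=%s members=%d weights=%d", ind,
                 len(data["members"]), len(data["weights"]))
        return data
    sim_cfg = config.simulate
    if sim_cfg.seed != config.seed:
        sim_cfg = type(sim_cfg).from_dict({**sim_cfg.to_dict(),
                                           "seed": config.seed})
    sim = simulate_dataset(sim_cfg)
    wio.write_members(sim.members, out / "members.csv")
    wio.write_weights(sim.weights, out / "weights.csv")
    wio.write_logins(sim.logins, out / "logins.csv")
    wio.write_usage(sim.usage, out / "usage.csv")
    if config.ground_truth:
        wio.write_ground_truth(sim.entry_truth, out / "ground_truth.csv")
    log.info("stage=simulate members=%d weights=%d logins=%d",
             len(sim.members), len(sim.weights), len(sim.logins))
    return {"members": sim.members, "weights": sim.weights,
            "logins": sim.logins, "usage": sim.usage,
            "entry_truth": sim.entry_truth if config.ground_truth else None}


def _stage_qc(config: PipelineConfig, data: dict, out: Path) -> dict:
    members, weights = data["members"], data["weights"]
    ledger = FlowLedger()
    retained, exclusions = apply_baseline_exclusions(members, weights,
                                                     config.thresholds)
    ledger.add("baseline_exclusions", len(members), len(exclusions))
    weights_kept = weights.loc[
        weights["member_id"].isin(set(retained["member_id"]))]

    report = run_all_filters(retained, weights_kept, config.thresholds)
    report.flags.to_csv(out / "flags.csv", index=False)
    template = (report.flags[["entry_id", "member_id"]]
                .drop_duplicates("entry_id").sort_values("entry_id"))
    template["verdict"] = ""
    template.to_csv(out / "review_template.csv", index=False)

    qc_ledger = {"filters": report.summary,
                 "baseline_exclusions": len(exclusions)}
    truth = data.get("entry_truth")
    if truth is not None and len(report.flags):
        labels, consensus = simulated_review_labels(
            report.flagged_entry_ids(), truth["entry_id"], config.seed,
            config.reviewer_flip_p)
        review = resolve_reviews(report.flagged_entry_ids(), labels, consensus)
        confirmed = review.confirmed_entry_ids
        qc_ledger["review"] = {
            "agreement": review.agreement, "kappa": review.kappa,
            "n_reviewed": review.n_reviewed,
            "n_disagreements": review.n_disagreements,
            "reviewers": "simulated-from-ground-truth",
        }
        qc_ledger["sensitivity"] = filter_sensitivity(report, truth,
                                                      weights_kept)
    else:
        confirmed = set()
        qc_ledger["review"] = {"note": "no labels supplied; nothing removed"}

    cleaned, removal = drop_confirmed_errors(
        weights_kept, confirmed, n_flagged=report.summary["n_flagged_entries"])
    qc_ledger["removal"] = removal
    wio.write_weights(cleaned, out / "cleaned_weights.csv")
    wio.write_json(qc_ledger, out / "qc_ledger.json")
    log.info("stage=qc in_entries=%d flagged=%d removed=%d", len(weights),
             report.summary["n_flagged_entries"], removal["n_confirmed_erroneous"])
    return {"members_retained": retained, "cleaned": cleaned,
            "qc_ledger": qc_ledger, "flow": ledger}


def _stage_cohort(data: dict, qc: dict, out: Path) -> dict:
    cohort, ledger = build_cohort(qc["members_retained"], qc["cleaned"],
                                  data["logins"], ledger=qc["flow"])
    cohort.to_csv(out / "cohort.csv", index=False)
    wio.write_json(ledger.to_dict(), out / "flow_ledger.json")
    regain = fraction_documenting_regain(qc["cleaned"], cohort["member_id"])
    log.info("stage=cohort final_n=%d regain_frac=%.3f", len(cohort), regain)
    return {"cohort": cohort, "ledger": ledger, "regain_fraction": regain}


def _stage_features(data: dict, qc: dict, cohort: pd.DataFrame,
                    out: Path) -> pd.DataFrame:
    totals = assemble_totals(data["usage"], data["logins"], qc["cleaned"])
    features = build_features(totals, cohort)
    features.to_csv(out / "features.csv", index=False)
    log.info("stage=features rows=%d", len(features))
    return features


def _stage_analyze(config: PipelineConfig, data: dict, cohort: pd.DataFrame,
                   features: pd.DataFrame, out: Path) -> dict:
    frame = (cohort.merge(features, on="member_id", validate="one_to_one")
             .merge(data["members"][["member_id", "age", "sex", "reg_source",
                                     "region"]],
                    on="member_id", validate="one_to_one"))
    confounders, screen_p = screen_confounders(
        frame, CONFOUNDER_CANDIDATES, outcome="net_change_kg",
        alpha=config.screen_p)

    binary_fits = {
        flag: fit_univariable_adjusted(frame, flag, outcome="net_change_kg",
                                       adjust=confounders)
        for flag in BINARY_FLAGS}
    categorical_fits = {
        var: fit_univariable_adjusted(frame, var,
                                      outcome="change_per_30d_kg",
                                      adjust=confounders)
        for var in CATEGORICAL_PREDICTORS}
    stepwise = fit_stepwise(frame,
                            ["baseline_bmi"] + CATEGORICAL_PREDICTORS,
                            outcome="change_per_30d_kg",
                            retain_p=config.retain_p)
    models = {
        "confounder_screen": {"retained": confounders, "pvalues": screen_p},
        "binary": {k: v.to_dict() for k, v in binary_fits.items()},
        "categorical": {k: v.to_dict() for k, v in categorical_fits.items()},
        "stepwise": stepwise.to_dict(),
    }
    wio.write_json(models, out / "models.json")
    log.info("stage=analyze n=%d confounders=%s stepwise_kept=%s",
             len(frame), confounders, stepwise.variables())
    return {"models": models, "binary_fits": binary_fits,
            "categorical_fits": categorical_fits, "stepwise": stepwise,
            "frame": frame}


def _fits_table(fits: dict) -> str:
    rows = []
    for var, fit in fits.items():
        for t in fit.terms:
            rows.append({"variable": var, "term": t.term,
                         "coef_kg": round(t.coef, 2),
                         "ci": f"({t.ci_low:.2f}, {t.ci_high:.2f})",
                         "p": round(t.p, 4),
                         "overall_p": round(fit.overall_p.get(var, np.nan), 4)})
    return pd.DataFrame(rows).to_string(index=False)


def render_report(results: dict) -> str:
    """Plain-text summary of the full run."""
    parts = ["weightflow pipeline report", "=" * 26, ""]
    parts.append("Member flow:")
    parts.append(results["cohort_stage"]["ledger"].to_frame().to_string(index=False))
    qc = results["qc"]["qc_ledger"]
    parts.append("")
    parts.append(f"QC: {qc['filters']['n_flagged_entries']} flagged entries "
                 f"among {qc['filters']['n_flagged_members']} members; "
                 f"{qc['removal']['n_confirmed_erroneous']} confirmed erroneous "
                 f"({qc['removal']['pct_of_all_entries_removed']}% of all "
                 f"entries).")
    if "review" in qc and "kappa" in qc["review"]:
        parts.append(f"Review agreement {qc['review']['agreement']:.3f}, "
                     f"kappa {qc['review']['kappa']:.3f}.")
    if "sensitivity" in qc and qc["sensitivity"]["sensitivity_overall"] is not None:
        s = qc["sensitivity"]
        parts.append(f"Injected-error sensitivity: overall "
                     f"{s['sensitivity_overall']:.3f}, eligible "
                     f"{s['sensitivity_eligible']:.3f} "
                     f"(n={s['n_injected']}).")
    parts.append("")
    parts.append(f"Members documenting regain: "
                 f"{100 * results['cohort_stage']['regain_fraction']:.1f}%")
    parts.append("")
    parts.append("Net weight change by weight-entry span:")
    parts.append(stratify_by_span(results["cohort_stage"]["cohort"])
                 .to_string(index=False))
    analysis = results["analysis"]
    parts.append("")
    parts.append("Confounder screen retained: "
                 + (", ".join(analysis["models"]["confounder_screen"]["retained"])
                    or "(none)"))
    parts.append("")
    parts.append("Binary usage models (net change, kg):")
    parts.append(_fits_table(analysis["binary_fits"]))
    parts.append("")
    parts.append("Categorical usage models (kg per 30 days):")
    parts.append(_fits_table(analysis["categorical_fits"]))
    parts.append("")
    sw = analysis["stepwise"]
    parts.append(f"Stepwise final model (kg per 30 days), n={sw.n}: "
                 + (", ".join(sw.variables()) or "(intercept only)"))
    for t in sw.terms:
        parts.append(f"  {t.term}: {t.coef:.2f} kg "
                     f"({t.ci_low:.2f} to {t.ci_high:.2f}), p={t.p:.4g}")
    parts.append("  removal trace: "
                 + (", ".join(f"{v} (p={p:.3f})" for v, p in sw.removal_trace)
                    or "(nothing removed)"))
    return "\n".join(parts) + "\n"


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute all stages in order; returns the in-memory report bundle.

    On a stage failure, partial outputs are kept and ``MANIFEST.json``
    records which stages completed and which failed before the error is
    re-raised.
    """
    config.validate()
    if dry_run:
        return {"plan": STAGES}
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed = []
    results: dict = {}
    try:
        data = _stage_simulate(config, out)
        completed.append("simulate")
        results["qc"] = _stage_qc(config, data, out)
        completed.append("qc")
        results["cohort_stage"] = _stage_cohort(data, results["qc"], out)
        completed.append("cohort")
        features = _stage_features(data, results["qc"],
                                   results["cohort_stage"]["cohort"], out)
        results["features"] = features
        completed.append("features")
        results["analysis"] = _stage_analyze(
            config, data, results["cohort_stage"]["cohort"], features, out)
        completed.append("analyze")
        text = render_report(results)
        (out / "report.txt").write_text(text)
        results["report_text"] = text
        completed.append("report")
        wio.write_json({"completed": completed, "failed_stage": None},
                       out / "MANIFEST.json")
    except Exception as exc:
        failed = STAGES[len(completed)] if len(completed) < len(STAGES) else "?"
        wio.write_json({"completed": completed, "failed_stage": failed,
                        "error": f"{type(exc).__name__}: {exc}"},
                       out / "MANIFEST.json")
        raise
    return results
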