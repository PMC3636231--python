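"""Weight-entry quality control: baseline exclusions, filters F1-F4,
review resolution with inter-rater agreement, and confirmed-error removal.

The screening chain mirrors standard practice for self-reported weight
logs.  Members with impossible baseline attributes are excluded outright.
Remaining entries pass through four automated filters:

* F1 - per-member quadratic (OLS) trend; an entry is flagged when its
  residual exceeds both ``f1_sd_multiplier`` residual SDs and
  ``f1_abs_lb`` pounds.  Needs >= 3 weigh-in days (3 days interpolate
  exactly, so flags require >= 4).
* F2 - consecutive-pair relative rate; flags both entries of a pair whose
  change exceeds ``f2_frac_per_day`` of the earlier weight per day
  (strict inequality).  Needs >= 3 weigh-in days.
* F3 - any-pair absolute jump of ``f3_pair_lb`` or more (inclusive); both
  entries of every offending pair are flagged.  Needs >= 3 weigh-in days.
* F4 - member-level range: max - min over the whole record of
  ``f4_range_lb`` or more (inclusive); the extreme entries are flagged.
  Needs >= 2 weigh-in days.

Multiple same-day entries collapse to the last entry of the day before any
filter runs, so "entry days" is the unit throughout and day gaps are never
zero.  Automated flags go to two human reviewers; the module computes raw
agreement and Cohen's kappa, requires a consensus verdict wherever the
reviewers disagree, and removes only confirmed-erroneous entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import QCThresholds
from .errors import DataIntegrityError, UnresolvedEntriesError, ValidationError

FLAG_COLUMNS = ["filter_id", "member_id", "entry_id", "level", "detail"]


def collapse_same_day(entries: pd.DataFrame) -> pd.DataFrame:
    """Keep the last entry of each (member, day); stable in input order."""
    collapsed = (entries
                 .sort_values(["member_id", "day"], kind="mergesort")
                 .drop_duplicates(["member_id", "day"], keep="last"))
    return collapsed.reset_index(drop=True)


def apply_baseline_exclusions(members: pd.DataFrame, entries: pd.DataFrame,
                              thresholds: QCThresholds | None = None):
    """Exclude members with impossible baseline attributes.

    Rules: age above ``baseline_age_max``; height above
    ``baseline_height_max_in``; baseline weight outside
    [``baseline_weight_min_lb``, ``baseline_weight_max_lb``] *with no
    follow-up weight entries* (an extreme first weight followed by later
    entries is left for the entry filters to adjudicate).

    Returns ``(retained_members, exclusion_ledger)`` where the ledger has
    one row per excluded member with '|'-joined reasons.
    """
    thresholds = (thresholds or QCThresholds()).validate()
    orphans = set(entries["member_id"]) - set(members["member_id"])
    if orphans:
        raise DataIntegrityError(
            f"{len(orphans)} members have weight entries but no roster row: "
            f"{sorted(orphans)[:10]}")

    day_counts = (collapse_same_day(entries)
                  .groupby("member_id")["day"].nunique())
    n_days = members["member_id"].map(day_counts).fillna(0).astype(int)

    age_bad = members["age"] > thresholds.baseline_age_max
    height_bad = members["height_in"] > thresholds.baseline_height_max_in
    weight_extreme = ((members["weight_lb"] < thresholds.baseline_weight_min_lb)
                      | (members["weight_lb"] > thresholds.baseline_weight_max_lb))
    weight_bad = weight_extreme & (n_days <= 1)

    reasons = []
    for a, h, w in zip(age_bad, height_bad, weight_bad):
        r = [name for name, bad in (("age", a), ("height", h),
                                    ("baseline_weight", w)) if bad]
        reasons.append("|".join(r))
    reasons = pd.Series(reasons, index=members.index)
    excluded = reasons != ""
    ledger = pd.DataFrame({
        "member_id": members.loc[excluded, "member_id"].to_numpy(),
        "reason": reasons[excluded].to_numpy(),
    })
    return members.loc[~excluded].reset_index(drop=True), ledger


def _member_arrays(entries: pd.DataFrame):
    ordered = entries.sort_values("day", kind="mergesort")
    return (ordered["day"].to_numpy(dtype=float),
            ordered["weight_lb"].to_numpy(dtype=float),
            ordered["entry_id"].to_numpy(),
            ordered["member_id"].iloc[0] if len(ordered) else None)


def filter_f1_polynomial(entries: pd.DataFrame,
                         thresholds: QCThresholds | None = None) -> list[dict]:
    """Quadratic-trend residual filter for one member's day-collapsed entries.

    Fits weight = a + b*t + c*t^2 by OLS and flags entries whose absolute
    residual exceeds both ``f1_sd_multiplier`` times the residual SD
    (n-1 denominator) and ``f1_abs_lb`` pounds.  Fewer than 3 entry days
    yields no flags; exactly 3 interpolate exactly and also yield none.
    """
    thresholds = (thresholds or QCThresholds()).validate()
    days, weights, ids, member_id = _member_arrays(entries)
    n = len(days)
    if n < thresholds.min_entry_days_f123:
        return []
    t = days - days.mean()  # centering for conditioning; flags are unaffected
    coef = np.polynomial.polynomial.polyfit(t, weights, 2)
    residuals = weights - np.polynomial.polynomial.polyval(t, coef)
    sd = residuals.std(ddof=1)
    mask = ((np.abs(residuals) > thresholds.f1_sd_multiplier * sd)
            & (np.abs(residuals) > thresholds.f1_abs_lb))
    return [{"filter_id": "F1", "member_id": member_id, "entry_id": ids[i],
             "level": "entry", "detail": f"residual={residuals[i]:.1f}lb"}
            for i in np.flatnonzero(mask)]


def filter_f2_rate(entries: pd.DataFrame,
                   thresholds: QCThresholds | None = None) -> list[dict]:
    """Consecutive-pair relative-rate filter (> ``f2_frac_per_day`` of the
    earlier weight per day, strict).  Both entries of the pair are flagged."""
    thresholds = (thresholds or QCThresholds()).validate()
    days, weights, ids, member_id = _member_arrays(entries)
    if len(days) < thresholds.min_entry_days_f123:
        return []
    ddays = np.diff(days)
    if (ddays <= 0).any():
        raise ValidationError(
            "filter_f2_rate requires day-collapsed entries with distinct days")
    frac_per_day = np.abs(np.diff(weights)) / (weights[:-1] * ddays)
    flagged: dict = {}
    for i in np.flatnonzero(frac_per_day > thresholds.f2_frac_per_day):
        detail = f"{100 * frac_per_day[i]:.1f}%/day over {int(ddays[i])}d"
        for j in (i, i + 1):
            flagged.setdefault(ids[j], {"filter_id": "F2",
                                        "member_id": member_id,
                                        "entry_id": ids[j], "level": "entry",
                                        "detail": detail})
    return list(flagged.values())


def filter_f3_jump(entries: pd.DataFrame,
                   thresholds: QCThresholds | None = None) -> list[dict]:
    """Any-pair absolute-jump filter (>= ``f3_pair_lb``, inclusive).

    Scans all entry pairs, not only consecutive ones; both members of every
    offending pair are flagged, deduplicated per entry.
    """
    thresholds = (thresholds or QCThresholds()).validate()
    days, weights, ids, member_id = _member_arrays(entries)
    n = len(days)
    if n < thresholds.min_entry_days_f123:
        return []
    if weights.max() - weights.min() < thresholds.f3_pair_lb:
        return []
    diff = np.abs(weights[:, None] - weights[None, :])
    mask = np.any(diff >= thresholds.f3_pair_lb, axis=1)
    return [{"filter_id": "F3", "member_id": member_id, "entry_id": ids[i],
             "level": "entry",
             "detail": f"max|pair diff|={diff[i].max():.1f}lb"}
            for i in np.flatnonzero(mask)]


def filter_f4_range(entries: pd.DataFrame,
                    thresholds: QCThresholds | None = None) -> list[dict]:
    """Member-level range filter (max - min >= ``f4_range_lb``, inclusive).

    The flag is member-level; it is materialized on the argmax and argmin
    entries so the review workflow has concrete entries to adjudicate.
    """
    thresholds = (thresholds or QCThresholds()).validate()
    days, weights, ids, member_id = _member_arrays(entries)
    if len(days) < thresholds.min_entry_days_f4:
        return []
    span = weights.max() - weights.min()
    if span < thresholds.f4_range_lb:
        return []
    detail = f"range={span:.1f}lb"
    extremes = {int(np.argmin(weights)), int(np.argmax(weights))}
    return [{"filter_id": "F4", "member_id": member_id, "entry_id": ids[i],
             "level": "member", "detail": detail} for i in sorted(extremes)]


@dataclass
class FlagReport:
    """Union of filter flags with per-filter provenance and counts."""

    flags: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def flagged_entry_ids(self) -> set:
        return set(self.flags["entry_id"])


def run_all_filters(members: pd.DataFrame, entries: pd.DataFrame,
                    thresholds: QCThresholds | None = None) -> FlagReport:
    """Apply F1-F4 to every member's day-collapsed entries.

    Baseline exclusions are assumed already applied.  Deterministic on a
    fixed input.  The summary counts flagged entries once each even when
    several filters agree; per-filter counts keep full provenance.
    """
    thresholds = (thresholds or QCThresholds()).validate()
    collapsed = collapse_same_day(entries)
    rows: list[dict] = []
    for _, group in collapsed.groupby("member_id", sort=True):
        rows.extend(filter_f1_polynomial(group, thresholds))
        rows.extend(filter_f2_rate(group, thresholds))
        rows.extend(filter_f3_jump(group, thresholds))
        rows.extend(filter_f4_range(group, thresholds))
    flags = pd.DataFrame(rows, columns=FLAG_COLUMNS)
    summary = {
        "n_entries": int(len(entries)),
        "n_entry_days": int(len(collapsed)),
        "n_flagged_entries": int(flags["entry_id"].nunique()),
        "n_flagged_members": int(flags["member_id"].nunique()),
        "flags_per_filter": flags.groupby("filter_id")["entry_id"]
                                 .nunique().to_dict(),
    }
    return FlagReport(flags=flags, summary=summary)


def filter_sensitivity(report: FlagReport, entry_truth: pd.DataFrame,
                       entries: pd.DataFrame) -> dict:
    """Sensitivity of the filter union against injected-error ground truth.

    Reports both the overall sensitivity (all corrupted entries) and the
    sensitivity among *eligible* entries - those belonging to members with
    at least two weigh-in days, the minimum any filter is defined on.
    Corruptions in single-entry records are structurally undetectable by
    trajectory filters and never reach any analysis.
    """
    flagged = report.flagged_entry_ids()
    truth_ids = set(entry_truth["entry_id"])
    day_counts = collapse_same_day(entries).groupby("member_id")["day"].nunique()
    eligible_members = set(day_counts[day_counts >= 2].index)
    eligible_truth = set(
        entry_truth.loc[entry_truth["member_id"].isin(eligible_members),
                        "entry_id"])
    n_flagged = len(flagged)

    def _sens(ids: set):
        return len(ids & flagged) / len(ids) if ids else None

    return {
        "n_injected": len(truth_ids),
        "n_injected_eligible": len(eligible_truth),
        "sensitivity_overall": _sens(truth_ids),
        "sensitivity_eligible": _sens(eligible_truth),
        "precision": (len(truth_ids & flagged) / n_flagged
                      if n_flagged else None),
    }


def cohen_kappa(verdicts_a: pd.Series, verdicts_b: pd.Series) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    ``p_e`` comes from the reviewers' marginal verdict frequencies.  If both
    reviewers are constant and identical, agreement is perfect and kappa is
    1 by convention.
    """
    a = np.asarray(verdicts_a)
    b = np.asarray(verdicts_b)
    if len(a) != len(b) or len(a) == 0:
        raise ValidationError("kappa needs two equal-length, non-empty vectors")
    p_o = float(np.mean(a == b))
    labels = np.union1d(a, b)
    p_e = float(sum(np.mean(a == lab) * np.mean(b == lab) for lab in labels))
    if p_e >= 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ReviewOutcome:
    confirmed_entry_ids: set
    agreement: float
    kappa: float
    n_reviewed: int
    n_disagreements: int


def resolve_reviews(flagged_entry_ids, labels: pd.DataFrame,
                    consensus: pd.DataFrame | None = None,
                    erroneous_label: str = "erroneous") -> ReviewOutcome:
    """Combine two reviewers' verdicts on flagged entries.

    ``labels`` has columns ``entry_id, reviewer_id, verdict`` with verdicts
    in {'erroneous', 'valid'}; every flagged entry needs a label from each
    of exactly two reviewers.  Where the reviewers disagree, a consensus
    verdict (``consensus``: columns ``entry_id, verdict``) is required;
    entries lacking one raise :class:`UnresolvedEntriesError`.

    The confirmed-erroneous set is the union of concordant 'erroneous'
    verdicts and consensus 'erroneous' resolutions.
    """
    flagged = set(flagged_entry_ids)
    labels = labels.loc[labels["entry_id"].isin(flagged)]
    bad = set(labels["verdict"]) - {"erroneous", "valid"}
    if bad:
        raise ValidationError(f"unknown verdicts: {sorted(bad)}")
    reviewers = sorted(labels["reviewer_id"].unique())
    if len(reviewers) != 2:
        raise ValidationError(
            f"expected labels from exactly 2 reviewers, got {reviewers}")
    if labels.duplicated(["entry_id", "reviewer_id"]).any():
        raise ValidationError("duplicate (entry, reviewer) labels")
    table = labels.pivot(index="entry_id", columns="reviewer_id",
                         values="verdict")
    missing = sorted((flagged - set(table.index))
                     | set(table.index[table.isna().any(axis=1)]))
    if missing:
        raise ValidationError(
            f"{len(missing)} flagged entries lack labels from both "
            f"reviewers: {missing[:10]}")

    a, b = table[reviewers[0]], table[reviewers[1]]
    agreement = float((a == b).mean())
    kappa = cohen_kappa(a, b)
    concordant_err = set(table.index[(a == erroneous_label)
                                     & (b == erroneous_label)])
    discordant = set(table.index[a != b])

    consensus_err: set = set()
    if discordant:
        if consensus is None:
            raise UnresolvedEntriesError(discordant)
        cons = consensus.set_index("entry_id")["verdict"]
        unresolved = discordant - set(cons.index)
        if unresolved:
            raise UnresolvedEntriesError(unresolved)
        consensus_err = {e for e in discordant
                         if cons.loc[e] == erroneous_label}
    return ReviewOutcome(
        confirmed_entry_ids=concordant_err | consensus_err,
        agreement=agreement, kappa=kappa,
        n_reviewed=len(table), n_disagreements=len(discordant))


def drop_confirmed_errors(entries: pd.DataFrame, confirmed_entry_ids,
                          n_flagged: int | None = None):
    """Remove confirmed-erroneous entries; report removal accounting.

    Returns ``(cleaned_entries, ledger)``.  The ledger reports the removal
    percentage of all entries (two decimals) and, when the flagged count is
    supplied, the confirmed share of flagged entries (nearest integer
    percent).
    """
    confirmed = set(confirmed_entry_ids)
    known = set(entries["entry_id"])
    missing = confirmed - known
    if missing:
        raise DataIntegrityError(
            f"{len(missing)} confirmed entries absent from input: "
            f"{sorted(missing)[:10]}")
    cleaned = entries.loc[~entries["entry_id"].isin(confirmed)].reset_index(
        drop=True)
    n_total = len(entries)
    ledger = {
        "n_entries": n_total,
        "n_confirmed_erroneous": len(confirmed),
        "n_retained": len(cleaned),
        "pct_of_all_entries_removed": round(100.0 * len(confirmed) / n_total, 2)
                                      if n_total else 0.0,
    }
    if n_flagged is not None:
        ledger["n_flagged"] = int(n_flagged)
        ledger["pct_of_flagged_confirmed"] = (
            int(round(100.0 * len(confirmed) / n_flagged)) if n_flagged else 0)
    return cleaned, ledger
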