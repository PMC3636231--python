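"""Analyzable-cohort construction from cleaned weight entries.

Stages: require at least two distinct weigh-in days; apply the temporality
rule (the member's last weigh-in falls on or after their last log-in, so
all feature use happens between the first and last weight entries); derive
per-member outcomes.  A :class:`FlowLedger` accounts for every member at
every stage, conserving counts like a study flow diagram.

The baseline weight is the first cleaned weight entry; the roster's
registration weight is used only for baseline exclusions.  Net weight
change (kg) is last minus baseline; the per-30-day change divides the net
change by span/30, where span is the days between first and last weigh-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataIntegrityError, ValidationError
from .qc import collapse_same_day
from .units import KG_PER_LB, bmi_imperial

#: Span strata (days, inclusive upper bounds) for the descriptive
#: weight-change table.
SPAN_BINS = [(1, 30, "Up to 30 days"), (31, 60, "31-60 days"),
             (61, 90, "61-90 days"), (91, 183, "91-183 days"),
             (184, 365, "184-365 days"), (366, 548, "366-548 days"),
             (549, 829, "549-829 days"), (830, None, "830+ days")]


@dataclass
class FlowLedger:
    """Ordered stage accounting: entering and excluded counts per stage."""

    stages: list = field(default_factory=list)

    def add(self, stage: str, entering: int, excluded: int) -> None:
        if excluded < 0 or excluded > entering:
            raise ValidationError(
                f"stage {stage}: excluded ({excluded}) must be in "
                f"[0, entering={entering}]")
        if self.stages and entering != self.next_entering:
            raise ValidationError(
                f"stage {stage}: entering ({entering}) != previous stage's "
                f"retained count ({self.next_entering})")
        self.stages.append({"stage": stage, "entering": int(entering),
                            "excluded": int(excluded)})

    @property
    def next_entering(self) -> int:
        last = self.stages[-1]
        return last["entering"] - last["excluded"]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.stages)
        frame["retained"] = frame["entering"] - frame["excluded"]
        return frame

    def to_dict(self) -> dict:
        return {"stages": self.to_frame().to_dict(orient="records"),
                "final_n": self.next_entering if self.stages else 0}


def require_two_weigh_days(entries: pd.DataFrame) -> set:
    """Members with >= 2 distinct weigh-in days (entries day-collapsed)."""
    counts = collapse_same_day(entries).groupby("member_id")["day"].nunique()
    return set(counts[counts >= 2].index)


def apply_temporality_rule(member_ids, entries: pd.DataFrame,
                           logins: pd.DataFrame) -> set:
    """Retain members whose last log-in is on or before their last weigh-in.

    Because every website activity generates a date-stamped log-in, this
    guarantees all feature use occurred between the first and last weight
    entries, so usage precedes the measured outcome.
    """
    member_ids = set(member_ids)
    last_weigh = entries.groupby("member_id")["day"].max()
    last_login = logins.groupby("member_id")["day"].max()
    missing = member_ids - set(last_login.index)
    if missing:
        raise DataIntegrityError(
            f"{len(missing)} members have weight entries but no log-ins "
            f"(every weigh-in should generate a log-in): "
            f"{sorted(missing)[:10]}")
    return {m for m in member_ids if last_login.loc[m] <= last_weigh.loc[m]}


def compute_outcomes(members: pd.DataFrame, entries: pd.DataFrame,
                     cohort_ids=None) -> pd.DataFrame:
    """Per-member outcome rows for the analyzable cohort.

    Columns: first/last weigh-in day and weight, ``weight_entry_span``
    (days, >= 1), ``baseline_bmi`` (from the first entry weight and roster
    height, imperial formula), ``net_change_kg`` (last - baseline), and
    ``change_per_30d_kg`` (net / (span/30), exactly).
    """
    collapsed = collapse_same_day(entries)
    if cohort_ids is not None:
        collapsed = collapsed.loc[collapsed["member_id"].isin(set(cohort_ids))]
    heights = members.set_index("member_id")["height_in"]

    grouped = collapsed.sort_values(["member_id", "day"]).groupby("member_id")
    first = grouped.first()
    last = grouped.last()
    n_days = grouped["day"].nunique()
    if (n_days < 2).any():
        raise ValidationError(
            "compute_outcomes requires members with >= 2 weigh-in days")
    span = (last["day"] - first["day"]).astype(int)
    net_kg = (last["weight_lb"] - first["weight_lb"]) * KG_PER_LB
    out = pd.DataFrame({
        "member_id": first.index,
        "first_day": first["day"].astype(int).to_numpy(),
        "last_day": last["day"].astype(int).to_numpy(),
        "weight_entry_span": span.to_numpy(),
        "n_weight_entry_days": n_days.to_numpy(),
        "baseline_weight_lb": first["weight_lb"].to_numpy(),
        "last_weight_lb": last["weight_lb"].to_numpy(),
        "baseline_bmi": bmi_imperial(first["weight_lb"].to_numpy(),
                                     first.index.map(heights).to_numpy()),
        "net_change_kg": net_kg.to_numpy(),
    }).reset_index(drop=True)
    out["change_per_30d_kg"] = out["net_change_kg"] / (
        out["weight_entry_span"] / 30.0)
    return out


def stratify_by_span(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD of net weight change within span strata.

    Bin edges are inclusive of their printed upper bounds; the final
    open-ended bin catches any span beyond the usual follow-up horizon.
    SD is the n-1 sample SD, NaN for singleton bins.
    """
    if len(cohort) == 0:
        raise ValidationError("stratify_by_span needs a non-empty cohort")
    rows = []
    total = len(cohort)
    for lo, hi, label in SPAN_BINS:
        mask = cohort["weight_entry_span"] >= lo
        if hi is not None:
            mask &= cohort["weight_entry_span"] <= hi
        sub = cohort.loc[mask, "net_change_kg"]
        rows.append({
            "span_bin": label,
            "n": int(mask.sum()),
            "pct": round(100.0 * mask.sum() / total, 1),
            "mean_change_kg": float(sub.mean()) if len(sub) else np.nan,
            "sd_change_kg": float(sub.std(ddof=1)) if len(sub) > 1 else np.nan,
        })
    table = pd.DataFrame(rows)
    if table["n"].sum() != total:
        raise ValidationError("span bins must partition the cohort")
    return table


def fraction_documenting_regain(entries: pd.DataFrame, cohort_ids) -> float:
    """Fraction of cohort members with at least one weight higher than some
    earlier entry (i.e. whose day-collapsed series is not non-increasing)."""
    cohort_ids = set(cohort_ids)
    if not cohort_ids:
        raise ValidationError("cohort must be non-empty")
    collapsed = collapse_same_day(entries)
    collapsed = collapsed.loc[collapsed["member_id"].isin(cohort_ids)]
    regain = (collapsed.sort_values(["member_id", "day"])
              .groupby("member_id")["weight_lb"]
              .apply(lambda w: bool((np.diff(w.to_numpy()) > 0).any())))
    return float(regain.reindex(sorted(cohort_ids), fill_value=False).mean())


def build_cohort(members: pd.DataFrame, cleaned_entries: pd.DataFrame,
                 logins: pd.DataFrame,
                 ledger: FlowLedger | None = None):
    """Run the cohort stages in order, recording flow accounting.

    Returns ``(cohort_outcomes, ledger)``.  ``members`` must already have
    baseline exclusions applied; ``cleaned_entries`` must be QC-cleaned.
    """
    ledger = ledger if ledger is not None else FlowLedger()
    roster_ids = set(members["member_id"])
    entries = cleaned_entries.loc[
        cleaned_entries["member_id"].isin(roster_ids)]

    with_two = require_two_weigh_days(entries) & roster_ids
    ledger.add("two_or_more_weigh_days", len(roster_ids),
               len(roster_ids) - len(with_two))
    entries_two = entries.loc[entries["member_id"].isin(with_two)]

    final_ids = apply_temporality_rule(with_two, entries_two, logins)
    ledger.add("temporality_rule", len(with_two),
               len(with_two) - len(final_ids))

    cohort = compute_outcomes(members, entries_two, final_ids)
    return cohort, ledger
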