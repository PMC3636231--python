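"""Website-engagement predictors: binary (ever/never) and per-30-day
categorical codings of the eight usage variables.

Rates share the weight-entry span as the exposure denominator, keeping the
predictors and the per-30-day outcome on the same window.  Category
boundaries follow the weekly-use convention: "4 or more events per 30
days" approximates weekly use; exercise minutes use 120 min/30 d (four
half-hour sessions); activity points use 20/30 d; the friend count is
categorized on the raw total (0 / 1 / 2+), not per-30-days.

Boundary conventions: the ">=" level is inclusive at its threshold, the
"0" level requires an exactly zero count, and the middle level covers
everything in between.
"""

from __future__ import annotations

import pandas as pd

from .errors import DataIntegrityError, ValidationError
from .qc import collapse_same_day

#: Variables coded ever/never.  Log-in days, weigh-in days, and activity
#: points are excluded: cohort members all have two or more log-ins and
#: weigh-ins, and nearly all earn at least some points.
BINARY_FLAGS = {
    "any_food_day": "food_entry_days",
    "any_exercise_day": "exercise_entry_days",
    "any_exercise_minute": "exercise_minutes",
    "any_forum_post": "forum_posts",
    "any_friend": "friends",
}

#: (count column, category column, middle threshold, upper threshold,
#:  has explicit zero level)
RATE_CODINGS = [
    ("login_days", "login_days_cat", None, 4.0, False),
    ("weight_entry_days", "weight_entry_days_cat", None, 4.0, False),
    ("food_entry_days", "food_entry_days_cat", None, 4.0, True),
    ("exercise_entry_days", "exercise_entry_days_cat", None, 4.0, True),
    ("exercise_minutes", "exercise_minutes_cat", None, 120.0, True),
    ("sparkpoints", "sparkpoints_cat", None, 20.0, True),
    ("forum_posts", "forum_posts_cat", None, 4.0, True),
]

USAGE_COUNT_COLUMNS = ["login_days", "weight_entry_days", "food_entry_days",
                       "exercise_entry_days", "exercise_minutes",
                       "sparkpoints", "forum_posts", "friends"]


def assemble_totals(usage: pd.DataFrame, logins: pd.DataFrame,
                    entries: pd.DataFrame) -> pd.DataFrame:
    """Combine undated usage totals with dated log-in/weigh-in day counts.

    Enforces the structural invariant that weigh-in days cannot exceed
    log-in days (every weigh-in generates a log-in).
    """
    login_days = logins.groupby("member_id")["day"].nunique()
    weigh_days = (collapse_same_day(entries)
                  .groupby("member_id")["day"].nunique())
    totals = usage.copy()
    totals["login_days"] = totals["member_id"].map(login_days).fillna(0).astype(int)
    totals["weight_entry_days"] = (totals["member_id"].map(weigh_days)
                                   .fillna(0).astype(int))
    bad = totals["login_days"] < totals["weight_entry_days"]
    if bad.any():
        raise DataIntegrityError(
            f"{int(bad.sum())} members have more weigh-in days than log-in "
            f"days: {totals.loc[bad, 'member_id'].head(10).tolist()}")
    return totals


def _validate_counts(totals: pd.DataFrame) -> None:
    present = [c for c in USAGE_COUNT_COLUMNS if c in totals.columns]
    bad = (totals[present] < 0).any()
    if bad.any():
        raise ValidationError(
            f"negative usage counts in columns: {list(bad[bad].index)}")


def code_binary(totals: pd.DataFrame) -> pd.DataFrame:
    """Ever/never flags: true iff the member used the feature at least once."""
    _validate_counts(totals)
    out = pd.DataFrame({"member_id": totals["member_id"]})
    for flag, col in BINARY_FLAGS.items():
        out[flag] = (totals[col] >= 1).astype(bool)
    return out


def _rate_category(count, rate, upper: float, has_zero: bool) -> str:
    if has_zero and count == 0:
        return "0"
    if rate >= upper:
        return f">={upper:g}"
    return f"{'1' if has_zero else '0'} to <{upper:g}"


def rate_levels(upper: float, has_zero: bool) -> list[str]:
    """Ordered category labels, reference (least use) first."""
    if has_zero:
        return ["0", f"1 to <{upper:g}", f">={upper:g}"]
    return [f"0 to <{upper:g}", f">={upper:g}"]


def code_rates(totals: pd.DataFrame, spans: pd.Series) -> pd.DataFrame:
    """Per-30-day rates and thresholded categories.

    ``spans`` maps member_id to weight-entry span in days (>= 1).  Every
    member receives exactly one level per variable; the friend count is
    categorized on the raw total.
    """
    _validate_counts(totals)
    spans = pd.Series(spans)
    if (spans < 1).any():
        raise ValidationError("weight_entry_span must be >= 1 day")
    missing = set(totals["member_id"]) - set(spans.index)
    if missing:
        raise ValidationError(
            f"{len(missing)} members lack a span: {sorted(missing)[:10]}")

    out = pd.DataFrame({"member_id": totals["member_id"]})
    span_days = totals["member_id"].map(spans).to_numpy(dtype=float)
    for count_col, cat_col, _, upper, has_zero in RATE_CODINGS:
        counts = totals[count_col].to_numpy(dtype=float)
        rates = counts / (span_days / 30.0)
        out[count_col + "_per30"] = rates
        labels = [_rate_category(c, r, upper, has_zero)
                  for c, r in zip(counts, rates)]
        out[cat_col] = pd.Categorical(labels,
                                      categories=rate_levels(upper, has_zero),
                                      ordered=True)
    friends = totals["friends"].to_numpy()
    out["friends_cat"] = pd.Categorical(
        ["0" if f == 0 else "1" if f == 1 else ">=2" for f in friends],
        categories=["0", "1", ">=2"], ordered=True)
    return out


#: Categorical predictors entering the multivariable model, in declared
#: order (used for deterministic tie-breaking during stepwise selection).
CATEGORICAL_PREDICTORS = ["login_days_cat", "weight_entry_days_cat",
                          "food_entry_days_cat", "exercise_entry_days_cat",
                          "exercise_minutes_cat", "sparkpoints_cat",
                          "forum_posts_cat", "friends_cat"]


def build_features(totals: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    """One row per cohort member: binary flags, rates, category labels."""
    cohort_totals = totals.loc[
        totals["member_id"].isin(set(cohort["member_id"]))]
    spans = cohort.set_index("member_id")["weight_entry_span"]
    binary = code_binary(cohort_totals)
    rates = code_rates(cohort_totals, spans)
    return binary.merge(rates, on="member_id", validate="one_to_one")
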