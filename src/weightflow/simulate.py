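"""Synthetic member rosters, event logs, and usage totals with ground truth.

The generator emulates the data structure of a free, self-directed online
weight-loss program: a roster of mostly female members with obese-range
baseline BMI, date-stamped log-in and weigh-in events with rapid attrition,
undated right-skewed usage totals, and self-reported weights subject to
data-entry errors (digit omission/addition/transposition and large jumps).

Two things make the output useful for testing rather than just plausible:

* every injected corruption is recorded in a ground-truth table, so filter
  sensitivity and precision can be measured exactly; and
* each member's weight trajectory is generated from a known per-30-day
  drift that switches on the member's *realized* weigh-in rate (>= 4 weigh
  days per 30 days), plus one-time net shifts tied to baseline BMI and
  forum use, so the downstream regressions have recoverable true
  coefficients.

Weight dynamics are a linear drift plus a Brownian component (variance
growing linearly in time) sampled at weigh-in days, plus i.i.d. 1-lb
measurement noise per entry.  The Brownian term reproduces the empirical
pattern that the spread of total weight change grows roughly with the
square root of the observation span.

Dates are integer day offsets from a study epoch; calendar rendering
happens only at I/O time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimConfig
from .errors import ConfigurationError
from .units import KG_PER_LB, LB_PER_KG, bmi_imperial

#: Minimum recordable entry weight (lb); keeps noisy entries positive.
_MIN_ENTRY_LB = 20.0

_MEMBER_STREAM, _EVENT_STREAM, _ERROR_STREAM = 0, 1, 2


def _stream(config: SimConfig, index: int) -> np.random.Generator:
    """Deterministic per-module substream of the config's master seed."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(int(config.seed)).spawn(3)[index]))


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal draws."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def generate_members(config: SimConfig) -> pd.DataFrame:
    """Draw the member roster.

    Returns a frame with columns ``member_id, age, sex, height_in,
    weight_lb, reg_date, reg_source, region``.  Ages and BMIs come from
    truncated normals; heights are sex-specific truncated normals within
    the plausible 49-78 in range; the baseline weight is derived from the
    sampled BMI and height.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = _stream(config, _MEMBER_STREAM)
    n = config.n_members

    sex = np.where(rng.random(n) < config.frac_female, "female", "male")
    age = _truncated_normal(rng, config.age_mean, config.age_sd,
                            *config.age_bounds, n)
    height = np.empty(n)
    fem = sex == "female"
    height[fem] = _truncated_normal(rng, config.height_female_mean,
                                    config.height_female_sd,
                                    *config.height_bounds, int(fem.sum()))
    height[~fem] = _truncated_normal(rng, config.height_male_mean,
                                     config.height_male_sd,
                                     *config.height_bounds, int((~fem).sum()))
    bmi = _truncated_normal(rng, config.bmi_mean, config.bmi_sd,
                            *config.bmi_bounds, n)
    weight_lb = bmi * height ** 2 / 703.0

    reg_date = rng.integers(0, config.registration_window_days + 1, n)
    sources = list(config.reg_source_probs)
    reg_source = rng.choice(sources, n, p=[config.reg_source_probs[s]
                                           for s in sources])
    regions = list(config.region_probs)
    region = rng.choice(regions, n, p=[config.region_probs[r] for r in regions])

    width = max(6, len(str(n)))
    member_id = np.array([f"M{i:0{width}d}" for i in range(1, n + 1)])
    return pd.DataFrame({
        "member_id": member_id,
        "age": np.round(age, 1),
        "sex": sex,
        "height_in": np.round(height, 1),
        "weight_lb": np.round(weight_lb, 1),
        "reg_date": reg_date.astype(int),
        "reg_source": reg_source,
        "region": region,
    })


def _login_days(rng, cls, config, reg_day: int) -> np.ndarray:
    """Absolute log-in days for one member (geometric attrition, gapped)."""
    k = config.min_login_days + int(rng.geometric(cls.attrition_p)) - 1
    if k == 1:
        return np.array([reg_day])
    extra_mean = cls.gap_mean - cls.gap_min
    p_gap = 1.0 / (extra_mean + 1.0)
    gaps = cls.gap_min + rng.geometric(p_gap, k - 1) - 1
    days = reg_day + np.concatenate([[0], np.cumsum(gaps)])
    return days[days <= config.study_end_day]


def _usage_totals(rng, n_logins: int, rates: dict) -> dict:
    """Right-skewed, zero-inflated usage totals for one member."""
    def zi_count(zero_p, mean, cap=None):
        if rng.random() < zero_p:
            return 0
        val = int(rng.geometric(1.0 / mean))
        return min(val, cap) if cap is not None else val

    food = zi_count(rates["food_zero_p"], rates["food_mean"], cap=n_logins)
    exercise = zi_count(rates["exercise_zero_p"], rates["exercise_mean"],
                        cap=n_logins)
    minutes = 0
    if exercise > 0:
        # entries may omit a duration, so minutes can be 0 with days > 0
        recorded = int(rng.binomial(exercise, rates["minutes_record_p"]))
        if recorded > 0:
            per_day = rng.lognormal(
                np.log(rates["exercise_minutes_per_day"]), 0.8, recorded)
            minutes = int(np.round(per_day.sum()))
    forum = zi_count(rates["forum_zero_p"], rates["forum_mean"])
    friends = zi_count(rates["friends_zero_p"], rates["friends_mean"])
    points = 0
    if rng.random() >= rates["points_zero_p"]:
        points = int(np.round(n_logins * rng.gamma(
            rates["points_per_login_shape"], rates["points_per_login_scale"])))
    return {"food_entry_days": food, "exercise_entry_days": exercise,
            "exercise_minutes": minutes, "sparkpoints": points,
            "forum_posts": forum, "friends": friends}


def generate_event_logs(members: pd.DataFrame, config: SimConfig):
    """Generate weigh-in entries, log-in events, usage totals, and truth.

    Returns ``(weights, logins, usage, member_truth)``.  Invariants by
    construction: every weigh-in day is also a log-in day for that member;
    no event predates registration; the first log-in always records the
    baseline weight.  Weights here are uncorrupted; see
    :func:`inject_errors`.
    """
    config.validate()
    if len(members) == 0:
        raise ConfigurationError("members: roster must be non-empty")
    rng = _stream(config, _EVENT_STREAM)

    weight_rows, login_rows, usage_rows, truth_rows = [], [], [], []
    entry_counter = 0
    walk_sd_lb = config.walk_sd_kg * LB_PER_KG
    floor_lb = config.floor_kg * LB_PER_KG

    for member_id, base_lb, height_in, reg_day in zip(
            members["member_id"].to_numpy(),
            members["weight_lb"].to_numpy(),
            members["height_in"].to_numpy(),
            members["reg_date"].to_numpy()):
        is_frequent = rng.random() < config.frac_frequent
        cls = config.frequent if is_frequent else config.casual
        days = _login_days(rng, cls, config, int(reg_day))
        n_logins = len(days)

        # weigh-in days: baseline on the first log-in, then propensity-driven
        weigh_mask = np.concatenate(
            [[True], rng.random(n_logins - 1) < cls.weigh_propensity])
        weigh_days = days[weigh_mask]

        # interior browse-only visits (site use without touching the scale)
        if cls.browse_insert_p > 0 and n_logins >= 2:
            gaps = np.diff(days)
            extra = []
            for start, gap in zip(days[:-1], gaps):
                if gap >= 2 and rng.random() < cls.browse_insert_p:
                    extra.append(start + int(rng.integers(1, gap)))
            if extra:
                days = np.unique(np.concatenate([days, extra]))
                n_logins = len(days)
        n_weigh = len(weigh_days)
        span = int(weigh_days[-1] - weigh_days[0]) if n_weigh >= 2 else 0
        rate = n_weigh / (span / 30.0) if span > 0 else 0.0
        is_freq_realized = bool(span > 0 and
                                rate >= config.weigh_rate_threshold_per30)

        usage = _usage_totals(rng, n_logins, config.usage_rates)

        drift_kg30 = (config.rate_intercept_kg30
                      + (config.true_beta_weigh_freq if is_freq_realized else 0.0)
                      + rng.normal(0.0, config.drift_sd_kg30))
        bmi = bmi_imperial(base_lb, height_in)
        # effects are centered contrasts: posters sit beta_forum_kg below
        # non-posters (and each BMI unit beta_bmi_kg below the mean) without
        # shifting the population-average trajectory
        forum_p = 1.0 - config.usage_rates["forum_zero_p"]
        forum_ind = 1.0 if usage["forum_posts"] >= 1 else 0.0
        delta_fixed_kg = (config.beta_bmi_kg * (bmi - config.bmi_mean)
                          + config.beta_forum_kg * (forum_ind - forum_p))

        offs = weigh_days - weigh_days[0]
        walk_lb = np.zeros(n_weigh)
        if n_weigh >= 2:
            increments = rng.normal(
                0.0, walk_sd_lb * np.sqrt(np.diff(offs) / 30.0))
            walk_lb[1:] = np.cumsum(increments)
        drift_lb30 = drift_kg30 * LB_PER_KG
        delta_lb = delta_fixed_kg * LB_PER_KG
        drift_days = np.minimum(offs, config.drift_plateau_days)
        true_lb = base_lb + walk_lb + drift_lb30 * drift_days / 30.0
        true_lb[1:] += delta_lb
        np.maximum(true_lb, floor_lb, out=true_lb)
        entry_lb = true_lb + rng.normal(0.0, config.measurement_sd_lb, n_weigh)
        np.maximum(entry_lb, _MIN_ENTRY_LB, out=entry_lb)

        for day, w in zip(weigh_days, entry_lb):
            entry_counter += 1
            weight_rows.append((f"E{entry_counter:07d}", member_id, int(day),
                               round(float(w), 1)))
        login_rows.extend((member_id, int(d)) for d in days)
        usage_rows.append({"member_id": member_id, **usage})
        truth_rows.append({
            "member_id": member_id,
            "engagement_class": "frequent" if is_frequent else "casual",
            "frequent_weigher": is_freq_realized,
            "drift_kg30": drift_kg30,
            "delta_fixed_kg": delta_fixed_kg,
            "n_weigh_days": n_weigh,
            "weigh_span_days": span,
        })

    weights = pd.DataFrame(weight_rows,
                           columns=["entry_id", "member_id", "day", "weight_lb"])
    logins = pd.DataFrame(login_rows, columns=["member_id", "day"])
    usage = pd.DataFrame(usage_rows)
    member_truth = pd.DataFrame(truth_rows)
    return weights, logins, usage, member_truth


_ENTRY_TRUTH_COLUMNS = ["entry_id", "member_id", "day", "true_weight_lb",
                        "corrupted_weight_lb", "error_type", "erroneous"]


def _corrupt_digits(rng, value_lb: float, mechanism: str, config: SimConfig):
    """Apply one corruption mechanism; returns the corrupted value or None
    if the mechanism cannot produce a changed positive value here."""
    if mechanism == "jump":
        magnitude = value_lb * rng.uniform(config.jump_frac_min,
                                           config.jump_frac_max)
        sign = -1.0 if rng.random() < 0.5 else 1.0
        corrupted = value_lb + sign * magnitude
        if corrupted <= 0:
            corrupted = value_lb + magnitude
        return round(corrupted, 1)

    digits = str(int(round(value_lb)))
    if mechanism == "omit_digit":
        if len(digits) < 2:
            return None
        pos = int(rng.integers(len(digits)))
        out = digits[:pos] + digits[pos + 1:]
        corrupted = int(out)
    elif mechanism == "add_digit":
        pos = int(rng.integers(len(digits) + 1))
        low = 1 if pos == 0 else 0
        out = digits[:pos] + str(int(rng.integers(low, 10))) + digits[pos:]
        corrupted = int(out)
    elif mechanism == "transpose_digits":
        # swap the leading two digits (e.g. 185 -> 815); swapping equal
        # digits or creating a leading zero is no corruption - resample
        if len(digits) < 2 or digits[0] == digits[1] or digits[1] == "0":
            return None
        swapped = digits[1] + digits[0] + digits[2:]
        corrupted = int(swapped)
    else:  # pragma: no cover - guarded by config validation
        raise ConfigurationError(f"error_mix: unknown mechanism {mechanism}")
    if corrupted <= 0 or corrupted == int(round(value_lb)):
        return None
    return float(corrupted)


def inject_errors(entries: pd.DataFrame, config: SimConfig,
                  rng: np.random.Generator | None = None):
    """Corrupt ``round(error_rate * n)`` weight entries and record them.

    Returns ``(corrupted_entries, entry_truth)``.  Each corrupted entry gets
    exactly one ground-truth record with the original and corrupted values
    and the mechanism used.  A corruption is required to change the value
    and keep it positive; mechanisms that cannot do so for a particular
    value (e.g. transposing equal digits) are resampled.
    """
    config.validate()
    if (entries["weight_lb"] <= 0).any():
        raise ConfigurationError("entries: weights must be positive")
    if rng is None:
        rng = _stream(config, _ERROR_STREAM)

    n_corrupt = int(round(config.error_rate * len(entries)))
    out = entries.copy()
    if n_corrupt == 0:
        return out, pd.DataFrame(columns=_ENTRY_TRUTH_COLUMNS)

    mechanisms = list(config.error_mix)
    probs = np.array([config.error_mix[m] for m in mechanisms])
    targets = rng.choice(len(entries), size=n_corrupt, replace=False)
    truth_rows = []
    weights = out["weight_lb"].to_numpy(copy=True)
    for idx in np.sort(targets):
        original = float(weights[idx])
        corrupted, mech = None, None
        while corrupted is None:
            mech = mechanisms[int(rng.choice(len(mechanisms), p=probs))]
            corrupted = _corrupt_digits(rng, original, mech, config)
        weights[idx] = corrupted
        row = out.iloc[idx]
        truth_rows.append((row["entry_id"], row["member_id"], row["day"],
                           original, corrupted, mech, True))
    out["weight_lb"] = weights
    truth = pd.DataFrame(truth_rows, columns=_ENTRY_TRUTH_COLUMNS)
    return out, truth


@dataclass
class SimResult:
    """Bundle of all generated tables for one simulated study."""

    config: SimConfig
    members: pd.DataFrame
    weights: pd.DataFrame          # possibly corrupted, per config.error_rate
    logins: pd.DataFrame
    usage: pd.DataFrame
    member_truth: pd.DataFrame
    entry_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the full generator: roster, events, usage, and error injection."""
    members = generate_members(config)
    weights, logins, usage, member_truth = generate_event_logs(members, config)
    weights, entry_truth = inject_errors(weights, config)
    return SimResult(config=config, members=members, weights=weights,
                     logins=logins, usage=usage, member_truth=member_truth,
                     entry_truth=entry_truth)
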