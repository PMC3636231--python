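"""Configuration dataclasses for simulation, QC thresholds, and the pipeline.

Every threshold that appears in the screening and analysis logic lives here
with its default; nothing is hard-coded in the operating code.  The
simulation defaults encode the study conditions the generator emulates: a
heavily female membership (~90.7%), age ~34 (SD 11), baseline BMI ~32
(SD 8), rapid attrition with most members recording very few weigh-ins,
right-skewed usage with a point mass at zero for social features, and an
engagement-linked weight-change signal with known coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import ConfigurationError


def _check(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"{name}: {msg}")


@dataclass
class EngagementClass:
    """Event-process parameters for one latent engagement stratum.

    Attrition is a per-log-in geometric stopping process: after each log-in
    the member quits with probability ``attrition_p``.  Gaps between
    successive log-ins are ``gap_min + Geometric`` days with mean
    ``gap_mean``.  Each log-in after the first includes a weigh-in with
    probability ``weigh_propensity`` (the first log-in always records the
    baseline weight).  ``browse_insert_p`` adds, per inter-log-in gap, an
    extra browse-only visit on an interior day - site use that never
    touches the scale.
    """

    attrition_p: float = 0.20
    gap_min: int = 12
    gap_mean: float = 50.0
    weigh_propensity: float = 0.12
    browse_insert_p: float = 0.0

    def validate(self, name: str) -> None:
        _check(0 < self.attrition_p <= 1, f"{name}.attrition_p", "must be in (0, 1]")
        _check(self.gap_min >= 1, f"{name}.gap_min", "must be >= 1 day")
        _check(self.gap_mean >= self.gap_min, f"{name}.gap_mean",
               "must be >= gap_min")
        _check(0 <= self.weigh_propensity <= 1, f"{name}.weigh_propensity",
               "must be a proportion in [0, 1]")
        _check(0 <= self.browse_insert_p <= 1, f"{name}.browse_insert_p",
               "must be a proportion in [0, 1]")


#: Default mix of corruption mechanisms for injected weight-entry errors.
DEFAULT_ERROR_MIX = {
    "omit_digit": 0.30,
    "add_digit": 0.30,
    "transpose_digits": 0.30,
    "jump": 0.10,
}

#: Registration-source and region marginals.  The source mix is a stated
#: default (no empirical distribution is available); the region mix follows
#: the membership profile the generator emulates.
DEFAULT_REG_SOURCE_PROBS = {"friend": 0.30, "search_ad": 0.50, "other": 0.20}
DEFAULT_REGION_PROBS = {
    "US-Midwest": 0.231,
    "US-Northeast": 0.149,
    "US-South": 0.318,
    "US-West": 0.167,
    "other-country": 0.135,
}

#: Undated usage-total parameters (zero-inflation probability and mean of
#: the positive part); forum posts and friendships have large point masses
#: at zero, matching the heavy skew of social-feature use.
DEFAULT_USAGE_RATES = {
    "food_zero_p": 0.35,
    "food_mean": 6.0,
    "exercise_zero_p": 0.45,
    "exercise_mean": 5.0,
    "exercise_minutes_per_day": 35.0,
    # an exercise diary entry can be logged without a duration, so total
    # minutes may be zero even when entry days are not
    "minutes_record_p": 0.85,
    "forum_zero_p": 0.80,
    "forum_mean": 6.0,
    "friends_zero_p": 0.60,
    "friends_mean": 2.5,
    "points_zero_p": 0.05,
    "points_per_login_shape": 2.0,
    "points_per_login_scale": 8.0,
}


@dataclass
class SimConfig:
    """Full parameterization of the synthetic-data generator.

    Weight-change truth
    -------------------
    Each member carries a per-30-day drift (kg):

        drift = rate_intercept_kg30
                + true_beta_weigh_freq * 1{realized weigh-in rate >= 4/30 d}
                + Normal(0, drift_sd_kg30)

    plus a Brownian wander of ``walk_sd_kg`` per sqrt(30 d), a one-time net
    shift of ``beta_bmi_kg * (BMI - bmi_mean) + beta_forum_kg * 1{any forum
    post}`` applied after the baseline entry, and i.i.d. per-entry
    measurement noise of ``measurement_sd_lb``.  The three beta defaults are
    the effect sizes the recovery tests target.
    """

    n_members: int = 26582
    seed: int = 0

    # roster demographics
    frac_female: float = 0.907
    age_mean: float = 33.6
    age_sd: float = 11.0
    age_bounds: tuple = (18.0, 100.0)
    bmi_mean: float = 31.6
    bmi_sd: float = 7.7
    bmi_bounds: tuple = (16.0, 75.0)
    height_female_mean: float = 64.5
    height_female_sd: float = 2.6
    height_male_mean: float = 69.5
    height_male_sd: float = 2.8
    height_bounds: tuple = (49.0, 78.0)
    reg_source_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_REG_SOURCE_PROBS))
    region_probs: dict = field(default_factory=lambda: dict(DEFAULT_REGION_PROBS))

    # study window: day 0 is the opening of the registration window; members
    # register uniformly within registration_window_days and events run
    # through study_end_day (830 d ~ a 27-month follow-up).
    registration_window_days: int = 89
    study_end_day: int = 830

    # event process: a small "frequent-weigher" stratum with tight log-in
    # gaps and high weigh-in propensity, embedded in a casual majority.
    frac_frequent: float = 0.08
    min_login_days: int = 1
    casual: EngagementClass = field(default_factory=EngagementClass)
    frequent: EngagementClass = field(default_factory=lambda: EngagementClass(
        attrition_p=0.08, gap_min=4, gap_mean=5.5, weigh_propensity=0.90))

    # weight-change truth (kg scale)
    rate_intercept_kg30: float = -0.15
    true_beta_weigh_freq: float = -5.09
    beta_forum_kg: float = -1.55
    beta_bmi_kg: float = -0.28
    weigh_rate_threshold_per30: float = 4.0
    drift_sd_kg30: float = 0.5
    #: weight-loss drift flattens after this many days (the familiar
    #: plateau after roughly six months of active loss)
    drift_plateau_days: float = 180.0
    walk_sd_kg: float = 1.2
    measurement_sd_lb: float = 1.0
    floor_kg: float = 25.0

    # undated usage totals
    usage_rates: dict = field(default_factory=lambda: dict(DEFAULT_USAGE_RATES))

    # data-entry error injection; jumps are a fraction of the current
    # weight, so every mechanism produces a gross distortion
    error_rate: float = 0.002
    error_mix: dict = field(default_factory=lambda: dict(DEFAULT_ERROR_MIX))
    jump_frac_min: float = 0.5
    jump_frac_max: float = 1.0

    def validate(self) -> "SimConfig":
        _check(self.n_members >= 1, "n_members", "must be >= 1")
        _check(int(self.seed) == self.seed, "seed", "must be an integer")
        for name in ("frac_female", "frac_frequent", "error_rate"):
            v = getattr(self, name)
            _check(0 <= v <= 1, name, "must be a proportion in [0, 1]")
        for name in ("age_sd", "bmi_sd", "height_female_sd", "height_male_sd",
                     "drift_sd_kg30", "walk_sd_kg", "measurement_sd_lb"):
            _check(getattr(self, name) > 0, name, "must be > 0")
        _check(self.min_login_days >= 1, "min_login_days", "must be >= 1")
        _check(self.study_end_day > self.registration_window_days,
               "study_end_day", "must exceed the registration window")
        self.casual.validate("casual")
        self.frequent.validate("frequent")
        mix_total = sum(self.error_mix.values())
        _check(abs(mix_total - 1.0) < 1e-9, "error_mix", "must sum to 1")
        _check(all(v >= 0 for v in self.error_mix.values()),
               "error_mix", "proportions must be non-negative")
        unknown = set(self.error_mix) - set(DEFAULT_ERROR_MIX)
        _check(not unknown, "error_mix", f"unknown mechanisms {sorted(unknown)}")
        _check(0 < self.jump_frac_min <= self.jump_frac_max, "jump_frac_min",
               "jump fractions must satisfy 0 < min <= max")
        _check(self.drift_plateau_days > 0, "drift_plateau_days", "must be > 0")
        for probs, name in ((self.reg_source_probs, "reg_source_probs"),
                            (self.region_probs, "region_probs")):
            _check(abs(sum(probs.values()) - 1.0) < 1e-9, name, "must sum to 1")
        return self

    @classmethod
    def cohort_scale(cls, n_members: int = 1258, seed: int = 0,
                     **overrides) -> "SimConfig":
        """Parameter-recovery study condition at final-cohort scale.

        Every member logs in on at least 3 days and weighs in at every
        log-in, so baseline exclusions, the two-weigh-day rule, and the
        temporality rule pass everyone and the analyzed cohort size equals
        ``n_members`` exactly.  The casual stratum's minimum weigh-in gap of
        12 days guarantees a casual member can never realize a weigh-in rate
        of 4+/30 d (30/12 * K/(K-1) < 4 for K >= 3 weigh days), so the
        frequent-weigher contrast is carried by the engaged stratum
        (~19% of members).  Interior browse-only visits keep log-in days
        strictly informative beyond weigh-in days.  Attrition is set so the
        two strata have comparable span distributions and per-30-day drift
        exposure stays well above the physiological floor, and the noise
        mix (between-member rate SD 2.5 kg/30 d, within-trajectory wander
        1 kg per sqrt(30 d)) keeps the per-30-day regression error
        dominated by its homoskedastic between-member component - the
        regime in which classical OLS intervals are calibrated and
        interval-coverage testing of the estimation chain is meaningful.
        Error injection is off: recovery isolates the estimation chain
        from the QC chain.
        """
        cfg = cls(
            n_members=n_members,
            seed=seed,
            frac_frequent=0.19,
            min_login_days=4,
            casual=EngagementClass(attrition_p=0.25, gap_min=12, gap_mean=13.5,
                                   weigh_propensity=1.0, browse_insert_p=0.5),
            frequent=EngagementClass(attrition_p=0.10, gap_min=4, gap_mean=7.0,
                                     weigh_propensity=1.0, browse_insert_p=0.5),
            drift_sd_kg30=2.5,
            drift_plateau_days=100000.0,  # linear drift throughout: the
            # recovery condition's per-30-day truths are exact at any span
            walk_sd_kg=1.0,
            error_rate=0.0,
        )
        for key, val in overrides.items():
            if not hasattr(cfg, key):
                raise ConfigurationError(f"unknown SimConfig field: {key}")
            setattr(cfg, key, val)
        return cfg.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        data = dict(data)
        preset = data.pop("preset", None)
        if preset is not None:
            if preset != "cohort_scale":
                raise ConfigurationError(f"unknown preset: {preset}")
            base = cls.cohort_scale().to_dict()
            base.update(data)
            data = base
        for key in ("casual", "frequent"):
            if key in data and isinstance(data[key], dict):
                data[key] = EngagementClass(**data[key])
        for key in ("age_bounds", "bmi_bounds", "height_bounds"):
            if key in data:
                data[key] = tuple(data[key])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**data).validate()


@dataclass
class QCThresholds:
    """Screening thresholds; defaults are the published filter settings."""

    f1_sd_multiplier: float = 3.0
    f1_abs_lb: float = 10.0
    f2_frac_per_day: float = 0.02
    f3_pair_lb: float = 50.0
    f4_range_lb: float = 100.0
    min_entry_days_f123: int = 3
    min_entry_days_f4: int = 2
    baseline_age_max: float = 100.0
    baseline_height_max_in: float = 120.0
    baseline_weight_min_lb: float = 100.0
    baseline_weight_max_lb: float = 800.0

    def validate(self) -> "QCThresholds":
        for name in ("f1_sd_multiplier", "f1_abs_lb", "f2_frac_per_day",
                     "f3_pair_lb", "f4_range_lb"):
            _check(getattr(self, name) > 0, name, "must be > 0")
        _check(self.min_entry_days_f123 >= 3, "min_entry_days_f123",
               "polynomial/rate/jump filters need >= 3 entry days")
        _check(self.min_entry_days_f4 >= 2, "min_entry_days_f4",
               "range filter needs >= 2 entry days")
        _check(self.baseline_weight_min_lb < self.baseline_weight_max_lb,
               "baseline_weight_min_lb", "must be < baseline_weight_max_lb")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "QCThresholds":
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(
                f"unknown QCThresholds fields: {sorted(unknown)}")
        return cls(**data).validate()


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (simulate -> qc -> cohort -> features ->
    analyze -> report)."""

    out_dir: str = "weightflow_out"
    in_dir: Optional[str] = None  # read CSVs here instead of simulating
    seed: int = 0
    simulate: SimConfig = field(default_factory=SimConfig)
    ground_truth: bool = True
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    #: Probability that a simulated reviewer mislabels a flagged entry
    #: relative to ground truth (emulates the manual-review step).
    reviewer_flip_p: float = 0.025
    screen_p: float = 0.05
    retain_p: float = 0.20

    def validate(self) -> "PipelineConfig":
        _check(0 < self.screen_p < 1, "screen_p", "must be in (0, 1)")
        _check(0 < self.retain_p < 1, "retain_p", "must be in (0, 1)")
        _check(0 <= self.reviewer_flip_p < 0.5, "reviewer_flip_p",
               "must be in [0, 0.5)")
        self.simulate.validate()
        self.thresholds.validate()
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "simulate" in data and isinstance(data["simulate"], dict):
            data["simulate"] = SimConfig.from_dict(data["simulate"])
        if "thresholds" in data and isinstance(data["thresholds"], dict):
            data["thresholds"] = QCThresholds.from_dict(data["thresholds"])
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(
                f"unknown PipelineConfig fields: {sorted(unknown)}")
        return cls(**data).validate()
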