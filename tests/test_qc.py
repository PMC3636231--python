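"""Quality control: baseline exclusions, the four trajectory filters
against brute-force oracles, review resolution, and removal accounting."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from weightflow import (DataIntegrityError, QCThresholds,
                        UnresolvedEntriesError, ValidationError,
                        apply_baseline_exclusions, cohen_kappa,
                        collapse_same_day, drop_confirmed_errors,
                        filter_f1_polynomial, filter_f2_rate, filter_f3_jump,
                        filter_f4_range, resolve_reviews, run_all_filters)
from conftest import (entries_frame, members_frame, oracle_jump_flags,
                      oracle_quadratic_flags, oracle_range_flag,
                      oracle_rate_flags)


class TestBaselineExclusions:
    def test_age_above_100_excluded(self):
        members = members_frame(["M1"], age=[101.0])
        entries = entries_frame([0, 10], [180, 179])
        retained, ledger = apply_baseline_exclusions(members, entries)
        assert len(retained) == 0
        assert ledger.iloc[0]["reason"] == "age"

    def test_low_weight_with_followup_retained(self):
        members = members_frame(["M1"], weight_lb=[99.0])
        entries = entries_frame([0, 5, 9], [99, 98, 97])
        retained, _ = apply_baseline_exclusions(members, entries)
        assert list(retained["member_id"]) == ["M1"]

    def test_low_weight_without_followup_excluded(self):
        members = members_frame(["M1"], weight_lb=[99.0])
        entries = entries_frame([0], [99])
        retained, ledger = apply_baseline_exclusions(members, entries)
        assert len(retained) == 0
        assert "baseline_weight" in ledger.iloc[0]["reason"]

    def test_height_above_ten_feet_excluded(self):
        members = members_frame(["M1"], height_in=[121.0])
        retained, ledger = apply_baseline_exclusions(
            members, entries_frame([0, 3], [180, 181]))
        assert len(retained) == 0 and ledger.iloc[0]["reason"] == "height"

    def test_orphan_entries_raise(self):
        members = members_frame(["M1"])
        entries = entries_frame([0], [180], member_id="GHOST")
        with pytest.raises(DataIntegrityError, match="GHOST"):
            apply_baseline_exclusions(members, entries)


def test_same_day_collapse_keeps_last_entry():
    entries = pd.DataFrame({
        "entry_id": ["a", "b", "c"],
        "member_id": "M1",
        "day": [3, 3, 7],
        "weight_lb": [200.0, 190.0, 189.0],
    })
    collapsed = collapse_same_day(entries)
    assert list(collapsed["entry_id"]) == ["b", "c"]


class TestPolynomialFilter:
    def quadratic(self, days, a=180.0, b=-0.5, c=0.01):
        days = np.asarray(days, dtype=float)
        return a + b * days + c * days ** 2

    def test_three_points_interpolate_exactly(self):
        entries = entries_frame([0, 10, 40], [250, 180, 222])
        assert filter_f1_polynomial(entries) == []

    def test_fewer_than_three_days_no_flags(self):
        assert filter_f1_polynomial(entries_frame([0, 9], [200, 120])) == []

    def test_large_spike_on_quadratic_is_the_only_flag(self):
        days = np.arange(0, 150, 10)  # 15 entries
        weights = self.quadratic(days)
        weights[7] += 80.0
        flags = filter_f1_polynomial(entries_frame(days, weights))
        assert [f["entry_id"] for f in flags] == ["M1-E8"]
        assert oracle_quadratic_flags(days, weights) == [7]

    def test_small_spike_below_absolute_threshold_not_flagged(self):
        days = np.arange(0, 150, 10)
        weights = self.quadratic(days)
        weights[7] += 8.0
        assert filter_f1_polynomial(entries_frame(days, weights)) == []
        assert oracle_quadratic_flags(days, weights) == []

    def test_single_spike_in_short_series_cannot_exceed_three_sd(self):
        """The largest standardized residual among n points is (n-1)/sqrt(n)
        (< 3 for n <= 10), so one spike in a 7-entry record is structurally
        invisible to the 3-SD rule - the spike inflates the SD it is judged
        against.  The oracle agrees."""
        days = [0, 10, 20, 30, 40, 50, 60]
        weights = self.quadratic(days)
        weights[3] += 80.0
        assert filter_f1_polynomial(entries_frame(days, weights)) == []
        assert oracle_quadratic_flags(days, weights) == []


class TestRateFilter:
    def test_two_and_a_half_percent_per_day_flags_both(self):
        entries = entries_frame([0, 2, 30], [200, 190, 189])
        flags = filter_f2_rate(entries)
        assert sorted(f["entry_id"] for f in flags) == ["M1-E1", "M1-E2"]

    def test_exactly_two_percent_is_not_flagged(self):
        entries = entries_frame([0, 1, 30], [200, 196, 195])
        assert filter_f2_rate(entries) == []

    def test_constant_series_no_flags(self):
        assert filter_f2_rate(entries_frame([0, 5, 9], [200, 200, 200])) == []

    def test_uncollapsed_duplicate_days_rejected(self):
        with pytest.raises(ValidationError):
            filter_f2_rate(entries_frame([0, 0, 9], [200, 195, 190]))


class TestJumpFilter:
    @pytest.mark.parametrize("second,expected", [
        (149.0, 2), (150.0, 2), (151.0, 0),
    ])
    def test_fifty_pound_boundary_is_inclusive(self, second, expected):
        entries = entries_frame([0, 10, 20], [200.0, second, 198.0])
        assert len(filter_f3_jump(entries)) == expected

    def test_nonconsecutive_pairs_are_scanned(self):
        entries = entries_frame([0, 5, 10], [200.0, 180.0, 149.0])
        flagged = {f["entry_id"] for f in filter_f3_jump(entries)}
        assert flagged == {"M1-E1", "M1-E3"}  # the 51-lb pair is days apart


class TestRangeFilter:
    @pytest.mark.parametrize("low,expected", [(199.0, True), (200.0, True),
                                              (201.0, False)])
    def test_hundred_pound_range_boundary(self, low, expected):
        entries = entries_frame([0, 30], [300.0, low])
        flags = filter_f4_range(entries)
        assert bool(flags) is expected
        if flags:
            assert all(f["level"] == "member" for f in flags)

    def test_monotone_99_lb_loss_not_flagged(self):
        entries = entries_frame([0, 30, 60], [280.0, 230.0, 181.0])
        assert filter_f4_range(entries) == []

    def test_flag_carries_extreme_entries(self):
        entries = entries_frame([0, 10, 20], [250.0, 149.0, 210.0])
        ids = {f["entry_id"] for f in filter_f4_range(entries)}
        assert ids == {"M1-E1", "M1-E2"}


class TestFilterOracleEquivalence:
    """All four filters against independent brute-force scans on random
    series (the acceptance check runs a larger version of this)."""

    def random_series(self, rng):
        n = int(rng.integers(2, 30))
        days = np.sort(rng.choice(400, size=n, replace=False))
        weights = np.round(rng.uniform(100, 320, size=n), 1)
        return days, weights

    def test_random_series_match_oracles(self):
        rng = np.random.default_rng(2024)
        thresholds = QCThresholds()
        for _ in range(200):
            days, weights = self.random_series(rng)
            entries = entries_frame(days, weights)
            idx = {e: i for i, e in enumerate(entries["entry_id"])}
            if len(days) >= 3:
                got = sorted(idx[f["entry_id"]]
                             for f in filter_f1_polynomial(entries, thresholds))
                assert got == oracle_quadratic_flags(days, weights)
                got = sorted(idx[f["entry_id"]]
                             for f in filter_f2_rate(entries, thresholds))
                assert got == oracle_rate_flags(days, weights)
                got = sorted(idx[f["entry_id"]]
                             for f in filter_f3_jump(entries, thresholds))
                assert got == oracle_jump_flags(weights)
            flagged, lo, hi = oracle_range_flag(weights)
            flags = filter_f4_range(entries, thresholds)
            assert bool(flags) == flagged
            if flagged:
                assert {f["entry_id"] for f in flags} == {
                    entries["entry_id"].iloc[lo], entries["entry_id"].iloc[hi]}

    def test_consecutive_50lb_pairs_always_flagged_by_f3(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            days, weights = self.random_series(rng)
            if len(days) < 3:
                continue
            flags = {f["entry_id"]
                     for f in filter_f3_jump(entries_frame(days, weights))}
            for i in range(len(days) - 1):
                if abs(weights[i + 1] - weights[i]) >= 50:
                    assert f"M1-E{i + 1}" in flags
                    assert f"M1-E{i + 2}" in flags


class TestRunAllFilters:
    def test_clean_smooth_trajectories_yield_no_flags(self):
        frames = []
        for m in range(10):
            days = np.arange(0, 70, 10)
            weights = 200 - 0.05 * days + m
            frames.append(entries_frame(days, weights, member_id=f"M{m}"))
        entries = pd.concat(frames, ignore_index=True)
        members = members_frame([f"M{m}" for m in range(10)])
        report = run_all_filters(members, entries)
        assert report.summary["n_flagged_entries"] == 0

    def test_deterministic_on_fixed_input(self):
        rng = np.random.default_rng(3)
        entries = pd.concat([
            entries_frame(np.sort(rng.choice(300, 8, replace=False)),
                          rng.uniform(100, 350, 8).round(1),
                          member_id=f"M{m}")
            for m in range(20)], ignore_index=True)
        members = members_frame([f"M{m}" for m in range(20)])
        a = run_all_filters(members, entries).flags
        b = run_all_filters(members, entries).flags
        pd.testing.assert_frame_equal(a, b)

    def test_rate_jump_range_filters_idempotent_after_cleaning(self):
        """Dropping every flagged entry and re-running yields no new
        F2/F3/F4 flags (F1 re-fits, so it is excluded from the property)."""
        rng = np.random.default_rng(5)
        entries = pd.concat([
            entries_frame(np.sort(rng.choice(300, 10, replace=False)),
                          rng.uniform(100, 350, 10).round(1),
                          member_id=f"M{m}")
            for m in range(20)], ignore_index=True)
        members = members_frame([f"M{m}" for m in range(20)])
        first = run_all_filters(members, entries)
        cleaned = entries.loc[
            ~entries["entry_id"].isin(first.flagged_entry_ids())]
        second = run_all_filters(members, cleaned)
        assert set(second.summary["flags_per_filter"]) <= {"F1"}


class TestReviewResolution:
    def labels(self, verdicts_a, verdicts_b):
        n = len(verdicts_a)
        ids = [f"E{i}" for i in range(n)]
        return ids, pd.DataFrame({
            "entry_id": ids * 2,
            "reviewer_id": ["R1"] * n + ["R2"] * n,
            "verdict": list(verdicts_a) + list(verdicts_b),
        })

    def test_perfect_agreement(self):
        ids, labels = self.labels(["erroneous", "valid"], ["erroneous", "valid"])
        out = resolve_reviews(ids, labels)
        assert out.agreement == 1.0 and out.kappa == 1.0
        assert out.confirmed_entry_ids == {"E0"}

    def test_kappa_matches_hand_derivation_for_2x2_table(self):
        a = ["erroneous"] * 45 + ["valid"] * 55
        b = ["erroneous"] * 40 + ["valid"] * 5 + ["erroneous"] * 5 + ["valid"] * 50
        assert cohen_kappa(pd.Series(a), pd.Series(b)) == pytest.approx(
            0.7980, abs=1e-4)

    def test_total_discordance(self):
        a = pd.Series(["erroneous"] * 10)
        b = pd.Series(["valid"] * 10)
        assert (a == b).mean() == 0.0
        assert cohen_kappa(a, b) <= 0.0

    def test_kappa_agrees_with_sklearn(self):
        rng = np.random.default_rng(12)
        a = rng.choice(["erroneous", "valid"], 200, p=[0.3, 0.7])
        b = np.where(rng.random(200) < 0.8, a,
                     rng.choice(["erroneous", "valid"], 200))
        assert cohen_kappa(pd.Series(a), pd.Series(b)) == pytest.approx(
            cohen_kappa_score(a, b), abs=1e-12)

    def test_missing_labels_listed(self):
        ids, labels = self.labels(["erroneous"], ["erroneous"])
        with pytest.raises(ValidationError, match="E9"):
            resolve_reviews(ids + ["E9"], labels)

    def test_disagreement_without_consensus_raises(self):
        ids, labels = self.labels(["erroneous", "valid"], ["valid", "valid"])
        with pytest.raises(UnresolvedEntriesError):
            resolve_reviews(ids, labels)

    def test_consensus_resolves_disagreement(self):
        ids, labels = self.labels(["erroneous", "valid"], ["valid", "valid"])
        consensus = pd.DataFrame({"entry_id": ["E0"], "verdict": ["erroneous"]})
        out = resolve_reviews(ids, labels, consensus)
        assert out.confirmed_entry_ids == {"E0"}
        assert out.n_disagreements == 1


class TestDropConfirmedErrors:
    def test_removal_percentages_match_reported_precision(self):
        entries = pd.DataFrame({
            "entry_id": [f"E{i}" for i in range(58574)],
            "member_id": "M1", "day": 0, "weight_lb": 180.0})
        confirmed = [f"E{i}" for i in range(73)]
        cleaned, ledger = drop_confirmed_errors(entries, confirmed,
                                                n_flagged=301)
        assert ledger["pct_of_all_entries_removed"] == 0.12
        assert ledger["pct_of_flagged_confirmed"] == 24
        assert len(cleaned) == 58574 - 73

    def test_empty_confirmed_set_is_identity(self):
        entries = entries_frame([0, 5], [200, 199])
        cleaned, ledger = drop_confirmed_errors(entries, set())
        pd.testing.assert_frame_equal(cleaned, entries)
        assert ledger["pct_of_all_entries_removed"] == 0.0

    def test_unknown_confirmed_id_raises(self):
        entries = entries_frame([0, 5], [200, 199])
        with pytest.raises(DataIntegrityError, match="NOPE"):
            drop_confirmed_errors(entries, {"NOPE"})
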