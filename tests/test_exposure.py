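"""Exposure engine vs a day-granular brute-force oracle, plus gap semantics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ttemu.cohort import build_cohort
from ttemu.config import GapBehavior, SimulationConfig
from ttemu.exposure import (BIG, build_timelines, coverage_days,
                            detect_discontinuation)
from ttemu.synthetic import generate_population

from conftest import day, micro_dataset


def oracle_coverage(fill_days, supply, window):
    """Day-by-day membership check against every fill interval."""
    w0, w1 = window
    out = np.zeros(w1 - w0 + 1, dtype=bool)
    for d in range(w0, w1 + 1):
        out[d - w0] = any(f <= d <= f + s - 1 for f, s in zip(fill_days, supply))
    return out


def oracle_discontinuation(fill_days, supply, gap_days, window):
    """First day d in the window whose preceding uncovered run exceeds gap."""
    w0, w1 = window
    cov = oracle_coverage(fill_days, supply, (w0 - 1, w1))
    run = 0
    for d in range(w0, w1 + 1):
        if cov[d - (w0 - 1)]:
            run = 0
        else:
            run += 1
            if run > gap_days:
                return d
    return None


def random_fill_case(rng):
    n_fills = rng.integers(0, 8)
    fills = np.sort(rng.integers(0, 300, n_fills))
    supply = rng.integers(1, 60, n_fills)
    gap = int(rng.choice([30, 60]))
    window = (0, int(rng.integers(50, 400)))
    return fills, supply, gap, window


class TestCoverageDays:
    def test_single_fill_covers_exactly_supply(self):
        cov = coverage_days([0], 30, (0, 100))
        assert cov.sum() == 30 and cov[:30].all() and not cov[30:].any()

    def test_back_to_back_fills_are_contiguous(self):
        cov = coverage_days([0, 30], 30, (0, 100))
        assert cov[:60].all() and cov.sum() == 60

    def test_overlapping_supply_does_not_stockpile(self):
        # second fill 10 days early: union ends at day 69, not 79
        cov = coverage_days([0, 20], 30, (0, 100))
        assert cov[:50].all() and not cov[50:].any()

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            fills, supply, _, window = random_fill_case(rng)
            fast = coverage_days(fills, supply, window)
            slow = oracle_coverage(fills, supply, window)
            assert (fast == slow).all()


class TestDetectDiscontinuation:
    def test_gap_25_under_30_day_rule_continues(self):
        # supply ends day 29, next fill day 55 -> 25 uncovered days; the
        # window ends while the second supply still runs
        assert detect_discontinuation([0, 55], 30, 30, (0, 84)) is None

    def test_gap_45_flags_under_30_not_under_60(self):
        # supply ends day 29, next fill day 75 -> 45 uncovered days
        assert detect_discontinuation([0, 75], 30, 30, (0, 104)) == 60
        assert detect_discontinuation([0, 75], 30, 60, (0, 104)) is None

    def test_empty_fill_list_discontinues_at_gap(self):
        assert detect_discontinuation([], [], 30, (10, 200)) == 40

    def test_window_end_before_gap_completes_means_none(self):
        assert detect_discontinuation([0], 30, 30, (0, 55)) is None

    def test_matches_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(99)
        checked = 0
        for _ in range(1200):
            fills, supply, gap, window = random_fill_case(rng)
            fast = detect_discontinuation(fills, supply, gap, window)
            slow = oracle_discontinuation(fills, supply, gap, window)
            assert fast == slow, (fills.tolist(), supply.tolist(), gap, window)
            checked += 1
        assert checked >= 1000

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        fills=st.lists(st.integers(0, 300), max_size=8),
        supply=st.integers(1, 90),
        gaps=st.tuples(st.integers(1, 90), st.integers(1, 90)),
        wend=st.integers(30, 400),
    )
    def test_gap_monotonicity_property(self, fills, supply, gaps, wend):
        """For any fill sequence, a wider gap allowance never creates or
        advances a discontinuation, and matches the day-level oracle."""
        g_small, g_large = min(gaps), max(gaps)
        supplies = [supply] * len(fills)
        window = (0, wend)
        d_small = detect_discontinuation(fills, supplies, g_small, window)
        d_large = detect_discontinuation(fills, supplies, g_large, window)
        assert d_small == oracle_discontinuation(fills, supplies, g_small, window)
        if d_large is not None:
            assert d_small is not None and d_small <= d_large

    def test_gap_monotonicity_on_random_sequences(self):
        """Enlarging the gap can only delay or remove a discontinuation."""
        rng = np.random.default_rng(7)
        for _ in range(400):
            fills, supply, _, window = random_fill_case(rng)
            d30 = detect_discontinuation(fills, supply, 30, window)
            d60 = detect_discontinuation(fills, supply, 60, window)
            if d60 is not None:
                assert d30 is not None and d30 <= d60


class TestDeviations:
    def _one_initiator(self, fills, events=(), deaths=()):
        rows = [(1, "adt_hormonal", "2015-06-15", 90)] + \
            [(1, "metformin", d, s) for d, s in fills]
        return micro_dataset([(1, "1945-06-15", "2015-06-15")], fills_rows=rows,
                             events_rows=list(events), deaths_rows=list(deaths))

    def test_contraindication_before_stop_exempts(self):
        # fills for 5 months; severe renal disease diagnosed in month 4
        fills = [("2015-06-15", 30), ("2015-07-15", 30), ("2015-08-15", 30),
                 ("2015-09-15", 30), ("2015-10-15", 30)]
        ds = self._one_initiator(fills, events=[(1, "severe_renal", "2015-10-20")])
        cohort, _ = build_cohort(ds)
        tl = build_timelines(ds, cohort, gap_days=30)
        assert tl.iloc[0]["deviation_reason"] == "none"
        assert tl.iloc[0]["discontinuation_day"] < BIG

    def test_initiator_stop_without_contraindication_deviates(self):
        fills = [("2015-06-15", 30), ("2015-07-15", 30)]
        ds = self._one_initiator(fills)
        cohort, _ = build_cohort(ds)
        tl = build_timelines(ds, cohort, gap_days=30)
        row = tl.iloc[0]
        assert row["deviation_reason"] == "discontinued_no_contraindication"
        # supply ends 2015-08-13; deviation at +31 days, month 3
        assert row["deviation_day"] == day("2015-08-13") + 31
        assert row["deviation_month"] == 3

    def test_noninitiator_indicated_start_is_compliant(self):
        ds = micro_dataset(
            [(1, "1945-06-15", "2015-06-15")],
            fills_rows=[(1, "adt_hormonal", "2015-06-15", 90),
                        (1, "metformin", "2016-01-20", 30)],  # month 7
            events_rows=[(1, "diabetes", "2015-12-20")])      # month 6
        cohort, _ = build_cohort(ds)
        tl = build_timelines(ds, cohort, gap_days=30)
        assert tl.iloc[0]["deviation_reason"] == "none"

    def test_noninitiator_unindicated_start_deviates_at_fill_month(self):
        ds = micro_dataset(
            [(1, "1945-06-15", "2015-06-15")],
            fills_rows=[(1, "adt_hormonal", "2015-06-15", 90),
                        (1, "metformin", "2016-01-20", 30)])
        cohort, _ = build_cohort(ds)
        tl = build_timelines(ds, cohort, gap_days=30)
        row = tl.iloc[0]
        assert row["deviation_reason"] == "initiated_no_indication"
        assert row["deviation_month"] == (day("2016-01-20") - day("2015-06-15")) // 30


class TestAgainstGeneratorTruth:
    @pytest.fixture(scope="class")
    def gapped(self):
        cfg = SimulationConfig(
            n_patients=3000, seed=31, treat_intercept=-1.0,
            gap_behavior=GapBehavior(long_gap_fraction=0.5, long_gap_days=45,
                                     long_gap_at_fill=3))
        return generate_population(cfg)

    @pytest.mark.parametrize("gap_days,col", [(30, "dev30_month"), (60, "dev60_month")])
    def test_deviation_months_match_truth(self, gapped, gap_days, col):
        cohort, _ = build_cohort(gapped)
        tl = build_timelines(gapped, cohort, gap_days=gap_days)
        truth = gapped.truth.set_index("patient_id").loc[cohort["patient_id"]]
        eng = tl.set_index("patient_id")["deviation_month"].clip(upper=BIG)
        assert (eng == truth[col].clip(upper=BIG)).all()

    def test_60_day_deviators_subset_of_30_day(self, gapped):
        cohort, _ = build_cohort(gapped)
        t30 = build_timelines(gapped, cohort, gap_days=30)
        t60 = build_timelines(gapped, cohort, gap_days=60)
        dev30 = set(t30.loc[t30["deviation_month"] < BIG, "patient_id"])
        dev60 = set(t60.loc[t60["deviation_month"] < BIG, "patient_id"])
        assert dev60 <= dev30
        assert len(dev60) < len(dev30)  # planted 45-day gaps separate the rules
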