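"""Odds-ratio arithmetic, CI back-calculation, and pair assembly."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import norm

from surrotrial import Endpoint, build_pairs, effect_from_reported, odds_ratio
from surrotrial.errors import InsufficientPairsError, ValidationError
from surrotrial.simulate import SyntheticConfig, generate_dataset

Z = norm.ppf(0.975)


class TestOddsRatio:
    def test_symmetric_table_is_null(self):
        est = odds_ratio(10, 100, 10, 100)
        assert est.log_effect == pytest.approx(0.0, abs=1e-15)
        assert not est.correction_applied

    def test_cross_product_and_woolf_se(self):
        # oracle: direct arithmetic on a = 10, b = 90, c = 20, d = 80
        est = odds_ratio(10, 100, 20, 100)
        assert est.log_effect == pytest.approx(math.log((10 * 80) / (90 * 20)),
                                               abs=1e-12)
        assert est.se == pytest.approx(
            math.sqrt(1 / 10 + 1 / 90 + 1 / 20 + 1 / 80), abs=1e-12)

    def test_haldane_correction_on_zero_cell(self):
        # corrected cells: a=0.5, b=10.5, c=5.5, d=5.5
        est = odds_ratio(0, 10, 5, 10)
        assert est.correction_applied
        assert math.exp(est.log_effect) == pytest.approx(
            (0.5 * 5.5) / (10.5 * 5.5), abs=1e-12)
        assert est.se == pytest.approx(
            math.sqrt(1 / 0.5 + 1 / 10.5 + 1 / 5.5 + 1 / 5.5), abs=1e-12)

    def test_double_zero_is_non_informative(self):
        est = odds_ratio(0, 50, 0, 60)
        assert not est.informative
        assert est.se is None

    def test_exclude_policy_drops_any_zero_cell(self):
        assert not odds_ratio(0, 10, 5, 10, zero_cell="exclude").informative
        assert odds_ratio(1, 10, 5, 10, zero_cell="exclude").informative

    def test_events_above_arm_size_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio(11, 10, 5, 10)

    @given(st.data())
    def test_arm_swap_negates_log_or_and_keeps_se(self, data):
        n1 = data.draw(st.integers(10, 500))
        n2 = data.draw(st.integers(10, 500))
        a = data.draw(st.integers(0, n1))
        c = data.draw(st.integers(0, n2))
        fwd = odds_ratio(a, n1, c, n2)
        rev = odds_ratio(c, n2, a, n1)
        assert fwd.informative == rev.informative
        if fwd.informative:
            assert fwd.log_effect == pytest.approx(-rev.log_effect, abs=1e-12)
            assert fwd.se == pytest.approx(rev.se, abs=1e-12)

    @given(a=st.integers(1, 50), c=st.integers(1, 50),
           n1=st.integers(100, 400), n2=st.integers(100, 400))
    def test_doubling_cells_keeps_or_shrinks_se(self, a, c, n1, n2):
        base = odds_ratio(a, n1, c, n2)
        doubled = odds_ratio(2 * a, 2 * n1, 2 * c, 2 * n2)
        assert doubled.log_effect == pytest.approx(base.log_effect, abs=1e-12)
        assert doubled.se < base.se
        assert not base.correction_applied  # all cells >= 1 by construction


class TestReportedEffects:
    @pytest.mark.parametrize("value,lo,hi", [
        (0.80, 0.64, 1.00),
        (2.0, 1.0, 4.0),
    ])
    def test_ci_back_calculation(self, value, lo, hi):
        est = effect_from_reported(value, lo, hi, "hr_reported")
        assert est.log_effect == pytest.approx(math.log(value), abs=1e-12)
        assert est.se == pytest.approx((math.log(hi) - math.log(lo)) / (2 * Z),
                                       abs=1e-12)

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValidationError):
            effect_from_reported(1.0, 1.0, 1.0, "hr_reported")

    def test_inconsistent_ci_rejected(self):
        with pytest.raises(ValidationError):
            effect_from_reported(0.5, 0.8, 1.2, "or_reported")

    def test_no_ci_gives_missing_se(self):
        est = effect_from_reported(0.9, None, None, "hr_reported")
        assert est.se is None
        assert est.log_effect == pytest.approx(math.log(0.9))


class TestBuildPairs:
    def test_pair_count_matches_row_scan(self, paper_scale_records):
        pairs = build_pairs(paper_scale_records, Endpoint.BLEED_MAJOR_MINOR,
                            Endpoint.DEATH_ALL)
        # independent row-by-row filter
        expected = 0
        for rec in paper_scale_records:
            ok = True
            for ep in (Endpoint.BLEED_MAJOR_MINOR, Endpoint.DEATH_ALL):
                pair = rec.events.get(ep)
                if pair is None or (pair[0] == 0 and pair[1] == 0):
                    ok = False
            expected += ok
        assert len(pairs) == expected
        assert [p.comparison_id for p in pairs] == [
            r.comparison_id for r in paper_scale_records
            if all(r.events.get(ep) is not None
                   and sum(r.events[ep]) > 0
                   for ep in (Endpoint.BLEED_MAJOR_MINOR, Endpoint.DEATH_ALL))]

    def test_missing_final_endpoint_drops_pair(self, small_records):
        missing = [r for r in small_records
                   if Endpoint.DEATH_CV not in r.events]
        pairs = build_pairs(small_records, Endpoint.BLEED_MAJOR,
                            Endpoint.DEATH_CV)
        ids = {p.comparison_id for p in pairs}
        assert all(r.comparison_id not in ids for r in missing)

    def test_hr_policy_restricts_to_reporting_articles(self, paper_scale_records):
        pairs = build_pairs(paper_scale_records, Endpoint.BLEED_MAJOR_MINOR,
                            Endpoint.DEATH_ALL, estimand_policy="hr_reported")
        by_id = {r.comparison_id: r for r in paper_scale_records}
        for p in pairs:
            rec = by_id[p.comparison_id]
            assert rec.reported_hr is not None
            assert p.y == pytest.approx(math.log(rec.reported_hr), abs=1e-12)

    def test_identical_endpoints_rejected(self, small_records):
        with pytest.raises(ValueError):
            build_pairs(small_records, Endpoint.DEATH_ALL, Endpoint.DEATH_ALL)

    def test_insufficient_pairs_raises(self):
        records = generate_dataset(SyntheticConfig(k_trials=4, seed=3,
                                                   multi_arm_pairs=0,
                                                   missing_death_cv=1.0))
        with pytest.raises(InsufficientPairsError):
            build_pairs(records, Endpoint.BLEED_MAJOR, Endpoint.DEATH_CV)
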