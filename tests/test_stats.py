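"""Fisher exact tests, distance enrichment, rank-sum comparison and
over-representation.

The Fisher oracle enumerates all tables with the observed margins and
sums hypergeometric point probabilities computed with exact rational
arithmetic — fully independent of the implementation path.
"""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from synreg.stats import (
    binned_distance_enrichment,
    compare_conservation,
    cumulative_distance_curves,
    feature_enrichment,
    fisher_2x2,
    overrepresentation,
)


def fisher_oracle(a, b, c, d):
    """Two-sided p by exhaustive enumeration with Fraction arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def point(x):
        return (
            Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))
        )

    observed = point(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = point(x)
        if p <= observed:
            total += p
    return float(total)


class TestFisher:
    def test_published_near_splice_table(self):
        res = fisher_2x2(310, 770, 921, 4032)
        assert res.odds_ratio == pytest.approx(1.76, abs=0.005)
        assert res.p_two_sided == pytest.approx(5.89e-13, rel=0.01)

    def test_symmetric_table(self):
        res = fisher_2x2(2, 2, 2, 2)
        assert res.odds_ratio == 1.0 and res.p_two_sided == pytest.approx(1.0)

    def test_hand_enumerated_small_table(self):
        res = fisher_2x2(3, 1, 1, 3)
        assert res.p_two_sided == pytest.approx(34 / 70, rel=1e-10)
        assert res.p_two_sided == pytest.approx(fisher_oracle(3, 1, 1, 3), rel=1e-10)

    def test_zero_cell_gives_infinite_or_with_corrected_companion(self):
        res = fisher_2x2(5, 5, 0, 10)
        assert math.isinf(res.odds_ratio)
        assert res.odds_ratio_corrected == pytest.approx((5.5 * 10.5) / (5.5 * 0.5))

    def test_all_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_2x2(0, 0, 5, 5)

    @settings(derandomize=True, max_examples=150)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    def test_agrees_with_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        assert fisher_2x2(a, b, c, d).p_two_sided == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(1, 10), st.integers(1, 10), st.integers(1, 10), st.integers(1, 10),
           st.integers(2, 5))
    def test_or_invariant_under_row_scaling(self, a, b, c, d, k):
        assert fisher_2x2(a * k, b * k, c, d).odds_ratio == pytest.approx(
            fisher_2x2(a, b, c, d).odds_ratio
        )


def _annotated(path_dist, neut_dist):
    rows = []
    for d in path_dist:
        rows.append({"class": "PATHOGENIC", "distance_bp": d})
    for d in neut_dist:
        rows.append({"class": "NEUTRAL", "distance_bp": d})
    return pd.DataFrame(rows)


class TestDistanceEnrichment:
    def test_pathogenic_excess_near_splice_orders_bin_ors(self):
        path = [5, 10, 15, 20, 25, 40, 80]
        neut = [5, 40, 50, 60, 80, 90, 100, 120, 150, 200]
        be = binned_distance_enrichment(_annotated(path, neut))
        first, last = be.results[0], be.results[-1]
        assert first.odds_ratio > 1 > last.odds_ratio

    def test_identical_distributions_give_unit_ors(self):
        dist = [5, 20, 40, 60, 90, 150] * 10
        be = binned_distance_enrichment(_annotated(dist, dist))
        for res in be.results:
            assert res.odds_ratio == pytest.approx(1.0)

    def test_degenerate_bin_reported_absent(self):
        be = binned_distance_enrichment(_annotated([5], [10]))
        assert be.results[-1] is None  # nobody beyond 70 bp
        frame = be.to_frame()
        assert np.isnan(frame.loc[2, "p"])

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            binned_distance_enrichment(_annotated([5], [10]), bins=[(1, 30), (20, 70)])


class TestCurves:
    def test_step_curve_values(self):
        df = _annotated([5, 10], [])
        x, y = cumulative_distance_curves(df)["PATHOGENIC"]
        assert list(x) == [5, 10] and list(y) == [0.5, 1.0]

    def test_identical_classes_identical_curves(self):
        df = _annotated([3, 7, 9], [3, 7, 9])
        curves = cumulative_distance_curves(df)
        xp, yp = curves["PATHOGENIC"]
        xn, yn = curves["NEUTRAL"]
        assert list(xp) == list(xn) and list(yp) == list(yn)

    def test_dominated_distances_dominate_pointwise(self):
        rng = np.random.default_rng(3)
        path = rng.integers(1, 60, size=2000)
        neut = rng.integers(1, 120, size=2000)
        df = _annotated(path, neut)
        curves = cumulative_distance_curves(df)
        xp, yp = curves["PATHOGENIC"]
        xn, yn = curves["NEUTRAL"]
        grid = np.arange(1, 130)
        fp = np.interp(grid, xp, yp, left=0.0)
        fn = np.interp(grid, xn, yn, left=0.0)
        assert (fp >= fn - 1e-12).all() and (fp - fn).max() > 0.1


class TestConservation:
    def test_exact_small_sample(self):
        assert compare_conservation([3, 4, 5], [1, 2]) == pytest.approx(0.1)

    def test_identical_groups_near_half(self):
        p = compare_conservation([1.0, 2.0, 3.0] * 30, [1.0, 2.0, 3.0] * 30)
        assert 0.4 < p < 0.6

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(40):
            a = rng.normal(2, 1, size=200)
            b = rng.normal(0, 1, size=200)
            if compare_conservation(a, b) < 0.01:
                hits += 1
        assert hits >= 38  # >= 95% power

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_conservation([], [1.0])


class TestOverrepresentation:
    UNIVERSE = {f"G{i}" for i in range(20)}
    TERM = {f"G{i}" for i in range(10)}

    def test_closed_form_hypergeometric_tail(self):
        query = {f"G{i}" for i in range(5)}
        df = overrepresentation(query, {"term": self.TERM}, self.UNIVERSE, min_hits=1)
        assert df.loc[0, "p"] == pytest.approx(
            math.comb(10, 5) / math.comb(20, 5), rel=1e-9
        )

    def test_terms_with_five_or_fewer_hits_filtered(self):
        query = {f"G{i}" for i in range(5)}
        df = overrepresentation(query, {"term": self.TERM}, self.UNIVERSE)
        assert len(df) == 0

    def test_bh_step_up_by_hand(self):
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        assert list(q) == pytest.approx([0.03, 0.03, 0.03])
        # and via the full operation: three disjoint significant terms
        universe = {f"G{i}" for i in range(60)}
        sets = {
            "t1": {f"G{i}" for i in range(10)},
            "t2": {f"G{i}" for i in range(10, 22)},
            "t3": {f"G{i}" for i in range(22, 36)},
        }
        query = {f"G{i}" for i in range(0, 36, 2)}
        df = overrepresentation(query, sets, universe, min_hits=1)
        assert (df["q"].to_numpy() >= df["p"].to_numpy() - 1e-12).all()
        assert (np.diff(df["q"].to_numpy()) >= -1e-12).all()

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overrepresentation({"NOPE"}, {"t": self.TERM}, self.UNIVERSE)


class TestFeatureEnrichmentCalibration:
    def test_null_feature_type_i_error_bounded(self):
        """Binomially generated null features: Fisher rejects at most ~5%
        at nominal 0.05 (direct simulation at the counts level)."""
        rng = np.random.default_rng(12)
        n1, n2, p0 = 400, 1600, 0.2
        rejections = 0
        reps = 2000
        for _ in range(reps):
            a = rng.binomial(n1, p0)
            c = rng.binomial(n2, p0)
            res = fisher_2x2(a, n1 - a, c, n2 - c)
            if res.p_two_sided < 0.05:
                rejections += 1
        assert rejections / reps <= 0.06

    def test_known_counts_recovered_from_frame(self):
        df = pd.DataFrame(
            {
                "class": ["PATHOGENIC"] * 4 + ["NEUTRAL"] * 6 + ["EXCLUDED"] * 2,
                "near_splice": [True, True, False, False, True, False,
                                False, False, False, True, True, True],
                "distance_bp": [1.0] * 12,
            }
        )
        res = feature_enrichment(df, "near_splice")
        assert (res.a, res.b, res.c, res.d) == (2, 2, 2, 4)

    def test_unknown_feature_raises(self):
        df = pd.DataFrame({"class": ["PATHOGENIC"], "near_splice": [True]})
        with pytest.raises(KeyError, match="unknown feature"):
            feature_enrichment(df, "does_not_exist")
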