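"""Signed-rank test against enumeration oracles; the three ROI criteria."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata
from scipy.stats import wilcoxon as scipy_wilcoxon

from invdecode.atlas import DK_ROI_NAMES
from invdecode.datatypes import ValidationError
from invdecode.selection import (criterion_above_average,
                                 criterion_comparable_to_max,
                                 criterion_social_vs_control,
                                 select_relevant_rois, wilcoxon_signed_rank)


def _enumeration_oracle(d, alternative):
    """Brute-force null: all 2^n sign assignments of the midranks."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    W = ranks[d > 0].sum()
    bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
    w_all = (bits * ranks).sum(axis=1)
    p_ge = np.mean(w_all >= W - 1e-9)
    p_le = np.mean(w_all <= W + 1e-9)
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank(np.arange(8.0), np.arange(8.0))
        assert res.pvalue == 1.0 and res.n_used == 0

    def test_five_equal_positive_differences(self):
        # 2 of the 32 sign assignments reach |W| = 15
        res = wilcoxon_signed_rank(np.ones(5), alternative="two-sided")
        assert res.pvalue == pytest.approx(0.0625)
        res_g = wilcoxon_signed_rank(np.ones(5), alternative="greater")
        assert res_g.pvalue == pytest.approx(1 / 32)

    @given(st.integers(0, 10_000))
    @settings(max_examples=250, deadline=None, derandomize=True)
    def test_matches_enumeration_oracle_small_n(self, case_seed):
        rng = np.random.default_rng(case_seed)
        n = int(rng.integers(5, 13))
        d = rng.standard_normal(n)
        if rng.uniform() < 0.5:
            d = d.round(1)  # induce ties and zeros
        d = d[d != 0]
        if d.size < 2:
            return
        for alt in ("two-sided", "greater", "less"):
            mine = wilcoxon_signed_rank(d, alternative=alt)
            assert mine.pvalue == pytest.approx(_enumeration_oracle(d, alt))

    def test_exact_branch_matches_scipy_untied_n23(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.standard_normal(23)
            y = rng.standard_normal(23)
            for alt in ("two-sided", "greater"):
                mine = wilcoxon_signed_rank(x, y, alternative=alt)
                ref = scipy_wilcoxon(x, y, alternative=alt, method="exact")
                assert mine.method == "exact"
                assert mine.pvalue == pytest.approx(ref.pvalue, abs=1e-12)
                # scipy reports min(W+, W-) for two-sided; we always report W+
                w_scipy = (min(mine.statistic, 23 * 24 / 2 - mine.statistic)
                           if alt == "two-sided" else mine.statistic)
                assert w_scipy == pytest.approx(ref.statistic)

    def test_normal_branch_close_to_exact(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30) + 0.4
        approx = wilcoxon_signed_rank(x, np.zeros(30))
        ref = scipy_wilcoxon(x, alternative="two-sided", method="approx",
                             correction=True)
        assert approx.method == "normal"
        assert approx.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(np.ones(5), alternative="sideways")
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(np.ones((2, 2)))


def _table(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, columns=list(DK_ROI_NAMES))


class TestCriteria:
    def test_identical_scores_trivial_outcomes(self, rng):
        base = rng.standard_normal(23)
        tab = _table(np.tile(base[:, None], (1, 68)))
        assert criterion_above_average(tab).members == []
        # nothing differs from the maximum: all 68 ROIs are comparable
        assert len(criterion_comparable_to_max(tab).members) == 68
        assert criterion_social_vs_control(tab, tab.copy()).members == []

    def test_test_family_sizes(self, rng):
        tab = _table(rng.standard_normal((23, 68)))
        ctrl = _table(rng.standard_normal((23, 68)))
        assert criterion_above_average(tab).n_tests == 68
        assert criterion_comparable_to_max(tab).n_tests == 67
        assert criterion_social_vs_control(tab, ctrl).n_tests == 68

    def test_single_elevated_roi_selected_by_each_criterion(self, rng):
        vals = np.tile(rng.standard_normal(23)[:, None], (1, 68))
        vals = vals + 0.01 * rng.standard_normal((23, 68))
        boosted = _table(vals.copy())
        roi = DK_ROI_NAMES[40]
        boosted[roi] += 10.0
        c1 = criterion_above_average(boosted)
        assert c1.members == [roi]
        c2 = criterion_comparable_to_max(boosted)
        assert c2.members == [roi]
        c3 = criterion_social_vs_control(boosted, _table(vals))
        assert roi in c3.members

    def test_monotonicity_of_criterion1(self, rng):
        """Adding a large constant to one ROI in every fold makes all its
        paired differences against the fold average positive, so the ROI
        must enter the criterion-1 set."""
        vals = rng.standard_normal((23, 68))
        tab = _table(vals)
        roi = DK_ROI_NAMES[10]
        tab2 = tab.copy()
        tab2[roi] += 50.0
        assert roi in criterion_above_average(tab2).members

    def test_insufficient_folds_rejected(self, rng):
        tab = _table(rng.standard_normal((3, 68)))
        with pytest.raises(ValidationError):
            criterion_above_average(tab)

    def test_shape_mismatch_rejected(self, rng):
        a = _table(rng.standard_normal((23, 68)))
        b = _table(rng.standard_normal((22, 68)))
        with pytest.raises(ValidationError):
            criterion_social_vs_control(a, b)


class TestSelection:
    def test_null_tables_select_nothing(self, rng):
        social = _table(rng.standard_normal((23, 68)))
        control = _table(rng.standard_normal((23, 68)))
        sel = select_relevant_rois(social, control)
        assert sel.selected == []
        assert sel.n_tests == (68, 67, 68)

    def test_six_roi_pattern_reproduced(self, rng):
        """A table in which exactly six ROIs jointly satisfy all three
        criteria yields exactly that six-ROI selection."""
        base = 0.05 * rng.standard_normal((23, 68))
        social = _table(base.copy())
        control = _table(base + 0.05 * rng.standard_normal((23, 68)))
        winners = [DK_ROI_NAMES[i] for i in (5, 17, 33, 41, 52, 60)]
        for w in winners:
            social[w] += 10.0 + 0.1 * rng.standard_normal(23)
        sel = select_relevant_rois(social, control)
        assert sorted(sel.selected) == sorted(winners)
        rep = sel.report
        assert rep.loc[winners, "selected"].all()
        assert rep["selected"].sum() == 6

    def test_effect_recovery_at_protocol_scale(self, rng):
        """Synthetic 23-fold tables with two boosted ROIs: the selection
        recovers both in at least 8 of 10 replicate tables."""
        effect = ["lateraloccipital-rh", "superiorparietal-rh"]
        hits = 0
        for rep in range(10):
            r = np.random.default_rng(100 + rep)
            social = _table(0.5 * r.standard_normal((23, 68)))
            control = _table(0.5 * r.standard_normal((23, 68)))
            for e in effect:
                social[e] += 3.0 + 0.5 * r.standard_normal(23)
            sel = select_relevant_rois(social, control)
            if all(e in sel.selected for e in effect):
                hits += 1
        assert hits >= 8
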