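"""Agreement statistics against hand arithmetic and reference oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from papkit.agreestats import (AgreementReport, bland_altman, dice,
                               icc_average_from_f, icc_consistency,
                               loa_from_summary, paired_t, pearson_r, roc_auc,
                               sensitivity_specificity, spearman_brown,
                               spearman_r, summarize_structure_scores,
                               t_from_summary)


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((5, 5, 5), dtype=bool)
        b = np.zeros((5, 5, 5), dtype=bool)
        a[0, 0, 0] = True
        b[4, 4, 4] = True
        assert dice(a, b) == 0.0

    def test_both_empty_defined_as_one(self):
        e = np.zeros((3, 3, 3), dtype=bool)
        assert dice(e, e) == 1.0

    def test_half_overlap_hand_count(self):
        a = np.zeros((4, 4, 1), dtype=bool)
        b = np.zeros((4, 4, 1), dtype=bool)
        a[:2] = True   # 8 voxels
        b[1:3] = True  # 8 voxels, 4 shared
        assert dice(a, b) == 2 * 4 / 16

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(np.zeros((2, 2, 2), dtype=bool), np.zeros((3, 3, 3), dtype=bool))


class TestSummarize:
    def test_identical_values_sd_zero(self):
        mean, sd = summarize_structure_scores([88.0] * 8)
        assert mean == 88.0 and sd == 0.0

    def test_single_value(self):
        mean, sd = summarize_structure_scores([91.6])
        assert mean == 91.6 and sd == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_structure_scores([])


class TestPairedT:
    def test_equal_samples(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rep = paired_t(x, x)
        assert rep.t == 0.0 and rep.p == 1.0
        assert rep.ci_low <= 0.0 <= rep.ci_high

    def test_hand_arithmetic_d_123(self):
        # differences (1,2,3): mean 2, sample sd 1, t = 2/(1/sqrt(3)) = 2*sqrt(3)
        rep = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert rep.t == pytest.approx(2 * math.sqrt(3))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_reference_implementation(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=25)
        y = x + rng.normal(0.3, 1.0, size=25)
        rep = paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert rep.t == pytest.approx(ref.statistic, abs=1e-6)
        assert rep.p == pytest.approx(ref.pvalue, abs=1e-6)
        lo, hi = ref.confidence_interval(0.95)
        assert rep.ci_low == pytest.approx(lo, abs=1e-6)
        assert rep.ci_high == pytest.approx(hi, abs=1e-6)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])


class TestSummaryReconstruction:
    def test_symmetric_ci_gives_zero_t(self):
        assert t_from_summary(0.0, -1.0, 1.0, 20) == 0.0

    def test_degenerate_ci_rejected(self):
        with pytest.raises(ValueError):
            t_from_summary(1.0, 2.0, 2.0, 20)

    def test_round_trip_with_paired_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = x + rng.normal(0.5, 1.0, size=30)
        rep = paired_t(x, y)
        t = t_from_summary(rep.mean_diff, rep.ci_low, rep.ci_high, rep.n)
        assert t == pytest.approx(rep.t)

    def test_loa_zero_differences(self):
        rep = bland_altman(np.arange(5.0), np.arange(5.0))
        assert rep.bias == 0.0
        assert rep.loa_low == rep.loa_high == 0.0

    def test_loa_width_identity_bitwise(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = x + rng.normal(1.0, 2.0, size=40)
        rep = bland_altman(x, y)
        assert rep.loa_high - rep.loa_low == 2 * 1.96 * rep.sd_diff

    def test_loa_from_summary_round_trip(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = x + rng.normal(0.8, 1.5, size=30)
        ba = bland_altman(x, y)
        t = paired_t(x, y).t
        lo, hi = loa_from_summary(ba.bias, t, ba.n)
        assert lo == pytest.approx(ba.loa_low)
        assert hi == pytest.approx(ba.loa_high)


class TestCorrelation:
    def test_linear_map_pearson_one(self):
        x = np.linspace(0, 1, 20)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_decreasing_monotone_spearman_minus_one(self):
        x = np.linspace(1, 5, 15)
        r, _ = spearman_r(x, np.exp(-x))
        assert r == pytest.approx(-1.0)

    def test_exact_permutation_p_with_ties_matches_enumeration(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 2.0, 4.0, 3.0, 3.0, 5.0])
        r, p = spearman_r(x, y)

        # independent enumeration oracle over all 7! orderings
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            hits += abs(np.corrcoef(rx, perm)[0, 1]) >= obs - 1e-12
        assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1])
        assert p == pytest.approx(hits / total)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError):
            spearman_r([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_large_n_p_uses_t_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r, p = pearson_r(x, y)
        ref_r, ref_p = stats.pearsonr(x, y)
        assert r == pytest.approx(ref_r)
        assert p == pytest.approx(ref_p, rel=1e-6)


class TestICC:
    def test_duplicated_column_gives_one(self):
        x = np.linspace(10, 50, 12)
        rep = icc_consistency(np.column_stack([x, x]))
        assert rep.icc_single == pytest.approx(1.0, abs=1e-9)
        assert rep.icc_average == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_internal_identities(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(10, 2))
        rep = icc_consistency(data)
        assert rep.icc_average == pytest.approx(
            2 * rep.icc_single / (1 + rep.icc_single), abs=1e-10)
        assert rep.icc_average == pytest.approx(1 - 1 / rep.F, abs=1e-10)
        assert rep.icc_average == pytest.approx(
            spearman_brown(rep.icc_single, 2), abs=1e-10)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(7)
        subject_effect = rng.normal(0, 2, size=20)
        data = subject_effect[:, None] + rng.normal(0, 1, size=(20, 3))
        rep = icc_consistency(data)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(20), 3),
            "rater": np.tile(np.arange(3), 20),
            "score": data.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="subject",
                                       raters="rater", ratings="score")
        ref = ref.set_index("Type")
        icc3 = ref.loc["ICC(C,1)"]
        icc3k = ref.loc["ICC(C,k)"]
        assert rep.icc_single == pytest.approx(icc3["ICC"], abs=1e-6)
        assert rep.icc_average == pytest.approx(icc3k["ICC"], abs=1e-6)
        assert rep.F == pytest.approx(icc3["F"], rel=1e-6)
        assert rep.icc_p == pytest.approx(icc3["pval"], abs=1e-9)
        # pingouin prints the CI rounded to 2 dp
        assert rep.icc_single_ci == pytest.approx(tuple(icc3["CI95"]),
                                                  abs=0.01)

    def test_missing_cells_rejected(self):
        data = np.ones((5, 2))
        data[0, 0] = np.nan
        with pytest.raises(ValueError):
            icc_consistency(data)


class TestSpearmanBrown:
    def test_zero_stays_zero(self):
        assert spearman_brown(0.0, 5) == 0.0

    def test_one_stays_one(self):
        assert spearman_brown(1.0, 3) == 1.0

    def test_icc_average_from_f_inverse(self):
        assert icc_average_from_f(2.0) == 0.5
        with pytest.raises(ValueError):
            icc_average_from_f(0.0)

    def test_bad_denominator_rejected(self):
        with pytest.raises(ValueError):
            spearman_brown(-0.9, 100)


class TestROC:
    def test_perfect_separation(self):
        auc, p = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_null_auc_near_half(self):
        inside = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = rng.normal(size=500)
            labels = rng.integers(0, 2, size=500)
            auc, _ = roc_auc(scores, labels)
            inside += 0.4 <= auc <= 0.6
        assert inside >= 18

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_concordant_pair_fraction_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 5, size=16).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=16)
        if labels.sum() in (0, 16):
            labels[0] = 1 - labels[0]
        auc, _ = roc_auc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum((1.0 if sp > sn else 0.5 if sp == sn else 0.0)
                   for sp in pos for sn in neg)
        assert auc == pytest.approx(conc / (len(pos) * len(neg)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestSensSpec:
    def test_perfect_and_inverted(self):
        truth = np.array([1, 1, 0, 0])
        assert sensitivity_specificity(truth, truth) == (1.0, 1.0)
        assert sensitivity_specificity(1 - truth, truth) == (0.0, 0.0)

    def test_hand_built_2x2(self):
        # TP=3, FN=1, TN=4, FP=2
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        pred = np.array([1, 1, 1, 0, 1, 1, 0, 0, 0, 0])
        sens, spec = sensitivity_specificity(pred, truth)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(2 / 3)


def test_report_to_dict_flattens_extras():
    rep = AgreementReport(n=5, t=1.0, extra={"auc": 0.9})
    d = rep.to_dict()
    assert d["auc"] == 0.9 and d["t"] == 1.0 and "extra" not in d
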