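"""Score models, screening metrics, cutoffs, Spearman machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from hfuscad.scoring import (
    CUSScore,
    SSSScore,
    UndefinedCorrelationError,
    bonferroni_alpha,
    classify_by_cutoff,
    cus_positive,
    derive_cutoff,
    indeterminate_zone,
    minmax_normalize,
    percent_change,
    screening_metrics,
    spearman,
    sss_class,
)


def brute_force_spearman(x, y):
    """Oracle: explicit average ranking, then covariance ratio."""
    def avranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = avranks(x), avranks(y)
    mx, my = np.mean(rx), np.mean(ry)
    cov = np.mean([(a - mx) * (b - my) for a, b in zip(rx, ry)])
    sx = np.sqrt(np.mean([(a - mx) ** 2 for a in rx]))
    sy = np.sqrt(np.mean([(b - my) ** 2 for b in ry]))
    return cov / (sx * sy)


class TestScoreModels:
    def test_cus_total_is_component_sum(self):
        s = CUSScore(parenchyma=2, relative_echogenicity=1, ascites=1)
        assert s.total == 4

    @pytest.mark.parametrize("kwargs", [
        {"parenchyma": 4, "relative_echogenicity": 0, "ascites": 0},
        {"parenchyma": 0, "relative_echogenicity": 3, "ascites": 0},
        {"parenchyma": 0, "relative_echogenicity": 0, "ascites": 2},
        {"parenchyma": -1, "relative_echogenicity": 0, "ascites": 0},
    ])
    def test_cus_component_ranges_enforced(self, kwargs):
        with pytest.raises(ValueError):
            CUSScore(**kwargs)

    def test_cus_positivity_threshold(self):
        assert not cus_positive(CUSScore(0, 0, 0))
        assert cus_positive(CUSScore(1, 0, 0))
        assert cus_positive(1) and not cus_positive(0)

    @pytest.mark.parametrize("total,code,label,flag", [
        (0, 0, "none", False), (1, 1, "mild", False), (2, 1, "mild", False),
        (3, 2, "moderate", False), (4, 2, "moderate", False),
        (5, 3, "severe", False), (7, 3, "severe", False),
        (8, 3, "severe", True), (9, 3, "severe", True),
    ])
    def test_sss_class_table(self, total, code, label, flag):
        cls = sss_class(total)
        assert (cls.code, cls.label, cls.out_of_table) == (code, label, flag)

    def test_sss_negative_rejected(self):
        with pytest.raises(ValueError):
            sss_class(-1)
        with pytest.raises(ValueError):
            SSSScore(macro=-1, micro=0, hypertrophy=0)

    def test_sss_total_is_component_sum(self):
        assert SSSScore(3, 2, 1).total == 6


class TestScreening:
    def test_perfect_prediction(self):
        r = screening_metrics([1, 1, 0, 0], [1, 1, 0, 0])
        assert (r.sensitivity, r.specificity, r.accuracy, r.ppv) == \
            (1.0, 1.0, 1.0, 1.0)

    def test_matches_hand_tallied_confusion_matrix(self):
        truth = [1, 1, 1, 0, 0, 0, 1, 0, 1, 0]
        pred_ = [1, 0, 1, 1, 0, 0, 1, 1, 0, 0]
        r = screening_metrics(truth, pred_)
        assert (r.tp, r.fp, r.tn, r.fn) == (3, 2, 3, 2)
        assert r.sensitivity == pytest.approx(3 / 5)
        assert r.specificity == pytest.approx(3 / 5)
        assert r.ppv == pytest.approx(3 / 5)
        assert r.accuracy == pytest.approx(6 / 10)

    def test_counts_sum_to_n(self, rng):
        truth = rng.random(50) > 0.5
        pred = rng.random(50) > 0.5
        r = screening_metrics(truth, pred)
        assert r.n == 50

    def test_swapped_labels_swap_sensitivity_and_specificity(self, rng):
        truth = rng.random(60) > 0.5
        pred = rng.random(60) > 0.5
        a = screening_metrics(truth, pred)
        b = screening_metrics(~truth, ~pred)
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)

    def test_zero_denominator_reported_as_nan(self):
        r = screening_metrics([0, 0], [0, 0])  # no positives anywhere
        assert np.isnan(r.sensitivity)
        assert np.isnan(r.ppv)
        assert r.specificity == 1.0


class TestCutoffs:
    def test_cutoff_is_max_of_reference(self):
        vals = [0.5, 0.69, 0.803, 1.2, 0.9]
        ref = [True, True, True, False, False]
        assert derive_cutoff(vals, ref) == pytest.approx(0.803)

    def test_second_stage_cutoff(self):
        vals = [0.7, 1.095, 0.9, 1.3, 1.5]
        mild = [True, True, True, False, False]
        assert derive_cutoff(vals, mild) == pytest.approx(1.095)

    def test_single_element_subset(self):
        assert derive_cutoff([0.7, 1.0], [True, False]) == 0.7

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            derive_cutoff([1.0], [False])

    def test_specificity_one_by_construction(self, rng):
        # every reference value is <= the cutoff, so with the strict rule
        # all reference subjects classify negative
        vals = rng.normal(0.7, 0.15, 80)
        ref = rng.random(80) > 0.5
        cutoff = derive_cutoff(vals, ref)
        pred = classify_by_cutoff(vals, cutoff)
        r = screening_metrics(~ref, pred)
        assert r.specificity == 1.0

    def test_indeterminate_zone_by_definition(self):
        low, high, empty = indeterminate_zone([0.5, 0.8, 0.6, 1.2],
                                              [False, False, True, True])
        assert (low, high, empty) == (0.6, 0.8, False)

    def test_disjoint_classes_flag_empty_zone(self):
        low, high, empty = indeterminate_zone([0.5, 0.9], [False, True])
        assert empty and low > high

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            indeterminate_zone([1.0, 2.0], [True, True])


class TestSpearman:
    def test_strict_monotone_gives_r_one(self):
        r = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.r == pytest.approx(1.0)
        assert r.p < 1e-12  # machine-tiny

    def test_tied_example_matches_rank_oracle(self):
        x, y = [1, 2, 2, 3], [10, 20, 20, 40]
        assert spearman(x, y).r == pytest.approx(brute_force_spearman(x, y),
                                                 abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=5, max_size=12),
           st.lists(st.integers(0, 5), min_size=5, max_size=12))
    def test_matches_brute_force_oracle_with_ties(self, xs, ys):
        n = min(len(xs), len(ys))
        xs, ys = xs[:n], ys[:n]
        if len(set(xs)) < 2 or len(set(ys)) < 2:
            return
        ours = spearman(xs, ys).r
        assert ours == pytest.approx(brute_force_spearman(xs, ys), abs=1e-10)
        assert ours == pytest.approx(sstats.spearmanr(xs, ys).statistic,
                                     abs=1e-10)

    def test_many_seeded_vectors_match_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(5, 15))
            x = rng.integers(0, 6, n)
            y = rng.integers(0, 6, n)
            if len(set(x.tolist())) < 2 or len(set(y.tolist())) < 2:
                continue
            assert spearman(x, y).r == pytest.approx(
                brute_force_spearman(x, y), abs=1e-10)

    def test_ci_brackets_r(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.8, size=30)
        res = spearman(x, y)
        assert res.ci_low <= res.r <= res.ci_high
        assert -1 <= res.ci_low and res.ci_high <= 1

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_bonferroni_gating(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [2, 1, 4, 3, 6, 5]  # weak-ish correlation
        res = spearman(x, y, n_tests=6)
        assert res.alpha == pytest.approx(0.05 / 6)
        assert res.significant == (res.p < 0.05 / 6)


class TestSmallOps:
    @pytest.mark.parametrize("alpha,m,expected", [
        (0.05, 1, 0.05), (0.05, 6, 0.05 / 6), (0.05, 5, 0.01),
    ])
    def test_bonferroni_threshold(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_minmax_basic(self):
        norm, flag = minmax_normalize([0.0, 5.0, 10.0])
        assert np.allclose(norm, [0.0, 0.5, 1.0])
        assert not flag

    def test_minmax_constant_flagged(self):
        norm, flag = minmax_normalize([3.0, 3.0, 3.0])
        assert flag and np.all(norm == 0.5)

    def test_minmax_preserves_order(self, rng):
        v = rng.normal(size=30)
        norm, _ = minmax_normalize(v)
        assert np.array_equal(np.argsort(v), np.argsort(norm))
        assert norm.min() == 0.0 and norm.max() == 1.0

    def test_percent_change_examples(self):
        assert percent_change(239.4, 262.8) == pytest.approx(9.8, abs=0.05)
        assert percent_change(90.5, 144.95) == pytest.approx(60.0, abs=0.5)
        assert percent_change(7.0, 7.0) == 0.0

    def test_percent_change_zero_reference(self):
        with pytest.raises(ZeroDivisionError):
            percent_change(0.0, 1.0)
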