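"""Agreement and diagnostic-accuracy statistics.

Cohen's kappa is checked two ways: against a direct-summation oracle written
with explicit loops over the cells, and against statsmodels' independent
implementation (value plus both standard errors).
"""

import numpy as np
import pytest
from scipy import stats as sps
from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa
from statsmodels.stats.proportion import proportion_confint

from miaconcord import (
    ConfusionMatrix,
    DiseaseCategory,
    category_accuracy,
    clopper_pearson,
    cohen_kappa,
    interpret_kappa,
    overall_agreement,
)
from miaconcord.stats import DegenerateMatrixError


def oracle_kappa(counts):
    """Brute-force kappa: explicit sums over cells, no shared code path."""
    counts = [[float(v) for v in row] for row in counts]
    k = len(counts)
    n = sum(sum(row) for row in counts)
    po = sum(counts[i][i] for i in range(k)) / n
    pe = 0.0
    for i in range(k):
        row_i = sum(counts[i][j] for j in range(k))
        col_i = sum(counts[j][i] for j in range(k))
        pe += (row_i / n) * (col_i / n)
    return (po - pe) / (1 - pe)


def _matrix(counts):
    counts = np.asarray(counts)
    return ConfusionMatrix(categories=DiseaseCategory.ordered()[:counts.shape[0]],
                           counts=counts)


def _random_matrices(rng, count, size=5):
    out = []
    while len(out) < count:
        m = rng.integers(0, 11, size=(size, size))
        n = m.sum()
        if n < 2:
            continue
        r, c = m.sum(1) / n, m.sum(0) / n
        if (r * c).sum() > 1 - 1e-9:
            continue
        out.append(m)
    return out


class TestKappa:
    def test_study_matrix_values(self, study_matrix):
        res = cohen_kappa(study_matrix)
        assert res.kappa == pytest.approx(0.70, abs=0.005)
        assert res.se_null == pytest.approx(0.0956, abs=5e-5)
        assert res.interpretation == "substantial"

    def test_perfect_agreement(self):
        res = cohen_kappa(_matrix(np.diag([5, 3, 0, 2, 1])))
        assert res.kappa == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        # cells equal to row x column products / n: observed == expected
        row = np.array([10, 40, 50])
        col = np.array([20, 20, 60])
        counts = np.outer(row, col) // 100  # exact integers for these margins
        assert counts.sum() == 100
        res = cohen_kappa(_matrix(counts))
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for counts in _random_matrices(rng, 1000):
            assert cohen_kappa(_matrix(counts)).kappa == pytest.approx(
                oracle_kappa(counts), abs=1e-12)

    def test_matches_statsmodels_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for counts in _random_matrices(rng, 50):
            mine = cohen_kappa(_matrix(counts))
            theirs = sm_kappa(counts)
            assert mine.kappa == pytest.approx(theirs.kappa, abs=1e-10)
            assert mine.se_null == pytest.approx(theirs.std_kappa0, abs=1e-10)
            assert mine.se_alt == pytest.approx(theirs.std_kappa, abs=1e-10)

    def test_kappa_never_exceeds_observed_agreement(self):
        rng = np.random.default_rng(3)
        for counts in _random_matrices(rng, 200):
            res = cohen_kappa(_matrix(counts))
            assert res.kappa <= res.p_observed + 1e-12

    def test_ci_truncated_to_domain(self):
        res = cohen_kappa(_matrix(np.diag([3, 2, 1, 1, 1])))
        assert res.ci_high == 1.0

    def test_degenerate_marginals_rejected(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 10  # everything in one cell: p_e == 1
        with pytest.raises(DegenerateMatrixError):
            cohen_kappa(_matrix(counts))


class TestInterpretation:
    @pytest.mark.parametrize("value,band", [
        (-0.2, "poor"), (0.0, "slight"), (0.20, "slight"), (0.21, "fair"),
        (0.40, "fair"), (0.41, "moderate"), (0.60, "moderate"),
        (0.61, "substantial"), (0.70, "substantial"), (0.80, "substantial"),
        (0.81, "almost perfect"), (1.0, "almost perfect"),
    ])
    def test_bands(self, value, band):
        assert interpret_kappa(value) == band

    def test_out_of_domain(self):
        with pytest.raises(ValueError):
            interpret_kappa(1.5)


class TestClopperPearson:
    @pytest.mark.parametrize("k,n,low,high", [
        (7, 7, 0.59, 1.00),
        (0, 2, 0.00, 0.84),
        (39, 42, 0.81, 0.99),
        (52, 54, 0.87, 1.00),
    ])
    def test_published_intervals(self, k, n, low, high):
        got = clopper_pearson(k, n)
        assert round(got[0], 2) == low
        assert round(got[1], 2) == high

    def test_boundaries_exact(self):
        assert clopper_pearson(0, 10)[0] == 0.0
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_matches_statsmodels_beta_method(self):
        for n in (1, 5, 20, 54):
            for k in range(n + 1):
                lo, hi = clopper_pearson(k, n)
                sm_lo, sm_hi = proportion_confint(k, n, method="beta")
                assert lo == pytest.approx(0.0 if k == 0 else sm_lo, abs=1e-12)
                assert hi == pytest.approx(1.0 if k == n else sm_hi, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 2)
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)

    def test_coverage_on_simulated_binomials(self):
        """Exact intervals must cover at >= nominal rate (they are conservative)."""
        rng = np.random.default_rng(2024)
        n, reps = 20, 10_000
        bounds = np.array([clopper_pearson(k, n) for k in range(n + 1)])
        mc_error = np.sqrt(0.95 * 0.05 / reps)
        for p in (0.1, 0.5, 0.9):
            ks = rng.binomial(n, p, size=reps)
            covered = (bounds[ks, 0] <= p) & (p <= bounds[ks, 1])
            assert covered.mean() >= 0.95 - 3 * mc_error


class TestAgreementAndAccuracy:
    def test_overall_agreement_study(self, study_matrix):
        est = overall_agreement(study_matrix)
        assert (est.k, est.n) == (48, 54)
        assert round(est.proportion * 100) == 89

    def test_identity_matrix_full_agreement(self):
        est = overall_agreement(_matrix(np.diag([10, 5, 3, 2, 1])))
        assert est.proportion == 1.0

    def test_no_agreement(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 1] = counts[1, 0] = 5
        assert overall_agreement(_matrix(counts)).proportion == 0.0

    def test_cells_always_sum_to_n(self, study_matrix):
        for cat in study_matrix.categories:
            acc = category_accuracy(study_matrix, cat)
            assert acc.tp + acc.fp + acc.fn + acc.tn == study_matrix.n

    def test_diagonal_matrix_all_metrics_perfect(self):
        m = _matrix(np.diag([4, 3, 2, 1, 1]))
        for cat in m.categories:
            acc = category_accuracy(m, cat)
            for metric in (acc.sensitivity, acc.specificity, acc.ppv,
                           acc.npv, acc.accuracy):
                assert metric is not None and metric.proportion == 1.0

    def test_zero_denominator_is_not_applicable(self, study_matrix):
        acc = category_accuracy(study_matrix, DiseaseCategory.CONGENITAL)
        assert acc.ppv is None          # the MIA never called congenital
        assert acc.sensitivity is not None
        ncl = category_accuracy(study_matrix, DiseaseCategory.NONCONCLUSIVE)
        assert ncl.sensitivity is None  # no gold-standard nonconclusive cases

    def test_ci_contains_point_estimate(self, study_matrix):
        for cat in study_matrix.categories:
            acc = category_accuracy(study_matrix, cat)
            for est in (acc.sensitivity, acc.specificity, acc.ppv, acc.npv,
                        acc.accuracy):
                if est is not None:
                    assert est.ci_low <= est.proportion <= est.ci_high
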