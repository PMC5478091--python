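"""Agreement and diagnostic-accuracy statistics.

Cohen's kappa over the MIA-vs-CDA category confusion matrix, with two
standard errors:

* ``se_null`` — the standard error under the null hypothesis kappa = 0,
  the quantity classically printed next to a kappa test;
* ``se_alt`` — the Fleiss–Cohen–Everitt large-sample standard error under
  the alternative, which is what a 95% confidence interval for kappa itself
  should use.

Both are reported so the distinction stays auditable; the CI uses
``se_alt`` and is truncated to kappa's domain [-1, 1].  Interpretation
follows the Landis–Koch bands (poor / slight / fair / moderate /
substantial / almost perfect).

Per-category diagnostic accuracy collapses the K x K matrix one-vs-rest and
reports sensitivity, specificity, predictive values and accuracy, each with
an exact (Clopper–Pearson) binomial confidence interval; a metric whose
denominator is zero is flagged not-applicable rather than 0/0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .cases import ConfusionMatrix
from .icd10 import DiseaseCategory

__all__ = [
    "KappaResult",
    "ProportionEstimate",
    "CategoryAccuracy",
    "DegenerateMatrixError",
    "cohen_kappa",
    "interpret_kappa",
    "overall_agreement",
    "category_accuracy",
    "clopper_pearson",
]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


class DegenerateMatrixError(ValueError):
    """Kappa is undefined: expected agreement equals 1 (degenerate marginals)."""


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch qualitative band for a kappa value.

    Bands (upper bounds closed): < 0 poor; 0-0.20 slight; 0.21-0.40 fair;
    0.41-0.60 moderate; 0.61-0.80 substantial; 0.81-1.00 almost perfect.
    """
    if not -1 <= kappa <= 1:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "poor"
    if kappa <= 0.20:
        return "slight"
    if kappa <= 0.40:
        return "fair"
    if kappa <= 0.60:
        return "moderate"
    if kappa <= 0.80:
        return "substantial"
    return "almost perfect"


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with both standard errors and the 95% CI from se_alt."""

    kappa: float
    p_observed: float
    p_expected: float
    se_null: float
    se_alt: float
    ci_low: float
    ci_high: float
    interpretation: str
    n: int

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "p_observed": self.p_observed,
            "p_expected": self.p_expected,
            "se_null": self.se_null,
            "se_alt": self.se_alt,
            "ci95_low": self.ci_low,
            "ci95_high": self.ci_high,
            "interpretation": self.interpretation,
            "n": self.n,
        }


def cohen_kappa(m: ConfusionMatrix) -> KappaResult:
    """Cohen's kappa for a two-rater confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement
    (diagonal proportion) and p_e the chance agreement implied by the
    marginals.  ``se_null`` uses the null-hypothesis variance

        var0 = [p_e + p_e^2 - sum_i r_i c_i (r_i + c_i)] / [n (1 - p_e)^2]

    (r_i, c_i marginal proportions); ``se_alt`` uses the Fleiss–Cohen–Everitt
    large-sample variance under the alternative.  The 95% CI is
    kappa +/- 1.96 se_alt, truncated to [-1, 1].
    """
    n = m.n
    if n < 2:
        raise ValueError(f"kappa needs n >= 2 observations, got {n}")
    p = m.counts / n
    r = p.sum(axis=1)  # MIA (row) marginals
    c = p.sum(axis=0)  # CDA (column) marginals
    p_o = float(np.trace(p))
    p_e = float(np.dot(r, c))
    if p_e >= 1.0 - 1e-15:
        raise DegenerateMatrixError(
            "expected agreement is 1; kappa is undefined for these marginals")
    kappa = (p_o - p_e) / (1.0 - p_e)

    var_null = (p_e + p_e ** 2 - float(np.sum(r * c * (r + c)))) / (n * (1.0 - p_e) ** 2)
    se_null = math.sqrt(max(var_null, 0.0))

    # Fleiss, Cohen & Everitt large-sample variance under the alternative
    k = len(m.categories)
    a = sum(p[i, i] * (1.0 - (r[i] + c[i]) * (1.0 - kappa)) ** 2 for i in range(k))
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (c[i] + r[j]) ** 2
        for i in range(k) for j in range(k) if i != j)
    c_term = (kappa - p_e * (1.0 - kappa)) ** 2
    var_alt = (a + b - c_term) / (n * (1.0 - p_e) ** 2)
    se_alt = math.sqrt(max(var_alt, 0.0))

    ci_low = max(kappa - _Z95 * se_alt, -1.0)
    ci_high = min(kappa + _Z95 * se_alt, 1.0)
    return KappaResult(
        kappa=kappa, p_observed=p_o, p_expected=p_e,
        se_null=se_null, se_alt=se_alt,
        ci_low=ci_low, ci_high=ci_high,
        interpretation=interpret_kappa(max(-1.0, min(1.0, kappa))),
        n=n,
    )


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper–Pearson) binomial confidence interval via beta quantiles.

    At the boundaries the interval is one-sided by construction: k = 0 gives
    a lower bound of exactly 0 (upper bound 1 - (alpha/2)^(1/n), the
    one-sided 97.5% limit), and symmetrically k = n gives an upper bound of
    exactly 1.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


@dataclass(frozen=True)
class ProportionEstimate:
    """A k/n proportion with its exact binomial 95% CI."""

    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, k: int, n: int, level: float = 0.95) -> "ProportionEstimate":
        low, high = clopper_pearson(k, n, level)
        return cls(k=k, n=n, proportion=k / n, ci_low=low, ci_high=high)

    def to_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "proportion": self.proportion,
                "ci95_low": self.ci_low, "ci95_high": self.ci_high}


def overall_agreement(m: ConfusionMatrix) -> ProportionEstimate:
    """Raw agreement: diagonal sum over n, with exact binomial 95% CI."""
    if m.n < 1:
        raise ValueError("empty confusion matrix")
    return ProportionEstimate.from_counts(int(m.diagonal.sum()), m.n)


@dataclass(frozen=True)
class CategoryAccuracy:
    """One-vs-rest diagnostic accuracy of the MIA for a single category.

    The CDA is the gold standard: tp is the diagonal cell, fn the remainder
    of the CDA column, fp the remainder of the MIA row.  Metrics with a zero
    denominator are ``None`` (not applicable).
    """

    category: DiseaseCategory
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Optional[ProportionEstimate]
    specificity: Optional[ProportionEstimate]
    ppv: Optional[ProportionEstimate]
    npv: Optional[ProportionEstimate]
    accuracy: ProportionEstimate

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_cases(self) -> int:
        """Number of gold-standard (CDA) cases in this category."""
        return self.tp + self.fn

    def to_dict(self) -> dict:
        def opt(est: Optional[ProportionEstimate]):
            return None if est is None else est.to_dict()
        return {
            "category": self.category.value,
            "n_cases": self.n_cases,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "sensitivity": opt(self.sensitivity),
            "specificity": opt(self.specificity),
            "ppv": opt(self.ppv),
            "npv": opt(self.npv),
            "accuracy": self.accuracy.to_dict(),
        }


def _maybe_proportion(k: int, n: int) -> Optional[ProportionEstimate]:
    return None if n == 0 else ProportionEstimate.from_counts(k, n)


def category_accuracy(m: ConfusionMatrix,
                      category: DiseaseCategory) -> CategoryAccuracy:
    """One-vs-rest collapse of the confusion matrix for one category."""
    if category not in m.categories:
        raise ValueError(f"category {category} not in matrix")
    i = m.categories.index(category)
    tp = int(m.counts[i, i])
    fn = int(m.col_totals[i]) - tp
    fp = int(m.row_totals[i]) - tp
    tn = m.n - tp - fn - fp
    return CategoryAccuracy(
        category=category, tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=_maybe_proportion(tp, tp + fn),
        specificity=_maybe_proportion(tn, tn + fp),
        ppv=_maybe_proportion(tp, tp + fp),
        npv=_maybe_proportion(tn, tn + fn),
        accuracy=ProportionEstimate.from_counts(tp + tn, m.n),
    )
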