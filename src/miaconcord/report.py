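"""Assembly and rendering of the full concordance report.

Bundles the confusion matrix, Cohen's kappa block, overall agreement,
per-category diagnostic accuracy, and the ICD-10 coincidence tabulation
into one result object with a JSON view (machine interface, full precision)
and a plain-text view (percentages to 0 dp, kappa to 2 dp, standard errors
to 4 dp — the conventional rendering for this kind of table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

from .cases import (
    CoincidenceTable,
    ConfusionMatrix,
    PairedCase,
    build_confusion_matrix,
    coincidence_table,
)
from .icd10 import BlockTable, CategoryMap, CoincidenceLevel, DiseaseCategory
from .stats import (
    CategoryAccuracy,
    KappaResult,
    ProportionEstimate,
    category_accuracy,
    cohen_kappa,
    overall_agreement,
)

__all__ = ["ConcordanceReport", "evaluate_cases"]

_CATEGORY_TITLES = {
    DiseaseCategory.INFECTIOUS: "Infectious diseases",
    DiseaseCategory.MALIGNANT: "Malignant tumors",
    DiseaseCategory.CONGENITAL: "Congenital malformations",
    DiseaseCategory.OTHER: "Other diseases",
    DiseaseCategory.NONCONCLUSIVE: "Nonconclusive",
}


@dataclass(frozen=True)
class ConcordanceReport:
    """Complete MIA-vs-CDA concordance analysis for one case series."""

    matrix: ConfusionMatrix
    kappa: KappaResult
    agreement: ProportionEstimate
    per_category: tuple[CategoryAccuracy, ...]
    coincidence: CoincidenceTable

    def to_dict(self) -> dict:
        cats = [c.value for c in self.matrix.categories]
        coin = {
            "n_concordant": self.coincidence.n,
            "overall": self.coincidence.merged_counts(),
            "per_category": {
                cat.value: self.coincidence.merged_counts(counter)
                for cat, counter in self.coincidence.per_category.items()
                if sum(counter.values())
            },
        }
        return {
            "n_cases": self.matrix.n,
            "confusion_matrix": {
                "categories": cats,
                "counts": self.matrix.counts.tolist(),
                "rows": "mia",
                "columns": "cda",
            },
            "kappa": self.kappa.to_dict(),
            "overall_agreement": self.agreement.to_dict(),
            "per_category": [acc.to_dict() for acc in self.per_category],
            "coincidence": coin,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    # ------------------------------------------------------- text rendering

    def render_text(self) -> str:
        lines: list[str] = []
        lines += self._render_matrix()
        lines.append("")
        lines += self._render_kappa()
        lines.append("")
        lines += self._render_accuracy()
        lines.append("")
        lines += self._render_coincidence()
        return "\n".join(lines)

    def _render_matrix(self) -> list[str]:
        titles = [_CATEGORY_TITLES[c] for c in self.matrix.categories]
        width = max(len(t) for t in titles) + 2
        head = "MIA \\ CDA".ljust(width) + "".join(t.rjust(width) for t in titles)
        lines = ["Category confusion matrix (rows MIA, columns CDA, gold standard)",
                 head + "Total".rjust(8)]
        for i, title in enumerate(titles):
            row = title.ljust(width)
            row += "".join(str(int(v)).rjust(width) for v in self.matrix.counts[i])
            row += str(int(self.matrix.row_totals[i])).rjust(8)
            lines.append(row)
        total = "Total".ljust(width)
        total += "".join(str(int(v)).rjust(width) for v in self.matrix.col_totals)
        total += str(self.matrix.n).rjust(8)
        lines.append(total)
        return lines

    def _render_kappa(self) -> list[str]:
        k = self.kappa
        a = self.agreement
        return [
            f"Overall agreement: {a.k}/{a.n} = {a.proportion * 100:.0f}% "
            f"(95% CI {a.ci_low * 100:.0f}-{a.ci_high * 100:.0f}%)",
            f"Kappa: {k.kappa:.2f} (SE under H0 {k.se_null:.4f}; "
            f"large-sample SE {k.se_alt:.4f}; "
            f"95% CI {k.ci_low:.2f}-{k.ci_high:.2f}) - {k.interpretation} concordance",
        ]

    @staticmethod
    def _fmt_metric(est: Optional[ProportionEstimate]) -> str:
        if est is None:
            return "N/A"
        return (f"{est.proportion * 100:.0f} ({est.ci_low * 100:.0f},"
                f"{est.ci_high * 100:.0f})")

    def _render_accuracy(self) -> list[str]:
        header = (f"{'Category':<26}{'n':>4}{'Sens':>14}{'Spec':>14}"
                  f"{'PPV':>14}{'NPV':>14}{'Accuracy':>14}")
        lines = ["Diagnostic accuracy of the MIA (percent, exact 95% CI)", header]
        for acc in self.per_category:
            lines.append(
                f"{_CATEGORY_TITLES[acc.category]:<26}{acc.n_cases:>4}"
                f"{self._fmt_metric(acc.sensitivity):>14}"
                f"{self._fmt_metric(acc.specificity):>14}"
                f"{self._fmt_metric(acc.ppv):>14}"
                f"{self._fmt_metric(acc.npv):>14}"
                f"{self._fmt_metric(acc.accuracy):>14}")
        return lines

    def _render_coincidence(self) -> list[str]:
        coin = self.coincidence
        n = coin.n
        lines = [f"ICD-10 code coincidence among the {n} category-concordant cases"]
        if n == 0:
            lines.append("  (no category-concordant cases)")
            return lines
        merged = coin.merged_counts()
        order = ["perfect_or_almost_perfect", "moderate", "low", "none"]
        labels = {"perfect_or_almost_perfect": "Perfect or almost perfect",
                  "moderate": "Moderate", "low": "Low", "none": "None"}
        for key in order:
            count = merged[key]
            lines.append(f"  {labels[key]:<28}{count:>4}  ({count / n * 100:.1f}%)")
        upto_moderate = merged["perfect_or_almost_perfect"] + merged["moderate"]
        lines.append(
            f"  Perfect/almost perfect/moderate: {upto_moderate}/{n} "
            f"= {upto_moderate / n * 100:.1f}%")
        return lines


def evaluate_cases(cases: Sequence[PairedCase],
                   category_map: Optional[CategoryMap] = None,
                   block_table: Optional[BlockTable] = None,
                   ) -> ConcordanceReport:
    """Run the full concordance analysis on a paired-case series."""
    matrix = build_confusion_matrix(cases, category_map, block_table)
    return ConcordanceReport(
        matrix=matrix,
        kappa=cohen_kappa(matrix),
        agreement=overall_agreement(matrix),
        per_category=tuple(category_accuracy(matrix, c)
                           for c in matrix.categories),
        coincidence=coincidence_table(cases, category_map, block_table),
    )
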