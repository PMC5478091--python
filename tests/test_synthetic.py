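"""Synthetic paired-case generator: determinism, degenerate designs,
convergence to the design's analytic agreement structure."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from miaconcord import (
    CoincidenceLevel,
    DiseaseCategory,
    SimDesign,
    analytic_kappa,
    build_confusion_matrix,
    coincidence_table,
    cohen_kappa,
    default_design,
    generate,
    write_cases,
)
from miaconcord.synthetic import DesignError

K = len(DiseaseCategory.ordered())


def _design(n_cases=54, confusion=None, depth=(1.0, 0.0, 0.0, 0.0), seed=0,
            probs=None):
    return SimDesign(
        n_cases=n_cases,
        category_probs=probs if probs is not None
                       else np.array([0.5, 0.2, 0.1, 0.15, 0.05]),
        confusion=np.eye(K) if confusion is None else confusion,
        depth_agreement=np.array(depth, dtype=float),
        seed=seed,
    )


class TestDesignValidation:
    def test_probs_must_be_simplex(self):
        with pytest.raises(DesignError, match="sum to 1"):
            _design(probs=np.array([0.5, 0.2, 0.1, 0.1, 0.2]))

    def test_confusion_rows_must_be_stochastic(self):
        bad = np.eye(K)
        bad[0, 0] = 0.5
        with pytest.raises(DesignError, match="confusion row"):
            _design(confusion=bad)

    def test_depth_agreement_bounded(self):
        with pytest.raises(DesignError, match="depth_agreement"):
            _design(depth=(0.9, 0.9, 0.0, 0.0))

    def test_yaml_round_trip(self, tmp_path):
        import yaml
        design = default_design(seed=11)
        doc = {
            "n_cases": design.n_cases,
            "category_probs": design.category_probs.tolist(),
            "confusion": design.confusion.tolist(),
            "depth_agreement": design.depth_agreement.tolist(),
            "evidence_certainty": design.evidence_certainty,
            "seed": design.seed,
        }
        path = tmp_path / "design.yaml"
        path.write_text(yaml.safe_dump(doc))
        loaded = SimDesign.from_file(path)
        assert loaded.seed == 11
        np.testing.assert_allclose(loaded.confusion, design.confusion)
        assert SimDesign.from_file(path, seed=99).seed == 99


class TestGenerate:
    def test_seed_determinism(self, tmp_path):
        design = default_design(seed=5)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cases(generate(design), a)
        write_cases(generate(design), b)
        assert a.read_bytes() == b.read_bytes()

    def test_identity_design_perfect_agreement(self):
        cases = generate(_design(n_cases=60, seed=1))
        m = build_confusion_matrix(cases)
        assert cohen_kappa(m).kappa == pytest.approx(1.0)
        ct = coincidence_table(cases)
        merged = ct.merged_counts()
        assert merged["perfect"] + ct.n_nonconclusive_pairs == 60

    def test_uniform_confusion_kappa_near_zero(self):
        design = _design(n_cases=4000, confusion=np.full((K, K), 1 / K), seed=9)
        cases = generate(design)
        kappa = cohen_kappa(build_confusion_matrix(cases)).kappa
        assert abs(kappa) < 0.05  # independence limit, generous MC band

    def test_generated_codes_respect_categories(self):
        design = default_design(n_cases=200, seed=13)
        cases = generate(design)
        m = build_confusion_matrix(cases)
        assert m.n == 200

    def test_study_design_expected_cells(self):
        """Mean cell counts over replicates approach n x joint probability."""
        design = default_design(seed=0)
        joint = design.category_probs[:, None] * design.confusion  # (cda, mia)
        expected = 54 * joint.T  # rows MIA, columns CDA
        reps = 300
        total = np.zeros((K, K))
        for i in range(reps):
            cases = generate(dataclasses.replace(design, seed=50_000 + i))
            total += build_confusion_matrix(cases).counts
        mean = total / reps
        # binomial SE per cell, 4 sigma band
        se = np.sqrt(np.maximum(expected * (1 - expected / 54), 1e-9) / reps)
        assert (np.abs(mean - expected) <= 4 * se + 0.05).all()


class TestAnalyticKappa:
    def test_identity_confusion(self):
        assert analytic_kappa(_design()) == pytest.approx(1.0)

    def test_independence(self):
        probs = np.array([0.5, 0.2, 0.1, 0.15, 0.05])
        # every row equal to the same MIA distribution: independence
        conf = np.tile(np.array([0.4, 0.3, 0.1, 0.1, 0.1]), (K, 1))
        assert analytic_kappa(_design(confusion=conf, probs=probs)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_matches_large_sample_estimate(self):
        design = default_design(n_cases=100_000, seed=21)
        cases = generate(design)
        est = cohen_kappa(build_confusion_matrix(cases))
        # 3 MC standard errors of the estimated kappa
        assert est.kappa == pytest.approx(analytic_kappa(design),
                                          abs=3 * est.se_alt)


class TestDepthDistribution:
    def test_depth_frequencies_converge(self):
        """Goodness of fit of coincidence levels among concordant pairs.

        Uses an infectious-only design: that category spans several chapters,
        so every depth level is structurally feasible and the sampled levels
        must follow depth_agreement exactly (no degradation involved).
        """
        base = default_design(n_cases=10_000, seed=17)
        design = SimDesign(
            n_cases=base.n_cases,
            category_probs=np.array([1.0, 0.0, 0.0, 0.0, 0.0]),
            confusion=np.eye(K),
            depth_agreement=base.depth_agreement,
            evidence_certainty=base.evidence_certainty,
            seed=17,
        )
        cases = generate(design)
        ct = coincidence_table(cases)
        order = (CoincidenceLevel.PERFECT, CoincidenceLevel.ALMOST_PERFECT,
                 CoincidenceLevel.MODERATE, CoincidenceLevel.LOW,
                 CoincidenceLevel.NONE)
        observed = np.array([ct.overall[lvl] for lvl in order], dtype=float)
        p = np.append(design.depth_agreement,
                      1 - design.depth_agreement.sum())
        expected = observed.sum() * p
        chi2 = ((observed - expected) ** 2 / expected).sum()
        pval = sps.chi2.sf(chi2, df=len(order) - 1)
        assert pval > 0.01

    def test_infeasible_depth_degrades_to_feasible(self):
        """Malignant codes live in one chapter: 'none' is impossible and the
        generator must fall back to a deeper agreement level."""
        design = SimDesign(
            n_cases=50,
            category_probs=np.array([0.0, 1.0, 0.0, 0.0, 0.0]),
            confusion=np.eye(K),
            depth_agreement=np.array([0.0, 0.0, 0.0, 0.0]),  # all "none"
            seed=23,
        )
        cases = generate(design)
        ct = coincidence_table(cases)
        assert ct.n == 50
        assert ct.overall[CoincidenceLevel.NONE] == 0
        assert ct.overall[CoincidenceLevel.LOW] == 50


class TestParameterRecovery:
    def test_mean_kappa_recovers_analytic_value(self):
        """Mean estimated kappa over replicates at the study size matches the
        design's closed-form kappa within Monte-Carlo error."""
        design = default_design(seed=0)
        target = analytic_kappa(design)
        reps = 500
        kappas = np.empty(reps)
        for i in range(reps):
            cases = generate(dataclasses.replace(design, seed=1000 + i))
            kappas[i] = cohen_kappa(build_confusion_matrix(cases)).kappa
        se = kappas.std(ddof=1) / np.sqrt(reps)
        assert abs(kappas.mean() - target) <= 3 * se
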