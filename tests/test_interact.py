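"""Disease-modulation, risk-interaction, and marginal models."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mitoscan.interact import (
    combination_report,
    marginal_disease_association,
    modulation_test,
    risk_interaction_test,
)
from mitoscan.scanner import ScanConfig, case_only_scan
from mitoscan.simcohort import DiseaseModel, SimConfig, simulate_cohort

from conftest import cohort_from_counts, cross_product_or, make_cohort

NO_COV = ScanConfig(covariate_count=0, min_cell_count=1)


def _counts_2x2x2(
    controls: tuple[int, int, int, int], cases: tuple[int, int, int, int]
) -> dict[tuple[int, int, int], int]:
    """Counts keyed (disease, mt, nuclear) with cell order (11, 10, 01, 00)."""
    out: dict[tuple[int, int, int], int] = {}
    for d, cells in ((0, controls), (1, cases)):
        for (m, x), c in zip(((1, 1), (1, 0), (0, 1), (0, 0)), cells):
            out[(d, m, x)] = c
    return out


class TestModulationTest:
    def test_saturated_counts_closed_form(self):
        """Interaction beta = log of the ratio of stratum-specific ORs."""
        controls, cases = (25, 25, 25, 25), (40, 20, 20, 20)
        cohort = cohort_from_counts(_counts_2x2x2(controls, cases))
        est = modulation_test(cohort, "mt.1000", "rs1", NO_COV)
        or_controls = cross_product_or(25, 25, 25, 25)  # 1.0
        or_cases = cross_product_or(40, 20, 20, 20)  # 2.0
        assert est.status == "ok"
        assert est.beta == pytest.approx(math.log(or_cases / or_controls), abs=1e-6)
        assert est.beta == pytest.approx(math.log(2.0), abs=1e-6)
        assert est.ci95[0] < est.or_ < est.ci95[1]

    def test_asymmetric_counts_closed_form(self):
        controls, cases = (30, 45, 50, 75), (60, 30, 25, 40)
        cohort = cohort_from_counts(_counts_2x2x2(controls, cases))
        est = modulation_test(cohort, "mt.1000", "rs1", NO_COV)
        expected = math.log(
            cross_product_or(*cases) / cross_product_or(*controls)
        )
        assert est.beta == pytest.approx(expected, abs=1e-6)

    def test_no_modulation_null_is_centered(self):
        """Equal mt-n coupling in both strata: interaction within 3 SE of 0."""
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 3000
            disease = (np.arange(n) < n // 2).astype(float)
            x = rng.integers(0, 2, n).astype(float)
            # identical coupling in both strata
            mt = np.where(rng.random(n) < 0.4, x, (rng.random(n) < 0.3).astype(float))
            cohort = make_cohort(x[:, None], mt[:, None], disease=disease)
            est = modulation_test(cohort, "mt.1000", "rs1", NO_COV)
            if abs(est.beta / est.se) > 3:
                hits += 1
        assert hits == 0

    def test_requires_both_strata(self, rng):
        cohort = make_cohort(
            (rng.random((40, 1)) < 0.4).astype(float) + 0.0,
            (rng.random((40, 1)) < 0.4).astype(float),
        )
        with pytest.raises(ValueError, match="both affected and unaffected"):
            modulation_test(cohort, "mt.1000", "rs1", NO_COV)


class TestRiskInteractionTest:
    def test_saturated_counts_closed_form(self):
        """Product-term beta equals the difference of mt-stratified
        disease log-ORs for the nuclear variant."""
        controls, cases = (30, 45, 50, 75), (60, 30, 25, 40)
        cohort = cohort_from_counts(_counts_2x2x2(controls, cases))
        est = risk_interaction_test(cohort, "mt.1000", "rs1", NO_COV)
        # disease x nuclear table within mt=1: cells (case&x, case&!x, ctrl&x, ctrl&!x)
        or_mt1 = cross_product_or(cases[0], cases[1], controls[0], controls[1])
        or_mt0 = cross_product_or(cases[2], cases[3], controls[2], controls[3])
        assert est.status == "ok"
        assert est.beta == pytest.approx(math.log(or_mt1 / or_mt0), abs=1e-6)

    def test_null_interaction_pvalues_uniform(self):
        """Main effects only: the product-term p-value is non-significant
        at the expected rate."""
        sig = 0
        reps = 40
        for seed in range(reps):
            dm = DiseaseModel(
                intercept=-1.0,
                nuclear_effects={0: 0.2},
                mito_effects={0: 0.2},
            )
            cfg = SimConfig(
                n_cases=300, n_controls=300, n_nuclear=1, n_mt=1,
                nuclear_base_freqs=(0.3,), mt_base_freqs=(0.35,),
                disease_model=dm, seed=seed,
            )
            cohort = simulate_cohort(cfg)
            est = risk_interaction_test(
                cohort, cohort.mito_variants[0].id, "rs1", NO_COV
            )
            if est.status == "ok" and est.p < 0.05:
                sig += 1
        # binomial(40, 0.05): >= 8 rejections has probability ~ 2e-4
        assert sig <= 7

    def test_recovers_planted_interaction(self):
        dm = DiseaseModel(
            intercept=-1.5, interaction_effects={(0, 0): math.log(2.0)}
        )
        cfg = SimConfig(
            n_cases=2000, n_controls=2000, n_nuclear=1, n_mt=1,
            nuclear_base_freqs=(0.3,), mt_base_freqs=(0.4,),
            disease_model=dm, seed=99,
        )
        cohort = simulate_cohort(cfg)
        est = risk_interaction_test(cohort, cohort.mito_variants[0].id, "rs1", NO_COV)
        assert est.status == "ok"
        assert abs(est.beta - math.log(2.0)) < 3 * est.se


class TestMarginalDiseaseAssociation:
    def test_two_by_two_cross_product(self):
        # (case&x, case&!x, ctrl&x, ctrl&!x) = (120, 880, 100, 900), binary x
        rows = (
            [(1, 0, 1)] * 120 + [(1, 0, 0)] * 880 + [(0, 0, 1)] * 100 + [(0, 0, 0)] * 900
        )
        counts: dict[tuple[int, int, int], int] = {}
        for key in rows:
            counts[key] = counts.get(key, 0) + 1
        cohort = cohort_from_counts(counts)
        est = marginal_disease_association(cohort, "rs1", NO_COV)
        assert est.or_ == pytest.approx((120 * 900) / (880 * 100), rel=1e-6)
        assert est.or_ == pytest.approx(1.2272727, rel=1e-5)

    def test_mt_variant_uses_haploid_indicator(self, rng):
        n = 2000
        disease = (np.arange(n) < n // 2).astype(float)
        mt = (rng.random(n) < np.where(disease == 1, 0.45, 0.30)).astype(float)
        x = (rng.random(n) < 0.3).astype(float)
        cohort = make_cohort(x[:, None], mt[:, None], disease=disease)
        est = marginal_disease_association(cohort, "mt.1000", NO_COV)
        a = ((disease == 1) & (mt == 1)).sum()
        b = ((disease == 1) & (mt == 0)).sum()
        c = ((disease == 0) & (mt == 1)).sum()
        d = ((disease == 0) & (mt == 0)).sum()
        assert est.or_ == pytest.approx(cross_product_or(a, b, c, d), rel=1e-6)

    def test_null_variant_not_significant(self):
        cfg = SimConfig(
            n_cases=300, n_controls=300, n_nuclear=2, n_mt=1,
            disease_model=DiseaseModel(intercept=-1.0), seed=4,
        )
        cohort = simulate_cohort(cfg)
        est = marginal_disease_association(cohort, "rs1", NO_COV)
        assert est.status == "ok"
        assert est.p > 1e-3  # no effect was planted


class TestCombinationReport:
    def test_empty_list(self, rng):
        cohort = make_cohort(
            (rng.random((20, 1)) < 0.4).astype(float) * 2,
            (rng.random((20, 1)) < 0.4).astype(float),
            disease=(np.arange(20) < 10).astype(float),
        )
        assert combination_report(cohort, []) == []

    def test_row_count_and_planted_signal(self):
        """The planted pair's risk-interaction p is the smallest reported."""
        top_hits = 0
        seeds = range(6)
        for seed in seeds:
            dm = DiseaseModel(
                intercept=-1.5, interaction_effects={(0, 0): math.log(2.5)}
            )
            cfg = SimConfig(
                n_cases=1200, n_controls=1200, n_nuclear=6, n_mt=2,
                nuclear_base_freqs=(0.3, 0.25, 0.35, 0.4, 0.3, 0.2),
                mt_base_freqs=(0.4, 0.3),
                disease_model=dm, seed=1000 + seed,
            )
            cohort = simulate_cohort(cfg)
            mt_ids = [v.id for v in cohort.mito_variants]
            pairs = [(m, f"rs{j + 1}") for m in mt_ids for j in range(6)]
            report = combination_report(cohort, pairs, NO_COV)
            assert len(report) == len(pairs)
            ok = [r for r in report if r.risk_interaction.status == "ok"]
            best = min(ok, key=lambda r: r.risk_interaction.p)
            if (best.mtsnp_id, best.nsnp_id) == (mt_ids[0], "rs1"):
                top_hits += 1
        assert top_hits >= 5

    def test_component_failure_recorded_not_fatal(self, rng):
        n = 60
        disease = (np.arange(n) < 30).astype(float)
        x = np.zeros((n, 1))  # monomorphic nuclear variant
        mt = (rng.random((n, 1)) < 0.4).astype(float)
        cohort = make_cohort(x, mt, disease=disease)
        report = combination_report(cohort, [("mt.1000", "rs1")], NO_COV)
        assert len(report) == 1
        assert report[0].risk_interaction.status == "skipped_low_count"
        assert report[0].n_disease.status == "skipped_low_count"


class TestCaseOnlyIdentity:
    def test_case_only_or_approximates_interaction_or(self):
        """Rare disease + independent variants: the case-only OR tracks the
        risk-interaction OR (single-replicate, 3-SE agreement)."""
        dm = DiseaseModel(
            intercept=math.log(0.01 / 0.99),
            nuclear_effects={0: 0.1},
            mito_effects={0: 0.1},
            interaction_effects={(0, 0): math.log(1.5)},
        )
        cfg = SimConfig(
            n_cases=2000, n_controls=2000, n_nuclear=1, n_mt=1,
            nuclear_base_freqs=(0.25,), mt_base_freqs=(0.3,),
            disease_model=dm, seed=77,
        )
        cohort = simulate_cohort(cfg)
        cases = cohort.affected()
        co = case_only_scan(cases, cases.mito_variants[0].id, ["rs1"], NO_COV)[0]
        ri = risk_interaction_test(cohort, cohort.mito_variants[0].id, "rs1", NO_COV)
        assert co.status == "ok" and ri.status == "ok"
        assert abs(co.beta - ri.beta) < 3 * math.hypot(co.se, ri.se)
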