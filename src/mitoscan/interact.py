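"""Combined-cohort interaction models for mitonuclear combinations.

Three questions follow once a mitonuclear association is found within a
disease cohort:

1. Is the association *modulated* by disease status?  Fit the mtSNP
   indicator on nSNP dosage, disease status, their product and the
   covariates; the disease x dosage coefficient measures how the
   mitonuclear association differs between strata.
2. Does the mtSNP x nSNP *combination* change disease risk?  Fit disease
   status on the mt indicator, the dosage, their product and covariates;
   the product-term OR is the interaction effect on risk.
3. Do the variants associate with disease *on their own*?  Marginal
   single-variant logistic fits.

Under a rare disease with mt and nuclear variants independent in the
source population, the case-only association OR (question 0, from the
scanner) approximates the risk-interaction OR (question 2) — the
identity that justifies the case-only design.

:func:`combination_report` assembles all five fits per combination into
one row, mirroring a significant-combinations summary table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genio import Cohort
from .scanner import (
    AssociationResult,
    ScanConfig,
    _code_nuclear,
    _single_test,
    fit_logistic,
)

__all__ = [
    "InteractionEstimate",
    "MarginalEstimate",
    "CombinationResult",
    "modulation_test",
    "risk_interaction_test",
    "marginal_disease_association",
    "combination_report",
]


@dataclass
class InteractionEstimate:
    """A single interaction coefficient with its Wald inference."""

    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_used: int
    status: str = "ok"


@dataclass
class MarginalEstimate:
    """Marginal disease association of one variant."""

    variant_id: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_used: int
    status: str = "ok"


@dataclass
class CombinationResult:
    """Five model fits summarising one mitonuclear combination."""

    mtsnp_id: str
    nsnp_id: str
    assoc_in_cases: AssociationResult
    modulation: InteractionEstimate
    mt_disease: MarginalEstimate
    n_disease: MarginalEstimate
    risk_interaction: InteractionEstimate

    @staticmethod
    def columns() -> tuple[str, ...]:
        return (
            "mtsnp_id", "nsnp_id",
            "case_p", "case_q", "case_or", "case_ci_low", "case_ci_high", "case_status",
            "modulation_p", "modulation_or", "modulation_ci_low", "modulation_ci_high",
            "modulation_status",
            "mt_disease_p", "mt_disease_or", "n_disease_p", "n_disease_or",
            "interaction_p", "interaction_or", "interaction_ci_low",
            "interaction_ci_high", "interaction_status",
        )

    def as_row(self) -> dict[str, object]:
        a, m, r = self.assoc_in_cases, self.modulation, self.risk_interaction
        return {
            "mtsnp_id": self.mtsnp_id,
            "nsnp_id": self.nsnp_id,
            "case_p": a.p,
            "case_q": a.q,
            "case_or": a.or_,
            "case_ci_low": a.ci95[0],
            "case_ci_high": a.ci95[1],
            "case_status": a.status,
            "modulation_p": m.p,
            "modulation_or": m.or_,
            "modulation_ci_low": m.ci95[0],
            "modulation_ci_high": m.ci95[1],
            "modulation_status": m.status,
            "mt_disease_p": self.mt_disease.p,
            "mt_disease_or": self.mt_disease.or_,
            "n_disease_p": self.n_disease.p,
            "n_disease_or": self.n_disease.or_,
            "interaction_p": r.p,
            "interaction_or": r.or_,
            "interaction_ci_low": r.ci95[0],
            "interaction_ci_high": r.ci95[1],
            "interaction_status": r.status,
        }


def _interaction_fit(
    response: np.ndarray,
    main_a: np.ndarray,
    main_b: np.ndarray,
    covars: np.ndarray,
) -> InteractionEstimate:
    """Fit response ~ a + b + a:b + covars; report the product term."""
    keep = ~np.isnan(response) & ~np.isnan(main_a) & ~np.isnan(main_b)
    if covars.shape[1]:
        keep &= ~np.isnan(covars).any(axis=1)
    yy = response[keep]
    n_used = int(keep.sum())

    def degenerate(status: str) -> InteractionEstimate:
        return InteractionEstimate(
            math.nan, math.nan, math.nan, (math.nan, math.nan), math.nan, n_used, status
        )

    if n_used == 0 or yy.min() == yy.max():
        return degenerate("skipped_low_count")
    a, b = main_a[keep], main_b[keep]
    X = np.column_stack([np.ones(n_used), a, b, a * b, covars[keep]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return degenerate("skipped_low_count")
    fit = fit_logistic(yy, X)
    if fit.status != "ok":
        return degenerate(fit.status)
    beta, se, p = float(fit.coef[3]), float(fit.se[3]), float(fit.p[3])
    return InteractionEstimate(
        beta,
        se,
        math.exp(beta),
        (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        max(p, 1e-300),
        n_used,
        "ok",
    )


def _require_both_strata(cohort: Cohort) -> np.ndarray:
    status = cohort.disease_status
    if status.min() == status.max():
        raise ValueError("combined cohort must contain both affected and unaffected samples")
    return status


def modulation_test(
    cohort: Cohort,
    mtsnp_id: str,
    nsnp_id: str,
    config: ScanConfig = ScanConfig(),
) -> InteractionEstimate:
    """Disease-status modulation of a mitonuclear association.

    Logistic fit of the mt minor-allele indicator on {intercept, nSNP
    dosage, disease status, disease x dosage, covariates} over the
    combined cohort; the disease x dosage term is reported.  A non-null
    coefficient means the mt-nuclear association differs between
    affected and unaffected strata.
    """
    status = _require_both_strata(cohort)
    mt = cohort.mito_calls(mtsnp_id)
    dosage = _code_nuclear(cohort.nuclear_dosage(nsnp_id), config.coding)
    covars = cohort.covariate_matrix(config.covariate_count)
    return _interaction_fit(mt, dosage, status, covars)


def risk_interaction_test(
    cohort: Cohort,
    mtsnp_id: str,
    nsnp_id: str,
    config: ScanConfig = ScanConfig(),
) -> InteractionEstimate:
    """Effect of the mtSNP x nSNP combination on disease risk.

    Logistic fit of disease status on {intercept, mt indicator, nSNP
    dosage, mt x dosage, covariates}; the product term's OR quantifies
    how the combination shifts risk beyond the two main effects.
    """
    status = _require_both_strata(cohort)
    mt = cohort.mito_calls(mtsnp_id)
    dosage = _code_nuclear(cohort.nuclear_dosage(nsnp_id), config.coding)
    covars = cohort.covariate_matrix(config.covariate_count)
    return _interaction_fit(status, mt, dosage, covars)


def marginal_disease_association(
    cohort: Cohort,
    variant_id: str,
    config: ScanConfig = ScanConfig(),
) -> MarginalEstimate:
    """Marginal association of one variant with disease status.

    The variant enters as a haploid indicator (mitochondrial) or coded
    dosage (nuclear) alongside the covariates.
    """
    status = _require_both_strata(cohort)
    variant = cohort.variant(variant_id)
    if variant.is_mitochondrial:
        x = cohort.mito_calls(variant_id)
    else:
        x = _code_nuclear(cohort.nuclear_dosage(variant_id), config.coding)
    covars = cohort.covariate_matrix(config.covariate_count)

    keep = ~np.isnan(status) & ~np.isnan(x)
    if covars.shape[1]:
        keep &= ~np.isnan(covars).any(axis=1)
    yy = status[keep]
    n_used = int(keep.sum())

    def degenerate(st: str) -> MarginalEstimate:
        return MarginalEstimate(
            variant_id, math.nan, math.nan, math.nan, (math.nan, math.nan),
            math.nan, n_used, st,
        )

    if n_used == 0 or yy.min() == yy.max():
        return degenerate("skipped_low_count")
    xs = x[keep]
    if xs.min() == xs.max():
        return degenerate("skipped_low_count")
    X = np.column_stack([np.ones(n_used), xs, covars[keep]])
    fit = fit_logistic(yy, X)
    if fit.status != "ok":
        return degenerate(fit.status)
    beta, se, p = float(fit.coef[1]), float(fit.se[1]), float(fit.p[1])
    return MarginalEstimate(
        variant_id,
        beta,
        se,
        math.exp(beta),
        (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        max(p, 1e-300),
        n_used,
        "ok",
    )


def combination_report(
    cohort: Cohort,
    combinations: list[tuple[str, str]],
    config: ScanConfig = ScanConfig(),
) -> list[CombinationResult]:
    """Assemble the five fits for each (mtSNP, nSNP) combination.

    The case-only association is computed within the affected stratum;
    the other four fits use the full combined cohort.  Component
    failures are recorded in-row as statuses, never raised.
    """
    if not combinations:
        return []
    affected = cohort.affected()
    covars = affected.covariate_matrix(config.covariate_count)
    out: list[CombinationResult] = []
    for mtsnp_id, nsnp_id in combinations:
        try:
            assoc = _single_test(
                affected.mito_calls(mtsnp_id),
                _code_nuclear(affected.nuclear_dosage(nsnp_id), config.coding),
                covars,
                config,
                mtsnp_id,
                nsnp_id,
            )
        except (ValueError, KeyError):
            assoc = AssociationResult(
                mtsnp_id, nsnp_id, math.nan, math.nan, math.nan,
                (math.nan, math.nan), math.nan, math.nan, 0, "skipped_low_count",
            )
        out.append(
            CombinationResult(
                mtsnp_id=mtsnp_id,
                nsnp_id=nsnp_id,
                assoc_in_cases=assoc,
                modulation=modulation_test(cohort, mtsnp_id, nsnp_id, config),
                mt_disease=marginal_disease_association(cohort, mtsnp_id, config),
                n_disease=marginal_disease_association(cohort, nsnp_id, config),
                risk_interaction=risk_interaction_test(cohort, mtsnp_id, nsnp_id, config),
            )
        )
    return out
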