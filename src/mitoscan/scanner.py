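"""Per-cohort case-only mitonuclear association scan.

For each selected mtSNP, every nuclear SNP is tested by logistic
regression of the mt minor-allele indicator on the nuclear dosage plus
leading covariates (typically principal-component scores, which absorb
population stratification).  Because mt and nuclear variants are
transmitted independently, any association within a well-mixed cohort of
affected individuals signals enrichment or depletion of specific
mitonuclear allele combinations — the case-only interaction signal.

False discovery rate is controlled by Benjamini-Hochberg across *all*
tests of a run (every mtSNP x nSNP combination examined), and the
genomic inflation factor / Q-Q coordinates diagnose residual
confounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .genio import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "AssociationResult",
    "LogisticFit",
    "additive_dosage",
    "dominant_coding",
    "fit_logistic",
    "case_only_scan",
    "scan",
    "bh_fdr",
    "genomic_inflation",
    "qq_data",
]

# exact 1-df chi-square median, the Q-Q / lambda reference point
CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


@dataclass(frozen=True)
class ScanConfig:
    """Tuning knobs shared by the scan and the interaction models.

    ``covariate_count``: number of leading sample covariates entered in
    every regression (PC scores by convention; 10 is the GWAS default).
    ``min_cell_count``: a test is skipped when any genotype class among
    complete cases is thinner than this, to avoid separation artifacts.
    ``coding``: nuclear genotype coding, additive dosage by default; the
    dominant (carrier) coding exists for closed-form 2x2 comparisons.
    """

    covariate_count: int = 10
    fdr_threshold: float = 0.05
    alpha_genomewide: float = 5e-8
    min_cell_count: int = 5
    coding: str = "additive"

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError(f"fdr_threshold must be in (0,1), got {self.fdr_threshold}")
        if self.covariate_count < 0:
            raise ValueError("covariate_count must be >= 0")
        if self.coding not in ("additive", "dominant"):
            raise ValueError(f"unknown coding {self.coding!r}")


@dataclass
class AssociationResult:
    """One mtSNP-nSNP logistic association test."""

    mtsnp_id: str
    nsnp_id: str
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    q: float
    n_used: int
    status: str = "ok"

    @staticmethod
    def columns() -> tuple[str, ...]:
        return (
            "mtsnp_id", "nsnp_id", "beta", "se", "or", "ci95_low", "ci95_high",
            "p", "q", "n_used", "status",
        )

    def as_row(self) -> dict[str, object]:
        return {
            "mtsnp_id": self.mtsnp_id,
            "nsnp_id": self.nsnp_id,
            "beta": self.beta,
            "se": self.se,
            "or": self.or_,
            "ci95_low": self.ci95[0],
            "ci95_high": self.ci95[1],
            "p": self.p,
            "q": self.q,
            "n_used": self.n_used,
            "status": self.status,
        }


# -- genotype codings ----------------------------------------------------------


def additive_dosage(calls: np.ndarray) -> np.ndarray:
    """Dosage in {0,1,2,missing} counting the cohort-minor allele.

    Cohort matrices already store minor-allele dosage; this re-checks the
    orientation so a column coded on the other cohort's minor allele is
    flipped (and logged) before analysis.
    """
    calls = np.asarray(calls, dtype=float)
    obs = calls[~np.isnan(calls)]
    if obs.size and obs.mean() / 2.0 > 0.5:
        logger.info("dosage column counts the major allele; flipping to minor")
        return np.where(np.isnan(calls), np.nan, 2.0 - calls)
    return calls.copy()


def dominant_coding(calls: np.ndarray) -> np.ndarray:
    """Carrier indicator: 1 if at least one minor allele."""
    dosage = additive_dosage(calls)
    return np.where(np.isnan(dosage), np.nan, (dosage > 0).astype(float))


# -- logistic regression core --------------------------------------------------


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    status: str  # ok | separation | not_converged
    n_used: int
    loglik: float


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe: log(1+exp(eta)) - y*eta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by Newton/IRLS.

    ``X`` must include the intercept column.  Convergence is declared
    when the log-likelihood improves by less than ``tol``; Wald standard
    errors come from the inverse observed information.  Complete or
    quasi-separation (a fitted probability within 1e-8 of 0 or 1 together
    with a diverging coefficient) yields status ``separation``; hitting
    ``max_iter`` yields ``not_converged``.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.ndim != 1 or X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"shape mismatch: y {y.shape}, X {X.shape}")
    if y.min() == y.max():
        raise ValueError("response is constant; logistic model undefined")

    n, k = X.shape
    beta = np.zeros(k)
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    beta[0] = math.log(ybar / (1 - ybar))  # assumes column 0 is the intercept
    ll = _loglik(y, X @ beta)
    status = "not_converged"
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # halve the step while it worsens the log-likelihood
        new_beta = beta + step
        new_ll = _loglik(y, X @ new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 20:
            step *= 0.5
            new_beta = beta + step
            new_ll = _loglik(y, X @ new_beta)
            halvings += 1
        beta, improve, ll = new_beta, new_ll - ll, new_ll
        if abs(improve) < tol:
            converged = True
            status = "ok"
            break

    mu = expit(X @ beta)
    boundary = (mu < 1e-8) | (mu > 1.0 - 1e-8)
    if boundary.any() and np.max(np.abs(beta)) > 15.0:
        status = "separation"
        converged = False

    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticFit(beta, se, z, p, converged, status, n, ll)


# -- the scan ------------------------------------------------------------------


def _code_nuclear(calls: np.ndarray, coding: str) -> np.ndarray:
    return additive_dosage(calls) if coding == "additive" else dominant_coding(calls)


def _single_test(
    response: np.ndarray,
    dosage: np.ndarray,
    covars: np.ndarray,
    config: ScanConfig,
    mtsnp_id: str,
    nsnp_id: str,
) -> AssociationResult:
    keep = ~np.isnan(response) & ~np.isnan(dosage)
    if covars.shape[1]:
        keep &= ~np.isnan(covars).any(axis=1)
    yy = response[keep]
    dd = dosage[keep]
    n_used = int(keep.sum())

    def degenerate(status: str) -> AssociationResult:
        return AssociationResult(
            mtsnp_id, nsnp_id, math.nan, math.nan, math.nan,
            (math.nan, math.nan), math.nan, math.nan, n_used, status,
        )

    # genotype-class guard: a present-but-thin class invites separation;
    # an absent class merely reduces the coding and is allowed
    classes = np.array([0.0, 1.0, 2.0]) if config.coding == "additive" else np.array([0.0, 1.0])
    counts = np.array([(dd == c).sum() for c in classes])
    present = counts > 0
    if n_used == 0 or present.sum() < 2 or (counts[present] < config.min_cell_count).any():
        return degenerate("skipped_low_count")
    if yy.min() == yy.max():
        return degenerate("skipped_low_count")

    X = np.column_stack([np.ones(n_used), dd, covars[keep]])
    fit = fit_logistic(yy, X)
    if fit.status != "ok":
        return degenerate(fit.status)
    beta, se, p = float(fit.coef[1]), float(fit.se[1]), float(fit.p[1])
    return AssociationResult(
        mtsnp_id,
        nsnp_id,
        beta,
        se,
        math.exp(beta),
        (math.exp(beta - 1.96 * se), math.exp(beta + 1.96 * se)),
        max(p, 1e-300),
        math.nan,
        n_used,
        "ok",
    )


def _scan_one_mt(
    cohort: Cohort,
    mtsnp_id: str,
    nsnp_ids: list[str],
    config: ScanConfig,
) -> list[AssociationResult]:
    response = cohort.mito_calls(mtsnp_id)
    obs = response[~np.isnan(response)]
    if obs.size == 0 or obs.min() == obs.max():
        raise ValueError(f"mtSNP {mtsnp_id} is monomorphic in this cohort")
    covars = cohort.covariate_matrix(config.covariate_count)
    return [
        _single_test(
            response,
            _code_nuclear(cohort.nuclear_dosage(nid), config.coding),
            covars,
            config,
            mtsnp_id,
            nid,
        )
        for nid in nsnp_ids
    ]


def _assign_q(results: list[AssociationResult]) -> list[AssociationResult]:
    ok_idx = [i for i, r in enumerate(results) if r.status == "ok"]
    if ok_idx:
        q = bh_fdr(np.array([results[i].p for i in ok_idx]))
        for i, qi in zip(ok_idx, q):
            results[i].q = float(qi)
    return results


def case_only_scan(
    cohort: Cohort,
    mtsnp_id: str,
    nsnp_ids: list[str] | None = None,
    config: ScanConfig = ScanConfig(),
) -> list[AssociationResult]:
    """Scan one mtSNP against a list of nuclear SNPs within a cohort.

    The response is the mt minor-allele indicator; predictors are an
    intercept, the coded nuclear genotype and the first
    ``config.covariate_count`` covariates, on complete cases.  q-values
    are BH-adjusted across the tests of this call; use :func:`scan` to
    pool the FDR family across several mtSNPs.
    """
    if nsnp_ids is None:
        nsnp_ids = [v.id for v in cohort.nuclear_variants]
    return _assign_q(_scan_one_mt(cohort, mtsnp_id, nsnp_ids, config))


def scan(
    cohort: Cohort,
    mtsnp_ids: list[str],
    nsnp_ids: list[str] | None = None,
    config: ScanConfig = ScanConfig(),
) -> list[AssociationResult]:
    """Scan several mtSNPs with one pooled FDR family.

    q-values are BH-adjusted over all mtSNP x nSNP tests of the run —
    the number of combinations examined.
    """
    if nsnp_ids is None:
        nsnp_ids = [v.id for v in cohort.nuclear_variants]
    results: list[AssociationResult] = []
    for mid in mtsnp_ids:
        results.extend(_scan_one_mt(cohort, mid, nsnp_ids, config))
    return _assign_q(results)


# -- multiple testing and diagnostics ------------------------------------------


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor lambda.

    Median of the 1-df chi-square quantiles implied by the p-values,
    divided by the null chi-square median (~0.4549); lambda > 1 signals
    confounding such as population stratification.  Requires >= 20 tests.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 20:
        raise ValueError(f"need >= 20 p-values for lambda, got {p.size}")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_1DF_MEDIAN)


def qq_data(p_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expected and observed -log10 p coordinates for a Q-Q plot.

    Observed values are sorted descending; expected values are
    ``-log10((i - 0.5)/m)`` for ranks ``i = 1..m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    m = p.size
    observed = np.sort(-np.log10(p))[::-1]
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    return expected, observed
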