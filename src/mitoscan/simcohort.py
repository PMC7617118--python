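"""Stratified case/control cohort simulator with joint mt-nuclear genotypes.

The generator reproduces the statistical structure the scan has to cope
with, without any real genotype data:

* **Population stratification** via the Balding-Nichols model: each
  subpopulation's allele frequency is a Beta draw around an ancestral
  frequency with variance ``Fst * p * (1 - p)``.  Mitochondrial allele
  frequencies may differ arbitrarily between subpopulations — the
  classic confounder for mitonuclear association scans, since mtDNA
  lineages track ancestry.
* **Local LD** through a latent Gaussian AR(1) copula within fixed-size
  blocks: haplotype alleles are thresholded correlated normals, giving
  exact marginal frequencies, first-order correlation inside a block and
  independence across blocks (so the genome-wide null stays exact).
* **Disease** by a logistic model on the log-odds scale with optional
  nuclear, mitochondrial and mt x nuclear interaction effects, followed
  by rejection sampling to the requested case/control counts — mimicking
  separately ascertained disease and population cohorts.
* **Direct mt-nuclear coupling** (disease-free) for power experiments:
  one designated pair is drawn from the 2x2 joint distribution with a
  specified odds ratio between the mt allele and nuclear carrier status.

Defaults target a cohort of 2000 individuals per arm, mtSNP frequencies
in the common range, and disease prevalence 0.01 so the rare-disease
case-only identity holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtri

from .genio import Cohort, SampleRecord, VariantRecord, recompute_mafs
from .powercalc import carrier_frequency, solve_joint_distribution
from .scanner import ScanConfig, case_only_scan

__all__ = [
    "DiseaseModel",
    "CouplingSpec",
    "SimConfig",
    "PowerExperimentResult",
    "draw_subpop_frequencies",
    "simulate_cohort",
    "compute_pcs",
    "attach_pcs",
    "power_experiment",
]

# rCRS-style positions for synthetic mtSNP ids
_DEFAULT_MT_POSITIONS = (2706, 3010, 7028, 9055, 11251, 11467, 12308, 12372, 13368, 16189)

_MAX_DRAWS = 10_000_000


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic disease model on the log-odds scale.

    ``intercept`` sets the baseline prevalence (default logit(0.01));
    effect dictionaries map variant indices (nuclear index, mt index, or
    (mt, nuclear) pairs) to log-odds coefficients.  Nuclear effects act
    per minor allele; mt effects per allele indicator; interactions on
    the product.
    """

    intercept: float = math.log(0.01 / 0.99)
    nuclear_effects: dict[int, float] = field(default_factory=dict)
    mito_effects: dict[int, float] = field(default_factory=dict)
    interaction_effects: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass(frozen=True)
class CouplingSpec:
    """Direct mt-nuclear association for one designated pair.

    The mt allele and nuclear *carrier* status are drawn jointly with
    cross-product ratio ``odds_ratio``; carrier genotypes split into
    het/hom by their HWE conditional probabilities.  Only defined for a
    single-subpopulation configuration.
    """

    mt_index: int
    n_index: int
    odds_ratio: float


@dataclass(frozen=True)
class SimConfig:
    """Full generative specification of a synthetic cohort."""

    n_cases: int = 2000
    n_controls: int = 2000
    n_nuclear: int = 200
    block_size: int = 10
    within_block_corr: float = 0.7
    n_mt: int = 6
    subpop_weights: tuple[float, ...] = (1.0,)
    fst: float = 0.0
    base_freq_range: tuple[float, float] = (0.1, 0.5)
    nuclear_base_freqs: tuple[float, ...] | None = None
    mt_base_freqs: tuple[float, ...] | None = None
    mt_freqs_by_subpop: tuple[tuple[float, ...], ...] | None = None
    disease_model: DiseaseModel = field(default_factory=DiseaseModel)
    coupling: CouplingSpec | None = None
    case_label: str = "case"
    control_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases + self.n_controls <= 0:
            raise ValueError("n_cases + n_controls must be positive")
        if abs(sum(self.subpop_weights) - 1.0) > 1e-9:
            raise ValueError("subpop_weights must sum to 1")
        if not (0.0 <= self.fst < 0.5):
            raise ValueError(f"fst must be in [0, 0.5), got {self.fst}")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must be in [0, 1)")
        lo, hi = self.base_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"base_freq_range must satisfy 0 < lo <= hi < 1, got {self.base_freq_range}")
        if self.coupling is not None and len(self.subpop_weights) != 1:
            raise ValueError("coupling_or is only defined for a single subpopulation")

    @property
    def n_subpops(self) -> int:
        return len(self.subpop_weights)


def draw_subpop_frequencies(
    base_freq: float, fst: float, n_subpops: int, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies around ``base_freq``.

    Independent Beta draws with mean ``base_freq`` and variance
    ``fst * base_freq * (1 - base_freq)``; ``fst = 0`` returns the base
    frequency exactly for every subpopulation.
    """
    if not (0.0 < base_freq < 1.0):
        raise ValueError(f"base_freq must be in (0, 1), got {base_freq}")
    if not (0.0 <= fst < 0.5):
        raise ValueError(f"fst must be in [0, 0.5), got {fst}")
    if fst == 0.0:
        return np.full(n_subpops, base_freq)
    scale = (1.0 - fst) / fst
    return rng.beta(base_freq * scale, (1.0 - base_freq) * scale, size=n_subpops)


# -- internal draws ------------------------------------------------------------


def _block_slices(m: int, block_size: int) -> list[slice]:
    return [slice(s, min(s + block_size, m)) for s in range(0, m, block_size)]


def _draw_haplotypes(
    rng: np.random.Generator,
    subpop_of_hap: np.ndarray,
    freqs: np.ndarray,  # (n_subpops, m)
    block_size: int,
    rho: float,
) -> np.ndarray:
    """Haplotype alleles via a blockwise AR(1) Gaussian copula."""
    h, m = subpop_of_hap.size, freqs.shape[1]
    z = np.empty((h, m))
    for sl in _block_slices(m, block_size):
        width = sl.stop - sl.start
        eps = rng.standard_normal((h, width))
        z[:, sl.start] = eps[:, 0]
        for j in range(1, width):
            z[:, sl.start + j] = rho * z[:, sl.start + j - 1] + math.sqrt(1 - rho * rho) * eps[:, j]
    thr = ndtri(np.clip(freqs, 1e-12, 1 - 1e-12))
    return (z < thr[subpop_of_hap, :]).astype(np.int8)


def _apply_coupling(
    rng: np.random.Generator,
    cfg: SimConfig,
    nuclear: np.ndarray,
    mito: np.ndarray,
    p_mt: float,
    maf_n: float,
) -> None:
    """Overwrite the designated pair with a jointly drawn 2x2 cell."""
    c = cfg.coupling
    assert c is not None
    p_car = carrier_frequency(maf_n)
    p11, p10, p01, p00 = solve_joint_distribution(p_mt, p_car, c.odds_ratio)
    b = nuclear.shape[0]
    cell = rng.choice(4, size=b, p=[p11, p10, p01, p00])
    mt_call = (cell <= 1).astype(float)  # cells 11, 10 have the mt allele
    carrier = (cell % 2 == 0).astype(bool)  # cells 11, 01 carry the nuclear allele
    # split carriers into het/hom by HWE conditionals
    p_hom_given_carrier = maf_n**2 / p_car
    hom = rng.random(b) < p_hom_given_carrier
    geno = np.where(carrier, np.where(hom, 2.0, 1.0), 0.0)
    mito[:, c.mt_index] = mt_call
    nuclear[:, c.n_index] = geno


def _disease_probability(
    model: DiseaseModel, nuclear: np.ndarray, mito: np.ndarray
) -> np.ndarray:
    eta = np.full(nuclear.shape[0], model.intercept)
    for j, beta in model.nuclear_effects.items():
        eta += beta * nuclear[:, j]
    for j, beta in model.mito_effects.items():
        eta += beta * mito[:, j]
    for (mj, nj), beta in model.interaction_effects.items():
        eta += beta * mito[:, mj] * nuclear[:, nj]
    return expit(eta)


def _resolve_frequencies(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subpopulation nuclear and mt frequency matrices."""
    s = cfg.n_subpops
    if cfg.nuclear_base_freqs is not None:
        if len(cfg.nuclear_base_freqs) != cfg.n_nuclear:
            raise ValueError("nuclear_base_freqs length must equal n_nuclear")
        base_n = np.asarray(cfg.nuclear_base_freqs, dtype=float)
    else:
        lo, hi = cfg.base_freq_range
        base_n = rng.uniform(lo, hi, size=cfg.n_nuclear)
    nuc = np.vstack([draw_subpop_frequencies(p, cfg.fst, s, rng) for p in base_n]).T

    if cfg.mt_freqs_by_subpop is not None:
        mt = np.asarray(cfg.mt_freqs_by_subpop, dtype=float)
        if mt.shape != (s, cfg.n_mt):
            raise ValueError(
                f"mt_freqs_by_subpop must be {s} x {cfg.n_mt}, got {mt.shape}"
            )
    else:
        if cfg.mt_base_freqs is not None:
            if len(cfg.mt_base_freqs) != cfg.n_mt:
                raise ValueError("mt_base_freqs length must equal n_mt")
            base_mt = np.asarray(cfg.mt_base_freqs, dtype=float)
        else:
            base_mt = rng.uniform(0.2, 0.5, size=cfg.n_mt)
        mt = np.vstack([draw_subpop_frequencies(p, cfg.fst, s, rng) for p in base_mt]).T
    return nuc, mt


def _variant_metadata(cfg: SimConfig) -> tuple[list[VariantRecord], list[VariantRecord]]:
    nuc = [
        VariantRecord(
            id=f"rs{j + 1}", chrom="1", pos=10_000 * (j + 1),
            ref_allele="A", alt_allele="G", maf=0.0,
        )
        for j in range(cfg.n_nuclear)
    ]
    positions = list(_DEFAULT_MT_POSITIONS)
    while len(positions) < cfg.n_mt:
        positions.append(positions[-1] + 101)
    mit = [
        VariantRecord(
            id=f"mt.{positions[j]}", chrom="MT", pos=positions[j],
            ref_allele="A", alt_allele="G", maf=0.0,
        )
        for j in range(cfg.n_mt)
    ]
    return nuc, mit


def simulate_cohort(
    config: SimConfig, return_subpops: bool = False
) -> Cohort | tuple[Cohort, np.ndarray]:
    """Draw a case/control cohort from the generative model.

    Individuals are drawn in batches — subpopulation, LD-blocked nuclear
    haplotypes, haploid mt calls, optional coupling, then disease status
    from the logistic model — and kept until exactly ``n_cases`` affected
    and ``n_controls`` unaffected individuals are collected (budget 10^7
    draws).  Deterministic given ``config.seed``.  Cases precede controls
    in the returned cohort; variant MAFs are recomputed from the realized
    matrices.  With ``return_subpops`` the true subpopulation labels are
    returned alongside (simulation truth, useful for diagnostics).
    """
    rng = np.random.default_rng(config.seed)
    nuc_freqs, mt_freqs = _resolve_frequencies(config, rng)
    weights = np.asarray(config.subpop_weights)

    need_cases, need_controls = config.n_cases, config.n_controls
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    case_mt: list[np.ndarray] = []
    control_mt: list[np.ndarray] = []
    case_sub: list[np.ndarray] = []
    control_sub: list[np.ndarray] = []
    got_cases = got_controls = 0
    drawn = 0
    # keep batches within ~1e7 matrix cells; adapt to the realized case rate
    max_batch = max(1000, int(1e7 / max(config.n_nuclear + config.n_mt, 1)))
    batch = min(max(2 * (need_cases + need_controls), 1000), max_batch)

    while got_cases < need_cases or got_controls < need_controls:
        if drawn >= _MAX_DRAWS:
            raise RuntimeError(
                f"ascertainment budget of {_MAX_DRAWS} draws exceeded with "
                f"{got_cases}/{need_cases} cases; the disease model's intercept "
                "implies too low a case probability — raise b0"
            )
        b = min(batch, _MAX_DRAWS - drawn)
        drawn += b
        sub = rng.choice(weights.size, size=b, p=weights)
        hap_sub = np.repeat(sub, 2)
        alleles = _draw_haplotypes(
            rng, hap_sub, nuc_freqs, config.block_size, config.within_block_corr
        )
        nuclear = (alleles[0::2] + alleles[1::2]).astype(float)
        mito = (rng.random((b, config.n_mt)) < mt_freqs[sub, :]).astype(float)
        if config.coupling is not None:
            _apply_coupling(
                rng, config, nuclear, mito,
                p_mt=float(mt_freqs[0, config.coupling.mt_index]),
                maf_n=float(nuc_freqs[0, config.coupling.n_index]),
            )
        prob = _disease_probability(config.disease_model, nuclear, mito)
        is_case = rng.random(b) < prob

        for stash_n, stash_m, stash_s, mask, got, need in (
            (case_rows, case_mt, case_sub, is_case, got_cases, need_cases),
            (control_rows, control_mt, control_sub, ~is_case, got_controls, need_controls),
        ):
            take = min(int(mask.sum()), need - got)
            if take > 0:
                idx = np.flatnonzero(mask)[:take]
                stash_n.append(nuclear[idx])
                stash_m.append(mito[idx])
                stash_s.append(sub[idx])
        got_cases = sum(len(x) for x in case_rows)
        got_controls = sum(len(x) for x in control_rows)
        # size the next batch from the realized rate of the scarcer class
        case_rate = max(is_case.mean(), 1.0 / b)
        deficits = []
        if got_cases < need_cases:
            deficits.append((need_cases - got_cases) / case_rate)
        if got_controls < need_controls:
            deficits.append((need_controls - got_controls) / max(1.0 - case_rate, 1.0 / b))
        if deficits:
            batch = int(min(max(1.3 * max(deficits), 1000), max_batch))

    def _stack(parts: list[np.ndarray], width: int) -> np.ndarray:
        return np.vstack(parts) if parts else np.empty((0, width))

    nuclear = np.vstack(
        [_stack(case_rows, config.n_nuclear), _stack(control_rows, config.n_nuclear)]
    )
    mito = np.vstack([_stack(case_mt, config.n_mt), _stack(control_mt, config.n_mt)])
    subpops = np.concatenate(
        [
            np.concatenate(case_sub) if case_sub else np.empty(0, dtype=int),
            np.concatenate(control_sub) if control_sub else np.empty(0, dtype=int),
        ]
    )
    samples = [
        SampleRecord(f"case_{i + 1:05d}", config.case_label, 1)
        for i in range(need_cases)
    ] + [
        SampleRecord(f"ctrl_{i + 1:05d}", config.control_label, 0)
        for i in range(need_controls)
    ]
    nuc_vars, mit_vars = _variant_metadata(config)
    cohort = recompute_mafs(Cohort(nuclear, mito, nuc_vars, mit_vars, samples))
    if return_subpops:
        return cohort, subpops
    return cohort


# -- principal components ------------------------------------------------------


def compute_pcs(nuclear: np.ndarray, k: int) -> np.ndarray:
    """Per-sample principal-component scores of a dosage matrix.

    Columns are centred by twice the allele frequency and scaled by
    ``sqrt(2 p (1-p))`` (unit variance under HWE); missing entries are
    mean-imputed.  Returns the first ``k`` left-singular-vector scores
    (U * S), deterministic up to column sign.
    """
    X = np.asarray(nuclear, dtype=float)
    n, m = X.shape
    if k == 0:
        return np.empty((n, 0))
    if k < 0 or k + 1 > n:
        raise ValueError(f"need at least k+1={k + 1} samples for k={k} PCs")
    p = np.nanmean(X, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if int(poly.sum()) < k:
        raise ValueError(f"need >= {k} polymorphic SNPs, found {int(poly.sum())}")
    Xp = X[:, poly]
    pp = p[poly]
    Xp = np.where(np.isnan(Xp), 2.0 * pp, Xp)
    Z = (Xp - 2.0 * pp) / np.sqrt(2.0 * pp * (1.0 - pp))
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    if k > S.size:
        raise ValueError(f"k={k} exceeds matrix rank {S.size}")
    return U[:, :k] * S[:k]


def attach_pcs(cohort: Cohort, k: int) -> Cohort:
    """Return a cohort whose sample covariates are its first k PC scores."""
    scores = compute_pcs(cohort.nuclear, k)
    samples = [
        SampleRecord(s.sample_id, s.cohort, s.disease_status, tuple(scores[i]))
        for i, s in enumerate(cohort.samples)
    ]
    return Cohort(
        cohort.nuclear, cohort.mito, cohort.nuclear_variants, cohort.mito_variants, samples
    )


# -- Monte-Carlo power ---------------------------------------------------------


@dataclass(frozen=True)
class PowerExperimentResult:
    rejection_rate: float
    se: float
    n_reps: int
    alpha: float


def power_experiment(
    config: SimConfig, n_reps: int, alpha: float
) -> PowerExperimentResult:
    """Empirical power of the coupled-pair association test.

    Repeats :func:`simulate_cohort` + a covariate-free, dominant-coded
    :func:`mitoscan.scanner.case_only_scan` of the designated pair and
    returns the fraction of replicates with p < ``alpha`` plus its
    binomial standard error.  This is the Monte-Carlo oracle for
    :func:`mitoscan.powercalc.association_power`.
    """
    if config.coupling is None:
        raise ValueError("power_experiment requires config.coupling")
    if n_reps < 100:
        raise ValueError(f"n_reps must be >= 100, got {n_reps}")
    scan_cfg = ScanConfig(covariate_count=0, coding="dominant", min_cell_count=1)
    seeds = np.random.SeedSequence(config.seed).generate_state(n_reps) % (2**31)
    mt_id_idx = config.coupling.mt_index
    n_id_idx = config.coupling.n_index
    rejections = 0
    from dataclasses import replace as dc_replace

    for rep in range(n_reps):
        cohort = simulate_cohort(dc_replace(config, seed=int(seeds[rep])))
        mt_id = cohort.mito_variants[mt_id_idx].id
        n_id = cohort.nuclear_variants[n_id_idx].id
        res = case_only_scan(cohort, mt_id, [n_id], scan_cfg)[0]
        if res.status == "ok" and res.p < alpha:
            rejections += 1
    rate = rejections / n_reps
    return PowerExperimentResult(
        rate, math.sqrt(rate * (1.0 - rate) / n_reps), n_reps, alpha
    )
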