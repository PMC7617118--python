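"""Shared data model and genotype/table I/O.

The central container is :class:`Cohort`: an aligned pair of genotype
matrices (diploid nuclear dosages, haploid mitochondrial calls) plus
variant and sample metadata.  Genotypes travel as VCF 4.2 (GT field only);
sample metadata as a tab-separated table with columns
``sample_id, cohort, disease_status, pc1..pck``.

Conventions
-----------
* Dosages count the cohort-minor allele; minor/major is decided at read
  time from the genotype matrix, never trusted from the input.  When the
  ALT allele is the major one the record's REF/ALT are swapped internally
  so that ``alt_allele`` is always the counted (minor) allele.
* Mitochondrial variants are haploid: calls are 0/1; heterozygous or
  heteroplasmic diploid-style MT calls are set missing.
* Missing values are ``numpy.nan`` in both matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MITO_CHROM_ALIASES = {"MT", "chrM", "chrMT", "M", "26"}

__all__ = [
    "VariantRecord",
    "SampleRecord",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "write_results",
]


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant.

    ``id`` follows dbSNP style for nuclear SNPs (``rsNNN``) and ``mt.POS``
    for mitochondrial ones; ``chrom`` is ``"MT"`` exactly when the id has
    the ``mt.`` prefix.  ``maf`` is recomputed from the genotype matrix.
    Positions are 1-based (GRCh37 convention).
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        is_mt_chrom = self.chrom == "MT"
        if is_mt_chrom != self.id.startswith("mt."):
            raise ValueError(
                f"variant {self.id}: chrom 'MT' is required exactly for ids "
                f"beginning 'mt.' (got chrom={self.chrom!r})"
            )
        if not (0.0 <= self.maf <= 0.5 + 1e-12):
            raise ValueError(f"variant {self.id}: maf {self.maf} outside [0, 0.5]")

    @property
    def is_mitochondrial(self) -> bool:
        return self.chrom == "MT"


@dataclass(frozen=True)
class SampleRecord:
    """One individual: cohort label, binary disease status, covariates."""

    sample_id: str
    cohort: str
    disease_status: int
    covariates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.disease_status not in (0, 1):
            raise ValueError(
                f"sample {self.sample_id}: disease_status must be 0 or 1, "
                f"got {self.disease_status!r}"
            )


@dataclass
class Cohort:
    """Aligned genotype matrices and metadata for one set of samples.

    ``nuclear`` is samples x nSNPs with dosages in {0, 1, 2, nan};
    ``mito`` is samples x mtSNPs with haploid calls in {0, 1, nan}.
    Row order matches ``samples``; column order matches the variant lists.
    """

    nuclear: np.ndarray
    mito: np.ndarray
    nuclear_variants: list[VariantRecord]
    mito_variants: list[VariantRecord]
    samples: list[SampleRecord]

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear, dtype=float)
        self.mito = np.asarray(self.mito, dtype=float)
        n = len(self.samples)
        if self.nuclear.shape != (n, len(self.nuclear_variants)):
            raise ValueError(
                f"nuclear matrix shape {self.nuclear.shape} does not match "
                f"{n} samples x {len(self.nuclear_variants)} variants"
            )
        if self.mito.shape != (n, len(self.mito_variants)):
            raise ValueError(
                f"mito matrix shape {self.mito.shape} does not match "
                f"{n} samples x {len(self.mito_variants)} variants"
            )
        ok_mito = np.isnan(self.mito) | (self.mito == 0) | (self.mito == 1)
        if not ok_mito.all():
            raise ValueError("mito matrix contains values other than 0, 1, missing")
        k = {len(s.covariates) for s in self.samples}
        if len(k) > 1:
            raise ValueError(f"covariate vector length differs across samples: {sorted(k)}")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def disease_status(self) -> np.ndarray:
        return np.array([s.disease_status for s in self.samples], dtype=float)

    @property
    def cohort_labels(self) -> np.ndarray:
        return np.array([s.cohort for s in self.samples], dtype=object)

    def covariate_matrix(self, k: int | None = None) -> np.ndarray:
        """First ``k`` covariate columns (all when ``k`` is None)."""
        full = np.array([s.covariates for s in self.samples], dtype=float)
        if full.size == 0:
            full = full.reshape(self.n_samples, 0)
        if k is None:
            return full
        return full[:, : min(k, full.shape[1])]

    def _index(self, variants: list[VariantRecord], variant_id: str) -> int:
        for i, v in enumerate(variants):
            if v.id == variant_id:
                return i
        raise KeyError(f"variant {variant_id!r} not in cohort")

    def nuclear_dosage(self, variant_id: str) -> np.ndarray:
        return self.nuclear[:, self._index(self.nuclear_variants, variant_id)]

    def mito_calls(self, variant_id: str) -> np.ndarray:
        return self.mito[:, self._index(self.mito_variants, variant_id)]

    def variant(self, variant_id: str) -> VariantRecord:
        for v in self.nuclear_variants + self.mito_variants:
            if v.id == variant_id:
                return v
        raise KeyError(f"variant {variant_id!r} not in cohort")

    def subset_samples(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask, dtype=bool)
        return Cohort(
            nuclear=self.nuclear[mask],
            mito=self.mito[mask],
            nuclear_variants=list(self.nuclear_variants),
            mito_variants=list(self.mito_variants),
            samples=[s for s, m in zip(self.samples, mask) if m],
        )

    def affected(self) -> "Cohort":
        return self.subset_samples(self.disease_status == 1)

    def unaffected(self) -> "Cohort":
        return self.subset_samples(self.disease_status == 0)


# -- helpers -------------------------------------------------------------------


def _matrix_maf(column: np.ndarray, ploidy: int) -> float:
    """Minor allele frequency of one dosage column; nan for all-missing."""
    obs = column[~np.isnan(column)]
    if obs.size == 0:
        return float("nan")
    f = float(obs.mean()) / ploidy
    return min(f, 1.0 - f)


def recompute_mafs(cohort: Cohort) -> Cohort:
    """Return a cohort whose VariantRecord mafs match the matrices."""
    nuc = [
        replace(v, maf=_matrix_maf(cohort.nuclear[:, j], 2))
        for j, v in enumerate(cohort.nuclear_variants)
    ]
    mit = [
        replace(v, maf=_matrix_maf(cohort.mito[:, j], 1))
        for j, v in enumerate(cohort.mito_variants)
    ]
    return Cohort(cohort.nuclear, cohort.mito, nuc, mit, list(cohort.samples))


# -- reading -------------------------------------------------------------------


def _read_sample_table(sample_path: str) -> pd.DataFrame:
    try:
        table = pd.read_csv(sample_path, sep="\t", dtype={"sample_id": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"malformed sample table {sample_path}: {exc}") from exc
    required = ["sample_id", "cohort", "disease_status"]
    for col in required:
        if col not in table.columns:
            raise ValueError(
                f"malformed sample table {sample_path}: missing column {col!r}"
            )
    bad = ~table["disease_status"].isin([0, 1])
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(
            f"malformed sample table {sample_path}: line {line}: "
            "disease_status must be 0 or 1"
        )
    return table


def read_cohort(genotype_path: str, sample_path: str) -> Cohort:
    """Read a VCF and sample table into a :class:`Cohort`.

    Samples are restricted to the intersection of IDs in the two inputs
    (VCF sample order).  Non-biallelic records are skipped with a warning.
    Records on a mitochondrial contig become haploid columns: diploid
    homozygous calls map to 0/1, heterozygous calls to missing.  MAF is
    recomputed per variant from the resulting matrix; when the ALT allele
    turns out to be the major one, dosages are flipped to count the minor
    allele and the record's REF/ALT are swapped accordingly.
    """
    from cyvcf2 import VCF

    table = _read_sample_table(sample_path)
    vcf = VCF(genotype_path)
    vcf_samples = list(vcf.samples)
    table_ids = set(table["sample_id"])
    keep_idx = [i for i, s in enumerate(vcf_samples) if s in table_ids]
    if not keep_idx:
        raise ValueError(
            f"no overlapping sample IDs between {genotype_path} and {sample_path}"
        )
    kept = [vcf_samples[i] for i in keep_idx]

    nuc_cols: list[np.ndarray] = []
    mit_cols: list[np.ndarray] = []
    nuc_vars: list[VariantRecord] = []
    mit_vars: list[VariantRecord] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            logger.warning(
                "skipping non-biallelic record %s:%s (%s)", rec.CHROM, rec.POS, rec.ID
            )
            continue
        is_mt = rec.CHROM in MITO_CHROM_ALIASES
        calls = np.full(len(keep_idx), np.nan)
        for out_i, vcf_i in enumerate(keep_idx):
            gt = rec.genotypes[vcf_i]
            alleles = [a for a in gt[:-1] if a >= 0]
            if not alleles:
                continue
            if is_mt:
                # haploid: distinct diploid alleles = heteroplasmy -> missing
                if len(set(alleles)) > 1:
                    continue
                calls[out_i] = float(alleles[0])
            else:
                if len(alleles) != 2:
                    continue  # partial/haploid nuclear call -> missing
                calls[out_i] = float(sum(alleles))
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        ref, alt = rec.REF, rec.ALT[0]
        ploidy = 1 if is_mt else 2
        maf = _matrix_maf(calls, ploidy)
        obs = calls[~np.isnan(calls)]
        if obs.size and obs.mean() / ploidy > 0.5:
            calls = np.where(np.isnan(calls), np.nan, ploidy - calls)
            ref, alt = alt, ref
            logger.info("variant %s: ALT is major allele; flipped to count minor", vid)
        record = VariantRecord(
            id=vid,
            chrom="MT" if is_mt else rec.CHROM,
            pos=rec.POS,
            ref_allele=ref,
            alt_allele=alt,
            maf=0.0 if math.isnan(maf) else maf,
        )
        if is_mt:
            mit_cols.append(calls)
            mit_vars.append(record)
        else:
            nuc_cols.append(calls)
            nuc_vars.append(record)

    sub = table.set_index("sample_id").loc[kept]
    cov_cols = [c for c in table.columns if c not in ("sample_id", "cohort", "disease_status")]
    samples = [
        SampleRecord(
            sample_id=sid,
            cohort=str(row["cohort"]),
            disease_status=int(row["disease_status"]),
            covariates=tuple(float(row[c]) for c in cov_cols),
        )
        for sid, row in sub.iterrows()
    ]
    n = len(samples)
    nuclear = np.column_stack(nuc_cols) if nuc_cols else np.empty((n, 0))
    mito = np.column_stack(mit_cols) if mit_cols else np.empty((n, 0))
    return Cohort(nuclear, mito, nuc_vars, mit_vars, samples)


# -- writing -------------------------------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "{contigs}"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def _gt_field(value: float, haploid: bool) -> str:
    if haploid:
        return "." if math.isnan(value) else str(int(value))
    if math.isnan(value):
        return "./."
    d = int(value)
    return {0: "0/0", 1: "0/1", 2: "1/1"}[d]


def write_cohort(cohort: Cohort, genotype_path: str, sample_path: str) -> None:
    """Write a cohort as VCF 4.2 plus a tab-separated sample table.

    Mitochondrial records go on contig ``MT`` with haploid GT fields.
    ``read_cohort(write_cohort(x))`` reproduces ``x``.
    """
    contigs = []
    for v in cohort.nuclear_variants + cohort.mito_variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in contigs)
    ids = [s.sample_id for s in cohort.samples]
    records = [(v, cohort.nuclear[:, j], False) for j, v in enumerate(cohort.nuclear_variants)]
    records += [(v, cohort.mito[:, j], True) for j, v in enumerate(cohort.mito_variants)]
    records.sort(key=lambda r: (contigs.index(r[0].chrom), r[0].pos))
    try:
        with open(genotype_path, "w") as fh:
            fh.write(_VCF_HEADER.format(contigs=contig_lines))
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(ids) + "\n")
            for v, col, haploid in records:
                gts = "\t".join(_gt_field(x, haploid) for x in col)
                fh.write(
                    f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref_allele}\t{v.alt_allele}"
                    f"\t.\t.\t.\tGT\t{gts}\n"
                )
    except OSError as exc:
        raise ValueError(f"cannot write genotypes to {genotype_path}: {exc}") from exc

    k = len(cohort.samples[0].covariates) if cohort.samples else 0
    cols = ["sample_id", "cohort", "disease_status"] + [f"pc{i + 1}" for i in range(k)]
    rows = [
        [s.sample_id, s.cohort, s.disease_status, *s.covariates] for s in cohort.samples
    ]
    frame = pd.DataFrame(rows, columns=cols)
    try:
        frame.to_csv(sample_path, sep="\t", index=False, float_format="%.10g")
    except OSError as exc:
        raise ValueError(f"cannot write sample table to {sample_path}: {exc}") from exc


def write_results(results: Sequence[object], path: str) -> None:
    """Write association or combination results as a TSV with a header.

    The list must be homogeneous; rows keep input order and floats carry
    at least six significant digits.
    """
    rows = [r.as_row() for r in results]
    if results:
        kinds = {type(r).__name__ for r in results}
        if len(kinds) > 1:
            raise ValueError(f"mixed result types: {sorted(kinds)}")
        columns = list(rows[0].keys())
    else:
        # header-only file for the empty case
        from .scanner import AssociationResult

        columns = list(AssociationResult.columns())
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
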