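"""Shared fixtures and cohort builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from mitoscan.genio import Cohort, SampleRecord, VariantRecord, recompute_mafs


def make_cohort(
    nuclear: np.ndarray,
    mito: np.ndarray,
    disease: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> Cohort:
    """Build a cohort straight from matrices, with synthetic metadata."""
    nuclear = np.asarray(nuclear, dtype=float)
    mito = np.asarray(mito, dtype=float)
    n = nuclear.shape[0]
    if disease is None:
        disease = np.zeros(n)
    nuc_vars = [
        VariantRecord(f"rs{j + 1}", "1", 1000 * (j + 1), "A", "G", 0.0)
        for j in range(nuclear.shape[1])
    ]
    mt_vars = [
        VariantRecord(f"mt.{1000 + j}", "MT", 1000 + j, "A", "G", 0.0)
        for j in range(mito.shape[1])
    ]
    samples = [
        SampleRecord(
            f"s{i + 1:04d}",
            "case" if disease[i] else "control",
            int(disease[i]),
            tuple(covariates[i]) if covariates is not None else (),
        )
        for i in range(n)
    ]
    return recompute_mafs(Cohort(nuclear, mito, nuc_vars, mt_vars, samples))


def cohort_from_counts(counts: dict[tuple[int, int, int], int]) -> Cohort:
    """Cohort from saturated 2x2x2 counts keyed (disease, mt, nuclear)."""
    rows_n, rows_m, dis = [], [], []
    for (d, m, x), c in counts.items():
        rows_n += [float(x)] * c
        rows_m += [float(m)] * c
        dis += [d] * c
    nuclear = np.array(rows_n)[:, None]
    mito = np.array(rows_m)[:, None]
    return make_cohort(nuclear, mito, disease=np.array(dis, dtype=float))


def cross_product_or(a: float, b: float, c: float, d: float) -> float:
    """Closed-form 2x2 odds ratio (a d)/(b c) for cells (11, 10, 01, 00)."""
    return (a * d) / (b * c)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)
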