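"""Selection of analysis-ready mitochondrial SNPs.

Common mtSNPs travel in tight linkage: variants defining the same mtDNA
lineage are near-perfectly correlated, so scanning all of them would test
the same haplotype repeatedly.  Selection is therefore two steps: drop
mtSNPs below a minimum MAF (the power-derived eligibility bound), then
prune near-duplicate variants by pairwise haploid R^2 — pairs above the
threshold are joined in a graph and each connected component keeps one
representative (highest MAF, ties broken by smallest position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genio import VariantRecord

logger = logging.getLogger(__name__)

__all__ = ["MtSelection", "haploid_maf", "haploid_r2", "prune_mtsnps"]


@dataclass
class MtSelection:
    """Outcome of MAF filtering plus R^2 pruning.

    ``retained`` lists the representative mtSNP ids; ``clusters`` maps
    each representative to the full set of ids it stands for;
    ``maf_table`` gives MAF per input id; ``r2_matrix`` is the pairwise
    R^2 matrix over the MAF-passing variants (nan where undefined),
    indexed by ``r2_ids``.
    """

    retained: list[str]
    clusters: dict[str, list[str]]
    maf_table: dict[str, float]
    r2_matrix: np.ndarray
    r2_ids: list[str]


def haploid_maf(calls: np.ndarray) -> float:
    """Minor allele frequency of a haploid 0/1 vector with missing values."""
    calls = np.asarray(calls, dtype=float)
    obs = calls[~np.isnan(calls)]
    if obs.size == 0:
        raise ValueError("all calls missing; MAF undefined")
    f = float(obs.mean())
    return min(f, 1.0 - f)


def haploid_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two haploid 0/1 vectors.

    Computed over jointly non-missing entries; returns nan (with a
    warning) when either vector is monomorphic on the joint support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    both = ~np.isnan(x) & ~np.isnan(y)
    if both.sum() < 2:
        raise ValueError("fewer than 2 jointly non-missing pairs")
    xs, ys = x[both], y[both]
    vx, vy = xs.var(), ys.var()
    if vx == 0.0 or vy == 0.0:
        logger.warning("R^2 undefined: variant monomorphic on joint support")
        return float("nan")
    cov = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return float(cov * cov / (vx * vy))


def prune_mtsnps(
    mito: np.ndarray,
    variants: list[VariantRecord],
    maf_min: float = 0.2,
    r2_high: float = 0.9,
) -> MtSelection:
    """MAF-filter then LD-prune a haploid genotype matrix.

    Variants with MAF < ``maf_min`` are dropped.  Among the survivors,
    pairs with R^2 strictly above ``r2_high`` are connected; each
    connected component retains its highest-MAF member (smallest position
    on ties) and forms one cluster.  Undefined R^2 (monomorphic joint
    support) never connects a pair.
    """
    mito = np.asarray(mito, dtype=float)
    if mito.shape[1] != len(variants):
        raise ValueError("matrix/variant list length mismatch")
    if len(variants) == 0:
        raise ValueError("need at least one mtSNP")

    maf_table = {v.id: haploid_maf(mito[:, j]) for j, v in enumerate(variants)}
    pass_idx = [j for j, v in enumerate(variants) if maf_table[v.id] >= maf_min]
    r2_ids = [variants[j].id for j in pass_idx]
    m = len(pass_idx)
    r2 = np.full((m, m), np.nan)
    rows, cols = [], []
    for a in range(m):
        r2[a, a] = 1.0
        for b in range(a + 1, m):
            val = haploid_r2(mito[:, pass_idx[a]], mito[:, pass_idx[b]])
            r2[a, b] = r2[b, a] = val
            if not np.isnan(val) and val > r2_high:
                rows.append(a)
                cols.append(b)

    if m:
        adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = 0, np.array([], dtype=int)

    retained: list[str] = []
    clusters: dict[str, list[str]] = {}
    for comp in range(n_comp):
        members = [pass_idx[a] for a in range(m) if labels[a] == comp]
        rep = min(members, key=lambda j: (-maf_table[variants[j].id], variants[j].pos))
        rep_id = variants[rep].id
        retained.append(rep_id)
        clusters[rep_id] = [variants[j].id for j in members]
    # deterministic output order: by position of the representative
    order = sorted(range(len(retained)), key=lambda i: _pos_of(variants, retained[i]))
    retained = [retained[i] for i in order]
    return MtSelection(retained, clusters, maf_table, r2, r2_ids)


def _pos_of(variants: list[VariantRecord], vid: str) -> int:
    return next(v.pos for v in variants if v.id == vid)
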