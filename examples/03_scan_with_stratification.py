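"""Population stratification inflates a mitonuclear scan; PCs repair it.

Two diverged subpopulations (Fst 0.05) whose mt allele frequencies
differ by 0.3 confound every nuclear SNP with the mt variant.  The scan
is run unadjusted and with four principal components as covariates, and
the genomic inflation factor lambda is compared.
"""

import numpy as np

import mitoscan as ms

cfg = ms.SimConfig(
    n_cases=0, n_controls=2000, n_nuclear=800, n_mt=1,
    within_block_corr=0.0, subpop_weights=(0.5, 0.5), fst=0.05,
    mt_freqs_by_subpop=((0.25,), (0.55,)),
    disease_model=ms.DiseaseModel(intercept=0.0), seed=5,
)
cohort = ms.simulate_cohort(cfg)
mt_id = cohort.mito_variants[0].id

raw = ms.case_only_scan(cohort, mt_id, config=ms.ScanConfig(covariate_count=0))
p_raw = np.array([r.p for r in raw if r.status == "ok"])

adjusted = ms.attach_pcs(cohort, 4)
adj = ms.case_only_scan(adjusted, mt_id, config=ms.ScanConfig(covariate_count=4))
p_adj = np.array([r.p for r in adj if r.status == "ok"])

print(f"tests: {p_raw.size} unadjusted, {p_adj.size} PC-adjusted")
print(f"lambda unadjusted : {ms.genomic_inflation(p_raw):6.2f}")
print(f"lambda 4 PCs      : {ms.genomic_inflation(p_adj):6.2f}")
n_fdr_raw = sum(1 for r in raw if r.status == "ok" and r.q < 0.05)
n_fdr_adj = sum(1 for r in adj if r.status == "ok" and r.q < 0.05)
print(f"FDR<0.05 hits     : {n_fdr_raw} unadjusted, {n_fdr_adj} adjusted")
print(
    "\nReading: lambda far above 1 signals that ancestry, not biology,"
    "\ndrives the unadjusted associations; with PC covariates lambda"
    "\nreturns to ~1 and the spurious discoveries disappear."
)
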