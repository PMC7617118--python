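"""Full pipeline on a cohort with one planted mitonuclear risk effect.

A disease whose risk rises only when a particular mt allele and nuclear
genotype co-occur (interaction OR 2, no main effects to speak of) is
simulated; the case-only scan finds the pair inside the affected
cohort, and the combined-cohort models quantify disease-status
modulation and the interaction effect on risk.
"""

import math

import mitoscan as ms

dm = ms.DiseaseModel(
    intercept=-2.5,
    nuclear_effects={0: 0.05},
    mito_effects={0: 0.05},
    interaction_effects={(0, 0): math.log(2.0)},
)
cfg = ms.SimConfig(
    n_cases=2000, n_controls=2000, n_nuclear=40, n_mt=4,
    mt_base_freqs=(0.4, 0.3, 0.35, 0.45),
    disease_model=dm, seed=17,
)
cohort = ms.simulate_cohort(cfg)
config = ms.ScanConfig(covariate_count=0)

cases = cohort.affected()
mt_ids = [v.id for v in cases.mito_variants]
results = ms.scan(cases, mt_ids, config=config)
hits = sorted(
    (r for r in results if r.status == "ok" and r.q < 0.05), key=lambda r: r.p
)
print(f"case-only scan: {len(results)} combinations, {len(hits)} with q < 0.05")
for r in hits[:3]:
    lo, hi = r.ci95
    print(f"  {r.mtsnp_id} x {r.nsnp_id}: OR {r.or_:.2f} ({lo:.2f}-{hi:.2f}), "
          f"p={r.p:.2e}, q={r.q:.3f}")

planted_rank = next(
    (i + 1 for i, r in enumerate(hits) if (r.mtsnp_id, r.nsnp_id) == (mt_ids[0], "rs1")),
    None,
)
print(f"planted pair {mt_ids[0]} x rs1 ranked #{planted_rank} of {len(hits)} hits "
      "(neighbours of rs1 in the same LD block carry the signal too)")

pairs = [(r.mtsnp_id, r.nsnp_id) for r in hits] or [(mt_ids[0], "rs1")]
report = ms.combination_report(cohort, pairs, config)
print("\ncombined-cohort report:")
for row in report:
    print(f"  {row.mtsnp_id} x {row.nsnp_id}:")
    print(f"    modulation by disease: OR {row.modulation.or_:.2f}, p={row.modulation.p:.2e}")
    print(f"    mtSNP with disease   : OR {row.mt_disease.or_:.2f}, p={row.mt_disease.p:.2g}")
    print(f"    nSNP with disease    : OR {row.n_disease.or_:.2f}, p={row.n_disease.p:.2g}")
    print(f"    mt x n on risk       : OR {row.risk_interaction.or_:.2f}, "
          f"p={row.risk_interaction.p:.2e}")

print(
    "\nReading: the planted pair tops the case-only scan, its association"
    "\nis modulated by disease status, and the mt x n term shifts disease"
    "\nrisk (~OR 2).  Note the case-only OR can appear on the protective"
    "\nside when enrichment pushes the risk allele past frequency 0.5"
    "\namong cases, flipping the cohort-minor coding; with a prevalence"
    "\nthis high (~10%) the rare-disease identity is only approximate."
)
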