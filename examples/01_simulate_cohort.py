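"""Generate a synthetic vaccination cohort and inspect its ground truth.

The generator emulates a three-timepoint (T0/T14/T90) whole-blood
methylation study: beta values confounded by leukocyte composition and
plate batch, spiked time effects, baseline CpGs tied to the trained-immunity
(TI) cytokine response, and SNP -> methylation-change -> TI mediation
triplets.  Every planted effect is recorded in a truth ledger.
"""

import epitrain as et

cfg = et.CohortConfig(n_subjects=80, n_probes=400, n_snps=60, seed=1)
cohort = et.generate_cohort(cfg)

print(f"betas: {cohort.betas.shape[0]} probes x {cohort.betas.shape[1]} samples")
print(f"subjects: {cfg.n_subjects}, timepoints: T0/T14/T90")
print("mean cell fractions (whole blood is neutrophil-dominated):")
print(cohort.cell_fractions.mean().round(3).to_string())
print(f"\nspiked trajectory probes: {len(cohort.ledger.trajectory)}")
print(f"TI-associated baseline probes: {len(cohort.ledger.ti_probes)}")
print(f"mediation triplets: {len(cohort.ledger.mediation)}")
trip = cohort.ledger.mediation[0]
print(f"  e.g. {trip['snp']} -> {trip['probe']} -> TI({trip['cytokine']}): "
      f"a={trip['a']}, b={trip['b']}, c'={trip['c_prime']}, "
      f"true ACME={trip['acme']:.2f}, proportion mediated={trip['prop_mediated']:.2f}")
# The ACME (average causal mediation effect) is a*b; the proportion mediated
# is a*b/(a*b + c') — the share of the genetic effect routed via methylation.
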