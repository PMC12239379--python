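"""Bidirectional mediation: SNP -> methylation change -> cytokine change.

Candidate triplets are SNPs associated (p < 0.05) with both the TI response
and a probe's residualized T90-T0 methylation change (DNAm-C).  For each
triplet, quasi-Bayesian mediation is run in both causal directions:
Direction 1 treats DNAm-C as the mediator of the genetic effect on TI,
Direction 2 treats TI as the mediator.
"""

import pandas as pd

import epitrain as et

# low technical noise so the methylation-change mediator is measured well;
# heavy probe noise attenuates the mediator->outcome path
cfg = et.CohortConfig(n_subjects=284, n_probes=400, n_snps=80,
                      sd_noise=0.3, seed=4)
cohort = et.generate_cohort(cfg)
m = et.beta_to_m(cohort.betas)
ti = et.compute_ti(cohort.cytokines)
ifng = ti[ti["cytokine"] == "IFNg"].set_index("subject_id")["ti_norm"]

resid = et.residualize_by_timepoint(m, cohort.samples,
                                    cell_fractions=cohort.cell_fractions)
by = {tp: g.set_index("subject_id")["sample_id"]
      for tp, g in cohort.samples.groupby("timepoint")}
subjects = by["T0"].index.tolist()
probes = [t["probe"] for t in cohort.ledger.mediation]
dnamc = pd.DataFrame(
    resid.loc[probes, by["T90"].loc[subjects]].to_numpy().T
    - resid.loc[probes, by["T0"].loc[subjects]].to_numpy().T,
    index=subjects, columns=probes)

covs = cohort.samples[cohort.samples["timepoint"] == "T0"].set_index(
    "subject_id")[["age", "sex"]]
qtl_ti = et.qtl_scan(cohort.dosages, ifng.reindex(subjects).to_frame("IFNg"),
                     covs)
qtl_dn = et.qtl_scan(cohort.dosages, dnamc, covs)
triplets = et.discover_triplets(qtl_ti, qtl_dn)
print(f"{len(triplets)} candidate triplets "
      f"({len([t for t in cohort.ledger.mediation])} were planted)\n")

for trip in (triplets.sort_values("p_dnamc").head(3)
             .itertuples(index=False)):
    g = cohort.dosages.loc[trip.snp_id, subjects].to_numpy(dtype=float)
    res = et.bidirectional_mediation(
        g, dnamc[trip.probe_id].to_numpy(),
        ifng.reindex(subjects).to_numpy(), n_sims=1000, seed=11)
    d1 = res["D1"]
    print(f"{trip.snp_id} / {trip.probe_id}: "
          f"ACME(D1) = {d1.acme:.3f} (p = {d1.acme_p:.3f}), "
          f"proportion mediated = {d1.prop_mediated:.2f}, "
          f"classification = {res['classification']}")
# ACME is the average causal mediation effect (product of the SNP->mediator
# and mediator->outcome coefficients); the proportion mediated is
# ACME / total effect.
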