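"""Association, conditional scanning and the residue/allele model ledger.

Simulates a cohort where a SNV tags DRB1*03:01:01G (r^2 = 0.9) and the
trait is driven by the DRB1-74Arg residue: the stepwise scan picks a
single signal, and the BIC ledger compares the residue model against its
covering allele group and the constituent alleles.
"""

import numpy as np
import pandas as pd

from hlamap.association import (
    compare_models,
    enumerate_nested_models,
    inverse_normal_transform,
    stepwise_conditional,
)
from hlamap.residues import ResidueTable
from hlamap.simulate import (
    EffectMap,
    SnvTag,
    allele_dosage_frame,
    residue_dosage_frame,
    simulate_cohort,
    simulate_phenotypes,
)

freqs = {"pop": {"DRB1": {
    "DRB1*03:01:01G": 0.25, "DRB1*03:02:01": 0.10,
    "DRB1*15:01:01G": 0.40, "DRB1*13:02:01": 0.25,
}}}
table = ResidueTable([
    ("DRB1", 74, "Arg", "DRB1*03:01:01G"),
    ("DRB1", 74, "Arg", "DRB1*03:02:01"),
    ("DRB1", 74, "Ala", "DRB1*15:01:01G"),
    ("DRB1", 74, "Gln", "DRB1*13:02:01"),
])
cohort = simulate_cohort(
    freqs, 2500,
    snv_tags=[SnvTag("rs_tag", "DRB1", "DRB1*03:01:01G", r2=0.9)],
    seed=21,
)
residues = residue_dosage_frame(cohort.typing, table)
alleles = allele_dosage_frame(cohort.typing)
groups = allele_dosage_frame(cohort.typing, n_fields=1)  # e.g. DRB1*03
dosages = pd.concat([residues, alleles, groups, cohort.snv_dosages], axis=1)

pheno = simulate_phenotypes(
    residues, EffectMap(effects={"DRB1-74Arg": -0.35}, target_r2=0.04), seed=22
)
trait = inverse_normal_transform(pheno["raw_titre"])
cov = pd.DataFrame({"time_weeks": pheno["time_weeks"]}, index=pheno.index)

signals = stepwise_conditional(dosages, trait, cov, threshold=5e-9)
print("stepwise index signals (conditioning absorbs the LD tag):")
for s in signals:
    print(f"  {s.variant}: beta={s.beta:+.3f} se={s.se:.3f} P={s.p:.2e}")

specs = enumerate_nested_models(table, "DRB1", 74, "Arg")
ledger, best = compare_models(list(specs.values()), dosages, trait, cov)
print("model ledger (lower BIC = more parsimonious):")
for m in sorted(ledger, key=lambda m: m.bic):
    print(f"  {m.spec.name:13s} terms={list(m.spec.terms)} "
          f"logL={m.loglik:9.2f} k={m.k} BIC={m.bic:9.2f}")
print(f"selected model: {best.name} — here the residue and its covering "
      "allele group carry identical dosages (74Arg is exactly the DRB1*03 "
      "group), so their fits tie and both beat the two-allele model, whose "
      "extra parameter is penalized by BIC")
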