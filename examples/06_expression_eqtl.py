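"""Personalized HLA reference, read counting, and cis-eQTL mapping.

Builds two DRB1 allele contigs (shared first exon, diverged second exon,
200-N spacers), simulates reads with a 3:1 allele-specific expression
skew, counts them under the two multimapping criteria, then maps a
planted negative cis-eQTL in a simulated 200-sample cohort.
"""

import numpy as np

from hlamap.expression import build_allele_contig, cis_eqtl, count_hla_reads
from hlamap.simulate import simulate_eqtl_dataset, simulate_rnaseq_reads

rng = np.random.default_rng(41)
seq = lambda n: "".join(rng.choice(list("ACGT"), n))
shared = seq(150)
c1 = build_allele_contig("DRB1*03:01", "DRB1", [shared, seq(150)])
c2 = build_allele_contig("DRB1*15:01", "DRB1", [shared, seq(150)])
print(f"contig lengths: {len(c1.sequence)} = 150 + 150 + 200-N spacer")

refs = {"DRB1*03:01": c1.sequence, "DRB1*15:01": c2.sequence,
        "background": seq(3000)}
genes = {"DRB1*03:01": "DRB1", "DRB1*15:01": "DRB1"}
_, records = simulate_rnaseq_reads(
    refs, genes, {"DRB1*03:01": 3.0, "DRB1*15:01": 1.0}, 2000, seed=42
)
counts = count_hla_reads(records)
print(f"gene counts: {counts.gene_counts.to_dict()}")
print(f"allele counts (unique reads only): {counts.allele_counts.to_dict()} "
      "— shared-exon reads hit both contigs and count once for the gene")

data = simulate_eqtl_dataset(200, beta=-0.5, seed=43)
scan = cis_eqtl(data["expression"], data["dosages"],
                data["variant_positions"], data["gene_coordinates"])
top = scan.sort_values("p").iloc[0]
print(f"top cis-eQTL: {top['variant']} beta={top['beta']:+.3f} "
      f"P={top['p']:.2e} P_BH={top['p_bh']:.2e} "
      "(negative: each alternate allele lowers normalized expression)")
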