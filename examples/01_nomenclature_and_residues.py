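"""Parse HLA allele names, reduce resolution, and use residue nesting.

The DRB1-74Arg residue variant is carried only by the DRB1*03 allele
group, so an individual typed DRB1*03:01:01G / DRB1*15:01:01G carries one
copy of it.
"""

from hlamap import parse_allele, reduce_resolution
from hlamap.nomenclature import GenotypeCall
from hlamap.residues import ResidueTable, residue_dosage

allele = parse_allele("HLA-DRB1*03:01:01G")
print(f"parsed      : gene={allele.gene} fields={allele.fields} G={allele.g_group}")
print(f"two-field   : {reduce_resolution(allele, 2)}")
print(f"one-field   : {reduce_resolution(allele, 1)}")

table = ResidueTable([
    ("DRB1", 74, "Arg", "DRB1*03:01:01G"),
    ("DRB1", 74, "Arg", "DRB1*03:02:01"),
    ("DRB1", 74, "Ala", "DRB1*15:01:01G"),
])
carriers = table.alleles_with("DRB1", 74, "Arg")
print(f"74Arg nested in: {sorted(str(a) for a in carriers)}")

call = GenotypeCall("infant_1", "DRB1",
                    parse_allele("DRB1*03:01:01G"),
                    parse_allele("DRB1*15:01:01G"))
dosage = residue_dosage([call], table, "DRB1", 74, "Arg")
print(f"DRB1-74Arg dosage for infant_1: {dosage['infant_1']:.0f} "
      "(one of the two chromosomes carries an Arg-bearing allele)")
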