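import pandas as pd
import pytest

from hlamap.residues import ResidueTable


@pytest.fixture
def drb1_74_table() -> ResidueTable:
    """Toy residue table for DRB1 position 74.

    Arg is carried only by the two DRB1*03 group alleles; the remaining
    alleles carry Ala or Gln, so the residue sets partition the alleles.
    """
    rows = [
        ("DRB1", 74, "Arg", "DRB1*03:01:01G"),
        ("DRB1", 74, "Arg", "DRB1*03:02:01"),
        ("DRB1", 74, "Ala", "DRB1*15:01:01G"),
        ("DRB1", 74, "Ala", "DRB1*11:01:01"),
        ("DRB1", 74, "Gln", "DRB1*13:02:01"),
    ]
    return ResidueTable(rows)


@pytest.fixture
def typing_pair() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The hand-scored truth/test pair used for confusion-metric checks.

    Truth genotypes {01:01, 01:01} and {01:01, 02:01}; test calls
    {01:01, 01:01} and {02:01, 03:01}.
    """

    def frame(genotypes):
        rows = []
        for ind, (a1, a2) in genotypes.items():
            rows.append(
                {
                    "individual_id": ind,
                    "locus": "A",
                    "allele_1": a1,
                    "allele_2": a2,
                    "posterior_1": None,
                    "posterior_2": None,
                }
            )
        return pd.DataFrame(rows)

    truth = frame({"i1": ("A*01:01", "A*01:01"), "i2": ("A*01:01", "A*02:01")})
    test = frame({"i1": ("A*01:01", "A*01:01"), "i2": ("A*02:01", "A*03:01")})
    return truth, test
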