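"""Peptide-binding comparisons between allele groups.

Binding predictions are consumed as input tables of percentile ranks (a
peptide's predicted IC50 ranked against a large random 15-mer reference;
lower = stronger binding).  Alleles are grouped by whether the
antibody-associated residues they carry show an excess (>1.5x) of
positive-beta or negative-beta effects, and the groups are compared on
per-allele best-binder rank (minimum percentile) and binding breadth
(fraction of peptides in the top 5th percentile) with a two-tailed
Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import HlaAllele
from .residues import ResidueTable

__all__ = [
    "AlleleGroup",
    "classify_alleles",
    "best_binder",
    "binding_breadth",
    "compare_groups",
    "sliding_15mers",
]

POSITIVE = "positive-excess"
NEGATIVE = "negative-excess"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class AlleleGroup:
    allele: str
    n_positive: int
    n_negative: int
    n_missing_positions: int
    label: str

    def __post_init__(self):
        if self.label not in (POSITIVE, NEGATIVE, UNCLASSIFIED):
            raise ValueError(f"unknown label {self.label!r}")


def _label(n_pos: int, n_neg: int, excess: float) -> str:
    if n_pos > excess * n_neg and n_pos > 0:
        return POSITIVE
    if n_neg > excess * n_pos and n_neg > 0:
        return NEGATIVE
    return UNCLASSIFIED


def classify_alleles(
    table: ResidueTable,
    associations: pd.DataFrame,
    alleles: Optional[Sequence] = None,
    p_threshold: float = 0.05,
    excess: float = 1.5,
) -> pd.DataFrame:
    """Label alleles by the balance of associated residues they carry.

    ``associations`` has columns gene, position, residue, beta, p — the
    residue-level association results for one trait.  Residues are first
    filtered to P < ``p_threshold``; each allele is then scored by how many
    of the retained positive-beta and negative-beta residues it carries,
    and labelled positive-excess / negative-excess when one count exceeds
    ``excess`` times the other, else unclassified.  Positions where an
    allele has no residue data are skipped and counted in the coverage
    column ``n_missing_positions``.  Alleles absent from the residue table
    entirely are labelled unclassified with a warning.
    """
    import warnings

    sig = associations[associations["p"] < p_threshold]
    if alleles is None:
        pool: set = set()
        for gene in table.genes():
            for pos in table.positions(gene):
                pool |= set(table.alleles_at(gene, pos))
        alleles = sorted(pool)
    rows = []
    for allele in alleles:
        name = str(allele)
        if allele not in table:
            warnings.warn(f"allele {name} absent from residue table", stacklevel=2)
            rows.append(AlleleGroup(name, 0, 0, 0, UNCLASSIFIED))
            continue
        n_pos = n_neg = n_missing = 0
        for rec in sig.itertuples():
            carried = table.residue_of(allele, int(rec.position))
            if carried is None:
                n_missing += 1
                continue
            if carried == rec.residue:
                if rec.beta > 0:
                    n_pos += 1
                elif rec.beta < 0:
                    n_neg += 1
        rows.append(
            AlleleGroup(name, n_pos, n_neg, n_missing, _label(n_pos, n_neg, excess))
        )
    return pd.DataFrame(
        [
            {
                "allele": g.allele,
                "n_positive": g.n_positive,
                "n_negative": g.n_negative,
                "n_missing_positions": g.n_missing_positions,
                "label": g.label,
            }
            for g in rows
        ]
    )


def best_binder(percentile_ranks: Sequence[float]) -> float:
    """Minimum percentile rank (the strongest predicted binder).

    Ties resolve to the first peptide by position, which for the scalar
    minimum is the same value.
    """
    ranks = np.asarray(list(percentile_ranks), dtype=float)
    if ranks.size == 0:
        raise ValueError("no peptides scored")
    if np.any((ranks < 0) | (ranks > 100)):
        raise ValueError("percentile ranks must lie in [0, 100]")
    return float(ranks.min())


def binding_breadth(
    percentile_ranks: Sequence[float], top_percentile: float = 5.0
) -> float:
    """Fraction of peptides predicted to bind within the top percentile."""
    ranks = np.asarray(list(percentile_ranks), dtype=float)
    if ranks.size == 0:
        raise ValueError("no peptides scored")
    if np.any((ranks < 0) | (ranks > 100)):
        raise ValueError("percentile ranks must lie in [0, 100]")
    return float((ranks <= top_percentile).mean())


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Two-tailed Mann-Whitney U comparison of two allele groups.

    Returns (U statistic for group a, two-sided P).  The exact null
    distribution is used for small tie-free samples; otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    small = max(a.size, b.size) <= exact_max_n and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if small else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def sliding_15mers(protein: str, length: int = 15) -> list[str]:
    """All overlapping ``length``-mers of a protein sequence (helper)."""
    protein = protein.strip().upper()
    if len(protein) < length:
        return []
    return [protein[i:i + length] for i in range(len(protein) - length + 1)]
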