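"""Amino-acid residue tables and residue<->allele nesting.

A residue table records, per gene and coding-sequence position, which
residue each classical allele carries.  Residue variants ("DRB1-74Arg":
an arginine at position 74 of the HLA-DRB1 protein) are biallelic markers
nested inside the multi-allelic classical alleles: the set of alleles
carrying a residue defines the nesting used when comparing residue-level
and allele-level association models.

Positions use the coding-sequence numbering convention throughout; a
single integer namespace per gene (mature-protein numbering is not
supported).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .nomenclature import GenotypeCall, HlaAllele, parse_allele

__all__ = ["ResidueTable", "residue_dosage", "nesting_alleles_for_residue"]

AlleleLike = Union[HlaAllele, str]


def _as_allele(a: AlleleLike) -> HlaAllele:
    return a if isinstance(a, HlaAllele) else parse_allele(a)


class ResidueTable:
    """Mapping (gene, position, residue) -> set of alleles carrying it.

    Invariant: an allele appearing at a (gene, position) carries exactly one
    residue there (enforced at construction).
    """

    def __init__(self, rows: Iterable[tuple[str, int, str, AlleleLike]]):
        # (gene, pos) -> residue -> set of alleles
        self._by_site: dict[tuple[str, int], dict[str, set[HlaAllele]]] = {}
        # (gene, allele) -> pos -> residue
        self._by_allele: dict[HlaAllele, dict[int, str]] = {}
        for gene, pos, residue, allele in rows:
            pos = int(pos)
            if pos <= 0:
                raise ValueError(f"position must be positive, got {pos}")
            al = _as_allele(allele)
            if al.gene != gene:
                raise ValueError(
                    f"allele {al} listed under gene {gene!r}"
                )
            carried = self._by_allele.setdefault(al, {})
            if pos in carried and carried[pos] != residue:
                raise ValueError(
                    f"allele {al} carries both {carried[pos]!r} and "
                    f"{residue!r} at {gene} position {pos}"
                )
            carried[pos] = residue
            self._by_site.setdefault((gene, pos), {}).setdefault(
                residue, set()
            ).add(al)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ResidueTable":
        """Build from a DataFrame with columns gene, position, residue, allele."""
        return cls(
            (r.gene, int(r.position), r.residue, r.allele)
            for r in frame.itertuples()
        )

    @classmethod
    def from_tsv(cls, path) -> "ResidueTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"residue": str}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": gene, "position": pos, "residue": res, "allele": str(al)}
            for (gene, pos), residues in sorted(self._by_site.items())
            for res, alleles in sorted(residues.items())
            for al in sorted(alleles)
        ]
        return pd.DataFrame(rows, columns=["gene", "position", "residue", "allele"])

    # -------------------------------------------------------------- queries

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self._by_site})

    def positions(self, gene: str) -> list[int]:
        return sorted(p for g, p in self._by_site if g == gene)

    def residues_at(self, gene: str, position: int) -> dict[str, frozenset[HlaAllele]]:
        """All residues observed at a site, each with its carrying alleles."""
        site = self._by_site.get((gene, int(position)), {})
        return {res: frozenset(alleles) for res, alleles in site.items()}

    def alleles_at(self, gene: str, position: int) -> frozenset[HlaAllele]:
        """All alleles with residue data at a site."""
        site = self._by_site.get((gene, int(position)), {})
        return frozenset().union(*site.values()) if site else frozenset()

    def alleles_with(
        self, gene: str, position: int, residue: str
    ) -> frozenset[HlaAllele]:
        """Alleles carrying ``residue`` at (gene, position).

        Unknown (gene, position) emits a warning and returns the empty set,
        so a typo is visible rather than silently scoring zero.
        """
        key = (gene, int(position))
        if key not in self._by_site:
            warnings.warn(
                f"no residue data at {gene} position {position}", stacklevel=2
            )
            return frozenset()
        return frozenset(self._by_site[key].get(residue, set()))

    def residue_of(self, allele: AlleleLike, position: int) -> Optional[str]:
        """Residue carried by ``allele`` at ``position`` (None if untyped)."""
        return self._by_allele.get(_as_allele(allele), {}).get(int(position))

    def residues_of(self, allele: AlleleLike) -> dict[int, str]:
        """All (position -> residue) data for one allele."""
        return dict(self._by_allele.get(_as_allele(allele), {}))

    def __contains__(self, allele: AlleleLike) -> bool:
        return _as_allele(allele) in self._by_allele


def nesting_alleles_for_residue(
    table: ResidueTable, gene: str, position: int, residue: str
) -> frozenset[HlaAllele]:
    """Exactly the alleles carrying ``residue`` at (gene, position).

    The union over residues at a position is the full allele set at that
    gene position, so these sets partition the alleles.
    """
    return table.alleles_with(gene, position, residue)


def residue_dosage(
    calls: Sequence[GenotypeCall],
    table: ResidueTable,
    gene: str,
    position: int,
    residue: str,
    use_posteriors: bool = True,
) -> pd.Series:
    """Per-individual dosage (0..2) of a residue variant.

    With hard calls (no posteriors) the dosage is the integer count of
    residue-bearing alleles carried.  With imputation posteriors the dosage
    is the expected count: each chromosome contributes its call posterior
    when the called allele carries the residue (mass not assigned to the
    call is treated as not carrying it), matching the use of posterior
    probabilities as additive variant dosages in regression.

    Raises
    ------
    KeyError
        If a called allele has no residue data at (gene, position); the
        message lists the allele.
    """
    carriers = table.alleles_with(gene, position, residue)
    known = table.alleles_at(gene, position)
    out: dict[str, float] = {}
    for call in calls:
        if call.locus != gene:
            continue
        total = 0.0
        for allele, post in (
            (call.allele_1, call.posterior_1),
            (call.allele_2, call.posterior_2),
        ):
            if allele is None:
                continue
            if allele not in known:
                raise KeyError(
                    f"allele {allele} has no residue data at {gene} "
                    f"position {position}"
                )
            if allele in carriers:
                w = post if (use_posteriors and post is not None) else 1.0
                total += w
        out[call.individual] = total
    return pd.Series(out, name=f"{gene}-{position}{residue}", dtype=float)
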