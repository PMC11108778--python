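"""HLA classical-allele nomenclature.

Classical HLA alleles are written ``HLA-DRB1*03:01:01G``: an optional
``HLA-`` prefix, a gene name, a ``*`` separator, one to three colon-separated
numeric fields of two or three digits each, and an optional trailing ``G``
marking a G group (alleles identical over the exons encoding the
peptide-binding domain).  Field strings keep their leading zeros: ``01`` and
``1`` are different tokens and only the former is valid.

The resolution of an allele is its number of fields: one field (a "two-digit"
allele group such as ``DRB1*03``), two fields (a "four-digit" protein-level
allele such as ``DRB1*03:01``) or three fields ("six-digit", typically a
G group).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "HlaAllele",
    "GenotypeCall",
    "AlleleParseError",
    "MISSING_TOKEN",
    "parse_allele",
    "format_allele",
    "reduce_resolution",
    "collapse_ambiguity",
]

#: Reserved token for a missing / novel (untypable) allele in typing tables.
MISSING_TOKEN = "XX"

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(?P<gene>[A-Z][A-Z0-9]*)\*(?P<fields>\d{2,3}(?::\d{2,3}){0,2})"
    r"\s?(?P<g>G)?$"
)


class AlleleParseError(ValueError):
    """Raised when an allele string does not match the nomenclature grammar."""


@dataclass(frozen=True, order=True)
class HlaAllele:
    """A classical HLA allele at one- to three-field resolution.

    Parameters
    ----------
    gene
        Gene name without the ``HLA-`` prefix, e.g. ``"DRB1"``.
    fields
        Ordered tuple of one to three numeric field strings; leading zeros
        are significant and preserved.
    g_group
        True when the allele names a G group (``G`` suffix).
    """

    gene: str
    fields: tuple[str, ...]
    g_group: bool = False

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if not 1 <= len(self.fields) <= 3:
            raise ValueError(f"expected 1-3 fields, got {len(self.fields)}")
        for f in self.fields:
            if not re.fullmatch(r"\d{2,3}", f):
                raise ValueError(f"field {f!r} is not a 2-3 digit string")

    @property
    def resolution(self) -> int:
        """Number of fields (1, 2 or 3)."""
        return len(self.fields)

    def name(self, prefix: bool = False) -> str:
        """Canonical string form, optionally with the ``HLA-`` prefix."""
        base = f"{self.gene}*{':'.join(self.fields)}"
        if self.g_group:
            base += "G"
        return ("HLA-" + base) if prefix else base

    def __str__(self) -> str:
        return self.name()


def parse_allele(text: str) -> HlaAllele:
    """Parse an allele string such as ``"HLA-DRB1*03:01:01G"``.

    The ``HLA-`` prefix is optional; the ``G`` suffix may be separated from
    the last field by a single space (as printed in some tables).

    Raises
    ------
    AlleleParseError
        If ``text`` does not match the grammar; the message names the
        offending token.
    """
    if not isinstance(text, str):
        raise AlleleParseError(f"expected a string, got {type(text).__name__}")
    s = text.strip()
    m = _ALLELE_RE.match(s)
    if m is None:
        # Identify the offending token for the error message.
        if "*" not in s:
            raise AlleleParseError(f"missing '*' separator in {s!r}")
        gene, _, rest = s.partition("*")
        gene = gene.removeprefix("HLA-")
        if not re.fullmatch(r"[A-Z][A-Z0-9]*", gene):
            raise AlleleParseError(f"invalid gene token {gene!r} in {s!r}")
        bad = next(
            (f for f in rest.rstrip("G").rstrip().split(":")
             if not re.fullmatch(r"\d{2,3}", f)),
            rest,
        )
        raise AlleleParseError(f"invalid field token {bad!r} in {s!r}")
    return HlaAllele(
        gene=m.group("gene"),
        fields=tuple(m.group("fields").split(":")),
        g_group=m.group("g") is not None,
    )


def format_allele(allele: HlaAllele, prefix: bool = False) -> str:
    """Inverse of :func:`parse_allele`: ``parse_allele(format_allele(a)) == a``."""
    return allele.name(prefix=prefix)


def reduce_resolution(allele: HlaAllele, n_fields: int) -> HlaAllele:
    """Truncate an allele to its first ``n_fields`` fields.

    The G-group flag is only meaningful at the allele's full stated
    resolution and is dropped whenever fields are actually removed, so
    ``DRB1*03:01:01G`` reduced to two fields is ``DRB1*03:01``.

    Raises
    ------
    ValueError
        If ``n_fields`` is not in ``[1, allele.resolution]``.
    """
    if not 1 <= n_fields <= len(allele.fields):
        raise ValueError(
            f"cannot reduce {allele} with {len(allele.fields)} field(s) "
            f"to {n_fields}"
        )
    if n_fields == len(allele.fields):
        return allele
    return HlaAllele(allele.gene, allele.fields[:n_fields], g_group=False)


def collapse_ambiguity(text: str) -> str:
    """Collapse a '/'-separated ambiguity list to its first listed allele.

    Typing platforms may report several candidate alleles per chromosome
    (``"DRB1*03:01/DRB1*03:22"``); comparisons use only the first, which by
    reporting convention is the common, well-documented candidate.
    """
    return text.split("/", 1)[0].strip()


@dataclass(frozen=True)
class GenotypeCall:
    """An unphased diploid call at one locus for one individual.

    ``allele_1`` / ``allele_2`` order carries no meaning.  Posteriors, when
    present, are per-chromosome call probabilities in [0, 1] (imputation
    output); typed calls leave them ``None``.
    """

    individual: str
    locus: str
    allele_1: Optional[HlaAllele]
    allele_2: Optional[HlaAllele]
    posterior_1: Optional[float] = None
    posterior_2: Optional[float] = None

    def __post_init__(self) -> None:
        for p in (self.posterior_1, self.posterior_2):
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"posterior {p} outside [0, 1]")

    @property
    def alleles(self) -> tuple[Optional[HlaAllele], Optional[HlaAllele]]:
        return (self.allele_1, self.allele_2)

    @property
    def is_complete(self) -> bool:
        return self.allele_1 is not None and self.allele_2 is not None
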