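"""Personalized HLA reference construction, multi-mapping-aware read
counting, normalization and cis-eQTL mapping.

HLA genes are too polymorphic to quantify against a single linear
reference: reads from a diverged allele fail to map or mis-map to a
paralog.  The approach here builds, per individual, one contig per
distinct classical allele carried: the allele's exon sequences
concatenated with 200-base runs of N as spacer "introns", with untyped
exons filled from the closest allele by sequence.  The ordinary genome
background has the HLA genes hard-masked to N, so every HLA-derived read
must align to an allele contig.  Reads are then counted under two
criteria: a read hitting exactly one allele contig counts for that allele
(and its gene); a read hitting several HLA contigs of one gene — but
nothing else in the genome — counts once for the gene.  Reads touching
any background region, or contigs of multiple genes, are discarded (a
fractional-assignment mode splits multi-gene reads instead).  Gene
expression is the sum of these counts.

Counts are normalized per population by median-of-ratios size factors
followed by log2(x + 1) — a monotone variance-stabilizing choice — and
cis-eQTLs are mapped by linear regression of normalized expression on
variant dosage within 1 Mb of each gene, with Benjamini-Hochberg
correction over the tested set and fixed-effects meta-analysis across
populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .association import AssocResult, MetaResult, associate, fixed_effects_meta

__all__ = [
    "Hit",
    "ReadHit",
    "AlleleContig",
    "fill_missing_exons",
    "build_allele_contig",
    "build_personalized_reference",
    "count_hla_reads",
    "read_sam_hits",
    "normalize_expression",
    "cis_eqtl",
    "meta_eqtl",
    "SPACER_LENGTH",
    "MAX_MULTIMAP",
]

SPACER_LENGTH = 200
#: Ingest ceiling on reported alignments per read; beyond it a read is
#: treated as unmapped (mirrors capping the aligner's multimap reporting).
MAX_MULTIMAP = 300


@dataclass(frozen=True)
class Hit:
    """One alignment of a read: a contig (allele or background) + position."""

    contig: str
    position: int
    is_hla: bool
    gene: Optional[str] = None

    def __post_init__(self):
        if self.is_hla and self.gene is None:
            raise ValueError("HLA hits must carry a gene")


@dataclass(frozen=True)
class ReadHit:
    """All alignments found for one read."""

    read_id: str
    hits: tuple[Hit, ...]

    def __post_init__(self):
        if not self.hits:
            raise ValueError("a counted read must have at least one hit")


@dataclass(frozen=True)
class AlleleContig:
    """Exon-concatenated contig for one classical allele.

    ``exon_intervals`` are 0-based half-open coordinates of each exon in
    the contig; consecutive exons are separated by ``spacer_len`` N bases.
    ``fill_source`` records, per exon, the allele whose sequence filled it
    (the allele itself when typed).
    """

    allele: str
    gene: str
    sequence: str
    exon_intervals: tuple[tuple[int, int], ...]
    fill_source: tuple[str, ...]
    spacer_len: int = SPACER_LENGTH

    def __post_init__(self):
        exon_total = sum(e - s for s, e in self.exon_intervals)
        expect = exon_total + self.spacer_len * (len(self.exon_intervals) - 1)
        if len(self.sequence) != expect:
            raise ValueError(
                f"contig length {len(self.sequence)} != "
                f"sum(exons) + {self.spacer_len}*(n_exons-1) = {expect}"
            )
        prev_end = None
        for s, e in self.exon_intervals:
            if prev_end is not None:
                if s != prev_end + self.spacer_len:
                    raise ValueError("exon intervals not ordered/spacer-separated")
                if set(self.sequence[prev_end:s]) not in ({"N"}, set()):
                    raise ValueError("spacer region contains non-N bases")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exon_intervals)


# ------------------------------------------------------- exon completion


def _exon_distance(a: str, b: str) -> int:
    """Mismatch count between two exon sequences.

    Hamming distance over the shared prefix plus the length difference;
    exons of one gene are typically length-matched so this is the plain
    mismatch count in practice.
    """
    m = min(len(a), len(b))
    return sum(x != y for x, y in zip(a[:m], b[:m])) + abs(len(a) - len(b))


def fill_missing_exons(
    allele: str,
    exons: Mapping[int, Optional[str]],
    database: Mapping[str, Mapping[int, Optional[str]]],
) -> tuple[dict[int, str], dict[int, str]]:
    """Fill untyped exons from the closest allele in the database.

    ``exons`` maps exon index -> sequence or None (untyped).  For each
    untyped exon the donor is the database allele with the fewest
    mismatches summed over exons typed in both, among alleles typed at the
    needed exon; ties break to the lexicographically smaller allele name.

    Returns (complete exon dict, fill provenance: exon -> donor allele).
    """
    typed = {i for i, s in exons.items() if s is not None}
    if not typed:
        raise ValueError(f"allele {allele} has no typed exon to anchor on")
    complete = {i: s for i, s in exons.items() if s is not None}
    provenance = {i: allele for i in typed}
    missing = sorted(i for i, s in exons.items() if s is None)
    for idx in missing:
        candidates = []
        for name, cand in database.items():
            if name == allele or cand.get(idx) is None:
                continue
            shared = [
                i for i in typed
                if cand.get(i) is not None
            ]
            dist = sum(_exon_distance(exons[i], cand[i]) for i in shared)
            candidates.append((dist, name))
        if not candidates:
            raise ValueError(
                f"no database allele provides exon {idx} for {allele}"
            )
        candidates.sort()
        dist, donor = candidates[0]
        complete[idx] = database[donor][idx]
        provenance[idx] = donor
    return complete, provenance


# -------------------------------------------------------- contig assembly


def build_allele_contig(
    allele: str,
    gene: str,
    exons: Sequence[str],
    fill_source: Optional[Sequence[str]] = None,
    spacer_len: int = SPACER_LENGTH,
) -> AlleleContig:
    """Concatenate ordered exon sequences with N spacers into one contig."""
    if not exons:
        raise ValueError("no exons supplied")
    exons = [e.upper() for e in exons]
    for e in exons:
        if not e or set(e) - set("ACGTN"):
            raise ValueError(f"exon contains non-ACGTN characters: {e[:20]!r}...")
    parts = []
    intervals = []
    pos = 0
    for i, e in enumerate(exons):
        if i > 0:
            parts.append("N" * spacer_len)
            pos += spacer_len
        intervals.append((pos, pos + len(e)))
        parts.append(e)
        pos += len(e)
    return AlleleContig(
        allele=allele,
        gene=gene,
        sequence="".join(parts),
        exon_intervals=tuple(intervals),
        fill_source=tuple(fill_source) if fill_source else tuple([allele] * len(exons)),
        spacer_len=spacer_len,
    )


def contig_annotation(contig: AlleleContig) -> pd.DataFrame:
    """GTF-style exon features for one contig (1-based inclusive)."""
    rows = [
        {
            "seqname": contig.allele,
            "feature": "exon",
            "start": s + 1,
            "end": e,
            "gene": contig.gene,
            "exon_number": i + 1,
            "fill_source": contig.fill_source[i],
        }
        for i, (s, e) in enumerate(contig.exon_intervals)
    ]
    return pd.DataFrame(rows)


def build_personalized_reference(
    typing: Mapping[str, Sequence[str]],
    database: Mapping[str, Mapping[int, Optional[str]]],
    allele_genes: Mapping[str, str],
    background: str,
    hla_intervals: Sequence[tuple[int, int]],
    spacer_len: int = SPACER_LENGTH,
) -> tuple[dict[str, str], list[AlleleContig], pd.DataFrame]:
    """Build one individual's reference: masked background + allele contigs.

    ``typing`` maps gene -> the individual's two allele names (a
    homozygote yields a single contig); ``database`` holds exon sequences
    (possibly with untyped exons, filled from the closest allele);
    ``hla_intervals`` are 0-based half-open background intervals replaced
    by N (hard masking), so no HLA-derived read can hit the background.

    Returns (fasta dict name -> sequence, contigs, merged annotation).
    """
    masked = list(background.upper())
    for s, e in hla_intervals:
        if not 0 <= s <= e <= len(masked):
            raise ValueError(f"mask interval ({s}, {e}) outside background")
        masked[s:e] = "N" * (e - s)
    fasta = {"background": "".join(masked)}
    contigs: list[AlleleContig] = []
    annotations = []
    for gene in sorted(typing):
        for name in sorted(set(typing[gene])):
            if name not in database:
                raise KeyError(f"allele {name} absent from exon database")
            complete, provenance = fill_missing_exons(name, database[name], database)
            order = sorted(complete)
            contig = build_allele_contig(
                allele=name,
                gene=allele_genes.get(name, gene),
                exons=[complete[i] for i in order],
                fill_source=[provenance[i] for i in order],
                spacer_len=spacer_len,
            )
            contigs.append(contig)
            fasta[name] = contig.sequence
            annotations.append(contig_annotation(contig))
    annotation = (
        pd.concat(annotations, ignore_index=True) if annotations else pd.DataFrame()
    )
    return fasta, contigs, annotation


def write_fasta(fasta: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in fasta.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ------------------------------------------------------------ read counting


@dataclass
class CountResult:
    gene_counts: pd.Series
    allele_counts: pd.Series
    discarded: pd.Series  # reason -> count

    @property
    def n_counted(self) -> int:
        return int(self.gene_counts.sum())


def count_hla_reads(
    read_hits: Iterable[ReadHit],
    multi_gene: str = "discard",
    max_multimap: int = MAX_MULTIMAP,
) -> CountResult:
    """Assign reads to alleles and genes under the two counting criteria.

    Per read:

    - any background (non-HLA) hit -> discarded ("the reads mapped to
      multiple HLA haplotypes *but no other regions in the genome*" read
      strictly);
    - more than ``max_multimap`` reported hits -> discarded (ingest cap);
    - hits on exactly one allele contig -> that allele +1 and its gene +1;
    - hits on several contigs all of one gene -> that gene +1, no allele
      increment;
    - hits spanning contigs of multiple genes -> discarded by default, or
      split 1/n_genes across genes with ``multi_gene="fractional"``.

    Gene expression is the sum of these counts per gene.
    """
    if multi_gene not in ("discard", "fractional"):
        raise ValueError("multi_gene must be 'discard' or 'fractional'")
    gene_counts: dict[str, float] = {}
    allele_counts: dict[str, float] = {}
    discarded: dict[str, int] = {}

    def discard(reason: str):
        discarded[reason] = discarded.get(reason, 0) + 1

    for record in read_hits:
        hits = record.hits
        if len(hits) > max_multimap:
            discard("too_many_hits")
            continue
        if any(not h.is_hla for h in hits):
            discard("background_hit")
            continue
        contigs = {h.contig for h in hits}
        genes = {h.gene for h in hits}
        if len(genes) > 1:
            if multi_gene == "discard":
                discard("multi_gene")
                continue
            share = 1.0 / len(genes)
            for g in genes:
                gene_counts[g] = gene_counts.get(g, 0.0) + share
            continue
        gene = next(iter(genes))
        gene_counts[gene] = gene_counts.get(gene, 0.0) + 1.0
        if len(contigs) == 1:
            allele = next(iter(contigs))
            allele_counts[allele] = allele_counts.get(allele, 0.0) + 1.0
    return CountResult(
        gene_counts=pd.Series(gene_counts, dtype=float).sort_index(),
        allele_counts=pd.Series(allele_counts, dtype=float).sort_index(),
        discarded=pd.Series(discarded, dtype=int).sort_index(),
    )


def read_sam_hits(
    path,
    hla_genes: Mapping[str, str],
) -> list[ReadHit]:
    """Ingest coordinate-or-name-sorted SAM records into ReadHit sets.

    ``hla_genes`` maps allele-contig names to genes; any other reference
    name is treated as background.  Secondary/supplementary alignments are
    kept (they carry the multimapping information); unmapped reads are
    dropped.
    """
    import pysam

    by_read: dict[str, list[Hit]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                continue
            contig = aln.reference_name
            by_read.setdefault(aln.query_name, []).append(
                Hit(
                    contig=contig,
                    position=int(aln.reference_start),
                    is_hla=contig in hla_genes,
                    gene=hla_genes.get(contig),
                )
            )
    return [ReadHit(read_id=r, hits=tuple(h)) for r, h in sorted(by_read.items())]


# ----------------------------------------------------------- normalization


def normalize_expression(
    counts: pd.DataFrame,
    populations: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Median-of-ratios size factors then log2(count/sf + 1), per population.

    ``counts`` is genes x individuals.  Size factors use the DESeq
    median-of-ratios construction (reference = geometric mean across the
    population's samples over genes expressed in all of them).  Genes with
    zero counts in every sample of a population are excluded from that
    population's output with a warning.
    """
    if counts.shape[1] < 2:
        raise ValueError("need >= 2 samples to normalize")
    pops = (
        pd.Series(["all"] * counts.shape[1], index=counts.columns)
        if populations is None
        else pd.Series([str(p) for p in populations], index=counts.columns)
    )
    pieces = []
    for pop in sorted(pops.unique()):
        sub = counts.loc[:, pops[pops == pop].index].astype(float)
        if sub.shape[1] < 2:
            raise ValueError(f"population {pop!r} has < 2 samples")
        all_zero = (sub == 0).all(axis=1)
        if all_zero.any():
            warnings.warn(
                f"{int(all_zero.sum())} all-zero gene(s) excluded in {pop!r}",
                stacklevel=2,
            )
            sub = sub.loc[~all_zero]
        positive = (sub > 0).all(axis=1)
        if positive.any():
            logref = np.log(sub.loc[positive]).mean(axis=1)
            ratios = np.log(sub.loc[positive]).sub(logref, axis=0)
            sf = np.exp(ratios.median(axis=0))
        else:
            sf = pd.Series(1.0, index=sub.columns)
        pieces.append(np.log2(sub.div(sf, axis=1) + 1.0))
    return pd.concat(pieces, axis=1)[
        [c for c in counts.columns if any(c in p.columns for p in pieces)]
    ]


# ------------------------------------------------------------------- eQTL


def cis_eqtl(
    expression: pd.DataFrame,
    dosages: pd.DataFrame,
    variant_positions: pd.DataFrame,
    gene_coordinates: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    window: int = 1_000_000,
    population: str = "pooled",
) -> pd.DataFrame:
    """cis-eQTL scan: regress expression on dosage within +-1 Mb of genes.

    ``expression``: individuals x genes (normalized); ``dosages``:
    individuals x variants; ``variant_positions``: index variant id,
    columns chromosome, position; ``gene_coordinates``: index gene,
    columns chromosome, start, end.  A variant is tested for a gene when
    its position lies in [start - window, end + window] on the same
    chromosome; variants without coordinates are excluded with a warning.
    P values are Benjamini-Hochberg adjusted within the tested set.
    """
    from .association import benjamini_hochberg

    no_coord = [v for v in dosages.columns if v not in variant_positions.index]
    if no_coord:
        warnings.warn(f"variants without coordinates excluded: {no_coord}",
                      stacklevel=2)
    rows = []
    for gene in expression.columns:
        if gene not in gene_coordinates.index:
            warnings.warn(f"gene {gene!r} has no coordinates; skipped", stacklevel=2)
            continue
        g = gene_coordinates.loc[gene]
        lo, hi = int(g["start"]) - window, int(g["end"]) + window
        for v in dosages.columns:
            if v in no_coord:
                continue
            vp = variant_positions.loc[v]
            if str(vp["chromosome"]) != str(g["chromosome"]):
                continue
            if not lo <= int(vp["position"]) <= hi:
                continue
            res = associate(
                dosages[v].to_numpy(),
                expression[gene].to_numpy(),
                covariates,
                variant=str(v),
                population=population,
            )
            rows.append({
                "gene": gene, "variant": str(v), "beta": res.beta,
                "se": res.se, "p": res.p, "n": res.n,
                "population": population,
            })
    out = pd.DataFrame(
        rows, columns=["gene", "variant", "beta", "se", "p", "n", "population"]
    )
    if len(out):
        out["p_bh"] = benjamini_hochberg(out["p"])
    else:
        out["p_bh"] = pd.Series(dtype=float)
    return out


def meta_eqtl(per_population: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects meta-analysis of per-population eQTL scans.

    Combines rows sharing (gene, variant) by inverse-variance weighting
    (delegating to the association module); pairs present in a single
    population pass through with Q absent.
    """
    stacked = pd.concat(per_population, ignore_index=True)
    rows = []
    for (gene, variant), sub in stacked.groupby(["gene", "variant"]):
        studies = [
            AssocResult(
                variant=str(variant), beta=float(r.beta), se=float(r.se),
                p=float(r.p), n=int(r.n), population=str(r.population),
            )
            for r in sub.itertuples()
        ]
        meta = fixed_effects_meta(studies)
        rows.append({
            "gene": gene, "variant": str(variant),
            "beta": meta.beta, "se": meta.se, "p": meta.p,
            "q": meta.q, "p_q": meta.p_q,
            "n_populations": len(studies),
        })
    return pd.DataFrame(rows)
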