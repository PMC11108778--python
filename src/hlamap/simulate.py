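"""Synthetic-data generators for every pipeline input.

The generators emulate the statistical structure the analyses assume so
the whole pipeline is testable without any external download:

- multi-population HLA allele frequencies drawn around a shared ancestral
  vector with a Dirichlet concentration controlling differentiation
  (small concentration = strongly differentiated populations);
- diploid cohorts simulated at the haplotype level, so SNVs placed on
  allele-defined haplotypes are in mechanically real LD with the classical
  alleles (conditioning and pruning then behave as on real data);
- imputation output: truth calls perturbed at a chosen per-chromosome
  error rate with posteriors drawn around a confidence level;
- phenotypes: additive variant effects on the inverse-normal scale plus a
  (negative by default) time-since-vaccination slope and Gaussian noise
  scaled to a target variance explained; raw titres are exponentiated and
  censored at an assay ceiling;
- RNA-seq-like reads from personalized allele contigs, with an exact
  substring toy aligner providing ground-truth hit sets;
- paired GWAS effect vectors with a chosen cross-study correlation and
  optional LD-block structure.

Everything is bit-reproducible under a fixed seed (one
``numpy.random.default_rng`` per call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .expression import AlleleContig, Hit, ReadHit
from .io import TYPING_COLUMNS
from .nomenclature import parse_allele
from .residues import ResidueTable

__all__ = [
    "PopulationModel",
    "EffectMap",
    "SnvTag",
    "CohortData",
    "simulate_population_frequencies",
    "simulate_cohort",
    "simulate_imputation_posteriors",
    "simulate_phenotypes",
    "simulate_rnaseq_reads",
    "simulate_paired_gwas",
    "simulate_eqtl_dataset",
    "exact_align",
    "allele_dosage_frame",
    "residue_dosage_frame",
]


# ------------------------------------------------------------------ models


@dataclass(frozen=True)
class PopulationModel:
    """Per-locus ancestral allele frequencies shared by a set of populations.

    ``concentration`` scales the Dirichlet around the ancestral vector:
    per-population frequencies ~ Dirichlet(concentration * ancestral).
    Large concentration -> populations share the ancestral frequencies
    (G_ST -> 0); small concentration -> strong differentiation.
    """

    populations: tuple[str, ...]
    frequencies: Mapping[str, Mapping[str, float]]  # locus -> allele -> freq
    concentration: float = 50.0
    seed: Optional[int] = None

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not self.populations:
            raise ValueError("need at least one population")
        for locus, freqs in self.frequencies.items():
            if not freqs:
                raise ValueError(f"empty allele list at locus {locus!r}")
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"frequencies at {locus!r} sum to {total}")
            if any(v < 0 for v in freqs.values()):
                raise ValueError(f"negative frequency at {locus!r}")


@dataclass(frozen=True)
class SnvTag:
    """Configuration for one SNV tagging a classical allele in LD.

    The SNV is placed on every haplotype carrying ``allele`` and on a
    computed fraction of other haplotypes so that the population r^2
    between SNV dosage and allele dosage equals ``r2`` in expectation
    (the SNV allele is a superset of the tagged allele's haplotypes).
    """

    snv_id: str
    locus: str
    allele: str
    r2: float = 1.0
    position: Optional[int] = None

    def __post_init__(self):
        if not 0.0 < self.r2 <= 1.0:
            raise ValueError(f"tag r2 {self.r2} outside (0, 1]")


@dataclass(frozen=True)
class EffectMap:
    """Planted genetic architecture for phenotype simulation.

    ``effects`` maps dosage-matrix column -> beta on the inverse-normal
    scale.  ``target_r2`` fixes the fraction of trait variance the planted
    variants explain (noise is scaled to hit it); alternatively a fixed
    ``noise_sd`` may be given.  Raw titres are exp(titre_log_mean +
    titre_log_sd * latent) censored above at ``censor_limit`` (assay upper
    limit of detection, 1,000 mIU/ml by default).  Time since vaccination
    is uniform over ``time_window`` weeks with slope ``time_slope``
    (negative by default: antibody wanes with time).
    """

    effects: Mapping[str, float]
    target_r2: Optional[float] = 0.05
    noise_sd: Optional[float] = None
    time_slope: float = -0.02
    time_window: tuple[float, float] = (4.0, 52.0)
    censor_limit: float = 1000.0
    titre_log_mean: float = 4.0
    titre_log_sd: float = 1.5

    def __post_init__(self):
        if self.target_r2 is not None and not 0.0 <= self.target_r2 < 1.0:
            raise ValueError("target variance explained must be in [0, 1)")
        if self.censor_limit <= 0:
            raise ValueError("censoring limit must be positive")
        if self.target_r2 is None and self.noise_sd is None:
            raise ValueError("give either target_r2 or noise_sd")


# ----------------------------------------------------- population frequencies


def simulate_population_frequencies(
    model: PopulationModel,
) -> dict[str, dict[str, dict[str, float]]]:
    """Draw per-population allele frequencies: pop -> locus -> allele -> freq."""
    rng = np.random.default_rng(model.seed)
    out: dict[str, dict[str, dict[str, float]]] = {}
    for pop in model.populations:
        out[pop] = {}
        for locus, freqs in model.frequencies.items():
            alleles = sorted(freqs)
            alpha = np.array([freqs[a] for a in alleles]) * model.concentration
            draw = rng.dirichlet(np.clip(alpha, 1e-9, None))
            out[pop][locus] = dict(zip(alleles, draw.tolist()))
    return out


# ------------------------------------------------------------------ cohort


@dataclass
class CohortData:
    typing: pd.DataFrame
    snv_dosages: pd.DataFrame
    relatedness: pd.DataFrame
    populations: pd.Series
    haplotypes: dict[str, np.ndarray]  # locus -> (n, 2) allele-name array


def _tag_carrier_prob(p: float, r2: float) -> tuple[float, float]:
    """SNV frequency q and off-haplotype carrier probability for target r2.

    With the SNV a superset of the allele's haplotypes,
    r2 = p (1 - q) / ((1 - p) q), giving q = p / (r2 (1 - p) + p).
    """
    if p <= 0 or p >= 1:
        raise ValueError(
            f"tagged allele frequency {p:.4f} admits no LD tag; attainable "
            "r2 requires frequency strictly inside (0, 1)"
        )
    q = p / (r2 * (1.0 - p) + p)
    c = (q - p) / (1.0 - p)
    return q, c


def simulate_cohort(
    frequencies: Mapping[str, Mapping[str, Mapping[str, float]]],
    n_individuals: Union[int, Mapping[str, int]],
    snv_tags: Sequence[SnvTag] = (),
    seed: Optional[int] = None,
    n_duplicate_pairs: int = 0,
    duplicate_relatedness: float = 0.95,
) -> CohortData:
    """Simulate a diploid cohort with SNVs in genuine LD with HLA alleles.

    ``frequencies``: pop -> locus -> allele -> frequency.  Haplotypes are
    drawn per chromosome, and each configured SNV is placed on the
    haplotypes of its tagged allele (plus a computed fraction of others)
    so the SNV-allele r^2 matches the tag configuration.  Optional
    duplicate pairs copy an individual's genotypes and set their
    relatedness entry near 1, exercising the IBD > 0.9 QC rule.
    """
    pops = sorted(frequencies)
    if isinstance(n_individuals, int):
        if n_individuals < 2:
            raise ValueError("need n >= 2 individuals")
        base = n_individuals // len(pops)
        counts = {p: base for p in pops}
        for p in pops[: n_individuals - base * len(pops)]:
            counts[p] += 1
    else:
        counts = {p: int(n_individuals[p]) for p in pops}
    rng = np.random.default_rng(seed)
    ids: list[str] = []
    pop_of: list[str] = []
    for pop in pops:
        for i in range(counts[pop]):
            ids.append(f"{pop}_{i:05d}")
            pop_of.append(pop)
    n = len(ids)

    loci = sorted({l for p in pops for l in frequencies[p]})
    haplotypes: dict[str, np.ndarray] = {}
    for locus in loci:
        hap = np.empty((n, 2), dtype=object)
        row = 0
        for pop in pops:
            freqs = frequencies[pop][locus]
            alleles = sorted(freqs)
            probs = np.array([freqs[a] for a in alleles], dtype=float)
            probs = probs / probs.sum()
            m = counts[pop]
            draw = rng.choice(len(alleles), size=(m, 2), p=probs)
            hap[row:row + m] = np.array(alleles, dtype=object)[draw]
            row += m
        haplotypes[locus] = hap

    snv = {}
    pop_index = pd.Series(pop_of, index=ids)
    for tag in snv_tags:
        if tag.locus not in haplotypes:
            raise KeyError(f"tag locus {tag.locus!r} not simulated")
        carrier = np.zeros((n, 2), dtype=bool)
        hap = haplotypes[tag.locus]
        for pop in pops:
            sel = (pop_index == pop).to_numpy()
            p = frequencies[pop][tag.locus].get(tag.allele, 0.0)
            on_allele = hap[sel] == tag.allele
            if p <= 0:
                carrier[sel] = False
                continue
            if tag.r2 >= 1.0:
                carrier[sel] = on_allele
                continue
            _, c = _tag_carrier_prob(p, tag.r2)
            extra = rng.random(on_allele.shape) < c
            carrier[sel] = on_allele | (~on_allele & extra)
        snv[tag.snv_id] = carrier.sum(axis=1).astype(float)
    snv_dosages = pd.DataFrame(snv, index=ids, dtype=float)

    rel = pd.DataFrame(np.eye(n), index=ids, columns=ids)
    if n_duplicate_pairs:
        if 2 * n_duplicate_pairs > n:
            raise ValueError("too many duplicate pairs for cohort size")
        picks = rng.choice(n, size=2 * n_duplicate_pairs, replace=False)
        for a_i, b_i in zip(picks[::2], picks[1::2]):
            a, b = ids[a_i], ids[b_i]
            for locus in loci:
                haplotypes[locus][b_i] = haplotypes[locus][a_i]
            if len(snv_dosages.columns):
                snv_dosages.loc[b] = snv_dosages.loc[a]
            rel.loc[a, b] = rel.loc[b, a] = duplicate_relatedness

    rows = []
    for locus in loci:
        hap = haplotypes[locus]
        for i, ind in enumerate(ids):
            rows.append({
                "individual_id": ind, "locus": locus,
                "allele_1": str(hap[i, 0]), "allele_2": str(hap[i, 1]),
                "posterior_1": np.nan, "posterior_2": np.nan,
            })
    typing = pd.DataFrame(rows, columns=TYPING_COLUMNS)
    return CohortData(
        typing=typing,
        snv_dosages=snv_dosages,
        relatedness=rel,
        populations=pop_index,
        haplotypes=haplotypes,
    )


# -------------------------------------------------------------- posteriors


def simulate_imputation_posteriors(
    truth: pd.DataFrame,
    error_rate: float,
    confidence: float = 0.9,
    seed: Optional[int] = None,
    concentration: float = 50.0,
) -> pd.DataFrame:
    """Perturb truth calls into imputation-like calls with posteriors.

    Per chromosome, with probability ``error_rate`` the allele is replaced
    by a different allele drawn from the locus's empirical frequencies
    (frequency-weighted wrong call); the emitted posterior is drawn from a
    Beta with mean ``confidence`` (concentration ``concentration``),
    independent of correctness.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    rng = np.random.default_rng(seed)
    a, b = confidence * concentration, (1 - confidence) * concentration
    out = truth.copy()
    locus_freqs: dict[str, pd.Series] = {}
    for locus, sub in truth.groupby("locus"):
        pool = pd.concat([sub["allele_1"], sub["allele_2"]]).dropna()
        locus_freqs[str(locus)] = pool.value_counts(normalize=True)
    for col_a, col_p in (("allele_1", "posterior_1"), ("allele_2", "posterior_2")):
        alleles = out[col_a].to_numpy(dtype=object).copy()
        posts = rng.beta(a, b, size=len(out))
        flip = rng.random(len(out)) < error_rate
        for i in np.flatnonzero(flip):
            freqs = locus_freqs[str(out["locus"].iat[i])]
            others = freqs[freqs.index != alleles[i]]
            if others.empty:
                continue
            p = others.to_numpy() / others.sum()
            alleles[i] = str(rng.choice(others.index.to_numpy(), p=p))
        out[col_a] = alleles
        out[col_p] = np.clip(posts, 1e-6, 1 - 1e-6)
    return out


# -------------------------------------------------------------- phenotypes


def simulate_phenotypes(
    dosages: pd.DataFrame,
    effect_map: EffectMap,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Simulate titres: planted additive effects + time covariate + noise.

    The latent trait is sum(beta * dosage) + time_slope * weeks + Gaussian
    noise with variance chosen so the planted variants explain
    ``target_r2`` of the genetic-plus-noise variance (or with the fixed
    ``noise_sd``).  The raw titre is exp(titre_log_mean + titre_log_sd *
    latent) censored above at the assay ceiling — censoring happens on the
    raw scale, before any inverse-normal transformation downstream.
    """
    missing = [v for v in effect_map.effects if v not in dosages.columns]
    if missing:
        raise KeyError(f"effect variants absent from dosages: {missing}")
    rng = np.random.default_rng(seed)
    n = len(dosages)
    g = np.zeros(n)
    for v, beta in effect_map.effects.items():
        g += beta * dosages[v].to_numpy(dtype=float)
    var_g = float(np.var(g))
    if effect_map.noise_sd is not None:
        noise_sd = effect_map.noise_sd
    else:
        r2 = effect_map.target_r2
        if r2 == 0:
            noise_sd = 1.0
        else:
            if var_g == 0:
                raise ValueError(
                    "target variance explained infeasible: planted effects "
                    "contribute zero variance"
                )
            noise_sd = math.sqrt(var_g * (1.0 - r2) / r2)
    lo, hi = effect_map.time_window
    weeks = rng.uniform(lo, hi, size=n)
    latent = g + effect_map.time_slope * weeks + rng.normal(0.0, noise_sd, size=n)
    raw = np.exp(effect_map.titre_log_mean + effect_map.titre_log_sd *
                 (latent - latent.mean()) / max(latent.std(), 1e-12))
    raw = np.minimum(raw, effect_map.censor_limit)
    return pd.DataFrame(
        {
            "individual_id": dosages.index.astype(str),
            "raw_titre": raw,
            "latent": latent,
            "genetic_value": g,
            "time_weeks": weeks,
            "sex": rng.integers(0, 2, size=n),
        }
    ).set_index("individual_id")


# ----------------------------------------------------------------- RNA-seq


def exact_align(read: str, references: Mapping[str, str],
                genes: Mapping[str, str]) -> list[Hit]:
    """All exact substring matches of a read across reference sequences.

    References whose name appears in ``genes`` are HLA allele contigs;
    anything else is background.  Reads containing N never match (spacer
    and masked regions are all N, so nothing aligns there).
    """
    hits: list[Hit] = []
    if "N" in read:
        return hits
    for name, seq in references.items():
        start = seq.find(read)
        while start != -1:
            hits.append(Hit(contig=name, position=start,
                            is_hla=name in genes, gene=genes.get(name)))
            start = seq.find(read, start + 1)
    return hits


def simulate_rnaseq_reads(
    references: Mapping[str, str],
    genes: Mapping[str, str],
    expression: Mapping[str, float],
    n_reads: int,
    read_length: int = 75,
    paired: bool = False,
    insert_size: int = 200,
    seed: Optional[int] = None,
) -> tuple[list[tuple[str, str]], list[ReadHit]]:
    """Sample reads from expressed contigs and align them exactly.

    ``expression`` maps contig name -> relative expression weight; reads
    start uniformly over each expressed contig's N-free windows, in
    numbers proportional to the weights.  Each read (or, for paired
    fragments, each mate — the hit set is the per-contig intersection of
    the mates') is aligned by exact substring search over *all*
    references, HLA and background alike, so shared exon segments yield
    genuine multi-contig hit sets.

    Returns (reads as (id, sequence), ReadHit records for reads with >= 1
    hit).
    """
    absent = [c for c in expression if c not in references]
    if absent:
        raise KeyError(f"expressed contigs absent from reference: {absent}")
    rng = np.random.default_rng(seed)
    span = read_length if not paired else insert_size
    windows: dict[str, np.ndarray] = {}
    for contig, level in expression.items():
        if level < 0:
            raise ValueError(f"negative expression for {contig}")
        seq = references[contig]
        if len(seq) < span:
            raise ValueError(
                f"contig {contig} shorter ({len(seq)}) than required span {span}"
            )
        ok = np.array([
            "N" not in seq[i:i + span] for i in range(len(seq) - span + 1)
        ])
        starts = np.flatnonzero(ok)
        if starts.size:
            windows[contig] = starts
    names = sorted(c for c in windows if expression[c] > 0)
    if not names:
        raise ValueError("no expressed contig admits a read")
    weights = np.array([expression[c] for c in names], dtype=float)
    weights /= weights.sum()
    picks = rng.choice(len(names), size=n_reads, p=weights)
    reads: list[tuple[str, str]] = []
    records: list[ReadHit] = []
    for r, ci in enumerate(picks):
        contig = names[ci]
        start = int(rng.choice(windows[contig]))
        seq = references[contig]
        if paired:
            frag = seq[start:start + insert_size]
            mate1 = frag[:read_length]
            mate2 = frag[-read_length:]
            rid = f"read_{r:06d}"
            reads.append((rid + "/1", mate1))
            reads.append((rid + "/2", mate2))
            h1 = exact_align(mate1, references, genes)
            h2 = exact_align(mate2, references, genes)
            shared = {h.contig for h in h1} & {h.contig for h in h2}
            hits = tuple(h for h in h1 if h.contig in shared)
        else:
            rid = f"read_{r:06d}"
            read = seq[start:start + read_length]
            reads.append((rid, read))
            hits = tuple(exact_align(read, references, genes))
        if hits:
            records.append(ReadHit(read_id=rid, hits=hits))
    return reads, records


# ------------------------------------------------------------- paired GWAS


def simulate_paired_gwas(
    n_variants: int,
    rho: float,
    ld_block_size: int = 1,
    ld_block_r: float = 0.0,
    se: float = 0.05,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two aligned GWAS effect vectors with cross-study correlation rho.

    Per-variant effect pairs are bivariate normal with correlation
    ``rho``; with ``ld_block_size > 1`` a block-shared component of weight
    ``ld_block_r`` induces within-block similarity in both studies
    (emulating LD), and the returned r^2 matrix is ``ld_block_r`` within
    blocks.  Returns (effects frame with beta_a, se_a, p_a, beta_b, se_b;
    LD r^2 frame).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho outside [-1, 1]")
    if not 0.0 <= ld_block_r < 1.0:
        raise ValueError("ld_block_r outside [0, 1)")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(2))

    def draw(size):
        return (L @ rng.standard_normal((2, size)))

    unique = draw(n_variants)
    n_blocks = math.ceil(n_variants / ld_block_size)
    shared = draw(n_blocks)
    block_of = np.arange(n_variants) // ld_block_size
    tau = ld_block_r
    pair = math.sqrt(1 - tau) * unique + math.sqrt(tau) * shared[:, block_of]
    ids = [f"var_{i:04d}" for i in range(n_variants)]
    beta_a, beta_b = pair[0], pair[1]
    from scipy import stats as _stats

    z = beta_a / se
    effects = pd.DataFrame(
        {
            "beta_a": beta_a, "se_a": se,
            "p_a": 2 * _stats.norm.sf(np.abs(z)),
            "beta_b": beta_b, "se_b": se,
        },
        index=pd.Index(ids, name="variant"),
    )
    ld = pd.DataFrame(
        np.where(block_of[:, None] == block_of[None, :], tau, 0.0),
        index=ids, columns=ids,
    )
    np.fill_diagonal(ld.values, 1.0)
    return effects, ld


# ------------------------------------------------------------ eQTL dataset


def simulate_eqtl_dataset(
    n_individuals: int = 200,
    beta: float = -0.5,
    maf: float = 0.3,
    n_null_variants: int = 20,
    gene: str = "DRB1",
    seed: Optional[int] = None,
) -> dict:
    """A small cis-eQTL problem with one planted expression-altering variant.

    Expression (already on the normalized scale, SD 1 noise) carries
    ``beta`` SD per allele of the causal variant; ``n_null_variants``
    additional variants within the cis window have no effect.  Returns a
    dict with keys expression, dosages, variant_positions,
    gene_coordinates, causal (the causal variant id).
    """
    rng = np.random.default_rng(seed)
    ids = [f"ind_{i:04d}" for i in range(n_individuals)]
    variants = ["rs_causal"] + [f"rs_null_{i:03d}" for i in range(n_null_variants)]
    dos = rng.binomial(2, maf, size=(n_individuals, len(variants))).astype(float)
    dosages = pd.DataFrame(dos, index=ids, columns=variants)
    expr = beta * dosages["rs_causal"].to_numpy() + rng.standard_normal(n_individuals)
    expression = pd.DataFrame({gene: expr}, index=ids)
    gene_start, gene_end = 32_550_000, 32_560_000
    positions = pd.DataFrame(
        {
            "chromosome": "6",
            "position": np.linspace(
                gene_start - 900_000, gene_end + 900_000, len(variants)
            ).astype(int),
        },
        index=pd.Index(variants, name="id"),
    )
    coords = pd.DataFrame(
        {"chromosome": ["6"], "start": [gene_start], "end": [gene_end]},
        index=pd.Index([gene], name="gene"),
    )
    return {
        "expression": expression,
        "dosages": dosages,
        "variant_positions": positions,
        "gene_coordinates": coords,
        "causal": "rs_causal",
    }


# ------------------------------------------------------------ dosage frames


def allele_dosage_frame(
    typing: pd.DataFrame,
    use_posteriors: bool = True,
    n_fields: Optional[int] = None,
) -> pd.DataFrame:
    """Individuals x classical-allele dosage matrix from a typing frame.

    Hard calls count allele copies (0/1/2); when posteriors are present
    and ``use_posteriors`` is set, each chromosome contributes its call
    posterior instead, giving fractional expected dosages.  With
    ``n_fields`` set, allele names are truncated first, so the columns are
    allele-group dosages (e.g. ``DRB1*03`` at one field).
    """
    from .nomenclature import reduce_resolution

    ids = sorted(typing["individual_id"].astype(str).unique())
    acc: dict[str, dict[str, float]] = {}
    for r in typing.itertuples():
        for a, p in ((r.allele_1, r.posterior_1), (r.allele_2, r.posterior_2)):
            if a in (None, "None") or pd.isna(a):
                continue
            name = str(a)
            if n_fields is not None:
                al = parse_allele(name)
                name = str(reduce_resolution(al, min(n_fields, al.resolution)))
            w = float(p) if (use_posteriors and p is not None and not pd.isna(p)) else 1.0
            d = acc.setdefault(name, {})
            key = str(r.individual_id)
            d[key] = d.get(key, 0.0) + w
    frame = pd.DataFrame(
        {a: [acc[a].get(i, 0.0) for i in ids] for a in sorted(acc)},
        index=pd.Index(ids, name="individual_id"),
    )
    return frame


def residue_dosage_frame(
    typing: pd.DataFrame, table: ResidueTable, use_posteriors: bool = True
) -> pd.DataFrame:
    """Individuals x residue-variant dosage matrix from typing + residues."""
    from .io import typing_frame_to_calls
    from .residues import residue_dosage

    calls = typing_frame_to_calls(typing)
    columns = {}
    for gene in table.genes():
        for pos in table.positions(gene):
            for res in table.residues_at(gene, pos):
                series = residue_dosage(
                    calls, table, gene, pos, res, use_posteriors=use_posteriors
                )
                columns[series.name] = series
    return pd.DataFrame(columns)
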