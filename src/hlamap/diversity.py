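"""Multi-allelic population differentiation: G_ST, Jost's D, allelic richness.

HLA loci are highly multi-allelic, so differentiation is measured with
statistics defined on full allele-frequency vectors rather than biallelic
F_ST: Nei's G_ST = (H_T - H_S)/H_T and Jost's D = [(H_T - H_S)/(1 - H_S)]
* n/(n - 1), where H_S is the mean within-population expected
heterozygosity 1 - sum(p_i^2) and H_T the expected heterozygosity of the
pooled (mean) frequency vector.  Populations are weighted equally by
default (a size-weighted mean is available); no small-sample bias
correction is applied unless requested (Nei & Chesser), since different
estimator variants circulate across packages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .nomenclature import HlaAllele, parse_allele, reduce_resolution

__all__ = [
    "DifferentiationResult",
    "pool_to_resolution",
    "differentiation",
    "pairwise_matrix",
    "allelic_richness",
]

FreqMap = Mapping[str, float]


@dataclass(frozen=True)
class DifferentiationResult:
    locus: str
    resolution: Optional[int]
    g_st: float
    jost_d: float
    h_s: float
    h_t: float
    n_populations: int

    def __post_init__(self):
        if not -1e-12 <= self.g_st <= 1 + 1e-12:
            raise ValueError(f"G_ST {self.g_st} outside [0, 1]")
        if self.h_s > self.h_t + 1e-12:
            raise ValueError("H_S exceeds H_T")


def _normalize(freqs: FreqMap, locus: str) -> dict[str, float]:
    total = float(sum(freqs.values()))
    if not freqs or total <= 0:
        raise ValueError(f"empty or zero frequency table for locus {locus!r}")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies at {locus!r} sum to {total}, not 1")
    if any(v < 0 for v in freqs.values()):
        raise ValueError(f"negative frequency at {locus!r}")
    return {str(a): v / total for a, v in freqs.items()}


def pool_to_resolution(freqs: FreqMap, resolution: Optional[int]) -> dict[str, float]:
    """Merge allele frequencies after truncating names to ``resolution`` fields.

    ``None`` leaves allele names untouched.  Alleles already below the
    requested resolution keep their name.
    """
    if resolution is None:
        return {str(a): float(v) for a, v in freqs.items()}
    pooled: dict[str, float] = {}
    for name, value in freqs.items():
        allele = parse_allele(str(name))
        reduced = reduce_resolution(allele, min(resolution, allele.resolution))
        pooled[str(reduced)] = pooled.get(str(reduced), 0.0) + float(value)
    return pooled


def _heterozygosities(
    tables: Sequence[dict[str, float]], weights: np.ndarray
) -> tuple[float, float]:
    alleles = sorted(set().union(*tables))
    mat = np.array([[t.get(a, 0.0) for a in alleles] for t in tables])
    within = 1.0 - (mat**2).sum(axis=1)
    h_s = float(weights @ within)
    pbar = weights @ mat
    h_t = float(1.0 - (pbar**2).sum())
    return h_s, h_t


def differentiation(
    freq_tables: Mapping[str, FreqMap],
    locus: str = "",
    resolution: Optional[int] = None,
    sample_sizes: Optional[Mapping[str, int]] = None,
    size_weighted: bool = False,
    nei_chesser: bool = False,
) -> DifferentiationResult:
    """G_ST and Jost's D across two or more populations at one locus.

    Parameters
    ----------
    freq_tables
        population -> (allele -> frequency); frequencies sum to 1.
    resolution
        Optional number of allele fields to pool to before comparison.
    sample_sizes
        Chromosome counts per population; required for size weighting or
        the Nei-Chesser small-sample correction.
    nei_chesser
        Apply the Nei & Chesser (1983) unbiased correction
        Hs_hat = n_tilde/(n_tilde - 1) * H_S with n_tilde the harmonic mean
        sample size (in diploid individuals).
    """
    pops = sorted(freq_tables)
    if len(pops) < 2:
        raise ValueError("differentiation needs >= 2 populations")
    tables = [
        pool_to_resolution(_normalize(freq_tables[p], locus), resolution)
        for p in pops
    ]
    if size_weighted:
        if sample_sizes is None:
            raise ValueError("size_weighted requires sample_sizes")
        w = np.array([float(sample_sizes[p]) for p in pops])
        weights = w / w.sum()
    else:
        weights = np.full(len(pops), 1.0 / len(pops))
    h_s, h_t = _heterozygosities(tables, weights)
    if nei_chesser:
        if sample_sizes is None:
            raise ValueError("nei_chesser requires sample_sizes")
        n_ind = np.array([sample_sizes[p] / 2.0 for p in pops])
        n_tilde = len(pops) / (1.0 / n_ind).sum()
        h_s = n_tilde / (n_tilde - 1.0) * h_s
        h_t = h_t + h_s / (2.0 * n_tilde * len(pops))
        h_s = min(h_s, h_t)  # correction can cross at tiny n; clamp
    n = len(pops)
    if h_t <= 0:
        warnings.warn(
            f"locus {locus!r} monomorphic in all populations; G_ST set to 0",
            stacklevel=2,
        )
        g_st, jost_d = 0.0, 0.0
    else:
        g_st = (h_t - h_s) / h_t
        jost_d = 0.0 if h_s >= 1.0 else ((h_t - h_s) / (1.0 - h_s)) * n / (n - 1)
    return DifferentiationResult(
        locus=locus,
        resolution=resolution,
        g_st=float(np.clip(g_st, 0.0, 1.0)),
        jost_d=float(jost_d),
        h_s=h_s,
        h_t=h_t,
        n_populations=n,
    )


def pairwise_matrix(
    freq_tables: Mapping[str, FreqMap],
    locus: str = "",
    resolution: Optional[int] = None,
    statistic: str = "g_st",
    **kwargs,
) -> pd.DataFrame:
    """Symmetric population x population differentiation matrix (zero diagonal)."""
    pops = sorted(freq_tables)
    if len(pops) < 2:
        raise ValueError("pairwise_matrix needs >= 2 populations")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            res = differentiation(
                {a: freq_tables[a], b: freq_tables[b]},
                locus=locus,
                resolution=resolution,
                **kwargs,
            )
            value = getattr(res, statistic)
            mat.loc[a, b] = mat.loc[b, a] = value
    return mat


def allelic_richness(
    alleles: Sequence[Union[str, HlaAllele]],
    subsample_size: int,
    n_boot: int = 1000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Bootstrap mean +- SE of the distinct-allele count in fixed subsamples.

    Draws ``n_boot`` resamples of ``subsample_size`` chromosomes with
    replacement from the observed allele calls and counts distinct alleles
    in each, giving a richness estimate comparable across populations with
    different sample sizes.

    Returns (mean, standard error of the bootstrap distribution).
    """
    pool = np.array([str(a) for a in alleles])
    if pool.size == 0:
        raise ValueError("empty allele sample")
    if subsample_size < 1 or subsample_size > pool.size:
        raise ValueError(
            f"subsample size {subsample_size} outside [1, {pool.size}]"
        )
    rng = np.random.default_rng(seed)
    counts = np.empty(n_boot)
    for b in range(n_boot):
        draw = rng.choice(pool, size=subsample_size, replace=True)
        counts[b] = len(np.unique(draw))
    return float(counts.mean()), float(counts.std(ddof=1))
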