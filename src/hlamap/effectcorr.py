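"""Correlating two GWAS effect architectures with a permutation null.

Given per-variant effect estimates from two studies aligned to the same
effect alleles (e.g., antigen antibody response vs a disease case-control
GWAS), the shared architecture is summarized by Pearson's r between the
two beta vectors.  Because HLA variants are heavily correlated, variants
are first greedily pruned by LD (keeping the most significant variant and
any variant with r^2 below a threshold against everything already kept).
Significance comes from a permutation null: variant identities of the
second study are reshuffled and r recomputed; the add-one estimator
P = (k + 1)/(n_perm + 1) counts permutations whose r is at least as
extreme as observed, so P is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationResult",
    "ld_prune",
    "effect_correlation",
    "permutation_pvalue",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_variants: int
    n_permutations: int
    n_exceedances: int
    p_perm: float
    two_sided: bool = True

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r outside [-1, 1]")
        if not 0.0 < self.p_perm <= 1.0:
            raise ValueError("P_perm outside (0, 1]")

    @property
    def bound(self) -> str:
        """Frequency-style bound printed when no permutation exceeded."""
        if self.n_exceedances == 0:
            return f"< 1/{self.n_permutations}"
        return f"= {self.n_exceedances}/{self.n_permutations}"


def ld_prune(
    effects: pd.DataFrame,
    ld: pd.DataFrame,
    r2_threshold: float = 0.35,
    p_column: str = "p_a",
) -> list[str]:
    """Greedy LD pruning keeping the most significant variants.

    Variants are visited in ascending order of ``p_column`` (ties by
    variant id, so the result is independent of input row order); a
    variant is kept iff its r^2 with every already-kept variant is below
    ``r2_threshold``.  The LD matrix must cover all variants.
    """
    ids = [str(v) for v in effects.index]
    missing = [v for v in ids if v not in ld.index or v not in ld.columns]
    if missing:
        raise KeyError(f"LD matrix lacks variants: {missing}")
    order = sorted(ids, key=lambda v: (float(effects.loc[v, p_column]), v))
    kept: list[str] = []
    for v in order:
        if all(float(ld.loc[v, u]) < r2_threshold for u in kept):
            kept.append(v)
    return kept


def effect_correlation(beta_a, beta_b) -> float:
    """Pearson correlation between two aligned effect-size vectors."""
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    if a.size != b.size:
        raise ValueError("effect vectors differ in length")
    if a.size < 3:
        raise ValueError("need >= 3 aligned effect pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("effect estimates must be finite")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in an effect vector")
    return float(np.corrcoef(a, b)[0, 1])


def _perm_correlations(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator,
    batch: int = 20000,
) -> np.ndarray:
    """Pearson r for ``n_perm`` random relabelings of b, vectorized.

    r is affine-invariant, so both vectors are standardized once and each
    permutation reduces to a dot product.
    """
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    n = a.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(batch, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)  # m independent perms
        out[done:done + m] = (az[None, :] * bz[idx]).sum(axis=1) / n
        done += m
    return out


def permutation_pvalue(
    beta_a,
    beta_b,
    n_perm: int = 100_000,
    seed: Optional[int] = None,
    two_sided: bool = True,
    escalate_until: int = 10,
    max_perm: Optional[int] = None,
) -> CorrelationResult:
    """Permutation P value for the correlation of two effect architectures.

    Shuffles the labels of ``beta_b``, recomputes Pearson's r, and counts
    permutations with ``|r_perm| >= |r_obs|`` (two-sided default; one-sided
    counts ``r_perm <= r_obs`` for negative observed r and ``>=`` for
    positive).  ``P = (k + 1)/(n_perm + 1)``.

    When fewer than ``escalate_until`` exceedances are seen, the
    permutation count doubles (fresh draws appended) until the target is
    reached or ``max_perm`` is hit — mirroring the practice of escalating
    permutations until the P value is reliably estimated.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    a = np.asarray(beta_a, dtype=float)
    b = np.asarray(beta_b, dtype=float)
    r_obs = effect_correlation(a, b)
    rng = np.random.default_rng(seed)
    cap = max_perm if max_perm is not None else n_perm

    def exceed(r_perm: np.ndarray) -> np.ndarray:
        if two_sided:
            return np.abs(r_perm) >= abs(r_obs) - 1e-15
        if r_obs < 0:
            return r_perm <= r_obs + 1e-15
        return r_perm >= r_obs - 1e-15

    total = 0
    k = 0
    block = n_perm
    while True:
        r_perm = _perm_correlations(a, b, block, rng)
        k += int(exceed(r_perm).sum())
        total += block
        if k >= escalate_until or total >= cap:
            break
        block = min(total, cap - total)  # doubling schedule
    return CorrelationResult(
        r=r_obs,
        n_variants=a.size,
        n_permutations=total,
        n_exceedances=k,
        p_perm=(k + 1) / (total + 1),
        two_sided=two_sided,
    )
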