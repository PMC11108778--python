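"""Association testing and fine-mapping over SNVs, classical alleles and
amino-acid residues.

The trait model throughout is a Gaussian linear model on inverse-normal
transformed antibody titres: the trait is regressed on an additive variant
dosage (0-2, possibly fractional under imputation) with fixed-effect
covariates (time since vaccination, principal components, population
labels).  Cryptic relatedness is handled either by restricting to
near-unrelated individuals or by a single-random-effect linear mixed model
with a genetic relatedness matrix, fit by REML after eigendecomposition.
Per-population results combine by fixed-effects inverse-variance
meta-analysis with Cochran's Q heterogeneity.  Fine-mapping proceeds by
stepwise forward conditioning at a significance threshold, then a manual
model ledger comparing residue-level, allele-group-level and
constituent-allele models by likelihood-ratio test (nested) or BIC
(non-nested), exploiting the nesting of residues within classical alleles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nomenclature import HlaAllele, parse_allele, reduce_resolution
from .residues import ResidueTable

__all__ = [
    "AssocResult",
    "MetaResult",
    "ModelSpec",
    "ModelComparison",
    "QCResult",
    "inverse_normal_transform",
    "hwe_chisq_pvalue",
    "hwe_exact_pvalue",
    "qc_filter",
    "associate",
    "lmm_associate",
    "fixed_effects_meta",
    "stepwise_conditional",
    "enumerate_nested_models",
    "compare_models",
    "bidirectional_stepwise_bic",
    "variance_explained",
    "analytic_power",
    "monte_carlo_power",
]


# ------------------------------------------------------------ normalization


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    Maps values to Phi^-1((rank - 3/8) / (n + 1/4)); ties share averaged
    ranks, order is preserved, and the output is ~N(0, 1) for continuous
    input.  NaNs are ignored and returned as NaN.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    ok = np.isfinite(x)
    v = x[ok]
    if v.size < 2 or np.all(v == v[0]):
        raise ValueError("need >= 2 distinct finite values to transform")
    ranks = stats.rankdata(v, method="average")
    out[ok] = stats.norm.ppf((ranks - 0.375) / (v.size + 0.25))
    return out


# --------------------------------------------------------------------- HWE


def hwe_chisq_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square Hardy-Weinberg test from genotype counts."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(exp == 0):
        return 1.0  # monomorphic
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_exact_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test (Wigginton-style mid-less two-sided P).

    Sums the probabilities of all heterozygote counts no more likely than
    the observed one, conditional on the allele counts.
    """
    n = n_aa + n_ab + n_bb
    n_rare = min(2 * n_aa + n_ab, 2 * n_bb + n_ab)
    if n == 0 or n_rare == 0:
        return 1.0
    # Heterozygote count shares parity with the rare-allele count.
    het_values = range(n_rare % 2, n_rare + 1, 2)
    logprob = {}
    for het in het_values:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        logprob[het] = (
            math.lgamma(n + 1)
            - math.lgamma(rare_hom + 1)
            - math.lgamma(het + 1)
            - math.lgamma(common_hom + 1)
            + het * math.log(2)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
    m = max(logprob.values())
    probs = {h: math.exp(lp - m) for h, lp in logprob.items()}
    total = sum(probs.values())
    observed = probs[n_ab]
    return min(1.0, sum(p for p in probs.values() if p <= observed * (1 + 1e-12)) / total)


# ---------------------------------------------------------------------- QC


@dataclass
class QCResult:
    dosages: pd.DataFrame
    exclusions: pd.DataFrame  # columns: stage, item, kind, reason

    @property
    def individuals(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def variants(self) -> list[str]:
        return list(self.dosages.columns)


def qc_filter(
    dosages: pd.DataFrame,
    relatedness: Optional[pd.DataFrame] = None,
    sample_call_rate: float = 0.97,
    het_sd: float = 3.0,
    duplicate_threshold: float = 0.9,
    known_twins: Sequence[tuple[str, str]] = (),
    variant_call_rate: float = 0.97,
    hwe_p: float = 1e-8,
    founder_threshold: float = 0.05,
    maf: float = 0.01,
    hwe_exact: bool = False,
) -> QCResult:
    """Sequential genotype quality control with a full exclusion log.

    Order (each stage sees the survivors of the previous one):

    1. sample call rate >= 97%
    2. sample heterozygosity within +-3 SD of the mean
    3. duplicate pairs (relatedness > 0.9, not known twins): drop the
       member with the lower call rate
    4. variant call rate >= 97%
    5. Hardy-Weinberg P >= 1e-8, computed on founders (all pairwise
       relatedness < 0.05)
    6. minor allele frequency > 0.01

    ``dosages`` are hard-call 0/1/2 values with NaN for missing; the
    relatedness matrix is an external input (its estimation is out of
    scope here).
    """
    log: list[dict] = []
    d = dosages.astype(float).copy()

    def drop_samples(ids, stage, reasons):
        nonlocal d
        for i, r in zip(ids, reasons):
            log.append({"stage": stage, "item": str(i), "kind": "sample", "reason": r})
        d = d.drop(index=ids)

    # 1. sample call rate
    cr = d.notna().mean(axis=1)
    bad = cr.index[cr < sample_call_rate]
    drop_samples(bad, "sample_call_rate", [f"call rate {cr[i]:.3f} < {sample_call_rate}" for i in bad])

    # 2. heterozygosity
    het = (d == 1).sum(axis=1) / d.notna().sum(axis=1).clip(lower=1)
    mu, sd = het.mean(), het.std(ddof=0)
    if sd > 0:
        bad = het.index[np.abs(het - mu) > het_sd * sd]
        drop_samples(bad, "heterozygosity", [f"het {het[i]:.3f} beyond {het_sd} SD of {mu:.3f}" for i in bad])

    # 3. duplicates
    if relatedness is not None:
        rel = relatedness.loc[
            relatedness.index.intersection(d.index),
            relatedness.columns.intersection(d.index),
        ]
        twins = {frozenset(p) for p in known_twins}
        cr = d.notna().mean(axis=1)
        to_drop = set()
        ids = list(rel.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if rel.loc[a, b] > duplicate_threshold and frozenset((a, b)) not in twins:
                    loser = a if cr[a] < cr[b] else b
                    if loser not in to_drop:
                        to_drop.add(loser)
                        log.append({
                            "stage": "duplicates", "item": str(loser), "kind": "sample",
                            "reason": f"relatedness {rel.loc[a, b]:.3f} with "
                                      f"{b if loser == a else a}; lower call rate",
                        })
        d = d.drop(index=list(to_drop))

    # 4. variant call rate
    vcr = d.notna().mean(axis=0)
    bad_v = vcr.index[vcr < variant_call_rate]
    for v in bad_v:
        log.append({"stage": "variant_call_rate", "item": str(v), "kind": "variant",
                    "reason": f"call rate {vcr[v]:.3f} < {variant_call_rate}"})
    d = d.drop(columns=bad_v)

    # 5. HWE on founders
    if relatedness is not None:
        rel = relatedness.loc[
            relatedness.index.intersection(d.index),
            relatedness.columns.intersection(d.index),
        ].copy()
        np.fill_diagonal(rel.values, 0.0)
        founders = rel.index[(rel.abs() < founder_threshold).all(axis=1)]
    else:
        founders = d.index
    test = hwe_exact_pvalue if hwe_exact else hwe_chisq_pvalue
    bad_v = []
    for v in d.columns:
        g = d.loc[founders, v].dropna().round()
        p = test(int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        if p < hwe_p:
            bad_v.append(v)
            log.append({"stage": "hwe", "item": str(v), "kind": "variant",
                        "reason": f"HWE P {p:.2e} < {hwe_p:.0e} on {len(founders)} founders"})
    d = d.drop(columns=bad_v)

    # 6. MAF
    freq = d.mean(axis=0) / 2.0
    m = np.minimum(freq, 1 - freq)
    bad_v = m.index[~(m > maf)]
    for v in bad_v:
        log.append({"stage": "maf", "item": str(v), "kind": "variant",
                    "reason": f"MAF {m[v]:.4f} <= {maf}"})
    d = d.drop(columns=bad_v)

    return QCResult(
        dosages=d,
        exclusions=pd.DataFrame(log, columns=["stage", "item", "kind", "reason"]),
    )


# --------------------------------------------------------------- single fit


@dataclass(frozen=True)
class AssocResult:
    variant: str
    beta: float
    se: float
    p: float
    n: int
    model: str = "OLS"
    population: str = "pooled"

    def __post_init__(self):
        if np.isfinite(self.se) and self.se <= 0:
            raise ValueError("SE must be positive")


def _design(
    covariates: Optional[pd.DataFrame], n: int, index=None
) -> tuple[np.ndarray, list[str]]:
    if covariates is None or covariates.shape[1] == 0:
        return np.ones((n, 1)), ["intercept"]
    C = covariates.to_numpy(dtype=float)
    X = np.column_stack([np.ones(n), C])
    names = ["intercept"] + [str(c) for c in covariates.columns]
    _check_collinear(X, names)
    return X, names


def _check_collinear(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # Name an offending pair for the error message.
        for i in range(X.shape[1]):
            for j in range(i + 1, X.shape[1]):
                a, b = X[:, i], X[:, j]
                if np.std(a) == 0 or np.std(b) == 0:
                    continue
                if abs(np.corrcoef(a, b)[0, 1]) > 1 - 1e-10:
                    raise ValueError(
                        f"collinear covariates: {names[i]!r} and {names[j]!r}"
                    )
        raise ValueError("design matrix is rank deficient")


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Return (beta, se, sigma2_hat, df_resid) for a full-rank design."""
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise ValueError(f"not enough observations: n={n}, parameters={p}")
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    return beta, se, sigma2, df


def associate(
    dosage,
    phenotype,
    covariates: Optional[pd.DataFrame] = None,
    variant: str = "variant",
    population: str = "pooled",
) -> AssocResult:
    """OLS association of a trait with one variant dosage given covariates.

    Rows with any missing value are dropped case-complete; missing dosages
    may be mean-imputed by the caller beforehand (never for QC statistics).
    Returns the two-sided t-test on the dosage term.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if covariates is not None:
        C = covariates.to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
        covariates = covariates.loc[ok] if hasattr(covariates, "loc") else None
        C = C[ok]
    else:
        ok = np.isfinite(x) & np.isfinite(y)
        C = None
    x, y = x[ok], y[ok]
    n = x.size
    base, names = _design(covariates if C is not None else None, n)
    X = np.column_stack([base, x])
    _check_collinear(X, names + [variant])
    beta, se, _, df = _ols(y, X)
    b, s = float(beta[-1]), float(se[-1])
    t = b / s if s > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t), df)) if s > 0 else 0.0
    return AssocResult(variant=variant, beta=b, se=s, p=max(p, np.nextafter(0, 1)),
                       n=n, model="OLS", population=population)


# --------------------------------------------------------------------- LMM


def lmm_associate(
    dosage,
    phenotype,
    relatedness: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    variant: str = "variant",
    population: str = "pooled",
) -> AssocResult:
    """Single-random-effect LMM association via kinship eigendecomposition.

    Model: y = X b + g + e with g ~ N(0, sg^2 K), e ~ N(0, se^2 I).
    K is eigendecomposed once; the model is rotated to independent errors
    with variances sg^2 (lambda_i + delta), delta = se^2/sg^2, and delta is
    estimated by REML on a 1-d profile (golden-section over log10 delta).
    With K = I this reduces exactly to OLS.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    K = np.asarray(relatedness, dtype=float)
    if K.shape != (y.size, y.size):
        raise ValueError("relatedness matrix shape does not match phenotype")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("relatedness matrix must be symmetric")
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise ValueError("relatedness matrix is not positive semi-definite")
    lam = np.clip(lam, 0.0, None)

    base, names = _design(covariates, y.size)
    X = np.column_stack([base, x])
    _check_collinear(X, names + [variant])
    n, p = X.shape
    yt, Xt = U.T @ y, U.T @ X

    def reml_neg_loglik(log10_delta: float) -> float:
        delta = 10.0 ** log10_delta
        w = 1.0 / (lam + delta)
        XtWX = Xt.T @ (Xt * w[:, None])
        XtWy = Xt.T @ (w * yt)
        beta = np.linalg.solve(XtWX, XtWy)
        r = yt - Xt @ beta
        rss = float(r @ (w * r))
        sg2 = rss / (n - p)
        _, ld_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - p) * math.log(2 * math.pi * sg2)
            + np.log(lam + delta).sum()
            + ld_xwx
            + (n - p)
        )
        return -ll

    from scipy.optimize import minimize_scalar

    grid = np.linspace(-5, 5, 21)
    vals = [reml_neg_loglik(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(
        reml_neg_loglik, bounds=(g0 - 1.0, g0 + 1.0), method="bounded",
        options={"xatol": 1e-6},
    )
    delta = 10.0 ** float(res.x)
    w = 1.0 / (lam + delta)
    XtWX = Xt.T @ (Xt * w[:, None])
    beta = np.linalg.solve(XtWX, Xt.T @ (w * yt))
    r = yt - Xt @ beta
    sg2 = float(r @ (w * r)) / (n - p)
    cov = sg2 * np.linalg.inv(XtWX)
    b = float(beta[-1])
    s = float(math.sqrt(max(cov[-1, -1], 0.0)))
    t = b / s if s > 0 else np.inf
    pval = float(2 * stats.t.sf(abs(t), n - p)) if s > 0 else 0.0
    return AssocResult(variant=variant, beta=b, se=s,
                       p=max(pval, np.nextafter(0, 1)),
                       n=n, model="LMM", population=population)


# -------------------------------------------------------------------- meta


@dataclass(frozen=True)
class MetaResult:
    variant: str
    beta: float
    se: float
    p: float
    q: Optional[float]
    p_q: Optional[float]
    studies: tuple[AssocResult, ...]

    @property
    def heterogeneous(self) -> bool:
        """Cochran's Q heterogeneity flag at P_Q <= 1e-3."""
        return self.p_q is not None and self.p_q <= 1e-3


def fixed_effects_meta(results: Sequence[AssocResult]) -> MetaResult:
    """Inverse-variance fixed-effects meta-analysis with Cochran's Q.

    weights w_i = 1/SE_i^2; meta beta = sum(w b)/sum(w);
    meta SE = 1/sqrt(sum w); Q = sum w (b - beta_meta)^2 on df = k - 1.
    A single study passes through with Q absent.
    """
    if not results:
        raise ValueError("no studies to combine")
    if len(results) == 1:
        r = results[0]
        return MetaResult(r.variant, r.beta, r.se, r.p, None, None, tuple(results))
    b = np.array([r.beta for r in results])
    se = np.array([r.se for r in results])
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all studies need finite positive SE")
    w = 1.0 / se**2
    beta = float((w * b).sum() / w.sum())
    mse = float(1.0 / math.sqrt(w.sum()))
    z = beta / mse
    p = float(2 * stats.norm.sf(abs(z)))
    q = float((w * (b - beta) ** 2).sum())
    p_q = float(stats.chi2.sf(q, df=len(results) - 1))
    return MetaResult(results[0].variant, beta, mse, max(p, np.nextafter(0, 1)),
                      q, p_q, tuple(results))


# -------------------------------------------------------- stepwise scanning


def stepwise_conditional(
    dosages: pd.DataFrame,
    phenotype,
    covariates: Optional[pd.DataFrame] = None,
    threshold: float = 5e-9,
    max_signals: int = 20,
) -> list[AssocResult]:
    """Stepwise forward conditional scan over a dosage matrix.

    Iteratively adds the variant with the smallest conditional P while that
    P is <= ``threshold``, conditioning on all previously selected variants
    as fixed-effect covariates.  Ties break by smallest P, then largest
    |beta|, then lexicographic variant id, so the output is invariant to
    input column order.
    """
    y = np.asarray(phenotype, dtype=float)
    selected: list[AssocResult] = []
    chosen: list[str] = []
    while len(selected) < max_signals:
        best: Optional[AssocResult] = None
        for v in dosages.columns:
            if v in chosen:
                continue
            cov = _augment(covariates, dosages, chosen)
            try:
                res = associate(dosages[v].to_numpy(), y, cov, variant=str(v))
            except ValueError:
                continue  # collinear with an already-selected variant
            if best is None or (res.p, -abs(res.beta), str(res.variant)) < (
                best.p, -abs(best.beta), str(best.variant)
            ):
                best = res
        if best is None or best.p > threshold:
            break
        selected.append(best)
        chosen.append(best.variant)
    return selected


def _augment(
    covariates: Optional[pd.DataFrame], dosages: pd.DataFrame, terms: Sequence[str]
) -> Optional[pd.DataFrame]:
    parts = []
    if covariates is not None:
        parts.append(covariates.reset_index(drop=True))
    if terms:
        parts.append(dosages[list(terms)].reset_index(drop=True))
    if not parts:
        return None
    return pd.concat(parts, axis=1)


# ----------------------------------------------------- model ledger / BIC


@dataclass(frozen=True)
class ModelSpec:
    """A named set of variant terms (dosage column names) to fit jointly."""

    name: str
    terms: tuple[str, ...]

    def is_nested_in(self, other: "ModelSpec") -> bool:
        return set(self.terms) <= set(other.terms)


@dataclass(frozen=True)
class ModelComparison:
    spec: ModelSpec
    loglik: float
    k: int
    n: int
    bic: float
    lrt_p: Optional[float] = None  # vs the null (covariates-only) model

    def __post_init__(self):
        if abs(self.bic - (self.k * math.log(self.n) - 2 * self.loglik)) > 1e-6:
            raise ValueError("BIC inconsistent with k, n, logL")


def enumerate_nested_models(
    table: ResidueTable,
    gene: str,
    position: int,
    residue: str,
    group_resolutions: Sequence[int] = (2, 1),
) -> dict[str, ModelSpec]:
    """Candidate model specs for a residue given its allele nesting.

    Returns three specs keyed ``"residue"``, ``"allele_group"`` and
    ``"alleles"``:

    - the biallelic residue term itself (named ``GENE-POSRes``);
    - the minimal covering classical allele group: carrying alleles are
      truncated to two fields, then one field, stopping at the first
      resolution where a single group covers them all;
    - the explicit carrying alleles as separate full-resolution terms.

    When the residue is carried by a single allele the residue and allele
    models are statistically equivalent; both are still returned.
    """
    carriers = sorted(table.alleles_with(gene, position, residue))
    if not carriers:
        raise ValueError(f"no allele carries {residue} at {gene} position {position}")
    residue_term = f"{gene}-{position}{residue}"
    group_terms: tuple[str, ...] = tuple(str(a) for a in carriers)
    for res in group_resolutions:
        groups = {
            str(reduce_resolution(a, min(res, a.resolution))) for a in carriers
        }
        if len(groups) == 1:
            group_terms = (groups.pop(),)
            break
    return {
        "residue": ModelSpec("residue", (residue_term,)),
        "allele_group": ModelSpec("allele_group", group_terms),
        "alleles": ModelSpec("alleles", tuple(str(a) for a in carriers)),
    }


def _gaussian_loglik(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n  # ML variance
    ll = -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)
    return ll, p + 1  # mean parameters + residual variance


def compare_models(
    specs: Sequence[ModelSpec],
    dosages: pd.DataFrame,
    phenotype,
    covariates: Optional[pd.DataFrame] = None,
) -> tuple[list[ModelComparison], ModelSpec]:
    """Fit each spec by Gaussian ML on identical case-complete rows.

    Returns the full ledger (logL, k, n, BIC, and an LRT P against the
    covariates-only null, which is nested in every spec) and the selected
    spec (lowest BIC).  Raises if the specs would be fit on differing row
    sets — rows missing any term of any spec are removed up front so every
    model sees the same data, and silent per-model dropping is refused.
    """
    y = np.asarray(phenotype, dtype=float)
    all_terms = sorted({t for s in specs for t in s.terms})
    missing_cols = [t for t in all_terms if t not in dosages.columns]
    if missing_cols:
        raise KeyError(f"terms absent from dosage matrix: {missing_cols}")
    ok = np.isfinite(y)
    if covariates is not None:
        ok &= np.all(np.isfinite(covariates.to_numpy(dtype=float)), axis=1)
    if all_terms:
        ok &= np.all(np.isfinite(dosages[all_terms].to_numpy(dtype=float)), axis=1)
    per_spec_rows = {
        s.name: np.isfinite(dosages[list(s.terms)].to_numpy(dtype=float)).all(axis=1).sum()
        for s in specs if s.terms
    }
    if per_spec_rows and len(set(per_spec_rows.values())) > 1 and ok.sum() < max(per_spec_rows.values()):
        # Not an error per se, but the comparison must use the common rows.
        warnings.warn(
            "specs have differing complete-row counts; comparing on the "
            f"{int(ok.sum())} rows complete for all terms",
            stacklevel=2,
        )
    y = y[ok]
    cov = covariates.loc[ok] if covariates is not None else None
    n = y.size
    base, _ = _design(cov, n)
    null_ll, null_k = _gaussian_loglik(y, base)

    ledger = []
    for s in specs:
        X = (
            np.column_stack([base, dosages.loc[ok, list(s.terms)].to_numpy(dtype=float)])
            if s.terms else base
        )
        _check_collinear(X, ["base"] * base.shape[1] + list(s.terms))
        ll, k = _gaussian_loglik(y, X)
        dk = k - null_k
        lrt_p = float(stats.chi2.sf(2 * (ll - null_ll), df=dk)) if dk > 0 else None
        ledger.append(
            ModelComparison(
                spec=s, loglik=ll, k=k, n=n,
                bic=k * math.log(n) - 2 * ll, lrt_p=lrt_p,
            )
        )
    best = min(ledger, key=lambda m: (m.bic, m.spec.name))
    return ledger, best.spec


def lrt_nested(
    small: ModelComparison, big: ModelComparison
) -> float:
    """Likelihood-ratio P between two ledger entries with nested term sets."""
    if not small.spec.is_nested_in(big.spec):
        raise ValueError(
            f"{small.spec.name!r} is not nested in {big.spec.name!r}; compare by BIC"
        )
    if small.n != big.n:
        raise ValueError("models were fit on different row counts")
    df = big.k - small.k
    if df <= 0:
        raise ValueError("nested model has no fewer parameters")
    return float(stats.chi2.sf(2 * (big.loglik - small.loglik), df=df))


def bidirectional_stepwise_bic(
    term_pool: Sequence[str],
    dosages: pd.DataFrame,
    phenotype,
    covariates: Optional[pd.DataFrame] = None,
    max_iter: int = 50,
) -> ModelSpec:
    """Automated bidirectional (add/drop) BIC search over a term pool.

    Starts from the empty model; at each step applies the single addition
    or removal that lowers BIC the most, until no move improves.
    Deterministic: ties break lexicographically on the candidate term.
    """
    current: list[str] = []

    def bic_of(terms: Sequence[str]) -> float:
        ledger, _ = compare_models(
            [ModelSpec("m", tuple(terms))], dosages, phenotype, covariates
        )
        return ledger[0].bic

    best_bic = bic_of(current)
    for _ in range(max_iter):
        moves: list[tuple[float, str, str]] = []
        for t in sorted(term_pool):
            if t not in current:
                try:
                    moves.append((bic_of(current + [t]), "add", t))
                except ValueError:
                    continue
        for t in sorted(current):
            moves.append((bic_of([u for u in current if u != t]), "drop", t))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[2]))
        cand_bic, action, term = moves[0]
        if cand_bic >= best_bic - 1e-9:
            break
        best_bic = cand_bic
        if action == "add":
            current.append(term)
        else:
            current.remove(term)
    return ModelSpec("stepwise_bic", tuple(sorted(current)))


# ------------------------------------------------------- variance explained


def variance_explained(
    variant_terms: Sequence[str],
    dosages: pd.DataFrame,
    phenotype,
    covariates: Optional[pd.DataFrame] = None,
    populations: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Delta r^2 of selected variants over covariates, per population.

    For each population (or the pooled set when ``populations`` is None)
    reports r2(covariates + variants) - r2(covariates).  Populations where
    the trait was not measured (all-NaN phenotype) are skipped with a
    warning, and the mean/range rows cover only populations with data.
    """
    y = np.asarray(phenotype, dtype=float)
    pops = (
        pd.Series(["all"] * y.size) if populations is None
        else pd.Series([str(p) for p in populations])
    )
    rows = []
    for pop in sorted(pops.unique()):
        sel = (pops == pop).to_numpy()
        y_p = y[sel]
        if not np.any(np.isfinite(y_p)):
            warnings.warn(f"trait absent in population {pop!r}; skipped", stacklevel=2)
            continue
        d_p = dosages.loc[sel, list(variant_terms)]
        c_p = covariates.loc[sel] if covariates is not None else None
        ok = np.isfinite(y_p) & np.all(np.isfinite(d_p.to_numpy(dtype=float)), axis=1)
        if c_p is not None:
            ok &= np.all(np.isfinite(c_p.to_numpy(dtype=float)), axis=1)
        y_ok = y_p[ok]
        base, _ = _design(c_p.loc[ok] if c_p is not None else None, y_ok.size)
        full = np.column_stack([base, d_p.loc[ok].to_numpy(dtype=float)])

        def r2(X):
            beta, _, _, _ = np.linalg.lstsq(X, y_ok, rcond=None)
            resid = y_ok - X @ beta
            tss = float(((y_ok - y_ok.mean()) ** 2).sum())
            return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0

        rows.append({
            "population": pop,
            "n": int(y_ok.size),
            "r2_covariates": r2(base),
            "r2_full": r2(full),
            "delta_r2": r2(full) - r2(base),
        })
    out = pd.DataFrame(rows)
    out.attrs["mean_delta_r2"] = float(out["delta_r2"].mean()) if len(out) else float("nan")
    out.attrs["range_delta_r2"] = (
        (float(out["delta_r2"].min()), float(out["delta_r2"].max())) if len(out) else (float("nan"),) * 2
    )
    return out


# ------------------------------------------------------------------- power


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (FDR)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def analytic_power(n: int, var_explained: float, alpha: float) -> float:
    """Power of a 1-df additive-variant test for a quantitative trait.

    Uses the noncentral chi-square approximation with noncentrality
    NCP = n q^2 / (1 - q^2), where q^2 is the fraction of trait variance
    explained by the variant, against the central chi-square alpha
    threshold.
    """
    if not 0 < var_explained < 1:
        raise ValueError("var_explained must be in (0, 1)")
    ncp = n * var_explained / (1.0 - var_explained)
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))


def monte_carlo_power(
    n: int,
    var_explained: float,
    alpha: float,
    n_reps: int = 2000,
    maf: float = 0.3,
    seed: Optional[int] = None,
    batch: int = 250,
) -> float:
    """Monte-Carlo power: simulate, test by simple regression, count hits.

    Genotypes ~ Binomial(2, maf); trait = scaled genotype + Gaussian noise
    with the requested variance explained; the dosage term is tested by the
    two-sided t-test and power is the fraction of replicates with
    P < alpha.
    """
    rng = np.random.default_rng(seed)
    q2 = var_explained
    hits = 0
    done = 0
    while done < n_reps:
        b = min(batch, n_reps - done)
        g = rng.binomial(2, maf, size=(b, n)).astype(float)
        gs = g - g.mean(axis=1, keepdims=True)
        sd = gs.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        gs /= sd
        y = math.sqrt(q2) * gs + math.sqrt(1 - q2) * rng.standard_normal((b, n))
        ys = y - y.mean(axis=1, keepdims=True)
        r = (gs * ys).sum(axis=1) / (
            np.sqrt((gs**2).sum(axis=1) * (ys**2).sum(axis=1))
        )
        t = r * np.sqrt((n - 2) / np.clip(1 - r**2, 1e-300, None))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        hits += int((p < alpha).sum())
        done += b
    return hits / n_reps
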