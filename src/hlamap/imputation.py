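"""Imputation evaluation: best-guess calling, confusion metrics, concordance,
five-fold cross-validation, and a frequency-baseline imputer.

Imputed HLA genotypes carry per-chromosome posterior probabilities.  A
"best-guess" call retains an allele only when its posterior reaches a
threshold (0.7 by default); raising the threshold trades call availability
for call quality.  Performance against a typed truth set is scored at a
chosen resolution (two fields by default) by comparing each individual's
unordered genotype with a maximum-agreement pairing, tallying per-allele
TP/FP/FN/TN over chromosome slots:

    sensitivity = TP / (TP + FN)        specificity = TN / (TN + FP)
    PPV         = TP / (TP + FP)        NPV         = TN / (TN + FN)
    accuracy    = (TP + TN) / (TP + FP + FN + TN)

Locus concordance is the fraction of chromosome slots called identically
(equivalently, the TP mass over scoreable slots).  Individuals with any
missing allele on either platform are excluded and counted.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .nomenclature import parse_allele, reduce_resolution

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "call_best_guess",
    "allele_performance",
    "locus_concordance",
    "FrequencyBaselineImputer",
    "kfold_crossvalidate",
    "expected_modal_concordance",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-allele chromosome-slot confusion counts at one locus."""

    locus: str
    allele: str
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


@dataclass
class PerformanceReport:
    """Per-allele metrics plus per-locus concordance and exclusion counts."""

    counts: list[ConfusionCounts]
    concordance: pd.Series  # locus -> fraction of matched slots
    n_excluded: pd.Series   # locus -> individuals dropped for missingness

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "locus": c.locus,
                "allele": c.allele,
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                "sensitivity": c.sensitivity,
                "specificity": c.specificity,
                "ppv": c.ppv,
                "npv": c.npv,
                "accuracy": c.accuracy,
            }
            for c in self.counts
        ]
        return pd.DataFrame(rows)


def call_best_guess(
    frame: pd.DataFrame,
    threshold: float = 0.7,
    per_genotype: bool = False,
) -> pd.DataFrame:
    """Apply the posterior-probability calling threshold.

    Per chromosome (default), an allele is retained iff its posterior is
    >= ``threshold``; with ``per_genotype=True`` both chromosomes must pass
    or the whole genotype is set missing.  Threshold 0 retains everything.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    post = frame[["posterior_1", "posterior_2"]].to_numpy(dtype=float)
    if np.nanmin(post, initial=1.0) < 0 or np.nanmax(post, initial=0.0) > 1:
        raise ValueError("posterior outside [0, 1]")
    out = frame.copy()
    with np.errstate(invalid="ignore"):
        pass1 = post[:, 0] >= threshold
        pass2 = post[:, 1] >= threshold
    # A missing posterior never passes a positive threshold.
    pass1 &= ~np.isnan(post[:, 0]) | (threshold == 0)
    pass2 &= ~np.isnan(post[:, 1]) | (threshold == 0)
    if per_genotype:
        both = pass1 & pass2
        pass1 = pass2 = both
    out.loc[~pass1, "allele_1"] = None
    out.loc[~pass2, "allele_2"] = None
    return out


def _reduce_name(name: str, n_fields: int) -> str:
    allele = parse_allele(name)
    return str(reduce_resolution(allele, min(n_fields, allele.resolution)))


def _genotypes_by_individual(
    frame: pd.DataFrame, n_fields: Optional[int]
) -> dict[str, dict[str, Optional[tuple[str, str]]]]:
    """locus -> individual -> (allele, allele) or None when incomplete."""
    out: dict[str, dict[str, Optional[tuple[str, str]]]] = {}
    for r in frame.itertuples():
        a1, a2 = r.allele_1, r.allele_2
        complete = not (
            a1 in (None, "None") or a2 in (None, "None")
            or pd.isna(a1) or pd.isna(a2)
        )
        if complete and n_fields is not None:
            a1, a2 = _reduce_name(str(a1), n_fields), _reduce_name(str(a2), n_fields)
        out.setdefault(str(r.locus), {})[str(r.individual_id)] = (
            (str(a1), str(a2)) if complete else None
        )
    return out


def _paired_genotypes(
    truth: pd.DataFrame, test: pd.DataFrame, n_fields: Optional[int]
):
    """Yield (locus, matched-genotype list, n_excluded) per locus.

    Individuals present in only one table, or with any missing allele on
    either platform, are excluded from scoring.
    """
    g_truth = _genotypes_by_individual(truth, n_fields)
    g_test = _genotypes_by_individual(test, n_fields)
    for locus in sorted(set(g_truth) | set(g_test)):
        t_map = g_truth.get(locus, {})
        s_map = g_test.get(locus, {})
        pairs = []
        excluded = 0
        for ind in set(t_map) | set(s_map):
            t = t_map.get(ind)
            s = s_map.get(ind)
            if t is None or s is None:
                excluded += 1
            else:
                pairs.append((t, s))
        yield locus, pairs, excluded


def _match_counts(t: tuple[str, str], s: tuple[str, str]) -> Counter:
    """Maximum-agreement multiset pairing: matched alleles = intersection."""
    return Counter(t) & Counter(s)


def allele_performance(
    truth: pd.DataFrame,
    test: pd.DataFrame,
    n_fields: Optional[int] = 2,
) -> PerformanceReport:
    """Per-allele confusion counts + metrics at ``n_fields`` resolution.

    Genotypes are unordered; truth and test alleles are paired to maximize
    agreement (the multiset intersection).  A matched slot is a TP for its
    allele; an unmatched test slot is an FP for the called allele and an FN
    for the truth allele it displaced; TN = remaining scoreable slots.
    A homozygote contributes two slots, so a half-right homozygote ->
    heterozygote call scores 1 TP + 1 FN for the truth allele.
    """
    counts: list[ConfusionCounts] = []
    concord = {}
    excluded = {}
    for locus, pairs, n_exc in _paired_genotypes(truth, test, n_fields):
        excluded[locus] = n_exc
        slots = 2 * len(pairs)
        tp: Counter = Counter()
        fp: Counter = Counter()
        fn: Counter = Counter()
        for t, s in pairs:
            matched = _match_counts(t, s)
            tp.update(matched)
            fn.update(Counter(t) - matched)
            fp.update(Counter(s) - matched)
        alleles = sorted(set(tp) | set(fp) | set(fn))
        for allele in alleles:
            a_tp, a_fp, a_fn = tp[allele], fp[allele], fn[allele]
            counts.append(
                ConfusionCounts(
                    locus=locus,
                    allele=allele,
                    tp=a_tp,
                    fp=a_fp,
                    fn=a_fn,
                    tn=slots - a_tp - a_fp - a_fn,
                )
            )
        concord[locus] = (sum(tp.values()) / slots) if slots else float("nan")
    return PerformanceReport(
        counts=counts,
        concordance=pd.Series(concord, name="concordance", dtype=float),
        n_excluded=pd.Series(excluded, name="n_excluded", dtype=int),
    )


def locus_concordance(
    truth: pd.DataFrame, test: pd.DataFrame, n_fields: Optional[int] = 2
) -> pd.Series:
    """Fraction of identically called chromosome slots per locus."""
    return allele_performance(truth, test, n_fields=n_fields).concordance


class Imputer(Protocol):
    def fit(self, training: pd.DataFrame) -> "Imputer": ...
    def predict(self, individual_ids: Sequence[str]) -> pd.DataFrame: ...


class FrequencyBaselineImputer:
    """Deterministic baseline: call the most frequent training allele.

    Every chromosome at a locus is assigned the modal training allele,
    with the allele's training frequency as the call posterior.  This is
    the no-genotype-information floor an informative imputation algorithm
    must beat; loci absent from training yield missing calls.
    """

    def __init__(self) -> None:
        self.modal_: dict[str, tuple[str, float]] = {}

    def fit(self, training: pd.DataFrame) -> "FrequencyBaselineImputer":
        if training.empty:
            raise ValueError("empty training set")
        self.modal_ = {}
        for locus, sub in training.groupby("locus"):
            alleles = pd.concat([sub["allele_1"], sub["allele_2"]]).dropna()
            alleles = alleles[alleles != "None"]
            if alleles.empty:
                continue
            freqs = alleles.value_counts(normalize=True)
            # value_counts sorts ties by first occurrence; make the modal
            # choice deterministic by (count desc, name asc).
            top = freqs[freqs == freqs.iloc[0]].sort_index().index[0]
            self.modal_[str(locus)] = (str(top), float(freqs[top]))
        return self

    def predict(self, individual_ids: Sequence[str]) -> pd.DataFrame:
        rows = []
        for ind in individual_ids:
            for locus, (allele, freq) in sorted(self.modal_.items()):
                rows.append(
                    {
                        "individual_id": str(ind),
                        "locus": locus,
                        "allele_1": allele,
                        "allele_2": allele,
                        "posterior_1": freq,
                        "posterior_2": freq,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "individual_id", "locus", "allele_1", "allele_2",
                "posterior_1", "posterior_2",
            ],
        )


def kfold_crossvalidate(
    panel: pd.DataFrame,
    imputer_factory: Callable[[], Imputer],
    k: int = 5,
    n_fields: Optional[int] = 2,
    seed: Optional[int] = None,
) -> tuple[list[PerformanceReport], pd.Series]:
    """K-fold cross-validated imputation performance on a reference panel.

    Individuals are shuffled once (seeded) and split into ``k`` disjoint,
    exhaustive folds (remainder spread over the first folds).  Each fold
    is imputed from the other k-1 and scored against its typed truth.

    Returns per-fold reports and the mean per-locus concordance.
    """
    individuals = np.array(sorted(panel["individual_id"].astype(str).unique()))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > individuals.size:
        raise ValueError(f"k={k} exceeds n={individuals.size} individuals")
    rng = np.random.default_rng(seed)
    order = rng.permutation(individuals)
    folds = np.array_split(order, k)
    reports = []
    for fold in folds:
        held = set(fold)
        train = panel[~panel["individual_id"].astype(str).isin(held)]
        truth = panel[panel["individual_id"].astype(str).isin(held)]
        imputer = imputer_factory()
        imputer.fit(train)
        predicted = imputer.predict(sorted(held))
        reports.append(allele_performance(truth, predicted, n_fields=n_fields))
    mean_conc = (
        pd.concat([r.concordance for r in reports], axis=1).mean(axis=1)
    )
    mean_conc.name = "mean_concordance"
    return reports, mean_conc


def expected_modal_concordance(frequencies: dict[str, float]) -> float:
    """Closed-form expected concordance of the modal-allele baseline.

    With truth chromosomes drawn iid from ``frequencies`` and every test
    slot called as the modal allele m, the expected matched-slot fraction
    is p_m: in a genotype (i, j) vs (m, m) the multiset intersection counts
    one match per truth chromosome equal to m.
    """
    if not frequencies:
        raise ValueError("empty frequency table")
    return max(frequencies.values()) / sum(frequencies.values())
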