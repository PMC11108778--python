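"""Tabular input/output for typing tables, dosages and study constants.

Formats
-------
Typing table
    TSV with columns ``individual_id, locus, allele_1, allele_2,
    posterior_1, posterior_2``.  Posterior columns are optional; ``.``
    marks an absent posterior, and the reserved allele token ``XX`` (or
    ``.``) marks a missing/novel allele.  Ambiguity lists
    (``allele1/allele2/...``) are collapsed to their first entry on read.
G-group table
    TSV mapping ``allele`` -> ``g_group`` label.
Dosage matrix
    TSV, individuals as rows, variants as columns; or a minimal VCF
    dialect restricted to the ``GT`` and ``DS`` FORMAT fields (1-based
    build-37 positions).
"""

from __future__ import annotations

import importlib.resources
from typing import Optional

import numpy as np
import pandas as pd

from .nomenclature import (
    MISSING_TOKEN,
    GenotypeCall,
    HlaAllele,
    collapse_ambiguity,
    parse_allele,
)

__all__ = [
    "read_typing_table",
    "write_typing_table",
    "typing_frame_to_calls",
    "calls_to_typing_frame",
    "read_g_group_table",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf_dosages",
    "load_reference_locus_counts",
    "load_cohort_sizes",
]

TYPING_COLUMNS = [
    "individual_id",
    "locus",
    "allele_1",
    "allele_2",
    "posterior_1",
    "posterior_2",
]

_NA_TOKENS = {".", "", MISSING_TOKEN, "nan"}


def _parse_allele_cell(text) -> Optional[HlaAllele]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if s in _NA_TOKENS:
        return None
    return parse_allele(collapse_ambiguity(s))


def _parse_posterior_cell(text) -> Optional[float]:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if s in _NA_TOKENS:
        return None
    return float(s)


def read_typing_table(path) -> pd.DataFrame:
    """Read a typing TSV into the canonical typing frame.

    Allele columns hold canonical allele strings (``None`` when missing);
    posterior columns hold floats (``NaN`` when absent).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TYPING_COLUMNS[:4] if c not in raw.columns]
    if missing:
        raise ValueError(f"typing table lacks columns: {missing}")
    frame = pd.DataFrame(
        {
            "individual_id": raw["individual_id"],
            "locus": raw["locus"],
        }
    )
    for col in ("allele_1", "allele_2"):
        frame[col] = [
            (str(a) if a is not None else None)
            for a in (_parse_allele_cell(v) for v in raw[col])
        ]
    for col in ("posterior_1", "posterior_2"):
        if col in raw.columns:
            frame[col] = [_parse_posterior_cell(v) for v in raw[col]]
        else:
            frame[col] = np.nan
    return frame


def write_typing_table(frame: pd.DataFrame, path) -> None:
    out = frame.copy()
    for col in ("allele_1", "allele_2"):
        out[col] = [MISSING_TOKEN if a in (None, "None") or pd.isna(a) else str(a)
                    for a in out[col]]
    for col in ("posterior_1", "posterior_2"):
        if col in out.columns:
            out[col] = ["." if pd.isna(p) else f"{p:.6g}" for p in out[col]]
        else:
            out[col] = "."
    out[TYPING_COLUMNS].to_csv(path, sep="\t", index=False)


def typing_frame_to_calls(frame: pd.DataFrame) -> list[GenotypeCall]:
    """Convert a typing frame to :class:`GenotypeCall` records."""
    calls = []
    for r in frame.itertuples():
        calls.append(
            GenotypeCall(
                individual=str(r.individual_id),
                locus=str(r.locus),
                allele_1=_parse_allele_cell(r.allele_1),
                allele_2=_parse_allele_cell(r.allele_2),
                posterior_1=_parse_posterior_cell(getattr(r, "posterior_1", None)),
                posterior_2=_parse_posterior_cell(getattr(r, "posterior_2", None)),
            )
        )
    return calls


def calls_to_typing_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "individual_id": c.individual,
                "locus": c.locus,
                "allele_1": None if c.allele_1 is None else str(c.allele_1),
                "allele_2": None if c.allele_2 is None else str(c.allele_2),
                "posterior_1": np.nan if c.posterior_1 is None else c.posterior_1,
                "posterior_2": np.nan if c.posterior_2 is None else c.posterior_2,
            }
        )
    return pd.DataFrame(rows, columns=TYPING_COLUMNS)


def read_g_group_table(path) -> dict[str, str]:
    """Read allele -> G-group label mapping."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"allele", "g_group"} <= set(frame.columns):
        raise ValueError("G-group table needs columns allele, g_group")
    return {
        str(parse_allele(a)): g for a, g in zip(frame["allele"], frame["g_group"])
    }


# ------------------------------------------------------------------ dosages


def read_dosage_tsv(path) -> pd.DataFrame:
    """Individuals x variants dosage matrix from TSV (first column = id)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    bad = frame.columns[((frame < 0) | (frame > 2)).any(axis=0)]
    if len(bad):
        raise ValueError(f"dosages outside [0, 2] for variants: {list(bad)}")
    return frame


def write_dosage_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index_label="individual_id")


def read_vcf_dosages(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal VCF-dialect reader returning (dosages, variant metadata).

    Only the ``GT`` and ``DS`` FORMAT fields are interpreted; ``DS`` is
    preferred when both are present.  Positions are 1-based as in the file.
    Returns the individuals x variants dosage frame and a per-variant
    metadata frame (id, chromosome, position, ref, alt).
    """
    samples: list[str] = []
    meta_rows = []
    dosage_cols: list[np.ndarray] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            if len(parts) < 10:
                raise ValueError(f"VCF record with no samples: {line[:60]!r}")
            chrom, pos, vid, ref, alt = parts[0], int(parts[1]), parts[2], parts[3], parts[4]
            fmt = parts[8].split(":")
            try:
                ds_i = fmt.index("DS")
            except ValueError:
                ds_i = None
            try:
                gt_i = fmt.index("GT")
            except ValueError:
                gt_i = None
            if ds_i is None and gt_i is None:
                raise ValueError(f"record {vid} has neither GT nor DS")
            values = np.empty(len(samples))
            for j, cell in enumerate(parts[9:]):
                sub = cell.split(":")
                if ds_i is not None and ds_i < len(sub) and sub[ds_i] not in (".", ""):
                    values[j] = float(sub[ds_i])
                elif gt_i is not None:
                    gt = sub[gt_i].replace("|", "/")
                    if "." in gt:
                        values[j] = np.nan
                    else:
                        values[j] = sum(int(x) > 0 for x in gt.split("/"))
                else:
                    values[j] = np.nan
            meta_rows.append(
                {"id": vid, "chromosome": chrom, "position": pos,
                 "ref": ref, "alt": alt}
            )
            dosage_cols.append(values)
    if not samples:
        raise ValueError("no #CHROM header line found")
    meta = pd.DataFrame(meta_rows).set_index("id")
    dosages = pd.DataFrame(
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0)),
        index=samples,
        columns=meta.index,
    )
    return dosages, meta


# ----------------------------------------------------- bundled study tables


def _data_path(name: str):
    return importlib.resources.files("hlamap.data").joinpath(name)


def load_reference_locus_counts() -> pd.Series:
    """Per-locus allele counts of the expression-reference allele set.

    The personalized-expression reference was assembled from the exon
    sequences of the distinct classical alleles observed in the typed
    populations; this table records how many alleles each locus
    contributed.  The total is the number of allele contigs in the
    reference.
    """
    frame = pd.read_csv(_data_path("reference_locus_counts.tsv"), sep="\t")
    return frame.set_index("locus")["n_alleles"]


def load_cohort_sizes() -> pd.Series:
    """Per-country cohort sizes of the infant vaccine study populations."""
    frame = pd.read_csv(_data_path("cohort_sizes.tsv"), sep="\t")
    return frame.set_index("cohort")["n_individuals"]
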