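"""Clonotype-table data model and repertoire-level filters.

A repertoire sample is a table of productive (or not) TCRbeta clonotypes:
CDR3 nucleotide and amino-acid sequence, V/J gene calls and a read/template
count.  Counts are treated as a single ``count`` column regardless of
whether the upstream assay reports "reads" or "templates".

Supported on-disk dialects
--------------------------
``airr``
    AIRR Rearrangement TSV: ``junction`` (nt), ``junction_aa``, ``v_call``,
    ``j_call``, ``duplicate_count``, ``productive`` (T/F).
``immunoseq``
    immunoSEQ-style export: ``nucleotide``, ``aminoAcid``, ``vGeneName``,
    ``jGeneName``, ``count (templates/reads)``, ``sequenceStatus`` ("In" ==
    productive in-frame).
``simple_tsv``
    The package's own columns: ``cdr3_nt``, ``cdr3_aa``, ``v_gene``,
    ``j_gene``, ``count``, ``productive``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("tilmotif")

TISSUES = ("tumor", "healthy_kidney", "pb", "pre_rep_til", "rep_til", "other")

#: minimum CDR3aa length retained; shorter sequences cannot host a length-3
#: motif inside the trimmed central region (head 3 + tail 2 + 3 = 8 would be
#: strict; 5 is the validation floor, trimming applies its own skip rule)
MIN_CDR3_LEN = 5

COLUMNS = ["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "count", "productive"]

_DIALECT_MAP = {
    "airr": {
        "junction": "cdr3_nt",
        "junction_aa": "cdr3_aa",
        "v_call": "v_gene",
        "j_call": "j_gene",
        "duplicate_count": "count",
        "productive": "productive",
    },
    "immunoseq": {
        "nucleotide": "cdr3_nt",
        "aminoAcid": "cdr3_aa",
        "vGeneName": "v_gene",
        "jGeneName": "j_gene",
        "count (templates/reads)": "count",
        "sequenceStatus": "productive",
    },
    "simple_tsv": {c: c for c in COLUMNS},
}

KEY_MODES = ("aa", "aa_vj", "nt_strict")


class RepertoireError(ValueError):
    """Malformed repertoire input (missing columns, empty file, bad values)."""


@dataclass
class FilterLog:
    """Per-sample record of rows dropped during validation/filtering."""

    sample_id: str = ""
    dropped: dict = field(default_factory=dict)

    def add(self, reason: str, n: int) -> None:
        if n:
            self.dropped[reason] = self.dropped.get(reason, 0) + int(n)
            logger.warning("%s: dropped %d rows (%s)", self.sample_id, n, reason)

    def to_json(self) -> str:
        return json.dumps({"sample_id": self.sample_id, "dropped": self.dropped})


@dataclass
class ClonotypeTable:
    """One repertoire sample.

    ``df`` holds one row per clonotype with columns ``cdr3_nt``, ``cdr3_aa``,
    ``v_gene``, ``j_gene``, ``count``, ``productive``.
    """

    df: pd.DataFrame
    sample_id: str = ""
    tissue: str = "other"
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise RepertoireError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise RepertoireError(f"clonotype table missing columns {missing}")
        self.df = self.df.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def total_reads(self) -> int:
        return int(self.df["count"].sum())

    @property
    def n_clonotypes(self) -> int:
        return len(self.df)

    def frequencies(self) -> np.ndarray:
        total = self.total_reads
        if total == 0:
            return np.zeros(len(self.df))
        return self.df["count"].to_numpy(float) / total

    def keys(self, mode: str = "aa_vj") -> pd.Series:
        """Clonotype keys under a keying mode (aa | aa_vj | nt_strict)."""
        if mode == "aa":
            return self.df["cdr3_aa"].astype(str)
        if mode == "aa_vj":
            return (
                self.df["cdr3_aa"].astype(str)
                + "|" + self.df["v_gene"].astype(str)
                + "|" + self.df["j_gene"].astype(str)
            )
        if mode == "nt_strict":
            if self.df["cdr3_nt"].eq("").any():
                raise RepertoireError("nt_strict keying requires cdr3_nt for every row")
            return self.df["cdr3_nt"].astype(str)
        raise RepertoireError(f"unknown key mode {mode!r}; expected one of {KEY_MODES}")

    def with_df(self, df: pd.DataFrame) -> "ClonotypeTable":
        return replace(self, df=df.reset_index(drop=True))

    def collapse(self, mode: str = "aa_vj") -> "ClonotypeTable":
        """Merge rows sharing a key (sums counts, keeps first annotation)."""
        g = self.df.assign(_key=self.keys(mode)).groupby("_key", sort=True)
        df = g.agg(
            cdr3_nt=("cdr3_nt", "first"),
            cdr3_aa=("cdr3_aa", "first"),
            v_gene=("v_gene", "first"),
            j_gene=("j_gene", "first"),
            count=("count", "sum"),
            productive=("productive", "all"),
        ).reset_index(drop=True)
        return self.with_df(df)

    def key_frequencies(self, mode: str = "aa_vj") -> pd.Series:
        """Frequency per clonotype key (duplicate keys summed)."""
        total = self.total_reads
        s = self.df["count"].groupby(self.keys(mode)).sum()
        return s / total if total else s.astype(float)


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _coerce_productive(col: pd.Series, dialect: str) -> pd.Series:
    if dialect == "immunoseq":
        return col.astype(str).str.strip().str.lower().eq("in")
    truthy = {"t", "true", "1", "yes", "y"}
    return col.map(lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in truthy)


def validate_rows(df: pd.DataFrame, log: FilterLog, min_cdr3_len: int = MIN_CDR3_LEN) -> pd.DataFrame:
    """Drop malformed rows, recording counts per reason.

    Dropped: non-positive/NaN counts, empty CDR3aa, CDR3aa shorter than
    ``min_cdr3_len``, productive rows whose CDR3aa contains a stop ('*').
    """
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad_count = counts.isna() | (counts < 1)
    log.add("count < 1 or non-numeric", bad_count.sum())
    df = df[~bad_count].copy()
    df["count"] = counts[~bad_count].astype(np.int64)

    aa = df["cdr3_aa"].astype(str)
    empty = aa.eq("") | aa.eq("nan")
    log.add("empty cdr3_aa", empty.sum())
    df, aa = df[~empty], aa[~empty]

    short = aa.str.len() < min_cdr3_len
    log.add(f"cdr3_aa shorter than {min_cdr3_len}", short.sum())
    df, aa = df[~short], aa[~short]

    bad_prod = df["productive"] & aa.str.contains(r"\*", regex=True)
    log.add("productive row with stop codon in cdr3_aa", bad_prod.sum())
    df = df[~bad_prod]
    return df.reset_index(drop=True)


def read_clonotype_table(
    path: str | Path,
    dialect: str = "simple_tsv",
    sample_id: str | None = None,
    tissue: str = "other",
    patient_id: str = "",
    min_cdr3_len: int = MIN_CDR3_LEN,
) -> tuple[ClonotypeTable, FilterLog]:
    """Read one repertoire sample from a TSV file.

    Returns the parsed table plus a :class:`FilterLog` of dropped rows.
    Raises :class:`RepertoireError` on an empty file or a missing required
    column (named in the message).
    """
    path = Path(path)
    if dialect not in _DIALECT_MAP:
        raise RepertoireError(f"unknown dialect {dialect!r}")
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise RepertoireError(f"{path}: empty file") from None
    if raw.empty:
        raise RepertoireError(f"{path}: file has a header but no rows")
    mapping = _DIALECT_MAP[dialect]
    missing = [c for c in mapping if c not in raw.columns]
    if missing:
        raise RepertoireError(f"{path}: missing required column(s) {missing} for dialect {dialect!r}")
    df = raw[list(mapping)].rename(columns=mapping)
    df["productive"] = _coerce_productive(df["productive"], dialect)
    df["cdr3_nt"] = df["cdr3_nt"].fillna("").astype(str)
    for c in ("v_gene", "j_gene"):
        df[c] = df[c].fillna("").astype(str)
    log = FilterLog(sample_id or path.stem)
    df = validate_rows(df, log, min_cdr3_len=min_cdr3_len)
    table = ClonotypeTable(df, sample_id=sample_id or path.stem, tissue=tissue, patient_id=patient_id)
    return table, log


def write_clonotype_table(table: ClonotypeTable, path: str | Path, dialect: str = "simple_tsv") -> None:
    """Write a table in any supported dialect (round-trips with the reader)."""
    if dialect not in _DIALECT_MAP:
        raise RepertoireError(f"unknown dialect {dialect!r}")
    inverse = {v: k for k, v in _DIALECT_MAP[dialect].items()}
    out = table.df[COLUMNS].rename(columns=inverse)
    prod_col = inverse["productive"]
    if dialect == "immunoseq":
        out[prod_col] = np.where(table.df["productive"], "In", "Out")
    else:
        out[prod_col] = np.where(table.df["productive"], "T", "F")
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_productive(table: ClonotypeTable) -> ClonotypeTable:
    """Keep productive rows only (in-frame, no stop codon).

    Raises :class:`RepertoireError` if a row is flagged productive but its
    CDR3aa contains '*' — an invariant violation rather than a filterable row.
    """
    bad = table.df["productive"] & table.df["cdr3_aa"].str.contains(r"\*", regex=True)
    if bad.any():
        raise RepertoireError(
            f"{table.sample_id}: {int(bad.sum())} rows flagged productive but contain a stop codon"
        )
    kept = table.df[table.df["productive"]].reset_index(drop=True)
    if kept.empty:
        logger.warning("%s: no productive clonotypes remain", table.sample_id)
    return table.with_df(kept)


def exclude_small_samples(
    tables: list[ClonotypeTable], min_reads: int = 10_000
) -> list[ClonotypeTable]:
    """Drop samples with fewer than ``min_reads`` total reads (default 10,000)."""
    if min_reads < 1:
        raise RepertoireError("min_reads must be >= 1")
    kept = []
    for t in tables:
        if t.total_reads >= min_reads:
            kept.append(t)
        else:
            logger.warning("excluding %s: %d reads < %d", t.sample_id, t.total_reads, min_reads)
    return kept


def remove_singletons(table: ClonotypeTable) -> ClonotypeTable:
    """Drop clonotypes supported by exactly one read."""
    kept = table.df[table.df["count"] > 1].reset_index(drop=True)
    if kept.empty and len(table.df):
        logger.warning("%s: all clonotypes were singletons", table.sample_id)
    return table.with_df(kept)


def downsample(table: ClonotypeTable, target_reads: int, seed: int) -> ClonotypeTable:
    """Subsample reads without replacement to exactly ``target_reads``.

    Multivariate-hypergeometric draw over the clone-count vector; clonotypes
    reduced to zero reads are dropped.  Reproducible for a given ``seed``.
    No upsampling: ``target_reads`` above the sample total is an error.
    """
    total = table.total_reads
    if target_reads > total:
        raise RepertoireError(
            f"{table.sample_id}: cannot downsample to {target_reads} > total {total}"
        )
    if target_reads == total:
        return table.with_df(table.df.copy())
    rng = np.random.default_rng(seed)
    counts = table.df["count"].to_numpy(np.int64)
    new = rng.multivariate_hypergeometric(counts, target_reads, method="marginals")
    df = table.df.copy()
    df["count"] = new
    return table.with_df(df[df["count"] > 0])
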