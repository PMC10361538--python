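"""Cross-sample clonotype tracking, overlap, expansion testing and
annotation against reference TCR tables.

Expansion testing follows the repertoire-comparison convention: for every
clonotype present in either sample, a 2x2 contingency table of its reads
against the remainder of each repertoire, a two-sided Fisher exact test,
Benjamini-Hochberg correction across all tested clonotypes, and a
minimum-frequency condition (default 0.1% in either sample) applied on top
of the adjusted significance threshold.  Full (non-downsampled) repertoires
are the intended input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .repertoire import ClonotypeTable, RepertoireError
from .stats import bh_adjust

logger = logging.getLogger("tilmotif")


def track_top_clonotypes(
    reference: ClonotypeTable,
    targets: list[ClonotypeTable],
    n: int = 20,
    mode: str = "aa",
) -> pd.DataFrame:
    """Frequencies of the top-``n`` reference clonotypes in every target.

    Rows are clonotype keys ordered by reference frequency (ties broken
    lexicographically by key); one column per sample (reference first);
    absent clones are 0.  A final ``__cumulative__`` row sums each column.
    """
    ref_freq = reference.key_frequencies(mode)
    if n > len(ref_freq):
        logger.warning(
            "track_top_clonotypes: n=%d > %d clonotypes in %s; using all",
            n, len(ref_freq), reference.sample_id,
        )
        n = len(ref_freq)
    order = ref_freq.sort_index().sort_values(ascending=False, kind="stable")
    top = order.iloc[:n]
    data = {reference.sample_id: top}
    for t in targets:
        tf = t.key_frequencies(mode)
        data[t.sample_id] = tf.reindex(top.index).fillna(0.0)
    out = pd.DataFrame(data)
    out.loc["__cumulative__"] = out.sum(axis=0)
    out.index.name = "clonotype"
    return out


@dataclass
class OverlapResult:
    shared: pd.DataFrame  # key, freq_a, freq_b
    n_shared: int
    n_only_a: int
    n_only_b: int
    rho: float  # NaN when < 3 shared clones
    p_value: float


def overlap(a: ClonotypeTable, b: ClonotypeTable, mode: str = "aa") -> OverlapResult:
    """Shared-clonotype table and Spearman correlation of log10 frequencies."""
    fa, fb = a.key_frequencies(mode), b.key_frequencies(mode)
    shared_keys = fa.index.intersection(fb.index)
    shared = pd.DataFrame(
        {"freq_a": fa.loc[shared_keys], "freq_b": fb.loc[shared_keys]}
    ).sort_index()
    shared.index.name = "clonotype"
    if len(shared) < 3:
        rho, p = float("nan"), float("nan")
    else:
        rho, p = sps.spearmanr(np.log10(shared["freq_a"]), np.log10(shared["freq_b"]))
        rho, p = float(rho), float(p)
    return OverlapResult(
        shared=shared,
        n_shared=len(shared),
        n_only_a=len(fa.index.difference(fb.index)),
        n_only_b=len(fb.index.difference(fa.index)),
        rho=rho,
        p_value=p,
    )


def test_expansion(
    a: ClonotypeTable,
    b: ClonotypeTable,
    alpha: float = 0.05,
    min_freq: float = 0.001,
    mode: str = "aa",
) -> pd.DataFrame:
    """Fisher-exact clonal expansion test between two repertoires.

    Returns one row per clonotype in the union of both samples with columns
    ``count_a``, ``count_b``, ``freq_a``, ``freq_b``, ``odds_ratio``,
    ``p_value``, ``p_adjusted`` and ``expanded_in`` ("a", "b" or "none").
    A clonotype is called expanded when p_adjusted < ``alpha`` AND its
    frequency in at least one sample is >= ``min_freq``; the direction is
    the sample with the larger frequency.
    """
    total_a, total_b = a.total_reads, b.total_reads
    if total_a == 0 or total_b == 0:
        raise RepertoireError("expansion test requires non-empty repertoires")
    ca = a.df["count"].groupby(a.keys(mode)).sum()
    cb = b.df["count"].groupby(b.keys(mode)).sum()
    keys = ca.index.union(cb.index).sort_values()
    xa = ca.reindex(keys).fillna(0).astype(np.int64).to_numpy()
    xb = cb.reindex(keys).fillna(0).astype(np.int64).to_numpy()

    pvals = np.array(
        [
            sps.fisher_exact(
                [[na, total_a - na], [nb, total_b - nb]], alternative="two-sided"
            )[1]
            for na, nb in zip(xa, xb)
        ]
    )
    padj = bh_adjust(pvals)
    fa, fb = xa / total_a, xb / total_b
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (xa * (total_b - xb)) / np.where(xb * (total_a - xa) == 0, np.nan, xb * (total_a - xa))
    sig = (padj < alpha) & (np.maximum(fa, fb) >= min_freq)
    direction = np.where(~sig, "none", np.where(fa > fb, "a", "b"))
    return pd.DataFrame(
        {
            "clonotype": keys,
            "count_a": xa,
            "count_b": xb,
            "total_a": total_a,
            "total_b": total_b,
            "freq_a": fa,
            "freq_b": fb,
            "odds_ratio": odds,
            "p_value": pvals,
            "p_adjusted": padj,
            "expanded_in": direction,
        }
    )


# ---------------------------------------------------------------------------
# reference-table annotation (VDJdb-like exact matching)
# ---------------------------------------------------------------------------

_REFERENCE_COLS = {
    "cdr3": "cdr3_aa",
    "v.segm": "v_gene",
    "antigen.epitope": "epitope",
    "antigen.species": "species",
}


def strip_allele(gene: str) -> str:
    """Drop the allele suffix of a gene call: 'TRBV9*01' -> 'TRBV9'."""
    return str(gene).split("*", 1)[0]


def load_reference_table(path: str | Path) -> pd.DataFrame:
    """Read a VDJdb-like TSV (cdr3, v.segm, antigen.epitope, antigen.species)."""
    ref = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REFERENCE_COLS if c not in ref.columns]
    if missing:
        raise RepertoireError(f"{path}: reference table missing column(s) {missing}")
    ref = ref.rename(columns=_REFERENCE_COLS)
    ref["reference_id"] = np.arange(len(ref))
    return ref


def annotate_against_reference(
    table: ClonotypeTable,
    reference: pd.DataFrame | str | Path,
    fields: tuple[str, ...] = ("cdr3_aa", "v_gene"),
) -> tuple[pd.DataFrame, dict]:
    """Exact-match clonotypes to an epitope-labelled reference table.

    Matching is exact string equality on ``fields`` after stripping gene
    alleles (truncate at '*').  Returns the hits plus a per-sample summary
    with the fraction of reads carried by annotated clonotypes.
    """
    if not isinstance(reference, pd.DataFrame):
        reference = load_reference_table(reference)
    elif "cdr3_aa" not in reference.columns and "cdr3" in reference.columns:
        reference = reference.rename(columns=_REFERENCE_COLS)
    for f in fields:
        if f not in ("cdr3_aa", "v_gene", "j_gene", "cdr3_nt"):
            raise RepertoireError(f"unknown annotation match field {f!r}")
        if f not in reference.columns:
            raise RepertoireError(f"reference table lacks match field {f!r}")
    left = table.df.copy()
    right = reference.copy()
    for f in fields:
        if f.endswith("_gene"):
            left[f] = left[f].map(strip_allele)
            right[f] = right[f].map(strip_allele)
    hits = left.merge(right, on=list(fields), how="inner", suffixes=("", "_ref"))
    annotated_reads = int(hits.drop_duplicates(subset=["cdr3_aa", "v_gene", "j_gene", "cdr3_nt"])["count"].sum())
    total = table.total_reads
    summary = {
        "sample_id": table.sample_id,
        "n_hits": int(len(hits)),
        "annotated_reads": annotated_reads,
        "annotated_read_fraction": annotated_reads / total if total else 0.0,
    }
    return hits, summary
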