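"""Quantify the proportion of TCRs carrying tumor-associated motifs in
arbitrary repertoires, and compare burdens between sample groups.

A clonotype is motif-bearing when at least one motif of the query set
occurs in its CDR3aa at one of that motif's discovery offsets (the
"same location" rule).  The union fraction is reported both read-weighted
(repertoire proportion, the default) and unique-clonotype-weighted; the
per-motif contribution map records each motif's own carrier-read fraction
(a clonotype may carry several motifs, so contributions can sum to more
than the union).

Cohort entry filters used upstream of burden calculations: blood samples
keep non-singleton TCRs only; RNA-derived external sets require >= 100 TCR
reads per sample; deep external repertoires are downsampled to 40,000
reads for comparability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .association import SampleMotifView
from .motifs import DEFAULT_HEAD, DEFAULT_K_SET, DEFAULT_TAIL, MotifIndex, MotifRecord
from .repertoire import ClonotypeTable, RepertoireError, downsample, remove_singletons
from .stats import rank_sum_test

logger = logging.getLogger("tilmotif")


@dataclass
class MotifBurden:
    sample_id: str
    tissue: str
    fraction_reads: float
    fraction_unique: float
    per_motif: dict[str, float] = field(default_factory=dict)  # read fraction per motif
    n_distinct_motifs: int = 0
    total_reads: int = 0
    n_clonotypes: int = 0


def _records(motifs: MotifIndex | list[MotifRecord]) -> list[MotifRecord]:
    if isinstance(motifs, MotifIndex):
        return [motifs[m] for m in motifs.motifs()]
    return list(motifs)


def motif_burden(
    table: ClonotypeTable,
    motifs: MotifIndex | list[MotifRecord],
    weighting: str = "reads",
    same_location: bool = True,
    view: SampleMotifView | None = None,
) -> MotifBurden:
    """Motif-bearing fraction of one repertoire for a motif set.

    ``weighting`` selects which union fraction is reported as the headline
    ``fraction_reads`` consumer value — both are always computed.
    """
    records = _records(motifs)
    if not records:
        raise RepertoireError("motif_burden: empty motif set")
    if weighting not in ("reads", "unique"):
        raise RepertoireError(f"unknown weighting {weighting!r}")
    if view is None:
        if isinstance(motifs, MotifIndex):
            p = motifs.params
            view = SampleMotifView(
                table,
                k_set=tuple(p.get("k_set", DEFAULT_K_SET)),
                head=p.get("head", DEFAULT_HEAD),
                tail=p.get("tail", DEFAULT_TAIL),
                allow_one_wildcard=p.get("allow_one_wildcard", True),
            )
        else:
            view = SampleMotifView(table)
    counts = table.df["count"].to_numpy()
    total = counts.sum()
    union_rows: set[int] = set()
    per_motif: dict[str, float] = {}
    n_distinct = 0
    for rec in records:
        rows = view.carrier_rows(rec.motif, rec.offsets if same_location else None)
        if rows:
            n_distinct += 1
            union_rows.update(rows)
            per_motif[rec.motif] = float(counts[rows].sum() / total) if total else 0.0
    rows = sorted(union_rows)
    frac_reads = float(counts[rows].sum() / total) if total else 0.0
    frac_unique = len(rows) / len(table.df) if len(table.df) else 0.0
    return MotifBurden(
        sample_id=table.sample_id,
        tissue=table.tissue,
        fraction_reads=frac_reads if weighting == "reads" else frac_unique,
        fraction_unique=frac_unique,
        per_motif=per_motif,
        n_distinct_motifs=n_distinct,
        total_reads=int(total),
        n_clonotypes=len(table.df),
    )


def prepare_for_burden(
    table: ClonotypeTable,
    drop_singletons: bool = False,
    min_reads: int | None = None,
    downsample_to: int | None = None,
    seed: int = 0,
) -> ClonotypeTable | None:
    """Apply the cohort entry filters for burden quantification.

    Returns ``None`` when the sample fails the ``min_reads`` floor (e.g. the
    100-read requirement for RNA-derived repertoires).  Downsampling (e.g.
    to 40,000 reads) is applied only when the sample is deeper than the
    target.
    """
    if drop_singletons:
        table = remove_singletons(table)
    if min_reads is not None and table.total_reads < min_reads:
        logger.warning(
            "%s excluded from burden analysis: %d reads < %d",
            table.sample_id, table.total_reads, min_reads,
        )
        return None
    if downsample_to is not None and table.total_reads > downsample_to:
        table = downsample(table, downsample_to, seed)
    return table


def compare_burden(groups: dict[str, list[MotifBurden]]) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum comparisons of group burdens.

    One row per unordered group pair with group medians, the shift
    direction, and the rank-sum p-value on ``fraction_reads``.
    """
    if len(groups) < 2:
        raise RepertoireError("compare_burden needs at least two groups")
    for label, bs in groups.items():
        if not bs:
            raise RepertoireError(f"group {label!r} is empty")
    rows = []
    for ga, gb in combinations(sorted(groups), 2):
        xa = np.array([b.fraction_reads for b in groups[ga]])
        xb = np.array([b.fraction_reads for b in groups[gb]])
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": med_a,
                "median_b": med_b,
                "direction": "a>b" if med_a > med_b else ("b>a" if med_b > med_a else "tie"),
                "p_value": rank_sum_test(xa, xb),
            }
        )
    return pd.DataFrame(rows)


def burden_ratio(burden: MotifBurden, reference_fraction: float) -> float:
    """Ratio of the motif-bearing fraction to a reference fraction
    (e.g. the anti-viral TCR fraction of the same sample).

    Returns NaN when the reference fraction is zero (undefined)."""
    if reference_fraction < 0:
        raise RepertoireError("reference fraction must be non-negative")
    if reference_fraction == 0:
        return float("nan")
    return burden.fraction_reads / reference_fraction


def burdens_to_frame(burdens: list[MotifBurden]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": b.sample_id,
                "tissue": b.tissue,
                "fraction_reads": b.fraction_reads,
                "fraction_unique": b.fraction_unique,
                "n_distinct_motifs": b.n_distinct_motifs,
                "total_reads": b.total_reads,
                "n_clonotypes": b.n_clonotypes,
            }
            for b in burdens
        ]
    )
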