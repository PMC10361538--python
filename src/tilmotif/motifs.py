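"""GLIPH2-style discovery of shared local CDR3beta motifs.

A "local motif" is a short amino-acid pattern (contiguous k-mer, or a
(k+1)-mer with exactly one internal position wildcarded as '*') drawn from
the central region of the CDR3beta — the loop minus a conserved head
(default 3 residues, e.g. 'CAS') and tail (default 2).  A motif is reported
when it is carried by at least ``min_cluster`` distinct TCRs in the pooled
cohort and is enriched over a naive reference repertoire (one-sided Fisher
exact test, BH-corrected, with a fold-change floor).

This is a reimplementation of the local-motif concept, not a port of
GLIPH2: global similarity clustering, HLA scoring and V-gene bias are out
of scope; every downstream step here operates on motif strings and their
discovery offsets.  Offsets are 0-based positions in the *full* CDR3aa.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .repertoire import ClonotypeTable, RepertoireError
from .stats import bh_adjust, fisher_greater_vec

logger = logging.getLogger("tilmotif")

DEFAULT_K_SET = (3, 4)
DEFAULT_HEAD = 3
DEFAULT_TAIL = 2
DEFAULT_MIN_CLUSTER = 3
DEFAULT_MIN_FOLD = 10.0
DEFAULT_ALPHA = 0.05


def trim_cdr3(cdr3_aa: str, head: int = DEFAULT_HEAD, tail: int = DEFAULT_TAIL):
    """Central CDR3 region used for motif enumeration.

    Returns ``(core, head_offset)`` mapping core position 0 to full-CDR3
    position ``head_offset``; returns ``None`` (skip sentinel) when the
    sequence is too short to have a non-empty core.
    """
    if len(cdr3_aa) <= head + tail:
        return None
    return cdr3_aa[head: len(cdr3_aa) - tail], head


def enumerate_motifs(
    core: str,
    head_offset: int = 0,
    k_set: tuple[int, ...] = DEFAULT_K_SET,
    allow_one_wildcard: bool = True,
) -> list[tuple[str, int]]:
    """All (motif, offset) occurrences in a trimmed core.

    For each k in ``k_set``: every contiguous k-mer, and — when wildcarding
    is on — every (k+1)-mer with exactly one internal position replaced by
    '*' ('*' is never terminal).  Offsets are in full-CDR3 coordinates.
    """
    out: list[tuple[str, int]] = []
    n = len(core)
    for k in sorted(k_set):
        for i in range(n - k + 1):
            out.append((core[i: i + k], head_offset + i))
        if allow_one_wildcard:
            w = k + 1
            for i in range(n - w + 1):
                seg = core[i: i + w]
                for j in range(1, w - 1):
                    out.append((seg[:j] + "*" + seg[j + 1:], head_offset + i))
    return out


def motif_matches_at(cdr3_aa: str, motif: str, offset: int,
                     head: int = DEFAULT_HEAD, tail: int = DEFAULT_TAIL) -> bool:
    """Does ``motif`` occur at absolute position ``offset`` of the CDR3,
    inside the trimmed central region?  '*' matches any residue."""
    end = offset + len(motif)
    if offset < head or end > len(cdr3_aa) - tail:
        return False
    return all(m == "*" or m == c for m, c in zip(motif, cdr3_aa[offset:end]))


def find_motif_offsets(cdr3_aa: str, motif: str,
                       head: int = DEFAULT_HEAD, tail: int = DEFAULT_TAIL) -> list[int]:
    """All central-region offsets at which ``motif`` occurs in the CDR3."""
    return [
        off
        for off in range(head, len(cdr3_aa) - tail - len(motif) + 1)
        if motif_matches_at(cdr3_aa, motif, off, head, tail)
    ]


# ---------------------------------------------------------------------------
# per-repertoire motif occurrence indexes
# ---------------------------------------------------------------------------

def _unique_tcrs(tables: list[ClonotypeTable]) -> pd.DataFrame:
    """Distinct TCRs (CDR3aa + V gene) pooled across samples, with the set
    of contributing samples per TCR."""
    frames = []
    for t in tables:
        frames.append(pd.DataFrame({
            "cdr3_aa": t.df["cdr3_aa"], "v_gene": t.df["v_gene"], "sample_id": t.sample_id,
        }))
    pooled = pd.concat(frames, ignore_index=True)
    g = pooled.groupby(["cdr3_aa", "v_gene"], sort=True)["sample_id"].agg(set)
    return g.reset_index().rename(columns={"sample_id": "samples"})


class MotifCounts:
    """Distinct-TCR carrier counts per motif for a pooled repertoire.

    Precompute once per reference repertoire and reuse across discovery runs.
    """

    def __init__(self, tables: list[ClonotypeTable] | ClonotypeTable,
                 k_set=DEFAULT_K_SET, head=DEFAULT_HEAD, tail=DEFAULT_TAIL,
                 allow_one_wildcard: bool = True):
        if isinstance(tables, ClonotypeTable):
            tables = [tables]
        self.k_set, self.head, self.tail = tuple(k_set), head, tail
        self.allow_one_wildcard = allow_one_wildcard
        tcrs = _unique_tcrs(tables)
        self.n_tcrs = len(tcrs)
        self.carriers: dict[str, set[str]] = defaultdict(set)
        self.offsets: dict[str, set[int]] = defaultdict(set)
        self.samples: dict[str, set[str]] = defaultdict(set)
        per_aa_cache: dict[str, list[tuple[str, int]]] = {}
        for aa, v, samples in tcrs.itertuples(index=False):
            occ = per_aa_cache.get(aa)
            if occ is None:
                trimmed = trim_cdr3(aa, head, tail)
                occ = [] if trimmed is None else enumerate_motifs(
                    trimmed[0], trimmed[1], self.k_set, allow_one_wildcard)
                per_aa_cache[aa] = occ
            key = f"{aa}|{v}"
            for motif, off in occ:
                self.carriers[motif].add(key)
                self.offsets[motif].add(off)
                self.samples[motif] |= samples

    def count(self, motif: str) -> int:
        return len(self.carriers.get(motif, ()))


@dataclass
class MotifRecord:
    """One discovered motif with its supporting evidence."""

    motif: str
    offsets: frozenset[int]
    cluster: frozenset[str]  # distinct CDR3aa|V keys carrying the motif
    cluster_size: int
    n_samples: int
    discovery_tissue: str
    count_cohort: int
    count_reference: int
    fold: float
    enrichment_p: float
    p_adjusted: float


@dataclass
class MotifIndex:
    """motif string -> MotifRecord for one cohort discovery run."""

    records: dict[str, MotifRecord]
    tissue: str
    params: dict = field(default_factory=dict)

    def __contains__(self, motif: str) -> bool:
        return motif in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, motif: str) -> MotifRecord:
        return self.records[motif]

    def motifs(self) -> list[str]:
        return sorted(self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "motif": r.motif,
                "offsets": ",".join(map(str, sorted(r.offsets))),
                "cluster_size": r.cluster_size,
                "n_samples": r.n_samples,
                "discovery_tissue": r.discovery_tissue,
                "count_cohort": r.count_cohort,
                "count_reference": r.count_reference,
                "fold": r.fold,
                "p": r.enrichment_p,
                "p_adj": r.p_adjusted,
            }
            for r in (self.records[m] for m in self.motifs())
        ]
        return pd.DataFrame(rows, columns=[
            "motif", "offsets", "cluster_size", "n_samples", "discovery_tissue",
            "count_cohort", "count_reference", "fold", "p", "p_adj",
        ])

    def write(self, tsv_path: str | Path) -> None:
        """TSV of records plus a JSON sidecar with the parameter record."""
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        with open(tsv_path.with_suffix(".params.json"), "w") as fh:
            json.dump({"tissue": self.tissue, **self.params}, fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, tsv_path: str | Path) -> "MotifIndex":
        """Load a serialized index (cluster membership is not serialized)."""
        tsv_path = Path(tsv_path)
        df = pd.read_csv(tsv_path, sep="\t", dtype={"motif": str, "offsets": str})
        params_path = tsv_path.with_suffix(".params.json")
        params = json.loads(params_path.read_text()) if params_path.exists() else {}
        records = {}
        for row in df.itertuples(index=False):
            records[row.motif] = MotifRecord(
                motif=row.motif,
                offsets=frozenset(int(x) for x in str(row.offsets).split(",") if x != ""),
                cluster=frozenset(),
                cluster_size=int(row.cluster_size),
                n_samples=int(row.n_samples),
                discovery_tissue=str(row.discovery_tissue),
                count_cohort=int(row.count_cohort),
                count_reference=int(row.count_reference),
                fold=float(row.fold),
                enrichment_p=float(row.p),
                p_adjusted=float(row.p_adj),
            )
        return cls(records=records, tissue=str(params.get("tissue", "other")), params=params)


def discover_cohort_motifs(
    cohort: list[ClonotypeTable],
    reference: MotifCounts | list[ClonotypeTable] | ClonotypeTable,
    min_cluster: int = DEFAULT_MIN_CLUSTER,
    min_fold: float = DEFAULT_MIN_FOLD,
    alpha: float = DEFAULT_ALPHA,
    min_motif_len: int = 3,
    k_set: tuple[int, ...] = DEFAULT_K_SET,
    head: int = DEFAULT_HEAD,
    tail: int = DEFAULT_TAIL,
    allow_one_wildcard: bool = True,
    tissue: str | None = None,
) -> MotifIndex:
    """Discover locally shared motifs in a pooled tissue cohort.

    Pools distinct TCRs (CDR3aa + V) across the cohort samples, counts
    carriers of every candidate motif in cohort vs reference, keeps
    candidates carried by >= ``min_cluster`` distinct TCRs, tests one-sided
    Fisher enrichment over the reference with BH correction, and retains
    motifs with adjusted p < ``alpha`` and fold >= ``min_fold``.

    Fold is the carrier-proportion ratio with the reference carrier count
    floored at 1 (a motif absent from the reference would otherwise have
    infinite fold).
    """
    if not cohort:
        raise RepertoireError("discover_cohort_motifs: empty cohort")
    if min(k_set) < min_motif_len:
        k_set = tuple(k for k in k_set if k >= min_motif_len)
        if not k_set:
            raise RepertoireError("k_set has no entries >= min_motif_len")
    if tissue is None:
        tissue = cohort[0].tissue
    cohort_counts = MotifCounts(cohort, k_set=k_set, head=head, tail=tail,
                                allow_one_wildcard=allow_one_wildcard)
    if not isinstance(reference, MotifCounts):
        reference = MotifCounts(reference, k_set=k_set, head=head, tail=tail,
                                allow_one_wildcard=allow_one_wildcard)
    if reference.k_set != cohort_counts.k_set or (reference.head, reference.tail) != (head, tail):
        raise RepertoireError("reference MotifCounts built with different enumeration parameters")

    candidates = sorted(
        m for m, carriers in cohort_counts.carriers.items() if len(carriers) >= min_cluster
    )
    if not candidates:
        return MotifIndex(records={}, tissue=tissue, params={})
    a = np.array([len(cohort_counts.carriers[m]) for m in candidates])
    b = np.array([reference.count(m) for m in candidates])
    n_c, n_r = cohort_counts.n_tcrs, reference.n_tcrs
    pvals = fisher_greater_vec(a, n_c, b, n_r)
    padj = bh_adjust(pvals)
    fold = (a / n_c) / (np.maximum(b, 1) / n_r)

    keep = (padj < alpha) & (fold >= min_fold)
    records = {}
    for i in np.flatnonzero(keep):
        m = candidates[i]
        records[m] = MotifRecord(
            motif=m,
            offsets=frozenset(cohort_counts.offsets[m]),
            cluster=frozenset(cohort_counts.carriers[m]),
            cluster_size=int(a[i]),
            n_samples=len(cohort_counts.samples[m]),
            discovery_tissue=tissue,
            count_cohort=int(a[i]),
            count_reference=int(b[i]),
            fold=float(fold[i]),
            enrichment_p=float(pvals[i]),
            p_adjusted=float(padj[i]),
        )
    logger.info(
        "discovered %d/%d candidate motifs in %s cohort (%d TCRs vs %d reference)",
        len(records), len(candidates), tissue, n_c, n_r,
    )
    return MotifIndex(
        records=records,
        tissue=tissue,
        params={
            "k_set": list(cohort_counts.k_set), "head": head, "tail": tail,
            "allow_one_wildcard": allow_one_wildcard, "min_cluster": min_cluster,
            "min_fold": min_fold, "alpha": alpha, "n_cohort_tcrs": n_c,
            "n_reference_tcrs": n_r,
        },
    )
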