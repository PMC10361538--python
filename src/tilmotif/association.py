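"""Classify discovered motifs as tumor-exclusive or tumor-enriched and
prune against control motif sets.

A motif discovered in the tumor cohort is *exclusive* when it is absent
from every comparator-tissue discovery index.  Shared motifs are compared
on per-sample pooled frequencies: within each sample all TCRs carrying the
motif are pooled (samples without the motif contribute 0), tumor vs
comparator distributions are tested with a two-sided Wilcoxon rank-sum
test, p-values are BH-corrected across motifs, and a motif is *enriched*
when adjusted p < alpha and log2 fold change > 1 against the healthy-kidney
and/or blood comparator (either suffices by default).  Motifs appearing in
any control set (validation cohorts, viral motif lists) are *pruned*;
exclusive + enriched survivors form the tumor-associated motif set.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np

from .motifs import (
    DEFAULT_HEAD,
    DEFAULT_K_SET,
    DEFAULT_TAIL,
    MotifIndex,
    MotifRecord,
    enumerate_motifs,
    trim_cdr3,
)
from .repertoire import ClonotypeTable, RepertoireError
from .stats import bh_adjust, rank_sum_test

logger = logging.getLogger("tilmotif")

STATUSES = ("exclusive", "enriched", "rejected", "pruned")


class SampleMotifView:
    """Inverted motif-occurrence index for one sample.

    Maps every enumerable motif of the sample's CDR3s to the rows (and
    full-CDR3 offsets) carrying it; makes repeated pooled-frequency and
    burden queries cheap.
    """

    def __init__(self, table: ClonotypeTable, k_set=DEFAULT_K_SET,
                 head=DEFAULT_HEAD, tail=DEFAULT_TAIL, allow_one_wildcard=True):
        self.table = table
        self.total_reads = table.total_reads
        self.occ: dict[str, list[tuple[int, int]]] = defaultdict(list)
        cache: dict[str, list[tuple[str, int]]] = {}
        for idx, aa in enumerate(table.df["cdr3_aa"].astype(str)):
            pairs = cache.get(aa)
            if pairs is None:
                trimmed = trim_cdr3(aa, head, tail)
                pairs = [] if trimmed is None else enumerate_motifs(
                    trimmed[0], trimmed[1], k_set, allow_one_wildcard)
                cache[aa] = pairs
            for motif, off in pairs:
                self.occ[motif].append((idx, off))

    def carrier_rows(self, motif: str, allowed_offsets=None) -> list[int]:
        hits = self.occ.get(motif, ())
        if allowed_offsets is None:
            return sorted({i for i, _ in hits})
        return sorted({i for i, off in hits if off in allowed_offsets})


def pooled_motif_frequency(
    sample: ClonotypeTable | SampleMotifView,
    motif: MotifRecord,
    weighting: str = "reads",
    same_location: bool = True,
) -> float:
    """Pooled frequency of all TCRs carrying ``motif`` in one sample.

    ``weighting='reads'``: summed read frequency of carrier clonotypes
    (default; repertoire proportion).  ``weighting='unique'``: fraction of
    distinct clonotypes that carry the motif.  With ``same_location`` the
    motif must occur at one of its discovery offsets.  Samples without the
    motif return 0.
    """
    if not motif.offsets:
        raise RepertoireError(f"motif {motif.motif} has no recorded offsets")
    view = sample if isinstance(sample, SampleMotifView) else SampleMotifView(sample)
    rows = view.carrier_rows(motif.motif, motif.offsets if same_location else None)
    if not rows:
        return 0.0
    if weighting == "unique":
        return len(rows) / len(view.table.df)
    if weighting != "reads":
        raise RepertoireError(f"unknown weighting {weighting!r}")
    total = view.total_reads
    if total == 0:
        return 0.0
    return float(view.table.df["count"].to_numpy()[rows].sum() / total)


@dataclass
class MotifAssociation:
    """Per-motif tumor-association verdict with supporting statistics."""

    motif: str
    status: str
    tumor_freqs: tuple = ()
    comparator_freqs: dict = field(default_factory=dict)
    wilcoxon_p: dict = field(default_factory=dict)
    p_adjusted: dict = field(default_factory=dict)
    log2fc: dict = field(default_factory=dict)
    pruned_by: list = field(default_factory=list)
    undefined_log2fc: bool = False


def _smallest_nonzero_freq(samples: list[ClonotypeTable]) -> float:
    totals = [s.total_reads for s in samples if s.total_reads > 0]
    if not totals:
        raise RepertoireError("comparator cohort has no reads")
    return 1.0 / max(totals)


def classify_motifs(
    tumor_idx: MotifIndex,
    comparator_idxs: dict[str, MotifIndex],
    tumor_samples: list[ClonotypeTable],
    comparator_samples: dict[str, list[ClonotypeTable]],
    alpha: float = 0.05,
    min_log2fc: float = 1.0,
    weighting: str = "reads",
    rule: str = "any",
    agg: str = "mean",
) -> list[MotifAssociation]:
    """Assign every tumor-discovered motif a status: exclusive, enriched
    or rejected.

    ``rule='any'``: enrichment against any single comparator suffices
    (healthy kidney and/or blood); ``rule='all'`` requires every comparator.
    ``agg`` selects the per-group location used for log2fc (mean | median);
    the zero-comparator pseudocount is the smallest representable nonzero
    frequency in that comparator pool (1 / largest sample depth).
    """
    if rule not in ("any", "all"):
        raise RepertoireError(f"unknown comparator rule {rule!r}")
    aggfun = {"mean": np.mean, "median": np.median}[agg]
    for name, samples in comparator_samples.items():
        if not samples:
            raise RepertoireError(f"comparator {name!r} has zero samples")

    params = tumor_idx.params
    view_kwargs = dict(
        k_set=tuple(params.get("k_set", DEFAULT_K_SET)),
        head=params.get("head", DEFAULT_HEAD),
        tail=params.get("tail", DEFAULT_TAIL),
        allow_one_wildcard=params.get("allow_one_wildcard", True),
    )
    tumor_views = [SampleMotifView(s, **view_kwargs) for s in tumor_samples]
    comp_views = {
        name: [SampleMotifView(s, **view_kwargs) for s in samples]
        for name, samples in comparator_samples.items()
    }
    eps = {name: _smallest_nonzero_freq(s) for name, s in comparator_samples.items()}

    shared: dict[str, list[str]] = {}
    for motif in tumor_idx.motifs():
        names = [n for n, idx in comparator_idxs.items() if motif in idx]
        if names:
            shared[motif] = names

    associations: dict[str, MotifAssociation] = {}
    pvals_by_comp: dict[str, dict[str, float]] = {n: {} for n in comparator_idxs}
    for motif in tumor_idx.motifs():
        rec = tumor_idx[motif]
        tf = tuple(
            pooled_motif_frequency(v, rec, weighting=weighting) for v in tumor_views
        )
        assoc = MotifAssociation(motif=motif, status="exclusive", tumor_freqs=tf)
        for name in shared.get(motif, ()):
            cf = tuple(
                pooled_motif_frequency(v, rec, weighting=weighting)
                for v in comp_views[name]
            )
            assoc.comparator_freqs[name] = cf
            p = rank_sum_test(tf, cf)
            assoc.wilcoxon_p[name] = p
            pvals_by_comp[name][motif] = p
            mt, mc = aggfun(tf), aggfun(cf)
            if mt == 0:
                assoc.undefined_log2fc = True
                assoc.log2fc[name] = float("nan")
            else:
                assoc.log2fc[name] = float(np.log2(mt / max(mc, eps[name])))
        if motif in shared:
            assoc.status = "rejected"  # upgraded to enriched after BH below
        associations[motif] = assoc

    for name, pmap in pvals_by_comp.items():
        if not pmap:
            continue
        motifs_tested = sorted(pmap)
        adj = bh_adjust(np.array([pmap[m] for m in motifs_tested]))
        for m, pa in zip(motifs_tested, adj):
            associations[m].p_adjusted[name] = float(pa)

    for motif, names in shared.items():
        assoc = associations[motif]
        hits = [
            assoc.p_adjusted[n] < alpha and assoc.log2fc.get(n, float("nan")) > min_log2fc
            for n in names
        ]
        ok = any(hits) if rule == "any" else (bool(hits) and all(hits))
        if ok and not assoc.undefined_log2fc:
            assoc.status = "enriched"
    return list(associations.values())


def prune_against_controls(
    associations: list[MotifAssociation],
    control_sets: list[tuple[str, set[str]]],
) -> list[MotifAssociation]:
    """Mark any motif appearing in a control set as pruned.

    Order-independent across control sets and idempotent; ``pruned_by``
    lists every control set containing the motif.
    """
    out = []
    for assoc in associations:
        names = sorted({name for name, motifs in control_sets if assoc.motif in motifs}
                       | set(assoc.pruned_by))
        if names:
            out.append(replace(assoc, status="pruned", pruned_by=list(names)))
        else:
            out.append(replace(assoc))
    return out


def associated_motifs(associations: list[MotifAssociation]) -> list[MotifAssociation]:
    """The tumor-associated set: exclusive plus enriched survivors."""
    return [a for a in associations if a.status in ("exclusive", "enriched")]


def associations_to_frame(associations: list[MotifAssociation], tumor_idx: MotifIndex | None = None):
    """Flat table of verdicts (one row per motif) for TSV export."""
    import pandas as pd

    rows = []
    for a in sorted(associations, key=lambda x: x.motif):
        row = {
            "motif": a.motif,
            "status": a.status,
            "mean_tumor_freq": float(np.mean(a.tumor_freqs)) if a.tumor_freqs else np.nan,
            "pruned_by": ",".join(a.pruned_by),
        }
        for name in sorted(a.comparator_freqs):
            row[f"mean_{name}_freq"] = float(np.mean(a.comparator_freqs[name]))
            row[f"p_{name}"] = a.wilcoxon_p.get(name, np.nan)
            row[f"p_adj_{name}"] = a.p_adjusted.get(name, np.nan)
            row[f"log2fc_{name}"] = a.log2fc.get(name, np.nan)
        if tumor_idx is not None and a.motif in tumor_idx:
            rec = tumor_idx[a.motif]
            row["offsets"] = ",".join(map(str, sorted(rec.offsets)))
            row["cluster_size"] = rec.cluster_size
        rows.append(row)
    return pd.DataFrame(rows)
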