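"""Map motifs onto single-cell clonotype-phenotype data.

For each motif, its *supporting cells* are the cells whose CDR3beta
carries the motif at one of its discovery offsets.  For every phenotype
label P a 2x2 contingency table over all phenotyped cells is formed
(motif x P membership) and the odds ratio computed; the phenotype with the
largest OR is the motif's dominant phenotype.  Calls are emitted only for
motifs with at least ``min_cells`` supporting cells (default 5).

Also provides expression-signature module scores in the binned-control
style: per-cell mean of the module genes minus the mean of
expression-matched control genes sampled from average-expression bins —
used for cytotoxicity (GZMB, GZMA, GZMH, PRF1, GNLY, FGFBP2), exhaustion
(PDCD1, LAG3, CTLA4, TIGIT, TOX, HAVCR2) and tissue residency (ITGA1,
ITGAE, ZNF683, CD69, IFNG, CCR5) signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import DEFAULT_HEAD, DEFAULT_TAIL, MotifIndex, MotifRecord, find_motif_offsets
from .repertoire import RepertoireError

logger = logging.getLogger("tilmotif")

CYTOTOXICITY_GENES = ("GZMB", "GZMA", "GZMH", "PRF1", "GNLY", "FGFBP2")
EXHAUSTION_GENES = ("PDCD1", "LAG3", "CTLA4", "TIGIT", "TOX", "HAVCR2")
TISSUE_RESIDENT_GENES = ("ITGA1", "ITGAE", "ZNF683", "CD69", "IFNG", "CCR5")

CELL_COLUMNS = ("cell_id", "cdr3_aa", "phenotype")


@dataclass
class MotifPhenotypeCall:
    motif: str
    n_supporting_cells: int
    odds_ratios: dict[str, float]
    counts: dict[str, tuple[int, int, int, int]]  # per phenotype: a, b, c, d
    dominant_phenotype: str
    dominant_or: float


def _validate_cells(cells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise RepertoireError(f"cell table missing column(s) {missing}")
    if cells["cell_id"].duplicated().any():
        raise RepertoireError("cell_id values must be unique")
    if cells["phenotype"].isna().any() or (cells["phenotype"].astype(str) == "").any():
        raise RepertoireError("phenotype label missing for some cells")
    return cells


def _haldane_or(a: int, b: int, c: int, d: int) -> float:
    # +0.5 to every cell when any margin cell is zero keeps argmax defined
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def assign_motif_phenotypes(
    cells: pd.DataFrame,
    motifs: MotifIndex | list[MotifRecord],
    min_cells: int = 5,
    head: int = DEFAULT_HEAD,
    tail: int = DEFAULT_TAIL,
    same_location: bool = True,
) -> list[MotifPhenotypeCall]:
    """Dominant-phenotype calls for every motif with enough supporting cells.

    Ties on the odds ratio are broken by the larger supporting-cell count
    within the phenotype, then lexicographically by label.
    """
    cells = _validate_cells(cells)
    records = (
        [motifs[m] for m in motifs.motifs()] if isinstance(motifs, MotifIndex) else list(motifs)
    )
    phenos = sorted(cells["phenotype"].astype(str).unique())
    pheno_arr = cells["phenotype"].astype(str).to_numpy()
    n_total = len(cells)
    aa_values = cells["cdr3_aa"].astype(str).to_numpy()

    # memoize per distinct CDR3aa: which (motif, offsets) it carries
    unique_aa = pd.unique(aa_values)
    calls: list[MotifPhenotypeCall] = []
    for rec in records:
        allowed = rec.offsets if same_location else None
        carrier_aa = set()
        for aa in unique_aa:
            offs = find_motif_offsets(aa, rec.motif, head, tail)
            if allowed is not None:
                offs = [o for o in offs if o in allowed]
            if offs:
                carrier_aa.add(aa)
        mask = np.isin(aa_values, sorted(carrier_aa)) if carrier_aa else np.zeros(n_total, bool)
        n_sup = int(mask.sum())
        if n_sup < min_cells:
            if n_sup:
                logger.info("motif %s: %d supporting cells < %d, skipped",
                            rec.motif, n_sup, min_cells)
            continue
        ors, counts = {}, {}
        for p in phenos:
            in_p = pheno_arr == p
            a = int((mask & in_p).sum())
            b = n_sup - a
            c = int(in_p.sum()) - a
            d = n_total - n_sup - c
            counts[p] = (a, b, c, d)
            ors[p] = _haldane_or(a, b, c, d)
        dominant = max(phenos, key=lambda p: (ors[p], counts[p][0], [-ord(ch) for ch in p]))
        calls.append(
            MotifPhenotypeCall(
                motif=rec.motif,
                n_supporting_cells=n_sup,
                odds_ratios=ors,
                counts=counts,
                dominant_phenotype=dominant,
                dominant_or=ors[dominant],
            )
        )
    return calls


def calls_to_frame(calls: list[MotifPhenotypeCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": c.motif,
                "n_supporting_cells": c.n_supporting_cells,
                "dominant_phenotype": c.dominant_phenotype,
                "dominant_or": c.dominant_or,
            }
            for c in sorted(calls, key=lambda c: c.motif)
        ]
    )


# ---------------------------------------------------------------------------
# module scores (binned expression-matched controls)
# ---------------------------------------------------------------------------

@dataclass
class ModuleScoreSpec:
    name: str
    genes: tuple[str, ...]
    n_bins: int = 24
    n_control_per_gene: int = 100
    seed: int = 0

    def __post_init__(self):
        if not self.genes:
            raise RepertoireError("module gene list must be non-empty")


DEFAULT_MODULES = (
    ModuleScoreSpec("cytotoxicity", CYTOTOXICITY_GENES),
    ModuleScoreSpec("exhaustion", EXHAUSTION_GENES),
    ModuleScoreSpec("tissue_resident", TISSUE_RESIDENT_GENES),
)


def module_score(expr: pd.DataFrame, spec: ModuleScoreSpec) -> pd.Series:
    """Per-cell module score on a log-normalized cells x genes matrix.

    Genes are binned into ``n_bins`` by average expression across cells;
    for each module gene, ``n_control_per_gene`` control genes are sampled
    with replacement from its bin; score = mean(module genes) - mean(all
    sampled controls), per cell.  Deterministic for a given spec seed.
    Module genes absent from the matrix are dropped with a warning; all
    absent is an error.
    """
    genes = [g for g in spec.genes if g in expr.columns]
    missing = sorted(set(spec.genes) - set(genes))
    if missing:
        logger.warning("module %s: genes absent from matrix and dropped: %s",
                       spec.name, ",".join(missing))
    if not genes:
        raise RepertoireError(f"module {spec.name}: no module genes present in matrix")
    n_bins = min(spec.n_bins, expr.shape[1])
    avg = expr.mean(axis=0)
    # rank-based cut gives equal-occupancy bins even with heavy ties
    bins = pd.qcut(avg.rank(method="first"), n_bins, labels=False)
    rng = np.random.default_rng(spec.seed)
    control_cols: list[str] = []
    gene_set = set(genes)
    # module genes are excluded from their own control pool
    by_bin = {b: [g for g in avg.index[bins == b] if g not in gene_set]
              for b in range(n_bins)}
    fallback = [g for g in avg.index if g not in gene_set]
    for g in genes:
        pool = by_bin[int(bins[g])] or fallback
        if not pool:
            raise RepertoireError("no control genes available outside the module")
        control_cols.extend(rng.choice(pool, size=spec.n_control_per_gene, replace=True))
    score = expr[genes].mean(axis=1) - expr[control_cols].mean(axis=1)
    score.name = spec.name
    return score


def log_normalize(counts: pd.DataFrame, scale: float = 10_000.0) -> pd.DataFrame:
    """ln(1 + scale * count / cell_total), the standard single-cell
    log-normalization feeding the module scores."""
    totals = counts.sum(axis=1).replace(0, 1)
    return np.log1p(counts.div(totals, axis=0) * scale)
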