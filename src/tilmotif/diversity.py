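"""Clonality and diversity indices on a single repertoire.

All indices are computed on the observed clone-count vector only — no
unseen-species correction except Chao1, whose purpose is exactly that.
Gini, inverse Simpson, Shannon and clonality are scale-invariant in the
counts; Chao1 is not (it depends on singleton/doubleton counts).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .repertoire import ClonotypeTable


class EmptyRepertoireError(ValueError):
    pass


def _counts(table: ClonotypeTable | np.ndarray) -> np.ndarray:
    if isinstance(table, ClonotypeTable):
        c = table.df["count"].to_numpy(float)
    else:
        c = np.asarray(table, dtype=float)
    if c.size == 0 or c.sum() <= 0:
        raise EmptyRepertoireError("diversity indices need a non-empty repertoire")
    return c


def gini_index(table: ClonotypeTable | np.ndarray) -> float:
    """Gini coefficient of the clone-frequency distribution, in [0, 1).

    Equals half the mean absolute pairwise difference divided by the mean
    (Lorenz-curve area form): 0 for a perfectly even repertoire, approaching
    1 when a single clone dominates.  A one-clone repertoire returns 0
    (degenerate: there is no inequality to measure).
    """
    c = np.sort(_counts(table))
    n = c.size
    if n == 1:
        return 0.0
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * c).sum() / (n * c.sum()))


def shannon_index(table: ClonotypeTable | np.ndarray) -> float:
    """Shannon entropy H = -sum p ln p (natural log)."""
    p = _counts(table)
    p = p / p.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inverse_simpson(table: ClonotypeTable | np.ndarray) -> float:
    """Inverse Simpson index 1 / sum(p_i^2); equals n for n even clones."""
    p = _counts(table)
    p = p / p.sum()
    return float(1.0 / (p**2).sum())


def chao1(table: ClonotypeTable | np.ndarray) -> float:
    """Chao1 richness estimate from integer counts.

    S_obs + F1^2 / (2 F2); when no doubletons exist the bias-corrected form
    S_obs + F1 (F1 - 1) / (2 (F2 + 1)) is used.  F1/F2 are the numbers of
    clonotypes seen exactly once/twice.
    """
    c = _counts(table)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def clonality(table: ClonotypeTable | np.ndarray) -> float:
    """1 - Pielou evenness = 1 - H / ln(S); 0 for uniform repertoires.

    Defined as 0 for a single-clone repertoire (ln S = 0 degenerate case).
    """
    c = _counts(table)
    if c.size <= 1:
        return 0.0
    return float(1.0 - shannon_index(c) / np.log(c.size))


@dataclass
class DiversitySummary:
    sample_id: str
    tissue: str
    n_clonotypes: int
    total_reads: int
    gini: float
    shannon: float
    inverse_simpson: float
    chao1: float
    clonality: float
    degenerate: bool  # single-clonotype repertoire

    def as_dict(self) -> dict:
        return asdict(self)


def diversity_summary(table: ClonotypeTable) -> DiversitySummary:
    """All indices for one sample, with the degenerate single-clone flag."""
    return DiversitySummary(
        sample_id=table.sample_id,
        tissue=table.tissue,
        n_clonotypes=table.n_clonotypes,
        total_reads=table.total_reads,
        gini=gini_index(table),
        shannon=shannon_index(table),
        inverse_simpson=inverse_simpson(table),
        chao1=chao1(table),
        clonality=clonality(table),
        degenerate=table.n_clonotypes == 1,
    )
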