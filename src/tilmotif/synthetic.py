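"""Synthetic TCR-repertoire cohorts with a ground-truth manifest.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage is testable without patient data:

* Zipf-like clone-size distributions per tissue compartment, with
  pre-expansion TIL cultures far more clonal than tumor tissue;
* short amino-acid motifs planted into tumor-biased carrier clonotypes —
  "exclusive" motifs appear only in tumor samples, "enriched" motifs also
  appear in healthy kidney / blood at one tenth the tumor incidence;
* paired pre-expansion / post-expansion TIL repertoires sharing a clone
  backbone, with designated clones whose frequencies differ by a known
  fold change in a known direction (expansion truth), mass-balanced so all
  non-designated clones keep identical true frequencies in both samples;
* viral spike-in clonotypes taken from a small packaged synthetic
  VDJdb-like reference table;
* a single-cell clonotype-phenotype table whose motif-bearing cells are
  biased toward a per-motif target phenotype, plus a negative-binomial
  expression matrix with log-normal effects on phenotype signature genes.

Every quantity needed to score a downstream result is recorded in the
:class:`CohortManifest`.  All draws are deterministic for a given seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .repertoire import COLUMNS, ClonotypeTable
from .motifs import find_motif_offsets

logger = logging.getLogger("tilmotif")

#: amino-acid alphabet used inside CDR3 cores (no cysteine: C is reserved
#: for the conserved first position of the loop)
CORE_ALPHABET = tuple("ADEFGHIKLMNPQRSTVWY")

V_SCAFFOLDS = (
    ("TRBV5-1", "CASS"), ("TRBV9", "CASS"), ("TRBV19", "CASS"), ("TRBV6-5", "CASS"),
    ("TRBV27", "CASS"), ("TRBV28", "CASS"), ("TRBV7-9", "CASS"), ("TRBV12-3", "CASS"),
)
J_SCAFFOLDS = (
    ("TRBJ2-1", "EQF"), ("TRBJ2-7", "QYF"), ("TRBJ1-1", "AFF"),
    ("TRBJ1-2", "YTF"), ("TRBJ2-3", "QYF"), ("TRBJ2-5", "ETF"),
)

#: seed of the deterministic naive reference background repertoire
REFERENCE_SEED = 20_240_101

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _reverse_translate(aa: str) -> str:
    return "".join(_CODON.get(ch, "NNN") for ch in aa)


@dataclass
class GeneratorConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror the structure of the emulated study: 20 tumor / 20
    healthy-kidney / 20 blood discovery samples, 7 matched TIL culture
    pairs, ~20,000 reads per sample, clone sizes Zipf-distributed with the
    TIL cultures dominated by their top clones, ten planted tumor-associated
    motifs (half exclusive, half 10x tumor-enriched) carried by five
    distinct TCRs per tumor sample, plus two control-contaminant motifs
    used to exercise pruning.
    """

    # cohort shape
    n_tumor: int = 20
    n_healthy: int = 20
    n_pb: int = 20
    n_til_pairs: int = 7
    clones_per_sample: int = 100
    til_clones: int = 120
    reads_per_sample: int = 20_000
    zipf_exponents: dict = field(default_factory=lambda: {
        "tumor": 1.2, "healthy_kidney": 1.0, "pb": 1.0,
        "pre_rep_til": 2.0, "rep_til": 1.4, "other": 1.0,
    })
    cdr3_len_range: tuple[int, int] = (11, 19)

    # planted motifs
    n_exclusive_motifs: int = 5
    n_enriched_motifs: int = 5
    n_contaminant_motifs: int = 2
    motif_lengths: tuple[int, ...] = (4, 4, 4, 5)  # cycled; length-5 carry one wildcard
    carriers_per_tumor_sample: int = 5
    comparator_incidence_ratio: float = 0.1  # enriched-motif incidence vs tumor
    carrier_rank_range: tuple[int, int] = (20, 90)  # clone ranks eligible as carriers
    motif_offset_range: tuple[int, int] = (4, 8)

    # paired TIL expansion
    n_expanded_per_direction: int = 4
    expansion_fold_range: tuple[float, float] = (10.0, 40.0)
    expanded_freq_range: tuple[float, float] = (0.05, 0.08)  # pre-expanded clone size
    til_backbone_carriers: int = 4
    til_carrier_rank_range: tuple[int, int] = (10, 40)

    # viral spikes
    n_viral_spikes: int = 3
    viral_spike_freq: float = 0.002
    spike_compartments: tuple[str, ...] = ("tumor", "pre_rep_til", "rep_til")

    # single-cell table / expression matrix
    n_cells: int = 2000
    phenotypes: tuple[str, ...] = (
        "CD8_Tex", "CD8_Tpex", "CD4_cytotoxic", "CD4_Tfh",
        "Treg", "CD8_Trm", "NK_like", "CD4_naive",
    )
    phenotype_bias: float = 0.9        # P(target phenotype | motif-bearing cell)
    cells_per_motif: float = 0.02      # expected carrier-cell share per motif
    n_genes: int = 220
    module_effect: float = 1.0         # log-scale elevation of signature genes
    nb_dispersion: float = 2.0         # negative-binomial size parameter


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class PlantedMotif:
    motif: str
    offset: int
    kind: str  # exclusive | enriched | contaminant
    target_phenotype: str | None = None
    carriers: dict = field(default_factory=dict)  # sample_id -> list of carrier CDR3aa


@dataclass
class TrueExpansion:
    patient_id: str
    cdr3_aa: str
    pre_freq: float
    rep_freq: float
    expanded_in: str  # "pre" | "rep"
    fold: float


@dataclass
class ViralSpike:
    sample_id: str
    cdr3_aa: str
    v_gene: str
    epitope: str
    count: int


@dataclass
class CohortManifest:
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    true_expansions: list[TrueExpansion] = field(default_factory=list)
    viral_spikes: list[ViralSpike] = field(default_factory=list)
    control_sets: dict = field(default_factory=dict)  # name -> sorted motif list
    seeds: list[int] = field(default_factory=list)
    generator_params: dict = field(default_factory=dict)

    def associated_motifs(self) -> list[PlantedMotif]:
        """Planted motifs expected to survive classification + pruning."""
        return [m for m in self.planted_motifs if m.kind in ("exclusive", "enriched")]

    def contaminant_motifs(self) -> list[str]:
        return sorted(m.motif for m in self.planted_motifs if m.kind == "contaminant")

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_motifs": [asdict(m) for m in self.planted_motifs],
                "true_expansions": [asdict(e) for e in self.true_expansions],
                "viral_spikes": [asdict(s) for s in self.viral_spikes],
                "control_sets": {k: sorted(v) for k, v in self.control_sets.items()},
                "seeds": self.seeds,
                "generator_params": self.generator_params,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "CohortManifest":
        raw = json.loads(text)
        return cls(
            planted_motifs=[PlantedMotif(**m) for m in raw.get("planted_motifs", [])],
            true_expansions=[TrueExpansion(**e) for e in raw.get("true_expansions", [])],
            viral_spikes=[ViralSpike(**s) for s in raw.get("viral_spikes", [])],
            control_sets={k: set(v) for k, v in raw.get("control_sets", {}).items()},
            seeds=list(raw.get("seeds", [])),
            generator_params=raw.get("generator_params", {}),
        )


@dataclass
class Cohort:
    tumor: list[ClonotypeTable]
    healthy: list[ClonotypeTable]
    pb: list[ClonotypeTable]
    til_pairs: list[tuple[ClonotypeTable, ClonotypeTable]]
    manifest: CohortManifest

    def all_tables(self) -> list[ClonotypeTable]:
        out = [*self.tumor, *self.healthy, *self.pb]
        for pre, rep in self.til_pairs:
            out.extend([pre, rep])
        return out


# ---------------------------------------------------------------------------
# low-level builders
# ---------------------------------------------------------------------------

def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    if exponent <= 0:
        raise ValueError("Zipf exponent must be > 0")
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _random_clone(rng: np.random.Generator, length: int) -> tuple[str, str, str]:
    """One random clonotype: (cdr3_aa, v_gene, j_gene)."""
    v_gene, v_prefix = V_SCAFFOLDS[rng.integers(len(V_SCAFFOLDS))]
    j_gene, j_suffix = J_SCAFFOLDS[rng.integers(len(J_SCAFFOLDS))]
    ncore = length - len(v_prefix) - len(j_suffix)
    core = "".join(rng.choice(CORE_ALPHABET, size=ncore))
    return v_prefix + core + j_suffix, v_gene, j_gene


def _random_clones(rng: np.random.Generator, n: int, len_range: tuple[int, int]) -> pd.DataFrame:
    lengths = rng.integers(len_range[0], len_range[1] + 1, size=n)
    rows = [_random_clone(rng, int(L)) for L in lengths]
    aa = [r[0] for r in rows]
    return pd.DataFrame({
        "cdr3_nt": [_reverse_translate(a) for a in aa],
        "cdr3_aa": aa,
        "v_gene": [r[1] for r in rows],
        "j_gene": [r[2] for r in rows],
    })


def _plant(rng: np.random.Generator, df: pd.DataFrame, row: int, motif: str,
           offset: int, len_range: tuple[int, int]) -> str:
    """Rewrite one clone's CDR3 so it carries ``motif`` at ``offset``.

    The clone gets a fresh sequence long enough to host the motif inside
    the trimmed central region; '*' wildcard positions are realized with a
    random residue.  Returns the new CDR3aa.
    """
    need = offset + len(motif) + 2  # + tail of the trimmed region
    if need > len_range[1]:
        raise ValueError(f"motif {motif!r} at offset {offset} cannot fit max CDR3 length")
    length = int(rng.integers(max(len_range[0], need), len_range[1] + 1))
    aa, v_gene, j_gene = _random_clone(rng, length)
    realized = "".join(rng.choice(CORE_ALPHABET) if ch == "*" else ch for ch in motif)
    aa = aa[:offset] + realized + aa[offset + len(motif):]
    df.loc[row, ["cdr3_aa", "cdr3_nt", "v_gene", "j_gene"]] = (
        aa, _reverse_translate(aa), v_gene, j_gene)
    return aa


def _finish_table(df: pd.DataFrame, counts: np.ndarray, sample_id: str,
                  tissue: str, patient_id: str) -> ClonotypeTable:
    out = df.copy()
    out["count"] = counts
    out["productive"] = True
    out = out[out["count"] > 0].reset_index(drop=True)
    return ClonotypeTable(out[COLUMNS], sample_id=sample_id, tissue=tissue,
                          patient_id=patient_id)


def load_viral_reference() -> pd.DataFrame:
    """The packaged synthetic VDJdb-like viral TCR table (fabricated
    epitope-labelled CDR3s; no real database entries)."""
    with resources.files("tilmotif.data").joinpath("synthetic_viral_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_repertoire(
    config: GeneratorConfig,
    tissue: str,
    patient: str,
    seed: int,
    planted: list[PlantedMotif] | None = None,
    clones: int | None = None,
    sample_id: str | None = None,
) -> ClonotypeTable:
    """One repertoire sample: Zipf clone sizes over random CDR3s, with the
    compartment-appropriate number of planted-motif carriers.

    Exclusive/contaminant motifs are embedded only when ``tissue`` is
    tumor; enriched motifs are embedded in comparator tissues at
    ``comparator_incidence_ratio`` times the tumor carrier count.
    """
    rng = np.random.default_rng(seed)
    n = clones or config.clones_per_sample
    sample_id = sample_id or f"{patient}_{tissue}"
    df = _random_clones(rng, n, config.cdr3_len_range)
    weights = _zipf_weights(n, config.zipf_exponents[tissue])

    lo, hi = config.carrier_rank_range
    eligible = [r for r in range(lo - 1, min(hi, n))]
    rng.shuffle(eligible)
    ptr = 0
    for pm in planted or []:
        if tissue == "tumor":
            k = config.carriers_per_tumor_sample
        elif pm.kind == "enriched" and tissue in ("healthy_kidney", "pb"):
            k = int(rng.binomial(config.carriers_per_tumor_sample,
                                 config.comparator_incidence_ratio))
        else:
            k = 0
        if k == 0:
            continue
        if ptr + k > len(eligible):
            raise ValueError("not enough eligible carrier ranks; widen carrier_rank_range")
        rows = eligible[ptr: ptr + k]
        ptr += k
        pm.carriers.setdefault(sample_id, [])
        for row in rows:
            aa = _plant(rng, df, row, pm.motif, pm.offset, config.cdr3_len_range)
            pm.carriers[sample_id].append(aa)
    counts = rng.multinomial(config.reads_per_sample, weights)
    return _finish_table(df, counts, sample_id, tissue, patient)


def generate_paired_til(
    config: GeneratorConfig,
    patient: str,
    seed: int,
    planted: list[PlantedMotif] | None = None,
) -> tuple[ClonotypeTable, ClonotypeTable, list[TrueExpansion]]:
    """Matched pre-expansion / post-expansion TIL repertoires.

    Designated clones come in mass-balanced pairs: one motif-carrying clone
    large before expansion that shrinks by a known fold, matched with one
    non-carrier clone that grows by the same construction — so every
    non-designated clone keeps the same true frequency in both samples and
    the expansion truth list is exact by construction.
    """
    rng = np.random.default_rng(seed)
    n_back = config.til_clones
    df = _random_clones(rng, n_back, config.cdr3_len_range)

    # backbone carriers (unchanged between pre and rep)
    lo, hi = config.til_carrier_rank_range
    eligible = [r for r in range(lo - 1, min(hi, n_back))]
    rng.shuffle(eligible)
    pre_id, rep_id = f"{patient}_pre_rep_til", f"{patient}_rep_til"
    planted = planted or []
    usable = [pm for pm in planted if pm.kind in ("exclusive", "enriched")]
    for i in range(min(config.til_backbone_carriers, len(eligible))):
        if not usable:
            break
        pm = usable[i % len(usable)]
        aa = _plant(rng, df, eligible[i], pm.motif, pm.offset, config.cdr3_len_range)
        for sid in (pre_id, rep_id):
            pm.carriers.setdefault(sid, []).append(aa)

    # designated expansion pairs, appended after the backbone
    m = config.n_expanded_per_direction
    f = rng.uniform(*config.expanded_freq_range, size=m)
    fold = rng.uniform(*config.expansion_fold_range, size=m)
    extra = _random_clones(rng, 2 * m, config.cdr3_len_range)
    truths: list[TrueExpansion] = []
    pre_extra = np.empty(2 * m)
    rep_extra = np.empty(2 * m)
    for i in range(m):
        # pre-expanded clone: big in pre, shrinks in rep; carries a planted
        # motif when any are configured (large pre clones are tumor-reactive)
        if usable:
            pm = usable[i % len(usable)]
            aa = _plant(rng, extra, i, pm.motif, pm.offset, config.cdr3_len_range)
            for sid in (pre_id, rep_id):
                pm.carriers.setdefault(sid, []).append(aa)
        else:
            aa = extra.loc[i, "cdr3_aa"]
        pre_extra[i], rep_extra[i] = f[i], f[i] / fold[i]
        # matched rep-expanded non-carrier clone: mirrors the mass exactly
        j = m + i
        aa2 = extra.loc[j, "cdr3_aa"]
        pre_extra[j], rep_extra[j] = f[i] / fold[i], f[i]
        # truth = designated clones that meet the expansion definition by
        # construction (a real frequency change and the 0.1% floor)
        if fold[i] > 1 and f[i] >= 0.001:
            truths.append(TrueExpansion(patient, aa, float(f[i]),
                                        float(f[i] / fold[i]), "pre", float(fold[i])))
            truths.append(TrueExpansion(patient, aa2, float(f[i] / fold[i]),
                                        float(f[i]), "rep", float(fold[i])))

    back_pre = _zipf_weights(n_back, config.zipf_exponents["pre_rep_til"])
    back_rep = _zipf_weights(n_back, config.zipf_exponents["pre_rep_til"])
    rest = 1.0 - pre_extra.sum()  # identical for both samples by construction
    w_pre = np.concatenate([back_pre * rest, pre_extra])
    w_rep = np.concatenate([back_rep * rest, rep_extra])
    full = pd.concat([df, extra], ignore_index=True)
    reads = config.reads_per_sample
    pre = _finish_table(full, np.random.default_rng(rng.integers(2**31)).multinomial(reads, w_pre),
                        pre_id, "pre_rep_til", patient)
    rep = _finish_table(full, np.random.default_rng(rng.integers(2**31)).multinomial(reads, w_rep),
                        rep_id, "rep_til", patient)
    return pre, rep, truths


def _add_viral_spikes(table: ClonotypeTable, config: GeneratorConfig,
                      rng: np.random.Generator, manifest: CohortManifest) -> ClonotypeTable:
    ref = load_viral_reference()
    picks = ref.iloc[rng.choice(len(ref), size=config.n_viral_spikes, replace=False)]
    spike_count = max(1, round(config.viral_spike_freq * config.reads_per_sample))
    rows = []
    for r in picks.itertuples(index=False):
        rows.append({
            "cdr3_nt": _reverse_translate(r.cdr3), "cdr3_aa": r.cdr3,
            "v_gene": r[picks.columns.get_loc("v.segm")],
            "j_gene": "TRBJ2-1", "count": spike_count, "productive": True,
        })
        manifest.viral_spikes.append(ViralSpike(
            sample_id=table.sample_id, cdr3_aa=r.cdr3,
            v_gene=r[picks.columns.get_loc("v.segm")],
            epitope=r[picks.columns.get_loc("antigen.epitope")],
            count=spike_count))
    df = pd.concat([table.df, pd.DataFrame(rows)], ignore_index=True)
    return table.with_df(df)


def _draw_motifs(config: GeneratorConfig, rng: np.random.Generator) -> list[PlantedMotif]:
    kinds = (["exclusive"] * config.n_exclusive_motifs
             + ["enriched"] * config.n_enriched_motifs
             + ["contaminant"] * config.n_contaminant_motifs)
    motifs: list[PlantedMotif] = []
    seen: set[str] = set()
    for i, kind in enumerate(kinds):
        length = config.motif_lengths[i % len(config.motif_lengths)]
        while True:
            chars = list(rng.choice(CORE_ALPHABET, size=length))
            if length >= 5:  # wildcard variants get one internal '*'
                chars[int(rng.integers(1, length - 1))] = "*"
            s = "".join(chars)
            if s not in seen:
                seen.add(s)
                break
        lo, hi = config.motif_offset_range
        offset = int(rng.integers(lo, hi + 1))
        target = config.phenotypes[i % len(config.phenotypes)] if kind != "contaminant" else None
        motifs.append(PlantedMotif(motif=s, offset=offset, kind=kind,
                                   target_phenotype=target))
    return motifs


def generate_cohort(config: GeneratorConfig | None = None, seed: int = 0) -> Cohort:
    """Full synthetic cohort: discovery compartments, matched TIL pairs,
    viral spikes, control motif sets and the ground-truth manifest."""
    config = config or GeneratorConfig()
    root = np.random.default_rng(seed)
    manifest = CohortManifest(seeds=[seed], generator_params={
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
    })
    motifs = _draw_motifs(config, root)
    manifest.planted_motifs = motifs

    def child() -> int:
        return int(root.integers(2**31))

    tumor, healthy, pb = [], [], []
    for i in range(config.n_tumor):
        t = generate_repertoire(config, "tumor", f"pt{i:03d}", child(), planted=motifs)
        if "tumor" in config.spike_compartments:
            t = _add_viral_spikes(t, config, root, manifest)
        tumor.append(t)
    for i in range(config.n_healthy):
        healthy.append(generate_repertoire(
            config, "healthy_kidney", f"pt{i:03d}", child(), planted=motifs))
    for i in range(config.n_pb):
        pb.append(generate_repertoire(config, "pb", f"pt{i:03d}", child(), planted=motifs))

    til_pairs = []
    for i in range(config.n_til_pairs):
        pre, rep, truths = generate_paired_til(config, f"pt{i:03d}", child(), planted=motifs)
        if "pre_rep_til" in config.spike_compartments:
            pre = _add_viral_spikes(pre, config, root, manifest)
        if "rep_til" in config.spike_compartments:
            rep = _add_viral_spikes(rep, config, root, manifest)
        til_pairs.append((pre, rep))
        manifest.true_expansions.extend(truths)

    # control motif sets: the planted contaminants plus control-only noise
    noise = _draw_motifs(
        GeneratorConfig(n_exclusive_motifs=6, n_enriched_motifs=0, n_contaminant_motifs=0),
        root)
    manifest.control_sets = {
        "validation_cohort": sorted(
            [m.motif for m in motifs if m.kind == "contaminant"]
            + [m.motif for m in noise[:3]]),
        "viral_motifs": sorted(m.motif for m in noise[3:]),
    }
    return Cohort(tumor=tumor, healthy=healthy, pb=pb, til_pairs=til_pairs,
                  manifest=manifest)


def naive_reference(n_tcrs: int = 2000, seed: int = REFERENCE_SEED,
                    config: GeneratorConfig | None = None) -> ClonotypeTable:
    """Deterministic naive background repertoire for motif discovery.

    Generated once from a fixed seed (no planted motifs), standing in for a
    bundled naive reference; user-replaceable by passing any repertoire to
    the discovery step.
    """
    config = config or GeneratorConfig()
    return generate_repertoire(config, "other", "reference", seed,
                               planted=None, clones=n_tcrs, sample_id="naive_reference")


# ---------------------------------------------------------------------------
# single-cell table + expression matrix
# ---------------------------------------------------------------------------

_MODULE_TARGETS = {
    "CD4_cytotoxic": ("GZMB", "GZMA", "GZMH", "PRF1", "GNLY", "FGFBP2"),
    "CD8_Tex": ("PDCD1", "LAG3", "CTLA4", "TIGIT", "TOX", "HAVCR2"),
    "CD8_Trm": ("ITGA1", "ITGAE", "ZNF683", "CD69", "IFNG", "CCR5"),
}


def generate_cell_table(
    config: GeneratorConfig | None = None,
    seed: int = 0,
    motifs: list[PlantedMotif] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CohortManifest]:
    """Single-cell clonotype-phenotype table plus an expression matrix.

    Cells carry clonotypes drawn Zipf; clonotypes bearing a planted motif
    send their cells to the motif's target phenotype with probability
    ``phenotype_bias``.  The count matrix is negative-binomial background
    with signature genes elevated (log-normal effect) in the phenotypes
    that own them.  Returns (cells, expression, manifest).
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(seed)
    manifest = CohortManifest(seeds=[seed],
                              generator_params={"n_cells": config.n_cells})
    if motifs is None:
        motifs = [m for m in _draw_motifs(config, rng) if m.kind != "contaminant"]
    manifest.planted_motifs = motifs

    n_clones = 300
    df = _random_clones(rng, n_clones, config.cdr3_len_range)
    weights = _zipf_weights(n_clones, 1.0)
    # carrier clonotypes: a few distinct clones per motif, boosted so each
    # motif's expected carrier-cell share is cells_per_motif
    clone_motif: dict[int, PlantedMotif] = {}
    free = list(range(n_clones))
    rng.shuffle(free)
    ptr = 0
    for pm in motifs:
        rows = free[ptr: ptr + 4]
        ptr += 4
        for row in rows:
            aa = _plant(rng, df, row, pm.motif, pm.offset, config.cdr3_len_range)
            pm.carriers.setdefault("cells", []).append(aa)
            clone_motif[row] = pm
            weights[row] = config.cells_per_motif / 4
    weights = weights / weights.sum()

    clone_idx = rng.choice(n_clones, size=config.n_cells, p=weights)
    phenos = np.array(config.phenotypes)
    labels = []
    for ci in clone_idx:
        pm = clone_motif.get(int(ci))
        if pm is not None and rng.random() < config.phenotype_bias:
            labels.append(pm.target_phenotype)
        else:
            labels.append(phenos[rng.integers(len(phenos))])
    cells = pd.DataFrame({
        "cell_id": [f"cell{i:05d}" for i in range(config.n_cells)],
        "cdr3_aa": df["cdr3_aa"].to_numpy()[clone_idx],
        "cdr3_nt": df["cdr3_nt"].to_numpy()[clone_idx],
        "v_gene": df["v_gene"].to_numpy()[clone_idx],
        "phenotype": labels,
    })

    module_genes = sorted({g for gs in _MODULE_TARGETS.values() for g in gs})
    background = [f"G{i:04d}" for i in range(config.n_genes - len(module_genes))]
    genes = module_genes + background
    base_mean = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    mean = np.tile(base_mean, (config.n_cells, 1))
    if config.module_effect > 0:
        for pheno, gs in _MODULE_TARGETS.items():
            rows = np.flatnonzero(cells["phenotype"].to_numpy() == pheno)
            cols = [genes.index(g) for g in gs]
            effect = rng.lognormal(mean=config.module_effect, sigma=0.2, size=len(cols))
            mean[np.ix_(rows, cols)] *= effect
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mean))
    expr = pd.DataFrame(counts, index=cells["cell_id"], columns=genes)
    return cells, expr, manifest


# ---------------------------------------------------------------------------
# manifest-based scoring of downstream results
# ---------------------------------------------------------------------------

def score_discovery(manifest: CohortManifest, associations, tumor_idx) -> dict:
    """Score a discovery + classification run against the manifest.

    *Sensitivity*: fraction of planted tumor-associated motif strings
    recovered in the exclusive/enriched set.  *False-discovery proportion*:
    among associated motifs, those whose carrier support does NOT come from
    planted carriers.  A motif counts as plant-derived when more than half
    of its carrier TCRs are manifest-recorded planted-carrier sequences
    (discovery reports sub-patterns and boundary-shifted variants of a
    planted insert; their support is the planted signal, not noise).
    """
    from .association import associated_motifs as _assoc

    truth = {m.motif for m in manifest.associated_motifs()}
    carriers_all: set[str] = set()
    for pm in manifest.planted_motifs:
        for aas in pm.carriers.values():
            carriers_all.update(aas)
    got = _assoc(associations)
    recovered = truth & {a.motif for a in got}
    n_false = 0
    for a in got:
        rec = tumor_idx[a.motif]
        cluster_aa = [key.rsplit("|", 1)[0] for key in rec.cluster]
        if not cluster_aa:
            continue
        frac = sum(aa in carriers_all for aa in cluster_aa) / len(cluster_aa)
        if frac <= 0.5:
            n_false += 1
    n_assoc = len(got)
    pruned = sorted(a.motif for a in associations if a.status == "pruned")
    return {
        "n_planted": len(truth),
        "n_recovered": len(recovered),
        "sensitivity": len(recovered) / len(truth) if truth else float("nan"),
        "n_associated": n_assoc,
        "n_false": n_false,
        "fdp": n_false / n_assoc if n_assoc else 0.0,
        "pruned_matches_contaminants": pruned == manifest.contaminant_motifs()
        or set(manifest.contaminant_motifs()) <= set(pruned),
        "pruned": pruned,
    }


def score_expansion(manifest: CohortManifest, patient_id: str, result) -> dict:
    """Compare one pair's expansion calls with the manifest truth list.

    ``result`` is the test_expansion frame (aa keying).  Returns per-pair
    true/false positive and false negative clonotype counts.
    """
    truth = {
        e.cdr3_aa: e.expanded_in
        for e in manifest.true_expansions
        if e.patient_id == patient_id
    }
    called = result[result["expanded_in"] != "none"]
    called_keys = set(called["clonotype"])
    tp = len(called_keys & set(truth))
    return {
        "n_truth": len(truth),
        "n_called": len(called_keys),
        "tp": tp,
        "fp": len(called_keys) - tp,
        "fn": len(truth) - tp,
    }


def score_phenotypes(manifest: CohortManifest, calls) -> dict:
    """Fraction of well-supported motif phenotype calls matching the
    manifest target phenotype."""
    target = {m.motif: m.target_phenotype for m in manifest.planted_motifs
              if m.target_phenotype}
    scored = [c for c in calls if c.motif in target and c.n_supporting_cells >= 10]
    n_match = sum(c.dominant_phenotype == target[c.motif] for c in scored)
    return {
        "n_scored": len(scored),
        "n_match": n_match,
        "concordance": n_match / len(scored) if scored else float("nan"),
    }


# ---------------------------------------------------------------------------
# audits and serialization
# ---------------------------------------------------------------------------

def audit_cohort(cohort: Cohort) -> dict:
    """Self-consistency check: every manifest quantity is recoverable from
    the generated tables (motif carriers present at their offsets in tumor,
    viral spikes present with their exact counts)."""
    ok_motifs = True
    for pm in cohort.manifest.planted_motifs:
        found = 0
        for t in cohort.tumor:
            carriers = {
                aa for aa in t.df["cdr3_aa"]
                if pm.offset in find_motif_offsets(aa, pm.motif)
            }
            found = max(found, len(carriers))
        if found < 3:
            ok_motifs = False
            logger.warning("motif %s: max %d distinct tumor carriers (< 3)", pm.motif, found)
    by_sample = {t.sample_id: t for t in cohort.all_tables()}
    ok_spikes = True
    for sp in cohort.manifest.viral_spikes:
        t = by_sample[sp.sample_id]
        row = t.df[t.df["cdr3_aa"] == sp.cdr3_aa]
        if row.empty or int(row["count"].sum()) != sp.count:
            ok_spikes = False
    return {"planted_motifs_discoverable": ok_motifs, "viral_spikes_exact": ok_spikes}


def write_cohort(cohort: Cohort, out_dir: str | Path, dialect: str = "airr") -> None:
    """Write every sample as a TSV, a sample catalog, and the manifest JSON."""
    from .repertoire import write_clonotype_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalog = []
    for t in cohort.all_tables():
        fname = f"{t.sample_id}.tsv"
        write_clonotype_table(t, out_dir / fname, dialect=dialect)
        catalog.append({"sample_id": t.sample_id, "tissue": t.tissue,
                        "patient_id": t.patient_id, "file": fname, "dialect": dialect})
    pd.DataFrame(catalog).to_csv(out_dir / "samples.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(cohort.manifest.to_json())


def read_cohort(in_dir: str | Path) -> Cohort:
    """Reload a cohort written by :func:`write_cohort`."""
    from .repertoire import read_clonotype_table

    in_dir = Path(in_dir)
    catalog = pd.read_csv(in_dir / "samples.tsv", sep="\t", dtype=str)
    manifest_path = in_dir / "manifest.json"
    manifest = (CohortManifest.from_json(manifest_path.read_text())
                if manifest_path.exists() else CohortManifest())
    tables: dict[str, ClonotypeTable] = {}
    by_tissue: dict[str, list[ClonotypeTable]] = {}
    for row in catalog.itertuples(index=False):
        t, _ = read_clonotype_table(in_dir / row.file, dialect=row.dialect,
                                    sample_id=row.sample_id, tissue=row.tissue,
                                    patient_id=row.patient_id if isinstance(row.patient_id, str) else "")
        tables[row.sample_id] = t
        by_tissue.setdefault(row.tissue, []).append(t)
    pairs = []
    for pre in by_tissue.get("pre_rep_til", []):
        rep_id = pre.sample_id.replace("pre_rep_til", "rep_til")
        if rep_id in tables:
            pairs.append((pre, tables[rep_id]))
    return Cohort(tumor=by_tissue.get("tumor", []),
                  healthy=by_tissue.get("healthy_kidney", []),
                  pb=by_tissue.get("pb", []),
                  til_pairs=pairs, manifest=manifest)
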