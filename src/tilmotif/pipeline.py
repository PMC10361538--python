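"""End-to-end orchestration: filters -> diversity -> expansion ->
motif discovery -> tumor association -> burden -> phenotype.

Each stage writes its outputs as TSV/JSON under the configured output
directory and is individually skippable; a provenance record (parameters,
seeds, input digests) suffices to re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    associated_motifs,
    associations_to_frame,
    classify_motifs,
    prune_against_controls,
)
from .burden import burden_ratio, burdens_to_frame, motif_burden, prepare_for_burden
from .diversity import diversity_summary
from .dynamics import annotate_against_reference, test_expansion
from .motifs import MotifCounts, discover_cohort_motifs
from .phenotype import assign_motif_phenotypes, calls_to_frame
from .repertoire import ClonotypeTable, downsample, exclude_small_samples, filter_productive
from .synthetic import (
    Cohort,
    GeneratorConfig,
    generate_cell_table,
    generate_cohort,
    load_viral_reference,
    naive_reference,
    read_cohort,
)

logger = logging.getLogger("tilmotif")

ALL_STAGES = ("filter", "diversity", "expansion", "discovery", "association",
              "burden", "phenotype")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage, self.cause = stage, cause


@dataclass
class PipelineConfig:
    """Thresholds default to the analysis conventions used throughout the
    package: 10,000-read sample floor, 40,000-read burden downsampling,
    0.1% expansion frequency floor, alpha 0.05, log2fc 1.0, cluster >= 3,
    motif length >= 3, >= 5 supporting cells."""

    out_dir: str = "tilmotif_out"
    input_dir: str | None = None  # cohort directory; None -> simulate
    seed: int = 0
    key_mode: str = "aa"
    min_reads: int = 10_000
    burden_downsample: int | None = 40_000
    burden_min_reads: int | None = 100
    min_freq: float = 0.001
    alpha: float = 0.05
    min_log2fc: float = 1.0
    min_cluster: int = 3
    min_motif_len: int = 3
    min_fold: float = 10.0
    min_cells: int = 5
    reference_size: int = 2000
    stages: tuple = ALL_STAGES
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen:
            cfg.generator = GeneratorConfig(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in gen.items()
            })
        return cfg

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages on a loaded or simulated cohort.

    Returns a run report: per-stage status and output paths.  A failing
    stage aborts with :class:`PipelineError` naming the stage; outputs of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "outputs": []}
    rng = np.random.default_rng(config.seed)

    def done(stage: str, outputs: list[Path], **extra) -> None:
        # file names only: keeps the report identical across output locations
        report["stages"][stage] = {"status": "completed",
                                   "outputs": [p.name for p in outputs], **extra}
        report["outputs"].extend(p.name for p in outputs)

    # --- input ----------------------------------------------------------
    input_digests = {}
    if config.input_dir:
        cohort = read_cohort(config.input_dir)
        for p in sorted(Path(config.input_dir).glob("*")):
            if p.is_file():
                input_digests[p.name] = _digest(p)
    else:
        cohort = generate_cohort(config.generator, seed=int(rng.integers(2**31)))
    done("input", [], n_samples=len(cohort.all_tables()))

    # --- filter ---------------------------------------------------------
    if "filter" in config.stages:
        try:
            groups: dict[str, list[ClonotypeTable]] = {}
            for t in cohort.all_tables():
                groups.setdefault(t.tissue, []).append(filter_productive(t))
            groups = {k: exclude_small_samples(v, config.min_reads) for k, v in groups.items()}
            cohort = Cohort(
                tumor=groups.get("tumor", []),
                healthy=groups.get("healthy_kidney", []),
                pb=groups.get("pb", []),
                til_pairs=_repair(groups),
                manifest=cohort.manifest,
            )
            done("filter", [], n_retained=len(cohort.all_tables()))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("filter", str(e)) from e

    # --- diversity ------------------------------------------------------
    if "diversity" in config.stages:
        try:
            rows = []
            for tissue, tables in _by_tissue(cohort).items():
                if not tables:
                    continue
                floor = min(t.total_reads for t in tables)
                for t in tables:
                    rows.append({"variant": "total", **diversity_summary(t).as_dict()})
                    ds = downsample(t, floor, seed=int(rng.integers(2**31)))
                    rows.append({"variant": "downsampled", **diversity_summary(ds).as_dict()})
            p = _write(pd.DataFrame(rows), out / "diversity.tsv")
            done("diversity", [p])
        except Exception as e:  # noqa: BLE001
            raise PipelineError("diversity", str(e)) from e

    # --- expansion ------------------------------------------------------
    if "expansion" in config.stages:
        try:
            paths, n_exp = [], 0
            for pre, rep in cohort.til_pairs:
                res = test_expansion(pre, rep, alpha=config.alpha,
                                     min_freq=config.min_freq, mode=config.key_mode)
                n_exp += int((res["expanded_in"] != "none").sum())
                paths.append(_write(res, out / f"expansion_{pre.patient_id or pre.sample_id}.tsv"))
            done("expansion", paths, n_expanded=n_exp)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("expansion", str(e)) from e

    # --- discovery ------------------------------------------------------
    indexes = {}
    if "discovery" in config.stages or "association" in config.stages:
        try:
            if not cohort.tumor:
                raise PipelineError("discovery", "no tumor cohort in input")
            ref = MotifCounts(naive_reference(config.reference_size))
            paths = []
            for tissue, tables in (("tumor", cohort.tumor),
                                   ("healthy_kidney", cohort.healthy),
                                   ("pb", cohort.pb)):
                if not tables:
                    continue
                idx = discover_cohort_motifs(
                    tables, ref, min_cluster=config.min_cluster,
                    min_fold=config.min_fold, alpha=config.alpha,
                    min_motif_len=config.min_motif_len, tissue=tissue)
                indexes[tissue] = idx
                path = out / f"motifs_{tissue}.tsv"
                idx.write(path)
                paths.append(path)
            done("discovery", paths,
                 n_motifs={k: len(v) for k, v in sorted(indexes.items())})
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("discovery", str(e)) from e

    # --- association ----------------------------------------------------
    assoc_records = []
    if "association" in config.stages:
        try:
            comp_idx = {k: v for k, v in indexes.items() if k != "tumor"}
            comp_samples = {}
            if cohort.healthy:
                comp_samples["healthy_kidney"] = cohort.healthy
            if cohort.pb:
                comp_samples["pb"] = cohort.pb
            if not comp_samples:
                raise PipelineError("association", "no comparator cohorts in input")
            assoc = classify_motifs(
                indexes["tumor"], comp_idx, cohort.tumor, comp_samples,
                alpha=config.alpha, min_log2fc=config.min_log2fc)
            controls = sorted(
                (name, set(motifs))
                for name, motifs in cohort.manifest.control_sets.items())
            assoc = prune_against_controls(assoc, controls)
            frame = associations_to_frame(assoc, indexes["tumor"])
            p = _write(frame, out / "tumor_associated_motifs.tsv")
            assoc_records = [indexes["tumor"][a.motif] for a in associated_motifs(assoc)]
            counts = (frame["status"].value_counts().sort_index() if len(frame)
                      else pd.Series(dtype=int))
            done("association", [p],
                 n_by_status={k: int(v) for k, v in counts.items()})
        except PipelineError:
            raise
        except Exception as e:  # noqa: BLE001
            raise PipelineError("association", str(e)) from e

    # --- burden ---------------------------------------------------------
    if "burden" in config.stages:
        try:
            viral_ref = load_viral_reference()
            rows = []
            burdens = []
            for t in cohort.all_tables():
                prepared = prepare_for_burden(
                    t,
                    drop_singletons=(t.tissue == "pb"),
                    min_reads=config.burden_min_reads,
                    downsample_to=config.burden_downsample,
                    seed=int(rng.integers(2**31)),
                )
                if prepared is None or not assoc_records:
                    continue
                b = motif_burden(prepared, assoc_records)
                _, viral = annotate_against_reference(prepared, viral_ref)
                burdens.append(b)
                rows.append({
                    **burdens_to_frame([b]).iloc[0].to_dict(),
                    "viral_fraction": viral["annotated_read_fraction"],
                    "burden_viral_ratio": burden_ratio(b, viral["annotated_read_fraction"]),
                })
            p = _write(pd.DataFrame(rows), out / "burden.tsv")
            done("burden", [p], n_samples=len(rows))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("burden", str(e)) from e

    # --- phenotype ------------------------------------------------------
    if "phenotype" in config.stages:
        try:
            cells, _, _ = generate_cell_table(
                config.generator, seed=int(rng.integers(2**31)),
                motifs=[m for m in cohort.manifest.planted_motifs
                        if m.kind != "contaminant"] or None)
            calls = assign_motif_phenotypes(cells, assoc_records,
                                            min_cells=config.min_cells)
            p = _write(calls_to_frame(calls), out / "phenotype_calls.tsv")
            done("phenotype", [p], n_calls=len(calls))
        except Exception as e:  # noqa: BLE001
            raise PipelineError("phenotype", str(e)) from e

    # --- provenance -----------------------------------------------------
    prov = {
        "package_version": __version__,
        "config": config.as_dict(),
        "input_digests": input_digests,
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    (out / "run_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _by_tissue(cohort: Cohort) -> dict[str, list[ClonotypeTable]]:
    groups: dict[str, list[ClonotypeTable]] = {}
    for t in cohort.all_tables():
        groups.setdefault(t.tissue, []).append(t)
    return groups


def _repair(groups: dict[str, list[ClonotypeTable]]) -> list[tuple]:
    by_id = {t.sample_id: t for ts in groups.values() for t in ts}
    pairs = []
    for pre in groups.get("pre_rep_til", []):
        rep = by_id.get(pre.sample_id.replace("pre_rep_til", "rep_til"))
        if rep is not None:
            pairs.append((pre, rep))
    return pairs
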