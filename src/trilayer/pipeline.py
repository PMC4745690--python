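"""End-to-end orchestration: filters, discovery, selection, systems, SPI.

A run executes, for each requested feature level: quality filtering →
replicate-intersection discovery at each Bonferroni cutoff → single-feature
accuracy ranking → the nine (cutoff x top-fraction) feature sets → one
voting classification system per non-empty feature set → SPI.  Every
artifact lands in one run directory as TSV/YAML, and a manifest records the
configuration and all derived seeds so a rerun reproduces the outputs
byte for byte.

For synthetic runs the SPI of each system is measured on a freshly drawn
held-out batch from the same synthetic population; for file-based runs it
is measured on the full input sample set.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import AnnotationModel, flatten_exonic_regions, read_annotation
from .classify import build_system, compute_spi, save_system
from .diffexpr import hypergeometric_overlap, map_to_genes
from .io import (
    CountMatrix,
    ExpressionMatrix,
    SampleMetadata,
    read_counts,
    read_expression,
    read_metadata,
    read_totals,
)
from .quantify import (
    apply_quality_filters,
    compute_naive_fpkm,
    default_min_nonzero_patients,
    exonic_region_expression,
    filter_short_regions,
    gene_expression_from_transcripts,
    pseudo_counts_from_fpkm,
)
from .selection import (
    RF_N_ESTIMATORS,
    derive_seeds,
    discover_all_cutoffs,
    rank_single_feature_accuracy,
    select_feature_set,
)
from .simulate import CohortSpec, PlantedEvent, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run (YAML-serializable)."""

    levels: tuple[str, ...] = ("gene", "transcript", "exonic_region")
    p_cutoffs: tuple[float, ...] = (0.05, 0.01, 0.001)
    top_fractions: tuple[float, ...] = (0.10, 0.05, 0.01)
    n_discovery_replicates: int = 5
    n_system_models: int = 100
    seed: int = 0
    stratify: bool = False
    deg_input: str = "counts"            # counts | fpkm
    rf_n_estimators: int = RF_N_ESTIMATORS
    min_short_region_bp: int = 100
    min_nonzero_patients: int | None = None  # None: ceil(n/2 + 0.5)
    build_systems: bool = True
    save_models: bool = False
    # data source: either a synthetic spec ...
    synthetic: dict | None = None
    # ... or input file paths
    annotation_path: str | None = None
    counts_paths: dict[str, str] = field(default_factory=dict)   # level -> TSV
    fpkm_transcript_path: str | None = None
    metadata_path: str | None = None
    totals_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_discovery_replicates < 2:
            raise ValueError("n_discovery_replicates must be >= 2")
        if self.deg_input not in ("counts", "fpkm"):
            raise ValueError("deg_input must be 'counts' or 'fpkm'")
        unknown = set(self.levels) - {"gene", "transcript", "exonic_region"}
        if unknown:
            raise ValueError(f"unknown levels: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("levels", "p_cutoffs", "top_fractions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("levels", "p_cutoffs", "top_fractions"):
            d[key] = list(d[key])
        return d


def _spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    events = [PlantedEvent(**e) for e in d.pop("planted_events", [])]
    return CohortSpec(planted_events=events, **d)


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        spec = _spec_from_dict(config.synthetic)
        cohort = generate_cohort(spec)
        return cohort.annotation, cohort.counts, cohort.tx_fpkm, cohort.metadata, cohort.totals, cohort
    if config.annotation_path is None or config.metadata_path is None:
        raise ValueError("file-based runs need annotation_path and metadata_path")
    annot = flatten_exonic_regions(read_annotation(config.annotation_path))
    counts = {
        level: read_counts(path, level) for level, path in config.counts_paths.items()
    }
    tx_fpkm = (
        read_expression(config.fpkm_transcript_path, "transcript")
        if config.fpkm_transcript_path
        else None
    )
    metadata = read_metadata(config.metadata_path)
    totals = read_totals(config.totals_path) if config.totals_path else None
    return annot, counts, tx_fpkm, metadata, totals, None


def _file_sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full workflow; returns the run directory."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        annot, counts, tx_fpkm, metadata, totals, cohort = _load_inputs(config)
        if cohort is not None:
            write_cohort(cohort, run_dir / "inputs")

        # ---- expression matrices per level (classifier inputs) ----------
        stage = "quantify"
        expr: dict[str, ExpressionMatrix] = {}
        if tx_fpkm is not None:
            expr["transcript"] = tx_fpkm
            expr["gene"] = gene_expression_from_transcripts(tx_fpkm, annot)
            expr["exonic_region"] = exonic_region_expression(tx_fpkm, annot)

        # ---- filters ----------------------------------------------------
        stage = "filters"
        (run_dir / "filters").mkdir(exist_ok=True)
        short_report = filter_short_regions(annot, config.min_short_region_bp)
        short_report.write_tsv(run_dir / "filters" / "short_regions.tsv")
        kept_regions = set(short_report.kept["exonic_region"])

        min_nz = config.min_nonzero_patients
        if min_nz is None:
            min_nz = default_min_nonzero_patients(len(metadata.paired_patients()))
        if tx_fpkm is not None:
            quality = apply_quality_filters(
                expr["gene"], tx_fpkm, annot, metadata, min_nonzero_patients=min_nz
            )
            quality.write_tsv(run_dir / "filters" / "quality.tsv")
            kept = {lvl: set(ids) for lvl, ids in quality.kept.items()}
        else:
            kept = {}

        # ---- per-level analysis -----------------------------------------
        summary_rows = []
        for level in config.levels:
            stage = f"{level}:counts"
            if level in counts and not (level == "gene" and config.deg_input == "fpkm"):
                cm = counts[level]
            elif expr.get(level) is not None and totals is not None:
                cm = pseudo_counts_from_fpkm(expr[level], annot, totals)
            else:
                raise ValueError(f"no count or FPKM input available at level {level}")

            keep_ids = [f for f in cm.feature_ids if f in kept.get(level, set(cm.feature_ids))]
            if level == "exonic_region":
                keep_ids = [f for f in keep_ids if f in kept_regions]
            cm = cm.subset_features(keep_ids)

            stage = f"{level}:discovery"
            disc_seeds = derive_seeds(config.seed, config.n_discovery_replicates, f"discovery-{level}")
            discoveries = discover_all_cutoffs(
                cm, metadata, disc_seeds, level,
                p_cutoffs=config.p_cutoffs, stratify=config.stratify,
            )
            (run_dir / "discovery").mkdir(exist_ok=True)
            for cutoff, disc in discoveries.items():
                pd.DataFrame(
                    {"feature_id": sorted(disc.features),
                     "mean_p": [disc.mean_p[f] for f in sorted(disc.features)]}
                ).to_csv(run_dir / "discovery" / f"{level}_p{cutoff}.tsv", sep="\t", index=False)

            class_data = expr.get(level)
            if class_data is None:
                class_data = cm  # classify on counts when no FPKM route exists

            stage = f"{level}:ranking"
            (run_dir / "ranking").mkdir(exist_ok=True)
            (run_dir / "feature_sets").mkdir(exist_ok=True)
            feature_sets = []
            for cutoff, disc in discoveries.items():
                if not disc.features:
                    ranked = []
                else:
                    ranked = rank_single_feature_accuracy(
                        sorted(disc.features), class_data, metadata, disc.splits,
                        mean_p=disc.mean_p, n_estimators=config.rf_n_estimators,
                        seed=derive_seeds(config.seed, 1, f"rank-{level}-{cutoff}")[0],
                    )
                pd.DataFrame(ranked, columns=["feature_id", "mean_accuracy"]).to_csv(
                    run_dir / "ranking" / f"{level}_p{cutoff}.tsv", sep="\t", index=False
                )
                for frac in config.top_fractions:
                    fs = select_feature_set(ranked, level, cutoff, frac)
                    feature_sets.append(fs)
                    pd.DataFrame({"feature_id": list(fs.feature_ids)}).to_csv(
                        run_dir / "feature_sets" / f"{level}_p{cutoff}_top{frac}.tsv",
                        sep="\t", index=False,
                    )

            # ---- systems + SPI ------------------------------------------
            if config.build_systems:
                stage = f"{level}:systems"
                (run_dir / "systems").mkdir(exist_ok=True)
                (run_dir / "spi").mkdir(exist_ok=True)
                if cohort is not None:
                    stage = f"{level}:heldout"
                    heldout_seed = derive_seeds(config.seed, 1, "heldout")[0]
                    heldout = generate_cohort(cohort.spec, samples_seed=heldout_seed)
                    spi_data_all = {
                        "transcript": heldout.tx_fpkm,
                        "gene": gene_expression_from_transcripts(heldout.tx_fpkm, annot),
                        "exonic_region": exonic_region_expression(heldout.tx_fpkm, annot),
                    }
                    spi_data, spi_meta = spi_data_all[level], heldout.metadata
                else:
                    spi_data, spi_meta = class_data, metadata
                for fs in feature_sets:
                    tag = f"{level}_p{fs.p_cutoff}_top{fs.top_fraction}"
                    if not fs.feature_ids:
                        summary_rows.append(
                            {"level": level, "p_cutoff": fs.p_cutoff,
                             "top_fraction": fs.top_fraction, "n_features": 0,
                             "system_built": False, "median_accuracy": np.nan, "spi": np.nan}
                        )
                        continue
                    system = build_system(
                        fs, class_data, metadata,
                        n_models=config.n_system_models,
                        seed=derive_seeds(config.seed, 1, f"system-{tag}")[0],
                        stratify=config.stratify,
                        n_estimators=config.rf_n_estimators,
                    )
                    if config.save_models:
                        save_system(system, run_dir / "systems" / tag)
                    pd.DataFrame(
                        {"replicate_id": range(system.n),
                         "validation_accuracy": system.validation_accuracies}
                    ).to_csv(run_dir / "systems" / f"{tag}_accuracy.tsv", sep="\t", index=False)
                    report = compute_spi(system, spi_data, spi_meta)
                    report.write_tsv(run_dir / "spi" / f"{tag}.tsv")
                    summary_rows.append(
                        {"level": level, "p_cutoff": fs.p_cutoff,
                         "top_fraction": fs.top_fraction, "n_features": len(fs),
                         "system_built": True,
                         "median_accuracy": float(np.median(system.validation_accuracies)),
                         "spi": report.spi}
                    )
            else:
                for fs in feature_sets:
                    summary_rows.append(
                        {"level": level, "p_cutoff": fs.p_cutoff,
                         "top_fraction": fs.top_fraction, "n_features": len(fs),
                         "system_built": False, "median_accuracy": np.nan, "spi": np.nan}
                    )

        stage = "report"
        pd.DataFrame(summary_rows).to_csv(run_dir / "summary.tsv", sep="\t", index=False)
        manifest = {
            "trilayer_version": __version__,
            "config": config.to_dict(),
            "discovery_seeds": {
                level: derive_seeds(config.seed, config.n_discovery_replicates, f"discovery-{level}")
                for level in config.levels
            },
            "files": {
                str(p.relative_to(run_dir)): _file_sha256(p)
                for p in sorted(run_dir.rglob("*.tsv"))
            },
        }
        with open(run_dir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        return run_dir
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {e}") from e


def compare_levels(run_dir: str | Path, p_cutoff: float = 0.05) -> pd.DataFrame:
    """Map DETs/DEEs to genes and test their overlap with the DEGs.

    Uses the discovery intersections of a completed run.  The universe is
    the union of genes covered by the run's tested features, read from the
    synthetic inputs' annotation; the hypergeometric p is the upper tail of
    the observed overlap.
    """
    run_dir = Path(run_dir)
    disc_dir = run_dir / "discovery"
    gene_file = disc_dir / f"gene_p{p_cutoff}.tsv"
    if not gene_file.exists():
        raise ValueError(f"gene-level discovery missing from {run_dir}")
    annot = flatten_exonic_regions(read_annotation(run_dir / "inputs" / "annotation.gtf"))
    universe = set(annot.genes)
    degs = set(pd.read_csv(gene_file, sep="\t")["feature_id"].astype(str))

    rows = []
    for level in ("transcript", "exonic_region"):
        f = disc_dir / f"{level}_p{p_cutoff}.tsv"
        if not f.exists():
            continue
        feats = set(pd.read_csv(f, sep="\t")["feature_id"].astype(str))
        mapped = map_to_genes(feats, level, annot)
        overlap = hypergeometric_overlap(degs, mapped, universe)
        rows.append({"level": level, "n_features": len(feats), "n_mapped_genes": len(mapped),
                     "n_degs": len(degs), **overlap.to_row()})
    if not rows:
        raise ValueError("no transcript- or exon-level discovery results to compare")
    df = pd.DataFrame(rows)
    df.to_csv(run_dir / f"level_overlap_p{p_cutoff}.tsv", sep="\t", index=False)
    return df
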