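"""Naive FPKM, cross-level expression aggregation, and quality filters.

Naive FPKM of a feature i is ``n_i / (n_T * l_i)`` with n_i the reads mapped
to the feature, n_T the sample's total mapped reads in millions and l_i the
feature length in kilobases.  It deliberately omits any effective-length
correction, which makes it exactly invertible back to integer counts.

Gene expression is the sum of the gene's transcript FPKM values, and the
expression of an exonic region is the sum of the FPKM values of the
transcripts that contain the region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotationModel
from .io import CountMatrix, ExpressionMatrix, SampleMetadata

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Which features the quality filters removed, and why.

    The removal reasons partition the removed features within each level:
    a feature appears under at most one reason, and ``kept[level]`` plus the
    removed ids of that level reconstitute the input feature list.
    """

    removed_multi_fpkm: set[str] = field(default_factory=set)        # gene ids
    removed_absent_transcript: set[str] = field(default_factory=set)  # gene ids
    removed_low_prevalence: set[str] = field(default_factory=set)     # gene or transcript ids
    removed_short_regions: set[str] = field(default_factory=set)      # region ids
    kept: dict[str, list[str]] = field(default_factory=dict)          # level -> feature ids

    def write_tsv(self, path: str | Path) -> None:
        rows = []
        for gid in sorted(self.removed_multi_fpkm):
            rows.append((gid, "gene", "multiple_fpkm"))
        for gid in sorted(self.removed_absent_transcript):
            rows.append((gid, "gene", "absent_transcript"))
        for fid in sorted(self.removed_low_prevalence):
            rows.append((fid, "", "low_prevalence"))
        for rid in sorted(self.removed_short_regions):
            rows.append((rid, "exonic_region", "short_region"))
        pd.DataFrame(rows, columns=["feature_id", "level", "reason"]).to_csv(
            path, sep="\t", index=False
        )


def _feature_lengths(annot: AnnotationModel, feature_ids, level: str) -> pd.Series:
    if level == "exonic_region":
        missing = [f for f in feature_ids if f not in annot.exonic_regions]
        if missing:
            raise ValueError(f"features absent from annotation exonic regions: {missing[:5]}")
        return pd.Series({f: annot.exonic_regions[f].length for f in feature_ids}, dtype=float)
    if level == "transcript":
        missing = [f for f in feature_ids if f not in annot.transcripts]
        if missing:
            raise ValueError(f"features absent from annotation transcripts: {missing[:5]}")
        return pd.Series({f: annot.transcripts[f].length for f in feature_ids}, dtype=float)
    if level == "gene":
        # union of exon intervals = sum of the gene's disjoint exonic regions
        if not annot.exonic_regions:
            raise ValueError("gene lengths need a flattened annotation")
        lengths: dict[str, int] = {}
        for region in annot.exonic_regions.values():
            lengths[region.gene_id] = lengths.get(region.gene_id, 0) + region.length
        missing = [f for f in feature_ids if f not in lengths]
        if missing:
            raise ValueError(f"genes without exonic regions in the annotation: {missing[:5]}")
        return pd.Series({f: lengths[f] for f in feature_ids}, dtype=float)
    raise ValueError(f"no length defined for level {level!r}")


def _totals_series(totals: Mapping[str, float] | pd.Series, sample_ids) -> pd.Series:
    t = pd.Series(dict(totals)) if not isinstance(totals, pd.Series) else totals
    missing = [s for s in sample_ids if s not in t.index]
    if missing:
        raise ValueError(f"total mapped reads missing for samples: {missing[:5]}")
    t = t.loc[list(sample_ids)].astype(float)
    if (t <= 0).any():
        raise ValueError("total mapped reads must be positive for every sample")
    return t


def compute_naive_fpkm(
    counts: CountMatrix,
    annot: AnnotationModel,
    total_mapped_reads: Mapping[str, float] | pd.Series,
) -> ExpressionMatrix:
    """Naive FPKM per feature and sample: count / (reads_in_millions * length_in_kb)."""
    lengths = _feature_lengths(annot, counts.feature_ids, counts.level)
    totals = _totals_series(total_mapped_reads, counts.sample_ids)
    denom = np.outer(lengths.to_numpy() / 1e3, totals.to_numpy() / 1e6)
    vals = counts.data.to_numpy(dtype=float) / denom
    return ExpressionMatrix(
        counts.level, pd.DataFrame(vals, index=counts.data.index, columns=counts.data.columns)
    )


def pseudo_counts_from_fpkm(
    fpkm: ExpressionMatrix,
    annot: AnnotationModel,
    total_mapped_reads: Mapping[str, float] | pd.Series,
) -> CountMatrix:
    """Invert the naive FPKM formula: count = round(FPKM * length_kb * reads_millions).

    Exact for counts produced by :func:`compute_naive_fpkm`; used to feed the
    count-based NB test when only FPKM matrices are available.  Missing
    (absent) values are not allowed here: filter them out first.
    """
    if fpkm.data.isna().any().any():
        raise ValueError("FPKM matrix contains absent (NA) values; apply quality filters first")
    lengths = _feature_lengths(annot, fpkm.feature_ids, fpkm.level)
    totals = _totals_series(total_mapped_reads, fpkm.sample_ids)
    scale = np.outer(lengths.to_numpy() / 1e3, totals.to_numpy() / 1e6)
    vals = np.rint(fpkm.data.to_numpy(dtype=float) * scale).astype(np.int64)
    return CountMatrix(
        fpkm.level, pd.DataFrame(vals, index=fpkm.data.index, columns=fpkm.data.columns)
    )


def gene_expression_from_transcripts(
    tx_fpkm: ExpressionMatrix, annot: AnnotationModel
) -> ExpressionMatrix:
    """Gene FPKM = sum of the gene's transcript FPKM values, per sample."""
    if tx_fpkm.level != "transcript":
        raise ValueError(f"expected a transcript-level matrix, got {tx_fpkm.level}")
    missing = [t for t in tx_fpkm.feature_ids if t not in annot.transcripts]
    if missing:
        raise ValueError(f"transcripts without a gene in the annotation: {missing[:5]}")
    gene_of = pd.Series({t: annot.transcripts[t].gene_id for t in tx_fpkm.feature_ids})
    summed = tx_fpkm.data.groupby(gene_of).sum(min_count=1)
    return ExpressionMatrix("gene", summed)


def exonic_region_expression(
    tx_fpkm: ExpressionMatrix, annot: AnnotationModel
) -> ExpressionMatrix:
    """Exonic-region FPKM = sum of FPKM of the transcripts containing the region."""
    if tx_fpkm.level != "transcript":
        raise ValueError(f"expected a transcript-level matrix, got {tx_fpkm.level}")
    if not annot.exonic_regions:
        raise ValueError("annotation has no exonic regions; flatten it first")
    rows = {}
    for rid, region in annot.exonic_regions.items():
        members = [t for t in region.member_transcript_ids if t in tx_fpkm.data.index]
        if not members:
            logger.warning("exonic region %s has no member transcript in the matrix; value 0", rid)
            rows[rid] = pd.Series(0.0, index=tx_fpkm.data.columns)
        else:
            rows[rid] = tx_fpkm.data.loc[members].sum(axis=0, min_count=1)
    out = pd.DataFrame(rows).T
    out = out.loc[sorted(out.index)]
    return ExpressionMatrix("exonic_region", out)


def default_min_nonzero_patients(n_patients: int) -> int:
    """Just over half the paired patients: ceil(n/2 + 0.5); 39 for a 77-patient cohort."""
    return math.ceil(n_patients / 2 + 0.5)


def apply_quality_filters(
    gene_fpkm: ExpressionMatrix,
    tx_fpkm: ExpressionMatrix,
    annot: AnnotationModel,
    metadata: SampleMetadata,
    min_nonzero_patients: int | None = None,
) -> FilterReport:
    """Apply the cohort-level quality filters and report the kept/removed features.

    Three successive filters:

    1. genes appearing more than once in the gene matrix (conflicting
       expression records from upstream quantification) are removed;
    2. genes for which any transcript value is *absent* (NA, as opposed to
       an observed zero) in any sample are removed with all their
       transcripts;
    3. when ``min_nonzero_patients`` is given (the five-replicate discovery
       mode), genes and transcripts must have non-zero FPKM in both the
       tumor and the normal sample of at least that many paired patients.
    """
    paired = metadata.paired_patients()
    if min_nonzero_patients is not None and min_nonzero_patients > len(paired):
        raise ValueError(
            f"min_nonzero_patients={min_nonzero_patients} exceeds the "
            f"{len(paired)} paired patients"
        )

    report = FilterReport()
    gene_ids = list(gene_fpkm.data.index)

    dup = gene_fpkm.data.index[gene_fpkm.data.index.duplicated(keep=False)]
    report.removed_multi_fpkm = set(dup)

    tx_gene = pd.Series({t: annot.transcripts[t].gene_id for t in tx_fpkm.feature_ids})
    absent_tx = tx_fpkm.data.isna().any(axis=1)
    absent_genes = set(tx_gene[absent_tx.to_numpy()]) - report.removed_multi_fpkm
    report.removed_absent_transcript = absent_genes

    removed_genes = report.removed_multi_fpkm | report.removed_absent_transcript
    kept_genes = [g for g in dict.fromkeys(gene_ids) if g not in removed_genes]
    kept_tx = [t for t in tx_fpkm.feature_ids if tx_gene[t] not in removed_genes]

    if min_nonzero_patients is not None:
        tumor_s, normal_s = [], []
        for pat in paired:
            samples = metadata.samples_of_patients([pat])
            tissues = metadata.tissue_of(samples)
            tumor_s.append(samples[list(tissues).index("tumor")])
            normal_s.append(samples[list(tissues).index("normal")])

        def low_prevalence(df: pd.DataFrame, feats: list[str]) -> set[str]:
            sub = df.loc[feats]
            both = (sub[tumor_s].to_numpy() > 0) & (sub[normal_s].to_numpy() > 0)
            n_ok = both.sum(axis=1)
            return set(np.asarray(feats)[n_ok < min_nonzero_patients])

        lp = low_prevalence(gene_fpkm.data[~gene_fpkm.data.index.duplicated()], kept_genes)
        lp |= low_prevalence(tx_fpkm.data, kept_tx)
        report.removed_low_prevalence = lp
        kept_genes = [g for g in kept_genes if g not in lp]
        kept_tx = [t for t in kept_tx if t not in lp]

    report.kept = {"gene": kept_genes, "transcript": kept_tx}
    return report


def filter_short_regions(annot: AnnotationModel, min_length_bp: int = 100) -> FilterReport:
    """Discard exonic regions shorter than ``min_length_bp`` (length < threshold).

    Lengths are closed-interval: end - start + 1, so a region spanning
    exactly ``min_length_bp`` bases is kept.
    """
    if not annot.exonic_regions:
        raise ValueError("annotation has no exonic regions; flatten it first")
    report = FilterReport()
    kept = []
    for rid, region in annot.exonic_regions.items():
        if region.length < min_length_bp:
            report.removed_short_regions.add(rid)
        else:
            kept.append(rid)
    report.kept = {"exonic_region": sorted(kept)}
    return report
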