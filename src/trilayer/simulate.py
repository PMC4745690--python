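"""Synthetic paired tumor/normal RNA-seq cohorts with known planted truth.

The generator emulates the structure of a paired-design cohort study: every
patient contributes one tumor and one normal transcriptome; genes carry
multiple transcript isoforms built from a shared exon pool, so flattening
yields both shared and transcript-private exonic regions; and three classes
of dysregulation can be planted:

``gene_de``
    every transcript of the gene changes by the same fold in tumor;
``transcript_switch``
    two isoforms of one gene move in opposite directions with the gene
    total exactly conserved in expectation (one transcript up by the fold,
    a sibling down by its reciprocal, baselines chosen to balance);
``exon_de``
    the transcripts containing one target exonic region change, leaving
    the gene's other isoforms untouched.

Expected transcript expression is ``baseline x patient_effect x
tissue_effect``; counts are negative-binomial around the expectation scaled
by a log-normal library size.  Exonic-region counts are derived from the
member transcripts' counts (scaled by the length fraction each region
occupies in its transcript), so region-level naive FPKM equals the sum of
member-transcript FPKM in expectation.  Transcript FPKM follows the naive
formula, making count/FPKM round trips exact.

Two seeds control the generator: ``CohortSpec.seed`` fixes the cohort
*structure* (annotation, baselines, planted-event placement), while the
optional ``samples_seed`` of :func:`generate_cohort` draws the patients
themselves.  Regenerating with a new ``samples_seed`` therefore yields a
fresh batch of patients from the identical population — a held-out
validation batch with the same planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationModel, ExonicRegion, Gene, Transcript, flatten_exonic_regions, write_annotation
from .io import CountMatrix, ExpressionMatrix, SampleMetadata, write_counts, write_expression, write_metadata, write_totals

EventKind = Literal["gene_de", "transcript_switch", "exon_de"]


@dataclass(frozen=True)
class PlantedEvent:
    kind: EventKind
    fold_change: float
    gene_id: str | None = None  # auto-assigned when None

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.kind not in ("gene_de", "transcript_switch", "exon_de"):
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe the scale routinely exercised in tests: 40 paired
    patients and 500 multi-isoform genes, moderate biological
    overdispersion (alpha = 0.2), log-normal library sizes (sd 0.3 around
    20 million mapped reads) and a per-patient log-scale random effect
    (sd 0.3) shared between a patient's two tissues, which induces the
    pairing structure the replicate splits respect.
    """

    n_patients: int = 40
    n_genes: int = 500
    transcripts_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.2, 2: 0.2, 3: 0.25, 4: 0.2, 5: 0.15}
    )
    exons_per_gene: tuple[int, int] = (4, 10)          # inclusive range of the exon pool
    exon_length: tuple[int, int] = (100, 400)           # bp, inclusive
    intron_length: tuple[int, int] = (100, 2000)        # bp, inclusive
    baseline_log_mean: float = math.log(100.0)          # log expected transcript count
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.2
    library_size_mean: float = 2.0e7                    # mapped reads
    library_size_log_sd: float = 0.3
    patient_effect_sd: float = 0.3
    planted_events: list[PlantedEvent] = field(default_factory=list)
    gender_proportions: dict[str, float] = field(default_factory=lambda: {"male": 0.5, "female": 0.5})
    smoking_proportions: dict[str, float] = field(
        default_factory=lambda: {"smoker": 0.5, "nonsmoker": 0.5}
    )
    stage_proportions: dict[str, float] = field(
        default_factory=lambda: {"I": 0.5, "II": 0.3, "III": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        genes = [e.gene_id for e in self.planted_events if e.gene_id is not None]
        if len(genes) != len(set(genes)):
            raise ValueError("planted events must target pairwise distinct genes")


@dataclass
class SyntheticTruth:
    """Planted truth: which features truly change, and by how much."""

    degs: set[str]
    dets: set[str]
    dees: set[str]
    table: pd.DataFrame  # feature_id, level, event_type, realized_fold
    annotation: AnnotationModel
    events: list[PlantedEvent] = field(default_factory=list)  # gene_id resolved

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass
class SyntheticCohort:
    annotation: AnnotationModel
    counts: dict[str, CountMatrix]          # gene / transcript / exonic_region
    tx_fpkm: ExpressionMatrix
    metadata: SampleMetadata
    totals: pd.Series                       # total mapped reads per sample
    truth: SyntheticTruth
    spec: CohortSpec


def _sample_categorical(rng: np.random.Generator, props: dict[str, float], n: int) -> list[str]:
    keys = sorted(props)
    p = np.array([props[k] for k in keys], dtype=float)
    p = p / p.sum()
    return [keys[i] for i in rng.choice(len(keys), size=n, p=p)]


def generate_annotation(spec: CohortSpec, rng: np.random.Generator | None = None) -> AnnotationModel:
    """Build a flattened annotation whose isoforms share and differ in exons.

    Each gene gets a pool of disjoint exons; the first transcript uses the
    whole pool and every further isoform drops a random non-empty proper
    subset, so flattening produces regions shared by all isoforms as well
    as regions private to a subset.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n_tx_values = sorted(spec.transcripts_per_gene)
    n_tx_p = np.array([spec.transcripts_per_gene[k] for k in n_tx_values], dtype=float)
    n_tx_p = n_tx_p / n_tx_p.sum()

    model = AnnotationModel()
    cursor = 1
    width = max(4, len(str(spec.n_genes)))
    for g in range(spec.n_genes):
        gid = f"G{g + 1:0{width}d}"
        model.genes[gid] = Gene(gene_id=gid, chrom="chr1", strand="+")
        n_exons = int(rng.integers(spec.exons_per_gene[0], spec.exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for _ in range(n_exons):
            length = int(rng.integers(spec.exon_length[0], spec.exon_length[1] + 1))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(spec.intron_length[0], spec.intron_length[1] + 1))
        cursor = pos + 10_000

        n_tx = int(n_tx_values[rng.choice(len(n_tx_values), p=n_tx_p)])
        keep_patterns: list[tuple[int, ...]] = [tuple(range(n_exons))]
        for _ in range(n_tx - 1):
            pattern = keep_patterns[0]
            for _attempt in range(10):
                n_drop = int(rng.integers(1, n_exons)) if n_exons > 1 else 0
                dropped = set(rng.choice(n_exons, size=n_drop, replace=False))
                cand = tuple(i for i in range(n_exons) if i not in dropped)
                if cand and cand not in keep_patterns:
                    pattern = cand
                    break
            keep_patterns.append(pattern)
        for j, pattern in enumerate(keep_patterns, start=1):
            tid = f"{gid}.t{j}"
            model.transcripts[tid] = Transcript(
                transcript_id=tid, gene_id=gid,
                exons=tuple(exons[i] for i in pattern),
            )
    return flatten_exonic_regions(model)


def _assign_event_genes(
    spec: CohortSpec, annot: AnnotationModel, rng: np.random.Generator
) -> list[PlantedEvent]:
    """Resolve auto-assigned event genes, pairwise disjoint, kind-eligible."""
    taken = {e.gene_id for e in spec.planted_events if e.gene_id is not None}
    tx_by_gene: dict[str, list[Transcript]] = {}
    for t in annot.transcripts.values():
        tx_by_gene.setdefault(t.gene_id, []).append(t)

    def eligible(gid: str, kind: EventKind) -> bool:
        txs = tx_by_gene.get(gid, [])
        if kind == "gene_de":
            return len(txs) >= 1
        if len(txs) < 2:
            return False
        if kind == "exon_de":
            return any(
                len(r.member_transcript_ids) < len(txs) for r in annot.regions_of_gene(gid)
            )
        return True  # transcript_switch

    resolved = []
    gene_order = list(np.array(sorted(annot.genes))[rng.permutation(len(annot.genes))])
    for event in spec.planted_events:
        if event.gene_id is not None:
            if not eligible(event.gene_id, event.kind):
                raise ValueError(
                    f"gene {event.gene_id} is not eligible for a {event.kind} event "
                    "(transcript_switch and exon_de need >=2 transcripts)"
                )
            resolved.append(event)
            continue
        gid = next((g for g in gene_order if g not in taken and eligible(g, event.kind)), None)
        if gid is None:
            raise ValueError(f"no eligible gene left for a {event.kind} event")
        taken.add(gid)
        resolved.append(replace(event, gene_id=gid))
    return resolved


def generate_cohort(spec: CohortSpec, samples_seed: int | None = None) -> SyntheticCohort:
    """Generate annotation, three-level counts, FPKM, metadata and truth.

    ``samples_seed`` defaults to a stream derived from ``spec.seed``; pass a
    different value to draw an independent batch of patients from the same
    synthetic population (same annotation, baselines and planted events).
    """
    structure_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    sample_entropy = [spec.seed, 1] if samples_seed is None else [samples_seed, 2]
    sample_rng = np.random.default_rng(np.random.SeedSequence(sample_entropy))

    annot = generate_annotation(spec, structure_rng)
    tx_ids = sorted(annot.transcripts)
    tx_index = {t: i for i, t in enumerate(tx_ids)}
    tx_len = np.array([annot.transcripts[t].length for t in tx_ids], dtype=float)
    gene_of = np.array([annot.transcripts[t].gene_id for t in tx_ids])

    baselines = np.exp(
        structure_rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, size=len(tx_ids))
    )
    tumor_mult = np.ones(len(tx_ids))
    events = _assign_event_genes(spec, annot, structure_rng)
    event_of_gene = {e.gene_id: e for e in events}

    for event in events:
        gid = event.gene_id
        member_tx = sorted(t for t in tx_ids if annot.transcripts[t].gene_id == gid)
        f = event.fold_change
        if event.kind == "gene_de":
            for t in member_tx:
                tumor_mult[tx_index[t]] = f
        elif event.kind == "transcript_switch":
            if len(member_tx) < 2:
                raise ValueError(f"transcript_switch on single-transcript gene {gid}")
            up, down = member_tx[0], member_tx[1]
            b = float(np.exp(structure_rng.normal(spec.baseline_log_mean, spec.baseline_log_sd)))
            # baselines (b, f*b) with multipliers (f, 1/f): tumor total f*b + b
            # equals the normal total b + f*b — conserved exactly.
            baselines[tx_index[up]] = b
            baselines[tx_index[down]] = f * b
            tumor_mult[tx_index[up]] = f
            tumor_mult[tx_index[down]] = 1.0 / f
        else:  # exon_de
            regions = annot.regions_of_gene(gid)
            private = [r for r in regions if len(r.member_transcript_ids) < len(member_tx)]
            if not private:
                raise ValueError(f"exon_de gene {gid} has no transcript-specific region")
            target = min(private, key=lambda r: (len(r.member_transcript_ids), r.region_id))
            for t in target.member_transcript_ids:
                tumor_mult[tx_index[t]] = f

    # ---- patients, samples, library sizes -------------------------------
    n_pat = spec.n_patients
    pat_ids = [f"P{i + 1:03d}" for i in range(n_pat)]
    sample_ids = [f"{p}{suffix}" for p in pat_ids for suffix in ("T", "N")]
    tissues = ["tumor", "normal"] * n_pat
    patient_of_sample = [p for p in pat_ids for _ in range(2)]

    patient_effect = np.exp(sample_rng.normal(0.0, spec.patient_effect_sd, size=n_pat))
    lib = spec.library_size_mean * np.exp(
        sample_rng.normal(0.0, spec.library_size_log_sd, size=len(sample_ids))
        - spec.library_size_log_sd**2 / 2
    )
    totals = pd.Series(lib, index=sample_ids, name="total_mapped_reads")

    # ---- transcript counts ----------------------------------------------
    mean = np.empty((len(tx_ids), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        pat = j // 2
        mult = tumor_mult if tissues[j] == "tumor" else 1.0
        mean[:, j] = baselines * patient_effect[pat] * mult * (lib[j] / spec.library_size_mean)
    if spec.nb_dispersion > 0:
        r = 1.0 / spec.nb_dispersion
        tx_counts = sample_rng.negative_binomial(r, r / (r + mean))
    else:
        tx_counts = sample_rng.poisson(mean)
    tx_counts = tx_counts.astype(np.int64)

    tx_df = pd.DataFrame(tx_counts, index=tx_ids, columns=sample_ids)
    gene_df = tx_df.groupby(pd.Series(gene_of, index=tx_ids)).sum()

    region_ids = sorted(annot.exonic_regions)
    region_rows = np.zeros((len(region_ids), len(sample_ids)))
    for i, rid in enumerate(region_ids):
        region = annot.exonic_regions[rid]
        for t in region.member_transcript_ids:
            region_rows[i] += tx_counts[tx_index[t]] * (region.length / tx_len[tx_index[t]])
    region_df = pd.DataFrame(np.rint(region_rows).astype(np.int64), index=region_ids, columns=sample_ids)

    fpkm_vals = tx_counts / np.outer(tx_len / 1e3, lib / 1e6)
    tx_fpkm = ExpressionMatrix("transcript", pd.DataFrame(fpkm_vals, index=tx_ids, columns=sample_ids))

    # ---- metadata -------------------------------------------------------
    gender = _sample_categorical(sample_rng, spec.gender_proportions, n_pat)
    smoking = _sample_categorical(sample_rng, spec.smoking_proportions, n_pat)
    stage = _sample_categorical(sample_rng, spec.stage_proportions, n_pat)
    pat_pos = {p: i for i, p in enumerate(pat_ids)}
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "patient_id": patient_of_sample,
                "tissue": tissues,
                "gender": [gender[pat_pos[p]] for p in patient_of_sample],
                "smoking_status": [smoking[pat_pos[p]] for p in patient_of_sample],
                "tumor_stage": [stage[pat_pos[p]] for p in patient_of_sample],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    truth = _derive_truth(annot, tx_ids, tx_index, tx_len, baselines, tumor_mult, event_of_gene)
    counts = {
        "gene": CountMatrix("gene", gene_df),
        "transcript": CountMatrix("transcript", tx_df),
        "exonic_region": CountMatrix("exonic_region", region_df),
    }
    return SyntheticCohort(
        annotation=annot, counts=counts, tx_fpkm=tx_fpkm,
        metadata=meta, totals=totals, truth=truth, spec=spec,
    )


_RATIO_TOL = 1e-9


def _derive_truth(
    annot: AnnotationModel,
    tx_ids: list[str],
    tx_index: dict[str, int],
    tx_len: np.ndarray,
    baselines: np.ndarray,
    tumor_mult: np.ndarray,
    event_of_gene: dict[str, PlantedEvent],
) -> SyntheticTruth:
    """Truth sets from the expected tumor/normal ratio of every feature."""
    rows = []
    degs, dets, dees = set(), set(), set()

    def etype(gid: str) -> str:
        e = event_of_gene.get(gid)
        return e.kind if e else ""

    for gid in sorted(annot.genes):
        member = [t for t in tx_ids if annot.transcripts[t].gene_id == gid]
        if not member:
            continue
        idx = [tx_index[t] for t in member]
        normal_total = baselines[idx].sum()
        tumor_total = (baselines[idx] * tumor_mult[idx]).sum()
        ratio = tumor_total / normal_total
        if abs(math.log(ratio)) > _RATIO_TOL:
            degs.add(gid)
            rows.append((gid, "gene", etype(gid), ratio))
    for t in tx_ids:
        ratio = float(tumor_mult[tx_index[t]])
        if abs(math.log(ratio)) > _RATIO_TOL:
            dets.add(t)
            rows.append((t, "transcript", etype(annot.transcripts[t].gene_id), ratio))
    for rid in sorted(annot.exonic_regions):
        region = annot.exonic_regions[rid]
        idx = [tx_index[t] for t in region.member_transcript_ids]
        w = region.length / tx_len[idx]
        normal = (baselines[idx] * w).sum()
        tumor = (baselines[idx] * tumor_mult[idx] * w).sum()
        ratio = tumor / normal if normal > 0 else 1.0
        if abs(math.log(ratio)) > _RATIO_TOL:
            dees.add(rid)
            rows.append((rid, "exonic_region", etype(region.gene_id), ratio))

    table = pd.DataFrame(rows, columns=["feature_id", "level", "event_type", "realized_fold"])
    return SyntheticTruth(
        degs=degs, dets=dets, dees=dees, table=table, annotation=annot,
        events=sorted(event_of_gene.values(), key=lambda e: e.gene_id),
    )


def simulate_null_counts(
    n_features: int,
    n_patients: int,
    dispersion: float = 0.2,
    baseline_log_mean: float = math.log(100.0),
    baseline_log_sd: float = 1.0,
    library_size_log_sd: float = 0.3,
    patient_effect_sd: float = 0.3,
    seed: int = 0,
) -> tuple[CountMatrix, SampleMetadata]:
    """Fast null cohort: NB gene counts with no tissue effect, paired design.

    Shares the distributional structure of :func:`generate_cohort` (baseline
    log-normal means, per-patient random effect shared across the pair,
    log-normal library-size factors, NB noise) without building an
    annotation — the workhorse for calibration simulations that need
    hundreds of independent null cohorts.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    feats = [f"G{i + 1:04d}" for i in range(n_features)]
    pats = [f"P{i + 1:03d}" for i in range(n_patients)]
    samples = [f"{p}{s}" for p in pats for s in ("T", "N")]
    tissues = ["tumor", "normal"] * n_patients

    base = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_features))
    pat_eff = np.exp(rng.normal(0.0, patient_effect_sd, size=n_patients))
    lib_factor = np.exp(rng.normal(0.0, library_size_log_sd, size=len(samples)) - library_size_log_sd**2 / 2)
    mean = base[:, None] * np.repeat(pat_eff, 2)[None, :] * lib_factor[None, :]
    if dispersion > 0:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mean))
    else:
        counts = rng.poisson(mean)
    cm = CountMatrix("gene", pd.DataFrame(counts.astype(np.int64), index=feats, columns=samples))
    meta = SampleMetadata(
        pd.DataFrame(
            {"patient_id": [p for p in pats for _ in range(2)], "tissue": tissues},
            index=pd.Index(samples, name="sample_id"),
        )
    )
    return cm, meta


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write the cohort in the same GTF/TSV formats the readers consume."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_annotation(cohort.annotation, directory / "annotation.gtf")
    for level, cm in cohort.counts.items():
        write_counts(cm, directory / f"counts_{level}.tsv")
    write_expression(cohort.tx_fpkm, directory / "fpkm_transcript.tsv")
    write_metadata(cohort.metadata, directory / "metadata.tsv")
    write_totals(cohort.totals, directory / "total_mapped_reads.tsv")
    cohort.truth.write_tsv(directory / "truth.tsv")
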