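"""Gene/transcript/exon annotation model and disjoint exonic regions.

The annotation is a three-level hierarchy: genes own transcripts, transcripts
own ordered exon intervals.  From the transcript models we derive, per gene,
the *exonic regions*: maximal disjoint intervals of the gene's exon union on
which the set of covering transcripts is constant.  These regions are the
counting bins for exon-level differential expression, and each records which
transcripts contain it, which is what lets exon-level expression be computed
by summing the FPKM of the containing transcripts.

Coordinates follow the GTF convention: 1-based, closed intervals, so an
interval (start, end) has length ``end - start + 1``.  Flattening ignores
strand; regions are indexed left to right along the chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable


Interval = tuple[int, int]


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    strand: str = "+"


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene_id: str
    exons: tuple[Interval, ...]  # sorted by start, 1-based closed

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class ExonicRegion:
    region_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    member_transcript_ids: frozenset[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationModel:
    """In-memory annotation: genes, transcripts, and derived exonic regions."""

    genes: dict[str, Gene] = field(default_factory=dict)
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    exonic_regions: dict[str, ExonicRegion] = field(default_factory=dict)

    def transcripts_of_gene(self, gene_id: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.gene_id == gene_id]

    def regions_of_gene(self, gene_id: str) -> list[ExonicRegion]:
        regs = [r for r in self.exonic_regions.values() if r.gene_id == gene_id]
        return sorted(regs, key=lambda r: r.start)

    def transcript_length(self, transcript_id: str) -> int:
        return self.transcripts[transcript_id].length

    def region_length(self, region_id: str) -> int:
        return self.exonic_regions[region_id].length

    def validate(self) -> None:
        for t in self.transcripts.values():
            if t.gene_id not in self.genes:
                raise ValueError(f"transcript {t.transcript_id} references unknown gene {t.gene_id}")
        for r in self.exonic_regions.values():
            if r.gene_id not in self.genes:
                raise ValueError(f"exonic region {r.region_id} references unknown gene {r.gene_id}")
            for tid in r.member_transcript_ids:
                if tid not in self.transcripts:
                    raise ValueError(f"exonic region {r.region_id} references unknown transcript {tid}")


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_annotation(path: str | Path) -> AnnotationModel:
    """Read an Ensembl-dialect GTF into an :class:`AnnotationModel`.

    Only ``gene`` and ``exon`` features are consulted; exon features must
    carry ``gene_id`` and ``transcript_id`` attributes.  A transcript whose
    gene has no ``gene`` feature line gets a gene record synthesized from
    the transcript span.  ``exonic_regions`` is left empty; call
    :func:`flatten_exonic_regions` to derive the counting bins.

    Raises
    ------
    ValueError
        On a malformed line (naming the line number) or an exon feature
        without a transcript_id.
    """
    path = Path(path)
    genes: dict[str, Gene] = {}
    tx_exons: dict[str, list[Interval]] = {}
    tx_gene: dict[str, str] = {}
    tx_chrom: dict[str, str] = {}
    tx_strand: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}: expected 9 tab-separated fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}: malformed GTF line {lineno}: non-integer coordinates") from None
            if start > end:
                raise ValueError(f"{path}: malformed GTF line {lineno}: start > end")
            attrs = _parse_attributes(attrs_s)
            if feature == "gene":
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}: malformed GTF line {lineno}: gene feature without gene_id")
                genes[gid] = Gene(gene_id=gid, chrom=chrom, strand=strand)
            elif feature == "exon":
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise ValueError(f"{path}: GTF line {lineno}: exon feature without transcript_id")
                gid = attrs.get("gene_id")
                if gid is None:
                    raise ValueError(f"{path}: GTF line {lineno}: exon feature without gene_id")
                tx_exons.setdefault(tid, []).append((start, end))
                tx_gene[tid] = gid
                tx_chrom[tid] = chrom
                tx_strand[tid] = strand

    model = AnnotationModel(genes=genes)
    for tid, exons in tx_exons.items():
        gid = tx_gene[tid]
        if gid not in model.genes:
            # no explicit gene feature: synthesize from the transcript
            model.genes[gid] = Gene(gene_id=gid, chrom=tx_chrom[tid], strand=tx_strand[tid])
        model.transcripts[tid] = Transcript(
            transcript_id=tid, gene_id=gid, exons=tuple(sorted(exons))
        )
    model.validate()
    return model


def write_annotation(model: AnnotationModel, path: str | Path) -> None:
    """Write gene and exon features back to a GTF file (inverse of read)."""
    with open(Path(path), "w") as fh:
        for gene in model.genes.values():
            tx = [t for t in model.transcripts.values() if t.gene_id == gene.gene_id]
            if tx:
                start = min(t.span[0] for t in tx)
                end = max(t.span[1] for t in tx)
            else:
                start = end = 1
            fh.write(
                f"{gene.chrom}\ttrilayer\tgene\t{start}\t{end}\t.\t{gene.strand}\t.\t"
                f'gene_id "{gene.gene_id}";\n'
            )
            for t in sorted(tx, key=lambda t: t.transcript_id):
                for s, e in t.exons:
                    fh.write(
                        f"{gene.chrom}\ttrilayer\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                        f'gene_id "{gene.gene_id}"; transcript_id "{t.transcript_id}";\n'
                    )


def flatten_exonic_regions(model: AnnotationModel) -> AnnotationModel:
    """Partition each gene's exon union into disjoint exonic regions.

    Per gene, every distinct exon start/end introduces a boundary; the union
    of exon intervals is cut at all boundaries into segments on which the
    covering transcript set is constant.  Each covered segment becomes one
    region with id ``gene_id:index`` (1-based, left to right).  Adjacent
    segments are kept separate even when their member sets coincide, so the
    region grid mirrors the exon structure.

    Returns a new model; the input is not mutated.
    """
    regions: dict[str, ExonicRegion] = {}
    by_gene: dict[str, list[Transcript]] = {}
    for t in model.transcripts.values():
        by_gene.setdefault(t.gene_id, []).append(t)

    for gid, txs in by_gene.items():
        chrom = model.genes[gid].chrom
        boundaries: set[int] = set()
        for t in txs:
            for s, e in t.exons:
                boundaries.add(s)
                boundaries.add(e + 1)  # half-open cut point
        cuts = sorted(boundaries)
        idx = 0
        for lo, hi in zip(cuts, cuts[1:]):
            seg = (lo, hi - 1)  # back to closed
            members = frozenset(
                t.transcript_id
                for t in txs
                if any(s <= seg[0] and seg[1] <= e for s, e in t.exons)
            )
            if not members:
                continue
            idx += 1
            rid = f"{gid}:{idx}"
            regions[rid] = ExonicRegion(
                region_id=rid, gene_id=gid, chrom=chrom,
                start=seg[0], end=seg[1], member_transcript_ids=members,
            )

    out = AnnotationModel(
        genes=dict(model.genes),
        transcripts=dict(model.transcripts),
        exonic_regions=regions,
    )
    out.validate()
    return out
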