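"""Transcript annotation models and strand-aware locus geometry.

Coordinates follow the GTF convention throughout: 1-based, closed intervals,
so a single-exon record ``100-300`` is 201 nt long.  Geometry between a
lncRNA locus and a candidate target gene is expressed as span-to-span
relations (overlap, or a gap in bp), with upstream/downstream oriented by
the *lncRNA's* strand — a gene past the lncRNA's 3' end is downstream of it.

The positional classification of overlapping lncRNA-gene pairs uses a fixed
precedence: exonic overlap beats full intronic containment beats mere span
overlap, and strand agreement selects the non-antisense form.  This yields
the six mutually exclusive overlap subtypes used in plant lncRNA surveys
(Sense, AntiSense, Intronic, AntiIntronic, Overlapping, AntiOverlapping)
plus Upstream/Downstream for near, non-overlapping neighbours.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class AnnotationError(ValueError):
    """Malformed or internally inconsistent annotation input."""


class GeometryError(ValueError):
    """Geometry requested for an invalid pair (e.g. different chromosomes)."""


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: the unit of filtering, geometry and classification.

    Exons are 1-based closed intervals, sorted and non-overlapping; ``length``
    is the summed exon length in nt.  ``origin`` distinguishes transcripts
    already present in the reference annotation (``known_mRNA``) from
    assembly-derived candidates (``novel_candidate``).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    origin: str = "novel_candidate"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise AnnotationError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id!r} has no exons")
        prev_end = 0
        for start, end in self.exons:
            if start < 1 or end < start:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: bad exon interval "
                    f"({start}, {end})"
                )
            if start <= prev_end:
                raise AnnotationError(
                    f"transcript {self.transcript_id!r}: exons unsorted or "
                    f"overlapping at ({start}, {end})"
                )
            prev_end = end
        if self.origin not in {"known_mRNA", "novel_candidate"}:
            raise AnnotationError(f"unknown origin {self.origin!r}")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Intervals strictly between consecutive exons (may be empty)."""
        out = []
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 - e1 > 1:
                out.append((e1 + 1, s2 - 1))
        return tuple(out)


class Relation(str, Enum):
    NO_OVERLAP_UPSTREAM = "no_overlap_upstream"
    NO_OVERLAP_DOWNSTREAM = "no_overlap_downstream"
    OVERLAP = "overlap"


class CisSubtype(str, Enum):
    SENSE = "Sense"
    ANTISENSE = "AntiSense"
    INTRONIC = "Intronic"
    ANTIINTRONIC = "AntiIntronic"
    OVERLAPPING = "Overlapping"
    ANTIOVERLAPPING = "AntiOverlapping"
    UPSTREAM = "Upstream"
    DOWNSTREAM = "Downstream"


OVERLAP_SUBTYPES = (
    CisSubtype.SENSE,
    CisSubtype.ANTISENSE,
    CisSubtype.INTRONIC,
    CisSubtype.ANTIINTRONIC,
    CisSubtype.OVERLAPPING,
    CisSubtype.ANTIOVERLAPPING,
)


@dataclass(frozen=True)
class LocusGeometry:
    """Span relation between one lncRNA and one candidate target gene."""

    lncrna_id: str
    gene_id: str
    relation: Relation
    gap_bp: int
    exonic_overlap: bool
    fully_intronic: bool
    same_strand: bool

    def __post_init__(self) -> None:
        if self.gap_bp < 0:
            raise GeometryError("gap_bp must be non-negative")
        # Overlap implies gap 0; the converse does not hold for adjacent
        # (touching but disjoint) closed intervals, which have gap 0 too.
        if self.relation is Relation.OVERLAP and self.gap_bp != 0:
            raise GeometryError("overlapping pair must have gap_bp 0")
        if self.fully_intronic and (self.relation is not Relation.OVERLAP or self.exonic_overlap):
            raise GeometryError("fully_intronic implies overlap without exonic overlap")


def _spans_intersect(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _span_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Nearest span-to-span distance in bp; 0 iff the spans intersect or touch."""
    if _spans_intersect(a, b):
        return 0
    if b[0] > a[1]:
        return b[0] - a[1] - 1
    return a[0] - b[1] - 1


def locus_geometry(lnc: TranscriptModel, gene: TranscriptModel) -> LocusGeometry:
    """Compute the span relation between a lncRNA and a gene on one chromosome.

    ``gap_bp`` is the nearest gene-span to lncRNA-span distance.  For
    non-overlapping pairs the relation is oriented by the lncRNA's strand:
    a gene beyond the lncRNA's 3' end is ``no_overlap_downstream``.
    ``fully_intronic`` is true iff the whole lncRNA span lies strictly inside
    one intron of the gene.
    """
    if lnc.chrom != gene.chrom:
        raise GeometryError(
            f"{lnc.transcript_id} ({lnc.chrom}) and {gene.transcript_id} "
            f"({gene.chrom}) are on different chromosomes"
        )
    lspan = (lnc.start, lnc.end)
    gspan = (gene.start, gene.end)
    overlap = _spans_intersect(lspan, gspan)
    gap = _span_gap(lspan, gspan)
    if overlap:
        relation = Relation.OVERLAP
    else:
        gene_after = gspan[0] > lspan[1]
        downstream = gene_after if lnc.strand == "+" else not gene_after
        relation = (
            Relation.NO_OVERLAP_DOWNSTREAM if downstream else Relation.NO_OVERLAP_UPSTREAM
        )
    exonic = overlap and any(
        _spans_intersect(le, ge) for le in lnc.exons for ge in gene.exons
    )
    intronic = overlap and not exonic and any(
        i[0] < lspan[0] and lspan[1] < i[1] for i in gene.introns
    )
    return LocusGeometry(
        lncrna_id=lnc.transcript_id,
        gene_id=gene.gene_id,
        relation=relation,
        gap_bp=gap,
        exonic_overlap=exonic,
        fully_intronic=intronic,
        same_strand=lnc.strand == gene.strand,
    )


def classify_cis_subtype(geom: LocusGeometry, window: int = 10_000) -> CisSubtype:
    """Assign the positional subtype of a cis lncRNA-gene pair.

    Precedence for overlapping pairs: exonic overlap -> Sense/AntiSense;
    else fully intronic -> Intronic/AntiIntronic; else Overlapping/
    AntiOverlapping.  Strand agreement selects the non-Anti form.
    Non-overlapping pairs within ``window`` bp are Upstream/Downstream by the
    lncRNA-oriented relation; beyond the window no subtype exists.
    """
    if geom.relation is Relation.OVERLAP:
        if geom.exonic_overlap:
            return CisSubtype.SENSE if geom.same_strand else CisSubtype.ANTISENSE
        if geom.fully_intronic:
            return CisSubtype.INTRONIC if geom.same_strand else CisSubtype.ANTIINTRONIC
        return CisSubtype.OVERLAPPING if geom.same_strand else CisSubtype.ANTIOVERLAPPING
    if geom.gap_bp > window:
        raise GeometryError(
            f"pair {geom.lncrna_id}/{geom.gene_id}: gap {geom.gap_bp} bp exceeds "
            f"the {window} bp cis window; no positional subtype"
        )
    return (
        CisSubtype.DOWNSTREAM
        if geom.relation is Relation.NO_OVERLAP_DOWNSTREAM
        else CisSubtype.UPSTREAM
    )


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def read_gtf(path, known_ids: Iterable[str] | None = None) -> list[TranscriptModel]:
    """Read transcripts from a GTF file (``gene_id "x"; transcript_id "y";`` dialect).

    Exon features are grouped by transcript_id, merged and sorted.  Records
    with strand '.' are rejected; a transcript whose records disagree on
    chromosome or strand raises :class:`AnnotationError`.  ``known_ids`` marks
    transcripts as ``known_mRNA`` origin.
    """
    known = set(known_ids or ())
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"{path}:{lineno}: expected 9 tab-separated fields")
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields[:9]
            if feature not in {"exon", "transcript"}:
                continue
            attr = _parse_attributes(attrs)
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id")
            if not tid:
                raise AnnotationError(f"{path}:{lineno}: record lacks transcript_id")
            if not gid:
                raise AnnotationError(f"{path}:{lineno}: record lacks gene_id")
            if strand not in {"+", "-"}:
                raise AnnotationError(
                    f"{path}:{lineno}: transcript {tid!r} is unstranded ({strand!r})"
                )
            if tid in meta:
                if meta[tid] != (gid, chrom, strand):
                    raise AnnotationError(
                        f"{path}:{lineno}: transcript {tid!r} has inconsistent "
                        f"gene/chrom/strand across records"
                    )
            else:
                meta[tid] = (gid, chrom, strand)
                order.append(tid)
            if feature == "exon":
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise AnnotationError(f"{path}:{lineno}: non-integer coordinates") from exc
                exons.setdefault(tid, []).append((start, end))
    out = []
    for tid in order:
        gid, chrom, strand = meta[tid]
        ex = _merge_intervals(exons.get(tid, []))
        if not ex:
            raise AnnotationError(f"transcript {tid!r} has no exon records")
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gid,
                chrom=chrom,
                strand=strand,
                exons=ex,
                origin="known_mRNA" if tid in known else "novel_candidate",
            )
        )
    return out


def _merge_intervals(intervals: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    if not intervals:
        return ()
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)
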