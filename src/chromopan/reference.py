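"""Reference-chromosome model shared by every pipeline stage.

A single chromosome is described by its sequence, an interval annotation of
transposable elements (TEs), gene models with coding exons, and the
breakpoints of the classical Triticeae chromosome partitioning into distal
(R1, R3), interstitial (R2a, R2b) and centromeric/pericentromeric (C)
segments.

All coordinates are 0-based half-open.  Conversion from 1-based closed (GFF)
or native 0-based half-open (BED) happens only at file boundaries, in
:mod:`chromopan.io`.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

__all__ = [
    "TeCopy",
    "GeneModel",
    "ReferenceModel",
    "NonRepeatSpace",
    "MappingSummary",
    "REGION_LABELS",
    "nonrepeat_space",
    "region_of",
    "coverage_summary",
]

#: Chromosome partition labels, left to right.
REGION_LABELS = ("R1", "R2a", "C", "R2b", "R3")

Interval = tuple[int, int]


@dataclass(frozen=True)
class TeCopy:
    """One annotated TE copy: a half-open interval tagged with its family."""

    te_id: str
    family: str
    superfamily: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"TE {self.te_id}: end ({self.end}) must exceed start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TE {self.te_id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its coding exons and translated protein."""

    gene_id: str
    start: int
    end: int
    coding_exons: tuple[Interval, ...]
    protein: str

    def __post_init__(self) -> None:
        if not self.coding_exons:
            raise ValueError(f"gene {self.gene_id}: at least one coding exon required")
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein")
        exons = sorted(self.coding_exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping coding exons")
        for s, e in exons:
            if s < self.start or e > self.end or e <= s:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene interval")

    @property
    def exon_bp(self) -> int:
        return sum(e - s for s, e in self.coding_exons)


@dataclass
class ReferenceModel:
    """Annotated chromosome: sequence + TE intervals + genes + region breaks.

    ``region_breaks`` are the four internal breakpoints separating the five
    R1/R2a/C/R2b/R3 segments; they are configuration inputs (the partition
    is cytogenetically, not sequence-, defined).
    """

    chrom_id: str
    sequence: str
    te_set: list[TeCopy] = field(default_factory=list)
    gene_set: list[GeneModel] = field(default_factory=list)
    region_breaks: tuple[int, int, int, int] = (0, 0, 0, 0)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated model invariant."""
        n = self.length
        tes = sorted(self.te_set, key=lambda t: (t.start, t.end))
        for te in tes:
            if te.start < 0 or te.end > n:
                raise ValueError(f"TE {te.te_id} outside chromosome bounds [0,{n})")
        for a, b in zip(tes, tes[1:]):
            if b.start < a.end:  # abutting allowed, overlap not
                raise ValueError(f"TE intervals overlap: {a.te_id} and {b.te_id}")
        for g in self.gene_set:
            if g.start < 0 or g.end > n:
                raise ValueError(f"gene {g.gene_id} outside chromosome bounds [0,{n})")
        if list(self.region_breaks) != sorted(set(self.region_breaks)):
            raise ValueError("region_breaks must be strictly increasing")
        for b in self.region_breaks:
            if not 0 < b < n:
                raise ValueError(f"region break {b} outside (0,{n})")

    def te_by_id(self) -> dict[str, TeCopy]:
        return {t.te_id: t for t in self.te_set}

    def gene_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.gene_set}


@dataclass(frozen=True)
class NonRepeatSpace:
    """Complement of the TE space: ordered disjoint intervals, genes retained."""

    intervals: tuple[Interval, ...]
    total_bp: int


@dataclass
class MappingSummary:
    """Per-accession quantities derived from read mapping.

    In real deployments these tables are computed from BAM files by an
    external aligner pipeline; here they are either read from TSV or
    emulated by :mod:`chromopan.simulate`.

    locus_depth
        mean depth (x) per non-repeat locus.
    gene_counts
        per gene: (read count, fraction of coding-exon bp covered).
    isbp_support
        junction-spanning read count per ISBP marker.
    allele_counts
        per site position: (reference-allele reads, alternate-allele reads).
    te_weighted_counts
        per TE copy: multi-mapping-weighted, length-normalised read count
        in coverage (x) units.
    """

    accession_id: str
    locus_depth: dict[str, float] = field(default_factory=dict)
    gene_counts: dict[str, tuple[int, float]] = field(default_factory=dict)
    isbp_support: dict[str, int] = field(default_factory=dict)
    allele_counts: dict[int, tuple[int, int]] = field(default_factory=dict)
    te_weighted_counts: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for g, (c, f) in self.gene_counts.items():
            if c < 0 or not 0.0 <= f <= 1.0:
                raise ValueError(f"gene {g}: bad count/covered_fraction ({c}, {f})")
        if any(v < 0 for v in self.isbp_support.values()):
            raise ValueError("negative isbp support")
        if any(r < 0 or a < 0 for r, a in self.allele_counts.values()):
            raise ValueError("negative allele counts")


def nonrepeat_space(model: ReferenceModel) -> NonRepeatSpace:
    """Complement the TE annotation over [0, length).

    Equivalent to an interval complement (``bedtools complement``) of the TE
    space; genes and non-genic low-copy sequence are retained.
    """
    tes = sorted((t.start, t.end) for t in model.te_set)
    out: list[Interval] = []
    cursor = 0
    for s, e in tes:
        if s > cursor:
            out.append((cursor, s))
        cursor = max(cursor, e)
    if cursor < model.length:
        out.append((cursor, model.length))
    return NonRepeatSpace(tuple(out), sum(e - s for s, e in out))


def region_of(position: int, model: ReferenceModel) -> str:
    """Label a position with its chromosome segment (R1/R2a/C/R2b/R3).

    Segments are half-open: a position equal to a breakpoint belongs to the
    segment starting there.
    """
    if not 0 <= position < model.length:
        raise ValueError(f"position {position} outside [0,{model.length})")
    return REGION_LABELS[bisect_right(model.region_breaks, position)]


def coverage_summary(summary: MappingSummary, loci, min_depth: float = 5.0) -> tuple[float, float]:
    """Covered fraction and mean depth of the non-repeat space.

    A locus counts as covered when its mean depth reaches ``min_depth``
    (default 5x).  ``loci`` is a :class:`chromopan.loci.LocusSet` (or any
    iterable of objects with ``locus_id``/``start``/``end``) tiling the
    space; the covered fraction is bp-weighted.
    """
    items = list(loci)
    if not items:
        raise ValueError("empty locus set")
    covered_bp = 0
    total_bp = 0
    depth_sum = 0.0
    for loc in items:
        d = summary.locus_depth[loc.locus_id]
        bp = loc.end - loc.start
        total_bp += bp
        depth_sum += d
        if d >= min_depth:
            covered_bp += bp
    return covered_bp / total_bp, depth_sum / len(items)
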