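"""ISBP junction markers and TE structural-variation calling.

An ISBP (insertion-site-based polymorphism) marker is a 150-bp window
spanning the junction between a TE end and its flanking DNA — 75 bp on each
side.  Because the flank is unique, the 150-mer is (after filtering) unique
in the reference, and a short read matching it end-to-end certifies that
the TE insertion exists in that accession.  Per-TE presence of the 5' and
3' junctions classifies each TE copy as present, partially absent (one
end) or fully absent (both ends); TEs present in every member of one group
and fully absent elsewhere are reported as group-specific insertions.
A depth-of-coverage route estimates per-family copy-number fold changes
from multi-mapping-weighted read counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import ReferenceModel, TeCopy

__all__ = [
    "IsbpMarker",
    "TeIndelCall",
    "FamilyCnv",
    "MARKER_LENGTH",
    "design_isbps",
    "match_reads_to_isbps",
    "call_isbp_presence",
    "classify_te_indels",
    "detect_group_specific_insertions",
    "te_family_cnv",
    "revcomp",
    "count_occurrences",
]

MARKER_LENGTH = 150
FLANK = 75

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def count_occurrences(haystack: str, needle: str) -> int:
    """Count (possibly overlapping) occurrences of ``needle`` in ``haystack``."""
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


@dataclass(frozen=True)
class IsbpMarker:
    """150-bp TE/flank junction marker.

    ``junction_pos`` is the first base of the TE for a 5' marker and the
    first base after the TE for a 3' marker; the window holds 75 bp of
    flank and 75 bp of TE around it.
    """

    marker_id: str
    te_id: str
    end: str  # "5" | "3"
    junction_pos: int
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != MARKER_LENGTH:
            raise ValueError(f"marker {self.marker_id}: length {len(self.sequence)} != {MARKER_LENGTH}")
        if self.end not in ("5", "3"):
            raise ValueError(f"marker {self.marker_id}: end must be '5' or '3'")

    @property
    def stop(self) -> int:  # half-open interval end in reference coords
        return self.start + MARKER_LENGTH

    @property
    def junction_offset(self) -> int:
        return self.junction_pos - self.start


@dataclass(frozen=True)
class TeIndelCall:
    te_id: str
    accession_id: str
    status: str  # present | partial_absent_5 | partial_absent_3 | full_absent | untestable
    n_markers: int


@dataclass(frozen=True)
class FamilyCnv:
    family: str
    accession_id: str
    weighted_count: float
    cs_weighted_count: float
    fold_change: float


def _candidates(model: ReferenceModel) -> list[IsbpMarker]:
    seq = model.sequence
    out = []
    for te in sorted(model.te_set, key=lambda t: (t.start, t.end)):
        for end, junction in (("5", te.start), ("3", te.end)):
            start = junction - FLANK
            if start < 0 or start + MARKER_LENGTH > model.length:
                continue  # window would extend past sequence bounds
            out.append(
                IsbpMarker(
                    marker_id=f"{te.te_id}_{end}p",
                    te_id=te.te_id,
                    end=end,
                    junction_pos=junction,
                    start=start,
                    sequence=seq[start : start + MARKER_LENGTH],
                )
            )
    out.sort(key=lambda m: (m.start, m.marker_id))
    return out


def design_isbps(model: ReferenceModel, max_overlap: int = 99) -> list[IsbpMarker]:
    """Design ISBP markers for every TE of the reference.

    Filters, in order: windows out of sequence bounds are skipped; of two
    neighbouring markers overlapping by more than ``max_overlap`` bp only
    the first by coordinate is kept; markers containing N are dropped;
    markers whose 150-mer (either strand) occurs more than once in the
    reference are dropped as non-unique.
    """
    cands = _candidates(model)

    # overlap dedup, left-most wins
    kept: list[IsbpMarker] = []
    for m in cands:
        if kept:
            prev = kept[-1]
            overlap = min(prev.stop, m.stop) - max(prev.start, m.start)
            if overlap > max_overlap:
                continue
        kept.append(m)

    kept = [m for m in kept if "N" not in m.sequence]

    seq = model.sequence
    unique: list[IsbpMarker] = []
    for m in kept:
        occ = count_occurrences(seq, m.sequence)
        rc = revcomp(m.sequence)
        if rc != m.sequence:
            occ += count_occurrences(seq, rc)
        if occ == 1:
            unique.append(m)
    return unique


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def match_reads_to_isbps(
    reads: Iterable[str],
    markers: Sequence[IsbpMarker],
    max_mismatch: int = 2,
    min_side: int = 20,
) -> tuple[dict[str, int], int]:
    """Count reads supporting each junction marker.

    A read supports a marker when it aligns end-to-end (ungapped, either
    strand) inside the 150-bp marker with at most ``max_mismatch``
    substitutions and its aligned span covers at least ``min_side`` bases
    on each side of the junction.  Returns ``(support_by_marker,
    n_rejected_too_long)``.
    """
    support = {m.marker_id: 0 for m in markers}
    enc = [(m, _encode(m.sequence)) for m in markers]
    too_long = 0
    for read in reads:
        L = len(read)
        if L > MARKER_LENGTH:
            too_long += 1
            continue
        fwd = _encode(read)
        rev = _encode(revcomp(read))
        for m, mseq in enc:
            j = m.junction_offset
            lo = max(0, j + min_side - L)
            hi = min(MARKER_LENGTH - L, j - min_side)
            if hi < lo:
                continue
            hit = False
            for off in range(lo, hi + 1):
                win = mseq[off : off + L]
                if np.count_nonzero(win != fwd) <= max_mismatch or np.count_nonzero(win != rev) <= max_mismatch:
                    hit = True
                    break
            if hit:
                support[m.marker_id] += 1
    return support, too_long


def call_isbp_presence(
    support_by_accession: Mapping[str, Mapping[str, float]],
    markers: Sequence[IsbpMarker],
    min_support: float = 5,
) -> pd.DataFrame:
    """Marker x accession presence matrix: present iff support >= min_support."""
    ids = [m.marker_id for m in markers]
    cols = {
        acc: np.array([sup.get(i, 0) >= min_support for i in ids], dtype=bool)
        for acc, sup in support_by_accession.items()
    }
    return pd.DataFrame(cols, index=pd.Index(ids, name="marker_id"))


def classify_te_indels(
    presence: pd.DataFrame,
    markers: Sequence[IsbpMarker],
    model: ReferenceModel,
) -> pd.DataFrame:
    """Classify each TE x accession from junction presence.

    Both markers present -> present; exactly one absent -> partial absence
    of the recorded side; both absent -> full_absent.  TEs with a single
    surviving marker can only be called present or partially absent on the
    known side; TEs with no surviving marker are untestable.
    """
    by_te: dict[str, dict[str, str]] = {}
    for m in markers:
        by_te.setdefault(m.te_id, {})[m.end] = m.marker_id
    rows = {}
    accs = list(presence.columns)
    for te in model.te_set:
        ends = by_te.get(te.te_id, {})
        statuses = []
        for acc in accs:
            if not ends:
                statuses.append("untestable")
                continue
            p5 = presence.at[ends["5"], acc] if "5" in ends else None
            p3 = presence.at[ends["3"], acc] if "3" in ends else None
            if p5 is None:  # 3'-only TE
                statuses.append("present" if p3 else "partial_absent_3")
            elif p3 is None:  # 5'-only TE
                statuses.append("present" if p5 else "partial_absent_5")
            elif p5 and p3:
                statuses.append("present")
            elif not p5 and not p3:
                statuses.append("full_absent")
            elif p5:
                statuses.append("partial_absent_3")
            else:
                statuses.append("partial_absent_5")
        rows[te.te_id] = statuses
    return pd.DataFrame.from_dict(rows, orient="index", columns=accs).rename_axis("te_id")


def detect_group_specific_insertions(
    status: pd.DataFrame,
    group_assignment: Mapping[str, str],
) -> dict[str, set[str]]:
    """TEs present in every member of one group and fully absent elsewhere.

    Such a pattern is the signature of a TE insertion private to (the
    ancestor of) that group.  Requires at least two groups.
    """
    groups = sorted(set(group_assignment.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    members = {g: [a for a, gg in group_assignment.items() if gg == g] for g in groups}
    out: dict[str, set[str]] = {g: set() for g in groups}
    for te_id, row in status.iterrows():
        for g in groups:
            if all(row[a] == "present" for a in members[g]) and all(
                row[a] == "full_absent" for a, gg in group_assignment.items() if gg != g
            ):
                out[g].add(te_id)
                break
    return out


def te_family_cnv(
    weighted_by_accession: Mapping[str, Mapping[str, float]],
    model: ReferenceModel,
    reference_accession: str,
    min_ref_depth: float = 50.0,
    normalize: bool = True,
) -> list[FamilyCnv]:
    """Per-family copy-number fold change versus the reference accession.

    Input weighted counts are per TE copy, multi-mapping weighted (a read
    hitting n copies contributes 1/n to each) and length-normalised, i.e.
    in coverage (x) units.  Family counts are sums over member copies;
    families whose mean per-copy depth in the reference accession is below
    ``min_ref_depth`` (default 50x) are omitted.  Accessions sequenced at
    different depths are made comparable by median-of-ratios
    normalisation: each accession's raw family ratios are divided by
    their median, so a genuinely amplified family does not drag the
    scaling factor with it.
    """
    if reference_accession not in weighted_by_accession:
        raise ValueError(f"reference accession {reference_accession!r} missing")
    fam_of = {t.te_id: t.family for t in model.te_set}
    fam_sizes: dict[str, int] = {}
    for t in model.te_set:
        fam_sizes[t.family] = fam_sizes.get(t.family, 0) + 1

    def family_sums(weights: Mapping[str, float]) -> dict[str, float]:
        s: dict[str, float] = {}
        for te_id, w in weights.items():
            fam = fam_of.get(te_id)
            if fam is not None:
                s[fam] = s.get(fam, 0.0) + w
        return s

    ref_sums = family_sums(weighted_by_accession[reference_accession])
    reported = [
        f for f, s in ref_sums.items() if s / fam_sizes[f] >= min_ref_depth
    ]

    out: list[FamilyCnv] = []
    for acc, weights in weighted_by_accession.items():
        sums = family_sums(weights)
        raw = {f: sums.get(f, 0.0) / ref_sums[f] for f in reported}
        scale = float(np.median(list(raw.values()))) if normalize and raw else 1.0
        if scale == 0:
            scale = 1.0
        for fam in reported:
            out.append(
                FamilyCnv(fam, acc, sums.get(fam, 0.0), ref_sums[fam], raw[fam] / scale)
            )
    return out
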