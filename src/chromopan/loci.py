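"""Locus tiling of the non-repeat space and deletion-block detection.

The non-repeat fraction of the chromosome is split into ~100-bp segment
loci (terminal remainders of 51-99 bp are kept as short loci, smaller ones
discarded), interleaved with the 150-bp ISBP junction loci.  Per-accession
presence/absence of each locus (5x depth rule) feeds a 50-locus sliding
window (step 5) that flags candidate deletion windows; runs of at least two
consecutive flagged windows, trimmed to the outermost absent loci, are
reported as deletion blocks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import NonRepeatSpace, ReferenceModel, region_of

__all__ = [
    "Locus",
    "LocusSet",
    "DeletionBlock",
    "build_locus_set",
    "locus_presence",
    "deletion_blocks",
    "sv_density_profile",
]


@dataclass(frozen=True)
class Locus:
    locus_id: str
    start: int
    end: int
    kind: str  # "segment" | "isbp"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class LocusSet:
    """Ordered loci (chromosomal order) over one chromosome."""

    loci: list[Locus]

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def __getitem__(self, i: int) -> Locus:
        return self.loci[i]

    def ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]


@dataclass(frozen=True)
class DeletionBlock:
    """A run of absent loci called by the sliding-window rule.

    ``start``/``end`` are bp coordinates trimmed to the outermost absent
    loci, so block size reflects deleted sequence rather than window
    quantisation.
    """

    accession_id: str
    first_locus: int
    last_locus: int
    start: int
    end: int
    n_absent_loci: int

    @property
    def length(self) -> int:
        return self.end - self.start


def build_locus_set(
    space: NonRepeatSpace,
    markers: Sequence = (),
    window: int = 100,
    min_remainder: int = 51,
) -> LocusSet:
    """Tile each non-repeat interval into ``window``-bp loci and interleave ISBPs.

    Full 100-bp windows are laid left to right; a terminal remainder of
    ``min_remainder``..``window-1`` bp is kept as a short locus, anything
    smaller is discarded.  ISBP marker loci (150 bp, overlapping the TE
    space by construction) are merged in by coordinate.
    """
    segs: list[Locus] = []
    i = 0
    for s, e in space.intervals:
        pos = s
        while pos + window <= e:
            segs.append(Locus(f"S{i:07d}", pos, pos + window, "segment"))
            i += 1
            pos += window
        if e - pos >= min_remainder:
            segs.append(Locus(f"S{i:07d}", pos, e, "segment"))
            i += 1
    isbps = [Locus(m.marker_id, m.start, m.stop, "isbp") for m in markers]
    loci = sorted(segs + isbps, key=lambda l: (l.start, l.end, l.kind))
    return LocusSet(loci)


def locus_presence(
    depth_by_accession: Mapping[str, Mapping[str, float]],
    loci: LocusSet,
    min_depth: float = 5.0,
) -> pd.DataFrame:
    """Presence matrix (locus x accession): present iff mean depth >= min_depth.

    Raises ``KeyError`` naming the first locus missing from an accession's
    depth table.
    """
    ids = loci.ids()
    cols = {}
    for acc, depths in depth_by_accession.items():
        try:
            cols[acc] = np.array([depths[i] >= min_depth for i in ids], dtype=bool)
        except KeyError as exc:
            raise KeyError(f"accession {acc}: no depth for locus {exc.args[0]}") from None
    return pd.DataFrame(cols, index=pd.Index(ids, name="locus_id"))


def deletion_blocks(
    presence: Sequence[bool] | np.ndarray,
    loci: LocusSet,
    accession_id: str = "",
    window: int = 50,
    step: int = 5,
    frac: float = 0.5,
    min_windows: int = 2,
) -> list[DeletionBlock]:
    """Call deletion blocks from one accession's ordered presence vector.

    A window of ``window`` neighbouring loci is flagged when *more than*
    ``frac`` of its loci are absent (strict; a 25/50 tie is not flagged).
    Runs of at least ``min_windows`` consecutive flagged windows (starts
    offset by ``step``) become blocks, trimmed to the outermost absent
    loci.  Overlapping trimmed blocks are merged.
    """
    absent = ~np.asarray(presence, dtype=bool)
    n = absent.size
    if n != len(loci):
        raise ValueError(f"presence vector length {n} != locus count {len(loci)}")
    if n < window:
        return []
    starts = np.arange(0, n - window + 1, step)
    # rolling absent count at each window start
    csum = np.concatenate([[0], np.cumsum(absent)])
    counts = csum[starts + window] - csum[starts]
    flagged = counts > frac * window

    spans: list[tuple[int, int]] = []  # locus-index spans of qualifying runs
    run_start = None
    for k, fl in enumerate(flagged):
        if fl and run_start is None:
            run_start = k
        if (not fl or k == len(flagged) - 1) and run_start is not None:
            run_end = k if fl else k - 1
            if run_end - run_start + 1 >= min_windows:
                spans.append((starts[run_start], starts[run_end] + window - 1))
            run_start = None

    blocks: list[DeletionBlock] = []
    for lo, hi in spans:
        idx = np.nonzero(absent[lo : hi + 1])[0]
        first = lo + int(idx[0])
        last = lo + int(idx[-1])
        if blocks and first <= blocks[-1].last_locus:
            prev = blocks.pop()
            first = prev.first_locus
        n_abs = int(absent[first : last + 1].sum())
        blocks.append(
            DeletionBlock(
                accession_id=accession_id,
                first_locus=first,
                last_locus=last,
                start=loci[first].start,
                end=loci[last].end,
                n_absent_loci=n_abs,
            )
        )
    return blocks


def sv_density_profile(
    calls: Iterable[tuple[str, int]],
    model: ReferenceModel,
    window: int = 10_000_000,
    step: int = 1_000_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sliding-window SV counts and per-region densities.

    ``calls`` yields (sv_class, position) pairs; every window overlapping a
    call's position counts it.  Returns ``(per_window, per_region)`` where
    per_window has one row per window start and one column per SV class,
    and per_region aggregates calls per Mb for each chromosome segment.
    """
    calls = list(calls)
    classes = sorted({c for c, _ in calls}) or ["none"]
    length = model.length
    w = min(window, length)
    starts = np.arange(0, max(length - w, 0) + 1, step)
    counts = {c: np.zeros(starts.size, dtype=int) for c in classes}
    for cls, pos in calls:
        # windows with start in (pos - w, pos]
        k0 = int(np.searchsorted(starts, pos - w, side="right"))
        k1 = int(np.searchsorted(starts, pos, side="right"))
        counts[cls][k0:k1] += 1
    per_window = pd.DataFrame(counts, index=pd.Index(starts, name="window_start"))

    bounds = [0, *model.region_breaks, length]
    rows = []
    from .reference import REGION_LABELS

    for lab, lo, hi in zip(REGION_LABELS, bounds, bounds[1:]):
        in_reg = [cls for cls, pos in calls if lo <= pos < hi]
        rows.append(
            {
                "region": lab,
                "start": lo,
                "end": hi,
                "n_sv": len(in_reg),
                "sv_per_mb": len(in_reg) / ((hi - lo) / 1e6) if hi > lo else float("nan"),
            }
        )
    per_region = pd.DataFrame(rows).set_index("region")
    return per_window, per_region
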