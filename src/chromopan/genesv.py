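"""Gene-level structural variation: PAV, upCNV and downCNV calling.

A gene is absent (PAV) in an accession when less than 10% of its
coding-exon length is covered by reads.  Copy-number candidates come from
the log2 ratio of normalised per-gene read counts between an accession and
the reference: per accession, a Tukey boxplot of all gene log2 ratios
yields upper/lower whiskers used as outlier thresholds.  An upCNV is a
candidate above the upper whisker that is corroborated by at least one
pseudo-heterozygous (class-3) SNP inside the gene — the footprint of a
slightly divergent extra copy.  A downCNV is a gene that is duplicated in
the reference (member of a protein-identity cluster of size >= 2) whose
log2 ratio falls below the lower whisker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .reference import GeneModel, ReferenceModel
from .snp import GenotypeMatrix, HET, HOM_ALT, classify_sites

__all__ = [
    "WhiskerThresholds",
    "GeneSvCall",
    "call_gene_pav",
    "analyzable_genes",
    "normalize_and_ratio",
    "fivenum",
    "whisker_thresholds",
    "pseudo_het_sites",
    "call_upcnv",
    "cluster_duplicated_genes",
    "call_downcnv",
]


@dataclass(frozen=True)
class WhiskerThresholds:
    """Tukey boxplot statistics of one accession's gene log2 ratios."""

    accession_id: str
    lower: float
    q1: float
    median: float
    q3: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.q1 <= self.median <= self.q3 <= self.upper):
            raise ValueError(f"{self.accession_id}: whisker ordering violated")


@dataclass(frozen=True)
class GeneSvCall:
    gene_id: str
    accession_id: str
    call: str  # PAV | upCNV_candidate | upCNV | downCNV
    log2ratio: float = float("nan")
    n_pseudo_het_sites: int = 0
    covered_fraction: float = float("nan")


def call_gene_pav(
    gene_counts: Mapping[str, tuple[int, float]],
    threshold: float = 0.10,
) -> set[str]:
    """Genes absent in this accession: coding-exon coverage strictly below 10%."""
    return {g for g, (_, frac) in gene_counts.items() if frac < threshold}


def analyzable_genes(reference_summary, min_depth_reads: int = 1) -> set[str]:
    """Reference-self QC: genes with read support in the reference's own mapping.

    Genes not covered when the reference accession is mapped onto itself
    cannot be scored in any accession and are excluded up front.
    """
    return {
        g
        for g, (count, frac) in reference_summary.gene_counts.items()
        if count >= min_depth_reads and frac > 0
    }


def normalize_and_ratio(
    gene_counts_by_accession: Mapping[str, Mapping[str, tuple[int, float]]],
    reference_accession: str,
    pav_by_accession: Mapping[str, set[str]] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Normalised per-gene counts and log2 ratios versus the reference.

    Two-step normalisation: (1) divide the raw count by the covered
    fraction of the gene; (2) divide by the accession's total raw count
    over all genes (library size).  ``log2ratio`` is left NaN for genes
    PAV-called in either the accession or the reference, so absent genes
    never produce -inf ratios.

    Returns a tidy frame indexed by (accession, gene) with columns
    raw_count, covered_fraction, normalized_count, log2ratio.
    """
    if reference_accession not in gene_counts_by_accession:
        raise ValueError(f"reference accession {reference_accession!r} missing")
    pav_by_accession = pav_by_accession or {}

    def normalized(acc: str) -> dict[str, float]:
        counts = gene_counts_by_accession[acc]
        total = sum(c for c, _ in counts.values())
        if total == 0:
            raise ValueError(f"accession {acc}: zero reads over all genes")
        pav = pav_by_accession.get(acc, set())
        out = {}
        for g, (c, frac) in counts.items():
            if genes is not None and g not in genes:
                continue
            if g in pav or frac == 0:
                out[g] = float("nan")
            else:
                out[g] = (c / frac) / total
        return out

    ref_norm = normalized(reference_accession)
    rows = []
    for acc, counts in gene_counts_by_accession.items():
        norm = normalized(acc)
        for g, n2 in norm.items():
            raw, frac = counts[g]
            ref_n2 = ref_norm.get(g, float("nan"))
            if math.isnan(n2) or math.isnan(ref_n2) or ref_n2 == 0:
                lr = float("nan")
            else:
                lr = math.log2(n2 / ref_n2)
            rows.append((acc, g, raw, frac, n2, lr))
    df = pd.DataFrame(
        rows,
        columns=["accession", "gene_id", "raw_count", "covered_fraction", "normalized_count", "log2ratio"],
    )
    return df.set_index(["accession", "gene_id"])


def fivenum(values: Sequence[float]) -> tuple[float, float, float, float, float]:
    """Tukey five-number summary (min, lower hinge, median, upper hinge, max).

    Hinges are medians of the lower/upper half of the sorted data, each
    half including the overall median when n is odd — the classical
    definition, matching R's ``fivenum``.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("empty input")
    n4 = math.floor((n + 3) / 2) / 2
    d = np.array([1, n4, (n + 1) / 2, n + 1 - n4, n])
    lo = np.floor(d).astype(int) - 1
    hi = np.ceil(d).astype(int) - 1
    out = 0.5 * (x[lo] + x[hi])
    return tuple(float(v) for v in out)


def whisker_thresholds(values: Sequence[float], accession_id: str = "") -> WhiskerThresholds:
    """Boxplot whiskers of one accession's log2 ratios.

    Fences sit at hinge +/- 1.5 IQR; each whisker is the most extreme
    datum within its fence.  NaN values are dropped; at least five finite
    values are required.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 5:
        raise ValueError(f"need >=5 finite values, got {x.size}")
    _, q1, med, q3, _ = fivenum(x)
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    lower = float(x[x >= lo_fence].min())
    upper = float(x[x <= hi_fence].max())
    return WhiskerThresholds(accession_id, lower, q1, med, q3, upper)


def pseudo_het_sites(
    matrix: GenotypeMatrix,
    model: ReferenceModel,
) -> dict[tuple[str, str], int]:
    """Count class-3 sites per (gene, accession) inside coding exons.

    A site counts for accession X when X is heterozygous there, no
    accession in the panel is homozygous-variant (so the variant cannot be
    a true polymorphism), and the position falls within the gene's coding
    exons.
    """
    cls = classify_sites(matrix)
    class3 = matrix.geno.loc[cls == 3]
    counts: dict[tuple[str, str], int] = {}
    if class3.empty:
        return counts
    positions = class3.index.to_numpy()
    for gene in model.gene_set:
        in_gene = np.zeros(positions.size, dtype=bool)
        for s, e in gene.coding_exons:
            in_gene |= (positions >= s) & (positions < e)
        if not in_gene.any():
            continue
        sub = class3.loc[in_gene]
        for acc in sub.columns:
            n = int((sub[acc] == HET).sum())
            if n:
                counts[(gene.gene_id, acc)] = n
    return counts


def call_upcnv(
    table: pd.DataFrame,
    whiskers: Mapping[str, WhiskerThresholds],
    pseudo_het_counts: Mapping[tuple[str, str], int],
) -> list[GeneSvCall]:
    """upCNV calls: log2ratio above the upper whisker, corroborated or not.

    Candidates lacking a pseudo-heterozygous site stay ``upCNV_candidate``;
    with at least one class-3 site in the gene they are promoted to
    ``upCNV``.
    """
    calls = []
    for (acc, gene), row in table.iterrows():
        w = whiskers.get(acc)
        if w is None:
            continue
        lr = row["log2ratio"]
        if np.isfinite(lr) and lr > w.upper:
            n3 = pseudo_het_counts.get((gene, acc), 0)
            calls.append(
                GeneSvCall(
                    gene_id=gene,
                    accession_id=acc,
                    call="upCNV" if n3 >= 1 else "upCNV_candidate",
                    log2ratio=float(lr),
                    n_pseudo_het_sites=n3,
                    covered_fraction=float(row["covered_fraction"]),
                )
            )
    return calls


_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1.0,
    mismatch_score=-1.0,
    open_gap_score=-2.0,
    extend_gap_score=-0.5,
)


def _global_identity(a: str, b: str) -> float:
    """Identity of the best global alignment: matches over alignment columns."""
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def cluster_duplicated_genes(
    proteins: Mapping[str, str],
    identity: float = 0.95,
    min_len_ratio: float = 0.5,
) -> list[list[str]]:
    """Greedy protein clustering in the CD-HIT style (-c 0.95 -s 0.5 -g 1).

    Sequences are sorted by length (descending, id as tie-break); each
    joins the best existing cluster whose representative passes the length
    ratio and global-alignment identity thresholds, otherwise founds a new
    cluster with itself as representative.  Word-filter heuristics are
    replaced by exact global alignment, affordable at chromosome scale.
    """
    if not proteins:
        raise ValueError("empty protein set")
    order = sorted(proteins, key=lambda g: (-len(proteins[g]), g))
    reps: list[str] = []
    clusters: list[list[str]] = []
    for g in order:
        seq = proteins[g]
        best_i, best_ident = -1, -1.0
        for i, rep in enumerate(reps):
            rep_seq = proteins[rep]
            ratio = min(len(seq), len(rep_seq)) / max(len(seq), len(rep_seq))
            if ratio < min_len_ratio:
                continue
            ident = _global_identity(seq, rep_seq)
            if ident >= identity and ident > best_ident:  # first cluster wins ties
                best_i, best_ident = i, ident
        if best_i >= 0:
            clusters[best_i].append(g)
        else:
            reps.append(g)
            clusters.append([g])
    return clusters


def call_downcnv(
    table: pd.DataFrame,
    whiskers: Mapping[str, WhiskerThresholds],
    clusters: Sequence[Sequence[str]],
) -> list[GeneSvCall]:
    """downCNV calls: duplicated genes whose log2ratio drops below the lower whisker."""
    duplicated = {g for cl in clusters if len(cl) >= 2 for g in cl}
    calls = []
    for (acc, gene), row in table.iterrows():
        if gene not in duplicated:
            continue
        w = whiskers.get(acc)
        if w is None:
            continue
        lr = row["log2ratio"]
        if np.isfinite(lr) and lr < w.lower:
            calls.append(
                GeneSvCall(
                    gene_id=gene,
                    accession_id=acc,
                    call="downCNV",
                    log2ratio=float(lr),
                    covered_fraction=float(row["covered_fraction"]),
                )
            )
    return calls
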