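"""Genotype calling from allele counts and SNP site classification.

Genotypes follow Varscan-style thresholds: a site needs 10x depth to be
called at all; the variant allele needs 10 supporting reads; an allele
frequency of 0.85 separates heterozygous from homozygous-variant calls and
0.02 is the minimum variant frequency.  No strand-bias filter is applied
(the allele-count model carries no strand information).

Sites are classified across the panel:

* class 1 — all non-missing genotypes homozygous, both homozygous states
  observed (AA/BB): ordinary diversity SNPs;
* class 2 — AA, AB and BB all observed;
* class 3 — at least one heterozygote and *no* homozygous variant.  In
  highly homozygous inbred lines such pseudo-heterozygous sites betray
  reads collapsing from slightly divergent paralogous copies onto a single
  reference locus, and are therefore used to corroborate upCNVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "GenotypeMatrix",
    "call_genotype",
    "call_genotypes_panel",
    "classify_sites",
    "maf_per_site",
    "maf_profile",
    "snp_density",
    "tstv_ratio",
]

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GENOTYPE_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class GenotypeMatrix:
    """Biallelic genotypes for a panel.

    ``sites`` is a DataFrame indexed by position with columns ``ref`` and
    ``alt`` (single-nucleotide alleles); ``geno`` is an int8 DataFrame with
    the same index, one column per accession, holding the genotype codes
    above.
    """

    sites: pd.DataFrame
    geno: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.sites.index.equals(self.geno.index):
            raise ValueError("sites and geno must share an index")

    @property
    def accessions(self) -> list[str]:
        return list(self.geno.columns)

    def __len__(self) -> int:
        return len(self.sites)


def call_genotype(
    ref_count: int,
    alt_count: int,
    min_cov: int = 10,
    min_alt_reads: int = 10,
    hom_freq: float = 0.85,
    min_var_freq: float = 0.02,
) -> int:
    """Call one genotype from (ref, alt) read counts.

    Decision table: depth below ``min_cov`` -> missing; otherwise, with
    f = alt/(ref+alt): f >= hom_freq with enough alt reads -> hom_alt;
    min_var_freq <= f < hom_freq with enough alt reads -> het; anything
    with sub-threshold variant evidence -> hom_ref.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("negative allele counts")
    depth = ref_count + alt_count
    if depth < min_cov:
        return MISSING
    freq = alt_count / depth
    if alt_count >= min_alt_reads:
        if freq >= hom_freq:
            return HOM_ALT
        if freq >= min_var_freq:
            return HET
    return HOM_REF


def call_genotypes_panel(
    allele_counts_by_accession: dict[str, dict[int, tuple[int, int]]],
    sites: pd.DataFrame,
    **thresholds,
) -> GenotypeMatrix:
    """Call genotypes for every accession at every site of ``sites``.

    A site absent from an accession's allele-count table is treated as
    having zero reads (missing call).
    """
    cols = {}
    for acc, counts in allele_counts_by_accession.items():
        cols[acc] = np.array(
            [call_genotype(*counts.get(pos, (0, 0)), **thresholds) for pos in sites.index],
            dtype=np.int8,
        )
    geno = pd.DataFrame(cols, index=sites.index)
    return GenotypeMatrix(sites=sites.copy(), geno=geno)


def classify_sites(matrix: GenotypeMatrix) -> pd.Series:
    """Per-site class in {1, 2, 3, 0} (0 = unclassified)."""
    g = matrix.geno.to_numpy()
    has_ref = (g == HOM_REF).any(axis=1)
    has_het = (g == HET).any(axis=1)
    has_alt = (g == HOM_ALT).any(axis=1)
    cls = np.zeros(g.shape[0], dtype=np.int8)
    cls[has_ref & has_alt & ~has_het] = 1
    cls[has_ref & has_alt & has_het] = 2
    cls[has_het & ~has_alt] = 3
    return pd.Series(cls, index=matrix.geno.index, name="snp_class")


def maf_per_site(matrix: GenotypeMatrix) -> pd.Series:
    """Minor allele frequency per site (two alleles per non-missing call)."""
    g = matrix.geno.to_numpy()
    alt_dose = np.where(g == MISSING, 0, g).sum(axis=1).astype(float)
    n_called = (g != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_dose / (2 * n_called)
    maf = np.minimum(p, 1 - p)
    maf[n_called == 0] = np.nan
    return pd.Series(maf, index=matrix.geno.index, name="maf")


def maf_profile(matrix: GenotypeMatrix, window: int, step: int, length: int) -> pd.Series:
    """Windowed mean MAF along the chromosome (NaN where no sites)."""
    maf = maf_per_site(matrix)
    pos = matrix.sites.index.to_numpy()
    starts = np.arange(0, max(length - window, 0) + 1, step)
    vals = []
    for s in starts:
        sel = (pos >= s) & (pos < s + window)
        vals.append(float(maf.to_numpy()[sel].mean()) if sel.any() else np.nan)
    return pd.Series(vals, index=pd.Index(starts, name="window_start"), name="mean_maf")


def snp_density(
    matrix: GenotypeMatrix,
    mappable: list[tuple[int, int]],
    window: int,
    step: int,
    length: int,
) -> pd.Series:
    """SNPs per kb of mappable sequence per window; NaN where no mappable bp."""
    pos = matrix.sites.index.to_numpy()
    m_starts = np.array([s for s, _ in mappable])
    m_ends = np.array([e for _, e in mappable])
    starts = np.arange(0, max(length - window, 0) + 1, step)
    vals = []
    for s in starts:
        e = s + window
        n = int(((pos >= s) & (pos < e)).sum())
        overlap = np.clip(np.minimum(m_ends, e) - np.maximum(m_starts, s), 0, None).sum()
        vals.append(n / (overlap / 1000) if overlap > 0 else np.nan)
    return pd.Series(vals, index=pd.Index(starts, name="window_start"), name="snp_per_kb")


def tstv_ratio(sites: pd.DataFrame) -> float:
    """Transition/transversion ratio over the site table (NaN if no Tv)."""
    pairs = list(zip(sites["ref"], sites["alt"]))
    ts = sum(1 for p in pairs if p in _TRANSITIONS)
    tv = len(pairs) - ts
    if tv == 0:
        return float("nan")
    return ts / tv
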