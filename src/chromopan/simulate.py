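"""Synthetic annotated chromosome with planted structural variants.

The generator builds a toy chromosome (random background sequence, TE
copies as mutated family consensus placements, genes with coding exons in
the TE complement, a few near-identical duplicate gene pairs), plants the
SV classes the callers are meant to recover — gene PAVs, upCNVs with
divergent extra copies, losses of one duplicate copy, full and partial TE
deletions, group-specific TE insertions, multi-kb deletion blocks and
group-private biallelic SNPs — and emulates the per-accession mapping
summaries with Poisson depth noise, binomial allele-count noise and
per-base read errors.  Raw reads can also be simulated for end-to-end
exercise of the junction matcher.

The panel follows a star phylogeny of groups: SNP alleles and TE
insertions are private to one group, everything else is drawn per
accession.  No panel accession is the reference itself; the reference
control ("CS") is a separate accession with an empty truth, simulated at
a higher depth as in a self-mapping positive control.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .isbp import IsbpMarker, design_isbps
from .loci import LocusSet, build_locus_set
from .reference import GeneModel, MappingSummary, ReferenceModel, TeCopy, nonrepeat_space
from .snp import HOM_ALT, HOM_REF

__all__ = [
    "SimulationConfig",
    "AccessionTruth",
    "SimulatedPanel",
    "generate_reference",
    "plant_accessions",
    "simulate_mapping_summary",
    "simulate_reads",
    "build_accession_sequence",
    "site_table",
    "make_panel",
    "REFERENCE_ID",
    "DUP_SUFFIX",
]

REFERENCE_ID = "CS"
DUP_SUFFIX = "_dup"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults are the toy scale used throughout the test suite: a 1-Mb
    chromosome carrying 100 TE copies (10 families), 60 genes of which 6
    near-identical duplicate pairs, and 12 accessions in 4 groups
    sequenced at 30x; the reference control is sequenced at 85x as in a
    deeply covered self-mapping.  Rates are per accession (per gene / per
    TE / per bp as appropriate).
    """

    chrom_length: int = 1_000_000
    n_te_families: int = 10
    copies_per_family: int = 10
    te_fraction: float = 0.40
    te_copy_divergence: float = 0.02
    n_genes: int = 60
    n_duplicate_pairs: int = 6
    n_accessions: int = 12
    n_groups: int = 4
    gene_pav_rate: float = 0.05
    upcnv_rate: float = 0.05
    downcnv_rate: float = 0.15
    te_full_del_rate: float = 0.08
    te_partial_del_rate: float = 0.08
    te_new_insertion_rate: float = 0.05
    snp_rate: float = 2e-4
    block_deletion_count: int = 3
    block_size: tuple[int, int] = (3000, 8000)
    duplicate_divergence: float = 0.01
    depth: float = 30.0
    reference_depth: float = 85.0
    read_length: int = 100
    base_error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "gene_pav_rate",
            "upcnv_rate",
            "downcnv_rate",
            "te_full_del_rate",
            "te_partial_del_rate",
            "te_new_insertion_rate",
            "duplicate_divergence",
            "base_error_rate",
            "te_copy_divergence",
            "te_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.depth <= 0 or self.read_length <= 0:
            raise ValueError("depth and read_length must be positive")

    def accession_ids(self) -> list[str]:
        return [f"acc{i:02d}" for i in range(self.n_accessions)]

    def group_assignment(self) -> dict[str, str]:
        """Contiguous blocks of accessions per group."""
        accs = self.accession_ids()
        per = -(-len(accs) // self.n_groups)
        return {a: f"G{i // per + 1}" for i, a in enumerate(accs)}


@dataclass
class AccessionTruth:
    """Ground truth of the variants planted in one accession.

    ``snp_genotypes`` covers *every* panel site (group SNPs and divergent
    duplicate sites) with hom-ref/hom-alt codes; pseudo-heterozygosity is
    implied by ``duplicated_genes`` (extra-copy count and divergent-site
    positions), not stored as a genotype.  ``te_deletions`` includes the
    implied full absence of TE insertions owned by other groups.
    """

    accession_id: str
    group: str = ""
    deleted_genes: set[str] = field(default_factory=set)
    duplicated_genes: dict[str, tuple[int, tuple[int, ...]]] = field(default_factory=dict)
    removed_duplicate_copies: set[str] = field(default_factory=set)
    te_deletions: dict[str, str] = field(default_factory=dict)  # full|partial5|partial3
    group_specific_insertions: set[str] = field(default_factory=set)
    deleted_blocks: list[tuple[int, int]] = field(default_factory=list)
    family_amplification: dict[str, float] = field(default_factory=dict)
    snp_genotypes: dict[int, int] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not (
            self.deleted_genes
            or self.duplicated_genes
            or self.removed_duplicate_copies
            or self.te_deletions
            or self.group_specific_insertions
            or self.deleted_blocks
            or self.family_amplification
            or any(g == HOM_ALT for g in self.snp_genotypes.values())
        )


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *stream])


def _acc_stream(accession_id: str) -> int:
    return zlib.crc32(accession_id.encode())


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate) -> np.ndarray:
    """Substitute each base independently with probability ``rate`` (scalar or per-base)."""
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _translate(dna: str) -> str:
    from Bio.Seq import Seq

    trimmed = dna[: len(dna) - len(dna) % 3]
    return str(Seq(trimmed).translate()).replace("*", "X")


def generate_reference(config: SimulationConfig) -> ReferenceModel:
    """Build the annotated toy chromosome (deterministic under the seed)."""
    rng = _rng(config, 0)
    L = config.chrom_length
    n_copies = config.n_te_families * config.copies_per_family

    # feature length plans
    te_base = config.te_fraction * L / n_copies if n_copies else 0
    te_lens = []
    for fam in range(config.n_te_families):
        for _ in range(config.copies_per_family):
            te_lens.append(max(400, int(round(te_base * rng.uniform(0.9, 1.1)))))

    n_singles = config.n_genes - 2 * config.n_duplicate_pairs
    if n_singles < 0:
        raise ValueError("n_genes smaller than 2 * n_duplicate_pairs")

    def gene_plan():
        n_ex = int(rng.integers(1, 6))
        exons = [int(rng.integers(50, 151)) * 3 for _ in range(n_ex)]
        introns = [int(rng.integers(80, 301)) for _ in range(n_ex - 1)]
        length = sum(exons) + sum(introns)
        rel = []
        pos = 0
        for k, ex in enumerate(exons):
            rel.append((pos, pos + ex))
            pos += ex
            if k < len(introns):
                pos += introns[k]
        return length, tuple(rel)

    # one plan per primary gene; duplicate partner reuses it
    plans = [gene_plan() for _ in range(n_singles + config.n_duplicate_pairs)]

    features: list[tuple] = []  # ("te", fam, copy, len) | ("gene", plan_idx, is_dup)
    k = 0
    for fam in range(config.n_te_families):
        for copy in range(config.copies_per_family):
            features.append(("te", fam, copy, te_lens[k]))
            k += 1
    for i in range(n_singles + config.n_duplicate_pairs):
        features.append(("gene", i, False))
        if i >= n_singles:
            features.append(("gene", i, True))
    rng.shuffle(features)

    def feat_len(f):
        return f[3] if f[0] == "te" else plans[f[1]][0]

    total = sum(feat_len(f) for f in features)
    min_gap = 200
    slack = L - total - min_gap * (len(features) + 1)
    if slack < 0:
        raise ValueError(
            f"chrom_length {L} too small for {len(features)} features totalling {total} bp"
        )
    # heavy-tailed gap sizes (Dirichlet with unit shape): mostly short gaps
    # plus occasional multi-kb intergenic stretches, as in real low-copy space
    w = rng.exponential(1.0, len(features) + 1)
    extra = np.floor(slack * w / w.sum()).astype(int)
    gaps = extra + min_gap

    seq = _random_bases(rng, L)
    consensus = [
        _random_bases(rng, te_lens[fam * config.copies_per_family])
        for fam in range(config.n_te_families)
    ]
    superfams = ("RLG", "RLC", "DTM")

    te_set: list[TeCopy] = []
    gene_raw: list[tuple] = []  # (plan_idx, is_dup, start)
    pos = 0
    for gap, feat in zip(gaps, features):
        pos += int(gap)
        ln = feat_len(feat)
        if feat[0] == "te":
            _, fam, copy, _ = feat
            cseq = consensus[fam]
            body = _mutate(rng, cseq[:ln] if ln <= cseq.size else np.resize(cseq, ln), config.te_copy_divergence)
            seq[pos : pos + ln] = body
            te_set.append(
                TeCopy(
                    te_id=f"TE{fam:02d}_{copy:02d}",
                    family=f"FAM{fam:02d}",
                    superfamily=superfams[fam % len(superfams)],
                    start=pos,
                    end=pos + ln,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
        else:
            gene_raw.append((feat[1], feat[2], pos))
        pos += ln

    # duplicate partners: overwrite with a mutated copy of the primary's DNA
    primary_pos = {pi: start for pi, is_dup, start in gene_raw if not is_dup}
    gene_set: list[GeneModel] = []
    for pi, is_dup, start in gene_raw:
        length, rel_exons = plans[pi]
        if is_dup:
            src = primary_pos[pi]
            # purifying selection: coding positions of a retained duplicate
            # diverge ~3x slower than introns/UTR, keeping the pair inside
            # the 95% protein-identity definition of a duplicated gene
            rate = np.full(length, config.duplicate_divergence)
            for s, e in plans[pi][1]:
                rate[s:e] = config.duplicate_divergence / 3
            seq[start : start + length] = _mutate(rng, seq[src : src + length], rate)
        gid = f"G{pi:04d}{DUP_SUFFIX if is_dup else ''}"
        exons = tuple((start + s, start + e) for s, e in rel_exons)
        cds = "".join(seq[s:e].tobytes().decode() for s, e in exons)
        gene_set.append(GeneModel(gid, start, start + length, exons, _translate(cds)))

    breaks = tuple(int(L * f) for f in (0.10, 0.35, 0.65, 0.90))
    model = ReferenceModel(
        chrom_id="chrSim",
        sequence=seq.tobytes().decode(),
        te_set=sorted(te_set, key=lambda t: t.start),
        gene_set=sorted(gene_set, key=lambda g: g.start),
        region_breaks=breaks,
    )
    model.validate()
    return model


def _alt_allele(ref: str, pos: int, seed: int) -> str:
    """Deterministic alternate allele: transition with probability 2/3.

    The 2:1 transition bias plants an expected Ts/Tv ratio of 2.
    """
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 77, pos])
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    if rng.random() < 2 / 3:
        return transition.get(ref, "A" if ref != "A" else "C")
    tvs = [b for b in "ACGT" if b != ref and b != transition.get(ref)]
    return tvs[int(rng.integers(0, len(tvs)))]


def _pair_partner(gene_id: str) -> str:
    return gene_id[: -len(DUP_SUFFIX)] if gene_id.endswith(DUP_SUFFIX) else gene_id + DUP_SUFFIX


def plant_accessions(model: ReferenceModel, config: SimulationConfig) -> list[AccessionTruth]:
    """Sample the per-accession and group-shared variant truth.

    The panel is a star of groups: TE insertion ownership and SNP allele
    privacy are group-level draws, and each deletion class (gene PAVs, TE
    deletions, deletion blocks) is split into a group-shared component —
    carried by every member, mimicking variants fixed in a species — and
    a private per-accession component.  The split preserves the marginal
    per-accession rate: the shared draw uses rate/2 and the private draw
    the conditional complement, so gene_pav_rate=1 still deletes every
    gene everywhere.  CNVs (up and down) are private: they do not mark
    the presence/absence space.  Every truth's ``snp_genotypes`` covers
    the full panel site list so each accession's mapping summary carries
    allele counts at all sites.
    """
    groups = config.group_assignment()
    space = nonrepeat_space(model)
    panel_rng = _rng(config, 999)

    pair_genes = sorted(g.gene_id for g in model.gene_set if DUP_SUFFIX in g.gene_id)
    pairs = [(p[: -len(DUP_SUFFIX)], p) for p in pair_genes]
    paired = {g for ab in pairs for g in ab}
    singles = sorted(g.gene_id for g in model.gene_set if g.gene_id not in paired)
    gene_by_id = model.gene_by_id()
    group_names = sorted(set(groups.values()))

    # Hierarchical lineage signal: besides group-private variation, nested
    # clades of groups (G1+G2, G1+G2+G3, ...) carry shared variants in both
    # the SNP and the deletion channel.  Groups of a pure star with equal
    # signal would join in an arbitrary, channel-dependent order, so SNP-
    # and PAV-derived trees could not agree above the group level; the
    # caterpillar-shaped shared signal makes the super-group topology a
    # recoverable property of the data.
    weights = np.arange(1, len(group_names) + 1, dtype=float)
    scale = weights / weights.mean()
    p_group = weights / weights.sum()
    group_scale = dict(zip(group_names, scale))
    clades = [frozenset(group_names[:k]) for k in range(2, len(group_names))]

    def weighted_group(rng: np.random.Generator) -> str:
        return group_names[int(rng.choice(len(group_names), p=p_group))]

    # panel-level: TE insertion ownership
    owner: dict[str, str] = {}
    for te in model.te_set:
        if panel_rng.random() < config.te_new_insertion_rate:
            owner[te.te_id] = weighted_group(panel_rng)

    # panel-level: lineage-private SNP sites in the non-repeat space; a
    # lineage is one group (60% of sites) or one nested clade of groups
    n_sites = int(round(config.snp_rate * space.total_bp))
    starts = np.array([s for s, _ in space.intervals])
    lens = np.array([e - s for s, e in space.intervals])
    offsets = np.concatenate([[0], np.cumsum(lens)])
    snp_sites: dict[int, frozenset[str]] = {}
    while len(snp_sites) < n_sites:
        flat = int(panel_rng.integers(0, space.total_bp))
        k = int(np.searchsorted(offsets, flat, side="right")) - 1
        pos = int(starts[k] + flat - offsets[k])
        if pos in snp_sites or model.sequence[pos] == "N":
            continue
        if not clades or panel_rng.random() < 0.6:
            snp_sites[pos] = frozenset([weighted_group(panel_rng)])
        else:
            # deeper clades carry proportionally more shared alleles,
            # mirroring the shared-deletion gradient
            p_clade = np.arange(1, len(clades) + 1) / (len(clades) * (len(clades) + 1) / 2)
            snp_sites[pos] = clades[int(panel_rng.choice(len(clades), p=p_clade))]

    n_shared_blocks = (2 * config.block_deletion_count) // 3
    n_private_blocks = config.block_deletion_count - n_shared_blocks

    # shared-deletion layers: one per group (probability scaled by group
    # weight) and one per nested clade (quarter rate); the private draw is
    # the conditional complement, keeping the per-accession marginal at
    # exactly the configured rate for gene PAVs (and approximately for the
    # competing full/partial TE kinds)
    r_pav = config.gene_pav_rate
    r_full, r_part = config.te_full_del_rate, config.te_partial_del_rate
    pav_s = {grp: min(r_pav / 2 * group_scale[grp], r_pav) for grp in group_names}
    full_s = {grp: min(r_full / 2 * group_scale[grp], r_full) for grp in group_names}
    part_s = {grp: min(r_part / 2 * group_scale[grp], r_part) for grp in group_names}
    pav_s_cl, full_s_cl, part_s_cl = r_pav / 4, r_full / 4, r_part / 4

    g_del_genes: dict[str, set[str]] = {}
    g_te_del: dict[str, dict[str, str]] = {}
    g_blocks: dict[str, list[tuple[int, int]]] = {}
    for grp in group_names:
        grng = _rng(config, 500, _acc_stream(grp))
        g_del_genes[grp] = {g for g in singles if grng.random() < pav_s[grp]}
        dels: dict[str, str] = {}
        for te in model.te_set:
            if te.te_id in owner:
                continue
            r = grng.random()
            if r < full_s[grp]:
                dels[te.te_id] = "full"
            elif r < full_s[grp] + part_s[grp]:
                dels[te.te_id] = "partial5" if grng.random() < 0.5 else "partial3"
        g_te_del[grp] = dels
        n_blk = max(1, round(n_shared_blocks * group_scale[grp])) if n_shared_blocks else 0
        g_blocks[grp] = _sample_blocks(grng, model, space, config, n_blk, [])

    c_del_genes: dict[frozenset, set[str]] = {}
    c_te_del: dict[frozenset, dict[str, str]] = {}
    c_blocks: dict[frozenset, list[tuple[int, int]]] = {}
    for ci, clade in enumerate(clades):
        crng = _rng(config, 600, ci)
        c_del_genes[clade] = {g for g in singles if crng.random() < pav_s_cl}
        dels = {}
        for te in model.te_set:
            if te.te_id in owner:
                continue
            r = crng.random()
            if r < full_s_cl:
                dels[te.te_id] = "full"
            elif r < full_s_cl + part_s_cl:
                dels[te.te_id] = "partial5" if crng.random() < 0.5 else "partial3"
        c_te_del[clade] = dels
        # deeper (more inclusive) clades carry more shared blocks, so the
        # distance from a clade member to an outside group grows with the
        # number of splits separating them — the recoverable caterpillar
        c_blocks[clade] = _sample_blocks(
            crng, model, space, config, n_shared_blocks * (ci + 1),
            [b for bl in g_blocks.values() for b in bl],
        )

    def shared_survival(grp: str, s_grp: dict[str, float], s_cl: float) -> float:
        surv = 1 - s_grp[grp]
        for clade in clades:
            if grp in clade:
                surv *= 1 - s_cl
        return surv

    pav_q: dict[str, float] = {}
    te_q: dict[str, tuple[float, float]] = {}
    for grp in group_names:
        c_pav = 1 - shared_survival(grp, pav_s, pav_s_cl)
        pav_q[grp] = (r_pav - c_pav) / (1 - c_pav) if c_pav < 1 else 0.0
        c_f = 1 - shared_survival(grp, full_s, full_s_cl)
        c_p = 1 - shared_survival(grp, part_s, part_s_cl)
        denom = 1 - c_f - c_p
        te_q[grp] = (
            max(r_full - c_f, 0.0) / denom if denom > 0 else 0.0,
            max(r_part - c_p, 0.0) / denom if denom > 0 else 0.0,
        )

    # per-accession draws on top of the shared layer
    truths: list[AccessionTruth] = []
    all_divergent: set[int] = set()
    for acc in config.accession_ids():
        rng = _rng(config, 1000, _acc_stream(acc))
        grp = groups[acc]
        t = AccessionTruth(accession_id=acc, group=grp)

        t.deleted_genes = set(g_del_genes[grp])
        for clade in clades:
            if grp in clade:
                t.deleted_genes |= c_del_genes[clade]
        for g in singles:
            if g not in t.deleted_genes and rng.random() < pav_q[grp]:
                t.deleted_genes.add(g)
        for g in singles:
            if g in t.deleted_genes:
                continue
            if rng.random() < config.upcnv_rate:
                gene = gene_by_id[g]
                sites = []
                for s, e in gene.coding_exons:
                    hit = np.nonzero(rng.random(e - s) < config.duplicate_divergence)[0]
                    sites.extend(int(s + i) for i in hit)
                t.duplicated_genes[g] = (1, tuple(sorted(sites)))
                all_divergent.update(sites)
        for a, b in pairs:
            if rng.random() < config.downcnv_rate:
                t.removed_duplicate_copies.add(b)

        t.te_deletions = dict(g_te_del[grp])
        for clade in clades:
            if grp in clade:
                for te_id, kind in c_te_del[clade].items():
                    t.te_deletions.setdefault(te_id, kind)
        for te in model.te_set:
            if te.te_id in owner:
                if owner[te.te_id] == grp:
                    t.group_specific_insertions.add(te.te_id)
                else:
                    t.te_deletions[te.te_id] = "full"
                continue
            if te.te_id in t.te_deletions:
                continue
            full_q, part_q = te_q[grp]
            r = rng.random()
            if r < full_q:
                t.te_deletions[te.te_id] = "full"
            elif r < full_q + part_q:
                t.te_deletions[te.te_id] = "partial5" if rng.random() < 0.5 else "partial3"

        shared_blocks = list(g_blocks[grp])
        for clade in clades:
            if grp in clade:
                shared_blocks.extend(c_blocks[clade])
        t.deleted_blocks = sorted(
            shared_blocks
            + _sample_blocks(rng, model, space, config, n_private_blocks, shared_blocks)
        )
        truths.append(t)

    # finalize genotypes over the full site list (lineage SNPs + divergent sites)
    for t in truths:
        for pos, lineage in snp_sites.items():
            t.snp_genotypes[pos] = HOM_ALT if t.group in lineage else HOM_REF
        for pos in all_divergent:
            t.snp_genotypes.setdefault(pos, HOM_REF)
    return truths


def _sample_blocks(
    rng: np.random.Generator,
    model: ReferenceModel,
    space,
    config: SimulationConfig,
    count: int,
    existing: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Deletion blocks inside the non-repeat space, clear of genes and TE flanks.

    A 200-bp buffer around genes and interval edges keeps block deletions
    from clipping coding exons or ISBP junction flanks, so the gene-PAV
    and junction truths stay exact.  New blocks avoid ``existing`` ones.
    """
    if count <= 0:
        return []
    pad = 200
    allowed: list[tuple[int, int]] = []
    genes = sorted((g.start - pad, g.end + pad) for g in model.gene_set)
    for s, e in space.intervals:
        s, e = s + pad, e - pad
        cur = s
        for gs, ge in genes:
            if ge <= cur or gs >= e:
                continue
            if gs > cur:
                allowed.append((cur, min(gs, e)))
            cur = max(cur, ge)
        if cur < e:
            allowed.append((cur, e))
    lo, hi = config.block_size
    allowed = [(s, e) for s, e in allowed if e - s >= lo]
    blocks: list[tuple[int, int]] = []
    taken = list(existing)
    attempts = 0
    while len(blocks) < count and attempts < 200:
        attempts += 1
        if not allowed:
            break
        k = int(rng.integers(0, len(allowed)))
        s, e = allowed[k]
        size = int(rng.integers(lo, min(hi, e - s) + 1))
        start = int(rng.integers(s, e - size + 1))
        block = (start, start + size)
        if any(not (block[1] <= b[0] or block[0] >= b[1]) for b in taken):
            continue
        blocks.append(block)
        taken.append(block)
    return sorted(blocks)


# -- deletion geometry -------------------------------------------------------


def _deletion_intervals(model: ReferenceModel, truth: AccessionTruth) -> list[tuple[int, int]]:
    gene_by_id = model.gene_by_id()
    te_by_id = model.te_by_id()
    out = list(truth.deleted_blocks)
    for g in truth.deleted_genes:
        gene = gene_by_id[g]
        out.append((gene.start, gene.end))
    for te_id, kind in truth.te_deletions.items():
        te = te_by_id[te_id]
        mid = (te.start + te.end) // 2
        if kind == "full":
            out.append((te.start, te.end))
        elif kind == "partial5":
            out.append((te.start, mid))
        elif kind == "partial3":
            out.append((mid, te.end))
        else:
            raise ValueError(f"unknown TE deletion kind {kind!r}")
    return _merge(out)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_bp(start: int, end: int, intervals: list[tuple[int, int]]) -> int:
    total = 0
    for s, e in intervals:
        if s >= end:
            break
        total += max(0, min(e, end) - max(s, start))
    return total


def simulate_mapping_summary(
    model: ReferenceModel,
    truth: AccessionTruth,
    config: SimulationConfig,
    markers: list[IsbpMarker] | None = None,
    loci: LocusSet | None = None,
    depth: float | None = None,
) -> MappingSummary:
    """Emulate the mapping-derived tables for one accession.

    Locus depth ~ Poisson(depth x copy ratio); gene counts ~ Poisson over
    coding-exon bp at the gene's copy ratio (0 deleted, 1+k duplicated,
    0.5 per reference locus of a duplicate pair with one copy lost);
    junction support ~ Poisson(depth) when the junction is intact, scaled
    by the probability that a read carries at most 2 sequencing errors;
    allele counts ~ Binomial(site depth, expected alt fraction) with alt
    fraction k/(k+1) at divergent sites of a gene with k extra copies and
    the read-error rate elsewhere.
    """
    depth = config.depth if depth is None else depth
    if markers is None:
        markers = design_isbps(model)
    if loci is None:
        loci = build_locus_set(nonrepeat_space(model), markers)
    rng = _rng(config, 2000, _acc_stream(truth.accession_id))
    eps = config.base_error_rate

    deletions = _deletion_intervals(model, truth)
    gene_by_id = model.gene_by_id()
    doubled = [
        (gene_by_id[g].start, gene_by_id[g].end, 1 + k)
        for g, (k, _) in truth.duplicated_genes.items()
    ]
    halved: list[tuple[int, int]] = []
    for g in truth.removed_duplicate_copies:
        for gid in (g, _pair_partner(g)):
            gene = gene_by_id[gid]
            halved.append((gene.start, gene.end))
    halved = _merge(halved)
    double_sorted = sorted(doubled)

    def ratio(start: int, end: int) -> float:
        n = end - start
        r = 1.0
        r -= _overlap_bp(start, end, deletions) / n
        r -= 0.5 * _overlap_bp(start, end, halved) / n
        for ds, de, mult in double_sorted:
            if ds >= end:
                break
            ov = max(0, min(de, end) - max(ds, start))
            r += (mult - 1) * ov / n
        return max(r, 0.0)

    summary = MappingSummary(accession_id=truth.accession_id)

    for loc in loci:
        summary.locus_depth[loc.locus_id] = float(rng.poisson(depth * ratio(loc.start, loc.end)))

    rl = config.read_length
    for gene in model.gene_set:
        if gene.gene_id in truth.deleted_genes:
            summary.gene_counts[gene.gene_id] = (0, 0.0)
            continue
        if gene.gene_id in truth.duplicated_genes:
            r = 1 + truth.duplicated_genes[gene.gene_id][0]
        elif _overlap_bp(gene.start, gene.end, halved):
            r = 0.5
        else:
            r = 1.0
        lam = depth * gene.exon_bp / rl * r
        summary.gene_counts[gene.gene_id] = (int(rng.poisson(lam)), 1.0)

    p_ok = float(stats.binom.cdf(2, rl, eps)) if eps > 0 else 1.0
    for m in markers:
        intact = _overlap_bp(m.start, m.stop, deletions) == 0
        summary.isbp_support[m.marker_id] = int(rng.poisson(depth * p_ok)) if intact else 0

    own_divergent = {
        pos: k for _, (k, sites) in truth.duplicated_genes.items() for pos in sites
    }
    for pos, gt in sorted(truth.snp_genotypes.items()):
        r = ratio(pos, pos + 1)
        d = int(rng.poisson(depth * r))
        if pos in own_divergent:
            k = own_divergent[pos]
            x = k / (k + 1)
        elif gt == HOM_ALT:
            x = 1.0
        else:
            x = 0.0
        f = (1 - eps) * x + (eps / 3) * (1 - x)
        alt = int(rng.binomial(d, f)) if d else 0
        summary.allele_counts[pos] = (d - alt, alt)

    fam_members: dict[str, list[TeCopy]] = {}
    for te in model.te_set:
        fam_members.setdefault(te.family, []).append(te)
    for fam, members in fam_members.items():
        amp = truth.family_amplification.get(fam, 1.0)
        ref_bp = sum(t.length for t in members)
        acc_bp = 0.0
        for t in members:
            kind = truth.te_deletions.get(t.te_id)
            frac = 0.0 if kind == "full" else 0.5 if kind else 1.0
            acc_bp += t.length * frac
        fam_ratio = amp * acc_bp / ref_bp if ref_bp else 0.0
        for t in members:
            lam = depth * fam_ratio * t.length / rl
            summary.te_weighted_counts[t.te_id] = float(rng.poisson(lam)) * rl / t.length
    return summary


def site_table(model: ReferenceModel, truths: list[AccessionTruth], config: SimulationConfig) -> pd.DataFrame:
    """Panel site table (pos -> ref, alt) for every planted site."""
    positions: set[int] = set()
    for t in truths:
        positions.update(t.snp_genotypes)
        for _, (_, sites) in t.duplicated_genes.items():
            positions.update(sites)
    rows = []
    for pos in sorted(positions):
        ref = model.sequence[pos]
        rows.append((pos, ref, _alt_allele(ref, pos, config.seed)))
    df = pd.DataFrame(rows, columns=["pos", "ref", "alt"])
    return df.set_index("pos")


def build_accession_sequence(
    model: ReferenceModel,
    truth: AccessionTruth,
    config: SimulationConfig,
) -> str:
    """Materialise the accession's chromosome implied by its truth.

    Homozygous-alternate SNPs are substituted in place; divergent extra
    gene copies are appended at the 3' end of the chromosome (their
    placement does not matter to any caller); deleted intervals are then
    excised.  Length = reference - deleted bp + inserted bp.
    """
    seq = np.frombuffer(model.sequence.encode(), dtype=np.uint8).copy()
    sites = site_table(model, [truth], config)
    for pos, gt in truth.snp_genotypes.items():
        if gt == HOM_ALT:
            seq[pos] = ord(sites.at[pos, "alt"])
    gene_by_id = model.gene_by_id()
    inserts: list[np.ndarray] = []
    for g, (k, div_sites) in truth.duplicated_genes.items():
        gene = gene_by_id[g]
        copy = seq[gene.start : gene.end].copy()
        for pos in div_sites:
            copy[pos - gene.start] = ord(sites.at[pos, "alt"])
        inserts.extend([copy] * k)
    deletions = _deletion_intervals(model, truth)
    keep = []
    cur = 0
    for s, e in deletions:
        keep.append(seq[cur:s])
        cur = e
    keep.append(seq[cur:])
    keep.extend(inserts)
    return np.concatenate(keep).tobytes().decode()


def simulate_reads(
    model: ReferenceModel,
    truth: AccessionTruth,
    config: SimulationConfig,
) -> list[tuple[str, str]]:
    """Uniform fixed-length reads with i.i.d. per-base errors.

    Read count is depth x genome length / read length, rounded; reads are
    drawn from the accession's mutated sequence, forward strand (the
    junction matcher checks both strands anyway).
    """
    seq = np.frombuffer(build_accession_sequence(model, truth, config).encode(), dtype=np.uint8)
    rng = _rng(config, 3000, _acc_stream(truth.accession_id))
    rl = config.read_length
    if seq.size < rl:
        raise ValueError("accession sequence shorter than read length")
    n_reads = int(round(config.depth * seq.size / rl))
    starts = rng.integers(0, seq.size - rl + 1, size=n_reads)
    eps = config.base_error_rate
    out = []
    for i, s in enumerate(starts):
        read = seq[s : s + rl].copy()
        if eps > 0:
            hit = np.nonzero(rng.random(rl) < eps)[0]
            for j in hit:
                choices = _BASES[_BASES != read[j]]
                read[j] = choices[rng.integers(0, 3)]
        out.append((f"{truth.accession_id}_r{i}", read.tobytes().decode()))
    return out


@dataclass
class SimulatedPanel:
    """A fully simulated study: reference, truth and mapping summaries."""

    config: SimulationConfig
    model: ReferenceModel
    markers: list[IsbpMarker]
    loci: LocusSet
    truths: list[AccessionTruth]
    summaries: dict[str, MappingSummary]
    reference_summary: MappingSummary
    sites: pd.DataFrame

    @property
    def groups(self) -> dict[str, str]:
        return {t.accession_id: t.group for t in self.truths}

    def truth_of(self, accession_id: str) -> AccessionTruth:
        return next(t for t in self.truths if t.accession_id == accession_id)


def make_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate reference, plant variants, and emulate all mapping summaries."""
    model = generate_reference(config)
    markers = design_isbps(model)
    loci = build_locus_set(nonrepeat_space(model), markers)
    truths = plant_accessions(model, config)

    ref_truth = AccessionTruth(accession_id=REFERENCE_ID)
    # the reference control carries allele-count rows at all panel sites
    if truths:
        for pos in truths[0].snp_genotypes:
            ref_truth.snp_genotypes[pos] = HOM_REF
    summaries = {
        t.accession_id: simulate_mapping_summary(model, t, config, markers, loci) for t in truths
    }
    reference_summary = simulate_mapping_summary(
        model, ref_truth, config, markers, loci, depth=config.reference_depth
    )
    return SimulatedPanel(
        config=config,
        model=model,
        markers=markers,
        loci=loci,
        truths=truths,
        summaries=summaries,
        reference_summary=reference_summary,
        sites=site_table(model, truths, config),
    )
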