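# Methods

`chromopan` implements a chromosome-scale structural-variation (SV) analysis
for a panel of accessions resequenced against a single annotated reference
chromosome, of the kind used for wheat chromosome 3B: presence–absence
variation (PAV) and copy-number variation (CNV) of genes, insertion/deletion
polymorphism of transposable elements (TEs) genotyped through junction
markers, deletion blocks in the non-repeat space, SNP site classes,
dendrogram-based phylogenies of the panel, and pan/core-gene accounting.
The package operates on *mapping summaries* — per-locus depth, per-gene read
counts, junction-support counts, per-site allele counts — that an upstream
aligner pipeline derives from BAM files; alignment itself is out of scope.

## Reference model and coordinates

A chromosome is a sequence plus a TE interval annotation (non-overlapping,
abutting allowed), gene models with coding exons and translated proteins,
and four breakpoints partitioning it into the classical distal (R1, R3),
interstitial (R2a, R2b) and centromeric/pericentromeric (C) segments.
All internal coordinates are 0-based half-open; BED is read natively and
GFF3 (1-based closed) is shifted at the file boundary only. The non-repeat
space is the interval complement of the TE annotation (genes retained).

A locus is "covered" at a mean depth of 5× (configurable), the same
threshold used for junction presence and locus presence throughout.

## ISBP markers and TE inDels

For every TE copy, up to two 150-bp windows are extracted around the 5′ and
3′ junctions, split 75 bp flank / 75 bp TE. The symmetric split maximises
the testable margin on both sides of the junction; windows running past the
sequence ends are skipped. Of two neighbouring windows overlapping by more
than 99 bp only the left-most survives; windows containing N are dropped;
windows whose 150-mer occurs more than once in the reference (either
strand, exact full-length occurrence scan) are dropped as non-unique. The
exact-occurrence uniqueness check is stricter than a short-read-mapper
based check and needs no aligner.

A read supports a junction when it aligns end-to-end within the marker —
ungapped, either strand, at most 2 substitutions — covering at least 20 bp
on each side of the junction. A junction is present at ≥ 5 supporting
reads. Per TE: both junctions present → present; exactly one absent →
partial absence of that side; both absent → full absence; no surviving
marker → untestable. A TE present in every member of one group and fully
absent in every other accession is reported as a group-specific insertion.
Note the intrinsic ambiguity: a full deletion fixed in *all* groups but one
is observationally identical to an insertion private to that group.

Per-family copy number uses multi-mapping-weighted, length-normalised read
counts per TE copy (a read hitting n best placements contributes 1/n to
each; per-copy counts are divided by copy length, giving coverage units).
Family counts are sums over member copies; only families with at least 50×
mean per-copy depth in the reference accession are reported. Fold changes
are normalised by the accession's **median family ratio** (median-of-ratios,
as in DESeq) rather than a total-count factor, so a genuinely amplified
family does not deflate its own fold change; accessions sequenced at
different depths remain comparable.

## Gene PAV and CNV

A gene is absent when less than 10% (strict) of its coding-exon length is
covered. Genes with no read support in the reference's own self-mapping are
excluded up front (self-QC). Copy-number screening uses a two-step
normalisation: raw count / covered fraction (n1), then n1 / total raw count
over all genes of the accession (n2), and the per-gene
log2ratio = log2(n2_accession / n2_reference). PAV genes get NaN rather
than −∞ and are excluded from threshold estimation.

Per accession, a Tukey boxplot of all analyzable gene log2ratios supplies
the thresholds: hinges are the classical fivenum hinges (medians of the
sorted halves, each half including the overall median when n is odd),
fences sit at hinge ± 1.5·IQR, and each whisker is the most extreme datum
inside its fence. Whiskers are computed per accession over all analyzable
genes. A candidate upCNV exceeds the upper whisker; it becomes an upCNV
call only when corroborated by at least one pseudo-heterozygous (class-3)
SNP inside the gene's coding exons — in highly homozygous material, an
apparently heterozygous site marks reads from a slightly divergent extra
copy collapsing onto one reference locus. Whisker outliers *are expected*
under pure sampling noise (that is what a whisker is), which is precisely
why the corroboration step exists; a reference-vs-self comparison produces
candidates occasionally but no corroborated call.

Duplicated reference genes are found by greedy protein clustering in the
CD-HIT style: length-sorted, each sequence joins the best representative
with global-alignment identity ≥ 0.95 and length ratio ≥ 0.5, else founds a
cluster. Identity is identical columns over alignment columns of an exact
global alignment (match +1, mismatch −1, gap open −2 / extend −0.5); the
word-filter heuristics of CD-HIT are unnecessary at desk scale. A downCNV
is a duplicate-cluster member whose log2ratio falls below the lower
whisker. When one copy of a near-identical pair is lost, reads from the
surviving copy split over both reference loci, so *both* pair members drop
to log2ratio ≈ −1 and both are called.

## Non-repeat loci and deletion blocks

Each non-repeat interval is tiled left-to-right into 100-bp loci; a
terminal remainder of 51–99 bp is kept as a short locus (scored by mean
depth like any other), smaller remainders are discarded; the 150-bp ISBP
windows are interleaved by coordinate. Locus presence uses the 5× rule on
mean depth — including for ISBP loci, whose flank half stays covered when
only the TE is deleted, so TE absence is visible to the junction-support
genotyper but not to the locus presence matrix; this is intentional
uniformity, the two channels answer different questions.

Deletion blocks: a sliding window of 50 neighbouring loci (step 5) is
flagged when *more than* half its loci are absent (a 25/50 tie is not
flagged); runs of at least two consecutive flagged windows become blocks,
trimmed to the outermost absent loci so block size reflects deleted
sequence rather than window quantisation; overlapping trimmed blocks merge.
SV positions are profiled in 10-Mb windows at 1-Mb steps and aggregated per
chromosome segment.

## SNPs

Genotypes follow Varscan-style thresholds: minimum depth 10, minimum 10
variant reads, heterozygous between allele frequency 0.02 and 0.85,
homozygous-variant at ≥ 0.85. Sub-threshold variant evidence yields
hom-ref (variant-caller convention) and sub-threshold depth yields missing.
The strand-bias filter of the original caller is dropped: the allele-count
model carries no strand information. Site classes over the panel:
class 1 — both homozygous states, no heterozygote; class 2 — all three
states; class 3 — at least one heterozygote and no homozygous variant
(pseudo-heterozygosity, the upCNV corroborator). MAF counts two alleles
per non-missing call; Ts/Tv is (A↔G + C↔T) over the rest and is undefined
(NaN) without transversions; SNP density is per kb of mappable sequence,
with empty windows missing rather than zero.

## Dendrograms and comparison

Distances between accessions are simple matching — disagreeing positions
over pairwise-complete positions — over class-1/2 genotype codes (SNP tree)
or the binary locus-presence matrix (PAV tree). Clustering is Ward.D2:
the Lance–Williams update applied to squared distances, merge height being
the unsquared updated distance (hence monotone); ties break on the smallest
cluster-id pair, making results order-deterministic. LD pruning of SNPs is
replaced by optional uniform thinning (divergence from the original
pipeline, which used an external LD tool).

Baker's gamma is the Spearman correlation of the two per-leaf-pair fusion
levels (number of clusters present just before the pair first co-clusters);
identical hierarchies give exactly 1 regardless of correlation flavour.
Entanglement is the L1.5 norm of leaf-rank differences between the two
displayed leaf orders, normalised by the reversed-order worst case (0 =
identical orders, 1 = reversed). Significance of gamma uses a
label-permutation null with p = (1 + #{null ≥ observed}) / (1 + n_iter).
Cluster support is an ordinary character bootstrap (resample rows, rebuild,
count containment); multiscale bootstrap probabilities are out of scope.
Note that for few leaves the fusion-level vectors are heavily tied, so
gamma cannot reach −1 on real trees: opposite 4-leaf caterpillars give
−29/60.

## Pan/core accounting

pan = reference genes + novel genes (assembled in ≥ 2 accessions, absent
from the reference); variable = genes affected by PAV or CNV anywhere in
the panel; core = pan − variable, which keeps core + variable = pan exact
by construction. Percentages are integers rounded half away from zero, as
printed. Whole-genome extrapolation applies the chromosome's variable rate
to the genome-wide gene count. When externally printed counts are supplied
the summary reports the computed pan − variable difference as-is, even
where it disagrees with an externally printed core count.

## Synthetic data: what it emulates and what it does not

The generator builds a toy chromosome — default 1 Mb, 10 TE families × 10
copies targeting a 40% TE fraction (copies are consensus placements mutated
at 2%, creating realistic within-family similarity), 60 genes of 1–5 coding
exons in the TE complement, of which 6 near-identical duplicate pairs —
and a panel of 12 accessions in 4 groups at 30× depth. The reference
control ("CS") is simulated at 85× as a deeply covered self-mapping and is
*not* a member of the panel; this allows group-specific TE insertions to be
planted for every group (a TE absent from the reference could not have been
annotated on it; a TE deleted in all non-members is observationally the
same thing).

Planted per accession (defaults, all configurable): gene PAVs at 5%,
upCNVs at 5% (one extra copy, 1% divergent sites in exons → expected alt
fraction k/(k+1) = 0.5 at a collapsed locus), loss of one copy of a
duplicate pair at 15%, full and partial TE deletions at 8% each,
group-specific insertion assignment of 5% of TEs, ~3 deletion blocks of
3–8 kb placed in the non-repeat space clear of genes and TE flanks (so
block deletions never clip exons or junction windows and the class truths
stay disjoint), and background SNPs at 2×10⁻⁴ per non-repeat bp with a
2:1 transition bias (expected Ts/Tv = 2).

The lineage signal is a caterpillar rather than a pure star: variants are
private to one group or shared by a nested clade of groups (G1+G2,
G1+G2+G3, …), with deeper clades carrying proportionally more shared
signal in both the SNP and the deletion channel, and per-group signal
sizes graded. A pure star with equal group signal leaves the order in
which groups join unidentifiable, so SNP- and PAV-derived trees could not
be expected to agree above the group level; the caterpillar makes the full
topology a recoverable property of the data. Deletion rates are split into
a group/clade-shared layer and a private layer whose conditional
probability keeps the per-accession marginal at exactly the configured
rate for gene PAVs (and approximately for the competing full/partial TE
kinds).

Noise models: locus depth ~ Poisson(depth × local copy ratio) with copy
ratio 0 for deleted material, 0.5 per reference locus of a pair with one
copy lost, 1+k for k extra copies; gene counts ~ Poisson over coding-exon
bp at the gene's ratio; junction support ~ Poisson(depth × intact), scaled
by the probability that a 100-bp read carries ≤ 2 sequencing errors (a
read-level model would further scale support by the fraction of read
placements leaving 20 bp on each side, ≈ (rl−40)/rl; the simpler rate is
used and the thresholds hold comfortably at 30×); allele counts ~
Binomial(Poisson site depth, f) with f = (1−ε)x + (ε/3)(1−x) for true alt
dosage x and per-base error ε. Coding positions of retained reference
duplicates diverge at a third of the configured rate (purifying
selection), keeping planted pairs inside the ≥ 95% protein-identity
definition of a duplicate — a pair below that identity could never be a
downCNV candidate by definition. Raw reads (uniform starts, fixed 100 bp,
i.i.d. substitution errors) can be simulated for end-to-end exercise of
the junction matcher; extra gene copies are appended at the 3′ end of the
accession sequence, which no caller inspects positionally.

Not modelled: TE nesting, indel sequencing errors, paired-end fragment
geometry, GC or amplification bias of sorted-chromosome DNA (the upstream
protocol amplifies flow-sorted DNA; no noise term is specified for it, so
none is invented), residual true heterozygosity, and gene-sequence/protein
coupling beyond what the callers read. Passing recovery tests on this
panel therefore demonstrates correctness of the calling logic under the
stated noise models, not performance on real amplified short-read data.

## Problem sizes and determinism

The default test panel (1 Mb, 12 accessions, ~200 markers, ~6,000 loci,
~300 SNP sites) simulates in a couple of seconds and the full suite runs
in well under a minute; read-level simulations in tests use 100–300 kb
fixtures. All randomness flows from a single integer seed through named
`numpy` generator streams (per accession, per group, per stage), so every
artefact is reproducible byte-for-byte; identical seeds give identical
panels, reads and trees.

## Known limitations

* The junction matcher is substitution-only (no gaps); reads with indels
  near a junction are not counted, which slightly understates support at
  realistic indel rates.
* Family fold changes assume the multi-mapping weighting was done upstream;
  the package does not re-derive weights from alignments.
* The PAV locus matrix scores ISBP loci by plain mean depth (see above);
  TE absence enters the PAV dendrogram only indirectly.
* Bootstrap support is plain (first-order) bootstrap; values are not
  comparable to multiscale-bootstrap probabilities.
* `upCNV_candidate` is reported for transparency but is not a final call
  class; counting candidates as calls would make the whisker rule
  self-refuting on null data.
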