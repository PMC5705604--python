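# Methods

This document describes the generative model behind the synthetic
trios, the statistical methods of each analysis module, and the
numerical conventions the package commits to.

## Trio model (`synthio`)

Three strains — two closely related ingroup strains (`ing1`, `ing2`)
and an outgroup (`out`) — descend from a common ancestor with topology
`((ing1, ing2), out)`. Branch lengths (in units of the base
substitution rate) default to 1.4 for the outgroup branch, 0.4 for the
shared ingroup stem and 1.0 for each terminal ingroup branch.
Substitutions are i.i.d. per site, Jukes–Cantor-like (a hit site moves
to one of the other three bases uniformly); indels occur only as
planted events.

A planning pass decides everything positional before any sequence
exists: chromosome classes (acrocentric vs non-acrocentric),
centromeric array intervals, hypomethylated domains inside arrays,
structural variants (on ingroup terminal branches only, so the
outgroup always carries the ancestral state) and TSS loci. Planted SVs
are insertions, deletions and inversions; a configurable fraction is
flanked by ~300-bp direct repeats at ≥ 98 % identity to emulate
NAHR-style breakpoints, the rest are blunt (NHEJ-style).

Centromeric arrays are concatenations of ~171-bp monomers. A small set
of ancestral monomer lineages is shared by all chromosomes; each
chromosome drifts its own lineage variants (chromosome segregation
precedes strain divergence), each copy carries light per-copy jitter,
and strain arrays then mutate along the phylogeny at a class-specific
rate — non-acrocentric arrays diverge at twice the acrocentric rate by
default. Exchange events copy blocks of monomers (size set by
`exchange_block_range`) between acrocentric arrays of the same strain,
homogenizing them; non-acrocentric arrays do not exchange.

Methylation: background CpGs are methylated; CpGs inside planted
hypomethylated domains and inside TSS-linked insertions are
unmethylated. Simulated bisulfite pileups have Poisson (or constant)
coverage with a per-read error rate. Hi-C contact intensity decays
exponentially with distance from a contig's true position;
inter-chromosomal contacts behave as if at a fixed large distance. TSS
tables carry tag counts for both ingroup strains and two-replicate
negative-binomial expression counts; an insertion-linked TSS has its
mean multiplied by `exp(tss_effect)` in the carrier strain.

Every planted feature is recorded in a ground-truth object, including
per-strain coordinate offset maps so ancestor positions can be mapped
into final strain coordinates (`map_position`).

## Coordinates

All user-facing region coordinates (methylation domains, alignment
blocks, SV events, windows) are 1-based and fully closed, so a printed
region has `length = end − start + 1`. Internal arrays are 0-based;
writers convert at the boundary (truth BED files are 0-based
half-open, per the BED convention).

## Satellite repeats (`repeatlib`)

Arrays are decomposed into monomers by local alignment against a
template; monomers cluster into families by single-linkage at 0.90
similarity, where similarity is matched bases over the shorter length
under Needleman–Wunsch alignment. Families with at least 11 members
contribute a representative. For each pair of chromosomes the
best-matching representative pair defines one inter-array similarity
record, categorized by the chromosome classes (AcroAcro, AcroNonAcro,
NonAcroNonAcro). One-sided Mann–Whitney rank-sum tests ask whether
NonAcroNonAcro similarities are lower than each of the other two
categories (exact p-values for small samples, asymptotic otherwise).

Two effects shape this comparison: faster sequence divergence of
non-acrocentric arrays lowers their inter-array similarity, and
exchange between acrocentric arrays raises theirs. Best-match
selection biases every category upward (each record is a maximum over
family pairs), which compresses — but does not invert — the contrast.

## Methylation (`methylome`)

CpG states are called by strict majority of the pileup (ties and empty
positions are no-calls); a concordance filter keeps positions with
coverage in an inclusive band. Segmentation finds maximal single-state
runs per chromosome, tolerating up to 2 opposite-state interruptions,
discarding runs with fewer than 40 same-state calls, and reporting
bounds at the first/last same-state call.

Domain sequences are compared through the k-spectrum kernel: the
k-mer count vector (k = 8) is Euclidean-normalized, the kernel is the
inner product, and the distance is `sqrt(2 − 2K)` — exactly the
Euclidean distance between the normalized spectra, bounded by
`sqrt(2)` for disjoint k-mer sets. UPGMA (average linkage) is
implemented from the definition with deterministic tie-breaking;
merge heights are half the inter-cluster average distance, making the
tree ultrametric. The SVM uses the same spectrum kernel
(precomputed Gram matrix) on non-overlapping 200-bp windows with
stratified five-fold cross-validation or leave-one-chromosome-out.

## Hi-C anchoring (`hicanchor`)

Marker-based ordering places contigs at their median marker position
and flags single-marker and wide-spread placements. The naive-Bayes
assigner models each chromosome's contact profile as a pseudocounted
mean composition with class priors proportional to contig counts and a
Poisson likelihood; posteriors are computed by log-sum-exp. Placement
along the chromosome takes the argmax of an edge-corrected sliding
mean of the binned contact track (window sums divided by in-range
window sizes, so flat tracks stay flat); a flat or weakly peaked track
is flagged low-confidence.

## Structural variants (`svkit`)

Local alignments come from unique 21-mer anchors merged into diagonal
blocks. Chaining is per-strand dynamic programming maximizing total
member score minus gap penalties `min(0.01·(gq + gt), cap)` with the
cap at the median member score; micro-overlaps up to 50 bp (seed
ambiguity at breakpoints) are tolerated and trimmed afterwards. Chain
gaps where one genome's gap exceeds the other's by ≥ 1 kb become
insertion/deletion candidates; opposite-strand blocks spanned by the
chain become inversions; anchor-span asymmetry marks duplications.
Mechanism classification looks for ≥ 50 bp of ≥ 80 %-identity direct
homology in the flanks outside the event (NAHR) versus blunt joins
(NHEJ). Polarization projects 2.5-kb flanks onto the outgroup: an
event is assigned to the branch whose state differs from the outgroup.

Breakpoints of homology-mediated events are ambiguous within the
repeat length (~300 bp), so truth matching and swap-consistency checks
use size tolerances of that order.

## TSS-proximal insertions (`tssins`)

TSSs pair with mid-sized (1–10 kb) insertions within 100 bp in exactly
one strain; the orthologous TSS of the other strain is the control.
Upstream 500-bp windows (strand-aware) are summarized by GC ratio,
CpG ratio and unmethylated-CpG fraction; one-sided paired Wilcoxon
tests ask whether insertion-bearing windows score higher. The
expression screen normalizes counts by median-ratio size factors,
pools a method-of-moments dispersion per group and applies a Wald test
on the log-fold change. With two replicates the Wald test is mildly
anticonservative (~1.6 % rejections at a nominal 1 % under a hard
negative-binomial null); the tests bound this at ≤ 3× nominal.

## Pipeline (`orchestra`)

A flat `key = value` config (with a `trio.`-prefixed generator block,
`CENEVOL_<KEY>` environment overrides and rejection of unknown keys)
drives the run. The simulation stage runs first; each analysis stage
depends only on it, so stages can be toggled independently and a stage
failure is recorded without aborting the rest. Reports carry a config
hash (first 16 hex characters of the SHA-256 of the sorted items) and
are written as JSON plus a text summary.

## Limitations

- The substitution model has no rate heterogeneity, no indel noise
  outside planted events, and no CpG-specific mutation dynamics.
- The SV caller targets mid-to-large (≥ 1 kb) events between highly
  similar genomes; it is not a general-purpose aligner and does not
  handle rearrangements spanning chromosomes.
- The Hi-C model is an exponential-decay caricature; it supports
  classifier and placement validation, not contact-map realism.
- The expression screen's Wald test is anticonservative at very small
  replicate counts; treat its p-values as a screen, not as calibrated
  inference.
- Monomer clustering thresholds (0.90 similarity, 11-member
  representative floor) are tuned to ~171-bp satellites at the
  simulated divergence scale and may need adjustment for other repeat
  families.
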