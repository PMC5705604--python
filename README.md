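# cenevol

Analysis toolkit for trio genome comparisons of centromere evolution,
CpG methylation and structural variation, packaged together with a
synthetic-data generator that plants a known ground truth.

## Scientific problem

Comparing two closely related inbred strains against a more distant
outgroup makes it possible to assign genomic changes to individual
branches of a three-taxon tree. This package implements the analyses
such a trio design enables:

- **Satellite repeat evolution** (`repeatlib`): decompose centromeric
  arrays into ~171-bp monomers, cluster them into families, associate
  best-matching families across chromosomes, and test whether arrays on
  non-acrocentric chromosomes diverge faster than acrocentric ones
  (rank-sum tests on inter-array similarities).
- **Methylation domains** (`methylome`): call CpG methylation states
  from pileups, segment chromosomes into hyper-/hypomethylated domains
  (1-based fully-closed coordinates), and build a k-mer-spectrum UPGMA
  phylogeny of domain sequences; a spectrum-kernel SVM quantifies how
  separable hypomethylated sequence is from its surroundings.
- **Hi-C contig anchoring** (`hicanchor`): order contigs by genetic
  markers, then assign and place unanchored contigs with a naive-Bayes
  classifier over chromosome-wide Hi-C contact profiles.
- **Structural variants** (`svkit`): chain local alignments by dynamic
  programming, call insertions/deletions/inversions/duplications from
  chain gaps, classify mechanisms (NAHR vs NHEJ) from breakpoint
  homology, and polarize events onto tree branches using the outgroup.
- **TSS-proximal insertions** (`tssins`): pair transcription start
  sites with nearby strain-specific insertions, compare upstream-window
  GC/CpG/methylation statistics with paired one-sided tests, and screen
  expression counts for insertion-linked changes.
- **Synthetic trios** (`synthio`): simulate three strains descending
  from a common ancestor — centromeric satellite arrays with exchange
  and lineage structure, hypomethylated domains, SVs on ingroup
  branches, Hi-C contacts, contig maps and TSS tag/expression counts —
  with every planted feature recorded as ground truth.
- **Pipeline** (`orchestra` + the `cenevol` CLI): a config-driven
  driver that simulates a trio, runs all analysis stages and writes a
  JSON report.

## Running the tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end checks; each validates
one claim against an independent oracle (brute-force enumeration, an
alternative implementation, or the planted truth of a synthetic trio).

## Worked example

Run the full pipeline on a small synthetic trio:

```sh
cat > demo.cfg <<'CFG'
seed = 7
outdir = demo_run
trio.n_chromosomes = 4
trio.chrom_length = 300000
trio.array_length_range = 15000,25000
trio.n_insertions = 1
trio.n_deletions = 1
trio.tss_count = 4
trio.tss_background = 10
trio.contigs_per_chromosome = 6
run_repeats = false
CFG
cenevol run --config demo.cfg
```

which prints a report like:

```
cenevol 0.1.0 report (seed=7, config=c3a93ad8688fa758)
  simulate: n_chromosomes=4, n_planted_svs=4, n_planted_tss=14
  repeats: skipped
  methylation: n_hypo_domains_in_arrays=24, n_leaves=24, n_planted_domains=24, newick=(...)
  hic: leave_one_out_accuracy=1, n_contigs=24
  sv: insertion_deletion_ratio=3, n_deletions=2, n_events=8, n_insertions=6
  tss: n_novel=0, n_pairs=4, n_significant_expression=1, n_tss=14
```

and writes `demo_run/report.json`. Individual steps are also exposed:

```sh
cenevol simulate --seed 1 --outdir trio_out      # FASTA + truth + tables
cenevol meth-segment trio_out/methylation_ing1.tsv | head
cenevol monomer-similarity ACGTACGT ACGTACGA     # -> 0.875000
cenevol tss-screen trio_out/tss_counts.tsv
```

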