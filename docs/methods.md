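# Methods

## The clustering model

`homeoclust` formalizes a two-stage definition of a *gene cluster* over
assembled transcriptome contigs of an allopolyploid:

1. **Top-hit binning.** Every contig is translated in six frames; each
   stop-to-stop ORF of ≥ `min_orf_aa` residues (default 30, start codon not
   required — EST contigs are frequently 5′-truncated) is aligned against
   the reference proteome by Smith–Waterman. A contig is *annotated* if its
   best hit has E < `tophit_evalue_max` (default 10⁻⁵, strict). Top-hit
   granularity is the gene/locus: a trailing `.<digits>` isoform suffix is
   stripped (configurable).
2. **Within-bin homology edges.** For every pair of contigs in the same bin,
   the longest ORF of one is aligned to the six-frame translation of the
   other (stop-free segments only); the pair E-value is the minimum over the
   two query/subject orientations, with search space m = peptide length,
   n = subject length / 3. Pairs with E < `edge_evalue_max` (default
   10⁻¹⁰⁰, strict) become edges.

Clusters are the connected components of the edge graph within each bin
(single linkage — membership is defined by homology "to at least one other
member", which is exactly a connected component). Isolated annotated
contigs are singleton clusters. The representative of a cluster is the
member with the lowest top-hit E-value (ties: higher bit score, then
lexicographically smallest id). Cluster ids `<gene>.<ordinal>` are assigned
by each component's smallest member id, making output deterministic and
independent of input order.

## Alignment and statistics

Local alignment is Smith–Waterman with affine gaps: a gap of length k costs
`gap_open + (k−1)·gap_extend` (defaults 11/1), substitution scores from
BLOSUM62. `X` is score-neutral (0 against everything); stops never appear
inside alignable segments because subjects are split at stops. Raw scores
are normalized to bits, S′ = (λS − ln K)/ln 2, and E = m·n·2^(−S′) with no
finite-size correction (second-order at the E ranges used here). The default
λ = 0.267, K = 0.041 are the published gapped BLOSUM62/11/1 values. Low-
complexity filtering and composition-based statistics are not modelled.

The reported alignment ends at the first optimal cell in query-major order
and the traceback prefers substitutions over gaps, then gaps in the query —
a deterministic convention; co-optimal alignments share the same score, so
none of the downstream decisions depend on it.

**Fast path.** Database searches use an inverted exact 5-mer index: a
query/subject pair is aligned only if it shares at least one 5-mer. Every
alignment that is run is the full dynamic program, so any reported hit
carries the exact optimal score; pairs without a shared 5-mer are skipped.
At the identities relevant here (≥ 75% amino-acid identity over ≥ 60
residues) the expected number of shared 5-mers is ≫ 1, so the filter is
effectively lossless for hits that could pass any of the pipeline's cutoffs;
`exhaustive=True` disables it, and the test suite verifies fast/exhaustive
agreement.

## Thresholds

| parameter | default | meaning |
|---|---|---|
| `tophit_evalue_max` | 1e-5 | annotation cutoff, strict `<` |
| `edge_evalue_max` | 1e-100 | within-cluster homology edge, strict `<` |
| `ortholog_score_min` | 150 | bit score must be strictly greater |
| `ortholog_coverage_min` | 0.20 | fraction of the query ORF aligned, `≥` |
| `min_read_length` | 40 bp | reads strictly shorter are discarded |
| `bootstrap_replicates` | 1000 | NJ bootstrap |

Boundary semantics are deliberate and tested: length 40 passes, bit score
150 fails, coverage 0.20 passes, E exactly 1e-5 fails.

An arithmetic consequence worth stating explicitly: under λ = 0.267,
K = 0.041, E < 10⁻¹⁰⁰ at search spaces of order 10⁴–10⁵ requires a raw
score near 890, i.e. roughly **170 aligned near-identical residues** (the
BLOSUM62 diagonal averages ≈ 5.3). Contigs or fragments carrying less
aligned coding sequence than that can never join a cluster, no matter how
similar they are. This is intrinsic to the clustering definition, not an
implementation artifact, and it is the sole cause of cluster over-counting
on synthetic data (see *Recovery behaviour* below).

## Read cleanup

Adapter trimming removes, per adapter and per end, the best terminal
occurrence (fewest mismatches under `max_mismatch_rate`, ties toward
removing more) together with everything outward of it; occurrences are
terminal if they start within one adapter length of an end, and when the
two windows overlap on short reads the occurrence is attributed to the side
that discards less sequence. Interior occurrences are untouched. The two
library PCR primers ship as the default adapter set. Poly-T (5′) and poly-A
(3′) runs of ≥ 10 bases are removed; a run may contain up to one
non-matching base, never two consecutively, and must end on a matching base
— a conservative generalization, configurable, since the original
protocol's tolerance for interrupted tails is unknown. Cleanup iterates to
a fixed point (removing a tail can expose an adapter) and then drops reads
shorter than 40 bp.

## The simulator

`simulate_transcriptome` emulates the data regime the pipeline targets, not
sequencing chemistry:

- **Genes** are independent random CDSs (uniform sense codons, ATG start,
  terminal stop on emission), length uniform in `cds_length_range`
  (default 150–500 codons). Independence puts between-family divergence at
  saturation, satisfying any `family_divergence` ≥ 0.5; sub-saturation
  paralog families are not modelled.
- **Homeologs**: each of `n_subgenomes` (default 3) copies diverges from
  the gene's ancestor by an independent Jukes–Cantor branch of
  `homeolog_divergence` substitutions/site (default 0.03). The per-site
  change probability is ¾(1−e^(−4d/3)); two homeologs therefore differ at a
  fraction ¾(1−e^(−8d/3)) of sites, the closed form exposed as
  `expected_identity`. Which sites mutate is drawn once; codons that would
  become stops have only their target nucleotides redrawn, preserving the
  per-site substitution probability exactly (verified by a 3-standard-error
  calibration test). Frame-preserving single-codon indels occur at
  `indel_rate` (default 0.001/site).
- **Reference proteome**: one protein per gene, translated from the
  ancestor after a `reference_divergence` branch (default 0.15) — each gene
  has exactly one correct top-hit target.
- **Contigs**: each homeolog survives with probability
  1 − `missing_homeolog_prob` (default 0.9) and is emitted as full-length,
  5′ fragment or 3′ fragment per `fragment_profile` (default
  0.5/0.25/0.25, mirroring full-length plus end-purified library types);
  fragments cover a uniform 40–100% of the CDS from the respective end.
  Every contig receives independent random UTR padding (20–60 nt per intact
  end). Ground truth records (gene, subgenome, fragment type) per contig.

The generator is byte-reproducible under its seed. What it does *not*
emulate — 454 homopolymer miscalls, chimeric contigs, expression-dependent
coverage, real codon usage and amino-acid composition — means that passing
recovery tests demonstrate the correctness and selectivity of the clustering
machinery, not the error tolerance of the original assembly workflow.

## Recovery behaviour on synthetic data

Pair precision is 1.0 in every tested condition: with unrelated gene
families the stringent edge threshold never merges contigs of different
genes. Recall and the cluster count are limited by the ~170-residue edge
requirement derived above: identical homeologs of a gene shorter than
~170 codons, and any fragment carrying less than ~170 codons of CDS, remain
singletons. Under the default conditions (200 genes, fragmentation on) this
yields adjusted Rand ≈ 0.75 and a cluster count ≈ 1.6× the gene count; in
the zero-divergence, full-length limit all genes of ≥ ~170 codons
consolidate exactly while the few shorter ones split. Raising the lower CDS
bound (or relaxing `edge_evalue_max`) moves recovery toward the ideal; both
are left at their documented defaults.

## Evaluation metrics

Pair precision/recall count unordered contig pairs; the adjusted Rand index
is computed from the partition contingency table, (Index − Expected)/(Max −
Expected). Contigs the pipeline leaves unannotated are scored as singletons
(keeping the two partitions on the same universe) and their count is
reported separately. ARI is undefined (NaN) below two contigs; identical
degenerate partitions score 1 by convention.

## Neighbor joining

Distances are p-distances with pairwise deletion (only columns where
neither sequence is gapped are compared; a pair with no comparable columns
is an error); an optional Kimura protein correction −ln(1 − p − p²/5) is
available. The agglomeration minimizes Q(i,j) = (n−2)d(i,j) − rᵢ − rⱼ,
breaking ties toward the lowest index pair, with the standard branch-length
and reduction formulas and a closed-form final trifurcation; negative
branch lengths are clamped to zero with the deficit moved to the sibling
edge so additive inputs are recovered exactly (topology and all leaf-to-leaf
path lengths, verified to 10⁻⁹). Bootstrap supports resample alignment
columns with replacement, rebuild the tree per replicate, and report the
percentage of replicates containing each internal bipartition of the
full-data tree, as integer internal-node labels in newick. Alignments are
consumed, not computed.

## Longest-ORF tie-break

When the maximal stop-free length is achieved in several frames, the
lexicographically smallest peptide wins (then frame order +1,+2,+3,−1,−2,−3,
then 5′-most). Lexicographic-first makes the choice strand-symmetric:
`longest_orf(s)` and `longest_orf(revcomp(s))` always return the same
peptide, which a frame-order-first rule cannot guarantee. Note that the
reverse complement of every stop codon is a sense codon, so stop-dense
sequences still carry ORFs on the opposite strand — six-frame intuition
built on the forward frames alone is unreliable.

## Problem sizes

Default test and acceptance runs use 100–500 simulated genes (300–1300
contigs), 8-taxon trees with 100 bootstrap replicates, and oracle sweeps of
500–1000 random instances; these sizes give stable statistics (3-SE
calibration margins, χ² at α = 0.01) while keeping a full run in the
minutes range on one CPU.
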