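# Methods

This note documents the models, estimators and design choices behind the
package, what the synthetic cohorts do and do not emulate, and the
numerical conventions a user should know before trusting or extending the
results.

## Data model

A clonotype is keyed by its V gene, CDR3 nucleotide sequence, CDR3
amino-acid sequence and J gene, and carries a UMI count — the number of
distinct cDNA molecules observed, which we treat as a molecule count (so
counts are integers ≥ 1 and frequencies are always recomputed as
count/total). Segment names are matched at the gene level; allele suffixes
(`*01`) are stripped on input. Rows whose amino-acid CDR3 contains a stop
symbol or whose nucleotide length is not three times the amino-acid length
are dropped on read (out-of-frame junctions carry no receptor).

Amino-acid-level analyses first collapse nucleotide variants by
(V gene, CDR3aa), summing counts. The same CDR3 under different V genes
remains distinct. Nucleotide-level analyses key on (V, J, CDR3nt); the J
segment is included there because the nucleotide junction identifies a
specific rearrangement event. Whether amino-acid clonotypes should also
require J agreement is genuinely open; we match V + CDR3aa, the convention
used for convergence analyses, and expose the key choice through the
`match_level` argument.

## Diversity

All metrics are computed on repertoires downsampled to a fixed depth
(default 1000 UMIs) by multivariate hypergeometric sampling — molecules are
drawn without replacement, since they are physical objects, not an
infinite multinomial pool. Samples under 700 UMIs are excluded; samples
between the threshold and the target depth are used at full depth.
Defaults are parameters, not constants.

* Chao1 uses the bias-corrected form S + n₁(n₁−1)/(2(n₂+1)), which is
  defined when there are no doubletons (the classical form divides by n₂).
* The normalized Shannon–Wiener index is H/ln S with natural logarithms —
  the only normalization for which a perfectly even repertoire scores
  exactly 1. The single-clonotype case is defined as 0; the exactly-even
  case returns 1.0 by construction rather than up to rounding.
* Group tests are Welch's t (unequal variances) of each challenge versus
  control; "parametric t-test" admits either pooled or Welch variants and
  Welch is the safer default. Metrics are computed on one downsample by
  default (`n_resamples` averages more).
* Diversity is computed on clonotypes as extracted (nucleotide level) by
  default; `level="aa"` aggregates first.

## Overlap

F2 between two top-N-renormalized repertoires is Σ√(p·q) over shared
clonotype keys. Two conventions deserve note:

* Frequencies are renormalized within the top-N selection before F2, so
  identical samples score exactly 1. Computing on full-sample frequencies
  instead would shrink every value by the tail mass without changing the
  ordering.
* Top-N selection shuffles rows with a seeded generator before a stable
  descending sort, so ties among equal counts (mostly counts 1–2) are
  broken randomly rather than alphabetically.

The distance for embedding and trees is d = 1 − F2: bounded, monotone, and
zero for identical samples. MDS is classical (Torgerson) by default with a
SMACOF option; the reported stress is Kruskal stress-1. Dendrograms use
average linkage (UPGMA), the common choice for repertoire trees, and are
serialized as newick with branch lengths (a two-sample tree is a cherry
with branches d/2).

## Motif clusters

The pooled unique CDR3 set forms a graph with edges joining equal-length
sequences differing at exactly one position. Construction masks one
position at a time and buckets sequences by the remainder, so it scales
near-linearly and is tested against an all-pairs oracle.

Enrichment per CDR3: observed = degree in the pooled graph; expected = the
CDR3's neighbor count within a baseline pool of random rearrangements,
scaled by |sample|/|baseline|; p = upper-tail Poisson with rate
max(expected, 1/|baseline|) — the floor avoids degenerate zero-rate
p-values. Correction is Benjamini–Hochberg at q = 0.05 by default; a CDR3
must also have at least one observed neighbor. These testing choices are
conventions of this implementation (the underlying enrichment idea fixes
only "more neighbors than expected"); they are validated by simulation:
on baseline-only samples the selected fraction stays below the nominal
level, and planted motifs at percent-scale frequencies are recovered
essentially completely.

Clusters are connected components of the enriched subgraph with ≥2 members
(singletons carry no homology evidence); ids are assigned by descending
size, then lexicographically smallest member — the numbering is
reproducible but otherwise arbitrary. Because edges require equal length,
clusters are length-homogeneous by construction. Cluster PWMs weight member
sequences by their total clonotype frequency across the cohort; columns are
the 20 residues, rows sum to 1, and the files render directly with
standard logo tools. The cluster × sample frequency matrix is ordered by
average-linkage hierarchical clustering of log₁₀(f + 10⁻⁵) (the
pseudo-count keeps absent clusters finite on the log scale).

The baseline size defaults to 10× the pooled unique CDR3 count — large
enough that expected-neighbor estimates are stable, small enough to stay
cheap; it is a parameter.

## Conversion and iNKT

Conversion between same-mouse eCD4/eTreg pairs is the nucleotide-level F2
of their top-100 clonesets (pairs with a sample under 100 clonotypes are
ineligible). We report the overlap statistic itself rather than a
directional rate: the direction of plasticity is a biological
interpretation, not something the repertoire overlap can resolve. Group
comparisons run per tissue against that tissue's control group, so the
challenge-site and systemic (spleen) contrasts are separate. The invariant
NKT fraction sums the frequencies of clonotypes matching TRAV11 +
CVVGDRGSALGRLHF + TRAJ18 exactly, at any nucleotide realization — it is
invariant to amino-acid aggregation and to splitting the clonotype into
synonymous variants.

## Synthetic cohorts: what they emulate, and what they do not

The recombination model draws a V 3′ tail, trims up to 6 nt from each
side, inserts 0–11 uniform random nucleotides and appends a trimmed J 5′
head, keeping in-frame stop-free products by rejection. Segments are
synthetic but mouse-style: ≥20 TRAV and ≥20 TRAJ, names TRAV1…/TRAJ1…
(including the literal TRAV11/TRAJ18), tails beginning with the conserved
cysteine codon and heads ending in a phenylalanine codon. The insertion
window of 12 lengths makes the raw in-frame fraction exactly 1/3, which
gives the rejection sampler a closed-form check. Segment usage is fixed at
package-constant Dirichlet draws.

Cohorts follow the study shape: 3–7 mice per challenge group, seven
possible tissues, two subsets, per-sample UMI totals log-normal around
subset means of 1360 (eTreg) and 3741 (eCD4) — the study's per-subset
means scaled down tenfold so the full demo generates in seconds — and
clone sizes Zipf(exponent 2.0) truncated at the sample depth, producing
the strong clonal skew the diversity metrics must detect. Planted
structure:

* Challenge motifs: a consensus CDR3 with three variable positions (seven
  amino-acid variants forming a Hamming-1 star), a fixed V/J, total
  frequency 0.05 per carrying sample, present at the challenge site and
  its draining node (lung + MLN). Each (mouse, subset) realizes the
  variants with independently drawn synonymous codons — the same
  amino-acid motif from different nucleotide rearrangements, i.e. explicit
  convergent recombination. Motifs are planted per subset because the
  eTreg and eCD4 responses are clonally distinct.
* Tissue-resident motifs: same construction, planted in one tissue across
  all challenges including control.
* Conversion: identical (V, J, CDR3nt) clonotypes with matched target
  frequencies in both subsets of a mouse, only at designated
  challenge/tissue sites (demo: LLC and PYMT lung at fraction 0.25 over
  15 clonotypes).
* iNKT: the exact invariant clonotype spiked at a set frequency (demo: 5%
  in LLC lung eTreg).

Not emulated: thymic selection and real germline segments (sequences are
synthetic), TCRβ pairing, cross-reactive clones spanning challenges,
shared tumor-associated motifs between cancer challenges, and biological
variability in motif frequency between mice beyond mild noise. Passing
tests therefore demonstrate that the estimators and the pipeline recover
structure of the planted kind at realistic scales and calibrate correctly
under the null — not that any particular biological effect size would be
detectable in real data.

## Scales, tolerances, degenerate inputs

Test and demo runs use the tenfold-scaled cohort with correspondingly
scaled analysis parameters (downsample depth 500 / minimum 350, overlap
top-300 / minimum 100 clonotypes); package defaults remain 1000/700,
top-1000/700 and top-100/100. Simulation-backed checks use 10–100
replicates or 20 seeds with majority criteria. Frequency invariants hold
to 1e-9 (per clonotype) and 1e-6 (per sample); F2 symmetry to 1e-12.
Empty repertoires are errors for all estimators; a single-clonotype
repertoire has normalized Shannon 0; downsampling to more molecules than a
sample holds raises directly but is an exclusion (not an error) in
pipeline context. All randomness is addressed by (seed, stage labels)
through CRC32-hashed seed sequences, so outputs are byte-identical across
runs and independent of stage order.
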