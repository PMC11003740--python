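# repseq

Analysis of murine TCRα repertoires from effector regulatory (eTreg) and
conventional (eCD4) CD4⁺ T cells across tissues and antigenic challenges.
The package is aimed at immunologists working with UMI-corrected clonotype
tables (one row per clonotype: UMI count, frequency, CDR3 nucleotide and
amino-acid sequence, V/J segments) who want to quantify clonal focusing,
repertoire convergence, motif formation, subset plasticity and tissue
residence — and at methodologists who need a fully synthetic, ground-truthed
test bed for those analyses.

## What it computes

**Depth-normalized diversity.** Samples are downsampled without replacement
to a fixed number of UMI-labeled cDNA molecules (default 1000; samples with
<700 UMIs excluded) and summarized by observed diversity *S*, the
bias-corrected Chao1 lower bound

&nbsp;&nbsp;&nbsp;&nbsp;Chao1 = *S* + *n*₁(*n*₁−1) / (2(*n*₂+1)),

with *n*₁/*n*₂ the singleton/doubleton counts, and the normalized
Shannon–Wiener index *H*/ln *S* with *H* = −Σ *pᵢ* ln *pᵢ*. Groups are
compared to control with Welch's t-test (star bins \*p<0.05 … \*\*\*\*p<0.0001).

**Clonotype-weighted overlap (F2).** For two repertoires reduced to their
top-N clonotypes (default 1000; ties among equal counts broken by a seeded
shuffle) and renormalized,

&nbsp;&nbsp;&nbsp;&nbsp;F2 = Σ_k √(*p_k q_k*)

over clonotype keys shared by both samples — (TRAV, CDR3aa) at the
amino-acid level, (TRAV, TRAJ, CDR3nt) at the nucleotide level. All-vs-all
F2 matrices feed an MDS embedding and an average-linkage dendrogram via the
distance d = 1 − F2.

**CDR3 motif clusters.** Pooled unique CDR3s form a graph with edges at
Hamming distance 1; each CDR3's neighbor count is tested (one-sided
Poisson, BH-corrected) against the count expected from a large pool of
random V(D)J rearrangements; connected components of the enriched CDR3s are
the convergent motif clusters, each with a position frequency matrix and a
cluster × sample frequency matrix.

**Conversion and iNKT.** eCD4→eTreg plasticity is scored as the
nucleotide-level F2 of the top-100 clonotypes of matched same-mouse subset
pairs (samples with <100 clonotypes excluded); the invariant NKT clonotype
(TRAV11-CVVGDRGSALGRLHF-TRAJ18) is tracked as a summed per-sample
frequency.

**Synthetic cohorts.** A seeded V(D)J recombination simulator (synthetic
mouse-style TRAV/TRAJ segments, junctional trimming, N insertions) doubles
as the enrichment null and as a cohort generator that plants convergent
challenge motifs (same amino-acid variants, different nucleotide
rearrangements per mouse and subset), tissue-resident motifs, site-specific
subset-shared clonotypes and NKT spikes — with ground truth attached for
validation.

## Worked example

```python
import numpy as np
import repseq as rs

cohort = rs.generate_cohort(rs.demo_design(0))   # 168 synthetic samples
table, stats = rs.conversion_table(cohort, rng=np.random.default_rng(0))
sig = stats[(stats.p < 0.05) & (stats["mean"] > stats.mean_control)]
print(sig[["tissue", "challenge", "mean", "p", "stars"]])
```

prints

```
tissue challenge     mean        p stars
  lung       LLC 0.308566 0.000052  ****
  lung      PYMT 0.296656 0.001735    **
```

i.e. only the two tumor-challenge lung groups — where the demo design
plants clonal subset sharing — show matched-pair nucleotide overlap above
control (mean F2 ≈ 0.3, against a control floor of ~0.001), exactly the
local, tumor-restricted plasticity signature the analysis is built to
detect. The scripts in `examples/` walk through each capability (diversity,
overlap/MDS/dendrogram, motif clusters, conversion/iNKT) the same way, and
`repseq --help` exposes the pipeline as a command-line tool
(`simulate`, `diversity`, `overlap`, `clusters`, `conversion`, `inkt`,
`run`, `demo`).

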