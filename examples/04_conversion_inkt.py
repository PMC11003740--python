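"""eCD4 -> eTreg conversion scoring and invariant NKT tracking.

Conversion is read from nucleotide-level overlap of the top-100 clonotypes
of matched same-mouse eCD4/eTreg pairs: identical (V, J, CDR3nt)
rearrangements in both subsets imply a shared clonal origin.  The demo
cohort plants conversion only at the LLC and PYMT lung sites, plus a 5%
invariant NKT spike in LLC lung eTreg.
"""

import numpy as np

import repseq as rs
from repseq.pipeline import demo_design

cohort = rs.generate_cohort(demo_design(0))

table, stats = rs.conversion_table(cohort, top_n=100, min_clonotypes=100,
                                   rng=np.random.default_rng(0))
summary = (table[table.eligible]
           .groupby(["tissue", "challenge"]).f2_nt.mean().unstack(0).round(4))
print("mean matched-pair F2 (nucleotide level, top-100):")
print(summary.to_string())

sig = stats[(stats.p < 0.05) & (stats["mean"] > stats.mean_control)]
print("\ngroups above control (Welch p < 0.05):")
print(sig[["tissue", "challenge", "mean", "p", "stars"]].to_string(index=False))

ink = rs.inkt_frame(cohort)
spike = ink[(ink.challenge == "LLC") & (ink.tissue == "lung") & (ink.subset == "eTreg")]
print(f"\niNKT ({rs.INKT_V}-{rs.INKT_AA}-{rs.INKT_J}) fraction, "
      f"LLC lung eTreg: {spike.inkt_fraction.mean():.4f}")
print(f"iNKT fraction elsewhere (max): {ink.inkt_fraction.drop(spike.index).max():.4f}")

print("""
Only the LLC and PYMT lung groups show nucleotide-level subset sharing —
the planted local, tumor-associated eCD4 -> eTreg plasticity — while spleen
pairs and other challenges stay at the coincidence floor.  The NKT fraction
recovers the planted 5% spike and is zero elsewhere.""")
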