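"""CDR3 homology clusters against the recombination null.

Pools CDR3s from challenged lung eTreg repertoires, scores each CDR3's
Hamming-1 neighbor count against a pool of random V(D)J rearrangements, and
extracts the enriched connected components (convergent motif clusters) with
their position frequency matrices.
"""

import numpy as np

import repseq as rs
from repseq.pipeline import demo_design
from repseq.simulate import generate_baseline

cohort = rs.generate_cohort(demo_design(0))
lung = cohort.filter(tissue="lung", subset="eTreg")
pooled = sorted({c.cdr3_aa for r in lung for c in r.clonotypes})
print(f"pooled unique CDR3s: {len(pooled)}")

baseline = [c.cdr3_aa for c in
            generate_baseline(rs.default_model(), 10 * len(pooled),
                              np.random.default_rng(0))]
records = rs.neighbor_enrichment(pooled, baseline, alpha=0.05, correction="bh")
selected = {r.cdr3_aa for r in records if r.selected}
print(f"enrichment-selected CDR3s: {len(selected)}")

graph = rs.build_cdr3_graph(pooled)
clusters = rs.extract_clusters(graph, selected)
print(f"motif clusters (connected components, >= 2 members): {len(clusters)}\n")

for cl in clusters[:3]:
    cl = rs.cluster_pwm(cl, cohort)
    print(f"cluster {cl.cluster_id}: {len(cl)} members, consensus {cl.consensus}")

truth = cohort.ground_truth["challenge_motifs"]
hit = max(len(set(clusters[0].members) & v) / len(set(clusters[0].members) | v)
          for v in truth.values())
print(f"\nbest Jaccard of the top cluster vs a planted motif: {hit:.2f}")

print("""
A cluster is a set of CDR3s one substitution apart that is denser than
random rearrangement statistics predict — the signature of antigen-driven
convergent selection.  The consensus/PWM summarizes the motif; the Jaccard
line confirms the top cluster is a planted ground-truth motif.""")
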