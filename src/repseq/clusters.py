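"""CDR3 sequence-homology clustering against a recombination null.

The procedure (TCRNET-style):

1. pool all CDR3 amino-acid sequences and build a graph on the unique set,
   with edges joining sequences at Hamming distance 1 (equal length, one
   substitution);
2. for every CDR3, compare its observed neighbor count with the count
   expected from a large pool of random V(D)J rearrangements (the null of
   recombination statistics without antigen selection), testing the excess
   with a one-sided Poisson tail and BH correction;
3. connected components of the enriched CDR3s are the motif clusters; each
   gets a per-position residue frequency matrix (PWM) and a per-sample
   frequency (summed frequency of member clonotypes).

Graph construction is index-based (mask one position, bucket by the rest),
i.e. near-linear in the number of sequences rather than all-pairs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from ._codons import AA_ALPHABET
from .repertoire import Clonotype, Cohort, Repertoire


@dataclass
class CDR3Graph:
    """Hamming-1 graph over unique CDR3 amino-acid sequences."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def degree(self, cdr3: str) -> int:
        return self.graph.degree(cdr3)


def _masked(s: str):
    for i in range(len(s)):
        yield (i, s[:i], s[i + 1 :])


def build_cdr3_graph(cdr3_set: Iterable[str]) -> CDR3Graph:
    """Exact Hamming-1 adjacency via single-position masking.

    Two distinct equal-length sequences share a masked key iff they differ
    at exactly that position, so each edge is discovered exactly once.
    """
    seqs = set(cdr3_set)
    if not seqs:
        raise ValueError("empty CDR3 set")
    g = nx.Graph()
    g.add_nodes_from(seqs)
    buckets: dict[tuple, list[str]] = defaultdict(list)
    for s in seqs:
        for key in _masked(s):
            buckets[key].append(s)
    for members in buckets.values():
        if len(members) > 1:
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    g.add_edge(members[i], members[j])
    return CDR3Graph(g)


@dataclass
class EnrichmentRecord:
    cdr3_aa: str
    observed_neighbors: int
    expected_neighbors: float
    p_value: float
    p_adjusted: float
    selected: bool


def _as_aa(seqs: Iterable[Union[str, Clonotype]]) -> list[str]:
    return [s.cdr3_aa if isinstance(s, Clonotype) else s for s in seqs]


def neighbor_enrichment(
    sample_cdr3s: Iterable[Union[str, Clonotype]],
    baseline_cdr3s: Sequence[Union[str, Clonotype]],
    alpha: float = 0.05,
    correction: str = "bh",
) -> list[EnrichmentRecord]:
    """Select CDR3s with more Hamming-1 neighbors than recombination predicts.

    observed = degree in the pooled-sample graph; expected = the sequence's
    neighbor count within the baseline pool, scaled by |sample|/|baseline|;
    the excess is tested with an upper-tail Poisson(λ = max(expected, ε))
    with ε = 1/|baseline| to avoid a degenerate zero rate.  A CDR3 is
    selected when its corrected p-value is below ``alpha`` and it has at
    least one observed neighbor.
    """
    sample = sorted(set(_as_aa(sample_cdr3s)))
    baseline = _as_aa(baseline_cdr3s)
    if not baseline:
        raise ValueError("empty baseline")
    if len(baseline) < len(sample):
        raise ValueError(
            f"baseline ({len(baseline)}) must be at least as large as the "
            f"sample ({len(sample)})"
        )
    graph = build_cdr3_graph(sample)

    bucket_counts: Counter = Counter()
    exact_counts: Counter = Counter(baseline)
    for s in exact_counts:
        for key in _masked(s):
            bucket_counts[key] += exact_counts[s]

    scale = len(sample) / len(baseline)
    eps = 1.0 / len(baseline)
    observed = np.array([graph.degree(s) for s in sample])
    expected = np.empty(len(sample))
    for i, s in enumerate(sample):
        raw = sum(bucket_counts.get(key, 0) for key in _masked(s))
        raw -= len(s) * exact_counts.get(s, 0)  # exact matches are not neighbors
        expected[i] = raw * scale
    lam = np.maximum(expected, eps)
    pvals = np.where(observed > 0, stats.poisson.sf(observed - 1, lam), 1.0)

    if correction == "bh":
        padj = stats.false_discovery_control(pvals, method="bh")
    elif correction == "by":
        padj = stats.false_discovery_control(pvals, method="by")
    elif correction == "bonferroni":
        padj = np.minimum(pvals * len(pvals), 1.0)
    elif correction == "none":
        padj = pvals
    else:
        raise ValueError(f"unknown correction {correction!r}")

    return [
        EnrichmentRecord(
            cdr3_aa=s,
            observed_neighbors=int(o),
            expected_neighbors=float(e),
            p_value=float(p),
            p_adjusted=float(q),
            selected=bool(q < alpha and o >= 1),
        )
        for s, o, e, p, q in zip(sample, observed, expected, pvals, padj)
    ]


def enrichment_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass
class CDR3Cluster:
    """A connected component of enriched CDR3s (all of one length)."""

    cluster_id: int
    members: frozenset[str]
    pwm: Optional[pd.DataFrame] = None
    consensus: str = ""
    sample_frequencies: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


def extract_clusters(graph: CDR3Graph, selected: Iterable[str]) -> list[CDR3Cluster]:
    """Connected components of the selected-node subgraph; singletons dropped.

    Cluster ids are assigned deterministically: descending member count,
    ties by the lexicographically smallest member.
    """
    selected = set(selected)
    extra = selected - set(graph.graph.nodes)
    if extra:
        raise ValueError(f"selected sequences not in graph: {sorted(extra)[:3]}...")
    sub = graph.graph.subgraph(selected)
    comps = [c for c in nx.connected_components(sub) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return [CDR3Cluster(cluster_id=i + 1, members=frozenset(c)) for i, c in enumerate(comps)]


def cluster_sample_frequencies(
    clusters: Sequence[CDR3Cluster], cohort: Union[Cohort, Iterable[Repertoire]]
) -> pd.DataFrame:
    """cluster × sample matrix of summed member-clonotype frequencies."""
    reps = cohort.repertoires if isinstance(cohort, Cohort) else list(cohort)
    member_of: dict[str, int] = {}
    for cl in clusters:
        for aa in cl.members:
            member_of[aa] = cl.cluster_id
    ids = [cl.cluster_id for cl in clusters]
    mat = pd.DataFrame(
        0.0, index=pd.Index(ids, name="cluster_id"), columns=[r.meta.sample_id for r in reps]
    )
    for rep in reps:
        for c in rep.clonotypes:
            cid = member_of.get(c.cdr3_aa)
            if cid is not None:
                mat.loc[cid, rep.meta.sample_id] += c.frequency
    for cl in clusters:
        cl.sample_frequencies = mat.loc[cl.cluster_id].to_dict()
    return mat


def cluster_frequency_matrix(
    clusters: Sequence[CDR3Cluster],
    cohort: Union[Cohort, Iterable[Repertoire]],
    linkage: str = "average",
    pseudo: float = 1e-5,
) -> pd.DataFrame:
    """The cluster × sample frequency matrix, rows/columns ordered by
    hierarchical clustering (average linkage, Euclidean on log10(f + pseudo))."""
    mat = cluster_sample_frequencies(clusters, cohort)
    if mat.empty:
        return mat
    logm = np.log10(mat.to_numpy() + pseudo)
    if mat.shape[0] > 2:
        row_order = hierarchy.leaves_list(hierarchy.linkage(pdist(logm), method=linkage))
        mat = mat.iloc[row_order]
        logm = logm[row_order]
    if mat.shape[1] > 2:
        col_order = hierarchy.leaves_list(hierarchy.linkage(pdist(logm.T), method=linkage))
        mat = mat.iloc[:, col_order]
    return mat


def cluster_pwm(
    cluster: CDR3Cluster, cohort: Union[Cohort, Iterable[Repertoire], None] = None
) -> CDR3Cluster:
    """Fill in the cluster's position frequency matrix and consensus.

    Residue proportions per position are weighted by the total clonotype
    frequency each member carries across the cohort (equal weights if no
    cohort is given or no member is observed).  The returned matrix has one
    row per CDR3 position and one column per residue, rows summing to 1 —
    directly consumable by sequence-logo renderers.
    """
    if not cluster.members:
        raise ValueError("empty cluster")
    members = sorted(cluster.members)
    length = len(members[0])
    weights = {m: 0.0 for m in members}
    if cohort is not None:
        reps = cohort.repertoires if isinstance(cohort, Cohort) else list(cohort)
        for rep in reps:
            for c in rep.clonotypes:
                if c.cdr3_aa in weights:
                    weights[c.cdr3_aa] += c.frequency
    if sum(weights.values()) <= 0:
        weights = {m: 1.0 for m in members}
    total = sum(weights.values())
    pwm = np.zeros((length, len(AA_ALPHABET)))
    col = {a: i for i, a in enumerate(AA_ALPHABET)}
    for m in members:
        w = weights[m] / total
        for pos, res in enumerate(m):
            pwm[pos, col[res]] += w
    df = pd.DataFrame(pwm, columns=list(AA_ALPHABET))
    df.index.name = "position"
    cluster.pwm = df
    cluster.consensus = "".join(AA_ALPHABET[i] for i in pwm.argmax(axis=1))
    return cluster
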