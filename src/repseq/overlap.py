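"""Clonotype-weighted repertoire overlap (F2), MDS and dendrograms.

F2 between two repertoires is the clonotype-wise sum of geometric mean
frequencies over shared clonotypes, ``F2 = Σ_k sqrt(p_k q_k)``; it reflects
the proportion of shared T cells and equals 1 for identical frequency
vectors.  Repertoires are first reduced to their top-N clonotypes (ties
among equal counts broken by a seeded shuffle so alphabetical input order
cannot leak in) and renormalized within the selection.

Clonotype matching levels:

* ``"aa"`` — identical V gene and CDR3 amino-acid sequence (nucleotide
  variants collapsed first);
* ``"nt"`` — identical V gene, J gene and CDR3 nucleotide sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .repertoire import Clonotype, Repertoire, aggregate_aa

MATCH_LEVELS = ("aa", "nt")


def _key_fn(match_level: str) -> Callable[[Clonotype], tuple]:
    if match_level == "aa":
        return lambda c: (c.v_segment, c.cdr3_aa)
    if match_level == "nt":
        return lambda c: (c.v_segment, c.j_segment, c.cdr3_nt)
    raise ValueError(f"unknown match level {match_level!r}; expected one of {MATCH_LEVELS}")


def top_n_clonotypes(
    rep: Repertoire, n: int, rng: Optional[np.random.Generator] = None
) -> Repertoire:
    """Top ``n`` clonotypes by count, shuffled-then-stably-sorted.

    The random shuffle before the stable descending sort removes any
    systematic (e.g. alphabetical) tie order among clonotypes with equal
    counts — relevant for counts 1 and 2, which dominate the tail.
    Frequencies are renormalized within the selection.  If the repertoire
    has fewer than ``n`` clonotypes all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    order = rng.permutation(len(rep.clonotypes))
    shuffled = [rep.clonotypes[i] for i in order]
    shuffled.sort(key=lambda c: -c.count)  # stable: preserves shuffled tie order
    return Repertoire.build(rep.meta, shuffled[:n], dropped_rows=rep.dropped_rows)


def f2_overlap(rep_a: Repertoire, rep_b: Repertoire, match_level: str = "aa") -> float:
    """Σ over matched clonotype keys of sqrt(p·q).

    Callers are expected to have reduced both repertoires to their top-N and
    renormalized (as :func:`top_n_clonotypes` does); the identity case then
    gives exactly 1.
    """
    if not rep_a.clonotypes or not rep_b.clonotypes:
        raise ValueError("F2 undefined for an empty repertoire")
    key = _key_fn(match_level)
    fa: dict[tuple, float] = {}
    for c in rep_a.clonotypes:
        k = key(c)
        fa[k] = fa.get(k, 0.0) + c.frequency
    fb: dict[tuple, float] = {}
    for c in rep_b.clonotypes:
        k = key(c)
        fb[k] = fb.get(k, 0.0) + c.frequency
    if len(fb) < len(fa):
        fa, fb = fb, fa
    return float(sum(np.sqrt(p * fb[k]) for k, p in fa.items() if k in fb))


@dataclass
class OverlapMatrix:
    """Symmetric all-vs-all F2 matrix over eligible samples."""

    sample_ids: list[str]
    f2: np.ndarray
    match_level: str
    top_n: int
    excluded: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.f2, index=self.sample_ids, columns=self.sample_ids)


def pairwise_overlap(
    samples: Sequence[Repertoire],
    n: int = 1000,
    match_level: str = "aa",
    min_clonotypes: int = 700,
    rng: Optional[np.random.Generator] = None,
) -> OverlapMatrix:
    """All-vs-all F2 over top-``n`` clonesets.

    Samples with fewer than ``min_clonotypes`` clonotypes are excluded (and
    listed in the result); at the amino-acid level nucleotide variants are
    collapsed before the top-N cut.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    eligible, excluded = [], []
    for rep in samples:
        (eligible if len(rep.clonotypes) >= min_clonotypes else excluded).append(rep)
    if len(eligible) < 2:
        raise ValueError(
            f"need at least 2 eligible samples (>= {min_clonotypes} clonotypes); "
            f"got {len(eligible)}"
        )
    reduced = []
    for rep in eligible:
        work = aggregate_aa(rep) if match_level == "aa" else rep
        reduced.append(top_n_clonotypes(work, n, rng))
    m = len(reduced)
    f2 = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            f2[i, j] = f2[j, i] = f2_overlap(reduced[i], reduced[j], match_level)
    return OverlapMatrix(
        sample_ids=[r.meta.sample_id for r in eligible],
        f2=f2,
        match_level=match_level,
        top_n=n,
        excluded=[r.meta.sample_id for r in excluded],
    )


def overlap_to_distance(m: OverlapMatrix) -> np.ndarray:
    """d = 1 − F2: bounded, monotone, zero for identical samples."""
    d = 1.0 - np.asarray(m.f2, dtype=float)
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, None)


@dataclass
class MDSResult:
    coords: np.ndarray
    stress: float


def _check_distance(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    return d


def mds_embedding(
    d: np.ndarray, dims: int = 2, seed: int = 0, method: str = "classical"
) -> MDSResult:
    """Metric MDS of a distance matrix.

    ``"classical"`` (default) uses the Torgerson double-centering
    eigendecomposition; ``"smacof"`` uses iterative stress majorization
    (scikit-learn), seeded.  Reported stress is Kruskal stress-1 of the
    embedding against the input distances.
    """
    d = _check_distance(d)
    n = d.shape[0]
    if dims > n - 1 or dims < 1:
        raise ValueError(f"dims must be in 1..{n - 1}")
    if method == "classical":
        j = np.eye(n) - np.full((n, n), 1.0 / n)
        b = -0.5 * j @ (d**2) @ j
        w, v = np.linalg.eigh(b)
        idx = np.argsort(w)[::-1][:dims]
        lam = np.clip(w[idx], 0.0, None)
        coords = v[:, idx] * np.sqrt(lam)
    elif method == "smacof":
        from sklearn.manifold import MDS

        mds = MDS(
            n_components=dims,
            dissimilarity="precomputed",
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(d)
    else:
        raise ValueError(f"unknown MDS method {method!r}")
    emb = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    iu = np.triu_indices(n, 1)
    denom = float((d[iu] ** 2).sum())
    stress = float(np.sqrt(((emb[iu] - d[iu]) ** 2).sum() / denom)) if denom > 0 else 0.0
    return MDSResult(coords=coords, stress=stress)


def hierarchical_dendrogram(
    d: np.ndarray, sample_ids: Sequence[str], linkage: str = "average"
) -> str:
    """Agglomerative tree of samples serialized as newick with branch lengths.

    Under average linkage (UPGMA) the tree is ultrametric: a leaf sits at
    half its merge distance, so two samples form a cherry with branch
    lengths d/2.
    """
    d = _check_distance(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a dendrogram")
    if len(sample_ids) != n:
        raise ValueError("sample_ids length mismatch")
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    tree = hierarchy.to_tree(z)

    def newick(node) -> str:
        if node.is_leaf():
            return str(sample_ids[node.id])
        parts = []
        for child in (node.get_left(), node.get_right()):
            bl = max((node.dist - child.dist) / 2.0, 0.0)
            parts.append(f"{newick(child)}:{bl:.6g}")
        return f"({','.join(parts)})"

    return newick(tree) + ";"


def cut_clusters(d: np.ndarray, k: int, linkage: str = "average") -> np.ndarray:
    """Flat cluster labels from cutting the agglomerative tree into k groups."""
    d = _check_distance(d)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)
    return hierarchy.fcluster(z, t=k, criterion="maxclust")
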