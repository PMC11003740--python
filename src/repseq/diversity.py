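"""Depth-normalized repertoire diversity and group-vs-control testing.

Diversity metrics are depth-confounded, so every sample is first downsampled
to a fixed number of UMI-labeled molecules (sampling without replacement —
molecules are physical objects) and samples below a minimum UMI total are
excluded.  Three metrics are reported per sample:

* observed diversity — the number of distinct clonotypes;
* Chao1 (bias-corrected) — a lower bound on total richness,
  ``S_obs + n1(n1-1) / (2(n2+1))`` with n1/n2 the singleton/doubleton counts;
* normalized Shannon–Wiener index — evenness, ``H / ln(S_obs)`` with
  ``H = -Σ p_i ln p_i`` (0 for a single clonotype by convention).

Group differences are assessed with Welch's two-sample t-test of each
challenge against the control group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import Cohort, Repertoire, aggregate_aa


@dataclass
class DiversityResult:
    sample_id: str
    depth_used: int
    observed: int
    chao1: float
    shannon_norm: float
    excluded: bool = False
    reason: str = ""


def downsample(rep: Repertoire, depth: int, rng: np.random.Generator) -> Repertoire:
    """Draw ``depth`` molecules without replacement (multivariate hypergeometric).

    The output total is exactly ``depth``; clonotypes drawn zero times are
    removed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    total = rep.total_count
    if total < depth:
        raise ValueError(f"cannot downsample {total} molecules to depth {depth}")
    if total == depth:
        return rep
    counts = np.array([c.count for c in rep.clonotypes], dtype=np.int64)
    new_counts = rng.multivariate_hypergeometric(counts, depth)
    kept = [
        type(c)(c.cdr3_nt, c.cdr3_aa, c.v_segment, c.j_segment, c.d_segment, int(n))
        for c, n in zip(rep.clonotypes, new_counts)
        if n > 0
    ]
    return Repertoire.build(rep.meta, kept, dropped_rows=rep.dropped_rows)


def observed_diversity(rep: Repertoire) -> int:
    """Number of distinct clonotype records."""
    return len(rep.clonotypes)


def chao1(rep: Repertoire) -> float:
    """Bias-corrected Chao1 richness lower bound."""
    if not rep.clonotypes:
        raise ValueError("chao1 undefined for an empty repertoire")
    counts = np.array([c.count for c in rep.clonotypes])
    n1 = int((counts == 1).sum())
    n2 = int((counts == 2).sum())
    return len(counts) + n1 * (n1 - 1) / (2.0 * (n2 + 1))


def normalized_shannon(rep: Repertoire) -> float:
    """Shannon entropy of clonotype frequencies over its maximum ln(S_obs)."""
    if not rep.clonotypes:
        raise ValueError("normalized Shannon index undefined for an empty repertoire")
    counts = np.array([c.count for c in rep.clonotypes], dtype=float)
    if len(counts) == 1:
        return 0.0
    if (counts == counts[0]).all():
        return 1.0  # perfectly even: exact by definition, not up to rounding
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / float(np.log(len(counts)))


def _metrics(rep: Repertoire) -> tuple[int, float, float]:
    return observed_diversity(rep), chao1(rep), normalized_shannon(rep)


def diversity_table(
    cohort: Union[Cohort, Iterable[Repertoire]],
    depth: int = 1000,
    min_umi: int = 700,
    n_resamples: int = 1,
    rng: Optional[np.random.Generator] = None,
    level: str = "nt",
) -> list[DiversityResult]:
    """Per-sample depth-normalized diversity.

    Samples with fewer than ``min_umi`` molecules are marked excluded;
    samples between ``min_umi`` and ``depth`` are used at full depth without
    downsampling; the rest are downsampled to ``depth``, averaging the
    metrics over ``n_resamples`` independent draws.  ``level`` selects the
    clonotype definition: ``"nt"`` (as extracted) or ``"aa"``
    ((V, CDR3aa)-aggregated).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    reps = cohort.repertoires if isinstance(cohort, Cohort) else list(cohort)
    results = []
    for rep in reps:
        total = rep.total_count
        if total < min_umi:
            results.append(
                DiversityResult(rep.meta.sample_id, total, 0, float("nan"), float("nan"),
                                excluded=True, reason=f"UMI total {total} < {min_umi}")
            )
            continue
        work = aggregate_aa(rep) if level == "aa" else rep
        if total < depth:
            obs, c1, sh = _metrics(work)
            results.append(DiversityResult(rep.meta.sample_id, total, obs, c1, sh))
            continue
        acc = np.zeros(3)
        for _ in range(max(n_resamples, 1)):
            acc += _metrics(downsample(work, depth, rng))
        acc /= max(n_resamples, 1)
        results.append(
            DiversityResult(rep.meta.sample_id, depth, int(round(acc[0])), acc[1], acc[2])
        )
    return results


def diversity_frame(
    cohort: Union[Cohort, Iterable[Repertoire]], **kwargs
) -> pd.DataFrame:
    """diversity_table as a DataFrame joined with sample metadata."""
    reps = cohort.repertoires if isinstance(cohort, Cohort) else list(cohort)
    rows = []
    for rep, res in zip(reps, diversity_table(reps, **kwargs)):
        rows.append(
            {
                "sample_id": res.sample_id,
                "mouse_id": rep.meta.mouse_id,
                "tissue": rep.meta.tissue,
                "subset": rep.meta.subset,
                "challenge": rep.meta.challenge,
                "depth_used": res.depth_used,
                "observed": res.observed,
                "chao1": res.chao1,
                "shannon_norm": res.shannon_norm,
                "excluded": res.excluded,
                "reason": res.reason,
            }
        )
    return pd.DataFrame(rows)


def star_bin(p: float) -> str:
    """Significance annotation: *p<0.05, **p<0.01, ***p<0.001, ****p<0.0001."""
    if not np.isfinite(p):
        return ""
    for stars, cut in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 5e-2)):
        if p < cut:
            return stars
    return ""


def group_vs_control_ttest(
    values: pd.DataFrame,
    value_col: str,
    group_col: str = "challenge",
    control_label: str = "control",
) -> pd.DataFrame:
    """Welch t-test of each group against the control group.

    Returns one row per non-control group with the test statistic, p-value
    and star annotation.  Groups with fewer than two usable samples get NaN
    with a warning.
    """
    df = values.dropna(subset=[value_col])
    control = df.loc[df[group_col] == control_label, value_col].to_numpy(float)
    if control.size == 0:
        raise ValueError(f"control group {control_label!r} is empty")
    rows = []
    for group, sub in df.groupby(group_col, sort=False):
        if group == control_label:
            continue
        vals = sub[value_col].to_numpy(float)
        if vals.size < 2 or control.size < 2:
            warnings.warn(f"group {group!r}: fewer than 2 samples, no test")
            t, p = float("nan"), float("nan")
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                t, p = stats.ttest_ind(vals, control, equal_var=False)
            t, p = float(t), float(p)
        rows.append(
            {
                group_col: group,
                "n": int(vals.size),
                "n_control": int(control.size),
                "mean": float(vals.mean()) if vals.size else float("nan"),
                "mean_control": float(control.mean()),
                "t": t,
                "p": p,
                "stars": star_bin(p),
            }
        )
    return pd.DataFrame(rows)
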