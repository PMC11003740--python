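"""eCD4→eTreg conversion scoring and invariant NKT tracking.

Clonal conversion between conventional and regulatory effector subsets is
read from nucleotide-level repertoire overlap: identical (V, J, CDR3nt)
rearrangements shared between the two subsets of the *same mouse* can only
come from a common clonal origin.  The score is the F2 overlap of the
top-100 nucleotide clonotypes of the matched pair; it is reported as the
overlap statistic itself, direction being a biological inference.

The invariant NKT clonotype is the canonical TRAV11-CVVGDRGSALGRLHF-TRAJ18
TCRα; its per-sample fraction is the summed frequency of matching
clonotypes at any nucleotide realization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .clusters import CDR3Cluster
from .diversity import group_vs_control_ttest
from .overlap import f2_overlap, top_n_clonotypes
from .repertoire import Cohort, Repertoire
from .simulate import INKT_AA, INKT_J, INKT_V


@dataclass
class ConversionRecord:
    mouse_id: str
    tissue: str
    challenge: str
    f2_nt: float
    eligible: bool
    reason: str = ""


def conversion_f2(
    ecd4: Repertoire,
    etreg: Repertoire,
    top_n: int = 100,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Nucleotide-level F2 between a mouse's matched eCD4/eTreg samples.

    Both samples are reduced to their top-``top_n`` clonotypes (seeded
    shuffle for ties) and renormalized; matching requires identical V gene,
    J gene and CDR3 nucleotide sequence.
    """
    if (ecd4.meta.mouse_id, ecd4.meta.tissue) != (etreg.meta.mouse_id, etreg.meta.tissue):
        raise ValueError("conversion is defined for same-mouse, same-tissue pairs")
    if len(ecd4) < top_n or len(etreg) < top_n:
        raise ValueError(
            f"both samples need >= {top_n} clonotypes "
            f"(got {len(ecd4)} and {len(etreg)})"
        )
    rng = rng if rng is not None else np.random.default_rng(0)
    a = top_n_clonotypes(ecd4, top_n, rng)
    b = top_n_clonotypes(etreg, top_n, rng)
    return f2_overlap(a, b, match_level="nt")


def conversion_table(
    cohort: Cohort,
    top_n: int = 100,
    min_clonotypes: int = 100,
    control_label: str = "control",
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-mouse conversion records plus per-(challenge, tissue) group tests.

    One record per (mouse, tissue) with both subsets present; samples with
    fewer than ``min_clonotypes`` clonotypes make the pair ineligible.  Each
    challenge group is compared against the control group of the *same
    tissue* with Welch's t-test, so the challenge site and systemic (spleen)
    contrasts are reported separately.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pairs: dict[tuple[str, str], dict[str, Repertoire]] = {}
    for rep in cohort.repertoires:
        pairs.setdefault((rep.meta.mouse_id, rep.meta.tissue), {})[rep.meta.subset] = rep
    records: list[ConversionRecord] = []
    for (mouse, tissue), subsets in sorted(pairs.items()):
        if "eCD4" not in subsets or "eTreg" not in subsets:
            warnings.warn(f"{mouse}/{tissue}: missing a subset, pair skipped")
            continue
        ecd4, etreg = subsets["eCD4"], subsets["eTreg"]
        challenge = ecd4.meta.challenge
        if len(ecd4) < min_clonotypes or len(etreg) < min_clonotypes:
            records.append(
                ConversionRecord(mouse, tissue, challenge, float("nan"), False,
                                 reason=f"< {min_clonotypes} clonotypes")
            )
            continue
        f2 = conversion_f2(ecd4, etreg, top_n=top_n, rng=rng)
        records.append(ConversionRecord(mouse, tissue, challenge, f2, True))
    if not records:
        raise ValueError("no matched eCD4/eTreg pairs in cohort")
    table = pd.DataFrame([r.__dict__ for r in records])

    stats_rows = []
    eligible = table[table.eligible]
    for tissue, sub in eligible.groupby("tissue", sort=False):
        if (sub.challenge == control_label).sum() == 0:
            continue
        res = group_vs_control_ttest(sub, "f2_nt", "challenge", control_label)
        res.insert(0, "tissue", tissue)
        stats_rows.append(res)
    stats = (
        pd.concat(stats_rows, ignore_index=True) if stats_rows else pd.DataFrame()
    )
    return table, stats


def inkt_fraction(rep: Repertoire) -> float:
    """Summed frequency of the invariant NKT clonotype.

    Matches all three fields — V gene TRAV11, CDR3 amino-acid sequence
    CVVGDRGSALGRLHF, J gene TRAJ18 — at any nucleotide realization.
    """
    return float(
        sum(
            c.frequency
            for c in rep.clonotypes
            if c.v_segment == INKT_V and c.cdr3_aa == INKT_AA and c.j_segment == INKT_J
        )
    )


def inkt_frame(cohort: Union[Cohort, list[Repertoire]]) -> pd.DataFrame:
    reps = cohort.repertoires if isinstance(cohort, Cohort) else list(cohort)
    return pd.DataFrame(
        [
            {
                "sample_id": r.meta.sample_id,
                "mouse_id": r.meta.mouse_id,
                "tissue": r.meta.tissue,
                "subset": r.meta.subset,
                "challenge": r.meta.challenge,
                "inkt_fraction": inkt_fraction(r),
            }
            for r in reps
        ]
    )


def cluster_share_in_subsets(cluster: CDR3Cluster, cohort: Cohort) -> pd.DataFrame:
    """Per-sample frequency of one CDR3 cluster, annotated by subset.

    Enables the comparison of a motif cluster's representation in eTreg vs
    eCD4 repertoires across tissues and challenges.
    """
    members = cluster.members
    rows = []
    for rep in cohort.repertoires:
        freq = sum(c.frequency for c in rep.clonotypes if c.cdr3_aa in members)
        rows.append(
            {
                "sample_id": rep.meta.sample_id,
                "mouse_id": rep.meta.mouse_id,
                "tissue": rep.meta.tissue,
                "subset": rep.meta.subset,
                "challenge": rep.meta.challenge,
                "cluster_id": cluster.cluster_id,
                "frequency": float(freq),
            }
        )
    return pd.DataFrame(rows)
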