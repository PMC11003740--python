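"""Core domain types for UMI-based TCR repertoires.

A *clonotype* is a unique receptor variant (V segment, CDR3 nucleotide and
amino-acid sequence, J segment) carrying a UMI count — the number of distinct
cDNA molecules observed for it.  A *repertoire* is one sorted sample of
clonotypes with its metadata (mouse, tissue, subset, challenge), and a
*cohort* is the full study design's collection of repertoires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

TISSUES = ("lung", "skin", "MLN", "AXLN", "IGLN", "spleen", "thymus")
SUBSETS = ("eTreg", "eCD4")
CHALLENGES = ("control", "influenza", "nippo", "bleomycin", "LLC", "PYMT", "B16")

#: residues that mark an out-of-frame / stop-containing junction in
#: clonotype tables produced by common repertoire extraction tools
STOP_SYMBOLS = ("*", "_")


def strip_allele(segment: str) -> str:
    """Drop an allele suffix, e.g. ``TRAV11*01`` -> ``TRAV11``.

    Segment matching throughout the package is at the gene level.
    """
    return segment.split("*", 1)[0].strip()


@dataclass(frozen=True)
class Clonotype:
    """One receptor variant with its UMI count and in-sample frequency."""

    cdr3_nt: str
    cdr3_aa: str
    v_segment: str
    j_segment: str
    d_segment: str = ""
    count: int = 1
    frequency: float = 0.0

    def is_in_frame(self) -> bool:
        if any(s in self.cdr3_aa for s in STOP_SYMBOLS) or not self.cdr3_aa:
            return False
        if self.cdr3_nt and len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
            return False
        return True


@dataclass(frozen=True)
class SampleMeta:
    """Sample identity within the study design."""

    sample_id: str
    mouse_id: str
    tissue: str
    subset: str
    challenge: str

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}; expected one of {SUBSETS}")
        if self.challenge not in CHALLENGES:
            raise ValueError(
                f"unknown challenge {self.challenge!r}; expected one of {CHALLENGES}"
            )


def _sort_key(c: Clonotype):
    # descending count, ties broken lexicographically by nucleotide sequence
    # so that written tables are reproducible
    return (-c.count, c.cdr3_nt, c.cdr3_aa, c.v_segment, c.j_segment)


@dataclass
class Repertoire:
    """One sample: an ordered clonotype list plus metadata.

    Use :meth:`build` to construct from raw clonotypes — it sorts by
    descending count and recomputes frequencies from counts so the
    Σ frequency = 1 invariant holds.
    """

    meta: SampleMeta
    clonotypes: list[Clonotype] = field(default_factory=list)
    dropped_rows: int = 0

    @classmethod
    def build(
        cls,
        meta: SampleMeta,
        clonotypes: Iterable[Clonotype],
        dropped_rows: int = 0,
    ) -> "Repertoire":
        clones = sorted(clonotypes, key=_sort_key)
        total = sum(c.count for c in clones)
        if total <= 0:
            raise ValueError(f"repertoire {meta.sample_id!r} has no molecules")
        clones = [replace(c, frequency=c.count / total) for c in clones]
        return cls(meta=meta, clonotypes=clones, dropped_rows=dropped_rows)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes)

    def validate(self) -> None:
        """Assert the repertoire invariants; raises AssertionError."""
        total = self.total_count
        assert total > 0, "empty repertoire"
        freq_sum = 0.0
        for c in self.clonotypes:
            assert c.count >= 1, f"non-positive count for {c.cdr3_nt}"
            assert c.is_in_frame(), f"out-of-frame clonotype {c.cdr3_aa}"
            assert math.isclose(c.frequency, c.count / total, abs_tol=1e-9)
            freq_sum += c.frequency
        assert math.isclose(freq_sum, 1.0, abs_tol=1e-6)


def aggregate_aa(rep: Repertoire) -> Repertoire:
    """Collapse nucleotide variants to amino-acid clonotypes.

    Grouping key is (V gene, CDR3 amino-acid sequence): convergent nucleotide
    rearrangements encoding the same protein-level receptor are summed.  The
    same CDR3 under two different V genes stays two clonotypes.  The
    representative nucleotide sequence and J segment are taken from the
    largest member (ties: lexicographically smallest nucleotide sequence).
    """
    groups: dict[tuple[str, str], list[Clonotype]] = {}
    for c in rep.clonotypes:
        groups.setdefault((c.v_segment, c.cdr3_aa), []).append(c)
    merged = []
    for (v, aa), members in groups.items():
        rep_member = min(members, key=_sort_key)
        merged.append(
            Clonotype(
                cdr3_nt=rep_member.cdr3_nt,
                cdr3_aa=aa,
                v_segment=v,
                j_segment=rep_member.j_segment,
                d_segment=rep_member.d_segment,
                count=sum(m.count for m in members),
            )
        )
    return Repertoire.build(rep.meta, merged, dropped_rows=rep.dropped_rows)


@dataclass
class Cohort:
    """All repertoires of a study plus the challenge → mice design map."""

    repertoires: list[Repertoire]
    design: dict[str, list[str]] = field(default_factory=dict)
    ground_truth: Optional[dict] = None

    def __len__(self) -> int:
        return len(self.repertoires)

    def __iter__(self) -> Iterator[Repertoire]:
        return iter(self.repertoires)

    @property
    def sample_ids(self) -> list[str]:
        return [r.meta.sample_id for r in self.repertoires]

    def get(self, mouse_id: str, tissue: str, subset: str) -> Optional[Repertoire]:
        for r in self.repertoires:
            m = r.meta
            if (m.mouse_id, m.tissue, m.subset) == (mouse_id, tissue, subset):
                return r
        return None

    def filter(
        self,
        tissue: Optional[str] = None,
        subset: Optional[str] = None,
        challenge: Optional[str] = None,
    ) -> list[Repertoire]:
        out = []
        for r in self.repertoires:
            if tissue is not None and r.meta.tissue != tissue:
                continue
            if subset is not None and r.meta.subset != subset:
                continue
            if challenge is not None and r.meta.challenge != challenge:
                continue
            out.append(r)
        return out

    def validate(self) -> None:
        seen = set()
        for r in self.repertoires:
            key = (r.meta.mouse_id, r.meta.tissue, r.meta.subset)
            if key in seen:
                raise ValueError(f"duplicate sample {key}")
            seen.add(key)
            if self.design:
                mice = self.design.get(r.meta.challenge, [])
                if r.meta.mouse_id not in mice:
                    raise ValueError(
                        f"mouse {r.meta.mouse_id} not in design for {r.meta.challenge}"
                    )
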