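"""Synthetic TCRα rearrangements and study-design cohorts.

Two roles:

* a V(D)J recombination null model — random rearrangements drawn from
  synthetic mouse-style TRAV/TRAJ segments with junctional trimming and
  non-templated N insertions, used as the baseline for CDR3 neighbor
  enrichment;
* a cohort generator that emulates the study design (challenges × mice ×
  tissues × eTreg/eCD4 subsets) with planted structure: challenge-specific
  convergent amino-acid motifs realized by *distinct* nucleotide
  rearrangements in each mouse, tissue-resident motifs independent of
  challenge, subset-shared nucleotide clonotypes (eCD4→eTreg conversion) at
  designated sites, and an invariant NKT clonotype spike.

Every stochastic choice is addressed by (seed, labels) so cohorts are
byte-identical across runs regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._codons import AA_TO_CODONS, translate
from ._rng import stage_rng
from .repertoire import Clonotype, Cohort, Repertoire, SampleMeta, SUBSETS, TISSUES

NT = "ACGT"

#: the invariant NKT receptor: V gene, CDR3 amino-acid sequence, J gene
INKT_V, INKT_AA, INKT_J = "TRAV11", "CVVGDRGSALGRLHF", "TRAJ18"


class ModelError(RuntimeError):
    """Degenerate recombination model (cannot produce in-frame products)."""


class DesignError(ValueError):
    """Inconsistent cohort design."""


@dataclass(frozen=True)
class Segment:
    """A germline segment contributing nucleotides to the CDR3 junction."""

    name: str
    sequence: str  # V: 3' tail (starts the CDR3); J: 5' head (ends it)


@dataclass
class RecombinationModel:
    """Generative model of TCRα CDR3 rearrangement.

    A product is V-tail (3' trimmed) + N insertions + J-head (5' trimmed);
    only in-frame, stop-free products are kept (rejection sampling).
    """

    v_segments: list[Segment]
    j_segments: list[Segment]
    v_usage: np.ndarray
    j_usage: np.ndarray
    deletion_probs: np.ndarray  # P(trim = 0..k) per side
    insertion_probs: np.ndarray  # P(N-length = 0..m)
    insertion_base_frequencies: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def validate(self) -> None:
        for name, vec in [
            ("v_usage", self.v_usage),
            ("j_usage", self.j_usage),
            ("deletion_probs", self.deletion_probs),
            ("insertion_probs", self.insertion_probs),
            ("insertion_base_frequencies", self.insertion_base_frequencies),
        ]:
            vec = np.asarray(vec, dtype=float)
            if vec.ndim != 1 or not math.isclose(vec.sum(), 1.0, abs_tol=1e-9):
                raise ModelError(f"{name} is not a probability vector")
            if (vec < 0).any():
                raise ModelError(f"{name} has negative entries")
        if len(self.v_usage) != len(self.v_segments):
            raise ModelError("v_usage length mismatch")
        if len(self.j_usage) != len(self.j_segments):
            raise ModelError("j_usage length mismatch")


def default_model(n_v: int = 24, n_j: int = 24, seed: int = 20210501) -> RecombinationModel:
    """The packaged default: synthetic mouse-style TRAV/TRAJ segments.

    Segment sequences are generated from a fixed internal seed, so the
    default model is a constant of the package.  Names are TRAV1..n and
    TRAJ1..m, which includes the literal TRAV11/TRAJ18 used by the invariant
    NKT definition.  Insertion lengths are uniform on 0..11 (a window of 12 =
    a whole number of codons, so the raw in-frame fraction is exactly 1/3)
    and trims are uniform on 0..6 per side.
    """
    if n_v < 20 or n_j < 20:
        raise ModelError("default model ships with at least 20 V and 20 J segments")
    rng = np.random.default_rng(seed)

    def random_nt(n: int) -> str:
        return "".join(NT[i] for i in rng.integers(0, 4, size=n))

    v_segments = []
    for i in range(1, n_v + 1):
        # CDR3 starts at the conserved cysteine: tails begin TGT GC. (C, A..)
        tail = "TGTGC" + random_nt(int(rng.integers(3, 9)))
        v_segments.append(Segment(f"TRAV{i}", tail))
    j_segments = []
    for i in range(1, n_j + 1):
        # heads end with a phenylalanine codon, the canonical CDR3 terminus
        head = random_nt(int(rng.integers(8, 14))) + ("TTT" if i % 2 else "TTC")
        j_segments.append(Segment(f"TRAJ{i}", head))

    v_usage = rng.dirichlet(np.full(n_v, 3.0))
    j_usage = rng.dirichlet(np.full(n_j, 3.0))
    return RecombinationModel(
        v_segments=v_segments,
        j_segments=j_segments,
        v_usage=v_usage,
        j_usage=j_usage,
        deletion_probs=np.full(7, 1 / 7),
        insertion_probs=np.full(12, 1 / 12),
        insertion_base_frequencies=np.array([0.25, 0.25, 0.25, 0.25]),
    )


def _assemble(model: RecombinationModel, vi: int, ji: int, dv: int, dj: int, ins: str) -> str:
    """Raw (pre-selection) junction for given draws; may be out of frame."""
    vtail = model.v_segments[vi].sequence
    jhead = model.j_segments[ji].sequence
    dv = min(dv, max(len(vtail) - 3, 0))  # keep the cysteine codon
    dj = min(dj, max(len(jhead) - 3, 0))
    return vtail[: len(vtail) - dv] + ins + jhead[dj:]


def _check(nt: str) -> Optional[str]:
    """Translate if in frame and stop-free, else None."""
    if not nt or len(nt) % 3:
        return None
    aa = translate(nt)
    return None if "*" in aa else aa


def _draw_params(model: RecombinationModel, n: int, rng: np.random.Generator):
    vis = rng.choice(len(model.v_segments), size=n, p=model.v_usage)
    jis = rng.choice(len(model.j_segments), size=n, p=model.j_usage)
    dvs = rng.choice(len(model.deletion_probs), size=n, p=model.deletion_probs)
    djs = rng.choice(len(model.deletion_probs), size=n, p=model.deletion_probs)
    lens = rng.choice(len(model.insertion_probs), size=n, p=model.insertion_probs)
    bases = rng.choice(4, size=int(lens.sum()), p=model.insertion_base_frequencies)
    return vis, jis, dvs, djs, lens, bases


def raw_products(model: RecombinationModel, n: int, rng: np.random.Generator) -> list[str]:
    """n raw junction sequences *before* in-frame/stop selection.

    Exposed so the pre-rejection in-frame fraction of a model can be
    measured directly.
    """
    vis, jis, dvs, djs, lens, bases = _draw_params(model, n, rng)
    out = []
    pos = 0
    for k in range(n):
        ln = int(lens[k])
        ins = "".join(NT[b] for b in bases[pos : pos + ln])
        pos += ln
        out.append(_assemble(model, int(vis[k]), int(jis[k]), int(dvs[k]), int(djs[k]), ins))
    return out


_MAX_REJECTIONS = 10**6


def sample_rearrangement(model: RecombinationModel, rng: np.random.Generator) -> Clonotype:
    """Draw one in-frame, stop-free rearrangement (rejection sampling)."""
    model.validate()
    batch = 16
    rejected = 0
    while rejected < _MAX_REJECTIONS:
        vis, jis, dvs, djs, lens, bases = _draw_params(model, batch, rng)
        pos = 0
        for k in range(batch):
            ln = int(lens[k])
            ins = "".join(NT[b] for b in bases[pos : pos + ln])
            pos += ln
            nt = _assemble(model, int(vis[k]), int(jis[k]), int(dvs[k]), int(djs[k]), ins)
            aa = _check(nt)
            if aa is not None:
                return Clonotype(
                    cdr3_nt=nt,
                    cdr3_aa=aa,
                    v_segment=model.v_segments[int(vis[k])].name,
                    j_segment=model.j_segments[int(jis[k])].name,
                    count=1,
                )
            rejected += 1
    raise ModelError("rejection sampling failed: model produces no in-frame products")


def generate_baseline(
    model: RecombinationModel, n: int, rng: np.random.Generator
) -> list[Clonotype]:
    """n independent rearrangements (duplicates allowed) — the null pool."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model.validate()
    out: list[Clonotype] = []
    attempts = 0
    while len(out) < n:
        want = n - len(out)
        batch = max(64, int(want * 3.5))
        vis, jis, dvs, djs, lens, bases = _draw_params(model, batch, rng)
        pos = 0
        for k in range(batch):
            ln = int(lens[k])
            ins = "".join(NT[b] for b in bases[pos : pos + ln])
            pos += ln
            nt = _assemble(model, int(vis[k]), int(jis[k]), int(dvs[k]), int(djs[k]), ins)
            aa = _check(nt)
            attempts += 1
            if aa is not None and len(out) < n:
                out.append(
                    Clonotype(
                        cdr3_nt=nt,
                        cdr3_aa=aa,
                        v_segment=model.v_segments[int(vis[k])].name,
                        j_segment=model.j_segments[int(jis[k])].name,
                        count=1,
                    )
                )
        if attempts > _MAX_REJECTIONS and not out:
            raise ModelError("rejection sampling failed: degenerate model")
    return out


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """One nucleotide realization of an amino-acid sequence with random
    synonymous codons — the mechanism behind convergent recombination."""
    return "".join(AA_TO_CODONS[a][int(rng.integers(len(AA_TO_CODONS[a])))] for a in aa)


# ---------------------------------------------------------------------------
# cohort design


@dataclass
class MotifSpec:
    """A planted convergent CDR3 motif.

    ``variable_positions`` maps a 0-based position in the consensus to the
    alternative residues allowed there; realized variants differ from the
    consensus at no more than one position, so the variant set is connected
    at Hamming distance 1 (star around the consensus).
    """

    consensus_aa: str
    variable_positions: dict[int, Sequence[str]] = field(default_factory=dict)
    target: str = "challenge"  # "challenge" or "tissue"
    target_label: str = ""
    subset_scope: str = "both"  # eTreg / eCD4 / both
    total_frequency: float = 0.05
    site_tissues: tuple[str, ...] = ("lung", "MLN")  # where challenge motifs appear
    v_segment: Optional[str] = None
    j_segment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.target not in ("challenge", "tissue"):
            raise DesignError(f"unknown motif target {self.target!r}")
        if not 0 < self.total_frequency <= 0.5:
            raise DesignError("motif total_frequency must be in (0, 0.5]")
        for pos in self.variable_positions:
            if not 0 <= pos < len(self.consensus_aa):
                raise DesignError(f"variable position {pos} outside consensus")

    def variants(self) -> list[str]:
        """Consensus plus every single-position alternative."""
        out = [self.consensus_aa]
        for pos, alts in sorted(self.variable_positions.items()):
            for alt in alts:
                if alt != self.consensus_aa[pos]:
                    out.append(
                        self.consensus_aa[:pos] + alt + self.consensus_aa[pos + 1 :]
                    )
        return out

    def applies_to(self, challenge: str, tissue: str, subset: str) -> bool:
        if self.subset_scope not in ("both", subset):
            return False
        if self.target == "challenge":
            return challenge == self.target_label and tissue in self.site_tissues
        return tissue == self.target_label


@dataclass
class ConversionSpec:
    """Identical (V, J, CDR3nt) clonotypes planted in both subsets of each
    mouse at one challenge/tissue combination — clonal subset sharing."""

    challenge: str
    tissue: str
    fraction: float
    n_clonotypes: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise DesignError("conversion fraction must be in [0, 1]")


@dataclass
class INKTSpec:
    """Spike of the invariant NKT clonotype in one sample class."""

    challenge: str
    tissue: str
    subset: str
    frequency: float

    def __post_init__(self) -> None:
        if not 0 <= self.frequency <= 1:
            raise DesignError("iNKT frequency must be in [0, 1]")


@dataclass
class CohortDesign:
    """Shape and planted structure of a synthetic study cohort."""

    challenges: dict[str, int]  # challenge -> number of mice (3..7)
    tissues: tuple[str, ...] = ("lung",)
    subsets: tuple[str, ...] = SUBSETS
    #: per-subset mean UMI depth; defaults are the study's per-subset means
    #: scaled down tenfold for desk-scale runs
    depth_mean: dict = field(default_factory=lambda: {"eTreg": 1360, "eCD4": 3741})
    depth_sigma: float = 0.3  # log-normal shape
    clone_size_exponent: float = 2.0  # Zipf exponent, truncated at depth
    planted_motifs: list[MotifSpec] = field(default_factory=list)
    conversion_specs: list[ConversionSpec] = field(default_factory=list)
    inkt_specs: list[INKTSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for challenge, n in self.challenges.items():
            if not 3 <= n <= 7:
                raise DesignError(
                    f"{challenge}: {n} mice per group outside the 3..7 design range"
                )
        for t in self.tissues:
            if t not in TISSUES:
                raise DesignError(f"unknown tissue {t!r}")
        for s in self.subsets:
            if s not in SUBSETS:
                raise DesignError(f"unknown subset {s!r}")
        # worst-case planted frequency per sample class
        for challenge in self.challenges:
            for tissue in self.tissues:
                for subset in self.subsets:
                    tot = sum(
                        m.total_frequency
                        for m in self.planted_motifs
                        if m.applies_to(challenge, tissue, subset)
                    )
                    tot += sum(
                        c.fraction
                        for c in self.conversion_specs
                        if (c.challenge, c.tissue) == (challenge, tissue)
                    )
                    tot += sum(
                        k.frequency
                        for k in self.inkt_specs
                        if (k.challenge, k.tissue, k.subset) == (challenge, tissue, subset)
                    )
                    if tot > 0.9:
                        raise DesignError(
                            f"planted frequency {tot:.2f} > 0.9 in "
                            f"({challenge}, {tissue}, {subset})"
                        )

    def mice(self, challenge: str) -> list[str]:
        return [f"{challenge}_m{i + 1}" for i in range(self.challenges[challenge])]


def _assign_motif_segments(design: CohortDesign, model: RecombinationModel) -> None:
    """Give each motif a fixed V/J (shared across mice — aa-level convergence)."""
    rng = stage_rng(design.seed, "motif-segments")
    for idx, m in enumerate(design.planted_motifs):
        if m.v_segment is None:
            m.v_segment = model.v_segments[
                int(rng.choice(len(model.v_segments), p=model.v_usage))
            ].name
        if m.j_segment is None:
            m.j_segment = model.j_segments[
                int(rng.choice(len(model.j_segments), p=model.j_usage))
            ].name


def _background_counts(remaining: int, exponent: float, rng: np.random.Generator) -> list[int]:
    """Zipf clone sizes, truncated so they sum exactly to ``remaining``."""
    counts: list[int] = []
    acc = 0
    while acc < remaining:
        c = int(rng.zipf(exponent))
        c = min(c, remaining - acc)
        counts.append(c)
        acc += c
    return counts


def _build_sample(
    design: CohortDesign,
    model: RecombinationModel,
    challenge: str,
    mouse: str,
    tissue: str,
    subset: str,
) -> Repertoire:
    rng = stage_rng(design.seed, "sample", challenge, mouse, tissue, subset)
    mean = design.depth_mean[subset]
    depth = max(int(round(rng.lognormal(math.log(mean), design.depth_sigma))), 50)

    # planted entries: (clonotype key, target frequency)
    planted: list[tuple[Clonotype, float]] = []
    for idx, motif in enumerate(design.planted_motifs):
        if not motif.applies_to(challenge, tissue, subset):
            continue
        variants = motif.variants()
        # the nucleotide realization is per (motif, mouse, subset): one
        # mouse carries the same clones in every tissue, but different mice
        # — and the two subsets, which expand from distinct naive pools —
        # carry different synonymous rearrangements of the same amino-acid
        # variants (convergent recombination)
        mrng = stage_rng(design.seed, "motif-nt", idx, mouse, subset)
        nts = [back_translate(aa, mrng) for aa in variants]
        # consensus dominates; leaves share the remainder evenly with mild
        # per-sample noise so frequencies differ between samples
        weights = np.r_[2.0, np.ones(len(variants) - 1)]
        weights = weights * rng.uniform(0.7, 1.3, size=len(variants))
        weights /= weights.sum()
        for aa, nt, w in zip(variants, nts, weights):
            c = Clonotype(nt, aa, motif.v_segment, motif.j_segment)
            planted.append((c, motif.total_frequency * float(w)))
    for cidx, conv in enumerate(design.conversion_specs):
        if (conv.challenge, conv.tissue) != (challenge, tissue):
            continue
        # derived without the subset label → identical clonotypes and matched
        # target frequencies in the mouse's eCD4 and eTreg samples
        crng = stage_rng(design.seed, "conversion", cidx, mouse)
        shared = generate_baseline(model, conv.n_clonotypes, crng)
        weights = crng.dirichlet(np.full(conv.n_clonotypes, 2.0))
        for c, w in zip(shared, weights):
            planted.append((c, conv.fraction * float(w)))
    for kidx, spec in enumerate(design.inkt_specs):
        if (spec.challenge, spec.tissue, spec.subset) != (challenge, tissue, subset):
            continue
        irng = stage_rng(design.seed, "inkt", kidx, mouse)
        nt = back_translate(INKT_AA, irng)
        planted.append((Clonotype(nt, INKT_AA, INKT_V, INKT_J), spec.frequency))

    merged: dict[tuple[str, str, str], list] = {}

    def add(c: Clonotype, count: int) -> None:
        key = (c.v_segment, c.j_segment, c.cdr3_nt)
        if key in merged:
            merged[key][1] += count
        else:
            merged[key] = [c, count]

    planted_total = 0
    for c, f in planted:
        count = max(1, int(round(f * depth)))
        add(c, count)
        planted_total += count
    remaining = max(depth - planted_total, 0)
    if remaining:
        counts = _background_counts(remaining, design.clone_size_exponent, rng)
        for c, count in zip(generate_baseline(model, len(counts), rng), counts):
            add(c, count)

    meta = SampleMeta(
        sample_id=f"{mouse}.{tissue}.{subset}",
        mouse_id=mouse,
        tissue=tissue,
        subset=subset,
        challenge=challenge,
    )
    return Repertoire.build(
        meta, [Clonotype(c.cdr3_nt, c.cdr3_aa, c.v_segment, c.j_segment, c.d_segment, n)
               for c, n in merged.values()]
    )


def generate_cohort(design: CohortDesign, model: Optional[RecombinationModel] = None) -> Cohort:
    """Generate the full cohort described by ``design``.

    Also records ground truth (planted motif variant sets, conversion sites,
    NKT spikes) on ``Cohort.ground_truth`` so recovery can be scored.
    """
    design.validate()
    model = model or default_model()
    model.validate()
    _assign_motif_segments(design, model)

    reps: list[Repertoire] = []
    design_map: dict[str, list[str]] = {}
    for challenge in design.challenges:
        mice = design.mice(challenge)
        design_map[challenge] = mice
        for mouse in mice:
            for tissue in design.tissues:
                for subset in design.subsets:
                    reps.append(
                        _build_sample(design, model, challenge, mouse, tissue, subset)
                    )

    truth = {
        "challenge_motifs": {
            (m.target_label, m.subset_scope): set(m.variants())
            for m in design.planted_motifs
            if m.target == "challenge"
        },
        "tissue_motifs": {
            (m.target_label, m.subset_scope): set(m.variants())
            for m in design.planted_motifs
            if m.target == "tissue"
        },
        "conversion_sites": [(c.challenge, c.tissue) for c in design.conversion_specs],
        "inkt": [(k.challenge, k.tissue, k.subset, k.frequency) for k in design.inkt_specs],
    }
    return Cohort(repertoires=reps, design=design_map, ground_truth=truth)
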