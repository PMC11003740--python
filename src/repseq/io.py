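"""Readers and writers for tab-separated clonotype tables and sample manifests.

The table dialect follows the common repertoire-table convention: one row per
clonotype with columns ``count, freq, cdr3nt, cdr3aa, v, d, j`` (configurable
via a column map).  Frequencies are always recomputed from counts on read.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .repertoire import (
    Clonotype,
    Cohort,
    Repertoire,
    SampleMeta,
    strip_allele,
)

logger = logging.getLogger(__name__)

#: default column mapping: logical field -> header name
DEFAULT_COLUMNS: dict[str, str] = {
    "count": "count",
    "freq": "freq",
    "cdr3_nt": "cdr3nt",
    "cdr3_aa": "cdr3aa",
    "v_segment": "v",
    "d_segment": "d",
    "j_segment": "j",
}

MANIFEST_COLUMNS = ["sample_id", "path", "mouse_id", "tissue", "subset", "challenge"]

PathLike = Union[str, os.PathLike]


class ClonotypeTableError(ValueError):
    """Malformed clonotype table (missing columns, empty, …)."""


def read_clonotype_table(
    path: PathLike,
    meta: SampleMeta,
    column_map: Optional[Mapping[str, str]] = None,
) -> Repertoire:
    """Read a TSV clonotype table into a :class:`Repertoire`.

    Rows that fail the in-frame invariant (stop symbol in the amino-acid
    CDR3, nucleotide length ≠ 3× amino-acid length) or carry a non-positive
    count are dropped with a logged warning; the number of dropped rows is
    available as ``Repertoire.dropped_rows``.
    """
    cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mandatory = ["count", "cdr3_nt", "cdr3_aa", "v_segment", "j_segment"]
    for field in mandatory:
        if cols[field] not in df.columns:
            raise ClonotypeTableError(
                f"{path}: missing mandatory column {cols[field]!r}"
            )
    if df.empty:
        raise ClonotypeTableError(f"{path}: empty clonotype table")

    clones: list[Clonotype] = []
    dropped = 0
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            count = int(float(rec[cols["count"]]))
        except ValueError:
            dropped += 1
            continue
        c = Clonotype(
            cdr3_nt=rec[cols["cdr3_nt"]].strip().upper(),
            cdr3_aa=rec[cols["cdr3_aa"]].strip(),
            v_segment=strip_allele(rec[cols["v_segment"]]),
            j_segment=strip_allele(rec[cols["j_segment"]]),
            d_segment=strip_allele(rec.get(cols["d_segment"], "") or ""),
            count=count,
        )
        if count < 1 or not c.is_in_frame():
            dropped += 1
            continue
        clones.append(c)
    if dropped:
        logger.warning("%s: dropped %d out-of-frame/invalid rows", path, dropped)
    if not clones:
        raise ClonotypeTableError(f"{path}: no valid clonotypes after filtering")
    return Repertoire.build(meta, clones, dropped_rows=dropped)


def write_clonotype_table(
    rep: Repertoire,
    path: PathLike,
    column_map: Optional[Mapping[str, str]] = None,
) -> None:
    """Write a repertoire as a TSV table (count desc, then CDR3nt asc)."""
    if not rep.clonotypes:
        raise ValueError("refusing to write an empty repertoire")
    cols = dict(DEFAULT_COLUMNS, **(column_map or {}))
    df = pd.DataFrame(
        {
            cols["count"]: [c.count for c in rep.clonotypes],
            cols["freq"]: [repr(c.frequency) for c in rep.clonotypes],
            cols["cdr3_nt"]: [c.cdr3_nt for c in rep.clonotypes],
            cols["cdr3_aa"]: [c.cdr3_aa for c in rep.clonotypes],
            cols["v_segment"]: [c.v_segment for c in rep.clonotypes],
            cols["d_segment"]: [c.d_segment for c in rep.clonotypes],
            cols["j_segment"]: [c.j_segment for c in rep.clonotypes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    """Read a sample manifest TSV (sample_id, path, mouse_id, tissue, subset, challenge)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ClonotypeTableError(f"{path}: manifest missing columns {missing}")
    return df


def validate_manifest(path: PathLike) -> list[str]:
    """Check a manifest: required columns, readable files, unique sample keys.

    Returns a list of problem strings (empty = valid).
    """
    problems: list[str] = []
    try:
        df = read_manifest(path)
    except ClonotypeTableError as exc:
        return [str(exc)]
    base = Path(path).parent
    seen: set[tuple[str, str, str]] = set()
    for row in df.itertuples(index=False):
        key = (row.mouse_id, row.tissue, row.subset)
        if key in seen:
            problems.append(f"{row.sample_id}: duplicate (mouse, tissue, subset) {key}")
        seen.add(key)
        try:
            SampleMeta(row.sample_id, row.mouse_id, row.tissue, row.subset, row.challenge)
        except ValueError as exc:
            problems.append(f"{row.sample_id}: {exc}")
        sample_path = Path(row.path)
        if not sample_path.is_absolute():
            sample_path = base / sample_path
        if not sample_path.is_file():
            problems.append(f"{row.sample_id}: file not found: {row.path}")
    return problems


def load_cohort(manifest_path: PathLike) -> Cohort:
    """Load every sample listed in a manifest into a :class:`Cohort`."""
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    reps: list[Repertoire] = []
    design: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        meta = SampleMeta(row.sample_id, row.mouse_id, row.tissue, row.subset, row.challenge)
        sample_path = Path(row.path)
        if not sample_path.is_absolute():
            sample_path = base / sample_path
        if not sample_path.is_file():
            raise FileNotFoundError(f"sample {row.sample_id}: missing file {sample_path}")
        reps.append(read_clonotype_table(sample_path, meta))
        design.setdefault(row.challenge, [])
        if row.mouse_id not in design[row.challenge]:
            design[row.challenge].append(row.mouse_id)
    return Cohort(repertoires=reps, design=design)


def write_cohort(cohort: Cohort, outdir: PathLike) -> Path:
    """Write one TSV per sample plus a manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rep in cohort.repertoires:
        fname = f"{rep.meta.sample_id}.tsv"
        write_clonotype_table(rep, outdir / fname)
        rows.append(
            {
                "sample_id": rep.meta.sample_id,
                "path": fname,
                "mouse_id": rep.meta.mouse_id,
                "tissue": rep.meta.tissue,
                "subset": rep.meta.subset,
                "challenge": rep.meta.challenge,
            }
        )
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest
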