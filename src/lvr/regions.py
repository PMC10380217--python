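"""Region annotation on a reference sequence and length profiling.

Homology is column-based: region coordinates are given once, 1-based and
inclusive, on the *ungapped* reference sequence, and are projected through
the alignment onto every other sequence.  The projected interval for a
region runs from the column of its first reference residue up to (but not
including) the column of the first reference residue *after* the region, so
insertions that other sequences carry relative to the reference inside the
region are attributed to that region.

An absent region (such as LVR G, which has zero length in all lace bugs
analysed to date) is encoded with ``end = start - 1`` and always yields an
empty interval and length 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .alignment import Alignment

__all__ = [
    "Region",
    "RegionAnnotation",
    "SubregionTemplate",
    "read_annotation",
    "write_annotation",
    "read_groups",
    "write_groups",
    "map_region_to_columns",
    "extract_region",
    "region_length_table",
    "collapse_by_group",
    "format_value_set",
    "parse_value_set",
    "subdivide_lvr_l",
]

#: canonical order of LVR L subregion segments along the sequence,
#: 5' to 3': the unpaired L2 segment, then the nested stem halves.
SUBREGION_ORDER = ("L2", "A1", "B1", "C1", "D1", "E1", "E2", "D2", "C2", "B2", "A2")

#: paired subregions; each comprises a 5' half (X1) and a 3' half (X2)
PAIRED_SUBREGIONS = ("LA", "LB", "LC", "LD", "LE")


@dataclass(frozen=True)
class Region:
    """A named interval, 1-based inclusive, on the ungapped reference."""

    region_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region {self.region_id}: start must be >= 1")
        if self.end < self.start - 1:
            raise ValueError(
                f"region {self.region_id}: end may be at most start - 1 "
                "(empty-region convention)"
            )

    @property
    def is_empty(self) -> bool:
        return self.end == self.start - 1

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class RegionAnnotation:
    """Region intervals anchored to one reference sequence."""

    reference_id: str
    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate region id: {dup!r}")

    def region(self, region_id: str) -> Region:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"unknown region id: {region_id!r}")

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(r.region_id for r in self.regions)


@dataclass(frozen=True)
class SubregionTemplate:
    """Tiling of the reference's LVR L into ordered subregion segments.

    Segment coordinates are 1-based inclusive *within* LVR L (position 1 is
    the first residue of LVR L on the reference).  The segments must tile
    LVR L contiguously in :data:`SUBREGION_ORDER`; a zero-length segment is
    encoded with ``end = start - 1``.
    """

    segments: tuple[Region, ...]

    def __post_init__(self) -> None:
        labels = tuple(s.region_id for s in self.segments)
        if labels != SUBREGION_ORDER:
            raise ValueError(
                f"subregion labels must be {SUBREGION_ORDER} in order, "
                f"got {labels}"
            )
        cursor = 1
        for seg in self.segments:
            if seg.start != cursor:
                raise ValueError(
                    f"subregion {seg.region_id} does not tile: expected "
                    f"start {cursor}, got {seg.start}"
                )
            cursor = seg.end + 1

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def segment(self, label: str) -> Region:
        for s in self.segments:
            if s.region_id == label:
                return s
        raise KeyError(f"unknown subregion label: {label!r}")


# ---------------------------------------------------------------------------
# TSV I/O


def read_annotation(path: str | Path, reference_id: str | None = None) -> RegionAnnotation:
    """Read a region annotation TSV (columns region_id, start, end).

    The reference identifier is taken from a ``#reference=<id>`` comment line
    if present, else from the *reference_id* argument.
    """
    path = Path(path)
    ref = reference_id
    for line in path.read_text().splitlines():
        if line.startswith("#reference="):
            ref = line.split("=", 1)[1].strip()
    if ref is None:
        raise ValueError(
            f"{path}: no '#reference=' line and no reference_id given"
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"region_id", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation TSV needs columns {sorted(required)}")
    regions = tuple(
        Region(str(r.region_id), int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    )
    return RegionAnnotation(ref, regions)


def write_annotation(ann: RegionAnnotation, path: str | Path) -> None:
    lines = [f"#reference={ann.reference_id}", "region_id\tstart\tend"]
    lines += [f"{r.region_id}\t{r.start}\t{r.end}" for r in ann.regions]
    Path(path).write_text("\n".join(lines) + "\n")


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a sequence-to-taxon-group mapping TSV (sequence_id, taxon_group)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"sequence_id", "taxon_group"}.issubset(df.columns):
        raise ValueError(
            f"{path}: groups TSV needs columns sequence_id, taxon_group"
        )
    return {str(r.sequence_id): str(r.taxon_group) for r in df.itertuples(index=False)}


def write_groups(groups: Mapping[str, str], path: str | Path) -> None:
    lines = ["sequence_id\ttaxon_group"]
    lines += [f"{sid}\t{grp}" for sid, grp in groups.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Coordinate projection


def _residue_columns(gapped: str) -> list[int]:
    """0-based column index of each ungapped residue, in residue order."""
    return [i for i, c in enumerate(gapped) if c != "-"]


def _interval_to_columns(
    gapped_ref: str, start: int, end: int, aln_length: int
) -> tuple[int, int]:
    """Project a 1-based inclusive ungapped interval to a half-open column span."""
    cols = _residue_columns(gapped_ref)
    n = len(cols)
    if end == start - 1:  # empty region
        if start > n + 1:
            raise ValueError(
                f"coordinate {start} beyond ungapped reference length {n}"
            )
        anchor = cols[start - 1] if start <= n else aln_length
        return (anchor, anchor)
    if end > n:
        raise ValueError(f"coordinate {end} beyond ungapped reference length {n}")
    col_start = cols[start - 1]
    col_stop = cols[end] if end < n else aln_length
    return (col_start, col_stop)


def map_region_to_columns(
    alignment: Alignment, annotation: RegionAnnotation
) -> dict[str, tuple[int, int]]:
    """Project every annotated region to a half-open 0-based column interval."""
    if annotation.reference_id not in alignment.ids:
        raise ValueError(
            f"reference {annotation.reference_id!r} absent from alignment"
        )
    ref = alignment.sequence(annotation.reference_id)
    return {
        r.region_id: _interval_to_columns(ref, r.start, r.end, alignment.length)
        for r in annotation.regions
    }


def extract_region(
    alignment: Alignment,
    annotation: RegionAnnotation,
    region_id: str,
    sequence_id: str,
) -> str:
    """Gap-stripped residues of *sequence_id* within the mapped region columns."""
    spans = map_region_to_columns(alignment, annotation)
    if region_id not in spans:
        raise KeyError(f"unknown region id: {region_id!r}")
    lo, hi = spans[region_id]
    seq = alignment.sequence(sequence_id)  # raises KeyError for unknown ids
    return seq[lo:hi].replace("-", "")


# ---------------------------------------------------------------------------
# Length tables


def region_length_table(
    alignment: Alignment,
    annotation: RegionAnnotation,
    groups: Mapping[str, str],
    region_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-sequence region lengths: one row per sequence, one column per region.

    Raises
    ------
    ValueError
        If any aligned sequence lacks a taxon-group assignment.
    """
    missing = [sid for sid in alignment.ids if sid not in groups]
    if missing:
        raise ValueError(
            "sequences missing a group assignment: " + ", ".join(missing)
        )
    if region_ids is None:
        region_ids = annotation.region_ids
    spans = map_region_to_columns(alignment, annotation)
    rows = []
    for sid in alignment.ids:
        seq = alignment.sequence(sid)
        row: dict[str, object] = {"sequence_id": sid, "taxon_group": groups[sid]}
        for rid in region_ids:
            lo, hi = spans[rid]
            row[rid] = hi - lo - seq.count("-", lo, hi)
        rows.append(row)
    return pd.DataFrame(rows)


def format_value_set(values: set[int] | frozenset[int]) -> str:
    """Render a set of integer lengths as ``"n"`` or ``"min-max"``."""
    if not values:
        raise ValueError("empty value set")
    lo, hi = min(values), max(values)
    return str(lo) if lo == hi else f"{lo}-{hi}"


def parse_value_set(text: str) -> frozenset[int]:
    """Parse ``"n"`` or ``"a-b"`` (hyphen or en-dash) into an integer set.

    A printed range is taken as the full closed integer interval.
    """
    text = str(text).strip().replace("–", "-")
    if "-" in text:
        a, b = text.split("-", 1)
        lo, hi = int(a), int(b)
        if hi < lo:
            raise ValueError(f"descending range: {text!r}")
        return frozenset(range(lo, hi + 1))
    return frozenset({int(text)})


def collapse_by_group(
    table: pd.DataFrame, region_ids: Sequence[str] | None = None
) -> dict[str, dict[str, frozenset[int]]]:
    """Collapse a per-sequence length table to per-group value sets.

    Returns ``{group: {region_id: frozenset of observed lengths}}``.
    """
    if region_ids is None:
        region_ids = [
            c for c in table.columns if c not in ("sequence_id", "taxon_group")
        ]
    out: dict[str, dict[str, frozenset[int]]] = {}
    for grp, sub in table.groupby("taxon_group", sort=False):
        out[str(grp)] = {
            rid: frozenset(int(v) for v in sub[rid]) for rid in region_ids
        }
    return out


# ---------------------------------------------------------------------------
# LVR L subdivision


def subdivide_lvr_l(
    sequence_id: str,
    alignment: Alignment,
    annotation: RegionAnnotation,
    template: SubregionTemplate,
    lvr_l_id: str = "L",
) -> dict[str, int]:
    """Count residues of *sequence_id* in each LVR L subregion segment.

    Returns a dict keyed by segment label (L2, A1...A2), by paired subregion
    (LA...LE = half1 + half2) and by ``"total"``.  The template must tile the
    reference's LVR L exactly.
    """
    lvr_l = annotation.region(lvr_l_id)
    if template.total_length != lvr_l.length:
        raise ValueError(
            f"subregion template (length {template.total_length}) does not "
            f"tile LVR {lvr_l_id} (length {lvr_l.length})"
        )
    # absolute segment coordinates on the ungapped reference
    abs_segments = tuple(
        Region(s.region_id, lvr_l.start + s.start - 1, lvr_l.start + s.end - 1)
        for s in template.segments
    )
    abs_ann = RegionAnnotation(annotation.reference_id, abs_segments)
    counts: dict[str, int] = {}
    for seg in abs_segments:
        counts[seg.region_id] = len(
            extract_region(alignment, abs_ann, seg.region_id, sequence_id)
        )
    for name in PAIRED_SUBREGIONS:
        half = name[1]  # 'A'..'E'
        counts[name] = counts[f"{half}1"] + counts[f"{half}2"]
    counts["total"] = sum(counts[lbl] for lbl in SUBREGION_ORDER)
    return counts
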