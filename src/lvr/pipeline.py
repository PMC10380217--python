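"""End-to-end pipeline: alignment -> site stats -> region tables -> calls.

Composes the library stages over files on disk and writes every stage
output as both TSV and JSON, plus a human-readable summary.  Re-running on
identical inputs produces identical reports.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .alignment import SiteSummary, read_alignment, summarize_alignment
from .apomorphy import (
    ApomorphyCall,
    CharacterMatrix,
    build_character_matrix,
    calls_to_frame,
    detect_autapomorphies,
    detect_synapomorphies,
)
from .regions import (
    PAIRED_SUBREGIONS,
    Region,
    SubregionTemplate,
    format_value_set,
    read_annotation,
    read_groups,
    region_length_table,
    subdivide_lvr_l,
)
from .structure import (
    PairCensus,
    SecondaryStructure,
    census_pairs,
    group_by_structure,
    parse_structure,
)

logger = logging.getLogger("lvr")

__all__ = ["ReportBundle", "run_pipeline", "read_subregion_template"]


def read_subregion_template(path: str | Path) -> SubregionTemplate:
    """Read a subregion template TSV (columns segment, start, end)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"segment", "start", "end"}.issubset(df.columns):
        raise ValueError(f"{path}: template TSV needs columns segment, start, end")
    return SubregionTemplate(
        tuple(
            Region(str(r.segment), int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        )
    )


@dataclass(frozen=True)
class ReportBundle:
    """All stage outputs of one pipeline run."""

    site_summary: SiteSummary
    region_table: pd.DataFrame
    group_table: pd.DataFrame
    subregion_table: pd.DataFrame | None
    lvr_matrix: CharacterMatrix
    subregion_matrix: CharacterMatrix | None
    autapomorphies: tuple[ApomorphyCall, ...]
    synapomorphies: tuple[ApomorphyCall, ...]
    pair_censuses: dict[str, PairCensus]
    consensus_groups: list[tuple[str, list[str]]]


def _group_table(matrix: CharacterMatrix) -> pd.DataFrame:
    df = matrix.to_frame()
    df.index.name = "taxon_group"
    return df.reset_index()


def _marked_matrix_frame(
    matrix: CharacterMatrix, calls: Sequence[ApomorphyCall]
) -> pd.DataFrame:
    """Matrix rendering with {auto}/{syn} text tags on called cells."""
    tags: dict[tuple[str, str], str] = {}
    for c in calls:
        tag = "auto" if c.call_type == "autapomorphy" else "syn"
        for g in c.bearer:
            tags[(g, c.character)] = tag
    rows = []
    for g in matrix.groups:
        row: dict[str, str] = {"taxon_group": g}
        for ch in matrix.characters:
            cell = format_value_set(matrix.cell(g, ch))
            if (g, ch) in tags:
                cell = f"{cell} {{{tags[(g, ch)]}}}"
            row[ch] = cell
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    alignment_path: str | Path,
    annotation_path: str | Path,
    groups_path: str | Path,
    outgroup: str,
    out_dir: str | Path,
    structures: Mapping[str, str | Path] | None = None,
    subregion_template_path: str | Path | None = None,
    reference_id: str | None = None,
) -> ReportBundle:
    """Run every analysis stage and write the report files into *out_dir*.

    *structures* optionally maps sequence ids to structure files (CT or
    dot-bracket) for the pair census and consensus grouping stages;
    *subregion_template_path* enables the LVR L subdivision stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    alignment = read_alignment(alignment_path)
    annotation = read_annotation(annotation_path, reference_id=reference_id)
    groups = read_groups(groups_path)
    logger.info(
        "loaded %d sequences x %d columns", alignment.n_records, alignment.length
    )

    site_summary = summarize_alignment(alignment)
    (out / "site_summary.tsv").write_text(site_summary.to_tsv())
    (out / "site_summary.json").write_text(site_summary.to_json() + "\n")

    table = region_length_table(alignment, annotation, groups)
    table.to_csv(out / "region_lengths.tsv", sep="\t", index=False)

    lvr_characters = [
        r.region_id for r in annotation.regions if r.region_id not in ("V2", "V4", "V7")
    ]
    lvr_matrix = build_character_matrix(table, outgroup, characters=lvr_characters)
    group_table = _group_table(lvr_matrix)
    group_table.to_csv(out / "lvr_lengths_by_group.tsv", sep="\t", index=False)

    subregion_table = None
    subregion_matrix = None
    if subregion_template_path is not None:
        template = read_subregion_template(subregion_template_path)
        sub_rows = []
        for sid in alignment.ids:
            counts = subdivide_lvr_l(sid, alignment, annotation, template)
            counts_row: dict[str, object] = {
                "sequence_id": sid,
                "taxon_group": groups[sid],
            }
            counts_row.update(counts)
            sub_rows.append(counts_row)
        subregion_table = pd.DataFrame(sub_rows)
        subregion_table.to_csv(out / "lvr_l_subregions.tsv", sep="\t", index=False)
        subregion_matrix = build_character_matrix(
            subregion_table, outgroup, characters=["L2", *PAIRED_SUBREGIONS]
        )

    call_matrix = subregion_matrix if subregion_matrix is not None else lvr_matrix
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        autapomorphies = tuple(detect_autapomorphies(lvr_matrix))
        synapomorphies = tuple(detect_synapomorphies(lvr_matrix))
        if subregion_matrix is not None:
            autapomorphies += tuple(detect_autapomorphies(subregion_matrix))
            synapomorphies += tuple(detect_synapomorphies(subregion_matrix))
    calls = list(autapomorphies) + list(synapomorphies)
    calls_to_frame(calls).to_csv(out / "apomorphy_calls.tsv", sep="\t", index=False)
    (out / "apomorphy_calls.json").write_text(
        json.dumps([c.to_dict() for c in calls], indent=2) + "\n"
    )
    _marked_matrix_frame(call_matrix, calls).to_csv(
        out / "character_matrix_marked.tsv", sep="\t", index=False
    )

    pair_censuses: dict[str, PairCensus] = {}
    consensus: list[tuple[str, list[str]]] = []
    if structures:
        parsed: dict[str, SecondaryStructure] = {
            sid: parse_structure(p) for sid, p in structures.items()
        }
        pair_censuses = {sid: census_pairs(s) for sid, s in parsed.items()}
        pd.DataFrame(
            [{"sequence_id": sid, **c.to_dict()} for sid, c in pair_censuses.items()]
        ).drop(columns=["breakdown"]).to_csv(
            out / "pair_census.tsv", sep="\t", index=False
        )
        consensus = group_by_structure(parsed)
        pd.DataFrame(
            [
                {"representative": rep, "members": ";".join(members)}
                for rep, members in consensus
            ]
        ).to_csv(out / "consensus_groups.tsv", sep="\t", index=False)

    summary = [
        f"sequences: {alignment.n_records}",
        f"alignment columns: {alignment.length}",
        f"conserved sites: {site_summary.n_conserved}",
        f"variable sites: {site_summary.n_variable} "
        f"(parsimony-informative {site_summary.n_parsimony_informative}, "
        f"singletons {site_summary.n_singleton})",
        f"autapomorphy calls: {len(autapomorphies)}",
        f"synapomorphy calls: {len(synapomorphies)}",
    ]
    if consensus:
        summary.append(f"consensus structure groups: {len(consensus)}")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)

    return ReportBundle(
        site_summary=site_summary,
        region_table=table,
        group_table=group_table,
        subregion_table=subregion_table,
        lvr_matrix=lvr_matrix,
        subregion_matrix=subregion_matrix,
        autapomorphies=autapomorphies,
        synapomorphies=synapomorphies,
        pair_censuses=pair_censuses,
        consensus_groups=consensus,
    )
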