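"""Seeded generator of 18S-like synthetic cohorts with known truth.

The generator emulates the variability structure of lace-bug 18S rRNA
sequences: a conserved backbone shared by all taxa, three hypervariable
regions (V2, V4, V7) hosting thirteen length-variable regions (LVRs B-X,
with LVR G empty in every taxon), and taxon groups that differ only in the
planted per-group LVR lengths.  Indels occur exclusively inside LVRs, so
the emitted alignment's column homology is exact by construction and every
truth table is computed from the plan rather than re-measured.

LVR L is built as a hairpin: the unpaired L2 segment followed by nested
stem halves A1 B1 C1 D1 E1 | loop | E2 D2 C2 B2 A2, with complementary
half-segments, so the exact maximum-pairing folder can recover the planted
stems and each group's planted structure serves as that group's archetype
for consensus grouping.

All randomness flows from one ``numpy`` generator stream; a given
(config, seed) is byte-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .alignment import Alignment, write_alignment
from .apomorphy import (
    ApomorphyCall,
    CharacterMatrix,
    build_character_matrix,
    detect_autapomorphies,
    detect_synapomorphies,
)
from .regions import (
    PAIRED_SUBREGIONS,
    SUBREGION_ORDER,
    Region,
    RegionAnnotation,
    SubregionTemplate,
    write_annotation,
    write_groups,
)
from .structure import SecondaryStructure, write_dotbracket

__all__ = [
    "GroupPlan",
    "SimulationConfig",
    "TruthBundle",
    "default_config",
    "generate_template",
    "simulate_cohort",
]

#: LVRs outside LVR L, in 5'->3' layout order
SHORT_LVRS = ("B", "D", "E", "F", "G", "M", "X", "U", "R", "S", "T", "W")

#: all thirteen LVR ids in the conventional (tabular) order
LVR_IDS = ("B", "D", "E", "F", "G", "L", "M", "S", "T", "U", "R", "W", "X")

# conserved spacer lengths of the backbone layout; "." entries are LVR slots
# and "[V" / "V]" mark hypervariable region boundaries
_LAYOUT: tuple[tuple[str, object], ...] = (
    ("spacer", 120),
    ("lvr", "B"),
    ("spacer", 60),
    ("lvr", "D"),
    ("spacer", 80),
    ("vstart", "V2"),
    ("spacer", 60),
    ("lvr", "E"),
    ("spacer", 60),
    ("lvr", "F"),
    ("spacer", 69),
    ("lvr", "G"),
    ("vend", "V2"),
    ("spacer", 100),
    ("lvr", "M"),
    ("spacer", 100),
    ("vstart", "V4"),
    ("spacer", 120),
    ("lvr", "L"),
    ("spacer", 117),
    ("lvr", "X"),
    ("vend", "V4"),
    ("spacer", 80),
    ("lvr", "U"),
    ("spacer", 40),
    ("lvr", "R"),
    ("spacer", 60),
    ("vstart", "V7"),
    ("spacer", 40),
    ("lvr", "S"),
    ("spacer", 38),
    ("lvr", "T"),
    ("vend", "V7"),
    ("spacer", 60),
    ("lvr", "W"),
    ("spacer", 120),
)

_BASES = np.array(list("ACGT"))
# stem pair alphabet with roughly rRNA-like class frequencies
_PAIR_CHOICES = ("GC", "CG", "AU", "UA", "GU", "UG")
_PAIR_WEIGHTS = (0.33, 0.33, 0.1, 0.1, 0.07, 0.07)


@dataclass(frozen=True)
class GroupPlan:
    """Planted lengths for one taxon group.

    ``lvr_lengths`` maps each short LVR id to the cycle of target lengths
    its sequences realise in turn (a one-element tuple plants a fixed
    length); ``subregion_halves`` gives the LVR L segment lengths in
    :data:`~lvr.regions.SUBREGION_ORDER`.
    """

    name: str
    n_sequences: int
    lvr_lengths: Mapping[str, tuple[int, ...]]
    subregion_halves: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_sequences < 1:
            raise ValueError(f"group {self.name}: n_sequences must be >= 1")
        missing = [r for r in SHORT_LVRS if r not in self.lvr_lengths]
        if missing:
            raise ValueError(f"group {self.name}: missing LVR lengths {missing}")
        missing = [s for s in SUBREGION_ORDER if s not in self.subregion_halves]
        if missing:
            raise ValueError(f"group {self.name}: missing subregions {missing}")
        if "L" in self.lvr_lengths:
            target = self.lvr_lengths["L"]
            total = self.lvr_l_total
            if tuple(target) != (total,):
                raise ValueError(
                    f"group {self.name}: LVR L target {target} inconsistent "
                    f"with subregion halves (sum {total})"
                )

    @property
    def lvr_l_total(self) -> int:
        return sum(self.subregion_halves[s] for s in SUBREGION_ORDER)

    def length_of(self, region: str, index: int) -> int:
        """Planted length of *region* for the group's *index*-th sequence."""
        if region == "L":
            return self.lvr_l_total
        cycle = tuple(self.lvr_lengths[region])
        return cycle[index % len(cycle)]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition description for one synthetic cohort."""

    seed: int = 0
    groups: tuple[GroupPlan, ...] = ()
    outgroup: str = "Outgroup"
    substitution_rate: float = 0.02
    min_loop: int = 3

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("config needs at least one group")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names")
        if self.outgroup not in names:
            raise ValueError(f"outgroup {self.outgroup!r} not among groups")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be in [0, 1]")


def _halves(l2, a1, a2, b1, b2, c1, c2, d1, d2, e1, e2) -> dict[str, int]:
    return {
        "L2": l2, "A1": a1, "A2": a2, "B1": b1, "B2": b2, "C1": c1,
        "C2": c2, "D1": d1, "D2": d2, "E1": e1, "E2": e2,
    }


def default_config(seed: int = 0) -> SimulationConfig:
    """The default cohort: five taxon groups mirroring the published LVR and
    LVR L subregion length profiles of Tingidae consensus species, with the
    group sizes of the secondary-structure analysis (3 outgroup, 4
    Acalyptaini, 1 Litadeini, 7 Tingini, 1 Cantacaderinae)."""

    def short(b, d, e, f, m, s, t, u, r, w, x) -> dict[str, tuple[int, ...]]:
        as_cycle = lambda v: tuple(v) if isinstance(v, (tuple, list)) else (v,)
        return {
            "B": as_cycle(b), "D": as_cycle(d), "E": as_cycle(e),
            "F": as_cycle(f), "G": (0,), "M": as_cycle(m), "S": as_cycle(s),
            "T": as_cycle(t), "U": as_cycle(u), "R": as_cycle(r),
            "W": as_cycle(w), "X": as_cycle(x),
        }

    groups = (
        GroupPlan(
            "Outgroup", 3,
            short(12, 6, 5, 4, 4, 6, 7, 13, 5, 3, 6),
            _halves(4, 9, 9, 10, 9, 3, 4, 6, 5, 8, 7),  # LVR L = 74
        ),
        GroupPlan(
            "Acalyptaini", 4,
            short(11, 5, 4, 5, 4, 5, 7, 13, 5, 3, (3, 4)),
            _halves(4, 10, 9, 11, 10, 4, 4, 5, 5, 8, 8),  # LVR L = 78
        ),
        GroupPlan(
            "Litadeini", 1,
            short(11, 4, 5, 5, 4, 5, 7, 13, 5, 3, 6),
            _halves(4, 10, 9, 13, 11, 4, 4, 5, 5, 8, 8),  # LVR L = 81
        ),
        GroupPlan(
            "Tingini", 7,
            short(11, 5, (4, 5), 5, 4, 5, 7, 13, 5, 3, (5, 6)),
            _halves(5, 10, 9, 11, 11, 3, 5, 6, 4, 7, 7),  # LVR L = 78
        ),
        GroupPlan(
            "Cantacaderinae", 1,
            short(11, 5, 5, 4, 4, 5, 7, 13, 5, 3, 5),
            _halves(4, 9, 9, 0, 0, 7, 5, 7, 7, 4, 5),  # LVR L = 57
        ),
    )
    return SimulationConfig(seed=seed, groups=groups)


@dataclass(frozen=True)
class TruthBundle:
    """A simulated cohort together with its plan-derived expectations."""

    config: SimulationConfig
    alignment: Alignment
    annotation: RegionAnnotation
    template: SubregionTemplate
    groups: dict[str, str]
    region_table: pd.DataFrame
    subregion_table: pd.DataFrame
    lvr_matrix: CharacterMatrix
    subregion_matrix: CharacterMatrix
    expected_autapomorphies: tuple[ApomorphyCall, ...]
    expected_synapomorphies: tuple[ApomorphyCall, ...]
    structures: dict[str, SecondaryStructure]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write alignment, annotation, subregion template, groups, planted
        structures and a truth JSON; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": out / "alignment.fasta",
            "annotation": out / "regions.tsv",
            "subregions": out / "subregions.tsv",
            "groups": out / "groups.tsv",
            "structures": out / "structures.dbn",
            "truth": out / "truth.json",
        }
        write_alignment(self.alignment, paths["alignment"])
        write_annotation(self.annotation, paths["annotation"])
        lines = ["segment\tstart\tend"] + [
            f"{s.region_id}\t{s.start}\t{s.end}" for s in self.template.segments
        ]
        paths["subregions"].write_text("\n".join(lines) + "\n")
        write_groups(self.groups, paths["groups"])
        with open(paths["structures"], "w") as fh:
            for sid in self.alignment.ids:
                fh.write(write_dotbracket(self.structures[sid], name=sid))
        truth = {
            "seed": self.config.seed,
            "outgroup": self.config.outgroup,
            "region_table": self.region_table.to_dict(orient="records"),
            "subregion_table": self.subregion_table.to_dict(orient="records"),
            "expected_autapomorphies": [
                c.to_dict() for c in self.expected_autapomorphies
            ],
            "expected_synapomorphies": [
                c.to_dict() for c in self.expected_synapomorphies
            ],
        }
        paths["truth"].write_text(json.dumps(truth, indent=2) + "\n")
        return paths


# ---------------------------------------------------------------------------
# sequence construction helpers


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def _build_lvr_l(
    rng: np.random.Generator, halves: Mapping[str, int], min_loop: int
) -> tuple[str, dict[int, int]]:
    """Build an LVR L hairpin realisation: sequence plus 0-based pairing map.

    Paired subregions get complementary half-segments; the innermost stem
    (E) leaves at least *min_loop* unpaired bases as the hairpin loop.
    """
    lengths = {s: halves[s] for s in SUBREGION_ORDER}
    offsets: dict[str, int] = {}
    pos = 0
    for s in SUBREGION_ORDER:
        offsets[s] = pos
        pos += lengths[s]
    total = pos
    seq = list(_random_bases(rng, total))
    pairs: dict[int, int] = {}
    for name in PAIRED_SUBREGIONS:
        half = name[1]
        h1, h2 = lengths[f"{half}1"], lengths[f"{half}2"]
        n_pair = min(h1, h2)
        if half == "E":  # innermost stem: reserve the hairpin loop
            n_pair = min(n_pair, max(0, (h1 + h2 - min_loop) // 2))
        for i in range(n_pair):
            p = offsets[f"{half}1"] + i
            q = offsets[f"{half}2"] + h2 - 1 - i
            a, b = rng.choice(_PAIR_CHOICES, p=_PAIR_WEIGHTS)
            seq[p], seq[q] = a.replace("U", "T"), b.replace("U", "T")
            pairs[p], pairs[q] = q, p
    return "".join(seq), pairs


def generate_template(
    config: SimulationConfig,
) -> tuple[str, RegionAnnotation, SubregionTemplate]:
    """Build the reference sequence (the outgroup archetype) and its
    region annotation and LVR L subregion template."""
    rng = np.random.default_rng(config.seed)
    outgroup_plan = next(g for g in config.groups if g.name == config.outgroup)
    parts: list[str] = []
    regions: list[Region] = []
    v_start: dict[str, int] = {}
    pos = 1  # 1-based ungapped coordinate of the next residue
    for kind, arg in _LAYOUT:
        if kind == "spacer":
            parts.append(_random_bases(rng, int(arg)))
            pos += int(arg)
        elif kind == "vstart":
            v_start[str(arg)] = pos
        elif kind == "vend":
            regions.append(Region(str(arg), v_start[str(arg)], pos - 1))
        elif kind == "lvr":
            rid = str(arg)
            if rid == "L":
                seq, _ = _build_lvr_l(
                    rng, outgroup_plan.subregion_halves, config.min_loop
                )
                length = len(seq)
            else:
                length = outgroup_plan.length_of(rid, 0)
                seq = _random_bases(rng, length)
            parts.append(seq)
            regions.append(Region(rid, pos, pos + length - 1))
            pos += length
    reference = "".join(parts)
    annotation = RegionAnnotation("reference", tuple(regions))
    segments = []
    cursor = 1
    for s in SUBREGION_ORDER:
        n = outgroup_plan.subregion_halves[s]
        segments.append(Region(s, cursor, cursor + n - 1))
        cursor += n
    return reference, annotation, SubregionTemplate(tuple(segments))


# ---------------------------------------------------------------------------
# cohort simulation


def _sequence_ids(config: SimulationConfig) -> list[tuple[str, str, int]]:
    """(sequence_id, group, within-group index) in emission order."""
    out = []
    for plan in config.groups:
        for i in range(plan.n_sequences):
            out.append((f"{plan.name}_{i + 1:02d}", plan.name, i))
    return out


def simulate_cohort(config: SimulationConfig | None = None, seed: int | None = None) -> TruthBundle:
    """Simulate an aligned cohort realising the config's planted lengths.

    Substitutions are applied only at conserved (non-LVR) sites, so every
    region length — and hence every character — matches the plan exactly.
    The first outgroup sequence is the annotation reference and receives no
    substitutions.
    """
    if config is None:
        config = default_config()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)

    # group-level LVR content: one realisation per (group, region, cycle slot)
    plans = {g.name: g for g in config.groups}
    lvr_content: dict[tuple[str, str, int], str] = {}
    lvr_l: dict[str, tuple[str, dict[int, int]]] = {}
    for plan in config.groups:
        lvr_l[plan.name] = _build_lvr_l(
            rng, plan.subregion_halves, config.min_loop
        )
        for rid in SHORT_LVRS:
            for slot, n in enumerate(plan.lvr_lengths[rid]):
                lvr_content[(plan.name, rid, slot)] = _random_bases(rng, n)

    # conserved spacer backbone, shared by the whole cohort
    spacers = [
        _random_bases(rng, int(arg)) for kind, arg in _LAYOUT if kind == "spacer"
    ]

    seq_info = _sequence_ids(config)
    reference_id = next(
        sid for sid, grp, i in seq_info if grp == config.outgroup and i == 0
    )

    def mutate(text: str) -> str:
        if config.substitution_rate == 0 or not text:
            return text
        chars = np.array(list(text))
        hit = rng.random(len(chars)) < config.substitution_rate
        if hit.any():
            chars[hit] = rng.choice(_BASES, size=int(hit.sum()))
        return "".join(chars)

    # assemble per-sequence segment lists; pad each variable block to the
    # cohort-wide maximum so columns are homologous by construction
    def segment_content(grp: str, idx: int, rid: str) -> str:
        plan = plans[grp]
        if rid == "L":
            return lvr_l[grp][0]
        cycle = tuple(plan.lvr_lengths[rid])
        return lvr_content[(grp, rid, idx % len(cycle))]

    rows: dict[str, list[str]] = {sid: [] for sid, _, _ in seq_info}
    spacer_iter_positions = [k for k, (kind, _) in enumerate(_LAYOUT) if kind == "spacer"]
    spacer_of = dict(zip(spacer_iter_positions, spacers))
    for k, (kind, arg) in enumerate(_LAYOUT):
        if kind == "spacer":
            text = spacer_of[k]
            for sid, grp, idx in seq_info:
                rows[sid].append(text if sid == reference_id else mutate(text))
        elif kind == "lvr" and arg != "L":
            contents = {
                sid: segment_content(grp, idx, str(arg))
                for sid, grp, idx in seq_info
            }
            width = max(len(c) for c in contents.values())
            for sid in rows:
                rows[sid].append(contents[sid].ljust(width, "-"))
        elif kind == "lvr" and arg == "L":
            # one padded block per subregion segment keeps half-homology exact
            for s in SUBREGION_ORDER:
                pieces = {}
                for sid, grp, idx in seq_info:
                    halves = plans[grp].subregion_halves
                    offset = sum(
                        halves[t] for t in SUBREGION_ORDER[: SUBREGION_ORDER.index(s)]
                    )
                    pieces[sid] = lvr_l[grp][0][offset : offset + halves[s]]
                width = max(len(p) for p in pieces.values())
                for sid in rows:
                    rows[sid].append(pieces[sid].ljust(width, "-"))
    alignment = Alignment(
        tuple((sid, "".join(rows[sid])) for sid, _, _ in seq_info)
    )

    # annotation anchored on the reference sequence
    _, annotation, template = _template_from_plan(config)
    annotation = RegionAnnotation(reference_id, annotation.regions)

    groups_map = {sid: grp for sid, grp, _ in seq_info}

    # truth tables straight from the plan
    region_rows = []
    sub_rows = []
    for sid, grp, idx in seq_info:
        plan = plans[grp]
        row: dict[str, object] = {"sequence_id": sid, "taxon_group": grp}
        for rid in LVR_IDS:
            row[rid] = plan.length_of(rid, idx)
        for vid in ("V2", "V4", "V7"):
            row[vid] = _v_region_length(plan, idx, vid)
        region_rows.append(row)
        srow: dict[str, object] = {"sequence_id": sid, "taxon_group": grp}
        for s in SUBREGION_ORDER:
            srow[s] = plan.subregion_halves[s]
        for name in PAIRED_SUBREGIONS:
            srow[name] = (
                plan.subregion_halves[f"{name[1]}1"]
                + plan.subregion_halves[f"{name[1]}2"]
            )
        srow["L2"] = plan.subregion_halves["L2"]
        srow["total"] = plan.lvr_l_total
        sub_rows.append(srow)
    region_table = pd.DataFrame(region_rows)
    subregion_table = pd.DataFrame(sub_rows)

    lvr_matrix = build_character_matrix(
        region_table, config.outgroup, characters=list(LVR_IDS)
    )
    subregion_matrix = build_character_matrix(
        subregion_table, config.outgroup, characters=["L2", *PAIRED_SUBREGIONS]
    )

    structures = {
        sid: SecondaryStructure(
            lvr_l[grp][0].replace("T", "U"), lvr_l[grp][1]
        )
        for sid, grp, _ in seq_info
    }

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        expected_auto = detect_autapomorphies(subregion_matrix)
        expected_syn = detect_synapomorphies(subregion_matrix)

    return TruthBundle(
        config=config,
        alignment=alignment,
        annotation=annotation,
        template=template,
        groups=groups_map,
        region_table=region_table,
        subregion_table=subregion_table,
        lvr_matrix=lvr_matrix,
        subregion_matrix=subregion_matrix,
        expected_autapomorphies=tuple(expected_auto),
        expected_synapomorphies=tuple(expected_syn),
        structures=structures,
    )


def _template_from_plan(
    config: SimulationConfig,
) -> tuple[None, RegionAnnotation, SubregionTemplate]:
    """Region annotation implied by the layout and the outgroup plan
    (coordinate arithmetic only; no sequence material is drawn)."""
    outgroup_plan = next(g for g in config.groups if g.name == config.outgroup)
    regions: list[Region] = []
    v_start: dict[str, int] = {}
    pos = 1
    for kind, arg in _LAYOUT:
        if kind == "spacer":
            pos += int(arg)
        elif kind == "vstart":
            v_start[str(arg)] = pos
        elif kind == "vend":
            regions.append(Region(str(arg), v_start[str(arg)], pos - 1))
        elif kind == "lvr":
            length = outgroup_plan.length_of(str(arg), 0)
            regions.append(Region(str(arg), pos, pos + length - 1))
            pos += length
    segments = []
    cursor = 1
    for s in SUBREGION_ORDER:
        n = outgroup_plan.subregion_halves[s]
        segments.append(Region(s, cursor, cursor + n - 1))
        cursor += n
    return None, RegionAnnotation("reference", tuple(regions)), SubregionTemplate(
        tuple(segments)
    )


def _v_region_length(plan: GroupPlan, idx: int, vid: str) -> int:
    """Planted length of a hypervariable region: its conserved spacers plus
    the planted lengths of the LVRs it hosts."""
    inside = False
    total = 0
    for kind, arg in _LAYOUT:
        if kind == "vstart" and arg == vid:
            inside = True
        elif kind == "vend" and arg == vid:
            break
        elif inside and kind == "spacer":
            total += int(arg)
        elif inside and kind == "lvr":
            total += plan.length_of(str(arg), idx)
    return total
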