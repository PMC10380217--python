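"""Rule-based detection of morpho-molecular apomorphies.

Characters are nucleotide counts of regions or subregions; a taxon group's
state for a character is the *set* of counts observed across its sequences
(a printed range such as ``3-4`` denotes the closed integer interval).
Character states are polarised against one designated outgroup:

* **autapomorphy** — an ingroup whose value set is disjoint from every other
  group's set (outgroup included) for that character;
* **synapomorphy** — a maximal set of two or more ingroups sharing one
  identical singleton value that occurs in no other group's set and not in
  the outgroup's.

The rules are purely value-based; no tree topology is consulted.  An
optional clade restriction can limit which ingroup subsets are considered
as synapomorphy bearers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .regions import collapse_by_group, format_value_set, parse_value_set

__all__ = [
    "CharacterMatrix",
    "ApomorphyCall",
    "build_character_matrix",
    "detect_autapomorphies",
    "detect_synapomorphies",
    "detect_apomorphies",
]


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxon-group x character matrix of integer value sets.

    Exactly one group is the outgroup; every cell is a non-empty frozenset
    of integers.
    """

    groups: tuple[str, ...]
    outgroup: str
    characters: tuple[str, ...]
    values: Mapping[tuple[str, str], frozenset[int]]

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group names")
        if len(set(self.characters)) != len(self.characters):
            raise ValueError("duplicate character names")
        if self.outgroup not in self.groups:
            raise ValueError(f"outgroup {self.outgroup!r} not among groups")
        for g in self.groups:
            for c in self.characters:
                cell = self.values.get((g, c))
                if not cell:
                    raise ValueError(f"empty or missing cell ({g!r}, {c!r})")
        object.__setattr__(self, "values", dict(self.values))

    @property
    def ingroups(self) -> tuple[str, ...]:
        return tuple(g for g in self.groups if g != self.outgroup)

    def cell(self, group: str, character: str) -> frozenset[int]:
        return self.values[(group, character)]

    def to_frame(self) -> pd.DataFrame:
        data = {
            c: [format_value_set(self.cell(g, c)) for g in self.groups]
            for c in self.characters
        }
        return pd.DataFrame(data, index=list(self.groups))

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "taxon_group"
        with open(path, "w") as fh:
            fh.write(f"#outgroup={self.outgroup}\n")
            df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, outgroup: str | None = None) -> "CharacterMatrix":
        """Read a groups x characters TSV; cells are ``n`` or ``a-b``.

        The outgroup comes from a ``#outgroup=<name>`` comment line or the
        *outgroup* argument.
        """
        path = Path(path)
        for line in path.read_text().splitlines():
            if line.startswith("#outgroup=") and outgroup is None:
                outgroup = line.split("=", 1)[1].strip()
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
        if outgroup is None:
            raise ValueError(f"{path}: no '#outgroup=' line and no outgroup given")
        groups = tuple(str(g) for g in df.index)
        characters = tuple(str(c) for c in df.columns)
        values = {
            (g, c): parse_value_set(df.loc[g, c]) for g in groups for c in characters
        }
        return cls(groups, outgroup, characters, values)


@dataclass(frozen=True)
class ApomorphyCall:
    """One derived-character call.

    ``bearer`` holds the ingroup(s) carrying the derived state;
    ``shared_value`` is the bearer state (the full value set for an
    autapomorphy, the single shared value for a synapomorphy).
    """

    character: str
    bearer: frozenset[str]
    call_type: str  # "autapomorphy" | "synapomorphy"
    shared_value: frozenset[int]

    def __post_init__(self) -> None:
        if self.call_type not in ("autapomorphy", "synapomorphy"):
            raise ValueError(f"unknown call type {self.call_type!r}")
        if self.call_type == "autapomorphy" and len(self.bearer) != 1:
            raise ValueError("autapomorphy must have exactly one bearer")
        if self.call_type == "synapomorphy" and len(self.bearer) < 2:
            raise ValueError("synapomorphy needs at least two bearers")

    def to_dict(self) -> dict[str, object]:
        return {
            "call_type": self.call_type,
            "character": self.character,
            "bearer": sorted(self.bearer),
            "shared_value": sorted(self.shared_value),
        }


def build_character_matrix(
    table: pd.DataFrame,
    outgroup: str,
    characters: Sequence[str] | None = None,
) -> CharacterMatrix:
    """Collapse a per-sequence region-length table into a character matrix.

    *table* needs ``sequence_id`` and ``taxon_group`` columns plus one column
    per character; each cell becomes the set of values observed in the group.
    """
    collapsed = collapse_by_group(table, characters)
    groups = tuple(collapsed)
    if outgroup not in groups:
        raise ValueError(f"outgroup {outgroup!r} not among groups {groups}")
    if characters is None:
        characters = [
            c for c in table.columns if c not in ("sequence_id", "taxon_group")
        ]
    values = {
        (g, c): frozenset(collapsed[g][c]) for g in groups for c in characters
    }
    return CharacterMatrix(groups, outgroup, tuple(characters), values)


def detect_autapomorphies(matrix: CharacterMatrix) -> list[ApomorphyCall]:
    """Call every (ingroup, character) whose value set is disjoint from all
    other groups' sets.  The outgroup never receives calls but participates
    in the disjointness test.  Calls are sorted by (character, group).
    """
    calls = []
    for character in matrix.characters:
        for g in matrix.ingroups:
            mine = matrix.cell(g, character)
            others = (
                matrix.cell(h, character) for h in matrix.groups if h != g
            )
            if all(mine.isdisjoint(o) for o in others):
                calls.append(
                    ApomorphyCall(character, frozenset({g}), "autapomorphy", mine)
                )
    return sorted(calls, key=lambda c: (c.character, min(c.bearer)))


def detect_synapomorphies(
    matrix: CharacterMatrix,
    clades: Iterable[frozenset[str]] | None = None,
) -> list[ApomorphyCall]:
    """Call shared derived states: per character, the maximal set of >= 2
    ingroups with one identical singleton value absent from the outgroup and
    from every group outside the set.

    Ingroups whose cell is a range (non-singleton) cannot be bearers — a
    warning is emitted when such cells are encountered — but their sets
    still exclude candidate values.  At most one call per character: if
    several shared values qualify, the largest bearer set wins, then the
    smallest value.  *clades* optionally restricts admissible bearer sets.
    """
    if clades is not None:
        clades = {frozenset(c) for c in clades}
    calls = []
    for character in matrix.characters:
        ranged = [
            g for g in matrix.ingroups if len(matrix.cell(g, character)) > 1
        ]
        if ranged:
            warnings.warn(
                f"character {character!r}: range-valued cells for "
                f"{', '.join(ranged)} cannot bear a synapomorphy",
                stacklevel=2,
            )
        # candidate shared values: singleton states among ingroups
        by_value: dict[int, set[str]] = {}
        for g in matrix.ingroups:
            cell = matrix.cell(g, character)
            if len(cell) == 1:
                (v,) = cell
                by_value.setdefault(v, set()).add(g)
        candidates = []
        for v, bearers in by_value.items():
            if len(bearers) < 2:
                continue
            if v in matrix.cell(matrix.outgroup, character):
                continue
            outside = [
                matrix.cell(h, character)
                for h in matrix.ingroups
                if h not in bearers
            ]
            if any(v in o for o in outside):
                continue
            if clades is not None and frozenset(bearers) not in clades:
                continue
            candidates.append((len(bearers), -v, frozenset(bearers), v))
        if candidates:
            _, _, bearers, v = max(candidates)
            calls.append(
                ApomorphyCall(character, bearers, "synapomorphy", frozenset({v}))
            )
    return sorted(calls, key=lambda c: c.character)


def detect_apomorphies(
    matrix: CharacterMatrix,
    clades: Iterable[frozenset[str]] | None = None,
) -> list[ApomorphyCall]:
    """All autapomorphy and synapomorphy calls for a matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return detect_autapomorphies(matrix) + detect_synapomorphies(matrix, clades)


def calls_to_frame(calls: Sequence[ApomorphyCall]) -> pd.DataFrame:
    """Tabulate calls (one row each) for TSV output."""
    return pd.DataFrame(
        [
            {
                "call_type": c.call_type,
                "character": c.character,
                "bearer": ";".join(sorted(c.bearer)),
                "shared_value": format_value_set(c.shared_value),
            }
            for c in calls
        ],
        columns=["call_type", "character", "bearer", "shared_value"],
    )
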