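"""RNA secondary-structure models: parsing, base-pair census, exact folding.

A :class:`SecondaryStructure` is an ungapped RNA sequence plus a partial
involution on its positions (each position unpaired or paired with exactly
one partner).  Structures come from CT ("connect") or Vienna dot-bracket
files; crossing pairs are representable via bracket tiers.

The pair census follows the three-way scheme used in comparative rRNA work:
canonical Watson-Crick pairs (G-C, A-U), wobble pairs (G-U) and everything
else as non-canonical (A:G, A:C, U:U, ...), with percentages of the pair
total rounded half-up to one decimal.

:func:`fold_max_pairs` is a maximum-base-pair (Nussinov-style) dynamic
program for short segments such as individual LVRs.  It is exact for its
objective, deterministic, and not a thermodynamic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping

__all__ = [
    "SecondaryStructure",
    "PairCensus",
    "parse_structure",
    "parse_ct",
    "parse_dotbracket",
    "write_ct",
    "write_dotbracket",
    "census_pairs",
    "census_from_counts",
    "fold_max_pairs",
    "group_by_structure",
]

_CANONICAL = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
_WOBBLE = frozenset({("G", "U"), ("U", "G")})

# bracket tiers; lettered tiers (A..Z / a..z) follow the Vienna extended
# dot-bracket convention for deeply crossing pairings
_OPEN = "([{<" + "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_CLOSE = ")]}>" + "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA sequence with a pairing map.

    ``pairs`` maps 0-based position -> 0-based partner, symmetrically
    (``pairs[i] == j`` iff ``pairs[j] == i``); unpaired positions are absent.
    """

    sequence: str
    pairs: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for i, j in self.pairs.items():
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"pair ({i + 1},{j + 1}) outside sequence 1..{n}")
            if i == j:
                raise ValueError(f"position {i + 1} pairs with itself")
            if self.pairs.get(j) != i:
                raise ValueError(
                    f"asymmetric pairing: {i + 1}->{j + 1} but "
                    f"{j + 1}->{self.pairs.get(j, 0)}"
                )
        object.__setattr__(self, "pairs", dict(self.pairs))

    @property
    def n_pairs(self) -> int:
        return len(self.pairs) // 2

    def pair_list(self) -> list[tuple[int, int]]:
        """Sorted (i, j) pairs with i < j, 0-based."""
        return sorted((i, j) for i, j in self.pairs.items() if i < j)

    def is_nested(self) -> bool:
        pl = self.pair_list()
        return not any(
            a < c < b < d for a, b in pl for c, d in pl if (a, b) != (c, d)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SecondaryStructure):
            return NotImplemented
        return (
            len(self.sequence) == len(other.sequence)
            and self.pair_list() == other.pair_list()
            and self.sequence == other.sequence
        )

    def __hash__(self) -> int:
        return hash((self.sequence, tuple(self.pair_list())))


@dataclass(frozen=True)
class PairCensus:
    """Counts and percentages of base-pair types in one structure."""

    n_pairs: int
    n_canonical: int
    n_wobble: int
    n_noncanonical: int
    pct_canonical: float
    pct_wobble: float
    pct_noncanonical: float
    paired_fraction: float
    breakdown: tuple[tuple[str, int], ...] = ()

    def to_dict(self) -> dict[str, object]:
        return {
            "n_pairs": self.n_pairs,
            "n_canonical": self.n_canonical,
            "n_wobble": self.n_wobble,
            "n_noncanonical": self.n_noncanonical,
            "pct_canonical": self.pct_canonical,
            "pct_wobble": self.pct_wobble,
            "pct_noncanonical": self.pct_noncanonical,
            "paired_fraction": self.paired_fraction,
            "breakdown": dict(self.breakdown),
        }


def _round1(x: float) -> float:
    """Round half-up to one decimal (450/584 -> 77.1)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _pct(part: int, whole: int) -> float:
    return _round1(100.0 * part / whole) if whole else 0.0


# ---------------------------------------------------------------------------
# Parsing and writing


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse Vienna-style input: a sequence line and a structure line.

    Accepts an optional ``>name`` header.  Bracket tiers ``()``, ``[]``,
    ``{}``, ``<>`` allow crossing pairs; ``.`` marks unpaired positions.
    """
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    lines = [ln for ln in lines if not ln.startswith(">")]
    if len(lines) < 2:
        raise ValueError("dot-bracket input needs a sequence and a structure line")
    seq, db = lines[0].upper().replace("T", "U"), lines[1].split()[0]
    if len(seq) != len(db):
        raise ValueError(
            f"sequence length {len(seq)} != structure length {len(db)}"
        )
    stacks: dict[int, list[int]] = {t: [] for t in range(len(_OPEN))}
    pairs: dict[int, int] = {}
    for i, ch in enumerate(db):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[_OPEN.index(ch)].append(i)
        elif ch in _CLOSE:
            tier = _CLOSE.index(ch)
            if not stacks[tier]:
                raise ValueError(f"unbalanced {ch!r} at position {i + 1}")
            j = stacks[tier].pop()
            pairs[i], pairs[j] = j, i
        else:
            raise ValueError(f"invalid structure character {ch!r} at {i + 1}")
    for tier, st in stacks.items():
        if st:
            raise ValueError(
                f"unbalanced {_OPEN[tier]!r} opened at position {st[-1] + 1}"
            )
    return SecondaryStructure(seq, pairs)


def write_dotbracket(s: SecondaryStructure, name: str | None = None) -> str:
    """Render as dot-bracket text, assigning tiers greedily to crossing pairs."""
    chars = ["."] * len(s.sequence)
    tiers: list[list[tuple[int, int]]] = [[] for _ in _OPEN]
    for i, j in s.pair_list():
        for t, placed in enumerate(tiers):
            if not any(a < i < b < j or i < a < j < b for a, b in placed):
                placed.append((i, j))
                chars[i], chars[j] = _OPEN[t], _CLOSE[t]
                break
        else:
            raise ValueError("structure needs more bracket tiers than available")
    head = f">{name}\n" if name else ""
    return f"{head}{s.sequence}\n{''.join(chars)}\n"


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a CT ("connect") file: header line then one line per position.

    Each body line is ``index base previous next partner natural_index``;
    partner 0 means unpaired.  Pairing symmetry is verified.
    """
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"malformed CT header: {lines[0]!r}") from exc
    if len(lines) - 1 < n:
        raise ValueError(f"CT file declares {n} bases but has {len(lines) - 1} rows")
    seq: list[str] = []
    partner: list[int] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        if len(parts) < 6:
            raise ValueError(f"malformed CT row: {ln!r}")
        seq.append(parts[1].upper().replace("T", "U"))
        partner.append(int(parts[4]))
    pairs: dict[int, int] = {}
    for i, p in enumerate(partner):
        if p == 0:
            continue
        j = p - 1
        if not (0 <= j < n):
            raise ValueError(f"CT position {i + 1} pairs outside 1..{n}")
        if partner[j] != i + 1:
            raise ValueError(
                f"asymmetric CT pairing: {i + 1}->{p} but {p}->{partner[j]}"
            )
        pairs[i] = j
    return SecondaryStructure("".join(seq), pairs)


def write_ct(s: SecondaryStructure, name: str = "structure") -> str:
    n = len(s.sequence)
    rows = [f"{n}\t{name}"]
    for i, base in enumerate(s.sequence):
        p = s.pairs.get(i)
        rows.append(
            f"{i + 1}\t{base}\t{i}\t{i + 2 if i + 1 < n else 0}\t"
            f"{0 if p is None else p + 1}\t{i + 1}"
        )
    return "\n".join(rows) + "\n"


def parse_structure(path: str | Path, format: str | None = None) -> SecondaryStructure:
    """Read a structure file; format ``"ct"`` or ``"dotbracket"``.

    If *format* is None it is inferred from the suffix (``.ct`` vs anything
    else).
    """
    path = Path(path)
    if format is None:
        format = "ct" if path.suffix.lower() == ".ct" else "dotbracket"
    text = path.read_text()
    if format == "ct":
        return parse_ct(text)
    if format == "dotbracket":
        return parse_dotbracket(text)
    raise ValueError(f"unknown structure format: {format!r}")


# ---------------------------------------------------------------------------
# Pair census


def classify_pair(a: str, b: str) -> str:
    """Classify one base pair: ``canonical``, ``wobble`` or ``noncanonical``."""
    key = (a.upper().replace("T", "U"), b.upper().replace("T", "U"))
    if key in _CANONICAL:
        return "canonical"
    if key in _WOBBLE:
        return "wobble"
    return "noncanonical"


def census_from_counts(
    n_canonical: int, n_wobble: int, n_noncanonical: int, sequence_length: int = 0
) -> PairCensus:
    """Build a census from class counts alone (e.g. from a published table)."""
    n_pairs = n_canonical + n_wobble + n_noncanonical
    paired = _pct(2 * n_pairs, sequence_length) if sequence_length else 0.0
    return PairCensus(
        n_pairs=n_pairs,
        n_canonical=n_canonical,
        n_wobble=n_wobble,
        n_noncanonical=n_noncanonical,
        pct_canonical=_pct(n_canonical, n_pairs),
        pct_wobble=_pct(n_wobble, n_pairs),
        pct_noncanonical=_pct(n_noncanonical, n_pairs),
        paired_fraction=paired,
    )


def census_pairs(s: SecondaryStructure) -> PairCensus:
    """Census the base-pair types of a structure.

    Orientation-independent (G-U and U-G are one wobble pair).  With zero
    pairs all percentages are reported as 0.0.
    """
    counts = {"canonical": 0, "wobble": 0, "noncanonical": 0}
    itemised: dict[str, int] = {}
    for i, j in s.pair_list():
        a, b = s.sequence[i], s.sequence[j]
        counts[classify_pair(a, b)] += 1
        key = "-".join(sorted((a, b)))
        itemised[key] = itemised.get(key, 0) + 1
    n_pairs = s.n_pairs
    return PairCensus(
        n_pairs=n_pairs,
        n_canonical=counts["canonical"],
        n_wobble=counts["wobble"],
        n_noncanonical=counts["noncanonical"],
        pct_canonical=_pct(counts["canonical"], n_pairs),
        pct_wobble=_pct(counts["wobble"], n_pairs),
        pct_noncanonical=_pct(counts["noncanonical"], n_pairs),
        paired_fraction=_pct(2 * n_pairs, len(s.sequence)),
        breakdown=tuple(sorted(itemised.items())),
    )


# ---------------------------------------------------------------------------
# Exact maximum-pairing folder


_DEFAULT_ALLOWED = frozenset({"GC", "AU", "GU"})


def _pairable(a: str, b: str, allowed: frozenset[str]) -> bool:
    return a + b in allowed or b + a in allowed


def fold_max_pairs(
    sequence: str,
    min_loop: int = 3,
    allowed: frozenset[str] | set[str] = _DEFAULT_ALLOWED,
) -> SecondaryStructure:
    """Fold a short RNA into the nested structure with the most base pairs.

    Dynamic program over subintervals; a pair (i, j) requires at least
    *min_loop* unpaired bases between i and j and a pair type listed in
    *allowed* (unordered, e.g. ``{"GC", "AU", "GU"}``).  Ties are broken
    deterministically: among maximal structures, the smallest 5' index that
    can be paired is paired, with its smallest admissible partner, applied
    recursively.

    DNA input is transcribed T->U with a warning.  Intended for LVR-scale
    segments (length <= ~200); complexity is cubic in length.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    if "T" in seq:
        warnings.warn("DNA input: transcribing T->U", stacklevel=2)
        seq = seq.replace("T", "U")
    allowed = frozenset(a.upper().replace("T", "U") for a in allowed)
    n = len(seq)
    best = [[0] * n for _ in range(n)]
    # best[i][j]: max pairs in seq[i..j]; intervals shorter than min_loop+2 hold 0
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            score = best[i + 1][j]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if _pairable(seq[i], seq[k], allowed):
                    inner = best[i + 1][k - 1] if k - i > 1 else 0
                    rest = best[k + 1][j] if k < j else 0
                    score = max(score, 1 + inner + rest)
            best[i][j] = score

    pairs: dict[int, int] = {}

    def traceback(i: int, j: int) -> None:
        while i < j:
            target = best[i][j]
            if target == 0:
                return
            paired_i = False
            for k in range(i + min_loop + 1, j + 1):
                if not _pairable(seq[i], seq[k], allowed):
                    continue
                inner = best[i + 1][k - 1] if k - i > 1 else 0
                rest = best[k + 1][j] if k < j else 0
                if 1 + inner + rest == target:
                    pairs[i], pairs[k] = k, i
                    traceback(i + 1, k - 1)
                    i = k + 1
                    paired_i = True
                    break
            if not paired_i:
                i += 1  # optimum leaves i unpaired

    traceback(0, n - 1)
    return SecondaryStructure(seq, pairs)


# ---------------------------------------------------------------------------
# Consensus grouping


def group_by_structure(
    structures: Mapping[str, SecondaryStructure],
) -> list[tuple[str, list[str]]]:
    """Partition ids by exact structure identity (length and pairing map).

    Returns ``(representative, members)`` per group; the representative is
    the lexicographically smallest member id — the "consensus species" of
    the group.  Groups are sorted by representative; singletons allowed.
    """
    buckets: dict[tuple[int, tuple[tuple[int, int], ...]], list[str]] = {}
    for sid, s in structures.items():
        key = (len(s.sequence), tuple(s.pair_list()))
        buckets.setdefault(key, []).append(sid)
    groups = [(min(members), sorted(members)) for members in buckets.values()]
    return sorted(groups)
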