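"""Independent brute-force oracles used only by the test-suite.

Each function recomputes a quantity by the most naive route available so
the library implementation is checked against a different algorithmic path.
"""

from collections import Counter
from itertools import combinations

_PAIRS = {"GC", "CG", "AU", "UA", "GU", "UG"}


def site_class_oracle(column: str) -> str:
    """Naive histogram classification of one alignment column."""
    hist = Counter(
        c.upper().replace("U", "T") for c in column if c.upper() in "ACGTU"
    )
    total = sum(hist.values())
    if total < 2:
        return "unclassified"
    if len(hist) == 1:
        return "conserved"
    if len([v for v in hist.values() if v >= 2]) >= 2:
        return "variable_parsimony_informative"
    return "variable_singleton"


def summarize_oracle(records) -> dict:
    """Column-by-column recount of site classes for a list of sequences."""
    n = len(records[0])
    tally = Counter(
        site_class_oracle("".join(seq[i] for seq in records)) for i in range(n)
    )
    return {
        "n_sites": n,
        "n_conserved": tally["conserved"],
        "n_parsimony_informative": tally["variable_parsimony_informative"],
        "n_singleton": tally["variable_singleton"],
        "n_unclassified": tally["unclassified"],
    }


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum pair count by exhaustive recursion over all nested structures
    (no memoisation; exponential, for short sequences only)."""
    seq = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in _PAIRS:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1) if seq else 0


def census_oracle(structure) -> tuple[int, int, int]:
    """Re-scan a pairing map pair by pair, counting the three classes."""
    canonical = wobble = other = 0
    seen = set()
    for i, j in structure.pairs.items():
        if (j, i) in seen:
            continue
        seen.add((i, j))
        duo = frozenset((structure.sequence[i], structure.sequence[j]))
        if duo in ({"G", "C"}, {"A", "U"}):
            canonical += 1
        elif duo == {"G", "U"}:
            wobble += 1
        else:
            other += 1
    return canonical, wobble, other


def synapomorphy_oracle(matrix):
    """Exhaustive scan over every ingroup subset of size >= 2: a subset
    qualifies if its cells are one identical singleton value absent from the
    outgroup's and every other group's set.  Per character the largest
    qualifying subset is kept, ties broken by the smallest shared value."""
    calls = {}
    ingroups = matrix.ingroups
    for character in matrix.characters:
        found = []
        for size in range(2, len(ingroups) + 1):
            for subset in combinations(ingroups, size):
                cells = [matrix.cell(g, character) for g in subset]
                if any(len(c) != 1 for c in cells):
                    continue
                values = {next(iter(c)) for c in cells}
                if len(values) != 1:
                    continue
                (v,) = values
                rest = [
                    matrix.cell(g, character)
                    for g in matrix.groups
                    if g not in subset
                ]
                if all(v not in r for r in rest):
                    found.append((size, -v, frozenset(subset), v))
        if found:
            _, _, subset, v = max(found)
            calls[character] = (subset, v)
    return calls
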