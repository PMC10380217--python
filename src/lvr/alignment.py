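"""Aligned-FASTA handling and per-column site classification.

Columns of a multiple sequence alignment are classified the way alignment
statistics programs (e.g. MEGA) report them: *conserved* (one residue type),
*parsimony-informative* (at least two residue types, each in at least two
sequences), *singleton* (variable but not parsimony-informative), or
*unclassified* (fewer than two unambiguous residues in the column, e.g.
gap- or N-dominated columns).  Gaps and IUPAC ambiguity codes never count as
residues; T and U are equivalent; case is ignored.
"""

from __future__ import annotations

import enum
import json
from collections import Counter
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Alignment",
    "SiteClass",
    "SiteSummary",
    "read_alignment",
    "write_alignment",
    "classify_site",
    "summarize_alignment",
]

#: residues that count towards site classification (T and U collapse to T)
_UNAMBIGUOUS = frozenset("ACGT")

#: full accepted alphabet: IUPAC nucleotide codes, N and the gap symbol
_ALPHABET = frozenset("ACGTURYSWKMBDHVN-")


class SiteClass(enum.Enum):
    """Classification of one alignment column."""

    CONSERVED = "conserved"
    SINGLETON = "variable_singleton"
    PARSIMONY_INFORMATIVE = "variable_parsimony_informative"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Alignment:
    """An immutable multiple sequence alignment (order-preserving).

    Parameters
    ----------
    records
        Ordered ``(identifier, sequence)`` tuples.  Sequences must share one
        length and use IUPAC nucleotide codes plus ``-``.
    """

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment contains no records")
        lengths = {len(s) for _, s in self.records}
        if len(lengths) != 1:
            offender = next(
                rid for rid, s in self.records if len(s) != len(self.records[0][1])
            )
            raise ValueError(
                f"unequal sequence lengths: record {offender!r} has length "
                f"{dict(self.records)[offender].__len__()}, expected "
                f"{len(self.records[0][1])}"
            )
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence identifier: {dup!r}")
        for rid, seq in self.records:
            for pos, ch in enumerate(seq):
                if ch.upper() not in _ALPHABET:
                    raise ValueError(
                        f"non-IUPAC character {ch!r} in record {rid!r} "
                        f"at position {pos + 1}"
                    )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0][1])

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rid for rid, _ in self.records)

    def sequence(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(f"unknown sequence id: {record_id!r}")

    def ungapped(self, record_id: str) -> str:
        return self.sequence(record_id).replace("-", "")

    def column(self, index: int) -> str:
        """Residues of 0-based column *index*, top to bottom."""
        return "".join(seq[index] for _, seq in self.records)

    def columns(self) -> Iterator[str]:
        for i in range(self.length):
            yield self.column(i)


@dataclass(frozen=True)
class SiteSummary:
    """Aggregate per-column classification counts for one alignment."""

    n_sites: int
    n_conserved: int
    n_parsimony_informative: int
    n_singleton: int
    n_unclassified: int

    def __post_init__(self) -> None:
        counts = (
            self.n_sites,
            self.n_conserved,
            self.n_parsimony_informative,
            self.n_singleton,
            self.n_unclassified,
        )
        if any(c < 0 for c in counts):
            raise ValueError("site counts must be non-negative")
        if (
            self.n_conserved + self.n_variable + self.n_unclassified
            != self.n_sites
        ):
            raise ValueError(
                "conserved + variable + unclassified must equal n_sites"
            )

    @property
    def n_variable(self) -> int:
        """Variable sites: parsimony-informative plus singletons."""
        return self.n_parsimony_informative + self.n_singleton

    def to_dict(self) -> dict[str, int]:
        d = asdict(self)
        d["n_variable"] = self.n_variable
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        d = self.to_dict()
        keys = [
            "n_sites",
            "n_conserved",
            "n_variable",
            "n_parsimony_informative",
            "n_singleton",
            "n_unclassified",
        ]
        return (
            "\t".join(keys) + "\n" + "\t".join(str(d[k]) for k in keys) + "\n"
        )


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Raises
    ------
    ValueError
        If the file is empty, sequences are ragged, identifiers repeat or a
        character outside the IUPAC nucleotide alphabet occurs.
    """
    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Alignment(tuple(records))


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA, preserving record order."""
    recs = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in alignment.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def classify_site(column: Iterable[str]) -> SiteClass:
    """Classify one alignment column.

    Only unambiguous residues (A, C, G, T/U; case-insensitive) are counted.
    A column with fewer than two of them is unclassified.
    """
    residues = [c.upper().replace("U", "T") for c in column]
    if not residues:
        raise ValueError("empty column")
    counts = Counter(r for r in residues if r in _UNAMBIGUOUS)
    n_residues = sum(counts.values())
    if n_residues < 2:
        return SiteClass.UNCLASSIFIED
    if len(counts) == 1:
        return SiteClass.CONSERVED
    if sum(1 for v in counts.values() if v >= 2) >= 2:
        return SiteClass.PARSIMONY_INFORMATIVE
    return SiteClass.SINGLETON


def summarize_alignment(alignment: Alignment) -> SiteSummary:
    """Classify every column and aggregate counts into a :class:`SiteSummary`."""
    tally = Counter(classify_site(col) for col in alignment.columns())
    return SiteSummary(
        n_sites=alignment.length,
        n_conserved=tally[SiteClass.CONSERVED],
        n_parsimony_informative=tally[SiteClass.PARSIMONY_INFORMATIVE],
        n_singleton=tally[SiteClass.SINGLETON],
        n_unclassified=tally[SiteClass.UNCLASSIFIED],
    )
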