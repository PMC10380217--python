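"""Reference datasets from the comparative 18S rRNA analysis of lace bugs.

The package ships the published length profiles of the Tingidae 18S rRNA
length-variable regions (LVRs B-X), the LVR L subregion counts of the five
consensus species, and the hypervariable-region lengths, as small TSV
tables, plus the published alignment-site and base-pair tallies.  These are
the worked inputs for the apomorphy engine and the reference points the
test-suite checks against.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .alignment import SiteSummary
from .apomorphy import CharacterMatrix
from .regions import PAIRED_SUBREGIONS, parse_value_set
from .structure import PairCensus, census_from_counts

__all__ = [
    "SITE_COUNTS",
    "PAIR_COUNTS",
    "reference_site_summary",
    "reference_pair_census",
    "load_lvr_length_matrix",
    "load_lvr_l_subregion_table",
    "load_lvr_l_subregion_matrix",
    "load_hypervariable_lengths",
]

#: published site tally for the 22-taxon 18S rDNA alignment (1931 columns)
SITE_COUNTS = {
    "n_sites": 1931,
    "n_conserved": 1536,
    "n_variable": 383,
    "n_parsimony_informative": 211,
    "n_singleton": 172,
}

#: base-pair class counts in the Acalypta sauteri 18S rRNA secondary
#: structure model: canonical (G-C, A-U), wobble (G-U), non-canonical
PAIR_COUNTS = {"n_canonical": 450, "n_wobble": 83, "n_noncanonical": 51}


def _data_path(name: str):
    return resources.files("lvr.data").joinpath(name)


def reference_site_summary() -> SiteSummary:
    """Published site classification as a :class:`SiteSummary`.

    Conserved + variable account for 1919 of 1931 columns; the remaining 12
    are carried as unclassified (columns without two unambiguous residues).
    """
    c = SITE_COUNTS
    return SiteSummary(
        n_sites=c["n_sites"],
        n_conserved=c["n_conserved"],
        n_parsimony_informative=c["n_parsimony_informative"],
        n_singleton=c["n_singleton"],
        n_unclassified=c["n_sites"] - c["n_conserved"] - c["n_variable"],
    )


def reference_pair_census() -> PairCensus:
    """Published base-pair census recomputed from its class counts."""
    return census_from_counts(**PAIR_COUNTS)


def load_lvr_length_matrix() -> CharacterMatrix:
    """LVR nucleotide counts (characters B-X) per taxon group."""
    with resources.as_file(_data_path("lvr_lengths.tsv")) as p:
        return CharacterMatrix.from_tsv(p)


def load_lvr_l_subregion_table() -> pd.DataFrame:
    """Raw LVR L subregion half-counts per consensus species."""
    with resources.as_file(_data_path("lvr_l_subregions.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_lvr_l_subregion_matrix() -> CharacterMatrix:
    """LVR L subregion totals (L2, LA..LE) as a character matrix.

    Paired subregion totals are computed as half1 + half2 from the shipped
    half-counts; the printed per-species totals are *not* used (one printed
    total disagrees with its own halves by one nucleotide, and this module
    always reports the computed sum).
    """
    df = load_lvr_l_subregion_table()
    groups = tuple(df["taxon_group"])
    characters = ("L2", *PAIRED_SUBREGIONS)
    values: dict[tuple[str, str], frozenset[int]] = {}
    for row in df.itertuples(index=False):
        values[(row.taxon_group, "L2")] = parse_value_set(row.L2)
        for name in PAIRED_SUBREGIONS:
            half = name[1]
            total = int(getattr(row, f"L{half}1")) + int(getattr(row, f"L{half}2"))
            values[(row.taxon_group, name)] = frozenset({total})
    return CharacterMatrix(groups, "Outgroup", characters, values)


def load_hypervariable_lengths() -> pd.DataFrame:
    """Hypervariable-region (V2, V4, V7) lengths of the consensus species."""
    with resources.as_file(_data_path("hypervariable_lengths.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
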