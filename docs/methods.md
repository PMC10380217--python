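# Methods

This note records the models, conventions and parameter choices behind the
package, and what the synthetic tests do and do not demonstrate.

## Site classification

A column is classified from its **unambiguous residues only** (A, C, G,
T/U; case-insensitive, T ≡ U).  Gaps, N and IUPAC ambiguity codes never
count.  With fewer than two unambiguous residues the column is
*unclassified*; with one distinct residue it is *conserved*; with ≥ 2
distinct residues each occurring ≥ 2 times it is *parsimony-informative*;
any other variable column is a *singleton*.  This is the common convention
of alignment-statistics software, and it is also the reconstruction that
makes published tallies of this kind internally consistent: in the
22-taxon lace-bug 18S alignment the conserved and variable counts
(1536 + 383) account for 1919 of 1931 sites, so 12 sites were evidently
excluded from the tally — exactly what the <2-unambiguous-residues rule
produces on gap- and N-rich columns.  Which 12 sites those were is not
recoverable from the published counts; the rule here is a plausible
operationalisation, not a verified reconstruction.

## Region model

Homology is defined **by alignment columns anchored to one annotated
reference sequence**; the package does not discover region boundaries de
novo.  Annotation coordinates are 1-based inclusive on the ungapped
reference; internally every region becomes a half-open, 0-based column
interval running from the column of the region's first reference residue
to the column of the first reference residue *after* the region.  This
convention attributes insertions that other sequences carry relative to
the reference inside a region (including at its 3′ edge) to that region.
The converters are bijective and property-tested.

Consequences worth knowing:

- An **empty region** (the LVR G convention, `end = start − 1`) maps to an
  empty column interval.  If the reference lacks a region that another
  sequence possesses, residues of that sequence cannot be assigned to the
  region — choose a reference that carries every region of interest, or
  accept length 0 for regions absent from the reference.
- Region lengths are invariant to gap-only realignment outside the region.

**LVR L subdivision** uses a template that tiles the reference's LVR L in
the fixed 5′→3′ segment order `L2, A1, B1, C1, D1, E1, E2, D2, C2, B2,
A2`; each paired subregion X is reported as X1 + X2.  The module always
reports the computed sum of subregion counts as the LVR L total.  On the
published consensus-species table this reproduces the printed totals 74,
81, 78 and 57, but computes 78 where the *Acalypta sauteri* row prints 79
— that row's printed total exceeds the sum of its own printed subregions
by one; the computed sum is carried everywhere.

Group-level values are **sets of integers** rendered `"n"` or
`"min-max"`.  When a rendered matrix is re-parsed, a range cell is
expanded to the full closed integer interval — a deliberate superset of
the (unrecoverable) observed multiset.

## Base-pair census

Pairs are classified orientation-independently into canonical (G–C, A–U),
wobble (G–U) and non-canonical (everything else, e.g. A:G, A:C, U:U),
with an itemised breakdown also emitted.  Percentages are of the pair
total, rounded **half-up** to one decimal (450/584 → 77.1).  With zero
pairs, percentages are reported as 0.0.  `paired_fraction` is
2·n_pairs / sequence length.

## Maximum-pairing folder

`fold_max_pairs` is an exact Nussinov-style dynamic program that maximises
the number of nested pairs drawn from an allowed set (default
{G–C, A–U, G–U}) subject to a minimum hairpin loop of `min_loop` unpaired
bases (default 3, the standard steric constraint; configurable).  It is
**not** a thermodynamic model: it exists so LVR-scale synthetic structures
have a deterministic, exactly optimal folder that tests can verify against
brute-force enumeration.  Ties are broken deterministically: among optimal
structures, the smallest 5′ index that can be paired is paired, with its
smallest admissible partner, recursively.  Complexity is cubic; intended
input length ≤ ~200 nt.

## Apomorphy rules

Calls are **purely value-based** (no tree input) and polarised against one
designated outgroup, which never receives calls but participates in every
disjointness test:

- *Autapomorphy of g on c*: `V_g(c)` disjoint from every other group's
  set.  Range cells participate via set disjointness.
- *Synapomorphy of S on c* (|S| ≥ 2): one identical singleton value `v`
  shared by all of S, absent from the outgroup's set and from every group
  outside S.  Range cells cannot bear a synapomorphy (a warning is
  emitted) but still exclude candidate values.  At most one call per
  character: the largest qualifying bearer set wins, ties broken by the
  smallest shared value.  An optional clade restriction limits admissible
  bearer sets.

On the published subregion matrix the rule reproduces the reported calls —
four Cantacaderinae autapomorphies (LB, LC, LD, LE), one each for
Acalyptaini and Litadeini, synapomorphies LA/LC/LD for the three Tinginae
tribes and LE (16 nt) for Acalyptaini + Litadeini — and additionally flags
Tingini on L2, LB and LE, where the published discussion counts only two
Tingini autapomorphies (L2, LB).  The value-based rule has no stated
grounds to exclude Tingini's unique LE count (14); the package reports all
rule-derived calls and leaves the narrower published count as an editorial
choice of the source analysis.

## Synthetic cohorts

The generator emulates the structure of variability the real data show —
not their evolutionary history:

- a **conserved backbone** (~1.5 kb here, vs ~1.9 kb for the real gene)
  shared by all sequences, with i.i.d. substitutions at
  `substitution_rate` (default 0.02/site) at conserved sites only;
- **indels confined to LVRs**: each group realises its planted per-region
  lengths; the alignment is emitted directly by construction (each
  variable segment padded to the cohort-wide maximum), so column homology
  is exact and truth tables are computed from the plan, never
  re-measured;
- **LVR L as a hairpin**: segments in the order L2, A1…E1, loop, E2…A2
  with complementary half-segments (pair types drawn ≈ 66% G–C, 20% A–U,
  14% G–U) and ≥ `min_loop` unpaired bases reserved at the apex; each
  group's realisation doubles as its planted secondary-structure
  archetype, so consensus grouping must recover exactly one group per
  archetype.

The default configuration *is* the study condition profile of the
lace-bug analysis: five groups (outgroup, Acalyptaini, Litadeini, Tingini,
Cantacaderinae) with 3/4/1/7/1 sequences — the composition of the
secondary-structure comparison — planted with the published LVR length
profiles and LVR L subregion half-vectors (74/78/81/78/57 nt totals,
including the complete LB loss in Cantacaderinae and the within-group
ranges for Acalyptaini LVR X {3,4} and Tingini E {4,5}, X {5,6}).

What passing synthetic tests shows: the measurement pipeline (projection,
extraction, subdivision, collapse, calling) is exact on data whose column
homology is true.  What it does not show: robustness to alignment error,
to indels outside LVRs, or to reference mis-annotation — real alignments
are produced by aligners and inherit their mistakes.

## Numerical and degenerate-input choices

- Percentage rounding: decimal half-up, 1 decimal.
- Folding an empty sequence, classifying an empty column, reading an empty
  FASTA: errors.  DNA input to the folder is transcribed T→U with a
  warning.
- Consensus grouping compares (sequence length, pairing map) exactly;
  representatives are the lexicographically smallest member id.
- All generator randomness flows from a single `numpy` Generator stream;
  identical (config, seed) gives byte-identical output files.

## Problem sizes in the test-suite

The suite simulates 16-sequence, ~1.5 kb cohorts; oracle equivalence runs
on 200 random alignments (≤ 10 × 50) and 1000 random foldable sequences
(≤ 12 nt, against exhaustive enumeration); randomised apomorphy matrices
are checked against an exhaustive subset scan.  These sizes keep each
oracle exact while exercising every code path.

## Known limitations

- No thermodynamic folding, pseudoknot prediction or tertiary-structure
  modelling; structure models are ingested, not predicted (the small exact
  folder excepted).
- No tree-aware character polarisation (no ancestral-state
  reconstruction); "derived" means "unique relative to the outgroup and
  all other groups" in the value-based sense above.
- The alignment itself is an input; the package neither builds nor
  end-truncates alignments, and the published 1931-site statistics can
  only be reproduced exactly from the original alignment file, which is
  not redistributed here.
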