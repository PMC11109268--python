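# Methods

## Problem and model

Fungal secondary-metabolite pathways are encoded in contiguous
biosynthetic gene clusters (BGCs). Cluster detectors that key on protein
domains miss clusters organized around *domainless* enzymes — families
like the Pyr4 transmembrane terpene cyclases that carry no detectable
Pfam domain. `bgcmine` inverts the search: the user supplies a profile
HMM of the family of interest, and cluster boundaries are inferred from
two evidence streams against a curated collection of known clusters:

1. profile-vs-protein hits (hmmscan per-domain tables), thresholded at a
   full-sequence E-value **and** a conditional E-value of 1e-5 — both
   must pass, applied inclusively (`<= 1e-5`);
2. pairwise protein alignments (12-column BLAST/DIAMOND tables), with
   query coverage computed as alignment span / query length, the
   best-identity row kept per query-subject pair, and self-hits removed.

The package never executes search binaries. A `SearchEngine` protocol
separates evidence production from evidence use; shipped
implementations are the tabular parsers (for externally produced
tables) and a deterministic mock engine that replays scripted tables.
This keeps the boundary algorithm — the part this package contributes —
fully testable offline, and mirrors how the searches are run in
practice (batched, on a cluster, ahead of time).

## Reference collection

Complete known clusters are GenBank files (FBGC-style identifiers) whose
CDS features carry `classification Name` product qualifiers; the name is
the last whitespace token, the classification everything before it.
Loose collections (FPROT-style directories of FASTA files) contribute
proteins to classification and linkage evidence but are excluded from
similarity-score denominators because their parental cluster's gene
count is unknown.

Domainless reference proteins (zero retained profile hits) are grouped
by single linkage over pairwise alignments — connected components of the
undirected alignment graph, so one directed hit suffices and the result
is invariant to edge order. The representative is the lexicographically
smallest member id (the collection literature names each family after a
representative member but states no rule; a deterministic rule is
required for reproducible profile names). Profile construction itself
(multiple alignment, `hmmbuild`) is an external step; the package emits
a manifest recording the exact member lists and commands.

## Per-gene annotation

A gene is **biosynthetic** under a union rule — any one of:

* a hit to any profile in the library;
* an alignment to the reference proteome at >= 25% identity and >= 50%
  query coverage (thresholds inclusive, configurable);
* a duplicate elsewhere in the same genome at >= 50% identity — a
  possible self-resistance copy. A >= 50% coverage floor is added so a
  shared single domain does not flag two unrelated multidomain proteins;
* a RiPP precursor-peptide signature (below).

**Core enzymes** are assigned by ordered rules over profile names:
PKS (ketosynthase), NRPS (adenylation *and* condensation domains
required together), terpene synthase/cyclase (including the Pyr4-family
profile), prenyltransferase (UbiA/PaxC/DMATS types), SHC/OSC. The rules
ship as editable data (`CoreRule`), each optionally carrying a bit-score
floor; the first matching rule wins.

**Small-protein filter**: proteins < 200 aa with no biosynthetic
evidence are removed before boundary inference (likely gene-prediction
artifacts); the bound is exclusive, so a 200-aa protein survives.

### RiPP precursor detection

A protein is a precursor-peptide candidate iff there exist **three or
more** pairwise non-overlapping windows of one common length >= 10 aa
that are mutually >= 90% identical (gapless Hamming identity), where
each window individually contains >= 3 distinct residues and at least
one KR/KK/RK/RR dipeptide (the Kex2-type protease motif). "More than
two" is read literally as >= 3 and is configurable.

The decision procedure is exact: for every unit length it considers all
window placements and searches for a mutually compatible set. Two
windows at >= 90% identity can differ in at most floor(L/10) positions,
so by pigeonhole they must agree exactly on one of floor(L/10)+1
disjoint chunks; candidate pairs are bucketed by chunk content and only
those verified — a pruning that cannot change the answer. The greedy
left-to-right family search (`find_repeats`) is kept as a separate
reporting operation; the detector deliberately does not reuse it,
because greedy seed extension can miss a valid window triple that an
exhaustive search finds, and the detector is specified to agree with
brute-force enumeration.

## Boundary inference

All coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention is converted only at the I/O boundary. Gene
distance is the gap between the closer feature boundaries, clamped at
zero for overlaps, strand-independent; joined CDS locations collapse to
their outer span (exon-aware distances would differ only for genes
nested in another gene's intron, which the curation format does not
represent).

Two genes are **clustered** when some known-cluster origin is hit by
both (at the 25/50 retention thresholds) and their distance is
< 15,000 bp (strict, "less than"), or — regardless of distance — when
both hit the same origin at >= 50% identity. Matching the same *origin*
is required, not the same reference protein: the rationale is shared
pathway ancestry, which any two members of one known cluster attest
equally well.

From every gene a forward scan tests the current boundary gene against
each next gene; success links the pair, advances the boundary and
resets the failure counter; three consecutive failures stop the scan.
Every gene strictly between two linked genes is marked clustered
(gap fill). Genes removed by the small-protein filter are invisible to
the scan but re-enter the final record when they lie inside the
accepted span, keeping records contiguous on the scaffold.

**Assembly** grows a candidate from each seed in both directions; a
neighbour joins while it is clustered with the run (direct link or gap
fill) or is biosynthetic and within 2,500 bp (inclusive, "within") of
the previous gene; extension halts at the first gene failing both.
**Acceptance**: a core-enzyme gene, or a RiPP precursor candidate plus
a UstY-like (DUF3328) protein. In targeted mode a lone target whose own
family is core-class is emitted as a `standalone-target` record, so
every target yields at least a single-gene record. Records sharing a
gene (nearby targets) merge, with the union of genes and target ids.

Targeted mode examines 20 genes per side of each target (the flank
count is per side; window truncation at scaffold ends makes
cross-scaffold clusters impossible). All-BGC mode seeds from every
core-enzyme gene and RiPP precursor candidate instead; the rest of the
pipeline is identical.

## Similarity score

Against each complete known cluster:

    score = average_identity% × n_homologous / n_known_total

A query gene is homologous when its best alignment to that cluster's
proteins reaches >= 45% identity and >= 50% coverage; each query gene
pairs with its best-identity partner, and several query genes may pair
with the same known protein (the formula defines counts, not a
matching; one-to-one greedy matching is available as a configuration).
The score is not capped, so duplication in the query can exceed 100.
The best match is the maximum-score complete origin, ties broken to the
lexicographically smaller origin id; loose origins are never scored
because the denominator needs a known gene total.

## Synthetic data and what it shows

The fixture generator emulates the study conditions end to end: a toy
reference collection (by default 3 known clusters × 5–8 proteins of
250 aa, uniform residue background), synthetic genomes whose planted
genes descend from reference proteins at *exact* designed identities
(`mutate_to_identity` keeps ceil(L·id/100) positions), intergenic gaps
placed exactly between feature spans on both sides of the 2,500 and
15,000 bp bounds, decoy genes (260 aa, no hits), and optional RiPP
precursor (three exact 12-aa units with a KK site, separated by unique
spacers — 68 aa total, deliberately under the small-protein bound) plus
a 300-aa UstY-like partner. Mock hit tables replay the designed
identities at 80% coverage. Ground truth is traced from the design
alone (kinds, identities, coordinates), never from the extraction code
or the hit tables.

What passing these tests does *not* show about real data: real homology
is not a single scripted best hit (paralogy, promiscuous domains and
partial alignments add noise the mock cannot produce); real identities
cluster near thresholds rather than sitting exactly on them; and gene
prediction errors produce translation artifacts richer than random
decoys. The threshold semantics, scanning, assembly, merging and
scoring arithmetic are exercised exactly; the quality of the evidence
streams is delegated to the external search programs.

## Numerical and design choices

* All identity/coverage thresholds inclusive (stated as ">=" wherever
  defined); the 15 kb linkage bound strict ("less than"); the 2.5 kb
  proximity bound inclusive ("within").
* Coverage is query coverage; min(query,subject) coverage is a
  configuration away.
* Identity comparisons for repeats use integer match counts
  (`matches >= ceil(0.9·L − 1e−9)`), avoiding float-equality traps.
* Determinism everywhere: fixed seeds give byte-identical fixtures;
  records, ids and report rows are sorted by scaffold and coordinate;
  the mock engine sorts scripted hits.
* Problem sizes in the shipped test battery (22 golden fixtures of
  9–13 genes, 100-trial oracle batteries, 200 random sequences ≤ 300 aa
  for the repeat detector) were chosen to cover every threshold
  boundary from both sides while keeping the whole suite under a minute
  on one core.

## Known limitations

* The per-profile core-detection criteria ship as documented defaults
  and must be adapted to the user's profile library.
* The duplicate search does not exclude paralogues inside the same
  candidate cluster; tandem-duplicated tailoring genes therefore count
  as self-resistance evidence.
* The distance-free strong-identity linkage requires same-origin, not
  same-protein, agreement; for very large known clusters this is the
  more permissive reading.
* HTML reports are static single files; no cross-cluster comparison
  figures.
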