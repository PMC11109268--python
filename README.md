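# bgcmine

Targeted mining of fungal biosynthetic gene clusters (BGCs) around
**domainless enzymes** — biosynthetic proteins with no detectable Pfam
domain, such as the Pyr4 family of noncanonical transmembrane terpene
cyclases. Domain-based cluster detectors (antiSMASH-style) cannot see
these families, so the clusters built around them go unmined. `bgcmine`
starts instead from a profile HMM of a user-chosen protein family, finds
its homologues in an annotated genome, and delimits the surrounding
cluster with linkage rules driven by a curated collection of known BGCs.

## Who it is for

Natural-product genome miners who (a) maintain or use a curated
known-BGC collection (GenBank files with `classification Name` product
qualifiers, plus loose protein directories for clusters known only from
partial data), and (b) want to extract, score and visualize every
cluster encoding a homologue of one protein family across many genomes.

## Method

For each target-profile hit (hmmscan, E-value and conditional E-value
≤ 1e-5) the 20 genes on each side are examined:

* **Biosynthetic-protein calls** (union of evidence): any profile hit in
  the library; an alignment to the known-BGC proteome at ≥ 25% identity
  and ≥ 50% query coverage; a genome duplicate at ≥ 50% identity
  (possible self-resistance enzyme); or a RiPP precursor-peptide
  signature — more than two non-overlapping windows ≥ 10 aa that are
  mutually ≥ 90% identical, each with ≥ 3 distinct residues and a basic
  KR/KK/RK/RR protease-site dipeptide. Proteins < 200 aa with no
  evidence are dropped as probable mispredictions.
* **Linkage**: genes *a* and *b* are clustered when both align to
  proteins of the same known cluster (the shared *origin*) and
  dist(a, b) < 15,000 bp, or — regardless of distance — when both
  alignments to that origin reach ≥ 50% identity. Scanning continues
  past unlinked genes until three consecutive genes fail; every gene
  between two clustered genes is clustered.
* **Assembly and acceptance**: from each seed the cluster grows while
  the next gene is clustered with the run or is biosynthetic and within
  2,500 bp of the previous gene. A candidate is kept if it encodes a
  core enzyme (PKS, NRPS, terpene synthase/cyclase, prenyltransferase,
  SHC/OSC) or both a RiPP precursor candidate and a UstY-like
  (DUF3328) protein.
* **Similarity score** against every complete known cluster:

  `score = avg_identity% × n_homologous / n_known_total`

  where a gene pair counts as homologous at ≥ 45% identity and ≥ 50%
  coverage. An identical cluster scores 100.

External search programs are never executed by the package: hmmscan
per-domain tables and 12-column BLAST/DIAMOND tables are parsed behind a
pluggable engine contract, and a deterministic mock engine replays
scripted tables so the whole pipeline runs without binaries.

## Worked example

Everything below is generated on the fly — no downloads:

```python
import tempfile
from bgcmine.fixtures import planted_cluster_spec, build_fixture
from bgcmine.cluster_extraction import extract_targeted
from bgcmine.scoring_report import score_records

spec = planted_cluster_spec(seed=1)  # decoys + target + 4 linked genes
with tempfile.TemporaryDirectory() as td:
    genome, index, engine, synthetic, _ = build_fixture(spec, td)
    records = extract_targeted(genome, "Pyr4", index, engine)
    score_records(records, index, engine)
    for r in records:
        print(r.bgc_id, r.scaffold_id, [g.index for g in r.genes],
              r.acceptance, round(r.similarity.score, 2))
```

prints

```
genome_seed1.BGC001 scf1 [2, 3, 4, 5, 6] core-enzyme 44.0
```

one cluster spanning scaffold genes 2–6 (the planted target plus its
four reference-derived neighbours; the flanking decoys are excluded),
accepted because the target family is core-class, with similarity score
44.0 against its best-matching known cluster: four of the query genes
are homologous to the five-gene known cluster at ≥ 45% identity
(60/60/55/45%, mean 55%), so 55 × 4/5 = 44.

The same run from a shell, using on-disk hit tables:

```bash
bgcmine run --genome genome.gb --refdb refdb/ --target-profile Pyr4 \
    --domain-table hits.domtblout --reference-table ref_hits.tsv --out results/
```

writes, per genome, one GenBank file per cluster, a `clusters.tsv`
summary and a self-contained HTML page with gene-arrow diagrams.

## Layout

| module | contents |
| --- | --- |
| `bgcmine.genome_io` | GenBank genomes in/out, 0-based coordinates, intergenic distance |
| `bgcmine.refdb` | reference collection, domainless partition, family grouping, profile manifest |
| `bgcmine.homology_search` | domtblout/tabular parsers, thresholds, engine contract, mock engine |
| `bgcmine.protein_annotation` | core rules, RiPP repeat detector, duplicates, small-protein filter |
| `bgcmine.cluster_extraction` | linkage, scanning, assembly, acceptance, targeted/all modes |
| `bgcmine.scoring_report` | similarity score, TSV/HTML/SVG reports, pipeline |
| `bgcmine.fixtures` | seeded synthetic collections/genomes/hit tables + planted ground truth |
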