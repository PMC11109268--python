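"""Deterministic synthetic data for every pipeline stage.

Real inputs to the miner are annotated genomes, a curated known-cluster
collection, and homology-search tables from external programs. This
module fabricates internally consistent versions of all three from a
single seeded specification:

* a toy reference collection (FBGC-style GenBank files, optional
  FPROT-style loose FASTA directories);
* a synthetic genome whose scaffolds carry planted clusters — genes
  derived from reference proteins at chosen identities, separated by
  chosen intergenic gaps — plus decoys and optional RiPP precursor /
  UstY-like pairs;
* mock hit tables that reproduce the planted homology structure exactly,
  so the :class:`~bgcmine.homology_search.MockEngine` stands in for
  hmmscan/DIAMOND.

Because identities and gaps are design inputs, the expected cluster
boundaries are known by construction; :func:`expected_records` traces
them from the design alone, giving planted ground truth for end-to-end
tests. Everything is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from bgcmine.homology_search import AlignHit, DomainHit, MockEngine

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: one fixed codon per residue; nucleotide content is irrelevant to the miner
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"

#: tandem-repeat unit for planted RiPP precursors: 12 aa, 8 distinct, has KK
RIPP_UNIT = "LLKKDVAEILNG"

_CLASSIFICATIONS = (
    "terpene cyclase",
    "polyketide synthase",
    "cytochrome P450 monooxygenase",
    "FAD-dependent monooxygenase",
    "acetyltransferase",
    "major facilitator superfamily transporter",
    "short-chain dehydrogenase",
    "methyltransferase",
)


# ---------------------------------------------------------------------------
# specification


@dataclass(frozen=True)
class PlantedGene:
    """One designed gene on a synthetic scaffold.

    ``kind`` is one of ``ref`` (derived from a reference protein at
    ``identity`` percent), ``target`` (ref-derived and hit by the target
    profile), ``decoy`` (random, no hits anywhere), ``ripp`` (tandem
    repeat precursor, no hits), ``usty`` (random, hit by the DUF3328
    profile). ``gap_before`` is the intergenic gap in bp to the previous
    gene (the leading offset for the first gene).
    """

    kind: str = "ref"
    origin: str | None = None
    ref_index: int = 0
    identity: float = 60.0
    gap_before: int = 500
    length: int = 250  # protein length for decoy/usty genes
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in ("ref", "target", "decoy", "ripp", "usty"):
            raise ValueError(f"unknown gene kind {self.kind!r}")
        if self.kind in ("ref",) and self.origin is None:
            raise ValueError("ref genes need an origin")


@dataclass(frozen=True)
class PlantedScaffold:
    scaffold_id: str
    genes: tuple[PlantedGene, ...]


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_known_bgcs: int = 3
    genes_per_bgc: int = 5
    n_fprot: int = 0
    fprot_proteins: int = 2
    ref_protein_length: int = 250
    scaffolds: tuple[PlantedScaffold, ...] = ()
    target_profile: str = "Pyr4"
    ripp_copies: int = 3


def origin_id(i: int) -> str:
    return f"FBGC{90001 + i}"


# ---------------------------------------------------------------------------
# sequence primitives


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def mutate_to_identity(
    seq: str, identity_pct: float, rng: int | np.random.Generator
) -> str:
    """Equal-length mutant at an exact gapless identity to ``seq``.

    Keeps ceil(len * identity / 100) positions and substitutes every
    other position with a different residue, so the realized identity is
    exactly ceil(len * id / 100) / len. Deterministic for a fixed seed.
    """
    if not 0.0 < identity_pct <= 100.0:
        raise ValueError("identity must be in (0, 100]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n = len(seq)
    n_keep = math.ceil(n * identity_pct / 100.0 - 1e-9)
    n_mut = n - n_keep
    if n_mut == 0:
        return seq
    positions = rng.choice(n, size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        choices = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _ripp_protein(rng: np.random.Generator, copies: int) -> str:
    """Tandem precursor: unique spacers around near-exact repeat units."""
    non_basic = [a for a in AMINO_ACIDS if a not in "KR"]
    parts = []
    for _ in range(copies):
        parts.append("".join(rng.choice(non_basic, size=8)))
        parts.append(RIPP_UNIT)
    parts.append("".join(rng.choice(non_basic, size=8)))
    return "".join(parts)


def back_translate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + _STOP


# ---------------------------------------------------------------------------
# toy reference collection


@dataclass
class ToyCollection:
    root: Path
    #: origin -> list of (protein_id, classification, name, sequence)
    proteins: dict[str, list[tuple[str, str, str, str]]]

    def sequence(self, origin: str, ref_index: int) -> str:
        return self.proteins[origin][ref_index][3]

    def protein_id(self, origin: str, ref_index: int) -> str:
        return self.proteins[origin][ref_index][0]


def make_toy_collection(spec: FixtureSpec, out_dir: str | Path) -> ToyCollection:
    """Write an FBGC/FPROT-style reference collection directory.

    Each known cluster gets ``genes_per_bgc`` random proteins laid out as
    CDS features with "classification Name" product qualifiers; the first
    protein of every cluster is a terpene cyclase so ref-derived targets
    have a core-classified family to descend from.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteins: dict[str, list[tuple[str, str, str, str]]] = {}
    for b in range(spec.n_known_bgcs):
        origin = origin_id(b)
        entries = []
        features = []
        nt_parts = []
        cursor = 0
        for g in range(spec.genes_per_bgc):
            name = f"Syn{b + 1}{chr(ord('A') + g)}"
            classification = _CLASSIFICATIONS[g % len(_CLASSIFICATIONS)]
            seq = random_protein(spec.ref_protein_length, rng)
            entries.append((f"{origin}|{name}", classification, name, seq))
            nt = back_translate(seq)
            start = cursor
            nt_parts.append(nt)
            cursor += len(nt)
            features.append(
                SeqFeature(
                    FeatureLocation(start, cursor, strand=1),
                    type="CDS",
                    qualifiers={
                        "gene": [name],
                        "product": [f"{classification} {name}"],
                        "translation": [seq],
                    },
                )
            )
            spacer = "".join(rng.choice(list("ACGT"), size=200))
            nt_parts.append(spacer)
            cursor += 200
        record = SeqRecord(
            Seq("".join(nt_parts)),
            id=origin,
            name=origin,
            description=f"synthetic known cluster {origin}",
            annotations={"molecule_type": "DNA"},
        )
        record.features = features
        SeqIO.write([record], str(out_dir / f"{origin}.gb"), "genbank")
        proteins[origin] = entries
    for f in range(spec.n_fprot):
        origin = f"FPROT{90001 + f}"
        sub = out_dir / origin
        sub.mkdir(exist_ok=True)
        entries = []
        with open(sub / "proteins.fasta", "w") as fh:
            for g in range(spec.fprot_proteins):
                name = f"Loose{f + 1}{chr(ord('A') + g)}"
                seq = random_protein(spec.ref_protein_length, rng)
                entries.append((f"{origin}|{name}", "", name, seq))
                fh.write(f">{name}\n{seq}\n")
        proteins[origin] = entries
    return ToyCollection(root=out_dir, proteins=proteins)


# ---------------------------------------------------------------------------
# synthetic genome


@dataclass(frozen=True)
class LaidOutGene:
    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    protein: str
    index: int
    design: PlantedGene


@dataclass
class SyntheticGenome:
    path: Path
    genes: list[LaidOutGene]

    def on_scaffold(self, scaffold_id: str) -> list[LaidOutGene]:
        return [g for g in self.genes if g.scaffold_id == scaffold_id]


def make_synthetic_genome(
    spec: FixtureSpec, collection: ToyCollection, out_dir: str | Path
) -> SyntheticGenome:
    """Write the designed genome as a multi-record GenBank file.

    Gene proteins are derived from the collection at the designed
    identities (or generated fresh for decoys/RiPP/UstY genes), genes are
    laid out with exactly the designed intergenic gaps, and translations
    are attached as qualifiers.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    laid_out: list[LaidOutGene] = []
    for scaffold in spec.scaffolds:
        features = []
        nt_parts = []
        cursor = 0
        for i, design in enumerate(scaffold.genes):
            gap = design.gap_before if i > 0 else max(design.gap_before, 100)
            nt_parts.append("".join(rng.choice(list("ACGT"), size=gap)))
            cursor += gap
            if design.kind in ("ref", "target") and design.origin is not None:
                template = collection.sequence(design.origin, design.ref_index)
                protein = mutate_to_identity(template, design.identity, rng)
            elif design.kind == "ripp":
                protein = _ripp_protein(rng, spec.ripp_copies)
            else:
                protein = random_protein(design.length, rng)
            nt = back_translate(protein)
            if design.strand == "-":
                nt = str(Seq(nt).reverse_complement())
            start = cursor
            cursor += len(nt)
            nt_parts.append(nt)
            gene_id = f"{scaffold.scaffold_id}_g{i + 1:03d}"
            features.append(
                SeqFeature(
                    FeatureLocation(start, cursor, strand=1 if design.strand == "+" else -1),
                    type="CDS",
                    qualifiers={"locus_tag": [gene_id], "translation": [protein]},
                )
            )
            laid_out.append(
                LaidOutGene(
                    gene_id=gene_id,
                    scaffold_id=scaffold.scaffold_id,
                    start=start,
                    end=cursor,
                    strand=design.strand,
                    protein=protein,
                    index=i,
                    design=design,
                )
            )
        nt_parts.append("".join(rng.choice(list("ACGT"), size=200)))
        record = SeqRecord(
            Seq("".join(nt_parts)),
            id=scaffold.scaffold_id,
            name=scaffold.scaffold_id[:16],
            description="synthetic scaffold",
            annotations={"molecule_type": "DNA"},
        )
        record.features = features
        records.append(record)
    path = out_dir / f"genome_seed{spec.seed}.gb"
    SeqIO.write(records, str(path), "genbank")
    return SyntheticGenome(path=path, genes=laid_out)


# ---------------------------------------------------------------------------
# mock hit tables


def make_mock_hits(
    spec: FixtureSpec, genome: SyntheticGenome, collection: ToyCollection
) -> MockEngine:
    """Script hit tables that mirror the planted homology exactly.

    Ref-derived genes get one reference alignment row at the designed
    identity (coverage 80%); target genes additionally hit the target
    profile, UstY genes the DUF3328 profile; decoys and RiPP precursors
    get no rows at all.
    """
    domain_hits: list[DomainHit] = []
    ref_hits: list[AlignHit] = []
    for gene in genome.genes:
        design = gene.design
        n = len(gene.protein)
        if design.kind == "target":
            domain_hits.append(
                DomainHit(
                    query_id=gene.gene_id,
                    profile_name=spec.target_profile,
                    full_evalue=1e-30,
                    conditional_evalue=1e-30,
                    bit_score=250.0,
                    env_start=0,
                    env_end=n,
                )
            )
        if design.kind == "usty":
            domain_hits.append(
                DomainHit(
                    query_id=gene.gene_id,
                    profile_name="DUF3328",
                    full_evalue=1e-20,
                    conditional_evalue=1e-20,
                    bit_score=120.0,
                    env_start=0,
                    env_end=n,
                )
            )
        if design.kind in ("ref", "target") and design.origin is not None:
            ref_hits.append(
                AlignHit(
                    query_id=gene.gene_id,
                    subject_id=collection.protein_id(design.origin, design.ref_index),
                    identity_pct=design.identity,
                    coverage_pct=80.0,
                    evalue=1e-50,
                    aln_len=n,
                )
            )
    return MockEngine(domain_hits=domain_hits, reference_hits=ref_hits, genome_hits=[])


def write_mock_tables(engine: MockEngine, out_dir: str | Path) -> tuple[Path, Path]:
    """Dump the engine's scripted hits as on-disk tabular files.

    The domain table uses the hmmscan per-domain dialect and the
    alignment table the 12-column BLAST dialect, so the files exercise
    the real parsers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    dom_path = out_dir / "domain_hits.domtblout"
    with open(dom_path, "w") as fh:
        fh.write("# synthetic hmmscan per-domain table\n")
        for h in engine.search_profiles(dict.fromkeys(_all_queries(engine), "")):
            qlen = h.env_end
            fh.write(
                f"{h.profile_name} - {qlen} {h.query_id} - {qlen} "
                f"{h.full_evalue:.2g} {h.bit_score:.1f} 0.0 1 1 "
                f"{h.conditional_evalue:.2g} {h.conditional_evalue:.2g} {h.bit_score:.1f} 0.0 "
                f"1 {qlen} 1 {qlen} {h.env_start + 1} {h.env_end} 0.99 -\n"
            )
    aln_path = out_dir / "reference_hits.tsv"
    with open(aln_path, "w") as fh:
        for h in engine.search_proteins(dict.fromkeys(_all_queries(engine), ""), "reference"):
            span = h.aln_len
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity_pct}\t{h.aln_len}\t0\t0\t"
                f"1\t{span}\t1\t{span}\t{h.evalue:.2g}\t200.0\n"
            )
    return dom_path, aln_path


def _all_queries(engine: MockEngine) -> set[str]:
    return {h.query_id for h in engine._domain_hits} | {
        h.query_id for hits in engine._align.values() for h in hits
    }


# ---------------------------------------------------------------------------
# design-level ground truth


@dataclass(frozen=True)
class GroundTruth:
    scaffold_id: str
    first_gene_index: int  # scaffold gene indices, inclusive
    last_gene_index: int
    acceptance: str
    target_indices: frozenset[int]


def _design_biosynthetic(g: LaidOutGene, ref_min_identity: float) -> bool:
    d = g.design
    if d.kind in ("target", "ripp", "usty"):
        return True
    return d.kind == "ref" and d.identity >= ref_min_identity


def _design_linked(
    a: LaidOutGene,
    b: LaidOutGene,
    max_linked_gap: int,
    strong_identity: float,
    ref_min_identity: float,
) -> bool:
    da, db = a.design, b.design
    if da.kind not in ("ref", "target") or db.kind not in ("ref", "target"):
        return False
    if da.origin is None or da.origin != db.origin:
        return False
    if da.identity < ref_min_identity or db.identity < ref_min_identity:
        return False
    gap = max(0, max(a.start, b.start) - min(a.end, b.end))
    if gap < max_linked_gap:
        return True
    return da.identity >= strong_identity and db.identity >= strong_identity


def expected_records(
    spec: FixtureSpec,
    genome: SyntheticGenome,
    max_linked_gap: int = 15_000,
    max_biosyn_gap: int = 2_500,
    flank_genes: int = 20,
    stop_run: int = 3,
    strong_identity: float = 50.0,
    ref_min_identity: float = 25.0,
    small_protein_min_len: int = 200,
) -> list[GroundTruth]:
    """Trace the expected targeted-mode records from the design alone.

    Works directly on the planted kinds, identities and coordinates —
    never on hit tables or the extraction code — replaying the documented
    rules: visibility (small-protein filter), shared-origin linkage with
    the distance bound and the strong-identity exception, the
    three-failure scan with between-gene fill, bidirectional assembly,
    acceptance, and overlap merging.
    """
    truths: list[GroundTruth] = []
    for scaffold in spec.scaffolds:
        genes = genome.on_scaffold(scaffold.scaffold_id)
        target_positions = [g.index for g in genes if g.design.kind == "target"]
        spans: list[tuple[int, int]] = []
        for t in target_positions:
            lo = max(0, t - flank_genes)
            hi = min(len(genes), t + flank_genes + 1)
            window = [
                g
                for g in genes[lo:hi]
                if len(g.protein) >= small_protein_min_len
                or _design_biosynthetic(g, ref_min_identity)
            ]
            pos = {g.index: p for p, g in enumerate(window)}
            n = len(window)
            pairs: set[tuple[int, int]] = set()
            filled: set[int] = set()
            for anchor in range(n):
                boundary, failures, j = anchor, 0, anchor + 1
                while j < n and failures < stop_run:
                    if _design_linked(
                        window[boundary], window[j], max_linked_gap, strong_identity,
                        ref_min_identity,
                    ):
                        pairs.add((boundary, j))
                        filled.update(range(boundary + 1, j))
                        boundary, failures = j, 0
                    else:
                        failures += 1
                    j += 1

            def joins(c: int, prev: int, included: set[int]) -> bool:
                if c in filled:
                    return True
                if any((min(c, i), max(c, i)) in pairs for i in included):
                    return True
                gap = max(
                    0,
                    max(window[c].start, window[prev].start)
                    - min(window[c].end, window[prev].end),
                )
                return _design_biosynthetic(window[c], ref_min_identity) and gap <= max_biosyn_gap

            seed = pos[t]
            included = {seed}
            last = seed
            for c in range(seed + 1, n):
                if joins(c, last, included):
                    included.add(c)
                    last = c
                else:
                    break
            first = seed
            for c in range(seed - 1, -1, -1):
                if joins(c, first, included):
                    included.add(c)
                    first = c
                else:
                    break
            spans.append((window[first].index, window[last].index))
        # merge overlapping spans (shared genes)
        merged: list[tuple[int, int]] = []
        for span in sorted(spans):
            if merged and span[0] <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], span[1]))
            else:
                merged.append(span)
        for first_idx, last_idx in merged:
            targets = frozenset(
                t for t in target_positions if first_idx <= t <= last_idx
            )
            acceptance = (
                "standalone-target" if first_idx == last_idx else "core-enzyme"
            )
            truths.append(
                GroundTruth(
                    scaffold_id=scaffold.scaffold_id,
                    first_gene_index=first_idx,
                    last_gene_index=last_idx,
                    acceptance=acceptance,
                    target_indices=targets,
                )
            )
    return truths


def write_ground_truth(truths: Sequence[GroundTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart_gene_idx\tend_gene_idx\tacceptance\ttargets\n")
        for t in truths:
            fh.write(
                f"{t.scaffold_id}\t{t.first_gene_index}\t{t.last_gene_index}\t"
                f"{t.acceptance}\t{','.join(map(str, sorted(t.target_indices)))}\n"
            )


# ---------------------------------------------------------------------------
# canned spec builders


def planted_cluster_spec(
    seed: int,
    gaps: Sequence[int] = (500, 800, 2_400, 1_000),
    identities: Sequence[float] = (60.0, 55.0, 30.0, 45.0),
    origin_index: int = 0,
    leading_decoys: int = 2,
    trailing_decoys: int = 2,
    with_ripp_pair: bool = False,
) -> FixtureSpec:
    """One scaffold: decoys, a target, then ref-derived genes.

    Gene i of the planted run descends from reference protein i of the
    chosen origin; ``gaps[i]`` is the intergenic gap before run gene i+1
    (the target is run gene 0 and descends from the origin's terpene
    cyclase at 60% identity). Enough reference proteins must exist for
    the run length.
    """
    origin = origin_id(origin_index)
    genes: list[PlantedGene] = [
        PlantedGene(kind="decoy", gap_before=1_000, length=260)
        for _ in range(leading_decoys)
    ]
    genes.append(
        PlantedGene(
            kind="target", origin=origin, ref_index=0, identity=60.0, gap_before=3_000
        )
    )
    for i, (gap, ident) in enumerate(zip(gaps, identities)):
        genes.append(
            PlantedGene(
                kind="ref",
                origin=origin,
                ref_index=(i + 1),
                identity=ident,
                gap_before=gap,
            )
        )
    if with_ripp_pair:
        genes.append(PlantedGene(kind="ripp", gap_before=1_500))
        genes.append(PlantedGene(kind="usty", gap_before=800, length=300))
    genes.extend(
        PlantedGene(kind="decoy", gap_before=4_000, length=260)
        for _ in range(trailing_decoys)
    )
    n_needed = 1 + len(gaps)
    return FixtureSpec(
        seed=seed,
        n_known_bgcs=max(3, origin_index + 1),
        genes_per_bgc=max(5, n_needed),
        scaffolds=(PlantedScaffold("scf1", tuple(genes)),),
    )


def build_fixture(spec: FixtureSpec, work_dir: str | Path):
    """Generate collection + genome + mock engine; return the working set.

    Returns (genome, index, engine, synthetic, collection) where genome
    is re-read from the written GenBank file and index from the written
    collection directory, so the whole I/O path is exercised.
    """
    from bgcmine.genome_io import read_genome
    from bgcmine.refdb import load_collection

    work_dir = Path(work_dir)
    collection = make_toy_collection(spec, work_dir / "refdb")
    synthetic = make_synthetic_genome(spec, collection, work_dir / "genome")
    engine = make_mock_hits(spec, synthetic, collection)
    genome = read_genome(synthetic.path)
    index = load_collection(collection.root)
    return genome, index, engine, synthetic, collection
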