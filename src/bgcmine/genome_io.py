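"""GenBank genome input/output and coordinate primitives.

Genomes must be supplied as GenBank flat files whose CDS features carry a
``translation`` qualifier; gene prediction is out of scope. Internally all
coordinates are 0-based half-open; the GenBank convention (1-based,
inclusive) is converted at the parse/write boundary only, which keeps the
distance arithmetic free of off-by-one ambiguity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: outer genomic span plus its translation.

    Joined (multi-exon) CDS locations are collapsed to their outer span;
    the protein sequence is taken verbatim from the ``translation``
    qualifier and never recomputed from the nucleotide sequence.
    """

    gene_id: str
    scaffold_id: str
    start: int  # 0-based, inclusive
    end: int  # 0-based, exclusive
    strand: str  # "+" or "-"
    protein: str
    index: int  # ordinal position on its scaffold

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if not self.protein:
            raise ValueError(f"gene {self.gene_id}: empty protein")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class Scaffold:
    """A contig/scaffold with its genes ordered by start coordinate."""

    scaffold_id: str
    length: int
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: str | None = None  # nucleotide sequence, if the record carried one

    def __post_init__(self) -> None:
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"scaffold {self.scaffold_id}: genes not ordered by start")


@dataclass
class Genome:
    genome_id: str
    scaffolds: list[Scaffold] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.scaffold_id for s in self.scaffolds]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate scaffold ids")

    def iter_genes(self) -> Iterator[GeneRecord]:
        for scaffold in self.scaffolds:
            yield from scaffold.genes

    @property
    def proteome(self) -> dict[str, str]:
        """gene_id -> protein sequence for every gene in the genome."""
        return {g.gene_id: g.protein for g in self.iter_genes()}

    def scaffold(self, scaffold_id: str) -> Scaffold:
        for s in self.scaffolds:
            if s.scaffold_id == scaffold_id:
                return s
        raise KeyError(scaffold_id)


def _feature_gene_id(feature: SeqFeature, scaffold_id: str, ordinal: int) -> str:
    for key in ("locus_tag", "gene", "protein_id"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"{scaffold_id}_cds{ordinal}"


def read_genome(path: str | Path, genome_id: str | None = None) -> Genome:
    """Parse a GenBank flat file into a :class:`Genome`.

    Each record becomes one scaffold; each CDS feature with a
    ``translation`` qualifier becomes one :class:`GeneRecord`. CDS features
    lacking a translation are skipped with a warning (the pipeline works
    on protein sequences and cannot use them). Multi-record files are read
    as multiple scaffolds of a single genome.
    """
    path = Path(path)
    scaffolds: list[Scaffold] = []
    for record in SeqIO.parse(str(path), "genbank"):
        genes: list[GeneRecord] = []
        n_cds = 0
        for feature in record.features:
            if feature.type != "CDS":
                continue
            n_cds += 1
            translation = feature.qualifiers.get("translation", [None])[0]
            if not translation:
                logger.warning(
                    "%s: CDS #%d on %s has no translation qualifier; skipped",
                    path.name, n_cds, record.id,
                )
                continue
            genes.append(
                GeneRecord(
                    gene_id=_feature_gene_id(feature, record.id, n_cds),
                    scaffold_id=record.id,
                    start=int(feature.location.start),
                    end=int(feature.location.end),
                    strand="-" if feature.location.strand == -1 else "+",
                    protein=str(translation),
                    index=0,  # re-assigned after sorting below
                )
            )
        genes.sort(key=lambda g: (g.start, g.end))
        genes = [
            GeneRecord(g.gene_id, g.scaffold_id, g.start, g.end, g.strand, g.protein, i)
            for i, g in enumerate(genes)
        ]
        try:
            seq = str(record.seq)
        except Exception:  # records without sequence content
            seq = None
        scaffolds.append(
            Scaffold(
                scaffold_id=record.id,
                length=len(record.seq) if seq is not None else (genes[-1].end if genes else 0),
                genes=genes,
                sequence=seq,
            )
        )
    if not scaffolds:
        raise ValueError(f"{path}: no GenBank records found")
    return Genome(genome_id=genome_id or path.stem, scaffolds=scaffolds)


def gene_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Intergenic gap in bp between two genes on the same scaffold.

    The gap between the closer feature boundaries, clamped at zero for
    overlapping spans; symmetric and strand-independent.
    """
    if a.scaffold_id != b.scaffold_id:
        raise ValueError(
            f"gene_distance requires genes on one scaffold "
            f"({a.scaffold_id!r} vs {b.scaffold_id!r})"
        )
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def write_bgc(bgc, genome: Genome, path: str | Path) -> None:
    """Write an extracted cluster as a single-record GenBank file.

    The record spans from the first gene's start to the last gene's end on
    the parent scaffold; coordinates are re-based to that slice. Every gene
    is emitted as a CDS feature with ``translation`` and a ``product``
    qualifier ("classification name"), mirroring the curated-collection
    convention, so the file round-trips through :func:`read_genome`.
    """
    scaffold_ids = {g.scaffold_id for g in bgc.genes}
    if len(scaffold_ids) != 1:
        raise ValueError("BGC genes must lie on a single scaffold")
    scaffold = genome.scaffold(next(iter(scaffold_ids)))
    offset = min(g.start for g in bgc.genes)
    end = max(g.end for g in bgc.genes)
    if scaffold.sequence is not None:
        nt = scaffold.sequence[offset:end]
    else:
        nt = "N" * (end - offset)

    record = SeqRecord(
        Seq(nt),
        id=getattr(bgc, "bgc_id", "BGC"),
        name=getattr(bgc, "bgc_id", "BGC")[:16],
        description=f"extracted cluster from {genome.genome_id} {scaffold.scaffold_id}",
        annotations={"molecule_type": "DNA"},
    )
    products = getattr(bgc, "products", {})
    for gene in bgc.genes:
        qualifiers = {
            "locus_tag": [gene.gene_id],
            "translation": [gene.protein],
        }
        if gene.gene_id in products:
            qualifiers["product"] = [products[gene.gene_id]]
        record.features.append(
            SeqFeature(
                FeatureLocation(
                    gene.start - offset, gene.end - offset, strand=1 if gene.strand == "+" else -1
                ),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
    SeqIO.write([record], str(path), "genbank")
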