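"""The curated known-BGC reference collection.

The collection holds two kinds of entries. Complete clusters are GenBank
files whose identifier starts with ``FBGC``; every CDS carries a
``product`` qualifier of the form "classification Name" (e.g. "terpene
cyclase Pyr4"). Clusters known only from loose gene/protein sequences live
in ``FPROT`` directories of FASTA files. Both contribute proteins to the
reference index used for gene classification and cluster linkage, but only
FBGC origins have a known total gene count and therefore take part in
similarity scoring.

This module also partitions the reference proteome into domain-bearing and
domainless proteins and groups the domainless ones into single-linkage
families — the seed step for building profile HMMs of enzyme families that
Pfam cannot see.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx
from Bio import SeqIO

from bgcmine.homology_search import AlignHit, DomainHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferenceProtein:
    """A protein from the curated collection, tagged with its parental BGC."""

    protein_id: str  # globally unique: "<origin>|<name>"
    origin: str  # FBGC- or FPROT-style identifier
    classification: str
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.origin:
            raise ValueError("origin must be non-empty")

    @property
    def is_complete_origin(self) -> bool:
        """True when the parental BGC is a complete (FBGC-style) cluster."""
        return self.origin.upper().startswith("FBGC")

    @property
    def product(self) -> str:
        return f"{self.classification} {self.name}".strip()


@dataclass
class ReferenceIndex:
    proteins: list[ReferenceProtein] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {p.protein_id: p for p in self.proteins}
        if len(self._by_id) != len(self.proteins):
            raise ValueError("duplicate protein ids in reference index")

    @property
    def by_origin(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for p in self.proteins:
            out.setdefault(p.origin, []).append(p.protein_id)
        return out

    @property
    def known_bgc_sizes(self) -> dict[str, int]:
        """Total gene count per complete (FBGC) origin.

        Loose FPROT origins are excluded: their parental cluster's true
        gene count is unknown, so they cannot appear in a similarity-score
        denominator.
        """
        return {
            origin: len(ids)
            for origin, ids in self.by_origin.items()
            if ids and self._by_id[ids[0]].is_complete_origin
        }

    @property
    def complete_origins(self) -> list[str]:
        return sorted(self.known_bgc_sizes)

    def get(self, protein_id: str) -> ReferenceProtein:
        return self._by_id[protein_id]

    def origin_of(self, protein_id: str) -> str:
        return self._by_id[protein_id].origin

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def write_tsv(self, tsv_path: str | Path, fasta_path: str | Path) -> None:
        """Persist the index as a TSV + FASTA pair."""
        with open(tsv_path, "w") as fh:
            fh.write("protein_id\torigin\tclassification\tname\tlength\n")
            for p in self.proteins:
                fh.write(
                    f"{p.protein_id}\t{p.origin}\t{p.classification}\t{p.name}\t{len(p.sequence)}\n"
                )
        with open(fasta_path, "w") as fh:
            for p in self.proteins:
                fh.write(f">{p.protein_id}\n{p.sequence}\n")


def split_product(product: str) -> tuple[str, str]:
    """Split a product qualifier into (classification, name).

    The last whitespace token is the protein name; everything before it is
    the classification ("terpene cyclase Pyr4" -> ("terpene cyclase",
    "Pyr4")).
    """
    tokens = product.split()
    if not tokens:
        return "", ""
    return " ".join(tokens[:-1]), tokens[-1]


def load_collection(root: str | Path) -> ReferenceIndex:
    """Load a reference collection directory into a :class:`ReferenceIndex`.

    ``root`` contains FBGC-style GenBank files (``FBGC*.gb[k]``) and/or
    FPROT-style subdirectories of FASTA files. The origin of each protein
    is the file stem (FBGC) or the directory name (FPROT). A CDS without a
    product qualifier is kept with an empty classification and logged.
    """
    root = Path(root)
    proteins: list[ReferenceProtein] = []
    gb_files = sorted(
        p for p in root.iterdir() if p.is_file() and p.suffix.lower() in (".gb", ".gbk", ".gbff")
    )
    for gb in gb_files:
        origin = gb.stem
        n = 0
        for record in SeqIO.parse(str(gb), "genbank"):
            for feat in record.features:
                if feat.type != "CDS":
                    continue
                translation = feat.qualifiers.get("translation", [None])[0]
                if not translation:
                    logger.warning("%s: CDS without translation skipped", gb.name)
                    continue
                n += 1
                product = feat.qualifiers.get("product", [None])[0]
                if product is None:
                    logger.warning("%s: CDS #%d has no product qualifier", gb.name, n)
                    classification, name = "", f"protein{n}"
                else:
                    classification, name = split_product(product)
                proteins.append(
                    ReferenceProtein(
                        protein_id=f"{origin}|{name}",
                        origin=origin,
                        classification=classification,
                        name=name,
                        sequence=str(translation),
                    )
                )
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        origin = sub.name
        for fasta in sorted(sub.glob("*.fa*")):
            for record in SeqIO.parse(str(fasta), "fasta"):
                classification, name = split_product(record.description.partition(" ")[2]) \
                    if " " in record.description else ("", record.id)
                proteins.append(
                    ReferenceProtein(
                        protein_id=f"{origin}|{record.id}",
                        origin=origin,
                        classification=classification,
                        name=name or record.id,
                        sequence=str(record.seq),
                    )
                )
    return ReferenceIndex(proteins=proteins)


def partition_domainless(
    index: ReferenceIndex, hits: Iterable[DomainHit]
) -> tuple[set[str], set[str]]:
    """Split the index into (with_domain, domainless) protein-id sets.

    ``hits`` must already be threshold-filtered; a protein is domainless
    iff it retained zero hits. The two sets partition the index.
    """
    hit_ids = {h.query_id for h in hits}
    all_ids = {p.protein_id for p in index.proteins}
    with_domain = all_ids & hit_ids
    return with_domain, all_ids - with_domain


@dataclass(frozen=True)
class ProteinGroup:
    """A single-linkage family of domainless reference proteins."""

    members: frozenset[str]
    representative: str
    profile_name: str

    def __post_init__(self) -> None:
        if self.representative not in self.members:
            raise ValueError("representative must be a member")


def _profile_name_for(representative: str, index: ReferenceIndex | None) -> str:
    if index is not None and representative in index:
        return index.get(representative).name
    # "<origin>|<name>" -> name
    return representative.rsplit("|", 1)[-1]


def group_domainless(
    domainless: Iterable[str],
    pair_hits: Iterable[AlignHit],
    index: ReferenceIndex | None = None,
) -> list[ProteinGroup]:
    """Group domainless proteins by single linkage over alignment hits.

    Two proteins that align (in either direction, E-value filtering done
    upstream at 0.01) share a group; groups are the connected components
    of the undirected alignment graph, so membership is invariant to edge
    order and direction. Singletons are kept. The representative is the
    lexicographically smallest member id and gives the group's profile
    name.
    """
    domainless = set(domainless)
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(domainless)
    for hit in pair_hits:
        if (
            hit.query_id in domainless
            and hit.subject_id in domainless
            and hit.query_id != hit.subject_id
        ):
            graph.add_edge(hit.query_id, hit.subject_id)
    groups = []
    for component in nx.connected_components(graph):
        representative = min(component)
        groups.append(
            ProteinGroup(
                members=frozenset(component),
                representative=representative,
                profile_name=_profile_name_for(representative, index),
            )
        )
    groups.sort(key=lambda g: g.representative)
    return groups


@dataclass(frozen=True)
class ManifestEntry:
    profile_name: str
    members: tuple[str, ...]
    align_command: str | None  # None for single-sequence profiles
    build_command: str


def build_profile_manifest(
    groups: Iterable[ProteinGroup], align_tool: str = "clustalo", build_tool: str = "hmmbuild"
) -> list[ManifestEntry]:
    """Plan profile construction for each domainless family.

    Multi-member groups are aligned before profile building; single-member
    groups become single-sequence profiles directly. The actual alignment
    and HMM construction are external-tool steps; the manifest records the
    exact commands so the step is reproducible.
    """
    entries = []
    for group in sorted(groups, key=lambda g: g.profile_name):
        members = tuple(sorted(group.members))
        fasta = f"{group.profile_name}.faa"
        if len(members) > 1:
            aln = f"{group.profile_name}.aln"
            align_cmd = f"{align_tool} -i {fasta} -o {aln}"
            build_cmd = f"{build_tool} {group.profile_name}.hmm {aln}"
        else:
            align_cmd = None
            build_cmd = f"{build_tool} --singlemx {group.profile_name}.hmm {fasta}"
        entries.append(
            ManifestEntry(
                profile_name=group.profile_name,
                members=members,
                align_command=align_cmd,
                build_command=build_cmd,
            )
        )
    return entries


def write_manifest(entries: Iterable[ManifestEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("profile_name\tn_members\tmembers\talign_command\tbuild_command\n")
        for e in entries:
            fh.write(
                f"{e.profile_name}\t{len(e.members)}\t{','.join(e.members)}\t"
                f"{e.align_command or '-'}\t{e.build_command}\n"
            )
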