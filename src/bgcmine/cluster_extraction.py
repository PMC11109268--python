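"""Cluster boundary inference.

The boundary algorithm works on one scaffold window at a time:

1. **Targets** — genes whose protein hits the user's profile at the
   E-value/conditional E-value cutoff (targeted mode), or all core-enzyme
   and RiPP precursor genes (all-BGC mode).
2. **Linkage** — two genes are *clustered* when they both align (at >= 25%
   identity, >= 50% coverage) to proteins from the same known cluster and
   lie within 15 kb of each other; or, regardless of distance, when both
   alignments reach >= 50% identity. Scanning proceeds past unlinked genes
   until three consecutive genes fail; every gene strictly between two
   clustered genes is itself clustered.
3. **Assembly** — starting from a seed, neighbours join while they are
   clustered with the growing run or encode a biosynthetic protein within
   2.5 kb of the previous gene.
4. **Acceptance** — a candidate is kept when it encodes a core enzyme, or
   both a RiPP precursor candidate and a UstY-like protein. A lone target
   gene whose family is itself core-class is kept as a standalone record.

All distance thresholds compare intergenic gaps (see
:func:`bgcmine.genome_io.gene_distance`); the 15 kb linkage bound is
strict ("less than"), the 2.5 kb proximity bound is inclusive ("within").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from bgcmine.genome_io import GeneRecord, Genome, gene_distance
from bgcmine.homology_search import (
    PROFILE_EVALUE_CUTOFF,
    AlignHit,
    SearchEngine,
    filter_align,
)
from bgcmine.protein_annotation import (
    AnnotationConfig,
    ProteinAnnotation,
    annotate_window,
    small_protein_filter,
)

ACCEPT_CORE = "core-enzyme"
ACCEPT_RIPP = "ripp-pair"
ACCEPT_STANDALONE = "standalone-target"


@dataclass(frozen=True)
class ClusterParams:
    """Tunable boundary parameters (defaults are the tool's standard run)."""

    max_linked_gap: int = 15_000  # bp; shared-origin linkage, strict upper bound
    max_biosyn_gap: int = 2_500  # bp; biosynthetic-neighbour proximity, inclusive
    flank_genes: int = 20  # genes examined per side of a target
    stop_run: int = 3  # consecutive unlinked genes that stop the scan
    strong_identity: float = 50.0  # %; distance-free linkage floor

    def __post_init__(self) -> None:
        if min(self.max_linked_gap, self.max_biosyn_gap, self.flank_genes, self.stop_run) <= 0:
            raise ValueError("all cluster parameters must be positive")


@dataclass
class BGCRecord:
    """An extracted candidate cluster: a contiguous run of scaffold genes."""

    bgc_id: str
    scaffold_id: str
    genes: list[GeneRecord]
    annotations: dict[str, ProteinAnnotation]
    target_gene_ids: frozenset[str]
    acceptance: str
    similarity: "object | None" = None  # SimilarityResult, attached by scoring
    products: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        indices = [g.index for g in self.genes]
        if indices != list(range(indices[0], indices[0] + len(indices))):
            raise ValueError(f"{self.bgc_id}: genes not contiguous on scaffold")

    @property
    def start(self) -> int:
        return self.genes[0].start

    @property
    def end(self) -> int:
        return self.genes[-1].end

    @property
    def core_categories(self) -> set[str]:
        return {
            a.core_category
            for a in self.annotations.values()
            if a.core_category is not None
        }

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(g.gene_id for g in self.genes)


# ---------------------------------------------------------------------------
# target identification


def find_targets(
    proteome: Mapping[str, str],
    target_profile: str,
    engine: SearchEngine,
    evalue_cutoff: float = PROFILE_EVALUE_CUTOFF,
) -> set[str]:
    """Gene ids whose protein passes both E-value cutoffs on the target profile."""
    hits = engine.search_profiles(dict(proteome), [target_profile])
    return {
        h.query_id
        for h in hits
        if h.full_evalue <= evalue_cutoff and h.conditional_evalue <= evalue_cutoff
    }


# ---------------------------------------------------------------------------
# pairwise linkage


def origin_identity_map(
    ref_hits: Iterable[AlignHit], origin_of
) -> dict[str, dict[str, float]]:
    """Per query gene: parental-BGC origin -> best alignment identity."""
    out: dict[str, dict[str, float]] = {}
    for h in ref_hits:
        origin = origin_of(h.subject_id)
        per = out.setdefault(h.query_id, {})
        if h.identity_pct > per.get(origin, -1.0):
            per[origin] = h.identity_pct
    return out


def clustered_pair(
    a: GeneRecord,
    b: GeneRecord,
    origin_map: Mapping[str, Mapping[str, float]],
    params: ClusterParams,
) -> bool:
    """Are two genes biosynthetically linked through the reference collection?

    True iff some known-cluster origin is hit by both proteins and the
    intergenic distance is under ``max_linked_gap``; or, as the
    distance-free exception, some origin is hit by both at >=
    ``strong_identity`` percent identity. ``origin_map`` must be built
    from hits already filtered at 25% identity / 50% coverage.
    """
    if a.scaffold_id != b.scaffold_id:
        return False
    origins_a = origin_map.get(a.gene_id, {})
    origins_b = origin_map.get(b.gene_id, {})
    shared = origins_a.keys() & origins_b.keys()
    if not shared:
        return False
    if gene_distance(a, b) < params.max_linked_gap:
        return True
    return any(
        origins_a[o] >= params.strong_identity and origins_b[o] >= params.strong_identity
        for o in shared
    )


@dataclass(frozen=True)
class LinkResult:
    """Symmetric linkage over window positions, with between-gene fill."""

    pairs: frozenset[tuple[int, int]]  # (i, j), i < j, directly linked
    filled: frozenset[int]  # positions strictly between a linked pair

    def linked(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.pairs

    @property
    def clustered_positions(self) -> frozenset[int]:
        return frozenset(i for p in self.pairs for i in p) | self.filled


def link_genes(
    genes: Sequence[GeneRecord],
    origin_map: Mapping[str, Mapping[str, float]],
    params: ClusterParams,
) -> LinkResult:
    """Propagate the clustered relation along a window.

    From every gene the scan walks outward, testing the current boundary
    gene against each next gene; a failure advances a counter, a success
    links the pair, moves the boundary and resets the counter; the walk
    stops after ``stop_run`` consecutive failures. Any gene strictly
    between two linked genes is marked clustered (fill). The relation is
    symmetric because every gene anchors a forward walk.
    """
    n = len(genes)
    pairs: set[tuple[int, int]] = set()
    filled: set[int] = set()
    for anchor in range(n):
        boundary = anchor
        failures = 0
        j = anchor + 1
        while j < n and failures < params.stop_run:
            if clustered_pair(genes[boundary], genes[j], origin_map, params):
                pairs.add((boundary, j))
                filled.update(range(boundary + 1, j))
                boundary = j
                failures = 0
            else:
                failures += 1
            j += 1
    return LinkResult(pairs=frozenset(pairs), filled=frozenset(filled))


# ---------------------------------------------------------------------------
# assembly and acceptance


def assemble_bgc(
    seed_pos: int,
    genes: Sequence[GeneRecord],
    annotations: Mapping[str, ProteinAnnotation],
    links: LinkResult,
    params: ClusterParams,
) -> tuple[int, int]:
    """Grow a candidate cluster outward from a seed window position.

    Returns the inclusive (first, last) window positions. A neighbour
    joins while it is clustered with the run so far (direct link to an
    included gene, or filled between a linked pair) or encodes a
    biosynthetic protein within ``max_biosyn_gap`` of the previous gene;
    extension halts at the first gene failing both.
    """

    def joins(candidate: int, previous: int, included: set[int]) -> bool:
        if candidate in links.filled:
            return True
        if any(links.linked(candidate, i) for i in included):
            return True
        ann = annotations[genes[candidate].gene_id]
        return (
            ann.is_biosynthetic
            and gene_distance(genes[candidate], genes[previous]) <= params.max_biosyn_gap
        )

    included = {seed_pos}
    last = seed_pos
    for c in range(seed_pos + 1, len(genes)):
        if joins(c, last, included):
            included.add(c)
            last = c
        else:
            break
    first = seed_pos
    for c in range(seed_pos - 1, -1, -1):
        if joins(c, first, included):
            included.add(c)
            first = c
        else:
            break
    return first, last


def accept_bgc(
    genes: Sequence[GeneRecord],
    annotations: Mapping[str, ProteinAnnotation],
    target_gene_ids: frozenset[str],
    mode: str,
) -> str | None:
    """Acceptance verdict for a candidate, or None when rejected.

    Kept when it encodes a core enzyme, or both a RiPP precursor
    candidate and a UstY-like protein. In targeted mode a single-gene
    candidate consisting of just the target is kept as a standalone record
    when the target's own family is core-class.
    """
    anns = [annotations[g.gene_id] for g in genes]
    has_core = any(a.core_category is not None for a in anns)
    if (
        mode == "targeted"
        and len(genes) == 1
        and genes[0].gene_id in target_gene_ids
        and has_core
    ):
        return ACCEPT_STANDALONE
    if has_core:
        return ACCEPT_CORE
    if any(a.is_ripp_pp for a in anns) and any(a.is_usty_like for a in anns):
        return ACCEPT_RIPP
    return None


# ---------------------------------------------------------------------------
# full extraction


def _product_for(gene: GeneRecord, ann: ProteinAnnotation, index) -> str:
    if ann.best_ref is not None and index is not None and ann.best_ref[0] in index:
        classification = index.get(ann.best_ref[0]).classification
    elif ann.core_category is not None:
        classification = ann.core_category
    elif ann.is_ripp_pp:
        classification = "RiPP precursor peptide candidate"
    else:
        classification = "hypothetical protein"
    return f"{classification} {gene.gene_id}".strip()


def _candidate_from_span(
    scaffold_genes: Sequence[GeneRecord],
    visible: Sequence[GeneRecord],
    span: tuple[int, int],
    annotations: dict[str, ProteinAnnotation],
    target_ids: set[str],
) -> tuple[list[GeneRecord], frozenset[str]]:
    """Materialize a window-position span as a contiguous scaffold gene run.

    Small-protein-filtered genes are invisible to the scan but re-enter
    the record when they lie inside the final span.
    """
    first_idx = visible[span[0]].index
    last_idx = visible[span[1]].index
    run = [g for g in scaffold_genes if first_idx <= g.index <= last_idx]
    targets = frozenset(g.gene_id for g in run if g.gene_id in target_ids)
    return run, targets


def _extract_on_scaffold(
    scaffold_genes: Sequence[GeneRecord],
    window: Sequence[GeneRecord],
    seeds: Iterable[str],
    target_ids: set[str],
    engine: SearchEngine,
    index,
    params: ClusterParams,
    config: AnnotationConfig,
    mode: str,
) -> list[tuple[list[GeneRecord], dict[str, ProteinAnnotation], frozenset[str], str]]:
    annotations = annotate_window(window, engine, index, config)
    visible = small_protein_filter(window, annotations, config.small_protein_min_len)
    if not visible:
        return []
    proteome = {g.gene_id: g.protein for g in visible}
    ref_hits = filter_align(
        engine.search_proteins(proteome, "reference"),
        config.ref_min_identity,
        config.ref_min_coverage,
    )
    origin_map = origin_identity_map(ref_hits, index.origin_of)
    links = link_genes(visible, origin_map, params)

    out = []
    pos_of = {g.gene_id: pos for pos, g in enumerate(visible)}
    for seed_id in seeds:
        if seed_id not in pos_of:
            continue
        span = assemble_bgc(pos_of[seed_id], visible, annotations, links, params)
        run, run_targets = _candidate_from_span(
            scaffold_genes, visible, span, annotations, target_ids
        )
        # genes re-entering via the span need annotations for acceptance/report
        missing = [g for g in run if g.gene_id not in annotations]
        if missing:
            annotations.update(annotate_window(missing, engine, index, config))
        verdict = accept_bgc(run, annotations, run_targets, mode)
        if verdict is not None:
            out.append((run, dict(annotations), run_targets, verdict))
    return out


def _merge_candidates(
    candidates: list[tuple[list[GeneRecord], dict[str, ProteinAnnotation], frozenset[str], str]],
    mode: str,
) -> list[tuple[list[GeneRecord], dict[str, ProteinAnnotation], frozenset[str], str]]:
    """Merge candidates sharing at least one gene (union of genes/targets)."""
    merged: list[tuple[list[GeneRecord], dict[str, ProteinAnnotation], frozenset[str], str]] = []
    for run, anns, targets, verdict in candidates:
        ids = {g.gene_id for g in run}
        absorbed = None
        for k, (mrun, manns, mtargets, _) in enumerate(merged):
            if ids & {g.gene_id for g in mrun}:
                absorbed = k
                by_id = {g.gene_id: g for g in mrun + run}
                union = sorted(by_id.values(), key=lambda g: g.index)
                manns.update(anns)
                new_targets = mtargets | targets
                new_verdict = accept_bgc(union, manns, new_targets, mode) or verdict
                merged[k] = (union, manns, new_targets, new_verdict)
                break
        if absorbed is None:
            merged.append((run, anns, targets, verdict))
    return merged


def _finalize(
    genome: Genome,
    per_scaffold: dict[str, list],
    index,
    mode: str,
) -> list[BGCRecord]:
    records: list[BGCRecord] = []
    counter = 1
    for scaffold in genome.scaffolds:
        candidates = _merge_candidates(per_scaffold.get(scaffold.scaffold_id, []), mode)
        candidates.sort(key=lambda c: c[0][0].start)
        for run, anns, targets, verdict in candidates:
            run_anns = {g.gene_id: anns[g.gene_id] for g in run}
            products = {
                g.gene_id: _product_for(g, run_anns[g.gene_id], index) for g in run
            }
            records.append(
                BGCRecord(
                    bgc_id=f"{genome.genome_id}.BGC{counter:03d}",
                    scaffold_id=scaffold.scaffold_id,
                    genes=run,
                    annotations=run_anns,
                    target_gene_ids=targets,
                    acceptance=verdict,
                    products=products,
                )
            )
            counter += 1
    return records


def extract_targeted(
    genome: Genome,
    target_profile: str,
    index,
    engine: SearchEngine,
    params: ClusterParams | None = None,
    config: AnnotationConfig | None = None,
) -> list[BGCRecord]:
    """Extract clusters around every homologue of the target family.

    Per target gene, the +/- ``flank_genes`` window is annotated and
    small-protein-filtered, linkage is propagated, a candidate is
    assembled from the target and kept if accepted. Overlapping records
    from nearby targets merge into one record carrying all target ids.
    Output is sorted by scaffold and start coordinate.
    """
    params = params or ClusterParams()
    config = config or AnnotationConfig()
    target_ids = find_targets(genome.proteome, target_profile, engine)
    per_scaffold: dict[str, list] = {}
    for scaffold in genome.scaffolds:
        scaffold_targets = [g for g in scaffold.genes if g.gene_id in target_ids]
        for target in scaffold_targets:
            lo = max(0, target.index - params.flank_genes)
            hi = min(len(scaffold.genes), target.index + params.flank_genes + 1)
            window = scaffold.genes[lo:hi]
            per_scaffold.setdefault(scaffold.scaffold_id, []).extend(
                _extract_on_scaffold(
                    scaffold.genes,
                    window,
                    [target.gene_id],
                    target_ids,
                    engine,
                    index,
                    params,
                    config,
                    "targeted",
                )
            )
    return _finalize(genome, per_scaffold, index, "targeted")


def extract_all(
    genome: Genome,
    index,
    engine: SearchEngine,
    params: ClusterParams | None = None,
    config: AnnotationConfig | None = None,
) -> list[BGCRecord]:
    """Extract every cluster seeded by a core enzyme or RiPP precursor.

    Same pipeline as targeted mode, but the seeds are all core-enzyme
    genes and RiPP precursor candidates instead of target-profile hits.
    """
    params = params or ClusterParams()
    config = config or AnnotationConfig()
    per_scaffold: dict[str, list] = {}
    for scaffold in genome.scaffolds:
        if not scaffold.genes:
            continue
        annotations = annotate_window(scaffold.genes, engine, index, config)
        seeds = [
            g.gene_id
            for g in scaffold.genes
            if annotations[g.gene_id].core_category is not None
            or annotations[g.gene_id].is_ripp_pp
        ]
        if not seeds:
            continue
        per_scaffold[scaffold.scaffold_id] = _extract_on_scaffold(
            scaffold.genes,
            scaffold.genes,
            seeds,
            set(),
            engine,
            index,
            params,
            config,
            "all",
        )
    return _finalize(genome, per_scaffold, index, "all")
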