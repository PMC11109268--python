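"""Per-protein verdicts that feed the cluster boundary algorithm.

For every gene in a candidate window the annotator decides:

* **core category** — does a profile hit match a core-enzyme rule (PKS,
  NRPS, terpene synthase/cyclase, prenyltransferase, SHC/OSC)?
* **biosynthetic** — union of all evidence: any core or family profile
  hit, any reference-proteome alignment, a genome duplicate (possible
  self-resistance copy), or a RiPP precursor-peptide signature;
* **RiPP precursor candidate** — tandem near-identical repeats flanked by
  basic protease sites (KR/KK/RK/RR), the hallmark of fungal RiPP
  precursors;
* **duplicated** — a close homologue (>= 50% identity) elsewhere in the
  same genome;
* **UstY-like** — DUF3328-family oxidase, which together with a precursor
  peptide marks a RiPP cluster.

Small proteins (< 200 aa) with no biosynthetic evidence are dropped as
probable gene-prediction artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from bgcmine.genome_io import GeneRecord
from bgcmine.homology_search import AlignHit, DomainHit, SearchEngine, filter_align

BASIC = frozenset("KR")


# ---------------------------------------------------------------------------
# core-enzyme rules


@dataclass(frozen=True)
class CoreRule:
    """Maps profile hits to a core-enzyme category.

    A gene matches when any of ``profiles`` is hit (at ``min_bit_score``
    if set) and every profile in ``required_co_profiles`` is also hit —
    e.g. an NRPS needs both an adenylation and a condensation domain.
    """

    category: str
    profiles: frozenset[str]
    min_bit_score: float | None = None
    required_co_profiles: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValueError("a core rule must name at least one profile")

    def matches(self, hits: Sequence[DomainHit]) -> bool:
        names = {h.profile_name for h in hits}
        primary = [
            h
            for h in hits
            if h.profile_name in self.profiles
            and (self.min_bit_score is None or h.bit_score >= self.min_bit_score)
        ]
        return bool(primary) and self.required_co_profiles <= names


def default_core_rules() -> list[CoreRule]:
    """Shipped core-detection rules; editable via config in the pipeline.

    Profile names follow the shipped library's conventions: Pfam-style
    names for canonical domains plus family profiles named after their
    representative member (Pyr4 for the transmembrane terpene cyclases).
    Rule order is the tie-break when a protein matches several rules.
    """
    return [
        CoreRule("PKS", frozenset({"PKS_KS", "ketoacyl-synt"})),
        CoreRule(
            "NRPS",
            frozenset({"AMP-binding"}),
            required_co_profiles=frozenset({"Condensation"}),
        ),
        CoreRule(
            "terpene cyclase",
            frozenset({"Pyr4", "Terpene_syn_C_2", "Terpene_synth_C", "TRI5"}),
        ),
        CoreRule(
            "prenyltransferase",
            frozenset({"UbiA", "UbiA_PT", "PaxC", "Trp_DMAT"}),
        ),
        CoreRule("SHC/OSC", frozenset({"SQHop_cyclase_C", "SQHop_cyclase_N", "OSC"})),
    ]


def classify_core(
    hits: Sequence[DomainHit], rules: Sequence[CoreRule] | None = None
) -> str | None:
    """Return the first matching rule's category, or None.

    ``hits`` are the (pre-filtered) profile hits of a single gene. Rules
    are tried in order; within a rule any qualifying hit suffices, so the
    bit score only matters against a rule's explicit floor.
    """
    rules = default_core_rules() if rules is None else rules
    for rule in rules:
        if rule.matches(hits):
            return rule.category
    return None


# ---------------------------------------------------------------------------
# tandem-repeat / RiPP precursor detection


@dataclass(frozen=True)
class RepeatFamily:
    """Non-overlapping, mutually >= min-identity repeat windows of one length."""

    unit_length: int
    occurrences: tuple[tuple[int, int], ...]  # [start, end) windows
    min_pairwise_identity: float


def _matches_needed(unit_length: int, min_identity: float) -> int:
    return math.ceil(min_identity * unit_length - 1e-9)


def _window_identity_ok(arr: np.ndarray, i: int, j: int, length: int, needed: int) -> bool:
    return int(np.count_nonzero(arr[i : i + length] == arr[j : j + length])) >= needed


def find_repeats(
    protein: str, min_len: int = 10, min_identity: float = 0.90
) -> list[RepeatFamily]:
    """Greedy gapless tandem-repeat search.

    For each unit length L in [min_len, len//3], windows are compared by
    Hamming identity; families are grown greedily left-to-right (every new
    occurrence must be non-overlapping and >= min_identity identical to
    all members). Families are reported at the L that maximizes the
    largest family size; families with a single occurrence are dropped.
    """
    n = len(protein)
    if n < min_len:
        return []
    arr = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)

    best_families: list[RepeatFamily] = []
    best_size = 1
    for length in range(min_len, n // 3 + 1):
        needed = _matches_needed(length, min_identity)
        used: set[int] = set()
        families: list[RepeatFamily] = []
        for seed in range(0, n - length + 1):
            if seed in used:
                continue
            members = [seed]
            j = seed + length
            while j <= n - length:
                if all(_window_identity_ok(arr, j, m, length, needed) for m in members):
                    members.append(j)
                    used.update(range(j, j + length))
                    j += length
                else:
                    j += 1
            if len(members) >= 2:
                used.update(range(seed, seed + length))
                min_identity_obs = min(
                    int(np.count_nonzero(arr[a : a + length] == arr[b : b + length])) / length
                    for idx, a in enumerate(members)
                    for b in members[idx + 1 :]
                )
                families.append(
                    RepeatFamily(
                        unit_length=length,
                        occurrences=tuple((m, m + length) for m in members),
                        min_pairwise_identity=min_identity_obs,
                    )
                )
        if families:
            size = max(len(f.occurrences) for f in families)
            if size > best_size:
                best_size = size
                best_families = families
    return best_families


def _qualifying_window_starts(protein: str, length: int, min_distinct: int = 3) -> list[int]:
    """Starts of windows with >= min_distinct residues and a basic dipeptide."""
    n = len(protein)
    dipep = [
        i for i in range(n - 1) if protein[i] in BASIC and protein[i + 1] in BASIC
    ]
    if not dipep:
        return []
    starts = []
    d = 0
    for i in range(0, n - length + 1):
        # advance to the first dipeptide start >= i
        while d < len(dipep) and dipep[d] < i:
            d += 1
        if d >= len(dipep) or dipep[d] > i + length - 2:
            continue
        if len(set(protein[i : i + length])) >= min_distinct:
            starts.append(i)
    return starts


def detect_ripp_precursor(
    protein: str,
    min_len: int = 10,
    min_identity: float = 0.90,
    min_repeats: int = 3,
    min_distinct: int = 3,
) -> bool:
    """Does the protein look like a RiPP precursor peptide?

    True iff there exist ``min_repeats`` pairwise non-overlapping windows
    of one common length >= ``min_len`` that are mutually >=
    ``min_identity`` identical (gapless Hamming identity) and each
    qualify individually: >= ``min_distinct`` different residues and at
    least one KR/KK/RK/RR dipeptide. The search is exact over all unit
    lengths and window placements, so it agrees with a brute-force
    enumeration by construction; a pigeonhole chunk filter merely prunes
    window pairs that cannot reach the identity floor.
    """
    n = len(protein)
    if n < min_repeats * min_len:
        return False
    # cheap necessary condition: min_repeats disjoint windows each holding
    # a basic dipeptide need min_repeats non-overlapping dipeptide instances
    if _count_disjoint_basic_dipeptides(protein) < min_repeats:
        return False
    arr = np.frombuffer(protein.encode("ascii"), dtype=np.uint8)
    for length in range(min_len, n // min_repeats + 1):
        starts = _qualifying_window_starts(protein, length, min_distinct)
        if len(starts) < min_repeats:
            continue
        needed = _matches_needed(length, min_identity)
        adjacency = _identity_adjacency(protein, arr, starts, length, needed)
        if _mutual_set_exists(starts, adjacency, length, min_repeats):
            return True
    return False


def _count_disjoint_basic_dipeptides(protein: str) -> int:
    count = 0
    i = 0
    while i < len(protein) - 1:
        if protein[i] in BASIC and protein[i + 1] in BASIC:
            count += 1
            i += 2
        else:
            i += 1
    return count


def _identity_adjacency(
    protein: str, arr: np.ndarray, starts: list[int], length: int, needed: int
) -> dict[int, set[int]]:
    """Window pairs at >= the identity floor, via pigeonhole pre-screen.

    Two windows with at most ``length - needed`` mismatches must agree
    exactly on one of ``length - needed + 1`` disjoint chunks, so only
    windows sharing a chunk (at the same chunk offset) are verified.
    """
    budget = length - needed
    n_chunks = budget + 1
    chunk = length // n_chunks
    buckets: dict[tuple[int, str], list[int]] = {}
    for i in starts:
        for c in range(n_chunks):
            off = c * chunk
            buckets.setdefault((c, protein[i + off : i + off + chunk]), []).append(i)
    adjacency: dict[int, set[int]] = {i: set() for i in starts}
    seen: set[tuple[int, int]] = set()
    for bucket in buckets.values():
        if len(bucket) < 2:
            continue
        for a_idx in range(len(bucket)):
            for b_idx in range(a_idx + 1, len(bucket)):
                a, b = bucket[a_idx], bucket[b_idx]
                if a == b or (a, b) in seen:
                    continue
                seen.add((a, b))
                if _window_identity_ok(arr, a, b, length, needed):
                    adjacency[a].add(b)
                    adjacency[b].add(a)
    return adjacency


def _mutual_set_exists(
    starts: list[int], adjacency: dict[int, set[int]], length: int, k: int
) -> bool:
    """Exact search for k non-overlapping, mutually-adjacent windows."""

    def extend(chosen: list[int], candidates: list[int]) -> bool:
        if len(chosen) == k:
            return True
        for idx, i in enumerate(candidates):
            if chosen and i < chosen[-1] + length:
                continue  # overlap (candidates ascending; chosen too)
            if all(i in adjacency[m] for m in chosen):
                if extend(chosen + [i], candidates[idx + 1 :]):
                    return True
        return False

    # only windows with enough partners can participate in a k-set
    viable = [i for i in starts if len(adjacency[i]) >= k - 1]
    return extend([], viable)


# ---------------------------------------------------------------------------
# genome duplicates (possible self-resistance copies)


def detect_duplicates(
    gene_ids: Iterable[str],
    genome_hits: Iterable[AlignHit],
    min_identity: float = 50.0,
    min_coverage: float = 50.0,
) -> dict[str, bool]:
    """Flag genes with a close homologue elsewhere in the same genome.

    ``genome_hits`` come from a proteome-vs-proteome search with
    self-pairs removed. The identity floor follows the self-resistance
    heuristic (a resistant duplicate of a housekeeping enzyme); the
    coverage floor guards against domain-only matches.
    """
    flagged = {
        h.query_id
        for h in genome_hits
        if h.identity_pct >= min_identity and h.coverage_pct >= min_coverage
    }
    return {gid: gid in flagged for gid in gene_ids}


# ---------------------------------------------------------------------------
# combined annotation


@dataclass(frozen=True)
class ProteinAnnotation:
    gene_id: str
    core_category: str | None = None
    families: frozenset[str] = frozenset()  # profile names hit
    best_ref: tuple[str, str, float] | None = None  # (subject, origin, identity)
    is_ripp_pp: bool = False
    is_duplicated: bool = False
    is_usty_like: bool = False

    @property
    def is_biosynthetic(self) -> bool:
        """Union rule: any single line of evidence marks the protein."""
        return (
            self.core_category is not None
            or bool(self.families)
            or self.best_ref is not None
            or self.is_duplicated
            or self.is_ripp_pp
        )


@dataclass(frozen=True)
class AnnotationConfig:
    """Thresholds for the annotation stage (all inclusive)."""

    ref_min_identity: float = 25.0
    ref_min_coverage: float = 50.0
    dup_min_identity: float = 50.0
    dup_min_coverage: float = 50.0
    usty_profiles: frozenset[str] = frozenset({"DUF3328"})
    ripp_min_len: int = 10
    ripp_min_identity: float = 0.90
    ripp_min_repeats: int = 3
    small_protein_min_len: int = 200
    core_rules: tuple[CoreRule, ...] = field(default_factory=lambda: tuple(default_core_rules()))


def annotate_window(
    genes: Sequence[GeneRecord],
    engine: SearchEngine,
    index,
    config: AnnotationConfig | None = None,
) -> dict[str, ProteinAnnotation]:
    """Annotate every gene of a window; returns gene_id -> annotation.

    Runs the full-library profile scan, the reference pairwise search
    (thresholded at 25%/50%), the genome duplicate search (50%/50%), the
    repeat-based RiPP precursor detector, and the UstY-like profile check,
    then combines the evidence under the union rule.
    """
    config = config or AnnotationConfig()
    proteome = {g.gene_id: g.protein for g in genes}

    domain_hits = engine.search_profiles(proteome)
    hits_by_gene: dict[str, list[DomainHit]] = {gid: [] for gid in proteome}
    for h in domain_hits:
        hits_by_gene[h.query_id].append(h)

    ref_hits = filter_align(
        engine.search_proteins(proteome, "reference"),
        config.ref_min_identity,
        config.ref_min_coverage,
    )
    best_ref: dict[str, tuple[str, str, float]] = {}
    for h in ref_hits:
        origin = index.origin_of(h.subject_id) if index is not None else ""
        prev = best_ref.get(h.query_id)
        if prev is None or h.identity_pct > prev[2]:
            best_ref[h.query_id] = (h.subject_id, origin, h.identity_pct)

    genome_hits = engine.search_proteins(proteome, "genome")
    duplicated = detect_duplicates(
        proteome, genome_hits, config.dup_min_identity, config.dup_min_coverage
    )

    annotations: dict[str, ProteinAnnotation] = {}
    for gene in genes:
        hits = hits_by_gene[gene.gene_id]
        annotations[gene.gene_id] = ProteinAnnotation(
            gene_id=gene.gene_id,
            core_category=classify_core(hits, config.core_rules),
            families=frozenset(h.profile_name for h in hits),
            best_ref=best_ref.get(gene.gene_id),
            is_ripp_pp=detect_ripp_precursor(
                gene.protein,
                config.ripp_min_len,
                config.ripp_min_identity,
                config.ripp_min_repeats,
            ),
            is_duplicated=duplicated[gene.gene_id],
            is_usty_like=any(h.profile_name in config.usty_profiles for h in hits),
        )
    return annotations


def small_protein_filter(
    genes: Sequence[GeneRecord],
    annotations: dict[str, ProteinAnnotation],
    min_len: int = 200,
) -> list[GeneRecord]:
    """Drop probable mispredictions: short proteins with no evidence.

    A gene is removed iff its protein is shorter than ``min_len`` residues
    AND it is not classified as biosynthetic. The boundary is exclusive:
    exactly ``min_len`` residues is retained.
    """
    return [
        g
        for g in genes
        if g.length_aa >= min_len or annotations[g.gene_id].is_biosynthetic
    ]
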