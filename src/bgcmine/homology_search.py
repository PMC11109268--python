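"""Parsing and thresholding of the two homology-evidence streams.

Two kinds of evidence drive cluster extraction:

* profile-vs-protein hits (hmmscan per-domain table, ``--domtblout``
  dialect), filtered at a full-sequence E-value AND conditional
  (per-domain) E-value of 1e-5;
* protein-vs-protein hits (BLAST/DIAMOND 12-column tabular dialect,
  ``outfmt 6``), with query coverage computed from the alignment span and
  identity/coverage thresholds applied inclusively.

Search programs are never executed here. The :class:`SearchEngine`
protocol is the seam: a real adapter shells out and parses, while
:class:`MockEngine` replays scripted hit tables, so the entire pipeline is
testable with no external binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

logger = logging.getLogger(__name__)

#: default E-value / conditional E-value cutoff for profile searches
PROFILE_EVALUE_CUTOFF = 1e-5


@dataclass(frozen=True)
class DomainHit:
    """One retained profile-HMM domain match on a query protein."""

    query_id: str
    profile_name: str
    full_evalue: float
    conditional_evalue: float
    bit_score: float
    env_start: int = 0  # envelope, 0-based half-open on the query
    env_end: int = 0

    def __post_init__(self) -> None:
        if self.full_evalue < 0 or self.conditional_evalue < 0:
            raise ValueError("E-values must be non-negative")


@dataclass(frozen=True)
class AlignHit:
    """One pairwise protein alignment (best local alignment per pair)."""

    query_id: str
    subject_id: str
    identity_pct: float
    coverage_pct: float  # query coverage
    evalue: float
    aln_len: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= 100.0):
            raise ValueError("identity_pct outside [0, 100]")
        if not (0.0 <= self.coverage_pct <= 100.0):
            raise ValueError("coverage_pct outside [0, 100]")


class SearchEngine(Protocol):
    """Contract every search backend satisfies (deterministic for fixed input)."""

    def search_profiles(
        self, proteins: dict[str, str], profiles: Sequence[str] | None = None
    ) -> list[DomainHit]:
        """Profile library vs the given proteins; thresholded DomainHits."""
        ...

    def search_proteins(self, queries: dict[str, str], database: str) -> list[AlignHit]:
        """Pairwise search of queries against a named database.

        ``database`` is ``"reference"`` (the curated known-BGC proteome) or
        ``"genome"`` (the query genome's own proteome, for duplicate
        detection). Self-hits are never returned.
        """
        ...


# ---------------------------------------------------------------------------
# tabular parsers


def parse_domain_table(
    text: str | Path,
    profile_allowlist: Iterable[str] | None = None,
    evalue_cutoff: float = PROFILE_EVALUE_CUTOFF,
    conditional_evalue_cutoff: float = PROFILE_EVALUE_CUTOFF,
) -> list[DomainHit]:
    """Parse an hmmscan per-domain table and apply both E-value cutoffs.

    Rows are retained only when full-sequence E-value <= cutoff AND the
    conditional E-value <= cutoff; an optional allow-list restricts hits to
    named profiles. Malformed rows are skipped with a warning.
    """
    if isinstance(text, Path):
        text = text.read_text()
    allow = set(profile_allowlist) if profile_allowlist is not None else None
    hits: list[DomainHit] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 22:
            raise ValueError(f"line {lineno}: not an hmmscan per-domain table row")
        try:
            # hmmscan --domtblout: target (profile) first, then query
            profile_name = fields[0]
            query_id = fields[3]
            full_evalue = float(fields[6])
            conditional_evalue = float(fields[11])
            bit_score = float(fields[13])
            env_start = int(fields[19]) - 1  # 1-based inclusive -> 0-based
            env_end = int(fields[20])
        except ValueError as exc:
            logger.warning("line %d skipped (%s)", lineno, exc)
            continue
        if allow is not None and profile_name not in allow:
            continue
        if full_evalue <= evalue_cutoff and conditional_evalue <= conditional_evalue_cutoff:
            hits.append(
                DomainHit(
                    query_id=query_id,
                    profile_name=profile_name,
                    full_evalue=full_evalue,
                    conditional_evalue=conditional_evalue,
                    bit_score=bit_score,
                    env_start=env_start,
                    env_end=env_end,
                )
            )
    return hits


def parse_align_table(text: str | Path, query_lengths: dict[str, int]) -> list[AlignHit]:
    """Parse a 12-column BLAST/DIAMOND tabular file.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Query coverage is the alignment span on
    the query divided by the query length; self-hits are removed; when a
    query-subject pair has several local alignments the best-identity row
    is kept.
    """
    if isinstance(text, Path):
        text = text.read_text()
    best: dict[tuple[str, str], AlignHit] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 12:
            raise ValueError(f"line {lineno}: expected 12 tab-separated columns")
        qseqid, sseqid = fields[0], fields[1]
        if qseqid == sseqid:
            continue
        if qseqid not in query_lengths:
            raise KeyError(f"line {lineno}: unknown query length for {qseqid!r}")
        pident = float(fields[2])
        aln_len = int(fields[3])
        qstart, qend = int(fields[6]), int(fields[7])
        coverage = (qend - qstart + 1) / query_lengths[qseqid] * 100.0
        hit = AlignHit(
            query_id=qseqid,
            subject_id=sseqid,
            identity_pct=pident,
            coverage_pct=min(coverage, 100.0),
            evalue=float(fields[10]),
            aln_len=aln_len,
        )
        key = (qseqid, sseqid)
        if key not in best or hit.identity_pct > best[key].identity_pct:
            best[key] = hit
    return list(best.values())


def filter_align(
    hits: Iterable[AlignHit], min_identity_pct: float, min_coverage_pct: float
) -> list[AlignHit]:
    """Keep hits at identity >= min_identity AND coverage >= min_coverage.

    Both thresholds are inclusive; filtering is idempotent and monotone in
    the thresholds.
    """
    return [
        h
        for h in hits
        if h.identity_pct >= min_identity_pct and h.coverage_pct >= min_coverage_pct
    ]


# ---------------------------------------------------------------------------
# mock engine


class MockEngine:
    """Fixture-table-backed :class:`SearchEngine`.

    Replays pre-scripted hit tables, restricted to the queried proteins
    (and, for profile searches, to an optional profile allow-list). Hits
    are returned in a deterministic order regardless of script order.
    """

    def __init__(
        self,
        domain_hits: Iterable[DomainHit] = (),
        reference_hits: Iterable[AlignHit] = (),
        genome_hits: Iterable[AlignHit] = (),
    ) -> None:
        self._domain_hits = sorted(
            domain_hits, key=lambda h: (h.query_id, h.profile_name, h.full_evalue)
        )
        self._align = {
            "reference": sorted(reference_hits, key=lambda h: (h.query_id, h.subject_id)),
            "genome": sorted(genome_hits, key=lambda h: (h.query_id, h.subject_id)),
        }

    def search_profiles(
        self, proteins: dict[str, str], profiles: Sequence[str] | None = None
    ) -> list[DomainHit]:
        allow = set(profiles) if profiles is not None else None
        return [
            h
            for h in self._domain_hits
            if h.query_id in proteins and (allow is None or h.profile_name in allow)
        ]

    def search_proteins(self, queries: dict[str, str], database: str) -> list[AlignHit]:
        if database not in self._align:
            raise KeyError(f"unknown database {database!r}")
        return [
            h
            for h in self._align[database]
            if h.query_id in queries and h.query_id != h.subject_id
        ]


def load_mock_engine(
    domain_table: str | Path | None = None,
    reference_table: str | Path | None = None,
    genome_table: str | Path | None = None,
    query_lengths: dict[str, int] | None = None,
) -> MockEngine:
    """Build a :class:`MockEngine` from on-disk fixture tables.

    The domain table is in hmmscan per-domain dialect and the two
    alignment tables in 12-column BLAST dialect, exactly as a real run
    would leave behind.
    """
    domain_hits = parse_domain_table(Path(domain_table)) if domain_table else []
    qlen = query_lengths or {}
    ref_hits = parse_align_table(Path(reference_table), qlen) if reference_table else []
    gen_hits = parse_align_table(Path(genome_table), qlen) if genome_table else []
    return MockEngine(domain_hits, ref_hits, gen_hits)
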