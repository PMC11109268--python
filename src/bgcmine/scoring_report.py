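"""Similarity scoring against known clusters, reporting, and the pipeline.

A candidate cluster is compared with every complete known cluster using

    similarity score = [average identity %] x n_homologous / n_known_total

where a query gene counts as homologous when its best alignment to a
protein of that known cluster reaches >= 45% identity and >= 50% query
coverage, ``n_homologous`` is the number of such query genes,
``average identity %`` their mean best identity, and ``n_known_total``
the known cluster's gene count. An identical cluster scores 100; the
score is not capped, so gene duplication in the query can push it higher.

The pipeline ties everything together: find targets, annotate, extract,
score, and write one GenBank file per cluster plus a TSV summary and a
self-contained HTML page with gene-arrow diagrams per genome.
"""

from __future__ import annotations

import html
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from bgcmine.cluster_extraction import BGCRecord, ClusterParams, extract_all, extract_targeted
from bgcmine.genome_io import Genome, read_genome, write_bgc
from bgcmine.homology_search import AlignHit, SearchEngine, filter_align
from bgcmine.protein_annotation import AnnotationConfig
from bgcmine.refdb import ReferenceIndex, load_collection

logger = logging.getLogger(__name__)

#: homology thresholds for the similarity calculation
SCORE_MIN_IDENTITY = 45.0
SCORE_MIN_COVERAGE = 50.0


@dataclass(frozen=True)
class SimilarityResult:
    known_bgc: str
    average_identity: float  # percent
    n_homologous: int
    n_known_total: int
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.average_identity <= 100.0):
            raise ValueError("average_identity outside [0, 100]")
        if self.n_homologous < 0:
            raise ValueError("n_homologous negative")


def similarity_score(
    bgc: BGCRecord,
    known_origin: str,
    hits: Iterable[AlignHit],
    index: ReferenceIndex,
    min_identity: float = SCORE_MIN_IDENTITY,
    min_coverage: float = SCORE_MIN_COVERAGE,
) -> SimilarityResult:
    """Score one candidate against one complete known cluster.

    Each candidate gene pairs with its best-identity homologous partner
    among the known cluster's proteins (several candidate genes may pair
    with the same protein; each counts). Zero pairs give score 0.
    """
    sizes = index.known_bgc_sizes
    if known_origin not in sizes:
        raise KeyError(f"{known_origin!r} is not a complete known cluster")
    n_total = sizes[known_origin]
    qualifying = [
        h
        for h in filter_align(hits, min_identity, min_coverage)
        if h.query_id in bgc.gene_ids and index.origin_of(h.subject_id) == known_origin
    ]
    best: dict[str, float] = {}
    for h in qualifying:
        if h.identity_pct > best.get(h.query_id, -1.0):
            best[h.query_id] = h.identity_pct
    n_hom = len(best)
    avg = sum(best.values()) / n_hom if n_hom else 0.0
    return SimilarityResult(
        known_bgc=known_origin,
        average_identity=avg,
        n_homologous=n_hom,
        n_known_total=n_total,
        score=avg * n_hom / n_total,
    )


def best_known_match(
    bgc: BGCRecord, index: ReferenceIndex, hits: Iterable[AlignHit]
) -> SimilarityResult | None:
    """Highest-scoring complete origin; ties go to the smaller origin id.

    Returns None when every origin scores zero (no known cluster shares a
    homologous gene with the candidate).
    """
    hits = list(hits)
    best: SimilarityResult | None = None
    for origin in index.complete_origins:  # sorted, so ties keep the first
        result = similarity_score(bgc, origin, hits, index)
        if result.score > 0 and (best is None or result.score > best.score):
            best = result
    return best


# ---------------------------------------------------------------------------
# TSV summary

SUMMARY_COLUMNS = [
    "bgc_id",
    "scaffold",
    "start",
    "end",
    "n_genes",
    "target_genes",
    "core_categories",
    "acceptance",
    "best_known_bgc",
    "similarity_score",
    "n_homologous",
    "average_identity",
]


def records_to_table(records: Sequence[BGCRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        sim = r.similarity
        rows.append(
            {
                "bgc_id": r.bgc_id,
                "scaffold": r.scaffold_id,
                "start": r.start,
                "end": r.end,
                "n_genes": len(r.genes),
                "target_genes": ";".join(sorted(r.target_gene_ids)) or "-",
                "core_categories": ";".join(sorted(r.core_categories)) or "-",
                "acceptance": r.acceptance,
                "best_known_bgc": sim.known_bgc if sim else "-",
                "similarity_score": round(sim.score, 4) if sim else 0.0,
                "n_homologous": sim.n_homologous if sim else 0,
                "average_identity": round(sim.average_identity, 4) if sim else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def write_summary(records: Sequence[BGCRecord], path: str | Path) -> None:
    records_to_table(records).to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# HTML / SVG report

_GENE_COLORS = {
    "target": "#d62728",
    "core": "#ff7f0e",
    "biosynthetic": "#1f77b4",
    "other": "#bbbbbb",
}


def _gene_color(record: BGCRecord, gene_id: str) -> str:
    if gene_id in record.target_gene_ids:
        return _GENE_COLORS["target"]
    ann = record.annotations[gene_id]
    if ann.core_category is not None:
        return _GENE_COLORS["core"]
    if ann.is_biosynthetic:
        return _GENE_COLORS["biosynthetic"]
    return _GENE_COLORS["other"]


def _record_svg(record: BGCRecord, width: int = 900, height: int = 60) -> str:
    span = max(record.end - record.start, 1)
    scale = (width - 20) / span
    y_mid = height // 2
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}">',
        f'<line x1="10" y1="{y_mid}" x2="{width - 10}" y2="{y_mid}" stroke="#888"/>',
    ]
    for gene in record.genes:
        x0 = 10 + (gene.start - record.start) * scale
        x1 = 10 + (gene.end - record.start) * scale
        head = min(8.0, x1 - x0)
        color = _gene_color(record, gene.gene_id)
        if gene.strand == "+":
            points = (
                f"{x0},{y_mid - 12} {x1 - head},{y_mid - 12} {x1},{y_mid} "
                f"{x1 - head},{y_mid + 12} {x0},{y_mid + 12}"
            )
        else:
            points = (
                f"{x1},{y_mid - 12} {x0 + head},{y_mid - 12} {x0},{y_mid} "
                f"{x0 + head},{y_mid + 12} {x1},{y_mid + 12}"
            )
        title = html.escape(f"{gene.gene_id} ({gene.length_aa} aa)")
        parts.append(
            f'<polygon points="{points}" fill="{color}" stroke="#333">'
            f"<title>{title}</title></polygon>"
        )
    parts.append("</svg>")
    return "".join(parts)


def _record_html(record: BGCRecord) -> str:
    sim = record.similarity
    sim_cell = (
        f"{sim.known_bgc} (score {sim.score:.1f}, {sim.n_homologous}/{sim.n_known_total} "
        f"genes, avg {sim.average_identity:.1f}%)"
        if sim
        else "no similar known cluster"
    )
    header = (
        "<table class='info'>"
        f"<tr><th>Cluster</th><td>{html.escape(record.bgc_id)}</td></tr>"
        f"<tr><th>Location</th><td>{html.escape(record.scaffold_id)}:"
        f"{record.start + 1}..{record.end}</td></tr>"
        f"<tr><th>Genes</th><td>{len(record.genes)}</td></tr>"
        f"<tr><th>Acceptance</th><td>{html.escape(record.acceptance)}</td></tr>"
        f"<tr><th>Core enzymes</th><td>{html.escape(';'.join(sorted(record.core_categories)) or '-')}</td></tr>"
        f"<tr><th>Best known cluster</th><td>{html.escape(sim_cell)}</td></tr>"
        "</table>"
    )
    gene_rows = []
    for gene in record.genes:
        ann = record.annotations[gene.gene_id]
        evidence = []
        if gene.gene_id in record.target_gene_ids:
            evidence.append("target")
        if ann.core_category:
            evidence.append(f"core: {ann.core_category}")
        if ann.families:
            evidence.append("profiles: " + ",".join(sorted(ann.families)))
        if ann.is_ripp_pp:
            evidence.append("RiPP precursor candidate")
        if ann.is_usty_like:
            evidence.append("UstY-like")
        if ann.is_duplicated:
            evidence.append("genome duplicate")
        ref = (
            f"{ann.best_ref[0]} ({ann.best_ref[2]:.1f}%)" if ann.best_ref else "-"
        )
        gene_rows.append(
            "<tr>"
            f"<td>{html.escape(gene.gene_id)}</td>"
            f"<td>{gene.length_aa}</td>"
            f"<td>{gene.strand}</td>"
            f"<td>{html.escape('; '.join(evidence) or '-')}</td>"
            f"<td>{html.escape(ref)}</td>"
            "</tr>"
        )
    gene_table = (
        "<table class='genes'><tr><th>Gene</th><th>Length (aa)</th><th>Strand</th>"
        "<th>Evidence</th><th>Best reference hit</th></tr>" + "".join(gene_rows) + "</table>"
    )
    return f"<section>{header}{_record_svg(record)}{gene_table}</section>"


def render_report(
    records: Sequence[BGCRecord], genome_id: str, out_dir: str | Path
) -> Path:
    """Write a single self-contained HTML page (with inline SVG) per genome."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    body = (
        "".join(_record_html(r) for r in records)
        if records
        else "<p>No biosynthetic gene clusters were extracted from this genome.</p>"
    )
    legend = "".join(
        f'<span style="color:{c}">&#9632;</span> {k}&nbsp;&nbsp;'
        for k, c in _GENE_COLORS.items()
    )
    page = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        f"<title>{html.escape(genome_id)} clusters</title>"
        "<style>body{font-family:sans-serif;margin:2em}section{margin-bottom:3em;"
        "border-bottom:1px solid #ddd}table{border-collapse:collapse;margin:0.5em 0}"
        "th,td{border:1px solid #ccc;padding:3px 8px;text-align:left;font-size:90%}"
        "</style></head><body>"
        f"<h1>{html.escape(genome_id)}: {len(records)} extracted cluster(s)</h1>"
        f"<p>{legend}</p>{body}</body></html>"
    )
    path = out_dir / f"{genome_id}.html"
    path.write_text(page)
    return path


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    genome_paths: list[Path]
    refdb_dir: Path
    out_dir: Path
    engine: SearchEngine
    mode: str = "targeted"  # "targeted" | "all"
    target_profile: str | None = None
    params: ClusterParams = field(default_factory=ClusterParams)
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)

    def validate(self) -> None:
        if self.mode not in ("targeted", "all"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "targeted" and not self.target_profile:
            raise ValueError("targeted mode requires a target profile")
        for p in self.genome_paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not Path(self.refdb_dir).is_dir():
            raise NotADirectoryError(self.refdb_dir)


def score_records(
    records: Sequence[BGCRecord], index: ReferenceIndex, engine: SearchEngine
) -> None:
    """Attach the best known-cluster match to every record (in place)."""
    for record in records:
        proteome = {g.gene_id: g.protein for g in record.genes}
        hits = engine.search_proteins(proteome, "reference")
        record.similarity = best_known_match(record, index, hits)


def run_pipeline(config: PipelineConfig) -> dict[str, list[BGCRecord]]:
    """Execute find -> annotate -> extract -> score -> report per genome.

    Writes, under ``out_dir/<genome_id>/``: one GenBank file per extracted
    cluster, a ``clusters.tsv`` summary, and an HTML report. Returns the
    records per genome id. Deterministic for fixed inputs.
    """
    config.validate()
    index = load_collection(config.refdb_dir)
    results: dict[str, list[BGCRecord]] = {}
    for genome_path in config.genome_paths:
        genome = read_genome(genome_path)
        if config.mode == "targeted":
            records = extract_targeted(
                genome,
                config.target_profile,
                index,
                config.engine,
                config.params,
                config.annotation,
            )
        else:
            records = extract_all(
                genome, index, config.engine, config.params, config.annotation
            )
        score_records(records, index, config.engine)
        genome_dir = Path(config.out_dir) / genome.genome_id
        genome_dir.mkdir(parents=True, exist_ok=True)
        for record in records:
            write_bgc(record, genome, genome_dir / f"{record.bgc_id}.gb")
        write_summary(records, genome_dir / "clusters.tsv")
        render_report(records, genome.genome_id, genome_dir)
        results[genome.genome_id] = records
        logger.info("%s: %d cluster(s) extracted", genome.genome_id, len(records))
    return results
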