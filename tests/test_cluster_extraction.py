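"""Linkage rules, scanning/assembly semantics, acceptance, full extraction."""

import pytest

from bgcmine.cluster_extraction import (
    ACCEPT_CORE,
    ACCEPT_RIPP,
    ACCEPT_STANDALONE,
    ClusterParams,
    accept_bgc,
    assemble_bgc,
    clustered_pair,
    extract_all,
    extract_targeted,
    find_targets,
    link_genes,
    origin_identity_map,
)
from bgcmine.fixtures import (
    FixtureSpec,
    PlantedGene,
    PlantedScaffold,
    build_fixture,
    expected_records,
    planted_cluster_spec,
)
from bgcmine.homology_search import AlignHit, DomainHit, MockEngine
from bgcmine.protein_annotation import ProteinAnnotation

from conftest import make_gene

PARAMS = ClusterParams()


def _genes_with_gaps(gaps, length_nt=750, scaffold="scf"):
    """Lay out genes so that consecutive intergenic gaps equal ``gaps``."""
    genes = []
    cursor = 0
    for i, gap in enumerate([0] + list(gaps)):
        cursor += gap
        genes.append(
            make_gene(f"g{i}", cursor, cursor + length_nt, scaffold_id=scaffold, index=i)
        )
        cursor += length_nt
    return genes


class TestClusteredPair:
    def _map(self, a_hits, b_hits):
        return {"g0": dict(a_hits), "g1": dict(b_hits)}

    def test_shared_origin_within_distance(self):
        a, b = _genes_with_gaps([9_000])
        omap = self._map({"FBGC1": 30.0}, {"FBGC1": 27.0})
        assert clustered_pair(a, b, omap, PARAMS) is True

    def test_shared_origin_beyond_distance(self):
        a, b = _genes_with_gaps([16_000])
        omap = self._map({"FBGC1": 30.0}, {"FBGC1": 27.0})
        assert clustered_pair(a, b, omap, PARAMS) is False

    def test_distance_bound_is_strict(self):
        a, b = _genes_with_gaps([14_999])
        omap = self._map({"FBGC1": 30.0}, {"FBGC1": 27.0})
        assert clustered_pair(a, b, omap, PARAMS) is True
        a, b = _genes_with_gaps([15_000])
        assert clustered_pair(a, b, omap, PARAMS) is False

    def test_strong_identity_ignores_distance(self):
        a, b = _genes_with_gaps([40_000])
        omap = self._map({"FBGC1": 55.0}, {"FBGC1": 52.0})
        assert clustered_pair(a, b, omap, PARAMS) is True
        # strong identity must hold for the SAME origin on both sides
        omap = self._map({"FBGC1": 55.0, "FBGC2": 30.0}, {"FBGC1": 40.0, "FBGC2": 52.0})
        assert clustered_pair(a, b, omap, PARAMS) is False
        # inclusive at exactly 50%
        omap = self._map({"FBGC1": 50.0}, {"FBGC1": 50.0})
        assert clustered_pair(a, b, omap, PARAMS) is True

    def test_no_shared_origin(self):
        a, b = _genes_with_gaps([1_000])
        omap = self._map({"FBGC1": 60.0}, {"FBGC2": 60.0})
        assert clustered_pair(a, b, omap, PARAMS) is False

    def test_different_scaffolds_never_cluster(self):
        a = make_gene("g0", 0, 750, scaffold_id="s1")
        b = make_gene("g1", 0, 750, scaffold_id="s2", index=1)
        omap = self._map({"FBGC1": 60.0}, {"FBGC1": 60.0})
        assert clustered_pair(a, b, omap, PARAMS) is False

    def test_filtered_hits_never_reach_the_map(self):
        """A 24%-identity hit is dropped by the 25/50 prefilter upstream."""
        hits = [
            AlignHit("g0", "FBGC1|A", 24.0, 90.0, 1e-20, 200),
            AlignHit("g1", "FBGC1|B", 60.0, 90.0, 1e-20, 200),
        ]
        from bgcmine.homology_search import filter_align

        omap = origin_identity_map(filter_align(hits, 25, 50), lambda s: s.split("|")[0])
        a, b = _genes_with_gaps([1_000])
        assert clustered_pair(a, b, omap, PARAMS) is False


def _omap(assignments):
    """gene_id -> origin map with uniform 30% identity unless given."""
    out = {}
    for gid, origins in assignments.items():
        out[gid] = {o: (i if isinstance(i, float) else 30.0) for o, i in origins.items()}
    return out


class TestLinkGenes:
    def test_gap_bridging_marks_middle_gene(self):
        genes = _genes_with_gaps([500, 500])
        omap = _omap({"g0": {"O1": 30.0}, "g2": {"O1": 30.0}})  # g1 hits nothing
        links = link_genes(genes, omap, PARAMS)
        assert links.linked(0, 2)
        assert 1 in links.filled
        assert links.clustered_positions == {0, 1, 2}

    def test_three_consecutive_failures_stop_the_scan(self):
        genes = _genes_with_gaps([500] * 4)
        omap = _omap({"g0": {"O1": 30.0}, "g4": {"O1": 30.0}})  # 3 unlinked between
        links = link_genes(genes, omap, PARAMS)
        assert not links.pairs  # g4 is beyond the stop run

    def test_linkable_gene_just_inside_the_stop_run_is_reached(self):
        genes = _genes_with_gaps([500] * 3)
        omap = _omap({"g0": {"O1": 30.0}, "g3": {"O1": 30.0}})  # 2 unlinked between
        links = link_genes(genes, omap, PARAMS)
        assert links.linked(0, 3)
        assert links.filled == {1, 2}

    def test_failure_counter_resets_on_success(self):
        genes = _genes_with_gaps([500] * 5)
        omap = _omap(
            {"g0": {"O1": 30.0}, "g3": {"O1": 30.0}, "g5": {"O1": 30.0}}
        )
        links = link_genes(genes, omap, PARAMS)
        assert links.linked(0, 3) and links.linked(3, 5)

    def test_no_links_anywhere(self):
        genes = _genes_with_gaps([500, 500])
        links = link_genes(genes, {}, PARAMS)
        assert not links.pairs and not links.filled


def _ann(gene_id, biosyn=False, core=None, ripp=False, usty=False):
    return ProteinAnnotation(
        gene_id=gene_id,
        core_category=core,
        families=frozenset({"x"}) if biosyn and core is None and not ripp else frozenset(),
        is_ripp_pp=ripp,
        is_usty_like=usty,
    )


class TestAssembleBGC:
    def test_biosynthetic_neighbor_within_2500(self):
        genes = _genes_with_gaps([2_400])
        anns = {"g0": _ann("g0", biosyn=True), "g1": _ann("g1", biosyn=True)}
        links = link_genes(genes, {}, PARAMS)
        assert assemble_bgc(0, genes, anns, links, PARAMS) == (0, 1)
        # inclusive at exactly 2500
        genes = _genes_with_gaps([2_500])
        assert assemble_bgc(0, genes, anns, links, PARAMS) == (0, 1)

    def test_biosynthetic_neighbor_beyond_2500_excluded(self):
        genes = _genes_with_gaps([2_600])
        anns = {"g0": _ann("g0", biosyn=True), "g1": _ann("g1", biosyn=True)}
        links = link_genes(genes, {}, PARAMS)
        assert assemble_bgc(0, genes, anns, links, PARAMS) == (0, 0)

    def test_extension_halts_at_first_failure(self):
        genes = _genes_with_gaps([500, 3_000, 500])
        anns = {f"g{i}": _ann(f"g{i}", biosyn=True) for i in range(4)}
        links = link_genes(genes, {}, PARAMS)
        # g2 is biosynthetic but 3000 bp away and unlinked: boundary before it
        assert assemble_bgc(0, genes, anns, links, PARAMS) == (0, 1)

    def test_fully_linked_run(self):
        genes = _genes_with_gaps([500] * 5)
        omap = _omap({f"g{i}": {"O1": 30.0} for i in range(6)})
        anns = {f"g{i}": _ann(f"g{i}", biosyn=True) for i in range(6)}
        links = link_genes(genes, omap, PARAMS)
        assert assemble_bgc(2, genes, anns, links, PARAMS) == (0, 5)


class TestAcceptBGC:
    def test_core_enzyme_accepts(self):
        genes = [make_gene("g0", 0, 750)]
        anns = {"g0": _ann("g0", core="PKS")}
        assert accept_bgc(genes, anns, frozenset(), "all") == ACCEPT_CORE

    def test_ripp_pair_accepts_without_core(self):
        genes = [make_gene("g0", 0, 750), make_gene("g1", 1000, 1750, index=1)]
        anns = {"g0": _ann("g0", ripp=True), "g1": _ann("g1", biosyn=True, usty=True)}
        assert accept_bgc(genes, anns, frozenset(), "all") == ACCEPT_RIPP

    def test_ripp_without_usty_rejected(self):
        genes = [make_gene("g0", 0, 750)]
        anns = {"g0": _ann("g0", ripp=True)}
        assert accept_bgc(genes, anns, frozenset(), "all") is None

    def test_tailoring_only_rejected(self):
        genes = [make_gene("g0", 0, 750)]
        anns = {"g0": _ann("g0", biosyn=True)}
        assert accept_bgc(genes, anns, frozenset(), "targeted") is None

    def test_lone_core_target_is_standalone(self):
        genes = [make_gene("t", 0, 750)]
        anns = {"t": _ann("t", core="terpene cyclase")}
        assert (
            accept_bgc(genes, anns, frozenset({"t"}), "targeted") == ACCEPT_STANDALONE
        )
        # same single gene in all-BGC mode is an ordinary core record
        assert accept_bgc(genes, anns, frozenset(), "all") == ACCEPT_CORE


class TestFindTargets:
    def test_cutoffs_applied(self):
        engine = MockEngine(
            domain_hits=[
                DomainHit("strong", "Pyr4", 1e-20, 1e-20, 100.0),
                DomainHit("weak", "Pyr4", 1e-3, 1e-3, 10.0),
                DomainHit("wrong", "DUF3328", 1e-20, 1e-20, 100.0),
            ]
        )
        proteome = {"strong": "M", "weak": "M", "wrong": "M"}
        assert find_targets(proteome, "Pyr4", engine) == {"strong"}


class TestExtractTargeted:
    def test_golden_planted_cluster(self, standard_fixture):
        fx = standard_fixture
        records = extract_targeted(fx["genome"], "Pyr4", fx["index"], fx["engine"])
        truths = expected_records(fx["spec"], fx["synthetic"])
        assert len(records) == len(truths) == 1
        record, truth = records[0], truths[0]
        indices = [g.index for g in record.genes]
        assert (indices[0], indices[-1]) == (
            truth.first_gene_index,
            truth.last_gene_index,
        )
        assert record.acceptance == truth.acceptance
        assert len(record.target_gene_ids) == 1
        # RiPP precursor and UstY-like genes were pulled into the record
        anns = record.annotations.values()
        assert any(a.is_ripp_pp for a in anns) and any(a.is_usty_like for a in anns)

    def test_two_targets_in_one_cluster_merge(self, tmp_path):
        origin = "FBGC90001"
        genes = (
            PlantedGene(kind="target", origin=origin, ref_index=0, identity=60.0),
            PlantedGene(kind="ref", origin=origin, ref_index=1, identity=40.0, gap_before=900),
            PlantedGene(kind="target", origin=origin, ref_index=2, identity=55.0, gap_before=900),
        )
        spec = FixtureSpec(seed=21, scaffolds=(PlantedScaffold("scf1", genes),))
        genome, index, engine, synthetic, _ = build_fixture(spec, tmp_path)
        records = extract_targeted(genome, "Pyr4", index, engine)
        assert len(records) == 1
        assert len(records[0].target_gene_ids) == 2
        assert [g.index for g in records[0].genes] == [0, 1, 2]

    def test_isolated_target_yields_standalone_record(self, tmp_path):
        genes = (
            PlantedGene(kind="decoy", gap_before=1_000, length=260),
            PlantedGene(kind="target", origin="FBGC90001", ref_index=0,
                        identity=60.0, gap_before=20_000),
            PlantedGene(kind="decoy", gap_before=20_000, length=260),
        )
        spec = FixtureSpec(seed=22, scaffolds=(PlantedScaffold("scf1", genes),))
        genome, index, engine, synthetic, _ = build_fixture(spec, tmp_path)
        records = extract_targeted(genome, "Pyr4", index, engine)
        assert len(records) == 1
        assert records[0].acceptance == ACCEPT_STANDALONE
        assert len(records[0].genes) == 1

    def test_no_targets_no_records(self, tmp_path):
        genes = (PlantedGene(kind="decoy", length=260),) * 3
        spec = FixtureSpec(seed=23, scaffolds=(PlantedScaffold("scf1", genes),))
        genome, index, engine, _, _ = build_fixture(spec, tmp_path)
        assert extract_targeted(genome, "Pyr4", index, engine) == []

    def test_determinism(self, standard_fixture):
        fx = standard_fixture
        r1 = extract_targeted(fx["genome"], "Pyr4", fx["index"], fx["engine"])
        r2 = extract_targeted(fx["genome"], "Pyr4", fx["index"], fx["engine"])
        assert [(r.bgc_id, [g.gene_id for g in r.genes], r.acceptance) for r in r1] == [
            (r.bgc_id, [g.gene_id for g in r.genes], r.acceptance) for r in r2
        ]


class TestExtractAll:
    def test_two_disjoint_clusters(self, tmp_path):
        o1, o2 = "FBGC90001", "FBGC90002"
        genes = (
            PlantedGene(kind="target", origin=o1, ref_index=0, identity=60.0),
            PlantedGene(kind="ref", origin=o1, ref_index=1, identity=40.0, gap_before=900),
            PlantedGene(kind="target", origin=o2, ref_index=0, identity=60.0, gap_before=30_000),
            PlantedGene(kind="ref", origin=o2, ref_index=1, identity=40.0, gap_before=900),
        )
        spec = FixtureSpec(seed=24, scaffolds=(PlantedScaffold("scf1", genes),))
        genome, index, engine, _, _ = build_fixture(spec, tmp_path)
        records = extract_all(genome, index, engine)
        assert len(records) == 2
        assert [[g.index for g in r.genes] for r in records] == [[0, 1], [2, 3]]

    def test_matches_targeted_mode_on_same_fixture(self, standard_fixture):
        fx = standard_fixture
        targeted = extract_targeted(fx["genome"], "Pyr4", fx["index"], fx["engine"])
        everything = extract_all(fx["genome"], fx["index"], fx["engine"])
        assert [[g.gene_id for g in r.genes] for r in targeted] == [
            [g.gene_id for g in r.genes] for r in everything
        ]

    def test_empty_genome(self, tmp_path):
        genes = (PlantedGene(kind="decoy", length=260),) * 2
        spec = FixtureSpec(seed=25, scaffolds=(PlantedScaffold("scf1", genes),))
        genome, index, engine, _, _ = build_fixture(spec, tmp_path)
        assert extract_all(genome, index, engine) == []

    def test_ripp_seed_without_usty_rejected(self, tmp_path):
        genes = (
            PlantedGene(kind="decoy", length=260),
            PlantedGene(kind="ripp", gap_before=1_000),
            PlantedGene(kind="decoy", gap_before=1_000, length=260),
        )
        spec = FixtureSpec(seed=26, scaffolds=(PlantedScaffold("scf1", genes),))
        genome, index, engine, _, _ = build_fixture(spec, tmp_path)
        assert extract_all(genome, index, engine) == []


class TestMonotonicity:
    def test_wider_linkage_gap_never_shrinks_records(self, tmp_path):
        spec = planted_cluster_spec(
            seed=31, gaps=(500, 12_000, 500), identities=(30.0, 30.0, 30.0)
        )
        genome, index, engine, _, _ = build_fixture(spec, tmp_path)
        narrow = extract_targeted(
            genome, "Pyr4", index, engine, ClusterParams(max_linked_gap=10_000)
        )
        wide = extract_targeted(
            genome, "Pyr4", index, engine, ClusterParams(max_linked_gap=20_000)
        )
        for rec in narrow:
            assert any(rec.gene_ids <= w.gene_ids for w in wide)


def test_every_targeted_record_contains_a_target(standard_fixture):
    fx = standard_fixture
    for record in extract_targeted(fx["genome"], "Pyr4", fx["index"], fx["engine"]):
        assert record.target_gene_ids
        assert record.target_gene_ids <= record.gene_ids
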