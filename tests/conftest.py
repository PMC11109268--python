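import pytest

from bgcmine.fixtures import build_fixture, planted_cluster_spec
from bgcmine.genome_io import GeneRecord


def make_gene(
    gene_id: str,
    start: int,
    end: int,
    scaffold_id: str = "scf",
    strand: str = "+",
    protein: str = "M" * 250,
    index: int = 0,
) -> GeneRecord:
    return GeneRecord(
        gene_id=gene_id,
        scaffold_id=scaffold_id,
        start=start,
        end=end,
        strand=strand,
        protein=protein,
        index=index,
    )


@pytest.fixture(scope="session")
def standard_fixture(tmp_path_factory):
    """One planted 5-gene cluster with a trailing RiPP precursor/UstY pair."""
    spec = planted_cluster_spec(seed=7, with_ripp_pair=True)
    work = tmp_path_factory.mktemp("standard_fixture")
    genome, index, engine, synthetic, collection = build_fixture(spec, work)
    return {
        "spec": spec,
        "genome": genome,
        "index": index,
        "engine": engine,
        "synthetic": synthetic,
        "collection": collection,
        "work": work,
    }
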