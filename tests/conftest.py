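import pytest

from editscan.refmodel import (
    AnnotationSet,
    GeneModel,
    KnownEditingSet,
    KnownVariantSet,
    ReferenceBundle,
    ReferenceGenome,
    RepeatMask,
)
from editscan.simulate import SimulationConfig, simulate_study


@pytest.fixture
def tiny_genome():
    #          1234567890123456789012345678901234567890
    chr1 = "ACGTACGTGGAAAAATGACGTACGTACGTACGTACGTACG" * 10
    return ReferenceGenome({"chr1": chr1, "chrM": "ACGT" * 10})


@pytest.fixture
def two_exon_gene():
    return GeneModel(gene_id="gA", gene_name="GA", contig="chr1", strand="+",
                     exons=[(1, 100), (201, 300)], cds=[(31, 100), (201, 270)])


@pytest.fixture
def annotation(two_exon_gene):
    single = GeneModel(gene_id="gB", gene_name="GB", contig="chr1", strand="+",
                       exons=[(350, 400)], cds=[])
    return AnnotationSet([two_exon_gene, single])


@pytest.fixture
def bundle(tiny_genome, annotation):
    return ReferenceBundle(
        genome=tiny_genome,
        annotation=annotation,
        repeats=RepeatMask({"chr1": [(380, 390)]}),
        known_variants=KnownVariantSet({("chr1", 50, "C", "T")}),
        known_editing=KnownEditingSet({("chr1", 60): ("+", "G-to-A")}),
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A small but complete simulated study, shared across integration tests."""
    cfg = SimulationConfig(
        seed=7, n_genes=5, contig_length=9_000, n_reference_cohort=3,
        n_edit_sites=20, n_diff_sites=5, n_germline_het=6, n_germline_hom=4,
        n_artifact_homopolymer=2, n_artifact_near_junction=2, n_artifact_mito=1,
    )
    outdir = tmp_path_factory.mktemp("small_run")
    manifest = simulate_study(cfg, outdir)
    return cfg, manifest, outdir
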