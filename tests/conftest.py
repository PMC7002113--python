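import pytest

from metasrna.annotation_io import Contig, GeneFeature, GenomeAnnotation, PipelineConfig
from metasrna.synthetic_community import generate_community


@pytest.fixture()
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def session_cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def bundle(session_cfg):
    """Small ground-truthed community: 5 contigs, 80 genes, 40 planted sRNAs
    plus the full boundary-decoy set."""
    return generate_community(5, 80, 40, seed=1, cfg=session_cfg)


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, session_cfg):
    out = tmp_path_factory.mktemp("bundle")
    generate_community(5, 80, 40, seed=1, cfg=session_cfg, out_dir=out)
    return out


def make_annotation(contig_len=10_000, genes=(), sequence=None):
    """One-contig annotation with the given (id, start, end, strand) genes."""
    contig = Contig("c1", contig_len, sequence)
    ann = GenomeAnnotation({"c1": contig}, [])
    for gid, start, end, strand in genes:
        ann.add_gene(GeneFeature(id=gid, contig_id="c1", start=start, end=end,
                                 strand=strand))
    return ann
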