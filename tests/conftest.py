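import numpy as np
import pytest

from scutr import fixtures


@pytest.fixture(scope="session")
def standard_fixture(tmp_path_factory):
    """A small ground-truth experiment: 4 genes x 4 clusters, seeded.

    geneAPA has cluster-distinct PDUIs (0.2 vs 0.8), geneNull equal PDUIs,
    geneMinus exercises the - strand, genePrimed carries a genomic A stretch
    across its proximal site.
    """
    clusters = ["c1", "c2", "c3", "c4"]
    genes = [
        fixtures.FixtureGene("geneAPA", "+", 1000, 400,
                             {"c1": 0.2, "c2": 0.8, "c3": 0.2, "c4": 0.8}),
        fixtures.FixtureGene("geneNull", "+", 1000, 400,
                             {k: 0.5 for k in clusters}),
        fixtures.FixtureGene("geneMinus", "-", 800, 300,
                             {"c1": 0.1, "c2": 0.9, "c3": 0.1, "c4": 0.9}),
        fixtures.FixtureGene("genePrimed", "+", 1000, 500,
                             {"c1": 0.3, "c2": 0.7, "c3": 0.3, "c4": 0.7},
                             a_rich=True),
    ]
    out = tmp_path_factory.mktemp("fixture")
    return fixtures.make_fixture(out, genes, clusters,
                                 reads_per_gene_cluster=300, seed=11)


def step_coverage(L, P, w_long, w_short):
    """Noiseless padded coverage of a two-isoform gene."""
    pos = np.arange(1, L + 1)
    return np.where(pos <= P, w_long + w_short, float(w_long)).astype(float)
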