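import numpy as np
import pytest

from merscape import census as census_mod
from merscape import simulate as sim
from merscape.model import Cohort, GeneFeature, Genome, Replicon


def make_genome(
    features,
    replicon_len=50_000,
    genome_id="G1",
    replicon_id="chr",
    kind="chromosome",
):
    """Build a one-replicon genome from (start, end, strand, name, product)."""
    feats = [
        GeneFeature(
            feature_id=f"{genome_id}_{i:04d}",
            replicon_id=replicon_id,
            start=s,
            end=e,
            strand=strand,
            gene_name=name,
            product=product,
        )
        for i, (s, e, strand, name, product) in enumerate(features)
    ]
    return Genome(
        genome_id=genome_id,
        replicons=[Replicon(replicon_id, replicon_len, "linear", kind)],
        features=feats,
    )


def operon_features(genes, start=10_000, strand="+", gap=100):
    """Feature tuples for a contiguous mer cassette in template order."""
    order = genes if strand == "+" else genes[::-1]
    out = []
    pos = start
    for g in order:
        length = sim.MER_GENE_LENGTHS[g]
        name, product = sim.MER_PRODUCTS[g]
        out.append((pos, pos + length, strand, name, product))
        pos += length + gap
    return out


@pytest.fixture(scope="session")
def standard_cohort():
    """The 30-genome / 20-operon validation cohort, categories assigned."""
    spec = sim.standard_validation_spec(seed=11)
    cohort, truth = sim.generate_cohort(spec)
    for g in cohort:
        census_mod.assign_categories(g)
    return cohort, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_cohort():
    g1 = make_genome(
        operon_features(["merR", "merT", "merP", "merC", "merA", "merB"]),
        genome_id="A",
    )
    g2 = make_genome(
        [(1000, 1900, "+", "", "citrate synthase")], genome_id="B"
    )
    for g in (g1, g2):
        census_mod.assign_categories(g)
    return Cohort(genomes=[g1, g2])
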