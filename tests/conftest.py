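import numpy as np
import pytest

from siambin import simulate as sim


@pytest.fixture(scope="session")
def small_community():
    """A cheap 6-genome community for unit-level pipeline tests."""
    return sim.generate_community(sim.CommunityConfig(
        n_genomes=6, genome_length_bp=120_000, rng_seed=7,
    ))


@pytest.fixture(scope="session")
def two_genome_profiles():
    """Feature vectors + genome labels for 2 well-separated genomes."""
    com = sim.generate_community(sim.CommunityConfig(
        n_genomes=2, genome_length_bp=200_000, rng_seed=3,
    ))
    from siambin import features as feat

    contigs = sorted(
        (c for c in com.contigs if c.length >= 1000), key=lambda c: c.contig_id
    )
    fm = feat.build_feature_matrix(contigs, com.coverage)
    labels = np.array([com.truth[c] for c in fm.contig_ids])
    return com, fm, labels
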