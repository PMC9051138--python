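import numpy as np
import pytest

from _oracles import finite_difference
from siambin import model as mdl
from siambin.types import ConstraintSet


class TestContrastiveLoss:
    def test_must_link_at_zero_distance(self):
        e = np.ones((1, 4))
        assert mdl.contrastive_loss(e, e, [1]) == 0.0

    def test_cannot_link_beyond_margin(self):
        e1 = np.zeros((1, 4))
        e2 = np.full((1, 4), 1.0)  # d = 2
        assert mdl.contrastive_loss(e1, e2, [0]) == 0.0

    def test_mixed_pair_hand_value(self):
        # one must-link at d=0.5 and one cannot-link at d=0.5:
        # (0.25 + 0.25) / 2 = 0.25
        e1 = np.zeros((2, 1))
        e2 = np.full((2, 1), 0.5)
        assert mdl.contrastive_loss(e1, e2, [1, 0]) == pytest.approx(0.25)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(0)
        e1, e2 = rng.normal(size=(2, 5, 8))
        y = np.array([1, 0, 1, 0, 1])
        assert mdl.contrastive_loss(e1, e2, y) == pytest.approx(
            mdl.contrastive_loss(e2, e1, y)
        )

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mdl.contrastive_loss(np.zeros((0, 3)), np.zeros((0, 3)), [])

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(1)
        e1 = rng.normal(scale=0.5, size=(6, 7))
        e2 = rng.normal(scale=0.5, size=(6, 7))
        y = np.array([1, 0, 1, 0, 0, 1], dtype=float)
        _, g1, g2 = mdl.contrastive_loss_grad(e1, e2, y)
        num1 = finite_difference(lambda: mdl.contrastive_loss(e1, e2, y), e1)
        num2 = finite_difference(lambda: mdl.contrastive_loss(e1, e2, y), e2)
        assert np.allclose(g1, num1, rtol=1e-4, atol=1e-7)
        assert np.allclose(g2, num2, rtol=1e-4, atol=1e-7)


class TestReconstructionLoss:
    def test_perfect_reconstruction(self):
        x = np.arange(6.0).reshape(2, 3)
        assert mdl.reconstruction_loss(x, x) == 0.0

    def test_hand_value(self):
        assert mdl.reconstruction_loss(np.zeros((1, 2)), np.ones((1, 2))) == 1.0

    def test_nonnegative_and_shape_checked(self):
        rng = np.random.default_rng(2)
        x, xh = rng.normal(size=(2, 4, 5))
        assert mdl.reconstruction_loss(x, xh) >= 0
        with pytest.raises(ValueError):
            mdl.reconstruction_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 5))
        xh = rng.normal(size=(4, 5))
        _, g = mdl.reconstruction_loss_grad(x, xh)
        num = finite_difference(lambda: mdl.reconstruction_loss(x, xh), xh)
        assert np.allclose(g, num, rtol=1e-4, atol=1e-8)


class TestNetwork:
    def test_parameter_count_closed_form(self):
        f, h1, h2, e = 136, 512, 512, 100
        cfg = mdl.NetworkConfig(input_dim=f)
        net = mdl.SiameseAutoencoder(cfg)

        def linear(a, b):
            return a * b + b

        def bn(n):
            return 2 * n

        expected = (
            linear(f, h1) + bn(h1) + linear(h1, h2) + bn(h2) + linear(h2, e)
            + linear(e, h2) + bn(h2) + linear(h2, h1) + bn(h1) + linear(h1, f)
        )
        assert net.n_parameters == expected

    def test_same_seed_identical_init(self):
        cfg = mdl.NetworkConfig(input_dim=20, hidden_dims=(16, 16), rng_seed=9)
        a = mdl.SiameseAutoencoder(cfg).state_dict()
        b = mdl.SiameseAutoencoder(cfg).state_dict()
        assert all(np.array_equal(a[k], b[k]) for k in a)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            mdl.NetworkConfig(input_dim=0)
        with pytest.raises(ValueError):
            mdl.NetworkConfig(input_dim=10, hidden_dims=(4,))
        with pytest.raises(ValueError):
            mdl.NetworkConfig(input_dim=10, dropout_rate=1.0)


def _tiny_training_setup(two_genome_profiles):
    com, fm, labels = two_genome_profiles
    cs = ConstraintSet()
    ids = fm.contig_ids
    by_genome = {}
    for cid, g in zip(ids, labels):
        by_genome.setdefault(g, []).append(cid)
    genomes = sorted(by_genome)
    # a handful of true constraints straight from the planted structure
    for g in genomes:
        members = by_genome[g]
        for a, b in zip(members, members[1:]):
            cs.add_must_link(a, b)
    for a in by_genome[genomes[0]][:6]:
        for b in by_genome[genomes[1]][:6]:
            cs.add_cannot_link(a, b, "scg_seed")
    cfg = mdl.NetworkConfig(
        input_dim=fm.feature_dim, hidden_dims=(64, 64), epochs=12,
        batch_pairs=64, rng_seed=4,
    )
    return fm, labels, cs, cfg


@pytest.fixture(scope="module")
def trained_tiny(two_genome_profiles):
    fm, labels, cs, cfg = _tiny_training_setup(two_genome_profiles)
    emb = mdl.train(fm.z, fm.contig_ids, cs, cfg, feature_regime=fm.regime)
    return fm, labels, emb


class TestTraining:
    def test_embedding_separates_planted_genomes(self, trained_tiny):
        fm, labels, emb = trained_tiny
        e = mdl.embed(emb, fm.z, fm.regime)
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(e))
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()

    def test_loss_descends_over_epochs(self, trained_tiny):
        _fm, _labels, emb = trained_tiny
        assert emb.training_history[-1] <= emb.training_history[0]

    def test_embed_deterministic_and_100_dim_default(self, trained_tiny):
        fm, _labels, emb = trained_tiny
        e1 = mdl.embed(emb, fm.z, fm.regime)
        e2 = mdl.embed(emb, fm.z, fm.regime)
        assert np.array_equal(e1, e2)
        assert e1.shape == (len(fm.contig_ids), emb.config.embedding_dim)
        assert mdl.NetworkConfig(input_dim=136).embedding_dim == 100

    def test_train_determinism(self, two_genome_profiles):
        fm, _labels, cs, cfg = _tiny_training_setup(two_genome_profiles)
        cfg2 = mdl.NetworkConfig(
            input_dim=fm.feature_dim, hidden_dims=(32, 32), epochs=2,
            batch_pairs=32, rng_seed=8,
        )
        runs = [
            mdl.train(fm.z, fm.contig_ids, cs, cfg2, feature_regime=fm.regime)
            for _ in range(2)
        ]
        e = [mdl.embed(r, fm.z, fm.regime) for r in runs]
        assert np.array_equal(e[0], e[1])

    def test_missing_constraint_classes_rejected(self, two_genome_profiles):
        fm, _labels, cs, cfg = _tiny_training_setup(two_genome_profiles)
        only_ml = ConstraintSet(must_link=set(cs.must_link))
        with pytest.raises(ValueError, match="cannot-link"):
            mdl.train(fm.z, fm.contig_ids, only_ml, cfg)
        only_cl = ConstraintSet(cannot_link=set(cs.cannot_link))
        with pytest.raises(ValueError, match="must-link"):
            mdl.train(fm.z, fm.contig_ids, only_cl, cfg)

    def test_unknown_contig_in_constraints_rejected(self, two_genome_profiles):
        fm, _labels, cs, cfg = _tiny_training_setup(two_genome_profiles)
        bad = ConstraintSet(must_link=set(cs.must_link), cannot_link={("nope", "zzz")})
        with pytest.raises(ValueError, match="unknown contig"):
            mdl.train(fm.z, fm.contig_ids, bad, cfg)


class TestSaveLoad:
    def test_roundtrip_embeddings_identical(self, trained_tiny, tmp_path):
        fm, _labels, emb = trained_tiny
        p = tmp_path / "model.npz"
        mdl.save(emb, p)
        loaded = mdl.load(p)
        assert loaded.feature_regime == emb.feature_regime
        assert np.array_equal(
            mdl.embed(emb, fm.z, fm.regime), mdl.embed(loaded, fm.z, fm.regime)
        )

    def test_wrong_feature_dim_rejected(self, trained_tiny, tmp_path):
        fm, _labels, emb = trained_tiny
        p = tmp_path / "model.npz"
        mdl.save(emb, p)
        loaded = mdl.load(p)
        with pytest.raises(ValueError, match="features"):
            mdl.embed(loaded, np.zeros((2, fm.feature_dim + 5)), fm.regime)

    def test_wrong_regime_rejected(self, trained_tiny):
        fm, _labels, emb = trained_tiny
        with pytest.raises(ValueError, match="regime"):
            mdl.embed(emb, fm.z, "kmer_plus_abundance(7)")
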