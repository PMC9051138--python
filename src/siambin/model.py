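"""Semi-supervised siamese autoencoder over contig feature vectors.

Two weight-shared encoder branches map a pair of contig feature vectors to
100-dimensional embeddings; a contrastive loss pulls must-link pairs together
and pushes cannot-link pairs beyond a unit margin. Jointly, a decoder
reconstructs the original features from the embedding under a mean-squared
error loss, so the embedding keeps structure shared by all contigs rather
than merely memorizing the constraints. Both losses are optimized together
(equal weights) with Adam.

The network is a dense stack: encoder F -> h1 -> h2 -> 100 and decoder
100 -> h2 -> h1 -> F, where the first two layers of each half are followed by
batch normalization, a leaky rectified linear unit, and dropout (rate 0.2).
The encoder output layer is linear. Implemented directly on NumPy with
hand-written backpropagation; training is deterministic for a fixed seed on
one device.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .types import ConstraintSet

MODEL_FORMAT_VERSION = 1
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1
_LEAKY_SLOPE = 0.01


# ---------------------------------------------------------------------------
# Losses (pure functions; used by the trainer and by gradient-check tests)


def contrastive_loss(emb1: np.ndarray, emb2: np.ndarray, labels: np.ndarray) -> float:
    """Mean over pairs of  y*d^2 + (1-y)*max(1-d, 0)^2.

    ``labels`` are 1 for must-link and 0 for cannot-link; ``d`` is the
    Euclidean distance between the two embeddings of a pair.
    """
    emb1, emb2 = np.asarray(emb1, float), np.asarray(emb2, float)
    labels = np.asarray(labels, float)
    if emb1.shape != emb2.shape or emb1.shape[0] != labels.shape[0]:
        raise ValueError("embedding/label shape mismatch")
    if emb1.shape[0] == 0:
        raise ValueError("empty pair set")
    d = np.linalg.norm(emb1 - emb2, axis=1)
    margin = np.maximum(1.0 - d, 0.0)
    return float(np.mean(labels * d**2 + (1.0 - labels) * margin**2))


def contrastive_loss_grad(
    emb1: np.ndarray, emb2: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus analytic gradients with respect to both embedding blocks."""
    emb1, emb2 = np.asarray(emb1, float), np.asarray(emb2, float)
    labels = np.asarray(labels, float)
    n = emb1.shape[0]
    if n == 0:
        raise ValueError("empty pair set")
    diff = emb1 - emb2
    d = np.linalg.norm(diff, axis=1)
    margin = np.maximum(1.0 - d, 0.0)
    loss = float(np.mean(labels * d**2 + (1.0 - labels) * margin**2))
    # d(y d^2)/d e1 = 2 y diff ; d((1-y) m^2)/d e1 = -2 (1-y) m diff / d
    safe_d = np.where(d > 0, d, 1.0)
    coef = 2.0 * labels - 2.0 * (1.0 - labels) * margin / safe_d
    coef = np.where(d > 0, coef, 2.0 * labels)  # margin term vanishes at d=0
    g1 = (coef[:, None] * diff) / n
    return loss, g1, -g1


def reconstruction_loss(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Mean squared elementwise reconstruction error, averaged over contigs."""
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2))


def reconstruction_loss_grad(x: np.ndarray, x_hat: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss plus the analytic gradient with respect to the reconstruction."""
    x, x_hat = np.asarray(x, float), np.asarray(x_hat, float)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    return float(np.mean((x - x_hat) ** 2)), 2.0 * (x_hat - x) / x.size


# ---------------------------------------------------------------------------
# Layers


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype) -> None:
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_in, n_out)).astype(dtype)
        self.b = rng.uniform(-bound, bound, size=n_out).astype(dtype)

    def params(self):
        return {"W": self.W, "b": self.b}

    def forward(self, x, training, rng):
        return x @ self.W + self.b, x

    def backward(self, g, cache):
        x = cache
        return g @ self.W.T, {"W": x.T @ g, "b": g.sum(axis=0)}


class _BatchNorm:
    def __init__(self, n: int, dtype) -> None:
        self.gamma = np.ones(n, dtype=dtype)
        self.beta = np.zeros(n, dtype=dtype)
        self.running_mean = np.zeros(n, dtype=dtype)
        self.running_var = np.ones(n, dtype=dtype)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += _BN_MOMENTUM * (mean - self.running_mean)
            self.running_var += _BN_MOMENTUM * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (x - mean) * inv_std
        return self.gamma * x_hat + self.beta, (x_hat, inv_std, training)

    def backward(self, g, cache):
        x_hat, inv_std, training = cache
        g_gamma = (g * x_hat).sum(axis=0)
        g_beta = g.sum(axis=0)
        if not training:
            return g * self.gamma * inv_std, {"gamma": g_gamma, "beta": g_beta}
        n = x_hat.shape[0]
        gxh = g * self.gamma
        gx = (inv_std / n) * (
            n * gxh - gxh.sum(axis=0) - x_hat * (gxh * x_hat).sum(axis=0)
        )
        return gx, {"gamma": g_gamma, "beta": g_beta}


class _LeakyReLU:
    def params(self):
        return {}

    def forward(self, x, training, rng):
        mask = x >= 0
        return np.where(mask, x, _LEAKY_SLOPE * x), mask

    def backward(self, g, cache):
        mask = cache
        return np.where(mask, g, _LEAKY_SLOPE * g), {}


class _Dropout:
    def __init__(self, rate: float) -> None:
        self.rate = rate

    def params(self):
        return {}

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            return x, None
        keep = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * keep, keep

    def backward(self, g, cache):
        return (g if cache is None else g * cache), {}


# ---------------------------------------------------------------------------
# Network


@dataclass
class NetworkConfig:
    """Architecture and optimization settings for the siamese autoencoder."""

    input_dim: int
    hidden_dims: tuple[int, int] = (512, 512)
    embedding_dim: int = 100
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    epochs: int = 20
    batch_pairs: int = 1024
    rng_seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if self.input_dim < 1:
            raise ValueError(f"input_dim must be >= 1, got {self.input_dim}")
        if len(self.hidden_dims) != 2 or any(h < 1 for h in self.hidden_dims):
            raise ValueError(f"hidden_dims must be two positive ints, got {self.hidden_dims}")
        if self.embedding_dim < 1:
            raise ValueError("embedding_dim must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate {self.dropout_rate} outside [0, 1)")


class SiameseAutoencoder:
    """Encoder/decoder stack with shared weights across the two branches.

    Weight sharing is structural: both members of a pair pass through the
    same layer objects (as one concatenated batch), so gradients from the two
    branches accumulate on one parameter set.
    """

    def __init__(self, config: NetworkConfig) -> None:
        self.config = config
        dtype = np.dtype(config.dtype)
        rng = np.random.default_rng(config.rng_seed)
        f, (h1, h2), e = config.input_dim, config.hidden_dims, config.embedding_dim
        dr = config.dropout_rate

        def block(n_in, n_out):
            return [
                _Linear(n_in, n_out, rng, dtype),
                _BatchNorm(n_out, dtype),
                _LeakyReLU(),
                _Dropout(dr),
            ]

        self.encoder = block(f, h1) + block(h1, h2) + [_Linear(h2, e, rng, dtype)]
        self.decoder = block(e, h2) + block(h2, h1) + [_Linear(h1, f, rng, dtype)]

    # -- parameter bookkeeping ------------------------------------------------

    def _layers(self):
        for half, layers in (("enc", self.encoder), ("dec", self.decoder)):
            for i, layer in enumerate(layers):
                yield f"{half}{i}", layer

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._layers():
            for pname, arr in layer.params().items():
                out[f"{name}.{pname}"] = arr
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = dict(self.parameters())
        for name, layer in self._layers():
            if isinstance(layer, _BatchNorm):
                state[f"{name}.running_mean"] = layer.running_mean
                state[f"{name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.state_dict()
        if set(own) != set(state):
            raise ValueError("model state does not match this architecture")
        for key, arr in state.items():
            if own[key].shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}")
            own[key][...] = arr

    # -- forward / backward ---------------------------------------------------

    @staticmethod
    def _forward(layers, x, training, rng):
        caches = []
        for layer in layers:
            x, cache = layer.forward(x, training, rng)
            caches.append(cache)
        return x, caches

    @staticmethod
    def _backward(layers, caches, g, grads):
        for name_layer, cache in zip(reversed(list(layers)), reversed(caches)):
            name, layer = name_layer
            g, pgrads = layer.backward(g, cache)
            for pname, arr in pgrads.items():
                key = f"{name}.{pname}"
                if key in grads:
                    grads[key] += arr
                else:
                    grads[key] = arr
        return g

    def _named(self, half):
        prefix = "enc" if half is self.encoder else "dec"
        return [(f"{prefix}{i}", layer) for i, layer in enumerate(half)]

    def encode(self, x: np.ndarray, training: bool = False, rng=None):
        x = np.asarray(x, dtype=self.config.dtype)
        return self._forward(self.encoder, x, training, rng)

    def decode(self, e: np.ndarray, training: bool = False, rng=None):
        return self._forward(self.decoder, e, training, rng)

    def embed(self, x: np.ndarray) -> np.ndarray:
        """Evaluation-mode embedding: running batch-norm statistics, no dropout."""
        out, _ = self.encode(np.atleast_2d(x), training=False)
        return np.asarray(out, dtype=np.float64)


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            p = self.params[key]
            m = self.m[key]
            v = self.v[key]
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            m_hat = m / (1 - b1**self.t)
            v_hat = v / (1 - b2**self.t)
            p -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.dtype)


# ---------------------------------------------------------------------------
# Trained model container and training loop


@dataclass
class TrainedEmbedder:
    """A trained siamese autoencoder plus the metadata needed to reapply it.

    ``feature_regime`` records whether the model consumed k-mer features only
    or k-mer plus scaled abundances (and for how many samples); applying a
    model to a sample in a different regime, or with a different feature
    dimension, is an error.
    """

    config: NetworkConfig
    network: SiameseAutoencoder
    feature_regime: str
    training_history: list[float] = field(default_factory=list)

    def check_compatible(self, input_dim: int, feature_regime: str) -> None:
        if input_dim != self.config.input_dim:
            raise ValueError(
                f"model expects {self.config.input_dim}-dim features, got {input_dim}"
            )
        if feature_regime != self.feature_regime:
            raise ValueError(
                f"model trained in regime {self.feature_regime!r}, "
                f"query is {feature_regime!r}"
            )


def train(
    x: np.ndarray,
    contig_ids: list[str],
    constraints: ConstraintSet,
    config: NetworkConfig,
    feature_regime: str = "kmer_only",
) -> TrainedEmbedder:
    """Train the siamese autoencoder on feature matrix ``x``.

    Each epoch iterates over all constraint pairs in shuffled batches; in
    parallel, the full contig set (shuffled, chunked to match the number of
    pair batches) passes through encoder+decoder for the reconstruction loss.
    The two losses are summed with equal weight and one Adam step is taken
    per batch. Deterministic for a fixed ``config.rng_seed``.
    """
    x = np.asarray(x, dtype=config.dtype)
    if x.ndim != 2 or x.shape[1] != config.input_dim:
        raise ValueError(f"feature matrix shape {x.shape} does not match F={config.input_dim}")
    index = {cid: i for i, cid in enumerate(contig_ids)}
    if len(index) != len(contig_ids):
        raise ValueError("duplicate contig ids in training set")

    constraints.validate()
    if not constraints.must_link:
        raise ValueError("no must-link constraints")
    if not constraints.cannot_link:
        raise ValueError("no cannot-link constraints")

    def pair_rows(pairs):
        rows = []
        for a, b in sorted(pairs):
            if a not in index or b not in index:
                raise ValueError(f"constraint references unknown contig {a!r}/{b!r}")
            rows.append((index[a], index[b]))
        return rows

    ml = pair_rows(constraints.must_link)
    cl = pair_rows(constraints.cannot_link)
    pair_idx = np.array(ml + cl, dtype=np.int64)
    labels = np.concatenate([np.ones(len(ml)), np.zeros(len(cl))]).astype(config.dtype)

    net = SiameseAutoencoder(config)
    opt = _Adam(net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))

    n_pairs = len(pair_idx)
    n_contigs = x.shape[0]
    enc_named = net._named(net.encoder)
    dec_named = net._named(net.decoder)
    history: list[float] = []

    for _epoch in range(config.epochs):
        perm = rng.permutation(n_pairs)
        contig_perm = rng.permutation(n_contigs)
        n_batches = max(1, int(np.ceil(n_pairs / config.batch_pairs)))
        recon_chunks = np.array_split(contig_perm, n_batches)
        epoch_loss = 0.0

        for b in range(n_batches):
            batch = perm[b * config.batch_pairs : (b + 1) * config.batch_pairs]
            rows = pair_idx[batch]
            y = labels[batch]
            grads: dict[str, np.ndarray] = {}

            # contrastive term: both branches share weights, so run them as
            # one concatenated batch through the encoder
            xb = np.concatenate([x[rows[:, 0]], x[rows[:, 1]]], axis=0)
            emb, caches = net._forward(net.encoder, xb, True, rng)
            e1, e2 = emb[: len(rows)], emb[len(rows) :]
            loss_con, g1, g2 = contrastive_loss_grad(e1, e2, y)
            g_emb = np.concatenate([g1, g2], axis=0).astype(config.dtype)
            net._backward(enc_named, caches, g_emb, grads)

            # reconstruction term on this epoch's chunk of the full contig set
            chunk = recon_chunks[b]
            loss_mse = 0.0
            if chunk.size:
                xc = x[chunk]
                e, enc_caches = net._forward(net.encoder, xc, True, rng)
                xhat, dec_caches = net._forward(net.decoder, e, True, rng)
                loss_mse, g_xhat = reconstruction_loss_grad(xc, xhat)
                g_e = net._backward(dec_named, dec_caches, g_xhat.astype(config.dtype), grads)
                net._backward(enc_named, enc_caches, g_e, grads)

            opt.step(grads)
            epoch_loss += loss_con + loss_mse
        history.append(epoch_loss / n_batches)

    return TrainedEmbedder(
        config=config, network=net, feature_regime=feature_regime,
        training_history=history,
    )


def embed(embedder: TrainedEmbedder, x: np.ndarray, feature_regime: str) -> np.ndarray:
    """Embed feature vectors with a trained model (evaluation mode)."""
    x = np.atleast_2d(np.asarray(x))
    embedder.check_compatible(x.shape[1], feature_regime)
    return embedder.network.embed(x)


# ---------------------------------------------------------------------------
# Serialization


def save(embedder: TrainedEmbedder, path: str | os.PathLike) -> None:
    """Serialize a trained model to a self-describing .npz container."""
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "feature_regime": embedder.feature_regime,
        "config": asdict(embedder.config),
        "training_history": embedder.training_history,
    }
    state = embedder.network.state_dict()
    with open(path, "wb") as fh:  # avoid np.savez appending ".npz"
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **state)


def load(path: str | os.PathLike) -> TrainedEmbedder:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta.get('format_version')!r}"
            )
        config = NetworkConfig(**meta["config"])
        net = SiameseAutoencoder(config)
        net.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return TrainedEmbedder(
        config=config, network=net, feature_regime=meta["feature_regime"],
        training_history=list(meta.get("training_history", [])),
    )
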