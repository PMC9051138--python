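"""From embeddings to bins: contig similarity, sparse graph construction,
map-equation community detection, and marker-guided reclustering.

Contig similarity is 1 minus a capped distance. With five or more samples the
distance is the Euclidean embedding distance alone (abundance is already part
of the model input); with fewer samples, per-sample read depth is modeled as
a normal distribution per contig and the embedding distance is multiplied by
the symmetrized Kullback-Leibler divergence between the two contigs' depth
distributions (averaged over samples, clamped), so contigs with clearly
different coverage are kept apart even when their composition is similar.

The implicit complete similarity graph is sparsified by keeping, per node,
the ``max_edges`` incident edges of highest weight; the same construction on
the original (un-embedded) feature vectors yields a second graph, and only
edges present in both survive — removing artefacts introduced by the
embedding. Communities of the surviving graph are found with Infomap, and
bins whose mean single-copy-marker count exceeds one are optionally
re-split with a weighted k-means seeded from the most duplicated marker.
"""

from __future__ import annotations

import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import igraph
import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .features import ABUNDANCE_REGIME_MIN_SAMPLES
from .types import Bin, MarkerHit

DEFAULT_MAX_EDGES = 200
DEFAULT_MIN_BIN_BP = 200_000
KL_CLAMP_LO = 1e-6
KL_CLAMP_HI = 1.0 - 1e-6


# ---------------------------------------------------------------------------
# Similarity


def _floor_variance(var: np.ndarray, mean: np.ndarray) -> np.ndarray:
    # zero-variance constant-depth contigs otherwise break the closed form
    return np.maximum(var, 1e-4 * mean + 1e-6)


def kl_normal(mean1, var1, mean2, var2) -> float:
    """Symmetrized KL divergence between univariate normal depth models.

    For several samples, the mean over samples of the per-sample divergence.
    Uses the closed form KL(N1||N2) = log(s2/s1) + (v1 + (m1-m2)^2)/(2 v2) - 1/2
    after flooring the variances.
    """
    m1 = np.atleast_1d(np.asarray(mean1, float))
    m2 = np.atleast_1d(np.asarray(mean2, float))
    v1 = _floor_variance(np.atleast_1d(np.asarray(var1, float)), m1)
    v2 = _floor_variance(np.atleast_1d(np.asarray(var2, float)), m2)
    if not (np.all(np.isfinite(m1)) and np.all(np.isfinite(m2))
            and np.all(np.isfinite(v1)) and np.all(np.isfinite(v2))):
        raise ValueError("non-finite depth parameters")
    kl12 = 0.5 * np.log(v2 / v1) + (v1 + (m1 - m2) ** 2) / (2 * v2) - 0.5
    kl21 = 0.5 * np.log(v1 / v2) + (v2 + (m1 - m2) ** 2) / (2 * v1) - 0.5
    return float(np.mean(0.5 * (kl12 + kl21)))


def pair_similarity(embed_dist: float, abundance_term: float | None, n_samples: int) -> float:
    """Similarity S in [0, 1] from an embedding distance and abundance term.

    S = 1 - min(d, 1) when n_samples >= 5 (abundance lives inside the
    embedding); otherwise S = 1 - min(d * a, 1) where ``a`` is the clamped
    coverage divergence.
    """
    if n_samples >= ABUNDANCE_REGIME_MIN_SAMPLES:
        return 1.0 - min(float(embed_dist), 1.0)
    if abundance_term is None:
        raise ValueError("abundance term required when n_samples < 5")
    return 1.0 - min(float(embed_dist) * float(abundance_term), 1.0)


def _abundance_matrix(abundance: np.ndarray, variance: np.ndarray) -> np.ndarray:
    """Pairwise clamped symmetric KL divergence matrix over contigs."""
    mean = np.asarray(abundance, float)
    var = _floor_variance(np.asarray(variance, float), mean)
    n, ns = mean.shape
    out = np.zeros((n, n))
    for s in range(ns):
        m = mean[:, s][:, None]
        v = var[:, s][:, None]
        dm2 = (m - m.T) ** 2
        kl12 = 0.5 * np.log(v.T / v) + (v + dm2) / (2 * v.T) - 0.5
        out += 0.5 * (kl12 + kl12.T)
    out /= ns
    return np.clip(out, KL_CLAMP_LO, KL_CLAMP_HI)


def similarity_matrix(
    vectors: np.ndarray,
    n_samples: int,
    abundance: np.ndarray | None = None,
    variance: np.ndarray | None = None,
) -> np.ndarray:
    """Dense pairwise similarity. ``vectors`` may be embeddings or raw features."""
    d = cdist(vectors, vectors)
    if n_samples >= ABUNDANCE_REGIME_MIN_SAMPLES:
        s = 1.0 - np.minimum(d, 1.0)
    else:
        if abundance is None or variance is None:
            raise ValueError("abundance model required when n_samples < 5")
        a = _abundance_matrix(abundance, variance)
        s = 1.0 - np.minimum(d * a, 1.0)
    np.fill_diagonal(s, 0.0)
    return s


# ---------------------------------------------------------------------------
# Sparse graph


@dataclass
class SimilarityGraph:
    """Weighted undirected graph over contig ids (weights in (0, 1])."""

    nodes: list[str]
    edges: dict[tuple[int, int], float] = field(default_factory=dict)

    def edge_key(self, i: int, j: int) -> tuple[int, int]:
        if i == j:
            raise ValueError("self-loop")
        return (i, j) if i < j else (j, i)

    def named_edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (self.nodes[i], self.nodes[j], w) for (i, j), w in self.edges.items()
        )


def write_graph(graph: SimilarityGraph, path) -> None:
    """Dump a similarity graph as a TSV (contig_1, contig_2, weight)."""
    with open(path, "w") as fh:
        fh.write("contig_1\tcontig_2\tweight\n")
        for a, b, w in graph.named_edges():
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def build_sparse_graph(
    node_ids: list[str],
    similarity: np.ndarray,
    max_edges: int = DEFAULT_MAX_EDGES,
) -> SimilarityGraph:
    """Keep, for each node, its ``max_edges`` highest-weight incident edges.

    The kept edge set is the union of the per-node nominations (so degrees
    can exceed ``max_edges``). Ties are broken lexicographically by neighbor
    id; zero-weight edges are never nominated.
    """
    n = len(node_ids)
    if n < 2:
        raise ValueError("graph needs at least 2 nodes")
    if similarity.shape != (n, n):
        raise ValueError("similarity matrix shape mismatch")
    order = np.argsort(node_ids)  # lexicographic neighbor rank for tie-breaks
    lexrank = np.empty(n, dtype=np.int64)
    lexrank[order] = np.arange(n)

    graph = SimilarityGraph(nodes=list(node_ids))
    for i in range(n):
        weights = similarity[i]
        candidates = [j for j in range(n) if j != i and weights[j] > 0.0]
        candidates.sort(key=lambda j: (-weights[j], lexrank[j]))
        for j in candidates[:max_edges]:
            graph.edges[graph.edge_key(i, j)] = float(weights[j])
    return graph


def intersect_graphs(embed_graph: SimilarityGraph, raw_graph: SimilarityGraph) -> SimilarityGraph:
    """Keep only edges present in both graphs, with weights from the first."""
    if embed_graph.nodes != raw_graph.nodes:
        raise ValueError("graphs are over different node sets")
    kept = {
        k: w for k, w in embed_graph.edges.items() if k in raw_graph.edges
    }
    return SimilarityGraph(nodes=list(embed_graph.nodes), edges=kept)


# ---------------------------------------------------------------------------
# Community detection


def partition(graph: SimilarityGraph, rng_seed: int = 0) -> list[list[str]]:
    """Two-level map-equation (Infomap) communities of the weighted graph.

    A single seeded trial; isolated nodes become singleton communities.
    Communities are returned sorted (members sorted, then by first member).
    """
    n = len(graph.nodes)
    g = igraph.Graph(n)
    edge_list = sorted(graph.edges.items())
    g.add_edges([k for k, _ in edge_list])
    weights = [w for _, w in edge_list]

    state = random.getstate()
    try:
        # python-igraph draws randomness from Python's random module
        random.seed(rng_seed)
        if g.ecount() > 0:
            clustering = g.community_infomap(edge_weights=weights, trials=1)
            membership = clustering.membership
        else:
            membership = list(range(n))
    finally:
        random.setstate(state)

    groups: dict[int, list[str]] = defaultdict(list)
    for idx, com in enumerate(membership):
        groups[com].append(graph.nodes[idx])
    return sorted((sorted(members) for members in groups.values()),
                  key=lambda ms: ms[0])


# ---------------------------------------------------------------------------
# Bins, reclustering, size filter


def make_bins(
    communities: list[list[str]],
    contig_lengths: dict[str, int],
    marker_hits: list[MarkerHit],
    marker_panel: set[str] | None = None,
) -> list[Bin]:
    """Wrap communities as bins with marker copy-number statistics.

    ``mean_scg_count`` is the total number of marker hits in the bin divided
    by the panel size (the distinct marker families seen in the whole input,
    unless a fixed panel is given); a clean single-genome bin with a complete
    panel scores 1.0, a merged two-genome bin about 2.0.
    """
    if marker_panel is None:
        marker_panel = {h.marker_id for h in marker_hits}
    hits_by_contig: dict[str, list[str]] = defaultdict(list)
    for h in marker_hits:
        if h.marker_id in marker_panel:
            hits_by_contig[h.contig_id].append(h.marker_id)

    bins = []
    for i, members in enumerate(communities):
        total = sum(contig_lengths[c] for c in members)
        n_hits = sum(len(hits_by_contig.get(c, ())) for c in members)
        mean_scg = n_hits / len(marker_panel) if marker_panel else 0.0
        bins.append(Bin(bin_id=f"community_{i:04d}", contig_ids=list(members),
                        total_bp=total, mean_scg_count=mean_scg))
    return bins


def recluster_bin(
    b: Bin,
    marker_hits: list[MarkerHit],
    embeddings: dict[str, np.ndarray],
    scaled_abundance: dict[str, np.ndarray],
    contig_lengths: dict[str, int],
) -> list[Bin]:
    """Re-split one bin with weighted k-means guided by marker duplication.

    Applies only to bins whose mean marker count exceeds one. k is the
    maximum copy number of any single marker within the bin; the initial
    centers are the k contigs carrying the most duplicated marker (ties by
    descending length, then id); features are the embedding concatenated
    with scaled abundances; sample weights are contig lengths in bp.
    """
    if b.mean_scg_count <= 1.0:
        return [b]
    members = sorted(b.contig_ids)
    member_set = set(members)
    copy_number: Counter[str] = Counter()
    carriers: dict[str, list[str]] = defaultdict(list)
    for h in marker_hits:
        if h.contig_id in member_set:
            copy_number[h.marker_id] += 1
            carriers[h.marker_id].append(h.contig_id)
    if not copy_number:
        return [b]
    k = max(copy_number.values())
    if k < 2:
        raise ValueError(
            f"bin {b.bin_id}: mean_scg_count {b.mean_scg_count:.2f} > 1 "
            f"but no marker is duplicated"
        )
    top_marker = min(copy_number, key=lambda m: (-copy_number[m], m))
    seeds = sorted(
        set(carriers[top_marker]),
        key=lambda c: (-contig_lengths[c], c),
    )[:k]
    if len(seeds) < k:
        return [b]

    features = np.vstack(
        [np.concatenate([embeddings[c], scaled_abundance[c]]) for c in members]
    )
    centers = np.vstack(
        [np.concatenate([embeddings[c], scaled_abundance[c]]) for c in seeds]
    )
    lengths = np.array([contig_lengths[c] for c in members], dtype=float)
    km = KMeans(n_clusters=k, init=centers, n_init=1, max_iter=300, tol=1e-4)
    labels = km.fit_predict(features, sample_weight=lengths)

    out = []
    for lab in range(k):
        sub = [c for c, l in zip(members, labels) if l == lab]
        if not sub:
            continue
        out.append(Bin(
            bin_id=f"{b.bin_id}_k{lab}",
            contig_ids=sub,
            total_bp=sum(contig_lengths[c] for c in sub),
        ))
    return out


def filter_small_bins(bins: list[Bin], min_bp: int = DEFAULT_MIN_BIN_BP) -> list[Bin]:
    """Drop bins below the minimum size; their contigs become unbinned."""
    return [b for b in bins if b.total_bp >= min_bp]
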