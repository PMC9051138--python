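"""End-to-end binning pipeline.

Orchestrates: length filtering -> feature assembly -> constraint generation
-> siamese training (or applying a pretrained model, or skipping the model
entirely for the ablation variants) -> embedding -> sparse similarity graphs
(embedded and raw) -> edge intersection -> Infomap partitioning -> optional
marker-guided reclustering -> bin-size filtering.

Variants mirror the semi-supervision ablation:

* ``full``    — train the siamese model and cluster the embeddings.
* ``nosemi``  — no model; cluster the raw feature vectors.
* ``m``       — no model; must-link pairs become weight-1 edges. (Must-link
  pairs join the two halves of one contig, so on the unsplit catalogue they
  collapse to self-pairs and this variant behaves like ``nosemi``.)
* ``c``       — no model; edges between cannot-link pairs are deleted.
* ``mc``      — both ``m`` and ``c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import constraints as cons
from . import features as feat
from . import graph as gr
from . import model as mdl
from .types import Bin, BinAssignment, Contig, ConstraintSet, CoverageRecord, MarkerHit, TaxonomyAnnotation

MODES = ("single", "coassembly", "multi")
VARIANTS = ("full", "nosemi", "m", "c", "mc")


@dataclass
class PipelineConfig:
    """Tunable settings of one binning run."""

    mode: str = "single"
    variant: str = "full"
    min_contig_len: int | None = None      # None: choose 1000/2500 automatically
    must_link_len: int | None = None       # None: 98%-basepair heuristic
    max_edges: int = gr.DEFAULT_MAX_EDGES
    min_bin_bp: int = gr.DEFAULT_MIN_BIN_BP
    max_cannot_link: int = cons.DEFAULT_MAX_CANNOT_LINK
    recluster: bool = True
    seed: int = 0
    network: dict = field(default_factory=dict)  # NetworkConfig overrides

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class PipelineResult:
    assignments: list[BinAssignment]
    bins: list[Bin]
    embedder: mdl.TrainedEmbedder | None
    min_contig_len: int
    must_link_len: int
    constraint_set: ConstraintSet | None


def _inherit_fragment_coverage(
    augmented: list[Contig],
    originals: set[str],
    coverage: list[CoverageRecord],
) -> list[CoverageRecord]:
    """Fragments of a split contig inherit the parent's coverage records."""
    by_parent: dict[str, list[CoverageRecord]] = {}
    for r in coverage:
        by_parent.setdefault(r.contig_id, []).append(r)
    out = list(coverage)
    for c in augmented:
        if c.contig_id in originals:
            continue
        for suffix in cons.FRAGMENT_SUFFIXES:
            if c.contig_id.endswith(suffix):
                parent = c.contig_id[: -len(suffix)]
                break
        else:  # pragma: no cover - fragments always carry a known suffix
            raise ValueError(f"unrecognized fragment id {c.contig_id!r}")
        for r in by_parent.get(parent, []):
            out.append(CoverageRecord(c.contig_id, r.sample_id, r.mean_depth, r.depth_variance))
    return out


def train_embedder(
    contigs: list[Contig],
    coverage: list[CoverageRecord],
    taxonomy: list[TaxonomyAnnotation],
    markers: list[MarkerHit],
    config: PipelineConfig,
) -> mdl.TrainedEmbedder:
    """Train a siamese embedder from one sample's contigs and annotations.

    This is the training half of the pipeline and also the entry point for
    pretraining a transferable model.
    """
    lengths = [c.length for c in contigs]
    min_len = config.min_contig_len or feat.select_min_length(lengths)
    filtered = [c for c in contigs if c.length >= min_len]
    if not filtered:
        raise ValueError("no contigs pass the length filter")
    flens = [c.length for c in filtered]
    threshold = config.must_link_len or feat.must_link_threshold(flens)

    base = feat.build_feature_matrix(filtered, coverage)
    augmented, cs = cons.build_constraints(
        filtered, threshold, taxonomy, markers,
        max_cannot=config.max_cannot_link, rng_seed=config.seed,
    )
    cov_aug = _inherit_fragment_coverage(
        augmented, {c.contig_id for c in filtered}, coverage
    )
    train_fm = feat.build_feature_matrix(
        augmented, cov_aug, sample_ids=base.sample_ids, scales=base.scales
    )
    net_cfg = mdl.NetworkConfig(
        input_dim=train_fm.feature_dim, rng_seed=config.seed, **config.network
    )
    return mdl.train(
        train_fm.z, train_fm.contig_ids, cs, net_cfg,
        feature_regime=train_fm.regime,
    )


def _bin_one_sample(
    contigs: list[Contig],
    coverage: list[CoverageRecord],
    taxonomy: list[TaxonomyAnnotation],
    markers: list[MarkerHit],
    config: PipelineConfig,
    embedder: mdl.TrainedEmbedder | None,
) -> PipelineResult:
    lengths = [c.length for c in contigs]
    min_len = config.min_contig_len or feat.select_min_length(lengths)
    filtered = sorted(
        (c for c in contigs if c.length >= min_len), key=lambda c: c.contig_id
    )
    if len(filtered) < 2:
        raise ValueError("fewer than two contigs pass the length filter")
    flens = [c.length for c in filtered]
    threshold = config.must_link_len or feat.must_link_threshold(flens)

    fm = feat.build_feature_matrix(filtered, coverage)
    contig_lengths = {c.contig_id: c.length for c in filtered}

    cs: ConstraintSet | None = None
    if config.variant == "full":
        if embedder is None:
            augmented, cs = cons.build_constraints(
                filtered, threshold, taxonomy, markers,
                max_cannot=config.max_cannot_link, rng_seed=config.seed,
            )
            cov_aug = _inherit_fragment_coverage(
                augmented, set(contig_lengths), coverage
            )
            train_fm = feat.build_feature_matrix(
                augmented, cov_aug, sample_ids=fm.sample_ids, scales=fm.scales
            )
            net_cfg = mdl.NetworkConfig(
                input_dim=train_fm.feature_dim, rng_seed=config.seed, **config.network
            )
            embedder = mdl.train(
                train_fm.z, train_fm.contig_ids, cs, net_cfg,
                feature_regime=train_fm.regime,
            )
        vectors = mdl.embed(embedder, fm.z, fm.regime)
    else:
        # ablations cluster the raw feature vectors
        if config.variant in ("m", "c", "mc"):
            _augmented, cs = cons.build_constraints(
                filtered, threshold, taxonomy, markers,
                max_cannot=config.max_cannot_link, rng_seed=config.seed,
            )
        vectors = fm.z

    sim_embed = gr.similarity_matrix(vectors, fm.n_samples, fm.abundance, fm.variance)
    g_embed = gr.build_sparse_graph(fm.contig_ids, sim_embed, config.max_edges)
    if config.variant == "full":
        sim_raw = gr.similarity_matrix(fm.z, fm.n_samples, fm.abundance, fm.variance)
        g_raw = gr.build_sparse_graph(fm.contig_ids, sim_raw, config.max_edges)
        g = gr.intersect_graphs(g_embed, g_raw)
    else:
        g = g_embed

    if cs is not None and config.variant in ("m", "mc"):
        index = {cid: i for i, cid in enumerate(g.nodes)}
        for a, b in sorted(cs.must_link):
            pa = a[:-2] if a.endswith(cons.FRAGMENT_SUFFIXES) else a
            pb = b[:-2] if b.endswith(cons.FRAGMENT_SUFFIXES) else b
            if pa != pb and pa in index and pb in index:
                g.edges[g.edge_key(index[pa], index[pb])] = 1.0
    if cs is not None and config.variant in ("c", "mc"):
        index = {cid: i for i, cid in enumerate(g.nodes)}
        for a, b in sorted(cs.cannot_link):
            if a in index and b in index:
                g.edges.pop(g.edge_key(index[a], index[b]), None)

    communities = gr.partition(g, rng_seed=config.seed)
    bins = gr.make_bins(communities, contig_lengths, markers)

    if config.recluster:
        emb_by_id = {cid: vectors[i] for i, cid in enumerate(fm.contig_ids)}
        scaled_ab = {
            cid: fm.abundance[i] / fm.scales for i, cid in enumerate(fm.contig_ids)
        }
        reclustered: list[Bin] = []
        for b in bins:
            reclustered.extend(
                gr.recluster_bin(b, markers, emb_by_id, scaled_ab, contig_lengths)
            )
        bins = reclustered

    kept = gr.filter_small_bins(bins, config.min_bin_bp)
    kept.sort(key=lambda b: (-b.total_bp, b.contig_ids))
    assignment_of: dict[str, str] = {}
    final_bins: list[Bin] = []
    for i, b in enumerate(kept):
        name = f"bin_{i:03d}"
        final_bins.append(replace_bin_id(b, name))
        for cid in b.contig_ids:
            assignment_of[cid] = name
    assignments = [
        BinAssignment(cid, assignment_of.get(cid, BinAssignment.UNBINNED))
        for cid in fm.contig_ids
    ]
    return PipelineResult(
        assignments=assignments, bins=final_bins, embedder=embedder,
        min_contig_len=min_len, must_link_len=threshold, constraint_set=cs,
    )


def replace_bin_id(b: Bin, new_id: str) -> Bin:
    return Bin(bin_id=new_id, contig_ids=list(b.contig_ids),
               total_bp=b.total_bp, mean_scg_count=b.mean_scg_count)


def run_pipeline(
    contigs: list[Contig],
    coverage: list[CoverageRecord],
    taxonomy: list[TaxonomyAnnotation],
    markers: list[MarkerHit],
    config: PipelineConfig | None = None,
    embedder: mdl.TrainedEmbedder | None = None,
) -> PipelineResult:
    """Run the full binning pipeline.

    In ``single`` and ``coassembly`` modes all contigs form one binning task
    (abundance may still span several samples). In ``multi`` mode contigs
    carry sample ids and each sample is binned separately, with abundance
    information aggregated across all samples; bin ids are then prefixed
    with the sample id. Passing a pretrained ``embedder`` skips training.
    """
    config = config or PipelineConfig()
    if config.mode in ("single", "coassembly"):
        return _bin_one_sample(contigs, coverage, taxonomy, markers, config, embedder)

    samples = sorted({c.sample_id for c in contigs})
    if samples == [""]:
        raise ValueError("multi mode requires contigs labeled with sample ids")
    all_assignments: list[BinAssignment] = []
    all_bins: list[Bin] = []
    last = None
    for sid in samples:
        sample_contigs = [c for c in contigs if c.sample_id == sid]
        ids = {c.contig_id for c in sample_contigs}
        sub = _bin_one_sample(
            sample_contigs,
            [r for r in coverage if r.contig_id in ids],
            [a for a in taxonomy if a.contig_id in ids],
            [h for h in markers if h.contig_id in ids],
            config,
            embedder,
        )
        for a in sub.assignments:
            bid = a.bin_id if a.bin_id == BinAssignment.UNBINNED else f"{sid}/{a.bin_id}"
            all_assignments.append(BinAssignment(a.contig_id, bid))
        for b in sub.bins:
            all_bins.append(replace_bin_id(b, f"{sid}/{b.bin_id}"))
        last = sub
    assert last is not None
    return PipelineResult(
        assignments=all_assignments, bins=all_bins, embedder=embedder,
        min_contig_len=last.min_contig_len, must_link_len=last.must_link_len,
        constraint_set=None,
    )
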