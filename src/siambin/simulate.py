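"""Synthetic community generator with planted ground truth.

Emulates the complete input of a binning run without any downloads or
external tools: genome sequences with distinct tetranucleotide signatures
(each genome is an order-2 Markov chain over ACGT with its own
Dirichlet-perturbed transition matrix), contigs cut from those genomes,
per-sample coverage summaries from a log-normal abundance model with
Poisson-like per-base depth (plus overdispersion), noisy taxonomy
annotations, and a panel of single-copy marker genes placed one-per-genome.

What it deliberately does not model: read-level errors, assembly artefacts
(chimeras, repeats collapsed across genomes), or inter-sample chimerism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .types import Contig, CoverageRecord, MarkerHit, TaxonomyAnnotation


@dataclass
class CommunityConfig:
    """Shape of the planted community.

    Defaults describe a small but non-trivial community: 20 genomes of
    300 kb observed in 3 samples, contig lengths log-normal around ~20 kb,
    per-genome per-sample abundance log-normal around 20x depth with 10%
    contig-to-contig jitter, and a 5% taxonomy error rate.
    """

    n_genomes: int = 20
    genome_length_bp: int = 300_000
    n_samples: int = 3
    # contig length distribution: exp(N(log_mean, log_sd)) clipped to [min, max]
    contig_log_mean: float = float(np.log(20_000))
    contig_log_sd: float = 0.4
    contig_min_bp: int = 4_000
    contig_max_bp: int = 60_000
    # per-genome per-sample mean depth ~ LogNormal(log(20), 1.0)
    abundance_log_mean: float = float(np.log(20.0))
    abundance_log_sd: float = 1.0
    contig_depth_jitter_sd: float = 0.10   # lognormal sd of contig-level depth
    depth_overdispersion: float = 0.5      # variance = mean * (1 + this)
    taxonomy_error_rate: float = 0.05
    taxonomy_score_range: tuple[float, float] = (0.85, 1.0)
    genus_group_size: int = 2              # genomes per genus
    marker_panel_size: int = 10
    markov_dirichlet_alpha: float = 8.0    # lower = more distinct signatures
    # strain pairs: copies of existing genomes with ~1% substitutions and
    # correlated abundance, added on top of n_genomes (the "hard" preset)
    n_strain_pairs: int = 0
    strain_substitution_rate: float = 0.01
    strain_abundance_ratio_sd: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1 or self.genome_length_bp < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.taxonomy_error_rate <= 1.0:
            raise ValueError("taxonomy_error_rate outside [0, 1]")


def hard_preset(rng_seed: int = 0, **overrides) -> CommunityConfig:
    """Community with two 1%-divergent strain pairs to exercise reclustering."""
    return CommunityConfig(n_strain_pairs=2, rng_seed=rng_seed, **overrides)


@dataclass
class Community:
    """A generated community: all pipeline inputs plus the planted truth."""

    config: CommunityConfig
    contigs: list[Contig]
    coverage: list[CoverageRecord]
    taxonomy: list[TaxonomyAnnotation]
    markers: list[MarkerHit]
    truth: dict[str, str]                      # contig_id -> genome_id
    genome_bp: dict[str, int] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.contigs, out / "contigs.fa")
        io.write_coverage_table(self.coverage, out / "coverage.tsv")
        io.write_taxonomy(self.taxonomy, out / "taxonomy.tsv")
        io.write_markers(self.markers, out / "markers.tsv")
        io.write_truth(self.truth, out / "truth.tsv")
        return out


_BASES = np.array(list("ACGT"))


def _chain_python(cum: np.ndarray, u: np.ndarray, seq: np.ndarray) -> np.ndarray:
    for i in range(2, seq.size):
        state = seq[i - 2] * 4 + seq[i - 1]
        seq[i] = np.searchsorted(cum[state], u[i], side="right")
    return seq


try:  # numba shaves the sequential chain loop from seconds to milliseconds
    from numba import njit

    @njit(cache=False)
    def _chain_fast(cum, u, seq):  # pragma: no cover - exercised via wrapper
        for i in range(2, seq.size):
            state = seq[i - 2] * 4 + seq[i - 1]
            row = cum[state]
            x = u[i]
            j = 0
            while j < 3 and x >= row[j]:
                j += 1
            seq[i] = j
        return seq

    _chain = _chain_fast
except ImportError:  # pragma: no cover
    _chain = _chain_python


def generate_genomes(config: CommunityConfig, rng: np.random.Generator) -> dict[str, str]:
    """Sample each genome from its own order-2 Markov chain over ACGT.

    Transition rows are Dirichlet draws centered on uniform; the shared
    concentration controls how distinct genome signatures are. Strain-pair
    genomes are copies of base genomes with point substitutions.
    """
    genomes: dict[str, str] = {}
    for g in range(config.n_genomes):
        trans = rng.dirichlet(
            np.full(4, config.markov_dirichlet_alpha), size=16
        )  # rows indexed by the previous dinucleotide
        L = config.genome_length_bp
        seq = np.empty(L, dtype=np.int64)
        seq[0:2] = rng.integers(0, 4, size=2)
        u = rng.random(L)
        cum = np.cumsum(trans, axis=1)
        seq = _chain(cum, u, seq)
        genomes[f"genome_{g:03d}"] = "".join(_BASES[np.minimum(seq, 3)])

    for p in range(config.n_strain_pairs):
        parent_id = f"genome_{p % config.n_genomes:03d}"
        parent = np.array(list(genomes[parent_id]))
        n_sub = rng.binomial(parent.size, config.strain_substitution_rate)
        pos = rng.choice(parent.size, size=n_sub, replace=False)
        shift = rng.integers(1, 4, size=n_sub)
        base_idx = np.searchsorted(_BASES, parent[pos])
        parent[pos] = _BASES[(base_idx + shift) % 4]
        genomes[f"{parent_id}s"] = "".join(parent)
    return genomes


def fragment_and_cover(
    genomes: dict[str, str], config: CommunityConfig, rng: np.random.Generator
) -> tuple[list[Contig], list[CoverageRecord], dict[str, str]]:
    """Cut genomes into contigs and draw per-sample coverage summaries.

    Contig lengths are log-normal, clipped to the configured bounds (the
    final piece of a genome may be shorter). Per-sample contig depth is the
    genome abundance times a log-normal contig-level jitter; the depth
    variance follows the Poisson model (variance ~ mean) inflated by the
    configured overdispersion. Strain genomes (ids ending in "s") reuse
    their parent's abundance times a moderate log-normal ratio, so related
    strains co-occur with similar but not identical depth.
    """
    contigs: list[Contig] = []
    coverage: list[CoverageRecord] = []
    truth: dict[str, str] = {}

    abundance: dict[str, np.ndarray] = {}
    for gid in sorted(genomes):
        if gid.endswith("s") and gid[:-1] in genomes:
            ratio = rng.lognormal(0.0, config.strain_abundance_ratio_sd,
                                  size=config.n_samples)
            abundance[gid] = abundance[gid[:-1]] * ratio
        else:
            abundance[gid] = rng.lognormal(
                config.abundance_log_mean, config.abundance_log_sd,
                size=config.n_samples,
            )

    for gid in sorted(genomes):
        seq = genomes[gid]
        pos = 0
        idx = 0
        while pos < len(seq):
            length = int(np.clip(
                rng.lognormal(config.contig_log_mean, config.contig_log_sd),
                config.contig_min_bp, config.contig_max_bp,
            ))
            piece = seq[pos : pos + length]
            pos += length
            cid = f"{gid}_c{idx:03d}"
            idx += 1
            contigs.append(Contig(cid, piece))
            truth[cid] = gid
            jitter = rng.lognormal(0.0, config.contig_depth_jitter_sd,
                                   size=config.n_samples)
            means = abundance[gid] * jitter
            for s in range(config.n_samples):
                mean = float(means[s])
                var = mean * (1.0 + config.depth_overdispersion)
                coverage.append(CoverageRecord(cid, f"S{s}", mean, var))
    return contigs, coverage, truth


def annotate(
    truth: dict[str, str],
    contigs: list[Contig],
    config: CommunityConfig,
    rng: np.random.Generator,
) -> tuple[list[TaxonomyAnnotation], list[MarkerHit]]:
    """Emit noisy taxonomy and single-copy marker tables.

    Every genome gets a distinct species label; genera are shared by groups
    of ``genus_group_size`` genomes (strains share their parent's species).
    Each contig is annotated with its genome's labels and scores drawn
    uniformly from the configured range, except that with probability
    ``taxonomy_error_rate`` the species (and genus) labels are swapped for
    another genome's. Each genome carries each marker of the panel on
    exactly one of its contigs of at least 2500 bp.
    """
    genome_ids = sorted({g for g in truth.values()})

    def base_genome(gid: str) -> str:
        return gid[:-1] if gid.endswith("s") and gid[:-1] in genome_ids else gid

    bases = sorted({base_genome(g) for g in genome_ids})
    species = {g: f"sp_{base_genome(g)}" for g in genome_ids}
    genus = {
        g: f"gen_{bases.index(base_genome(g)) // config.genus_group_size:03d}"
        for g in genome_ids
    }

    lo, hi = config.taxonomy_score_range
    annotations: list[TaxonomyAnnotation] = []
    for c in sorted(contigs, key=lambda c: c.contig_id):
        gid = truth[c.contig_id]
        label_gid = gid
        if len(genome_ids) > 1 and rng.random() < config.taxonomy_error_rate:
            others = [g for g in genome_ids if g != gid]
            label_gid = others[rng.integers(len(others))]
        annotations.append(TaxonomyAnnotation(
            contig_id=c.contig_id,
            species_label=species[label_gid],
            species_score=float(rng.uniform(lo, hi)),
            genus_label=genus[label_gid],
            genus_score=float(rng.uniform(lo, hi)),
        ))

    by_genome: dict[str, list[str]] = {g: [] for g in genome_ids}
    for c in contigs:
        if c.length >= 2500:
            by_genome[truth[c.contig_id]].append(c.contig_id)
    markers: list[MarkerHit] = []
    for gid in genome_ids:
        hosts = sorted(by_genome[gid])
        if not hosts:
            continue
        for m in range(config.marker_panel_size):
            host = hosts[rng.integers(len(hosts))]
            markers.append(MarkerHit(host, f"scg_{m:03d}"))
    return annotations, markers


def generate_community(config: CommunityConfig | None = None) -> Community:
    """Generate a full community deterministically from ``config.rng_seed``."""
    config = config or CommunityConfig()
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 3]))
    genomes = generate_genomes(config, rng)
    contigs, coverage, truth = fragment_and_cover(genomes, config, rng)
    taxonomy, markers = annotate(truth, contigs, config, rng)
    genome_bp = {g: len(seq) for g, seq in genomes.items()}
    return Community(
        config=config, contigs=contigs, coverage=coverage,
        taxonomy=taxonomy, markers=markers, truth=truth, genome_bp=genome_bp,
    )
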