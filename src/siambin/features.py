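"""Contig features: canonical k-mer frequencies, abundance scaling, and the
length-filter heuristics.

Every contig is represented by its canonical tetranucleotide relative
frequencies (136 dimensions, reverse-complement pairs collapsed) and, when
five or more samples are available, by per-sample abundances rescaled to the
same order of magnitude as the frequencies. With fewer than five samples the
model input is the k-mer vector alone and abundance enters later through the
coverage-divergence term of the contig similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .types import Contig, CoverageRecord

PSEUDOCOUNT = 1e-5
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Number of samples at or above which abundances join the model input.
ABUNDANCE_REGIME_MIN_SAMPLES = 5


def reverse_complement(kmer: str) -> str:
    return kmer.translate(_COMPLEMENT)[::-1]


def canonical_kmer_index(k: int) -> dict[str, int]:
    """Map each canonical k-mer (lexicographic min of the pair
    {kmer, reverse complement}) to a column index.

    Indices are assigned in lexicographic order of the canonical form. For
    k=4 the map has 136 entries; in general (4^k + 4^(k/2)) / 2 for even k
    and 4^k / 2 for odd k (odd-length k-mers are never self-complementary).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    canon = sorted(
        {min(km, reverse_complement(km))
         for km in ("".join(p) for p in product("ACGT", repeat=k))}
    )
    return {km: i for i, km in enumerate(canon)}


_INDEX_CACHE: dict[int, dict[str, int]] = {}


def _index(k: int) -> dict[str, int]:
    if k not in _INDEX_CACHE:
        _INDEX_CACHE[k] = canonical_kmer_index(k)
    return _INDEX_CACHE[k]


def kmer_frequencies(sequence: str, k: int = 4) -> np.ndarray:
    """Canonical k-mer relative frequencies of one contig.

    Counts every overlapping window on the given strand (canonicalization
    makes the choice of strand irrelevant), skips windows containing N, adds
    a small pseudo-count to every canonical k-mer, and normalizes so the
    vector sums to one. All entries are therefore strictly positive.
    """
    index = _index(k)
    counts = np.zeros(len(index), dtype=np.float64)
    seq = sequence.upper()
    n_valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        col = index.get(window)
        if col is None:
            col = index.get(reverse_complement(window))
        if col is None:  # window contains N (or other ambiguity)
            continue
        counts[col] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError("sequence too short for k-mer features")
    counts += PSEUDOCOUNT
    return counts / counts.sum()


def scale_constant(mean_abundance: float) -> float:
    """Abundance scale s = 100 * ceil(mean / 100), with s >= 100 always.

    A zero mean (e.g. a sample with no mapped reads) maps to s = 100 so that
    the downstream division is well defined.
    """
    if mean_abundance < 0:
        raise ValueError(f"negative mean abundance {mean_abundance}")
    return 100.0 * max(1, math.ceil(mean_abundance / 100.0))


def assemble_z(
    kmer_freq: np.ndarray,
    abundances: np.ndarray,
    per_sample_scales: np.ndarray,
    n_samples: int,
) -> np.ndarray:
    """Assemble the model input vector.

    With ``n_samples >= 5`` the vector is the k-mer frequencies followed by
    the per-sample abundances divided by their sample scales; with fewer
    samples the abundances are left out (they enter through the similarity's
    coverage term instead).
    """
    abundances = np.asarray(abundances, dtype=np.float64)
    scales = np.asarray(per_sample_scales, dtype=np.float64)
    if abundances.shape != (n_samples,) or scales.shape != (n_samples,):
        raise ValueError(
            f"expected {n_samples} abundances/scales, got "
            f"{abundances.shape}/{scales.shape}"
        )
    if np.any(scales <= 0):
        raise ValueError("abundance scales must be positive")
    if n_samples >= ABUNDANCE_REGIME_MIN_SAMPLES:
        return np.concatenate([np.asarray(kmer_freq, float), abundances / scales])
    return np.asarray(kmer_freq, dtype=np.float64).copy()


def select_min_length(contig_lengths, short_fraction: float = 0.05) -> int:
    """Choose the minimum contig length for binning (1000 or 2500 bp).

    If contigs of 1000-2500 bp hold less than ``short_fraction`` of the total
    basepairs (over contigs of at least 1000 bp), they are cheap to include
    and the threshold drops to 1000; otherwise it stays at 2500.
    """
    lengths = [int(x) for x in contig_lengths]
    if not lengths:
        raise ValueError("empty length list")
    eligible = [x for x in lengths if x >= 1000]
    total = sum(eligible)
    if total == 0:
        return 2500
    short = sum(x for x in eligible if x < 2500)
    return 1000 if short < short_fraction * total else 2500


def must_link_threshold(contig_lengths, bp_fraction: float = 0.98) -> int:
    """Smallest contig length worth splitting for must-link pairs.

    Scans the distinct observed lengths from the largest downward and keeps
    the largest threshold L such that contigs of length >= L still hold at
    least ``bp_fraction`` of the total basepairs; the result is floored at
    4000 bp so both fragments stay long enough to carry stable k-mer and
    coverage signals.
    """
    lengths = np.asarray(sorted(contig_lengths), dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("empty length list")
    total = lengths.sum()
    best = int(lengths[0])
    # suffix_bp[i] = total bp in contigs with length >= lengths[i]
    suffix = total - np.concatenate([[0], np.cumsum(lengths)[:-1]])
    for length, bp_at_or_above in zip(lengths, suffix):
        if bp_at_or_above >= bp_fraction * total:
            best = int(length)
        else:
            break
    return max(4000, best)


@dataclass
class FeatureMatrix:
    """Profiles for a set of contigs in one binning task.

    ``kmer`` rows align with ``contig_ids``; ``abundance`` and ``variance``
    are (n_contigs, n_samples) with samples ordered by ``sample_ids``;
    ``z`` is the assembled model input (regime decided by n_samples).
    """

    contig_ids: list[str]
    sample_ids: list[str]
    kmer: np.ndarray
    abundance: np.ndarray
    variance: np.ndarray
    scales: np.ndarray
    z: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.contig_ids)
        ns = len(self.sample_ids)
        if self.kmer.shape[0] != n or self.abundance.shape != (n, ns):
            raise ValueError("feature matrix shape mismatch")
        if ns >= ABUNDANCE_REGIME_MIN_SAMPLES:
            self.z = np.hstack([self.kmer, self.abundance / self.scales])
        else:
            self.z = self.kmer.copy()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def feature_dim(self) -> int:
        return self.z.shape[1]

    @property
    def regime(self) -> str:
        if self.n_samples >= ABUNDANCE_REGIME_MIN_SAMPLES:
            return f"kmer_plus_abundance({self.n_samples})"
        return "kmer_only"

    def index_of(self, contig_id: str) -> int:
        try:
            return self.contig_ids.index(contig_id)
        except ValueError:
            raise KeyError(f"no profile for contig {contig_id!r}") from None

    def subset(self, contig_ids: list[str]) -> "FeatureMatrix":
        rows = [self.index_of(c) for c in contig_ids]
        return FeatureMatrix(
            contig_ids=list(contig_ids),
            sample_ids=list(self.sample_ids),
            kmer=self.kmer[rows],
            abundance=self.abundance[rows],
            variance=self.variance[rows],
            scales=self.scales,
        )


def build_feature_matrix(
    contigs: list[Contig],
    coverage: list[CoverageRecord],
    sample_ids: list[str] | None = None,
    k: int = 4,
    scales: np.ndarray | None = None,
) -> FeatureMatrix:
    """Assemble per-contig profiles from sequences and coverage summaries.

    Every contig must have exactly one coverage record per sample. Per-sample
    abundance scales default to ``scale_constant`` of the mean abundance over
    the supplied contigs; precomputed scales may be passed instead (used when
    fragments must inherit the scales of the full catalogue).
    """
    if sample_ids is None:
        sample_ids = sorted({r.sample_id for r in coverage})
    if not sample_ids:
        raise ValueError("no samples in coverage table")
    cov = {(r.contig_id, r.sample_id): r for r in coverage}

    ids = [c.contig_id for c in contigs]
    kmer = np.vstack([kmer_frequencies(c.sequence, k=k) for c in contigs])
    n, ns = len(ids), len(sample_ids)
    abundance = np.zeros((n, ns))
    variance = np.zeros((n, ns))
    for i, cid in enumerate(ids):
        for j, sid in enumerate(sample_ids):
            rec = cov.get((cid, sid))
            if rec is None:
                raise ValueError(f"missing coverage for contig {cid!r} in sample {sid!r}")
            abundance[i, j] = rec.mean_depth
            variance[i, j] = rec.depth_variance
    if scales is None:
        scales = np.array([scale_constant(abundance[:, j].mean()) for j in range(ns)])
    return FeatureMatrix(
        contig_ids=ids,
        sample_ids=list(sample_ids),
        kmer=kmer,
        abundance=abundance,
        variance=variance,
        scales=np.asarray(scales, dtype=np.float64),
    )
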