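"""Must-link and cannot-link constraint generation.

Must-link pairs are manufactured by splitting long contigs into two halves:
the two fragments demonstrably belong to the same genome. Cannot-link pairs
come from two sources: contig pairs whose confident taxonomic annotations
disagree (species calls both scored > 0.95, or genus calls both > 0.80), and
seed contigs that carry the same single-copy marker gene and therefore
represent different genomes. The pooled cannot-link set is capped (default
four million) by uniform subsampling to bound training cost.
"""

from __future__ import annotations

from collections import defaultdict
from itertools import combinations

import numpy as np

from .types import Contig, ConstraintSet, MarkerHit, TaxonomyAnnotation

DEFAULT_MAX_CANNOT_LINK = 4_000_000

SPECIES_SCORE_MIN = 0.95
GENUS_SCORE_MIN = 0.80

FRAGMENT_SUFFIXES = ("_1", "_2")


def fragment_ids(contig_id: str) -> tuple[str, str]:
    return tuple(contig_id + s for s in FRAGMENT_SUFFIXES)  # type: ignore[return-value]


def split_for_must_link(
    contigs: list[Contig], threshold: int
) -> tuple[list[Contig], list[tuple[str, str]]]:
    """Split every contig of length >= ``threshold`` into two half fragments.

    The first fragment takes the first ceil(L/2) bases, the second the
    remaining floor(L/2); ids are ``<id>_1`` and ``<id>_2`` and the pair
    becomes a must-link constraint. Fragments exist only for training; the
    original contig remains the unit of binning.
    """
    if threshold < 8:
        raise ValueError(
            f"threshold {threshold} too small: fragments must support 4-mers"
        )
    fragments: list[Contig] = []
    pairs: list[tuple[str, str]] = []
    for c in contigs:
        if c.length < threshold:
            continue
        half = (c.length + 1) // 2
        id1, id2 = fragment_ids(c.contig_id)
        fragments.append(Contig(id1, c.sequence[:half], c.sample_id))
        fragments.append(Contig(id2, c.sequence[half:], c.sample_id))
        pairs.append((id1, id2))
    return contigs + fragments, pairs


def cannot_link_from_taxonomy(
    annotations: list[TaxonomyAnnotation],
    eligible_contig_ids: set[str],
) -> list[tuple[str, str, str]]:
    """Cannot-link pairs from disagreeing confident taxonomy calls.

    A pair is emitted when both species scores exceed 0.95 and the species
    labels differ, or both genus scores exceed 0.80 and the genus labels
    differ. Returns (id1, id2, source) triples with id1 < id2.
    """
    ann = [a for a in annotations if a.contig_id in eligible_contig_ids]
    out: dict[tuple[str, str], str] = {}
    for a1, a2 in combinations(ann, 2):
        if a1.contig_id == a2.contig_id:
            continue
        key = ConstraintSet.key(a1.contig_id, a2.contig_id)
        if (
            a1.species_label is not None and a2.species_label is not None
            and a1.species_score is not None and a2.species_score is not None
            and a1.species_score > SPECIES_SCORE_MIN
            and a2.species_score > SPECIES_SCORE_MIN
            and a1.species_label != a2.species_label
        ):
            out.setdefault(key, "taxonomy_species")
        elif (
            a1.genus_label is not None and a2.genus_label is not None
            and a1.genus_score is not None and a2.genus_score is not None
            and a1.genus_score > GENUS_SCORE_MIN
            and a2.genus_score > GENUS_SCORE_MIN
            and a1.genus_label != a2.genus_label
        ):
            out.setdefault(key, "taxonomy_genus")
    return sorted((k[0], k[1], v) for k, v in out.items())


def scg_seed_cannot_link(
    marker_hits: list[MarkerHit],
    eligible_contig_ids: set[str],
) -> list[tuple[str, str, str]]:
    """Cannot-link pairs between single-copy-marker seed contigs.

    Seeds are the contigs carrying the marker family observed on the largest
    number of distinct eligible contigs (ties broken lexicographically by
    marker id): each carrier of a single-copy gene should come from a
    different genome, so all seed pairs are cannot-links.
    """
    carriers: dict[str, set[str]] = defaultdict(set)
    for hit in marker_hits:
        if hit.contig_id in eligible_contig_ids:
            carriers[hit.marker_id].add(hit.contig_id)
    if not carriers:
        return []
    best_marker = min(carriers, key=lambda m: (-len(carriers[m]), m))
    seeds = sorted(carriers[best_marker])
    return [(a, b, "scg_seed") for a, b in combinations(seeds, 2)]


def subsample_cannot_link(
    pairs: list[tuple[str, str, str]],
    max_cannot: int = DEFAULT_MAX_CANNOT_LINK,
    rng_seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Uniformly subsample the pooled cannot-link set down to ``max_cannot``."""
    if max_cannot <= 0:
        raise ValueError(f"max_cannot must be positive, got {max_cannot}")
    if len(pairs) <= max_cannot:
        return list(pairs)
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 2]))
    keep = rng.choice(len(pairs), size=max_cannot, replace=False)
    return [pairs[i] for i in sorted(keep)]


def build_constraints(
    contigs: list[Contig],
    threshold: int,
    annotations: list[TaxonomyAnnotation],
    marker_hits: list[MarkerHit],
    max_cannot: int = DEFAULT_MAX_CANNOT_LINK,
    rng_seed: int = 0,
) -> tuple[list[Contig], ConstraintSet]:
    """Full constraint generation for one training set.

    Returns the augmented contig list (originals plus fragments) and the
    constraint set. Cannot-link pairs are generated between original contigs
    (fragments carry their parent's annotation, so fragment pairs would only
    duplicate parent pairs); taxonomy and seed pairs are pooled before the
    subsampling cap is applied.
    """
    augmented, ml_pairs = split_for_must_link(contigs, threshold)
    eligible = {c.contig_id for c in contigs}
    cl = cannot_link_from_taxonomy(annotations, eligible)
    cl += scg_seed_cannot_link(marker_hits, eligible)
    # pooled cap over both cannot-link sources
    dedup: dict[tuple[str, str], str] = {}
    for a, b, src in cl:
        dedup.setdefault((a, b), src)
    pooled = sorted((a, b, src) for (a, b), src in dedup.items())
    pooled = subsample_cannot_link(pooled, max_cannot, rng_seed)

    cs = ConstraintSet()
    for a, b in ml_pairs:
        cs.add_must_link(a, b, "split")
    for a, b, src in pooled:
        cs.add_cannot_link(a, b, src)
    cs.validate()
    return augmented, cs


def write_constraints(cs: ConstraintSet, path) -> None:
    """Dump a constraint set as a TSV (contig_1, contig_2, link, source)."""
    with open(path, "w") as fh:
        fh.write("contig_1\tcontig_2\tlink\tsource\n")
        for kind, pairs in (("must", cs.must_link), ("cannot", cs.cannot_link)):
            for a, b in sorted(pairs):
                fh.write(f"{a}\t{b}\t{kind}\t{cs.provenance[(a, b)]}\n")
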