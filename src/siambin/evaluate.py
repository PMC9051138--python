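"""Scoring of binning results against a planted ground truth.

Basepair-weighted semantics: each bin is mapped to the genome contributing
the most basepairs to it; completeness (recall) is the mapped genome's
basepairs recovered in the bin divided by the genome size, purity
(precision) is the mapped genome's basepairs divided by the bin size, and
contamination is 1 - purity. Unbinned contigs never penalize purity.

Quality tiers follow the usual MAG conventions: high means completeness
> 90% with contamination < 5%; medium means completeness >= 50% with
contamination < 10% (and not high); low means completeness < 50% with
contamination < 10%; anything else is unranked.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .types import BinAssignment

TIERS = ("high", "medium", "low", "none")
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}


@dataclass
class BinScore:
    bin_id: str
    mapped_genome: str
    completeness: float
    purity: float
    f1: float
    tier: str


def _tier(completeness: float, contamination: float) -> str:
    if completeness > 0.90 and contamination < 0.05:
        return "high"
    if contamination < 0.10:
        return "medium" if completeness >= 0.50 else "low"
    return "none"


def score_bins(
    assignments: list[BinAssignment],
    ground_truth: dict[str, str],
    contig_lengths: dict[str, int],
    genome_bp: dict[str, int] | None = None,
) -> list[BinScore]:
    """Score each bin against the planted genome assignment.

    ``genome_bp`` defaults to the total contig basepairs per genome in the
    truth table. Every binned contig must appear in both the truth and the
    length table.
    """
    if genome_bp is None:
        genome_bp = defaultdict(int)
        for cid, gid in ground_truth.items():
            if cid not in contig_lengths:
                raise ValueError(f"no length for contig {cid!r}")
            genome_bp[gid] += contig_lengths[cid]

    bins: dict[str, list[str]] = defaultdict(list)
    for a in assignments:
        if a.bin_id == BinAssignment.UNBINNED:
            continue
        if a.contig_id not in ground_truth:
            raise ValueError(f"contig {a.contig_id!r} missing from ground truth")
        if a.contig_id not in contig_lengths:
            raise ValueError(f"contig {a.contig_id!r} missing from length table")
        bins[a.bin_id].append(a.contig_id)

    scores: list[BinScore] = []
    for bin_id in sorted(bins):
        members = bins[bin_id]
        bin_bp = sum(contig_lengths[c] for c in members)
        overlap: dict[str, int] = defaultdict(int)
        for c in members:
            overlap[ground_truth[c]] += contig_lengths[c]
        # plurality genome by basepair overlap; lexicographic tie-break
        mapped = min(overlap, key=lambda g: (-overlap[g], g))
        completeness = overlap[mapped] / genome_bp[mapped]
        purity = overlap[mapped] / bin_bp
        f1 = (
            0.0 if completeness + purity == 0
            else 2 * completeness * purity / (completeness + purity)
        )
        scores.append(BinScore(
            bin_id=bin_id, mapped_genome=mapped,
            completeness=completeness, purity=purity, f1=f1,
            tier=_tier(completeness, 1.0 - purity),
        ))
    return scores


def count_distinct_recovered(scores: list[BinScore], tier: str = "high") -> int:
    """Distinct genomes with at least one bin at the requested tier or better."""
    if tier not in _TIER_RANK or tier == "none":
        raise ValueError(f"unknown tier {tier!r}")
    cutoff = _TIER_RANK[tier]
    return len({
        s.mapped_genome for s in scores if _TIER_RANK[s.tier] <= cutoff
    })


def tier_counts(scores: list[BinScore]) -> dict[str, int]:
    out = {t: 0 for t in TIERS}
    for s in scores:
        out[s.tier] += 1
    return out


def write_report(scores: list[BinScore], path) -> None:
    with open(path, "w") as fh:
        fh.write("bin_id\tmapped_genome\tcompleteness\tpurity\tf1\ttier\n")
        for s in scores:
            fh.write(
                f"{s.bin_id}\t{s.mapped_genome}\t{s.completeness:.4f}\t"
                f"{s.purity:.4f}\t{s.f1:.4f}\t{s.tier}\n"
            )
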