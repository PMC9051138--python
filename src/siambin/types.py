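"""Core domain records shared across the pipeline.

All coordinates, where exposed, are 0-based half-open. Contig identifiers are
plain strings; in multi-sample mode a catalogue id has the form
``"<sample_id><sep><name>"`` and is split on the first separator.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Contig:
    """An assembled contig.

    ``sample_id`` is empty in single-sample and co-assembly modes; in
    multi-sample mode it names the sample the contig was assembled from.
    """

    contig_id: str
    sequence: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.contig_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: non-ACGTN characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CoverageRecord:
    """Per-contig, per-sample read-depth summary.

    ``mean_depth`` is the average number of reads covering each base of the
    contig in one sample; ``depth_variance`` is the population variance of the
    per-base depth. Together they parameterize the normal approximation used
    for the abundance similarity term.
    """

    contig_id: str
    sample_id: str
    mean_depth: float
    depth_variance: float

    def __post_init__(self) -> None:
        if self.mean_depth < 0:
            raise ValueError(
                f"coverage for {self.contig_id!r}/{self.sample_id!r}: "
                f"negative mean depth {self.mean_depth}"
            )
        if self.depth_variance < 0:
            raise ValueError(
                f"coverage for {self.contig_id!r}/{self.sample_id!r}: "
                f"negative depth variance {self.depth_variance}"
            )


@dataclass(frozen=True)
class TaxonomyAnnotation:
    """Taxonomic assignment of a contig with per-rank confidence scores.

    Fields are ``None`` when the annotator made no call at that rank. A
    species call implies a genus call.
    """

    contig_id: str
    species_label: str | None = None
    species_score: float | None = None
    genus_label: str | None = None
    genus_score: float | None = None

    def __post_init__(self) -> None:
        for name, score in (
            ("species_score", self.species_score),
            ("genus_score", self.genus_score),
        ):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"annotation for {self.contig_id!r}: {name}={score} "
                    "outside [0, 1]"
                )
        if self.species_label is not None and self.genus_label is None:
            raise ValueError(
                f"annotation for {self.contig_id!r}: species call without genus"
            )


@dataclass(frozen=True)
class MarkerHit:
    """A single-copy marker gene family found on a contig."""

    contig_id: str
    marker_id: str


@dataclass(frozen=True)
class BinAssignment:
    """Final placement of one contig; ``bin_id`` is ``"unbinned"`` for leftovers."""

    contig_id: str
    bin_id: str

    UNBINNED = "unbinned"


@dataclass
class Bin:
    """A set of contigs proposed to originate from one genome."""

    bin_id: str
    contig_ids: list[str]
    total_bp: int
    mean_scg_count: float = 0.0


@dataclass
class ConstraintSet:
    """Must-link / cannot-link contig-id pairs with per-pair provenance.

    Pairs are stored as sorted tuples so that (a, b) and (b, a) coincide.
    Provenance values: ``split``, ``taxonomy_species``, ``taxonomy_genus``,
    ``scg_seed``.
    """

    must_link: set[tuple[str, str]] = field(default_factory=set)
    cannot_link: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    @staticmethod
    def key(a: str, b: str) -> tuple[str, str]:
        if a == b:
            raise ValueError(f"self-pair for contig {a!r}")
        return (a, b) if a < b else (b, a)

    def add_must_link(self, a: str, b: str, source: str = "split") -> None:
        k = self.key(a, b)
        if k in self.cannot_link:
            raise ValueError(f"pair {k} is both must-link and cannot-link")
        self.must_link.add(k)
        self.provenance[k] = source

    def add_cannot_link(self, a: str, b: str, source: str) -> None:
        k = self.key(a, b)
        if k in self.must_link:
            raise ValueError(f"pair {k} is both must-link and cannot-link")
        if k not in self.cannot_link:
            self.cannot_link.add(k)
            self.provenance[k] = source

    def validate(self) -> None:
        overlap = self.must_link & self.cannot_link
        if overlap:
            raise ValueError(f"{len(overlap)} pairs are in both constraint sets")
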