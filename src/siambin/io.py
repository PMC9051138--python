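"""Readers and writers for every on-disk format the binner touches.

Everything external tools would normally produce (read mappers, taxonomic
annotators, marker-gene callers) enters through small documented TSV
contracts, so the pipeline runs with no binaries beyond Python:

* coverage TSV: ``contig_id  sample_id  mean_depth  depth_variance``
* taxonomy TSV: ``contig_id  species_label  species_score  genus_label  genus_score``
  (empty fields encode missing calls)
* marker TSV:   ``contig_id  marker_id``
* assignment TSV: ``contig_id  bin_id``

All readers validate rows eagerly and report line numbers on failure.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    BinAssignment,
    Contig,
    CoverageRecord,
    MarkerHit,
    TaxonomyAnnotation,
)

COVERAGE_HEADER = ["contig_id", "sample_id", "mean_depth", "depth_variance"]
TAXONOMY_HEADER = [
    "contig_id",
    "species_label",
    "species_score",
    "genus_label",
    "genus_score",
]
MARKER_HEADER = ["contig_id", "marker_id"]
ASSIGNMENT_HEADER = ["contig_id", "bin_id"]
TRUTH_HEADER = ["contig_id", "genome_id"]

DEFAULT_SAMPLE_SEP = ":"


# ---------------------------------------------------------------------------
# FASTA


def join_catalog_id(sample_id: str, name: str, sep: str = DEFAULT_SAMPLE_SEP) -> str:
    """Build a multi-sample catalogue id ``"<sample><sep><name>"``."""
    if sep in sample_id:
        raise ValueError(f"sample_id {sample_id!r} contains the separator {sep!r}")
    return f"{sample_id}{sep}{name}"


def split_catalog_id(catalog_id: str, sep: str = DEFAULT_SAMPLE_SEP) -> tuple[str, str]:
    """Invert :func:`join_catalog_id` by splitting on the first separator."""
    if sep not in catalog_id:
        raise ValueError(
            f"contig id {catalog_id!r} lacks the sample separator {sep!r}"
        )
    sample_id, name = catalog_id.split(sep, 1)
    return sample_id, name


def read_fasta(
    path: str | os.PathLike,
    multi_sample: bool = False,
    sep: str = DEFAULT_SAMPLE_SEP,
) -> list[Contig]:
    """Read contigs from FASTA; headers are truncated at the first whitespace.

    With ``multi_sample=True``, ids of the form ``"<sample><sep><name>"`` are
    split into (sample_id, contig_id).
    """
    contigs: list[Contig] = []
    seen: set[tuple[str, str]] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: contig {record.id!r} has an empty sequence")
        if multi_sample:
            sample_id, name = split_catalog_id(record.id, sep)
        else:
            sample_id, name = "", record.id
        key = (sample_id, name)
        if key in seen:
            raise ValueError(f"{path}: duplicate contig id {record.id!r}")
        seen.add(key)
        contigs.append(Contig(contig_id=name, sequence=seq, sample_id=sample_id))
    return contigs


def write_fasta(
    contigs: Iterable[Contig],
    path: str | os.PathLike,
    multi_sample: bool = False,
    sep: str = DEFAULT_SAMPLE_SEP,
) -> None:
    records = []
    for c in contigs:
        cid = join_catalog_id(c.sample_id, c.contig_id, sep) if multi_sample else c.contig_id
        records.append(SeqRecord(Seq(c.sequence), id=cid, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# TSV plumbing


def _read_tsv(path: str | os.PathLike, header: Sequence[str]):
    """Yield (line_number, fields) for each data row, validating the header."""
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.split("\t") != list(header):
            raise ValueError(
                f"{path}:1: expected header {list(header)}, got {first.split(chr(9))}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(fields)}"
                )
            yield lineno, fields


def _write_tsv(path: str | os.PathLike, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def _parse_float(value: str, path, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed {what} {value!r}") from None


# ---------------------------------------------------------------------------
# Coverage


def read_coverage_table(path: str | os.PathLike) -> list[CoverageRecord]:
    records: list[CoverageRecord] = []
    seen: set[tuple[str, str]] = set()
    for lineno, f in _read_tsv(path, COVERAGE_HEADER):
        mean = _parse_float(f[2], path, lineno, "mean_depth")
        var = _parse_float(f[3], path, lineno, "depth_variance")
        key = (f[0], f[1])
        if key in seen:
            raise ValueError(f"{path}:{lineno}: duplicate coverage row for {key}")
        seen.add(key)
        try:
            records.append(CoverageRecord(f[0], f[1], mean, var))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return records


def write_coverage_table(records: Iterable[CoverageRecord], path: str | os.PathLike) -> None:
    _write_tsv(
        path,
        COVERAGE_HEADER,
        (
            (r.contig_id, r.sample_id, repr(r.mean_depth), repr(r.depth_variance))
            for r in records
        ),
    )


def depth_array_to_record(
    contig_id: str, sample_id: str, per_base_depths
) -> CoverageRecord:
    """Summarize a per-base depth array into (mean, population variance)."""
    depths = np.asarray(per_base_depths, dtype=float)
    if depths.size == 0:
        raise ValueError(f"contig {contig_id!r}: empty depth array")
    if np.any(depths < 0):
        raise ValueError(f"contig {contig_id!r}: negative per-base depth")
    return CoverageRecord(
        contig_id=contig_id,
        sample_id=sample_id,
        mean_depth=float(depths.mean()),
        depth_variance=float(depths.var()),  # population variance (ddof=0)
    )


# ---------------------------------------------------------------------------
# Taxonomy and markers


def read_taxonomy(path: str | os.PathLike) -> list[TaxonomyAnnotation]:
    out: list[TaxonomyAnnotation] = []
    for lineno, f in _read_tsv(path, TAXONOMY_HEADER):
        def opt_label(s: str) -> str | None:
            return s if s else None

        def opt_score(s: str) -> float | None:
            return _parse_float(s, path, lineno, "score") if s else None

        try:
            out.append(
                TaxonomyAnnotation(
                    contig_id=f[0],
                    species_label=opt_label(f[1]),
                    species_score=opt_score(f[2]),
                    genus_label=opt_label(f[3]),
                    genus_score=opt_score(f[4]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_taxonomy(annotations: Iterable[TaxonomyAnnotation], path: str | os.PathLike) -> None:
    def fmt(x) -> str:
        return "" if x is None else (repr(x) if isinstance(x, float) else str(x))

    _write_tsv(
        path,
        TAXONOMY_HEADER,
        (
            (a.contig_id, fmt(a.species_label), fmt(a.species_score),
             fmt(a.genus_label), fmt(a.genus_score))
            for a in annotations
        ),
    )


def read_markers(path: str | os.PathLike) -> list[MarkerHit]:
    return [MarkerHit(f[0], f[1]) for _, f in _read_tsv(path, MARKER_HEADER)]


def write_markers(hits: Iterable[MarkerHit], path: str | os.PathLike) -> None:
    _write_tsv(path, MARKER_HEADER, ((h.contig_id, h.marker_id) for h in hits))


# ---------------------------------------------------------------------------
# Ground truth (synthetic communities)


def read_truth(path: str | os.PathLike) -> dict[str, str]:
    return {f[0]: f[1] for _, f in _read_tsv(path, TRUTH_HEADER)}


def write_truth(truth: dict[str, str], path: str | os.PathLike) -> None:
    _write_tsv(path, TRUTH_HEADER, sorted(truth.items()))


# ---------------------------------------------------------------------------
# Bin output


def read_assignments(path: str | os.PathLike) -> list[BinAssignment]:
    return [BinAssignment(f[0], f[1]) for _, f in _read_tsv(path, ASSIGNMENT_HEADER)]


def write_assignments(assignments: Iterable[BinAssignment], path: str | os.PathLike) -> None:
    _write_tsv(path, ASSIGNMENT_HEADER, ((a.contig_id, a.bin_id) for a in assignments))


def write_bins(
    assignments: Sequence[BinAssignment],
    contigs: Sequence[Contig],
    out_dir: str | os.PathLike,
    overwrite: bool = False,
) -> Path:
    """Write one FASTA per bin plus a contig->bin assignment TSV.

    Bins are named ``bin_<index>`` with the index zero-padded and ordered by
    descending total basepairs (ties by member ids), so output naming is
    deterministic. Returns the path of the assignment TSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {c.contig_id: c for c in contigs}

    groups: dict[str, list[str]] = {}
    for a in assignments:
        if a.contig_id not in by_id:
            raise ValueError(f"assignment references unknown contig {a.contig_id!r}")
        if a.bin_id != BinAssignment.UNBINNED:
            groups.setdefault(a.bin_id, []).append(a.contig_id)

    ordered = sorted(
        groups.items(),
        key=lambda kv: (-sum(by_id[cid].length for cid in kv[1]), sorted(kv[1])),
    )
    rename = {old: f"bin_{i:03d}" for i, (old, _members) in enumerate(ordered)}

    tsv_path = out_dir / "bins.tsv"
    if tsv_path.exists() and not overwrite:
        raise FileExistsError(f"{tsv_path} exists (pass overwrite=True to replace)")

    for old, members in ordered:
        fa_path = out_dir / f"{rename[old]}.fa"
        if fa_path.exists() and not overwrite:
            raise FileExistsError(f"{fa_path} exists (pass overwrite=True to replace)")
        write_fasta([by_id[cid] for cid in sorted(members)], fa_path)

    rows = sorted(
        (a.contig_id, rename.get(a.bin_id, BinAssignment.UNBINNED))
        for a in assignments
    )
    _write_tsv(tsv_path, ASSIGNMENT_HEADER, rows)
    return tsv_path
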