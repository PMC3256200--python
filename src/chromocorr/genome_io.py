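"""Genomic interval containers and FASTA/BED input/output.

All coordinates are 0-based half-open (BED convention) throughout the
package; conversion to Mb happens only at display time. Sequence characters
outside the unambiguous alphabet ``ACGT`` are treated as unassayed and end
up in the mask; lowercase (soft-masked) bases count as assayed sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomeInterval",
    "IntervalSet",
    "MaskSet",
    "FeatureSet",
    "FormatError",
    "read_fasta",
    "build_mask",
    "read_bed",
    "write_bed",
]

_ACGT = frozenset("ACGT")


class FormatError(ValueError):
    """Raised for malformed FASTA/BED input."""


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A half-open span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomeInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def _canonical(chrom: str, intervals: Iterable[GenomeInterval], chrom_length: int,
               what: str) -> tuple[GenomeInterval, ...]:
    ivs = tuple(sorted(intervals, key=lambda iv: (iv.start, iv.end)))
    for iv in ivs:
        if iv.chrom != chrom:
            raise ValueError(f"{what} interval on {iv.chrom!r}, expected {chrom!r}")
        if iv.end > chrom_length:
            raise ValueError(
                f"{what} interval {iv.start}-{iv.end} exceeds chrom_length {chrom_length}"
            )
    for a, b in itertools.pairwise(ivs):
        if b.start < a.end:
            raise ValueError(
                f"overlapping {what} intervals {a.start}-{a.end} and {b.start}-{b.end}"
            )
    return ivs


@dataclass(frozen=True)
class IntervalSet:
    """Ordered, pairwise-disjoint intervals on one chromosome."""

    chrom: str
    intervals: tuple[GenomeInterval, ...]
    chrom_length: int

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        object.__setattr__(
            self, "intervals",
            _canonical(self.chrom, self.intervals, self.chrom_length, type(self).__name__),
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomeInterval]:
        return iter(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def starts(self) -> np.ndarray:
        return np.array([iv.start for iv in self.intervals], dtype=np.int64)

    @property
    def ends(self) -> np.ndarray:
        return np.array([iv.end for iv in self.intervals], dtype=np.int64)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts if len(self) else np.array([], dtype=np.int64)


class MaskSet(IntervalSet):
    """Unassayed (ambiguous or missing) sequence on one chromosome."""

    def complement(self) -> "MaskSet":
        """Assayed segments: the gaps between mask intervals, tiling the chromosome."""
        out, pos = [], 0
        for iv in self.intervals:
            if iv.start > pos:
                out.append(GenomeInterval(self.chrom, pos, iv.start))
            pos = iv.end
        if pos < self.chrom_length:
            out.append(GenomeInterval(self.chrom, pos, self.chrom_length))
        return MaskSet(self.chrom, tuple(out), self.chrom_length)


class FeatureSet(IntervalSet):
    """Non-overlapping genomic features (e.g. CpG islands) on one chromosome.

    The 5' start positions are the data points of the pair statistics; the
    mean intensity is N / chromosome length.
    """

    @property
    def n(self) -> int:
        return len(self.intervals)

    @property
    def intensity(self) -> float:
        return self.n / self.chrom_length


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a (possibly multi-record, wrapped) FASTA file.

    Returns ``(identifier, sequence)`` pairs in file order with sequences
    uppercased. Duplicate identifiers, a missing first header, or an empty
    file raise :class:`FormatError`.
    """
    from Bio import SeqIO

    with open(path) as fh:
        head = fh.read(1)
        if head not in ("", ">", ";"):
            raise FormatError(f"{path}: sequence before first header")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: empty FASTA header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def build_mask(sequence: str, chrom: str = "chr") -> MaskSet:
    """Derive the unassayed mask from a sequence: maximal runs of non-ACGT bases.

    All IUPAC ambiguity codes (N, R, Y, ...) are masked, not just N. Case is
    ignored: soft-masked lowercase counts as assayed.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    ivs = tuple(
        GenomeInterval(chrom, int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])
    )
    return MaskSet(chrom, ivs, len(sequence))


def _merge_union(ivs: Sequence[GenomeInterval], chrom: str) -> list[GenomeInterval]:
    out: list[GenomeInterval] = []
    for iv in sorted(ivs, key=lambda v: (v.start, v.end)):
        if out and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomeInterval(chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def read_bed(path: str | Path, chrom_length: int, chrom: str | None = None,
             merge: bool = False, as_mask: bool = False) -> FeatureSet | MaskSet:
    """Read BED3+ records (0-based half-open) for one chromosome.

    Records are sorted on output. Overlapping records raise unless
    ``merge=True``, in which case overlapping/touching records are unioned.
    If ``chrom`` is None, the file must contain a single chromosome.
    """
    ivs: list[GenomeInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 tab-separated fields")
            c, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if chrom is not None and c != chrom:
                continue
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if end > chrom_length:
                raise FormatError(
                    f"{path}:{lineno}: coordinate {end} beyond chrom_length {chrom_length}"
                )
            ivs.append(GenomeInterval(c, start, end))
    chroms = {iv.chrom for iv in ivs}
    if len(chroms) > 1:
        raise FormatError(f"{path}: multiple chromosomes {sorted(chroms)}; pass chrom=")
    use_chrom = chrom if chrom is not None else (chroms.pop() if chroms else "chr")
    if merge:
        ivs = _merge_union(ivs, use_chrom)
    cls = MaskSet if as_mask else FeatureSet
    try:
        return cls(use_chrom, tuple(ivs), chrom_length)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc} (pass merge=True to union overlaps)") from exc


def write_bed(features: IntervalSet, path: str | Path) -> None:
    """Write intervals as BED3. Round-trips bit-exactly through read_bed."""
    with open(path, "w") as fh:
        for iv in features:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
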