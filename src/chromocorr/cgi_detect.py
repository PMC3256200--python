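"""Sliding-window CpG-island detection (Takai-Jones criteria).

A CpG island is reported when a contiguous region satisfies, over its whole
extent, three criteria: G+C fraction >= ``min_gc``, observed/expected CpG
ratio >= ``min_obs_exp``, and length >= ``min_length``. Candidate regions
are built from chains of passing ``window``-bp windows whose start positions
are at most ``window`` bp apart, then trimmed symmetrically (1 bp off each
end per step) until the whole region passes. Accepted islands closer than
``merge_gap`` bp are merged when the merged span itself passes all criteria.

Windows never overlap unassayed (non-ACGT) bases: the detector runs
independently inside each assayed segment, so islands cannot span masked
sequence. The construction is symmetric under reverse complement because GC
content and CpG dinucleotide counts are reverse-complement invariant and no
step depends on scan direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genome_io import FeatureSet, GenomeInterval, build_mask

__all__ = ["CgiParams", "gc_fraction", "obs_exp_cpg", "detect_cgi"]


@dataclass(frozen=True)
class CgiParams:
    """Detection thresholds; defaults target promoter-associated islands
    while excluding most Alu repeats."""

    window: int = 200
    min_gc: float = 0.55
    min_obs_exp: float = 0.65
    min_length: int = 500
    merge_gap: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.min_gc <= 1):
            raise ValueError("min_gc must be in (0, 1]")
        if self.min_obs_exp <= 0:
            raise ValueError("min_obs_exp must be positive")
        if self.min_length < self.window:
            raise ValueError("min_length must be >= window")


def _check_acgt(segment: str) -> str:
    if not segment:
        raise ValueError("empty segment")
    seq = segment.upper()
    if set(seq) - set("ACGT"):
        raise ValueError("segment contains non-ACGT bases; pre-mask ambiguous sequence")
    return seq


def gc_fraction(segment: str) -> float:
    """(G + C) / length of an unambiguous segment."""
    seq = _check_acgt(segment)
    return (seq.count("G") + seq.count("C")) / len(seq)


def obs_exp_cpg(segment: str) -> float:
    """Observed/expected CpG ratio: #CG * length / (#C * #G); 0 if #C*#G == 0."""
    seq = _check_acgt(segment)
    c, g = seq.count("C"), seq.count("G")
    if c * g == 0:
        return 0.0
    return seq.count("CG") * len(seq) / (c * g)


class _SegmentCounts:
    """O(1) window statistics over one ACGT segment via prefix sums."""

    def __init__(self, seq: str):
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = arr == ord("C")
        is_g = arr == ord("G")
        self.n = len(arr)
        z = np.zeros(1, dtype=np.int64)
        self.cum_c = np.concatenate((z, np.cumsum(is_c)))
        self.cum_g = np.concatenate((z, np.cumsum(is_g)))
        cg = is_c[:-1] & is_g[1:] if self.n > 1 else np.zeros(0, dtype=bool)
        # cum_cg[i] = number of CG dimers starting before position i (length n)
        self.cum_cg = np.concatenate((z, np.cumsum(cg)))

    def gc(self, start: int, end: int) -> float:
        c = self.cum_c[end] - self.cum_c[start]
        g = self.cum_g[end] - self.cum_g[start]
        return (c + g) / (end - start)

    def obs_exp(self, start: int, end: int) -> float:
        c = int(self.cum_c[end] - self.cum_c[start])
        g = int(self.cum_g[end] - self.cum_g[start])
        if c * g == 0:
            return 0.0
        # CG dimers fully inside [start, end): starting positions start..end-2
        cg = int(self.cum_cg[end - 1] - self.cum_cg[start])
        return cg * (end - start) / (c * g)

    def passes(self, start: int, end: int, p: CgiParams) -> bool:
        return self.gc(start, end) >= p.min_gc and self.obs_exp(start, end) >= p.min_obs_exp


def _window_pass_starts(counts: _SegmentCounts, p: CgiParams) -> np.ndarray:
    """Start positions of every passing window, vectorized over the segment."""
    w, n = p.window, counts.n
    if n < w:
        return np.zeros(0, dtype=np.int64)
    starts = np.arange(n - w + 1)
    c = counts.cum_c[starts + w] - counts.cum_c[starts]
    g = counts.cum_g[starts + w] - counts.cum_g[starts]
    cg = counts.cum_cg[starts + w - 1] - counts.cum_cg[starts]
    # divide (not cross-multiply) so thresholds compare identically to the
    # scalar whole-region test at exact boundary values like 0.55
    gc_ok = (c + g) / w >= p.min_gc
    denom = c * g
    with np.errstate(divide="ignore", invalid="ignore"):
        oe_ok = np.where(denom > 0, cg * w / np.maximum(denom, 1), 0.0) >= p.min_obs_exp
    return starts[gc_ok & oe_ok]


def _trim(counts: _SegmentCounts, start: int, end: int, p: CgiParams) -> tuple[int, int] | None:
    """Shrink [start, end) one bp off both ends per step until it passes all
    criteria; None if it drops below min_length first."""
    while end - start >= p.min_length:
        if counts.passes(start, end, p):
            return start, end
        start += 1
        end -= 1
    return None


def _detect_in_segment(seq: str, p: CgiParams) -> list[tuple[int, int]]:
    counts = _SegmentCounts(seq)
    passing = _window_pass_starts(counts, p)
    if passing.size == 0:
        return []
    # chain passing windows whose starts are <= window bp apart
    breaks = np.flatnonzero(np.diff(passing) > p.window)
    chain_bounds = np.concatenate(([0], breaks + 1, [passing.size]))
    islands: list[tuple[int, int]] = []
    for lo, hi in zip(chain_bounds[:-1], chain_bounds[1:]):
        region = _trim(counts, int(passing[lo]), int(passing[hi - 1]) + p.window, p)
        if region is not None:
            islands.append(region)
    # merge accepted islands separated by < merge_gap when the union passes
    merged: list[tuple[int, int]] = []
    for s, e in islands:
        if merged and s - merged[-1][1] < p.merge_gap:
            ms, me = merged[-1][0], e
            if me - ms >= p.min_length and counts.passes(ms, me, p):
                merged[-1] = (ms, me)
                continue
        merged.append((s, e))
    return merged


def detect_cgi(sequence: str, params: CgiParams | None = None,
               chrom: str = "chr") -> FeatureSet:
    """Detect CpG islands in a chromosome sequence.

    Ambiguous bases split the sequence into assayed segments; each segment is
    scanned independently so no island crosses a mask boundary. Returns a
    sorted, non-overlapping :class:`FeatureSet`. A sequence shorter than the
    window yields an empty result with a warning.
    """
    p = params or CgiParams()
    seq = sequence.upper()
    if len(seq) < p.window:
        warnings.warn("sequence shorter than detection window; no islands reported")
        return FeatureSet(chrom, (), max(len(seq), 1))
    mask = build_mask(seq, chrom)
    ivs: list[GenomeInterval] = []
    for seg in mask.complement():
        if seg.length < p.window:
            continue
        for s, e in _detect_in_segment(seq[seg.start:seg.end], p):
            ivs.append(GenomeInterval(chrom, seg.start + s, seg.start + e))
    return FeatureSet(chrom, tuple(ivs), len(seq))
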