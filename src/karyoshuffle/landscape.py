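"""Per-arm binned feature-coverage profiles and genome composition.

Each chromosomal arm is split into 50 equal-width bins (the widths differ
between arms) and the fraction of each bin covered by genes, TE classes,
low-complexity regions and satellites is profiled along the
centromere-to-telomere axis. Overlaps between repeat classes are resolved
by the masking precedence satellite > low-complexity > TE classes >
gene: what an earlier masking round claimed is trimmed from later
classes. Genes are profiled without repeat trimming - gene and repeat
tracks are independent annotations of the same sequence. Whole-genome
composition then partitions the assembly into disjoint repeat-class
fractions plus the single-copy remainder.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .io_formats import GenomicInterval

#: masking precedence, highest first; ``gene`` is trimmed last but is
#: normally profiled untrimmed
PRECEDENCE = [
    "satellite",
    "low_complexity",
    "TIR_MITE",
    "LTR",
    "LINE",
    "other_TE",
    "gene",
]
REPEAT_CLASSES = PRECEDENCE[:-1]
FEATURE_CLASSES = PRECEDENCE + ["single_copy"]


@dataclass(frozen=True)
class BinProfile:
    species: str
    element: str
    feature_class: str
    values: tuple[float, ...]

    def __post_init__(self):
        if any(not 0 <= v <= 1 for v in self.values):
            raise ValidationError("bin coverage must lie in [0, 1]")


@dataclass(frozen=True)
class CompositionSummary:
    fractions: dict  # class -> genome fraction, including "single_copy"

    @property
    def single_copy(self) -> float:
        return self.fractions["single_copy"]


# ---------------------------------------------------------------------------
# Interval arithmetic (per chromosome, sorted half-open intervals)
# ---------------------------------------------------------------------------

def _union(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda x: x.start)
        cur_s, cur_e, label = ivs[0].start, ivs[0].end, ivs[0].label
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e, label=label))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e, label=label))
    return out


def _subtract(
    intervals: Sequence[GenomicInterval], blockers: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    blocked: dict[str, list[GenomicInterval]] = {}
    for b in blockers:
        blocked.setdefault(b.chrom, []).append(b)
    out = []
    for iv in intervals:
        pieces = [(iv.start, iv.end)]
        for b in sorted(blocked.get(iv.chrom, []), key=lambda x: x.start):
            nxt = []
            for s, e in pieces:
                if b.end <= s or b.start >= e:
                    nxt.append((s, e))
                    continue
                if b.start > s:
                    nxt.append((s, b.start))
                if b.end < e:
                    nxt.append((b.end, e))
            pieces = nxt
        out.extend(
            GenomicInterval(iv.chrom, s, e, label=iv.label) for s, e in pieces
        )
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def resolve_precedence(
    intervals_by_class: Mapping[str, Sequence[GenomicInterval]]
) -> dict[str, list[GenomicInterval]]:
    """Make the per-class annotations disjoint: union within each class,
    then trim every class by all higher-precedence classes."""
    unknown = set(intervals_by_class) - set(PRECEDENCE)
    if unknown:
        raise ValidationError(f"unknown feature classes: {sorted(unknown)}")
    resolved: dict[str, list[GenomicInterval]] = {}
    claimed: list[GenomicInterval] = []
    for cls in PRECEDENCE:
        if cls not in intervals_by_class:
            continue
        merged = _union(intervals_by_class[cls]) if intervals_by_class[cls] else []
        trimmed = _subtract(merged, claimed)
        resolved[cls] = trimmed
        claimed = _union(claimed + trimmed) if trimmed or claimed else []
    return resolved


def bin_edges(arm_length: int, n_bins: int = 50) -> np.ndarray:
    """Equal-width bin boundaries; the last bin absorbs the remainder."""
    if arm_length < n_bins:
        raise ValidationError("arm shorter than the number of bins")
    width = arm_length // n_bins
    edges = np.arange(0, n_bins + 1) * width
    edges[-1] = arm_length
    return edges


def bin_profile(
    arm_length: int,
    intervals: Sequence[GenomicInterval],
    n_bins: int = 50,
) -> np.ndarray:
    """Per-bin covered fraction of one feature class along one arm.

    Input intervals are unioned first (so overlapping gene models do not
    double-count); an interval outside [0, arm_length) is an error.
    """
    edges = bin_edges(arm_length, n_bins)
    cov = np.zeros(n_bins)
    for iv in _union(intervals):
        if iv.start < 0 or iv.end > arm_length:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside arm of {arm_length} bp"
            )
        lo = int(np.searchsorted(edges, iv.start, side="right") - 1)
        hi = int(np.searchsorted(edges, iv.end, side="left"))
        for b in range(lo, hi):
            cov[b] += min(iv.end, edges[b + 1]) - max(iv.start, edges[b])
    widths = np.diff(edges)
    return cov / widths


def arm_profiles(
    arm: str,
    arm_length: int,
    intervals_by_class: Mapping[str, Sequence[GenomicInterval]],
    n_bins: int = 50,
    centromere_end: str = "start",
    species: str = "",
) -> dict[str, BinProfile]:
    """Binned profiles for every class on one arm, oriented so that bin 0
    is centromere-proximal. Repeat classes are precedence-trimmed; genes
    are profiled as annotated."""
    if centromere_end not in ("start", "end"):
        raise ValidationError("centromere_end must be 'start' or 'end'")
    resolved = resolve_precedence(
        {c: ivs for c, ivs in intervals_by_class.items() if c != "gene"}
    )
    if "gene" in intervals_by_class:
        resolved["gene"] = list(intervals_by_class["gene"])
    out = {}
    for cls, ivs in resolved.items():
        values = bin_profile(arm_length, [iv for iv in ivs if iv.chrom == arm], n_bins)
        if centromere_end == "end":
            values = values[::-1]
        out[cls] = BinProfile(
            species=species, element=arm, feature_class=cls,
            values=tuple(float(v) for v in values),
        )
    return out


def genome_composition(
    disjoint_intervals: Mapping[str, Sequence[GenomicInterval]],
    genome_length: int,
) -> CompositionSummary:
    """Genome fraction per repeat class plus the single-copy remainder
    (genes are not repeats and are excluded from the partition)."""
    if genome_length <= 0:
        raise ValidationError("genome_length must be positive")
    fractions = {}
    for cls in REPEAT_CLASSES:
        if cls in disjoint_intervals:
            fractions[cls] = total_bp(disjoint_intervals[cls]) / genome_length
    repeat_sum = sum(fractions.values())
    if repeat_sum > 1 + 1e-9:
        raise ValidationError(
            "repeat fractions exceed 1 - precedence was not applied"
        )
    fractions["single_copy"] = 1.0 - repeat_sum
    return CompositionSummary(fractions=fractions)
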