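"""Chromosome-quotient (CQ) scan for male-specific regions.

The CQ of a reference fragment is the number of female alignments
divided by the number of male alignments. Sequence present only on the
male-determining chromosome copy (hemizygous, like the M locus) attracts
essentially no female reads and half-depth male reads, so its CQ falls
near zero. Following the published filtering rules, the repeat-masked
assembly is split into 1-kb fragments, fragments with fewer than 10 male
alignments are excluded (small-denominator bias), and CQ < 0.05 calls a
fragment male-specific. Region merging of the flagged fragments is this
package's addition - defaults are chosen to resolve a multi-Mb region
from 1-kb fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ValidationError
from .io_formats import FragmentCounts, GenomicInterval, SequenceRecord


@dataclass(frozen=True)
class CQConfig:
    fragment_size: int = 1_000
    min_male_alignments: int = 10
    cq_cutoff: float = 0.05
    merge_gap: int = 100_000
    min_fragments_per_region: int = 5
    max_masked_fraction: float = 0.9

    def __post_init__(self):
        if self.fragment_size <= 0:
            raise ValidationError("fragment_size must be positive")
        if self.cq_cutoff <= 0:
            raise ValidationError("cq_cutoff must be positive")
        if self.min_male_alignments < 1:
            raise ValidationError("min_male_alignments must be >= 1")


@dataclass(frozen=True)
class CQResult:
    fragment: GenomicInterval
    female_count: int
    male_count: int
    cq: float | None          # None when excluded (male count below cutoff)
    male_specific: bool

    @property
    def excluded(self) -> bool:
        return self.cq is None


@dataclass(frozen=True)
class MaleRegion:
    interval: GenomicInterval
    n_fragments: int
    fraction_male_specific: float


def fragment_genome(
    records: Sequence[SequenceRecord], config: CQConfig | None = None
) -> list[GenomicInterval]:
    """Split each sequence into consecutive fragment_size windows (the
    terminal remainder stays as a short fragment); windows made of >=
    ``max_masked_fraction`` masked bases (N or lowercase) are dropped."""
    config = config or CQConfig()
    size = config.fragment_size
    out = []
    for rec in records:
        seq = rec.sequence
        for start in range(0, len(seq), size):
            window = seq[start : start + size]
            masked = sum(1 for ch in window if ch == "N" or ch.islower())
            if masked / len(window) >= config.max_masked_fraction:
                continue
            end = start + len(window)
            out.append(
                GenomicInterval(rec.id, start, end, label=f"{rec.id}:{start}-{end}")
            )
    return out


def compute_cq(
    counts: Iterable[FragmentCounts], config: CQConfig | None = None
) -> list[CQResult]:
    """CQ per fragment; fragments with fewer than ``min_male_alignments``
    male alignments are excluded (CQ reported as missing, never 0 or
    infinity), the rest flagged male-specific when CQ < ``cq_cutoff``."""
    config = config or CQConfig()
    out = []
    for fc in counts:
        if fc.female_count < 0 or fc.male_count < 0:
            raise ValidationError("negative alignment counts")
        if fc.male_count < config.min_male_alignments:
            out.append(CQResult(fc.fragment, fc.female_count, fc.male_count, None, False))
        else:
            cq = fc.female_count / fc.male_count
            out.append(
                CQResult(
                    fc.fragment, fc.female_count, fc.male_count, cq,
                    cq < config.cq_cutoff,
                )
            )
    return out


def call_male_regions(
    results: Sequence[CQResult], config: CQConfig | None = None
) -> list[MaleRegion]:
    """Merge male-specific fragments on the same chromosome lying within
    ``merge_gap`` of each other; keep merged regions with at least
    ``min_fragments_per_region`` flagged fragments and report the
    male-specific fraction over all non-excluded fragments they span."""
    config = config or CQConfig()
    results = sorted(results, key=lambda r: (r.fragment.chrom, r.fragment.start))
    flagged = [r for r in results if r.male_specific]
    regions: list[MaleRegion] = []
    cluster: list[CQResult] = []

    def flush():
        if len(cluster) < config.min_fragments_per_region:
            return
        chrom = cluster[0].fragment.chrom
        start, end = cluster[0].fragment.start, cluster[-1].fragment.end
        spanned = [
            r for r in results
            if r.fragment.chrom == chrom
            and r.fragment.start >= start
            and r.fragment.end <= end
            and not r.excluded
        ]
        frac = len(cluster) / len(spanned) if spanned else 0.0
        regions.append(
            MaleRegion(
                interval=GenomicInterval(chrom, start, end, label="male_specific"),
                n_fragments=len(cluster),
                fraction_male_specific=frac,
            )
        )

    for r in flagged:
        if (
            cluster
            and r.fragment.chrom == cluster[-1].fragment.chrom
            and r.fragment.start - cluster[-1].fragment.end <= config.merge_gap
        ):
            cluster.append(r)
        else:
            flush()
            cluster = [r]
    if cluster:
        flush()
    return regions
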