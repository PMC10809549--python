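"""Rearrangement rates and sex-chromosome / autosome rate ratios.

Per-branch inversion counts are normalized to breaks per Mb of
repeat-masked arm per million years; a second normalization additionally
divides by the arm's synteny-block count, since both denominators are in
use (Methods-style per-block, figure-style per-Mb-per-MY) and consumers
should be able to choose. Divergence times default to 134.6 MY for the
Anophelinae/Culicinae split and 62.3 MY for Culex/Aedes; both are plain
config values, not inferences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError

RATE_COLUMNS = [
    "lineage", "element", "n_inversions", "arm_mb", "t_my",
    "block_count", "rate", "rate_per_block",
]


@dataclass(frozen=True)
class RateConfig:
    t_root_my: float = 134.6
    t_culex_aedes_my: float = 62.3
    arm_sizes_masked_mb: dict = field(default_factory=dict)   # (lineage, element) -> Mb
    block_counts: dict = field(default_factory=dict)          # (lineage, element) -> int

    def __post_init__(self):
        if self.t_root_my <= 0 or self.t_culex_aedes_my <= 0:
            raise ValidationError("divergence times must be positive")
        if any(v <= 0 for v in self.arm_sizes_masked_mb.values()):
            raise ValidationError("arm sizes must be positive")


def rearrangement_rate(
    n_inversions: int, arm_mb: float, t_my: float, block_count: int | None = None
) -> tuple[float, float | None]:
    """(breaks per Mb per MY, and the same further divided by the arm's
    synteny-block count when given)."""
    if arm_mb <= 0 or t_my <= 0:
        raise ValidationError("arm_mb and t_my must be positive")
    if n_inversions < 0:
        raise ValidationError("n_inversions must be non-negative")
    rate = n_inversions / (arm_mb * t_my)
    per_block = rate / block_count if block_count else None
    return rate, per_block


def build_rate_table(
    inversion_counts: Mapping[tuple[str, str], int],
    config: RateConfig,
    times_my: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble the per-(lineage, element) rate table.

    ``inversion_counts`` maps (lineage, element) to the inferred number
    of inversions on that lineage's branch; ``times_my`` maps lineage to
    its divergence time (default: root time for every lineage)."""
    rows = []
    for (lineage, element), n in sorted(inversion_counts.items()):
        key = (lineage, element)
        if key not in config.arm_sizes_masked_mb:
            raise ValidationError(f"no masked arm size configured for {key}")
        arm_mb = config.arm_sizes_masked_mb[key]
        t_my = (times_my or {}).get(lineage, config.t_root_my)
        blocks = config.block_counts.get(key)
        rate, per_block = rearrangement_rate(n, arm_mb, t_my, blocks)
        rows.append((lineage, element, n, arm_mb, t_my, blocks, rate, per_block))
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def rate_ratios(
    rate_table: pd.DataFrame,
    sex_elements: str | Sequence[str],
    value: str = "rate",
) -> dict[str, dict[str, float]]:
    """Per lineage: rate of each sex-linked element divided by the
    unweighted mean rate of the autosomal elements.

    For Culicine genomes with a two-armed sex-determining chromosome,
    pass both arms (e.g. ["1p", "1q"]) to get a ratio per arm."""
    if isinstance(sex_elements, str):
        sex_elements = [sex_elements]
    sex_elements = list(sex_elements)
    out: dict[str, dict[str, float]] = {}
    for lineage, sub in rate_table.groupby("lineage"):
        sex = sub[sub["element"].isin(sex_elements)]
        autosomes = sub[~sub["element"].isin(sex_elements)]
        if sex.empty:
            raise ValidationError(f"lineage {lineage!r} has no sex element")
        if autosomes.empty:
            raise ValidationError(f"lineage {lineage!r} has no autosomal element")
        mean_auto = autosomes[value].mean()
        if mean_auto == 0:
            raise ValidationError(f"lineage {lineage!r}: autosomal mean rate is zero")
        out[lineage] = {
            row.element: getattr(row, value) / mean_auto
            for row in sex.itertuples(index=False)
        }
    return out


def masked_arm_mb(arm_length_bp: int, masked_intervals) -> float:
    """Helper: repeat-masked arm size in Mb = arm length minus the bp
    covered by the given (already disjoint) repeat intervals."""
    masked = sum(len(iv) for iv in masked_intervals)
    if masked > arm_length_bp:
        raise ValidationError("masked bp exceeds arm length")
    return (arm_length_bp - masked) / 1e6
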