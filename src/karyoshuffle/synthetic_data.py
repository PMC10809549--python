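"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators stand in for the four mosquito genome assemblies:

* signed block orders evolved by known numbers of paracentric inversions
  (and optional whole-arm translocations) down a fixed four-taxon tree,
  emitted as per-species ortholog hit tables;
* female/male per-fragment alignment counts over a reference carrying a
  hemizygous male-only region (female mean ~ 0, male mean halved);
* per-class interval annotations whose per-bin coverage follows declared
  gradients, e.g. pericentromere-to-telomere repeat decay.

Every generator returns a :class:`TruthLog` that, together with the seed,
fully determines the output - the ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import FragmentCounts, GenomicInterval, ORTHOLOG_COLUMNS
from .rearrangements import SpeciesTree, reverse_segment

_ARM_SLOTS = "pq"

# repeat classes are placed before genes; satellites and low-complexity
# before TEs so that they never overlap TE intervals (masking order)
_PLACEMENT_ORDER = [
    "satellite",
    "low_complexity",
    "TIR_MITE",
    "LTR",
    "LINE",
    "other_TE",
    "gene",
]
_REPEAT_PLACEMENT = _PLACEMENT_ORDER[:-1]


@dataclass
class TruthLog:
    """Ground truth of one synthetic dataset (seed + parameters determine
    everything; recovery tests compare against these fields)."""

    seed: int
    planted_inversions: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    planted_translocations: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    m_region: GenomicInterval | None = None
    feature_targets: dict[str, list[float]] | None = None
    ancestor_orders: dict[str, tuple[int, ...]] = field(default_factory=dict)
    species_orders: dict[str, dict[str, tuple[int, ...]]] = field(default_factory=dict)
    species_arms: dict[str, dict[str, str]] = field(default_factory=dict)
    ancestor_pairing: dict[str, tuple[str, ...]] = field(default_factory=dict)
    species_pairing: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Rearranged genomes
# ---------------------------------------------------------------------------

def _branch_order(tree: SpeciesTree) -> list[str]:
    s1, s2 = tree.cherry1
    s3, s4 = tree.cherry2
    return ["cherry1", s1, s2, "cherry2", s3, s4]


def _normalize_counts(spec, branches: Sequence[str]) -> dict[str, int]:
    if spec is None:
        return {b: 0 for b in branches}
    if isinstance(spec, int):
        return {b: spec for b in branches}
    out = {b: int(spec.get(b, 0)) for b in branches}
    unknown = set(spec) - set(branches)
    if unknown:
        raise ValidationError(f"unknown branches in count map: {sorted(unknown)}")
    return out


def simulate_rearranged_genomes(
    n_blocks: int,
    tree: SpeciesTree | None = None,
    inversions_per_branch=2,
    translocations_per_branch=None,
    anchors_per_block: int = 2,
    intra_block_gap_bp: int = 1_000,
    inter_block_gap_bp: int = 20_000,
    gene_bp: int = 2_000,
    karyotype: Mapping[str, tuple[str, ...]] | None = None,
    seed: int = 0,
) -> tuple[dict[str, pd.DataFrame], TruthLog]:
    """Evolve ancestral signed block orders down the tree and emit
    per-species ortholog tables.

    Each ancestral arm starts as the identity order 1..n_blocks. On each
    branch the planted number of reversals is applied at uniform
    breakpoints (the real inversion length spectrum is unknown, so no
    length bias), and whole-arm translocations exchange arms between
    chromosomes. Every block is written out as ``anchors_per_block``
    single-copy ortholog hits whose coordinates and strands are
    consistent with the block's orientation.
    """
    if n_blocks < 2:
        raise ValidationError("need n_blocks >= 2")
    if anchors_per_block < 2:
        raise ValidationError("need anchors_per_block >= 2")
    tree = tree or SpeciesTree()
    branches = _branch_order(tree)
    inv = _normalize_counts(inversions_per_branch, branches)
    trans = _normalize_counts(translocations_per_branch, branches)
    if karyotype is None:
        if any(trans.values()):
            karyotype = {"1": ("e1", "e2"), "2": ("e3", "e4"), "3": ("e5", "e6")}
        else:
            karyotype = {"1": ("e1",)}
    chroms = sorted(karyotype)
    arms = [a for c in chroms for a in karyotype[c]]
    if any(trans.values()) and len(chroms) < 2:
        raise ValidationError("whole-arm translocations need >= 2 chromosomes")

    rng = np.random.default_rng(seed)
    # fixed ancestral strand per ortholog, shared by all species
    member_strand = {
        (arm, b, k): int(rng.choice((1, -1)))
        for arm in arms
        for b in range(1, n_blocks + 1)
        for k in range(anchors_per_block)
    }

    truth = TruthLog(
        seed=seed,
        ancestor_orders={arm: tuple(range(1, n_blocks + 1)) for arm in arms},
        ancestor_pairing={c: tuple(karyotype[c]) for c in chroms},
        params=dict(
            n_blocks=n_blocks,
            anchors_per_block=anchors_per_block,
            intra_block_gap_bp=intra_block_gap_bp,
            inter_block_gap_bp=inter_block_gap_bp,
            gene_bp=gene_bp,
        ),
    )

    def evolve(state, branch):
        orders = dict(state[0])
        pairing = {c: list(v) for c, v in state[1].items()}
        for _ in range(inv[branch]):
            arm = arms[int(rng.integers(len(arms)))]
            i, j = sorted(int(x) for x in rng.integers(0, n_blocks, size=2))
            orders[arm] = reverse_segment(orders[arm], i, j)
            truth.planted_inversions.setdefault(branch, []).append((arm, i, j))
        for _ in range(trans[branch]):
            c1, c2 = (chroms[int(x)] for x in rng.choice(len(chroms), 2, replace=False))
            s1 = int(rng.integers(len(pairing[c1])))
            s2 = int(rng.integers(len(pairing[c2])))
            a1, a2 = pairing[c1][s1], pairing[c2][s2]
            pairing[c1][s1], pairing[c2][s2] = a2, a1
            truth.planted_translocations.setdefault(branch, []).append((a1, a2))
        return orders, pairing

    root = ({arm: tuple(range(1, n_blocks + 1)) for arm in arms},
            {c: list(karyotype[c]) for c in chroms})
    cherry1_node = evolve(root, "cherry1")
    cherry2_node = evolve(root, "cherry2")
    s1, s2 = tree.cherry1
    s3, s4 = tree.cherry2
    leaf_states = {
        s1: evolve(cherry1_node, s1),
        s2: evolve(cherry1_node, s2),
        s3: evolve(cherry2_node, s3),
        s4: evolve(cherry2_node, s4),
    }

    tables: dict[str, pd.DataFrame] = {}
    for species in tree.species:
        orders, pairing = leaf_states[species]
        rows = []
        arm_map: dict[str, str] = {}
        order_map: dict[str, tuple[int, ...]] = {}
        for chrom in chroms:
            for slot, anc_arm in zip(_ARM_SLOTS, pairing[chrom]):
                sp_chrom = f"{chrom}{slot}"
                arm_map[sp_chrom] = anc_arm
                order_map[sp_chrom] = orders[anc_arm]
                cursor = 10_000
                for x in orders[anc_arm]:
                    b = abs(x)
                    members = range(anchors_per_block)
                    if x < 0:
                        members = reversed(list(members))
                    for k in members:
                        strand = member_strand[(anc_arm, b, k)] * (1 if x > 0 else -1)
                        rows.append(
                            (
                                f"{anc_arm}_b{b:03d}_g{k}",
                                species,
                                "single",
                                sp_chrom,
                                cursor,
                                cursor + gene_bp,
                                "+" if strand > 0 else "-",
                            )
                        )
                        cursor += gene_bp + intra_block_gap_bp
                    cursor += inter_block_gap_bp - intra_block_gap_bp
        tables[species] = pd.DataFrame(rows, columns=ORTHOLOG_COLUMNS)
        truth.species_orders[species] = order_map
        truth.species_arms[species] = arm_map
        truth.species_pairing[species] = {
            c: tuple(pairing[c]) for c in chroms
        }
    return tables, truth


# ---------------------------------------------------------------------------
# Sex-specific coverage
# ---------------------------------------------------------------------------

def simulate_sex_coverage(
    genome_length: int,
    m_region: GenomicInterval | None,
    depth: float,
    fragment_size: int = 1_000,
    read_length: int = 150,
    leak_rate: float = 0.0,
    noise_model: str = "poisson",
    nb_dispersion: float = 0.1,
    chrom: str = "1p",
    seed: int = 0,
) -> tuple[list[FragmentCounts], TruthLog]:
    """Per-fragment female/male alignment counts over a reference with an
    optional hemizygous male-only region.

    Outside the region both sexes draw from the same mean
    ``depth * fragment_size / read_length``; inside it, the male mean is
    halved (one copy instead of two) and the female mean is
    ``leak_rate`` times the background (mismapping leak, 0 by default).
    ``negative_binomial`` adds overdispersion ``nb_dispersion`` (variance
    = mean + dispersion * mean^2).
    """
    if fragment_size <= 0:
        raise ValidationError("fragment_size must be positive")
    if depth < 0:
        raise ValidationError("depth must be non-negative")
    if m_region is not None and (m_region.chrom != chrom or m_region.end > genome_length):
        raise ValidationError("m_region must lie inside the simulated chromosome")
    rng = np.random.default_rng(seed)
    base_mean = depth * fragment_size / read_length

    starts = np.arange(0, genome_length, fragment_size)
    ends = np.minimum(starts + fragment_size, genome_length)
    widths = (ends - starts).astype(float)
    if m_region is None:
        omega = np.zeros_like(widths)
    else:
        ov = np.minimum(ends, m_region.end) - np.maximum(starts, m_region.start)
        omega = np.clip(ov, 0, None) / widths

    scale = widths / fragment_size
    female_mean = base_mean * scale * ((1 - omega) + leak_rate * omega)
    male_mean = base_mean * scale * ((1 - omega) + 0.5 * omega)

    def draw(mean: np.ndarray) -> np.ndarray:
        if noise_model == "poisson":
            return rng.poisson(mean)
        if noise_model == "negative_binomial":
            r = 1.0 / nb_dispersion
            p = r / (r + np.maximum(mean, 1e-12))
            out = rng.negative_binomial(r, p)
            out[mean == 0] = 0
            return out
        raise ValidationError(f"unknown noise model {noise_model!r}")

    females = draw(female_mean)
    males = draw(male_mean)
    counts = [
        FragmentCounts(
            GenomicInterval(chrom, int(s), int(e), label=f"{chrom}:{int(s)}-{int(e)}"),
            int(f),
            int(m),
        )
        for s, e, f, m in zip(starts, ends, females, males)
    ]
    truth = TruthLog(
        seed=seed,
        m_region=m_region,
        params=dict(
            genome_length=genome_length,
            depth=depth,
            fragment_size=fragment_size,
            read_length=read_length,
            leak_rate=leak_rate,
            noise_model=noise_model,
        ),
    )
    return counts, truth


# ---------------------------------------------------------------------------
# Feature annotations
# ---------------------------------------------------------------------------

def _as_gradient(value, n_bins: int) -> np.ndarray:
    arr = np.full(n_bins, float(value)) if np.isscalar(value) else np.asarray(value, float)
    if arr.shape != (n_bins,):
        raise ValidationError(f"gradient must be scalar or length {n_bins}")
    if (arr < 0).any() or (arr > 1).any():
        raise ValidationError("target coverage must lie in [0, 1] in every bin")
    return arr


def simulate_feature_annotation(
    arm_lengths: Mapping[str, int],
    class_gradients: Mapping[str, object],
    seed: int = 0,
    n_bins: int = 50,
    interval_bp: int = 2_000,
) -> tuple[dict[str, list[GenomicInterval]], TruthLog]:
    """Place non-overlapping feature intervals whose per-bin coverage
    follows the per-class target gradients (bin 0 = centromere end).

    Repeat classes are placed in masking order - satellites and
    low-complexity first, then TE classes - into the space left free by
    higher-priority classes, so realized repeat annotations are disjoint.
    Genes are placed independently and may overlap repeats. The realized
    covered bp per bin equals the target bp exactly (up to 1-bp
    rounding); randomness only shuffles interval positions.
    """
    unknown = set(class_gradients) - set(_PLACEMENT_ORDER)
    if unknown:
        raise ValidationError(f"unknown feature classes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    gradients = {
        cls: _as_gradient(val, n_bins) for cls, val in class_gradients.items()
    }
    repeat_total = sum(
        (g for c, g in gradients.items() if c != "gene"),
        start=np.zeros(n_bins),
    )
    if (repeat_total > 1).any():
        raise ValidationError("summed repeat-class target coverage exceeds 1 in a bin")

    out: dict[str, list[GenomicInterval]] = {c: [] for c in gradients}
    for arm in sorted(arm_lengths):
        length = int(arm_lengths[arm])
        width = length // n_bins
        if width < 1:
            raise ValidationError(f"arm {arm} shorter than n_bins")
        edges = [i * width for i in range(n_bins)] + [length]
        repeat_free = [[(edges[i], edges[i + 1])] for i in range(n_bins)]
        gene_free = [[(edges[i], edges[i + 1])] for i in range(n_bins)]
        for cls in _PLACEMENT_ORDER:
            if cls not in gradients:
                continue
            free = gene_free if cls == "gene" else repeat_free
            for i in range(n_bins):
                need = int(round(gradients[cls][i] * (edges[i + 1] - edges[i])))
                segs = free[i]
                while need > 0 and segs:
                    weights = np.array([s[1] - s[0] for s in segs], float)
                    k = int(rng.choice(len(segs), p=weights / weights.sum()))
                    s0, s1 = segs.pop(k)
                    size = min(interval_bp, need, s1 - s0)
                    off = int(rng.integers(0, s1 - s0 - size + 1))
                    a, b = s0 + off, s0 + off + size
                    out[cls].append(GenomicInterval(arm, a, b, label=cls))
                    if a > s0:
                        segs.append((s0, a))
                    if b < s1:
                        segs.append((b, s1))
                    need -= size
    for cls in out:
        out[cls].sort(key=lambda iv: (iv.chrom, iv.start))
    truth = TruthLog(
        seed=seed,
        feature_targets={c: list(map(float, g)) for c, g in gradients.items()},
        params=dict(
            arm_lengths=dict(arm_lengths), n_bins=n_bins, interval_bp=interval_bp
        ),
    )
    return out, truth
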