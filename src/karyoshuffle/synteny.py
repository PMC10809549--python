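"""Chaining anchors into conserved synteny blocks and deriving per-arm
signed block orders, element homology and arm associations.

A conserved synteny block is a run of at least two anchors that sit near
each other with conserved relative order and orientation in every
compared genome. Chaining walks the anchors along a designated reference
species and joins neighbours that are co-chromosomal everywhere, closer
than the gap budget (summed over genomes by default, the multi-genome
"total gap" reading; a per-genome maximum is available), and collinear or
jointly reversed in every species.

Chromosome arms are then assigned to the ancestral chromosomal elements
(e1..e5 in the Anopheles nomenclature) by majority of block span, and
whole-arm translocations show up as changed element pairings between the
two-armed chromosomes of different species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .anchors import AnchorPoint
from .errors import ValidationError
from .io_formats import GenomicInterval
from .rearrangements import SignedPermutation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntenyConfig:
    min_anchors: int = 2
    max_total_gap: int = 750_000
    gap_metric: str = "sum_over_species"
    reference_species: str | None = None

    def __post_init__(self):
        if self.min_anchors < 2:
            raise ValidationError("min_anchors must be >= 2")
        if self.max_total_gap <= 0:
            raise ValidationError("max_total_gap must be positive")
        if self.gap_metric not in ("sum_over_species", "max_over_species"):
            raise ValidationError(f"unknown gap metric {self.gap_metric!r}")


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: int
    anchor_ids: tuple[str, ...]
    placement: dict  # species -> (chrom, GenomicInterval, sign)

    @property
    def n_anchors(self) -> int:
        return len(self.anchor_ids)


@dataclass(frozen=True)
class ElementCall:
    species: str
    arm: str
    element: str | None
    vote_fraction: float
    mosaic: bool
    fractions: dict


@dataclass(frozen=True)
class ElementMap:
    calls: dict  # (species, arm) -> ElementCall

    def mapping(self) -> dict:
        return {
            key: call.element for key, call in self.calls.items() if call.element
        }


@dataclass(frozen=True)
class TranslocationEvent:
    species_a: str
    species_b: str
    lost: tuple[str, ...]
    gained: tuple[str, ...]


def _gap(a: GenomicInterval, b: GenomicInterval) -> int:
    if b.start >= a.end:
        return b.start - a.end
    if a.start >= b.end:
        return a.start - b.end
    return 0


def chain_blocks(
    anchors: Sequence[AnchorPoint], config: SyntenyConfig | None = None
) -> list[SyntenyBlock]:
    """Chain anchors into maximal consistent runs; runs shorter than
    ``min_anchors`` are discarded (and logged with coordinates)."""
    config = config or SyntenyConfig()
    if not anchors:
        return []
    species = sorted(anchors[0].placement)
    ref = config.reference_species or species[0]
    if ref not in species:
        raise ValidationError(f"unknown reference species {ref!r}")

    ordered = sorted(
        anchors, key=lambda a: (a.placement[ref][0], a.placement[ref][1].start)
    )

    def joinable(a: AnchorPoint, b: AnchorPoint) -> bool:
        gaps = []
        for sp in species:
            ca, iva, sa = a.placement[sp]
            cb, ivb, sb = b.placement[sp]
            if ca != cb:
                return False
            gaps.append(_gap(iva, ivb))
            flip_a = sa * a.placement[ref][2]
            flip_b = sb * b.placement[ref][2]
            if flip_a != flip_b:
                return False
            if flip_a == 1 and ivb.start < iva.start:
                return False
            if flip_a == -1 and ivb.start >= iva.start:
                return False
        total = sum(gaps) if config.gap_metric == "sum_over_species" else max(gaps)
        return total <= config.max_total_gap

    runs: list[list[AnchorPoint]] = []
    current = [ordered[0]]
    for nxt in ordered[1:]:
        if joinable(current[-1], nxt):
            current.append(nxt)
        else:
            runs.append(current)
            current = [nxt]
    runs.append(current)

    blocks: list[SyntenyBlock] = []
    for run in runs:
        if len(run) < config.min_anchors:
            c, iv, _ = run[0].placement[ref]
            logger.info(
                "discarding run of %d anchor(s) at %s:%d-%d (< min_anchors)",
                len(run), c, iv.start, iv.end,
            )
            continue
        placement = {}
        for sp in species:
            chrom = run[0].placement[sp][0]
            start = min(a.placement[sp][1].start for a in run)
            end = max(a.placement[sp][1].end for a in run)
            # orientation relative to the reference: +1 when the run reads
            # in the same direction, -1 when jointly reversed
            flip = run[0].placement[sp][2] * run[0].placement[ref][2]
            placement[sp] = (chrom, GenomicInterval(chrom, start, end), flip)
        blocks.append(
            SyntenyBlock(
                block_id=len(blocks) + 1,
                anchor_ids=tuple(a.anchor_id for a in run),
                placement=placement,
            )
        )
    return blocks


def signed_permutation(
    blocks: Iterable[SyntenyBlock],
    species: str,
    chrom: str,
    reference_species: str | None = None,
) -> SignedPermutation:
    """Signed block order along one chromosome of one species, with block
    ids relabeled 1..m by their order in the reference species (so the
    reference itself reads +1..+m)."""
    blocks = [b for b in blocks if b.placement.get(species, (None,))[0] == chrom]
    if not blocks:
        return SignedPermutation(())
    ref = reference_species or sorted(blocks[0].placement)[0]
    by_ref = sorted(
        blocks, key=lambda b: (b.placement[ref][0], b.placement[ref][1].start)
    )
    local_id = {b.block_id: i for i, b in enumerate(by_ref, start=1)}
    by_sp = sorted(blocks, key=lambda b: b.placement[species][1].start)
    if len({b.block_id for b in by_sp}) != len(by_sp):
        raise ValidationError(f"duplicate block on {species} {chrom}")
    elems = tuple(
        local_id[b.block_id] * (b.placement[species][2] * b.placement[ref][2])
        for b in by_sp
    )
    return SignedPermutation(elems)


def assign_elements(
    blocks: Iterable[SyntenyBlock],
    reference_element_labels: Mapping[str, str],
    reference_species: str | None = None,
    mosaic_threshold: float = 0.10,
) -> ElementMap:
    """Assign each non-reference arm to the ancestral element providing
    the majority of its block span; a secondary element above
    ``mosaic_threshold`` flags the arm as a mosaic."""
    blocks = list(blocks)
    if not blocks:
        return ElementMap(calls={})
    species = sorted(blocks[0].placement)
    ref = reference_species or species[0]

    span_votes: dict[tuple[str, str], dict[str, int]] = {}
    for b in blocks:
        ref_chrom = b.placement[ref][0]
        element = reference_element_labels.get(ref_chrom)
        if element is None:
            raise ValidationError(f"reference chromosome {ref_chrom!r} has no element label")
        for sp in species:
            chrom, iv, _ = b.placement[sp]
            votes = span_votes.setdefault((sp, chrom), {})
            votes[element] = votes.get(element, 0) + len(iv)

    calls = {}
    for (sp, arm), votes in sorted(span_votes.items()):
        total = sum(votes.values())
        fractions = {e: v / total for e, v in votes.items()}
        ranked = sorted(fractions.items(), key=lambda kv: (-kv[1], kv[0]))
        top_element, top_frac = ranked[0]
        if top_frac <= 0.5:
            logger.warning("arm %s/%s: no majority element (%s)", sp, arm, fractions)
            element = None
        else:
            element = top_element
        mosaic = len(ranked) > 1 and ranked[1][1] >= mosaic_threshold
        calls[(sp, arm)] = ElementCall(
            species=sp,
            arm=arm,
            element=element,
            vote_fraction=top_frac,
            mosaic=mosaic,
            fractions=fractions,
        )
    return ElementMap(calls=calls)


def _chromosome_of(arm: str) -> str:
    return arm[:-1] if arm and arm[-1] in "pq" else arm


def arm_associations(element_map: ElementMap, species: str) -> set[frozenset]:
    """Unordered element pairs carried by the two-armed chromosomes of
    one species."""
    by_chrom: dict[str, list[str]] = {}
    for (sp, arm), call in element_map.calls.items():
        if sp != species or call.element is None:
            continue
        by_chrom.setdefault(_chromosome_of(arm), []).append(call.element)
    return {
        frozenset(elems) for elems in by_chrom.values() if len(elems) == 2
    }


def detect_arm_associations(
    element_map: ElementMap,
) -> tuple[dict[str, set[frozenset]], list[TranslocationEvent]]:
    """Element pairings per species plus the whole-arm translocation
    events implied by pairings that differ between species."""
    species = sorted({sp for sp, _ in element_map.calls})
    assoc = {sp: arm_associations(element_map, sp) for sp in species}
    events = []
    for i, sa in enumerate(species):
        for sb in species[i + 1 :]:
            lost = assoc[sa] - assoc[sb]
            gained = assoc[sb] - assoc[sa]
            if lost or gained:
                fmt = lambda pairs: tuple(
                    sorted("+".join(sorted(p)) for p in pairs)
                )
                events.append(
                    TranslocationEvent(
                        species_a=sa, species_b=sb, lost=fmt(lost), gained=fmt(gained)
                    )
                )
    return assoc, events
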