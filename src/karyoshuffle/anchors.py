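"""Non-overlapping, orientation-signed anchor points.

Per-species ortholog hits are reduced to anchors shared by every species:
single-copy filtering first, then de-duplication of overlapping
orthologs. Orthologs whose intervals overlap (or are bookended, gap 0)
somewhere are merged into one anchor only when their order and relative
orientation agree in every species; conflicting overlap groups are
discarded entirely and logged - a conservative policy, since partial
overlaps cannot be polarized without an aligner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError
from .io_formats import GenomicInterval, OrthologHit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnchorPoint:
    """One ortholog-derived marker placed in every species."""

    anchor_id: str
    members: tuple[str, ...]
    placement: dict  # species -> (chrom, GenomicInterval, sign)

    @property
    def n_members(self) -> int:
        return len(self.members)


def filter_single_copy(
    hits: Iterable[OrthologHit], species_list: Sequence[str]
) -> list[OrthologHit]:
    """Keep orthologs that are single-copy with exactly one placement in
    every listed species; everything else is dropped."""
    species_list = list(species_list)
    by_og: dict[str, dict[str, list[OrthologHit]]] = {}
    seen_species = set()
    for h in hits:
        seen_species.add(h.species)
        by_og.setdefault(h.ortholog_id, {}).setdefault(h.species, []).append(h)
    missing = [s for s in species_list if s not in seen_species]
    if missing:
        raise ValidationError(f"no hits at all for species: {missing}")
    kept: list[OrthologHit] = []
    for og in sorted(by_og):
        placements = by_og[og]
        ok = all(
            len(placements.get(s, [])) == 1
            and placements[s][0].copy_status == "single"
            for s in species_list
        )
        if ok:
            kept.extend(placements[s][0] for s in species_list)
    return kept


def _hit_index(hits: Iterable[OrthologHit]):
    by_og: dict[str, dict[str, OrthologHit]] = {}
    for h in hits:
        by_og.setdefault(h.ortholog_id, {})[h.species] = h
    species = sorted({s for m in by_og.values() for s in m})
    bad = [og for og, m in by_og.items() if set(m) != set(species)]
    if bad:
        raise ValidationError(
            f"hits are not single-copy-filtered; incomplete orthologs: {sorted(bad)[:5]}"
        )
    return by_og, species


def build_anchors(
    hits: Iterable[OrthologHit],
    discarded: list | None = None,
) -> list[AnchorPoint]:
    """Merge overlapping orthologs into non-overlapping anchors.

    Two orthologs conflict-free merge when, in every species, they sit on
    the same chromosome, overlap or are adjacent, and keep a consistent
    relative order and orientation. Groups violating this are dropped
    (appended to ``discarded`` when given, and logged). Anchors inherit
    the union interval per species and a sign consistent with the member
    order; by construction surviving anchors never overlap.
    """
    by_og, species = _hit_index(hits)
    canonical = species[0]
    ogs = sorted(by_og)

    # overlap-or-adjacent graph across all species
    graph = nx.Graph()
    graph.add_nodes_from(ogs)
    for sp in species:
        placed = sorted(ogs, key=lambda og: (by_og[og][sp].chrom, by_og[og][sp].interval.start))
        cluster_rep, cluster_chrom, cluster_end = None, None, -1
        for og in placed:
            h = by_og[og][sp]
            if h.chrom == cluster_chrom and h.interval.start <= cluster_end:
                graph.add_edge(cluster_rep, og)
                cluster_end = max(cluster_end, h.interval.end)
            else:
                cluster_rep, cluster_chrom, cluster_end = og, h.chrom, h.interval.end

    anchors: list[AnchorPoint] = []
    for comp in nx.connected_components(graph):
        members = sorted(comp)
        if len(members) == 1:
            og = members[0]
            placement = {
                sp: (h.chrom, h.interval, h.sign)
                for sp, h in ((sp, by_og[og][sp]) for sp in species)
            }
            anchors.append(AnchorPoint(anchor_id="", members=(og,), placement=placement))
            continue
        merged = _try_merge(members, by_og, species, canonical)
        if merged is None:
            if discarded is not None:
                discarded.append(tuple(members))
            logger.warning(
                "discarding inconsistent overlap group: %s", ",".join(members)
            )
        else:
            anchors.append(merged)

    # stable ids ordered along the canonical species
    anchors.sort(
        key=lambda a: (a.placement[canonical][0], a.placement[canonical][1].start)
    )
    return [
        AnchorPoint(anchor_id=f"a{i:05d}", members=a.members, placement=a.placement)
        for i, a in enumerate(anchors, start=1)
    ]


def _try_merge(members, by_og, species, canonical) -> AnchorPoint | None:
    order_c = sorted(
        members, key=lambda og: by_og[og][canonical].interval.start
    )
    sign_c = {og: by_og[og][canonical].sign for og in members}
    placement = {}
    for sp in species:
        hits_sp = {og: by_og[og][sp] for og in members}
        chroms = {h.chrom for h in hits_sp.values()}
        if len(chroms) != 1:
            return None
        order_s = sorted(members, key=lambda og: hits_sp[og].interval.start)
        # contiguity: no positive gap anywhere along the member chain
        max_end = hits_sp[order_s[0]].interval.end
        for b in order_s[1:]:
            if hits_sp[b].interval.start > max_end:
                return None
            max_end = max(max_end, hits_sp[b].interval.end)
        flips = {og: hits_sp[og].sign * sign_c[og] for og in members}
        if len(set(flips.values())) != 1:
            return None
        flip = flips[order_c[0]]
        expected = order_c if flip == 1 else list(reversed(order_c))
        if order_s != expected:
            return None
        start = min(h.interval.start for h in hits_sp.values())
        end = max(h.interval.end for h in hits_sp.values())
        chrom = chroms.pop()
        placement[sp] = (
            chrom,
            GenomicInterval(chrom, start, end, label="+".join(order_c)),
            flip * sign_c[order_c[0]],
        )
    return AnchorPoint(anchor_id="", members=tuple(order_c), placement=placement)


def anchors_as_hits(anchors: Iterable[AnchorPoint]) -> list[OrthologHit]:
    """View anchors as single-copy hits (e.g. to feed them back through
    the builder; the operation is idempotent)."""
    out = []
    for a in anchors:
        for sp, (chrom, interval, sign) in a.placement.items():
            out.append(
                OrthologHit(
                    ortholog_id=a.anchor_id or "+".join(a.members),
                    species=sp,
                    chrom=chrom,
                    interval=interval,
                    sign=sign,
                    copy_status="single",
                )
            )
    return out
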