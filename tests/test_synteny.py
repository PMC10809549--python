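import pytest

from karyoshuffle.anchors import AnchorPoint, build_anchors, filter_single_copy
from karyoshuffle.errors import ValidationError
from karyoshuffle.io_formats import GenomicInterval, dataframe_to_hits
from karyoshuffle.rearrangements import inversion_distance
from karyoshuffle.synteny import (
    SyntenyConfig,
    assign_elements,
    chain_blocks,
    detect_arm_associations,
    signed_permutation,
)
from karyoshuffle.synthetic_data import simulate_rearranged_genomes

SPECIES = ["spA", "spB"]


def anchor(aid, a_start, b_start, length=10_000, sign_b=1, chrom_b="c1", order_b=None):
    """Two-species anchor; spA at a_start on c1, spB at b_start (or
    order_b) on chrom_b with relative sign sign_b."""
    b_start = b_start if order_b is None else order_b
    return AnchorPoint(
        anchor_id=aid,
        members=(aid,),
        placement={
            "spA": ("c1", GenomicInterval("c1", a_start, a_start + length), 1),
            "spB": (chrom_b, GenomicInterval(chrom_b, b_start, b_start + length), sign_b),
        },
    )


class TestChainBlocks:
    def test_collinear_anchors_chain(self):
        anchors = [anchor(f"a{i}", i * 110_000, i * 110_000) for i in range(3)]
        blocks = chain_blocks(anchors, SyntenyConfig(reference_species="spA"))
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 3

    def test_summed_gap_over_budget_breaks_chain(self):
        # per-species gap 400 kb; summed over two species = 800 kb > 750 kb
        anchors = [anchor("a0", 0, 0), anchor("a1", 410_000, 410_000)]
        blocks = chain_blocks(
            anchors, SyntenyConfig(gap_metric="sum_over_species", reference_species="spA")
        )
        assert blocks == []  # two singleton runs, both below min_anchors

    def test_max_gap_metric_allows_the_same_pair(self):
        anchors = [anchor("a0", 0, 0), anchor("a1", 410_000, 410_000)]
        blocks = chain_blocks(
            anchors, SyntenyConfig(gap_metric="max_over_species", reference_species="spA")
        )
        assert len(blocks) == 1

    def test_orientation_conflict_breaks_chain(self):
        anchors = [anchor("a0", 0, 0), anchor("a1", 20_000, 20_000, sign_b=-1)]
        assert chain_blocks(anchors, SyntenyConfig(reference_species="spA")) == []

    def test_different_chromosome_breaks_chain(self):
        anchors = [anchor("a0", 0, 0), anchor("a1", 20_000, 20_000, chrom_b="c2")]
        assert chain_blocks(anchors, SyntenyConfig(reference_species="spA")) == []

    def test_jointly_reversed_run_chains_with_negative_sign(self):
        anchors = [
            anchor("a0", 0, 0, sign_b=-1, order_b=200_000),
            anchor("a1", 20_000, 0, sign_b=-1, order_b=100_000),
            anchor("a2", 40_000, 0, sign_b=-1, order_b=0),
        ]
        blocks = chain_blocks(anchors, SyntenyConfig(reference_species="spA"))
        assert len(blocks) == 1
        assert blocks[0].placement["spB"][2] == -1

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValidationError):
            chain_blocks([anchor("a0", 0, 0)], SyntenyConfig(reference_species="nope"))

    def test_gap_budget_monotonicity(self, tree):
        tables, _ = simulate_rearranged_genomes(12, tree, inversions_per_branch=2, seed=8)
        hits = [h for df in tables.values() for h in dataframe_to_hits(df)]
        anchors = build_anchors(filter_single_copy(hits, list(tree.species)))
        counts = []
        for gap in (40_000, 200_000, 750_000, 2_000_000):
            blocks = chain_blocks(
                anchors,
                SyntenyConfig(max_total_gap=gap, reference_species=tree.species[0]),
            )
            counts.append(sum(b.n_anchors for b in blocks))
        assert counts == sorted(counts)

    def test_anchors_partition_into_blocks(self, tree):
        tables, _ = simulate_rearranged_genomes(10, tree, inversions_per_branch=1, seed=3)
        hits = [h for df in tables.values() for h in dataframe_to_hits(df)]
        anchors = build_anchors(filter_single_copy(hits, list(tree.species)))
        blocks = chain_blocks(anchors, SyntenyConfig(reference_species=tree.species[0]))
        ids = [aid for b in blocks for aid in b.anchor_ids]
        assert len(ids) == len(set(ids))  # every anchor in at most one block


class TestSignedPermutation:
    def pipeline_blocks(self, tree, seed=5):
        tables, truth = simulate_rearranged_genomes(
            12, tree, inversions_per_branch=1, seed=seed
        )
        hits = [h for df in tables.values() for h in dataframe_to_hits(df)]
        anchors = build_anchors(filter_single_copy(hits, list(tree.species)))
        return (
            chain_blocks(anchors, SyntenyConfig(reference_species=tree.species[0])),
            truth,
        )

    def test_reference_reads_identity(self, tree):
        blocks, _ = self.pipeline_blocks(tree)
        p = signed_permutation(blocks, tree.species[0], "1p", tree.species[0])
        assert tuple(p) == tuple(range(1, len(p) + 1))

    def test_empty_input_gives_empty_permutation(self):
        assert tuple(signed_permutation([], "spA", "c9")) == ()

    def test_pipeline_distance_matches_truth(self, tree):
        blocks, truth = self.pipeline_blocks(tree)
        ref = tree.species[0]
        for sp in tree.species[1:]:
            p = signed_permutation(blocks, sp, "1p", ref)
            expected = inversion_distance(
                truth.species_orders[sp]["1p"], truth.species_orders[ref]["1p"]
            )
            assert inversion_distance(p) == expected

    def test_duplicate_block_rejected(self, tree):
        blocks, _ = self.pipeline_blocks(tree)
        with pytest.raises(ValidationError):
            signed_permutation(blocks + [blocks[0]], tree.species[0], "1p", tree.species[0])


class TestElements:
    def make_blocks(self, fractions, arm="2p"):
        """Blocks on spB arm drawing their span from reference chroms with
        the given element labels."""
        from karyoshuffle.synteny import SyntenyBlock

        blocks = []
        offset = 0
        for i, (ref_chrom, length) in enumerate(fractions, start=1):
            blocks.append(
                SyntenyBlock(
                    block_id=i,
                    anchor_ids=(f"a{i}",),
                    placement={
                        "spA": (ref_chrom, GenomicInterval(ref_chrom, 0, length), 1),
                        "spB": (arm, GenomicInterval(arm, offset, offset + length), 1),
                    },
                )
            )
            offset += length + 1000
        return blocks

    def test_unanimous_span_assigns_element(self):
        blocks = self.make_blocks([("X", 100_000), ("X", 50_000)])
        emap = assign_elements(blocks, {"X": "e3"}, reference_species="spA")
        call = emap.calls[("spB", "2p")]
        assert (call.element, call.vote_fraction, call.mosaic) == ("e3", 1.0, False)

    def test_secondary_element_flags_mosaic(self):
        blocks = self.make_blocks([("X", 60_000), ("Y", 40_000)])
        emap = assign_elements(blocks, {"X": "e2", "Y": "e4"}, reference_species="spA")
        call = emap.calls[("spB", "2p")]
        assert call.element == "e2" and call.mosaic
        assert call.vote_fraction == pytest.approx(0.6)

    def test_even_split_is_unassigned(self):
        blocks = self.make_blocks([("X", 50_000), ("Y", 50_000)])
        emap = assign_elements(blocks, {"X": "e2", "Y": "e4"}, reference_species="spA")
        assert emap.calls[("spB", "2p")].element is None


class TestArmAssociations:
    def run_sim(self, tree, seed, trans):
        tables, truth = simulate_rearranged_genomes(
            5, tree, inversions_per_branch=0,
            translocations_per_branch=trans, seed=seed,
        )
        hits = [h for df in tables.values() for h in dataframe_to_hits(df)]
        anchors = build_anchors(filter_single_copy(hits, list(tree.species)))
        blocks = chain_blocks(anchors, SyntenyConfig(reference_species=tree.species[0]))
        ref_labels = dict(truth.species_arms[tree.species[0]])
        emap = assign_elements(blocks, ref_labels, reference_species=tree.species[0])
        return detect_arm_associations(emap), truth

    def test_identical_karyotypes_produce_no_events(self, tree):
        (assoc, events), _ = self.run_sim(tree, seed=1, trans=0)
        assert events == []
        assert all(assoc[sp] == assoc[tree.species[0]] for sp in tree.species)

    def test_planted_exchanges_recovered_exactly(self, tree):
        for seed in range(5):
            (assoc, events), truth = self.run_sim(
                tree, seed=seed,
                trans={"Cx_quinquefasciatus": 1, "cherry1": 1},
            )
            for sp in tree.species:
                expected = {
                    frozenset(arms) for arms in truth.species_pairing[sp].values()
                }
                assert assoc[sp] == expected
            assert events  # differing pairings were reported
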