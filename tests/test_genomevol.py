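"""Intron phases, duplicated-block detection, duplication typing."""
import pytest

from genefam.errors import ValidationError
from genefam.genomevol import (
    GeneLocus,
    GeneModel,
    classify_duplication,
    find_duplicated_blocks,
    intron_phases,
    rank_loci,
)
from genefam.simulate import LayoutSpec, simulate_genome_layout

from tests import _oracles


def two_exon_gene(cds1: int, cds2: int, utr5: int = 50, utr3: int = 50) -> GeneModel:
    e1 = (1, utr5 + cds1)
    e2 = (e1[1] + 101, e1[1] + 100 + cds2 + utr3)
    return GeneModel("g", "s1", "+", (e1, e2), (cds1, cds2))


class TestIntronPhases:
    @pytest.mark.parametrize(
        "cds1,cds2,expected", [(300, 300, 0), (100, 200, 1), (200, 100, 2), (99, 501, 0)]
    )
    def test_phase_is_upstream_cds_mod_3(self, cds1, cds2, expected):
        assert intron_phases(two_exon_gene(cds1, cds2)) == [expected]

    def test_utr_only_introns_flagged(self):
        model = GeneModel(
            "g", "s1", "+",
            ((1, 100), (201, 500), (601, 700)),
            (0, 300, 0),
        )
        assert intron_phases(model) == [None, None]

    def test_cds_length_must_be_codon_multiple(self):
        with pytest.raises(ValidationError):
            intron_phases(two_exon_gene(100, 201))

    def test_two_exon_genes_with_codon_aligned_first_exon_are_phase_zero(self):
        """Two-exon genes whose first coding exon ends on a codon boundary
        all report intron phase 0 (the family-wide pattern)."""
        for cds1 in (3, 300, 501, 999):
            assert intron_phases(two_exon_gene(cds1, 303)) == [0]


class TestRanking:
    def test_ranks_are_per_scaffold_permutations(self):
        loci = rank_loci(
            [
                GeneLocus("b", "s1", 500, 600, "+"),
                GeneLocus("a", "s1", 100, 200, "-"),
                GeneLocus("c", "s2", 50, 80, "+"),
            ]
        )
        assert loci["a"].rank == 0 and loci["b"].rank == 1 and loci["c"].rank == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            rank_loci(
                [GeneLocus("a", "s1", 1, 2, "+"), GeneLocus("a", "s2", 1, 2, "+")]
            )


def grid_loci(n_scaffolds=2, genes=30):
    out = []
    for s in range(n_scaffolds):
        for k in range(genes):
            out.append(
                GeneLocus(f"s{s}g{k}", f"s{s}", 100 + 1000 * k, 900 + 1000 * k, "+")
            )
    return rank_loci(out)


class TestBlockDetection:
    def test_three_anchor_block_found(self):
        """Homologs at ranks (2,5,9) vs (3,7,11) chain into one block."""
        loci = grid_loci()
        homologs = [("s0g2", "s1g3"), ("s0g5", "s1g7"), ("s0g9", "s1g11")]
        blocks = find_duplicated_blocks(loci, homologs)
        assert len(blocks) == 1
        assert blocks[0].anchors == (
            ("s0g2", "s1g3"), ("s0g5", "s1g7"), ("s0g9", "s1g11")
        )

    def test_two_anchors_are_not_enough(self):
        loci = grid_loci()
        blocks = find_duplicated_blocks(
            loci, [("s0g2", "s1g3"), ("s0g5", "s1g7")]
        )
        assert blocks == []

    def test_window_bound_splits_distant_anchors(self):
        loci = grid_loci(genes=80)
        homologs = [("s0g0", "s1g0"), ("s0g5", "s1g5"), ("s0g40", "s1g40")]
        assert find_duplicated_blocks(loci, homologs) == []

    def test_input_order_invariance(self, rng):
        loci = grid_loci(genes=60)
        homologs = [("s0g2", "s1g3"), ("s0g5", "s1g7"), ("s0g9", "s1g11"),
                    ("s0g30", "s1g30"), ("s0g33", "s1g35"), ("s0g40", "s1g41")]
        base = find_duplicated_blocks(loci, homologs)
        for _ in range(5):
            perm = [homologs[i] for i in rng.permutation(len(homologs))]
            assert find_duplicated_blocks(loci, perm) == base

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValidationError):
            find_duplicated_blocks(grid_loci(), [("s0g2", "nope")])

    def test_equals_exhaustive_oracle_on_random_layouts(self, rng):
        """Detection equals naive label-propagation + chain enumeration."""
        for trial in range(25):
            n = int(rng.integers(5, 25))
            genes = 200
            loci = grid_loci(2, genes)
            ranks = rng.integers(0, genes, size=(n, 2))
            homologs = [(f"s0g{a}", f"s1g{b}") for a, b in ranks]
            blocks = find_duplicated_blocks(loci, homologs, window=15)
            anchor_list = sorted({(int(a), int(b)) for a, b in ranks})
            expected = _oracles.oracle_blocks(anchor_list, window=15)
            got = [
                frozenset(
                    anchor_list.index((loci[ga].rank, loci[gb].rank))
                    for ga, gb in blk.anchors
                )
                for blk in blocks
            ]
            assert sorted(got, key=sorted) == sorted(expected, key=sorted)

    def test_reported_blocks_satisfy_their_invariants(self):
        loci, homologs, _ = simulate_genome_layout(LayoutSpec(n_blocks=3, n_scaffolds=10), seed=2)
        for blk in find_duplicated_blocks(loci, homologs):
            assert len(blk.anchors) >= 3
            assert blk.scaffold_a != blk.scaffold_b
            ranks_a = [loci[a].rank for a, _ in blk.anchors]
            ranks_b = [loci[b].rank for _, b in blk.anchors]
            assert ranks_a == sorted(ranks_a)
            for i in range(len(ranks_a) - 1):
                assert ranks_a[i + 1] - ranks_a[i] <= 15
                assert abs(ranks_b[i + 1] - ranks_b[i]) <= 15


class TestDuplicationTyping:
    def test_adjacent_same_scaffold_is_tandem(self):
        loci = grid_loci()
        call = classify_duplication(("s0g4", "s0g5"), [], loci)
        assert call.dup_type == "tandem"

    def test_block_anchor_is_wgd(self):
        loci = grid_loci()
        homologs = [("s0g2", "s1g3"), ("s0g5", "s1g7"), ("s0g9", "s1g11")]
        blocks = find_duplicated_blocks(loci, homologs)
        call = classify_duplication(("s0g5", "s1g7"), blocks, loci)
        assert call.dup_type == "WGD"

    def test_distant_same_scaffold_pair_is_dispersed(self):
        loci = grid_loci(genes=60)
        call = classify_duplication(("s0g0", "s0g45"), [], loci)
        assert call.dup_type == "dispersed"

    def test_partition_every_pair_gets_exactly_one_type(self):
        loci, homologs, truth = simulate_genome_layout(LayoutSpec(), seed=5)
        blocks = find_duplicated_blocks(loci, homologs)
        for pair in homologs:
            call = classify_duplication(pair, blocks, loci)
            assert call.dup_type in {"tandem", "WGD", "dispersed"}

    def test_missing_gene_rejected(self):
        with pytest.raises(ValidationError):
            classify_duplication(("s0g0", "nope"), [], grid_loci())


class TestPlantedLayouts:
    def test_planted_blocks_recovered_exactly(self):
        for seed in range(5):
            spec = LayoutSpec(n_blocks=2, n_tandem=2, n_decoys=1)
            loci, homologs, truth = simulate_genome_layout(spec, seed=seed)
            blocks = find_duplicated_blocks(loci, homologs)
            assert sorted(tuple(b.anchors) for b in blocks) == sorted(truth.blocks)

    def test_decoy_chains_produce_no_blocks(self):
        spec = LayoutSpec(n_blocks=0, n_tandem=0, n_decoys=3, n_scaffolds=8)
        loci, homologs, truth = simulate_genome_layout(spec, seed=9)
        assert find_duplicated_blocks(loci, homologs) == []

    def test_truth_calls_recovered(self):
        loci, homologs, truth = simulate_genome_layout(LayoutSpec(), seed=13)
        blocks = find_duplicated_blocks(loci, homologs)
        for pair in truth.tandem_pairs:
            assert classify_duplication(pair, blocks, loci).dup_type == "tandem"
        for chain in truth.blocks:
            for pair in chain:
                assert classify_duplication(pair, blocks, loci).dup_type == "WGD"

    def test_determinism(self):
        a = simulate_genome_layout(LayoutSpec(), seed=21)
        b = simulate_genome_layout(LayoutSpec(), seed=21)
        assert a[1] == b[1] and a[2] == b[2]


class TestGff3Input:
    def test_gene_features_become_ranked_loci(self, tmp_path):
        from genefam.io import read_gff3_loci

        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "s1\tsrc\tgene\t100\t1099\t.\t+\t.\tID=gA\n"
            "s1\tsrc\tgene\t2100\t3099\t.\t-\t.\tID=gB\n"
            "s2\tsrc\tgene\t50\t900\t.\t+\t.\tID=gC\n"
        )
        loci = read_gff3_loci(gff)
        assert loci["gA"].rank == 0 and loci["gB"].rank == 1
        assert loci["gB"].strand == "-"
        assert loci["gC"].scaffold == "s2" and loci["gC"].rank == 0
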