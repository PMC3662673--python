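"""Disparity index, Monte-Carlo homogeneity test and branch-length spread."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import heterogeneity as het
from mitocomp.model import AlignmentBlock
from mitocomp.synthetic_data import TreeSpec, generate_tree


class TestCompleteDeletion:
    def test_identity_without_gaps(self):
        block = AlignmentBlock(taxa=["a", "b"], rows=["ACGT", "ACGT"])
        assert het.complete_deletion(block).rows == block.rows

    def test_all_gap_row_leaves_nothing(self):
        block = AlignmentBlock(taxa=["a", "b"], rows=["ACGT", "----"])
        with pytest.raises(ValueError):
            het.complete_deletion(block)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce_column_filter(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa, n_cols = int(rng.integers(2, 6)), int(rng.integers(1, 30))
        chars = rng.choice(list("ACGT-N"), size=(n_taxa, n_cols),
                           p=[0.2, 0.2, 0.2, 0.2, 0.1, 0.1])
        rows = ["".join(r) for r in chars]
        block = AlignmentBlock(taxa=[f"t{i}" for i in range(n_taxa)], rows=rows)
        keep = [c for c in range(n_cols)
                if all(r[c] in "ACGT" for r in rows)]
        if not keep:
            with pytest.raises(ValueError):
                het.complete_deletion(block)
            return
        expected = ["".join(r[c] for c in keep) for r in rows]
        assert het.complete_deletion(block).rows == expected


class TestSelectPartition:
    def _toy(self):
        block = AlignmentBlock(taxa=["a", "b"],
                               rows=["ACGTACGTA", "ACGTACGTA"])
        return block, [1, 2, 3, 1, 2, 3, 1, 2, 3]

    def test_pcg1_selects_first_positions(self):
        block, pm = self._toy()
        out = het.select_partition(block, pm, "PCG1")
        assert out.rows[0] == "ATG"  # columns 0, 3, 6

    def test_pcg123_is_identity(self):
        block, pm = self._toy()
        assert het.select_partition(block, pm, "PCG123").rows == block.rows

    def test_pcg12_cardinality(self):
        block, pm = self._toy()
        n12 = het.select_partition(block, pm, "PCG12").n_cols
        n1 = het.select_partition(block, pm, "PCG1").n_cols
        n2 = het.select_partition(block, pm, "PCG2").n_cols
        assert n12 == n1 + n2

    def test_pcg12r_appends_rrna(self):
        block, pm = self._toy()
        rrna = AlignmentBlock(taxa=["a", "b"], rows=["AATT", "AATT"])
        out = het.select_partition(block, pm, "PCG12R", rrna=rrna)
        assert out.n_cols == 6 + 4

    def test_unknown_partition_rejected(self):
        block, pm = self._toy()
        with pytest.raises(ValueError):
            het.select_partition(block, pm, "PCG4")


class TestCompositionDistance:
    def test_identical(self):
        assert het.composition_distance("ACGT", "ACGT") == (0.0, 0)

    def test_maximal_directional_bias(self):
        dc, nd = het.composition_distance("AAAA", "TTTT")
        assert (dc, nd) == (4.0, 4)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bruteforce_oracle_and_dc_le_nd(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 100))
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = "".join(rng.choice(list("ACGT"), size=n))
        dc, nd = het.composition_distance(a, b)
        assert nd == sum(x != y for x, y in zip(a, b))
        assert dc == pytest.approx(
            0.5 * sum(abs(a.count(x) - b.count(x)) for x in "ACGT"))
        assert dc <= nd + 1e-9


class TestIdTest:
    def test_identical_sequences_degenerate(self):
        r = het.id_test("ACGT" * 10, "ACGT" * 10, seed=0)
        assert (r.id, r.p_value) == (0.0, 1.0)

    def test_directional_pair_significant(self):
        a = "A" * 50 + "CGCG" * 200
        b = "T" * 50 + "CGCG" * 200
        r = het.id_test(a, b, replicates=1000, seed=1)
        assert r.dc == r.nd == 50
        assert r.p_value < 0.01 and r.significant

    def test_null_monte_carlo_matches_per_site_coin_flips(self):
        """The grouped-binomial sampler must agree in distribution with the
        literal per-site direction swap."""
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), size=300))
        b = "".join(rng.choice(list("ACGT"), size=300))
        m = het._pair_type_counts(a, b)
        grouped = het._null_dc_samples(m, 4000, np.random.default_rng(3))
        # literal resampling
        diffs = [(x, y) for x, y in zip(a, b) if x != y]
        lit = []
        r2 = np.random.default_rng(4)
        for _ in range(4000):
            counts = dict.fromkeys("ACGT", 0)
            for x, y in diffs:
                if r2.random() < 0.5:
                    x, y = y, x
                counts[x] += 1
                counts[y] -= 1
            lit.append(0.5 * sum(abs(v) for v in counts.values()))
        assert np.mean(grouped) == pytest.approx(np.mean(lit), rel=0.05)
        assert np.std(grouped) == pytest.approx(np.std(lit), rel=0.10)

    def test_replicate_floor_enforced(self):
        with pytest.raises(ValueError):
            het.id_test("ACGT", "ACGA", replicates=10, seed=0)


class TestPairwiseMatrix:
    def test_pair_count(self, outlier_alignment):
        block, pm, _ = outlier_alignment
        m = het.pairwise_id_matrix(block, replicates=100, seed=0,
                                   position_map=pm, spec="PCG123")
        assert len(m) == 55

    def test_taxon_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        rows = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(4)]
        b1 = AlignmentBlock(taxa=["t1", "t2", "t3", "t4"], rows=rows)
        perm = [2, 0, 3, 1]
        b2 = AlignmentBlock(taxa=[b1.taxa[i] for i in perm],
                            rows=[rows[i] for i in perm])
        m1 = het.pairwise_id_matrix(b1, replicates=200, seed=9)
        m2 = het.pairwise_id_matrix(b2, replicates=200, seed=9)
        assert m1.keys() == m2.keys()
        for k in m1:
            assert m1[k].id == pytest.approx(m2[k].id)
            assert m1[k].p_value == pytest.approx(m2[k].p_value)


class TestTaxonSummaryAndRanking:
    def test_hand_set_ids(self):
        mk = lambda pair, val: het.DisparityResult(
            pair=pair, usable_sites=10, nd=1, dc=val, e_dc_null=0.0, id=val,
            p_value=0.5, replicates=100, seed=0, significant=False)
        matrix = {("A", "B"): mk(("A", "B"), 1.0),
                  ("A", "C"): mk(("A", "C"), 2.0),
                  ("B", "C"): mk(("B", "C"), 3.0)}
        summ = {s.taxon: s for s in het.taxon_id_summary(matrix)}
        assert summ["A"].sum_id == pytest.approx(3.0)
        assert summ["A"].mean_id == pytest.approx(1.5)
        assert summ["C"].sum_id == pytest.approx(5.0)

    def test_rank_partitions_orders_by_grand_mean(self):
        s = lambda v: [het.TaxonIDSummary("t", v, v, 1, 0)]
        ranked = het.rank_partitions({"P_hi": s(2.0), "P_lo": s(0.5)})
        assert [name for name, _, _ in ranked] == ["P_lo", "P_hi"]

    def test_equal_means_tie_flag(self):
        s = lambda v: [het.TaxonIDSummary("t", v, v, 1, 0)]
        ranked = het.rank_partitions({"X": s(1.0), "Y": s(1.0)})
        assert [r[0] for r in ranked] == ["X", "Y"]
        assert ranked[1][2] is True


def brute_force_depths(newick: str) -> dict[str, float]:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    out = {}
    for leaf in tree.leaf_node_iter():
        total = 0.0
        node = leaf
        while node.parent_node is not None:
            total += node.edge.length
            node = node.parent_node
        out[leaf.taxon.label] = total
    return out


class TestTipDepths:
    def test_ultrametric_toy(self):
        depths = {t.taxon: t.depth
                  for t in het.tip_depths("((A:1,B:1):1,C:2):0;")}
        assert depths == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_uneven_toy(self):
        depths = {t.taxon: t.depth
                  for t in het.tip_depths("((A:1,B:3):1,C:2):0;")}
        assert depths["B"] == 4.0

    def test_missing_length_rejected(self):
        with pytest.raises(ValueError):
            het.tip_depths("((A:1,B):1,C:2):0;")

    def test_basal_polytomy_rejected(self):
        with pytest.raises(ValueError):
            het.tip_depths("(A:1,B:1,C:1):0;")

    def test_reroot_on_outgroup(self):
        depths = {t.taxon: t.depth
                  for t in het.tip_depths("(A:1,B:1,C:4):0;", root_on="C")}
        assert depths["C"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_path_sums(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        mult = tuple(float(m) for m in rng.uniform(0.5, 3.0, size=n))
        newick, truth = generate_tree(TreeSpec(n_tips=n, multipliers=mult,
                                               seed=seed))
        got = {t.taxon: t.depth for t in het.tip_depths(newick)}
        oracle = brute_force_depths(newick)
        for taxon in oracle:
            assert got[taxon] == pytest.approx(oracle[taxon])
            assert got[taxon] == pytest.approx(truth["targets"][taxon],
                                               abs=1e-6)


class TestDepthHeterogeneity:
    def test_ultrametric_cv_zero(self):
        tips = het.tip_depths("((A:1,B:1):1,C:2):0;")
        out = het.depth_heterogeneity(tips)
        assert out["cv"] == pytest.approx(0.0)
        assert out["max_min_ratio"] == pytest.approx(1.0)

    def test_planted_long_branch_group_maximal(self):
        mult = tuple([1.0] * 7 + [3.0])
        newick, _ = generate_tree(TreeSpec(n_tips=8, multipliers=mult, seed=2))
        tips = het.tip_depths(newick)
        groups = {f"taxon{i:02d}": ("long" if i == 7 else "short")
                  for i in range(8)}
        out = het.depth_heterogeneity(tips, groups=groups)
        assert out["group_means"]["long"] > out["group_means"]["short"]
        assert out["max_min_ratio"] == pytest.approx(3.0)
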