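"""Twin-domain TCDS scores: signs, decay, linearity, brute-force oracles."""

import math

import numpy as np
import pytest

from tests.conftest import random_gene_table
from topochron.core import (
    CircularGenome,
    ExpressionMatrix,
    GeneRecord,
    GeneTable,
    circular_distance,
)
from topochron.tcds import (
    TCDSParams,
    contribution_sign,
    group_mean_tcds,
    partition_thirds,
    tcds_at_gene,
    tcds_matrix,
)

L = 100_000


def naive_tcds(focal, genes, expr_col, params, length):
    """All-pairs oracle: enumerate every neighbor without the range cutoff
    and zero the terms with d > range_bp."""
    p = focal.start if focal.strand == "+" else focal.end - 1
    total = 0.0
    for n in genes:
        if n.gene_id == focal.gene_id:
            continue
        if n.start <= p < n.end:
            continue
        d_start = min((p - n.start) % length, (n.start - p) % length)
        d_end = min((p - (n.end - 1)) % length, ((n.end - 1) - p) % length)
        if d_start <= d_end:
            facing, d = n.start, d_start
        else:
            facing, d = n.end - 1, d_end
        five_prime = n.start if n.strand == "+" else n.end - 1
        sign = -1.0 if facing == five_prime else 1.0
        term = sign * expr_col.get(n.gene_id, 0.0) * math.exp(-d / params.decay_bp)
        if d > params.range_bp:
            term = 0.0
        total += term
    return total


class TestContributionSign:
    def test_divergent_neighbor_gives_negative(self):
        # focal promoter at 5000; minus-strand neighbor upstream: its 5'
        # end (3999) faces the promoter -> negative supercoils arrive
        neighbor = GeneRecord("n", 0, 4000, "-")
        assert contribution_sign(5000, neighbor, L) == -1

    def test_tandem_neighbor_pointing_at_promoter_gives_positive(self):
        neighbor = GeneRecord("n", 0, 4000, "+")
        assert contribution_sign(5000, neighbor, L) == +1

    def test_mirror_image_same_sign(self):
        # reflect the divergent configuration around the promoter: the
        # neighbor now lies downstream with its 5' end still facing
        neighbor = GeneRecord("n", 6001, 10_001, "+")
        assert contribution_sign(5000, neighbor, L) == -1
        neighbor = GeneRecord("n", 6001, 10_001, "-")
        assert contribution_sign(5000, neighbor, L) == +1

    def test_promoter_inside_neighbor_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            contribution_sign(2000, GeneRecord("n", 0, 4000, "+"), L)


class TestTcdsAtGene:
    def make_genes(self, *records):
        return GeneTable(records, L)

    def test_empty_neighborhood_is_zero(self):
        focal = GeneRecord("f", 50_000, 51_000, "+")
        far = GeneRecord("n", 0, 1000, "+")
        genes = self.make_genes(focal, far)
        assert tcds_at_gene(focal, genes, {"n": 5.0}) == 0.0

    def test_adjacent_divergent_neighbor_at_zero_distance(self):
        # neighbor's 5' end exactly at the focal promoter - 0 bp: weight 1
        focal = GeneRecord("f", 5000, 6000, "+")
        neighbor = GeneRecord("n", 1000, 5000, "-")
        genes = self.make_genes(focal, neighbor)
        d = circular_distance(5000, 4999, L)
        expected = -3.0 * math.exp(-d / 2500.0)
        assert tcds_at_gene(focal, genes, {"n": 3.0}) == pytest.approx(expected)

    def test_balanced_flanks_cancel(self):
        focal = GeneRecord("f", 10_000, 11_000, "+")
        left = GeneRecord("a", 5000, 9000, "-")   # 5' at 8999 -> -1, d=1001
        right = GeneRecord("b", 12_001, 16_001, "-")  # 3' at 12001 -> +1, d=2001
        genes = self.make_genes(focal, left, right)
        score = tcds_at_gene(focal, genes, {"a": 2.0, "b": 2.0})
        # left: facing end 8999 is 5' of minus gene -> -1 at d=1001
        # right: facing end 12001 is 3' of minus gene -> +1 at d=2001
        expected = (-2.0 * math.exp(-1001 / 2500.0)
                    + 2.0 * math.exp(-2001 / 2500.0))
        assert score == pytest.approx(expected)

    def test_exact_cancellation_of_symmetric_pair(self):
        focal = GeneRecord("f", 10_000, 11_000, "+")
        left = GeneRecord("a", 5000, 9000, "-")    # -1 at d = 1001
        right = GeneRecord("b", 11_001, 15_001, "-")  # 3' end at 11001 -> +1 at d = 1001
        genes = self.make_genes(focal, left, right)
        score = tcds_at_gene(focal, genes, {"a": 2.0, "b": 2.0})
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_promoter_inside_neighbor_skipped(self):
        focal = GeneRecord("f", 2000, 3000, "+")  # promoter 2000 inside n
        inside = GeneRecord("n", 1000, 4000, "+")
        genes = self.make_genes(focal, inside)
        assert tcds_at_gene(focal, genes, {"n": 9.0}) == 0.0

    def test_matches_all_pairs_oracle_random_instances(self, rng):
        params = TCDSParams()
        for trial in range(30):
            length = int(rng.integers(30_000, 100_000))
            genes = random_gene_table(rng, length, int(rng.integers(5, 40)))
            if len(genes) < 2:
                continue
            expr = {g.gene_id: float(rng.random() * 10) for g in genes}
            focal = genes[int(rng.integers(0, len(genes)))]
            got = tcds_at_gene(focal, genes, expr, params, length)
            want = naive_tcds(focal, genes, expr, params, length)
            assert got == pytest.approx(want, abs=1e-9)


class TestTcdsMatrix:
    def build(self, rng, n_genes=20, n_t=5, length=60_000):
        genes = random_gene_table(rng, length, n_genes)
        values = rng.random((len(genes), n_t)) * 10
        expr = ExpressionMatrix(genes.gene_ids, np.arange(n_t) * 10.0, values)
        return genes, expr

    def test_zero_expression_gives_zero_matrix(self, rng):
        genes, expr = self.build(rng)
        zero = ExpressionMatrix(expr.gene_ids, expr.timepoints,
                                np.zeros_like(expr.values))
        assert np.all(tcds_matrix(genes, zero).values == 0.0)

    def test_linearity_under_scaling(self, rng):
        genes, expr = self.build(rng)
        base = tcds_matrix(genes, expr).values
        scaled = ExpressionMatrix(expr.gene_ids, expr.timepoints,
                                  expr.values * 3.5)
        assert np.allclose(tcds_matrix(genes, scaled).values, base * 3.5)

    def test_missing_gene_in_table_rejected(self, rng):
        genes, expr = self.build(rng)
        bad = ExpressionMatrix(expr.gene_ids + ["ghost"], expr.timepoints,
                               np.vstack([expr.values, np.ones(5)]))
        with pytest.raises(ValueError, match="ghost"):
            tcds_matrix(genes, bad)

    def test_matches_per_cell_oracle(self, rng):
        genes, expr = self.build(rng, n_genes=50, n_t=4)
        params = TCDSParams()
        mat = tcds_matrix(genes, expr, params)
        for j in range(4):
            col = {g: expr.values[i, j] for i, g in enumerate(expr.gene_ids)}
            for i, gid in enumerate(expr.gene_ids):
                want = naive_tcds(genes.get(gid), genes, col, params,
                                  genes.genome_length)
                assert mat.values[i, j] == pytest.approx(want, abs=1e-9)

    def test_locality_far_perturbation_leaves_curve_unchanged(self, rng):
        # perturbing a gene farther than range_bp from every promoter in a
        # set cannot move that set's mean curve
        length = 200_000
        records = [GeneRecord(f"g{i}", s, s + 500, "+")
                   for i, s in enumerate(range(0, 20_000, 2000))]
        far = GeneRecord("far", 100_000, 100_500, "+")
        genes = GeneTable(records + [far], length)
        ids = genes.gene_ids
        values = rng.random((len(ids), 3)) * 5
        expr1 = ExpressionMatrix(ids, [0.0, 10.0, 20.0], values)
        values2 = values.copy()
        values2[ids.index("far")] *= 100
        expr2 = ExpressionMatrix(ids, [0.0, 10.0, 20.0], values2)
        close_set = [f"g{i}" for i in range(10)]
        c1 = group_mean_tcds(tcds_matrix(genes, expr1), close_set)
        c2 = group_mean_tcds(tcds_matrix(genes, expr2), close_set)
        assert np.array_equal(c1.values, c2.values)


class TestPartitionThirds:
    def genome(self, length=9000):
        return CircularGenome("ACGT" * (length // 4), 0, length // 2)

    def table(self, n, length=9000):
        spacing = length // (n + 1)
        return GeneTable(
            [GeneRecord(f"g{i}", i * spacing, i * spacing + 10, "+")
             for i in range(n)], length)

    def test_exact_division(self):
        parts = partition_thirds(self.table(9), self.genome())
        assert [len(parts[k]) for k in ("ori", "mid", "ter")] == [3, 3, 3]

    def test_remainder_goes_to_ori_then_mid(self):
        parts = partition_thirds(self.table(10), self.genome())
        assert [len(parts[k]) for k in ("ori", "mid", "ter")] == [4, 3, 3]
        parts = partition_thirds(self.table(11), self.genome())
        assert [len(parts[k]) for k in ("ori", "mid", "ter")] == [4, 4, 3]

    def test_extreme_genes_in_extreme_sets(self):
        genome = self.genome()
        parts = partition_thirds(self.table(9), genome)
        assert "g0" in parts["ori"]          # promoter at ori
        # most distant promoter belongs to ter
        from topochron.thermo import gene_ori_distance
        t = self.table(9)
        far = max(t, key=lambda g: gene_ori_distance(g, genome)).gene_id
        assert far in parts["ter"]

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            partition_thirds(self.table(2), self.genome())


class TestGroupMeanTcds:
    def test_singleton_returns_row(self, rng):
        genes = random_gene_table(rng, 50_000, 10)
        expr = ExpressionMatrix(genes.gene_ids, [0.0, 10.0],
                                rng.random((len(genes), 2)))
        mat = tcds_matrix(genes, expr)
        gid = genes.gene_ids[0]
        assert np.array_equal(group_mean_tcds(mat, [gid]).values, mat.row(gid))

    def test_thirds_decompose_global_mean(self, rng, small_bundle):
        b = small_bundle
        mat = tcds_matrix(b.genes, b.expression)
        parts = partition_thirds(b.genes, b.genome)
        total = np.zeros_like(mat.timepoints)
        for ids in parts.values():
            total = total + group_mean_tcds(mat, ids).values * len(ids)
        assert np.allclose(total / len(b.genes), mat.values.mean(axis=0))

    def test_empty_set_rejected(self, rng):
        genes = random_gene_table(rng, 50_000, 5)
        expr = ExpressionMatrix(genes.gene_ids, [0.0],
                                rng.random((len(genes), 1)))
        with pytest.raises(ValueError, match="empty"):
            group_mean_tcds(tcds_matrix(genes, expr), [])
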