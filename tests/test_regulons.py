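import numpy as np
import pytest

from hemoconcord import (
    ClusterLabeling,
    NormMatrix,
    RegulonSet,
    aucell_score,
    differential_activity,
    rank_genes_per_cell,
)
from hemoconcord.io import ValidationError
from hemoconcord.regulons import ActivityMatrix


def norm_from(values):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return NormMatrix(values, [f"c{i}" for i in range(n)], [f"g{i}" for i in range(g)])


def brute_force_auc(rank_of_gene: dict, regulon_genes, G, top_fraction):
    """Oracle: build the recovery step curve explicitly and integrate."""
    T = int(np.ceil(top_fraction * G))
    curve = [sum(1 for g in regulon_genes if rank_of_gene[g] <= x) for x in range(1, T + 1)]
    area = sum(curve)
    best = [min(x, len(regulon_genes)) for x in range(1, T + 1)]
    return area / sum(best)


class TestRanking:
    def test_strictly_decreasing_is_identity(self):
        values = np.arange(10, 0, -1)[None, :].astype(float)
        ranking = rank_genes_per_cell(norm_from(values), seed=0)
        np.testing.assert_array_equal(ranking.ranks[0], np.arange(1, 11))

    def test_all_zero_cell_follows_permutation(self):
        values = np.zeros((1, 10))
        ranking = rank_genes_per_cell(norm_from(values), seed=3)
        # gene at permutation position k gets rank k+1
        expected = np.empty(10, dtype=int)
        expected[ranking.permutation] = np.arange(1, 11)
        np.testing.assert_array_equal(ranking.ranks[0], expected)

    def test_tie_block_consecutive_in_permutation_order(self):
        values = np.array([[5.0, 1.0, 1.0, 1.0, 9.0]])
        ranking = rank_genes_per_cell(norm_from(values), seed=1)
        r = ranking.ranks[0]
        assert r[4] == 1 and r[0] == 2
        assert sorted(r[1:4]) == [3, 4, 5]
        tied = [1, 2, 3]
        perm_order = [g for g in ranking.permutation if g in tied]
        ranks_in_perm_order = [r[g] for g in perm_order]
        assert ranks_in_perm_order == sorted(ranks_in_perm_order)

    def test_deterministic(self, rng):
        values = rng.poisson(1, (5, 20)).astype(float)
        r1 = rank_genes_per_cell(norm_from(values), seed=9)
        r2 = rank_genes_per_cell(norm_from(values), seed=9)
        np.testing.assert_array_equal(r1.ranks, r2.ranks)


class TestAucell:
    def test_all_targets_on_top_score_one(self):
        values = np.array([[9.0, 8.0, 7.0] + [0.0] * 17])
        ranking = rank_genes_per_cell(norm_from(values), seed=0)
        rs = RegulonSet({"R": {"g0", "g1", "g2"}})
        act = aucell_score(ranking, rs, top_fraction=0.25)
        assert act.values.loc["R"].iloc[0] == pytest.approx(1.0)

    def test_no_target_in_top_fraction_scores_zero(self):
        values = np.array([[float(20 - i) for i in range(20)]])
        ranking = rank_genes_per_cell(norm_from(values), seed=0)
        rs = RegulonSet({"R": {"g18", "g19"}})  # ranks 19, 20
        act = aucell_score(ranking, rs, top_fraction=0.25)
        assert act.values.loc["R"].iloc[0] == 0.0

    def test_worked_example_g20(self):
        """G=20, threshold 5, targets at ranks 2 and 4."""
        values = np.array([[float(20 - i) for i in range(20)]])  # identity ranking
        ranking = rank_genes_per_cell(norm_from(values), seed=0)
        rs = RegulonSet({"R": {"g1", "g3"}})
        act = aucell_score(ranking, rs, top_fraction=0.25)
        # recovery curve over x=1..5: [0,1,1,2,2] -> area 6; max curve
        # [1,2,2,2,2] -> area 9
        assert act.values.loc["R"].iloc[0] == pytest.approx(6 / 9)

    def test_matches_brute_force_oracle(self, rng):
        """Vectorized AUC equals explicit step-curve integration on random
        instances with G <= 50."""
        for trial in range(30):
            G = int(rng.integers(10, 51))
            n_cells = int(rng.integers(1, 5))
            values = rng.poisson(2, (n_cells, G)).astype(float)
            norm = norm_from(values)
            ranking = rank_genes_per_cell(norm, seed=trial)
            m = int(rng.integers(1, min(8, G)))
            targets = set(rng.choice([f"g{i}" for i in range(G)], m, replace=False))
            top_fraction = float(rng.uniform(0.05, 0.5))
            act = aucell_score(ranking, RegulonSet({"R": targets}), top_fraction)
            for ci in range(n_cells):
                rank_of = {f"g{g}": ranking.ranks[ci, g] for g in range(G)}
                oracle = brute_force_auc(rank_of, targets, G, top_fraction)
                assert act.values.loc["R"].iloc[ci] == pytest.approx(oracle, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        values = rng.uniform(0.1, 5, (4, 30))
        r1 = rank_genes_per_cell(norm_from(values), seed=2)
        r2 = rank_genes_per_cell(norm_from(np.sqrt(values)), seed=2)
        rs = RegulonSet({"R": {"g3", "g11", "g20"}})
        a1 = aucell_score(r1, rs, 0.2)
        a2 = aucell_score(r2, rs, 0.2)
        np.testing.assert_allclose(a1.values.to_numpy(), a2.values.to_numpy())

    def test_absent_targets_warn_empty_errors(self, rng):
        values = rng.poisson(1, (2, 10)).astype(float)
        ranking = rank_genes_per_cell(norm_from(values), seed=0)
        with pytest.warns(UserWarning, match="absent"):
            aucell_score(ranking, RegulonSet({"R": {"g1", "nope"}}), 0.3)
        with pytest.raises(ValidationError):
            aucell_score(ranking, RegulonSet({"R": {"nope"}}), 0.3)


def activity_from(values, regulons=("R",)):
    import pandas as pd

    n = values.shape[1]
    df = pd.DataFrame(values, index=list(regulons), columns=[f"c{i}" for i in range(n)])
    return ActivityMatrix(values=df, top_fraction=0.05, tie_seed=0)


class TestDifferentialActivity:
    def test_identical_distribution_z_zero(self):
        act = activity_from(np.tile([0.3], (1, 12)))
        lab = ClusterLabeling({f"c{i}": ("A" if i < 6 else "B") for i in range(12)})
        res = differential_activity(act, lab)
        row = res.table[(res.table.regulon == "R") & (res.table.cluster == "A")].iloc[0]
        assert row["U"] == pytest.approx(18.0)
        assert row["z"] == 0.0 and not row["selected"]

    def test_fully_separated_5v5_exact(self):
        vals = np.array([[0.9, 0.8, 0.85, 0.95, 0.87, 0.1, 0.2, 0.15, 0.12, 0.18]])
        act = activity_from(vals)
        lab = ClusterLabeling({f"c{i}": ("A" if i < 5 else "B") for i in range(10)})
        res = differential_activity(act, lab)
        row = res.table[(res.table.regulon == "R") & (res.table.cluster == "A")].iloc[0]
        assert row["U"] == 25.0
        assert row["p_exact"] == pytest.approx(2 / 252)
        assert row["z"] > 0

    def test_selection_rule(self):
        """z just above 2 selects, just below does not; sign orients to the
        cluster."""
        rng = np.random.default_rng(0)
        base = rng.normal(0.5, 0.1, 60)
        shifted = base.copy()
        shifted[:20] += 0.08
        act = activity_from(shifted[None, :])
        lab = ClusterLabeling({f"c{i}": ("A" if i < 20 else "B") for i in range(60)})
        res = differential_activity(act, lab, z_threshold=2.0)
        t = res.table.set_index("cluster")
        assert t.loc["A", "z"] == pytest.approx(-t.loc["B", "z"])
        assert t.loc["A", "selected"] == (abs(t.loc["A", "z"]) > 2)

    def test_degenerate_cluster_rejected(self):
        act = activity_from(np.random.default_rng(1).uniform(0, 1, (1, 10)))
        lab = ClusterLabeling({f"c{i}": ("A" if i < 2 else "B") for i in range(10)})
        with pytest.raises(ValidationError):
            differential_activity(act, lab)

    def test_z_matrix_rows_clustered(self, rng):
        vals = rng.uniform(0, 1, (5, 30))
        act = activity_from(vals, regulons=[f"R{i}" for i in range(5)])
        lab = ClusterLabeling({f"c{i}": f"K{i % 3}" for i in range(30)})
        res = differential_activity(act, lab)
        assert set(res.z_matrix.index) == {f"R{i}" for i in range(5)}
        assert res.z_matrix.shape == (5, 3)
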