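import numpy as np
import pandas as pd
import pytest

from hemoconcord import (
    ClusterLabeling,
    NormMatrix,
    annotate_best_match,
    correlate,
    identify_hemocyte_cluster,
    pseudo_transcriptome,
    specific_signature,
)
from hemoconcord.io import ValidationError
from hemoconcord.pseudobulk import PseudoTranscriptome


def norm_from(values, genes=None):
    values = np.asarray(values, dtype=float)
    n, g = values.shape
    return NormMatrix(
        values, [f"c{i}" for i in range(n)], genes or [f"g{i}" for i in range(g)]
    )


def pseudo_from(df):
    return PseudoTranscriptome(values=df, cell_counts={c: 1 for c in df.columns})


class TestPseudoTranscriptome:
    def test_hand_computed_means(self):
        values = np.log1p(np.array([[1.0, 2.0], [3.0, 0.0], [5.0, 4.0]]))
        norm = norm_from(values)
        lab = ClusterLabeling({"c0": "A", "c1": "A", "c2": "B"})
        pt = pseudo_transcriptome(norm, lab)
        np.testing.assert_allclose(pt.values["A"], [2.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(pt.values["B"], [5.0, 4.0], atol=1e-12)
        assert pt.cell_counts == {"A": 2, "B": 1}

    def test_single_cell_column_equals_cell(self):
        values = np.log1p(np.array([[1.0, 7.0], [2.0, 3.0]]))
        norm = norm_from(values)
        lab = ClusterLabeling({"c0": "A", "c1": "B"})
        pt = pseudo_transcriptome(norm, lab)
        np.testing.assert_allclose(pt.values["B"], [2.0, 3.0], atol=1e-12)

    def test_identical_cells_identical_columns(self):
        values = np.tile(np.log1p([1.0, 2.0, 3.0]), (6, 1))
        norm = norm_from(values)
        lab = ClusterLabeling({f"c{i}": f"S{i%3}" for i in range(6)})
        pt = pseudo_transcriptome(norm, lab)
        assert pt.values.nunique(axis=1).max() == 1


class TestCorrelate:
    def test_identical_column_r_one(self, rng):
        base = pd.DataFrame({"A": rng.uniform(0, 10, 20)}, index=[f"g{i}" for i in range(20)])
        ref = base.rename(columns={"A": "R1"}).assign(R2=rng.uniform(0, 10, 20))
        ct = correlate(pseudo_from(base), pseudo_from(ref))
        assert ct.r.loc["A", "R1"] == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        genes = [f"g{i}" for i in range(5)]
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        # anti-correlated on the log1p scale used for r
        q = pd.DataFrame({"Q": np.expm1(x)}, index=genes)
        r = pd.DataFrame({"R": np.expm1(x.max() - x)}, index=genes)
        ct = correlate(pseudo_from(q), pseudo_from(r))
        assert ct.r.loc["Q", "R"] == pytest.approx(-1.0)

    def test_matches_closed_form(self, rng):
        genes = [f"g{i}" for i in range(100)]
        q = pd.DataFrame({"Q": rng.uniform(0, 50, 100)}, index=genes)
        r = pd.DataFrame({"R": rng.uniform(0, 50, 100)}, index=genes)
        ct = correlate(pseudo_from(q), pseudo_from(r))
        x, y = np.log1p(q["Q"]), np.log1p(r["R"])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert ct.r.loc["Q", "R"] == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self, rng):
        genes = [f"g{i}" for i in range(30)]
        a = pd.DataFrame(rng.uniform(0, 10, (30, 2)), index=genes, columns=["A1", "A2"])
        b = pd.DataFrame(rng.uniform(0, 10, (30, 3)), index=genes, columns=["B1", "B2", "B3"])
        fwd = correlate(pseudo_from(a), pseudo_from(b))
        rev = correlate(pseudo_from(b), pseudo_from(a))
        np.testing.assert_allclose(fwd.r.to_numpy(), rev.r.to_numpy().T, atol=1e-12)

    def test_gene_order_invariance(self, rng):
        genes = [f"g{i}" for i in range(30)]
        a = pd.DataFrame({"A": rng.uniform(0, 10, 30)}, index=genes)
        b = pd.DataFrame({"B": rng.uniform(0, 10, 30)}, index=genes)
        shuffled = a.sample(frac=1, random_state=0)
        r1 = correlate(pseudo_from(a), pseudo_from(b)).r.iloc[0, 0]
        r2 = correlate(pseudo_from(shuffled), pseudo_from(b)).r.iloc[0, 0]
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_too_few_shared_genes(self):
        a = pd.DataFrame({"A": [1.0, 2.0]}, index=["g1", "g2"])
        b = pd.DataFrame({"B": [1.0, 2.0]}, index=["g1", "g9"])
        with pytest.raises(ValidationError, match="shared genes"):
            correlate(pseudo_from(a), pseudo_from(b))

    def test_zero_variance_reported_nan(self, rng):
        genes = [f"g{i}" for i in range(10)]
        a = pd.DataFrame({"A": np.ones(10)}, index=genes)
        b = pd.DataFrame({"B": rng.uniform(0, 5, 10)}, index=genes)
        with pytest.warns(UserWarning, match="zero-variance"):
            ct = correlate(pseudo_from(a), pseudo_from(b))
        assert np.isnan(ct.r.loc["A", "B"])


class TestAnnotate:
    def test_single_reference(self):
        ct_df = pd.DataFrame({"R1": [0.7]}, index=["Q"])
        from hemoconcord.pseudobulk import CorrelationTable

        res = annotate_best_match(CorrelationTable(r=ct_df, n_genes=10))
        assert res.loc[0, "reference"] == "R1"
        assert np.isnan(res.loc[0, "margin"])

    def test_tie_break_lexicographic_and_flagged(self):
        from hemoconcord.pseudobulk import CorrelationTable

        ct_df = pd.DataFrame({"R2": [0.5], "R1": [0.5], "R3": [0.1]}, index=["Q"])
        res = annotate_best_match(CorrelationTable(r=ct_df, n_genes=10), top_k=2)
        assert list(res["reference"]) == ["R1", "R2"]
        assert res["tie"].all()

    def test_noisy_query_recovers_source(self, rng):
        """A query built from one reference subgroup plus noise ranks that
        subgroup first in >=95% of 20 seeds."""
        genes = [f"g{i}" for i in range(200)]
        ref = pd.DataFrame(
            rng.lognormal(0, 1, (200, 4)), index=genes, columns=["R1", "R2", "R3", "R4"]
        )
        hits = 0
        for seed in range(20):
            local = np.random.default_rng(seed)
            q = ref["R3"] * local.lognormal(0, 0.3, 200)
            ct = correlate(pseudo_from(pd.DataFrame({"Q": q})), pseudo_from(ref))
            res = annotate_best_match(ct, top_k=1)
            hits += res.loc[0, "reference"] == "R3"
        assert hits >= 19


class TestHemocyteIdentification:
    def test_planted_maximum(self):
        genes = ["Srp", "Hml", "Pxn", "NimC1", "He", "Crq", "Sn", "other"]
        df = pd.DataFrame(
            {"tissue1": 1.0, "tissue2": 1.0, "hemo": 10.0},
            index=genes,
        )
        df.loc["other"] = [5.0, 5.0, 5.0]
        passing, evidence = identify_hemocyte_cluster(pseudo_from(df))
        assert passing == ["hemo"]
        assert evidence.groupby("cluster")["quantile"].mean()["hemo"] == pytest.approx(1.0)

    def test_no_marker_expressed(self):
        df = pd.DataFrame({"t1": [0.0], "t2": [0.0]}, index=["Srp"])
        with pytest.warns(UserWarning):
            passing, evidence = identify_hemocyte_cluster(pseudo_from(df))
        assert passing == [] and evidence.empty

    def test_split_markers_neither_passes(self):
        genes = ["Srp", "Hml", "Pxn", "NimC1", "He", "Crq", "Sn"]
        df = pd.DataFrame({"t1": 0.0, "t2": 0.0, "t3": 0.0}, index=genes)
        df.loc[["Srp", "Hml", "Pxn"], "t1"] = 10.0
        df.loc[["NimC1", "He", "Crq", "Sn"], "t2"] = 10.0
        passing, evidence = identify_hemocyte_cluster(pseudo_from(df))
        assert passing == []
        assert set(evidence["cluster"]) == {"t1", "t2", "t3"}


class TestSpecificSignature:
    def test_identical_to_reference_empty(self, rng):
        genes = [f"g{i}" for i in range(20)]
        ref = pd.DataFrame({"R1": rng.uniform(0, 10, 20)}, index=genes)
        pct = pd.Series(1.0, index=genes)
        sig = specific_signature(ref["R1"], ref, pct)
        assert len(sig) == 0

    def test_planted_exclusive_gene(self, rng):
        genes = [f"g{i}" for i in range(20)]
        ref = pd.DataFrame({"R1": np.ones(20), "R2": np.ones(20)}, index=genes)
        q = pd.Series(1.0, index=genes)
        q["g7"] = 50.0
        sig = specific_signature(q, ref, pd.Series(1.0, index=genes))
        assert list(sig["gene"]) == ["g7"]

    def test_graded_folds_boundary_inclusive(self):
        genes = ["lo", "mid", "hi"]
        ref = pd.DataFrame({"R": [3.0, 3.0, 3.0]}, index=genes)
        # query tuned so (q+1)/(ref_max+1) is exactly 1.5, 2.0, 2.5
        q = pd.Series([5.0, 7.0, 9.0], index=genes)
        sig = specific_signature(q, ref, pd.Series(1.0, index=genes), fold_min=2.0)
        assert list(sig["gene"]) == ["hi", "mid"]

    def test_detection_filter(self):
        genes = ["a", "b"]
        ref = pd.DataFrame({"R": [1.0, 1.0]}, index=genes)
        q = pd.Series([10.0, 10.0], index=genes)
        pct = pd.Series([0.9, 0.2], index=genes)
        sig = specific_signature(q, ref, pct, detect_min=0.5)
        assert list(sig["gene"]) == ["a"]
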