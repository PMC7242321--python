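import numpy as np
import pandas as pd
import pytest

from gebvnet import (ContrastDesign, GEBVMatrix, ExpressionMatrix, RIF,
                     pca_scores, rif_overall, rif_per_trait,
                     select_contrast_by_score, select_contrast_by_trait)
from gebvnet.rif import significance_call


def _gebv(values, samples=None, traits=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{i:03d}" for i in range(values.shape[0])]
    traits = traits or [f"t{j}" for j in range(values.shape[1])]
    return GEBVMatrix(pd.DataFrame(values, index=samples, columns=traits))


class TestContrastSelection:
    def test_thirty_samples_group_fifteen_exhausts(self):
        gebv = _gebv(np.arange(30.0).reshape(-1, 1))
        d = select_contrast_by_trait(gebv, "t0", 15)
        assert sorted(d.high_samples + d.low_samples) == gebv.sample_ids

    def test_order_statistics(self):
        gebv = _gebv(np.arange(1.0, 114.0).reshape(-1, 1))
        d = select_contrast_by_trait(gebv, "t0", 15)
        ids = gebv.sample_ids
        assert sorted(d.low_samples) == ids[:15]
        assert sorted(d.high_samples) == ids[98:]

    def test_ties_broken_by_sample_id(self, caplog):
        gebv = _gebv(np.zeros((10, 1)))
        with caplog.at_level("WARNING"):
            d = select_contrast_by_trait(gebv, "t0", 3)
        assert d.low_samples == gebv.sample_ids[:3]
        assert d.high_samples == gebv.sample_ids[-3:]
        assert any("equal" in m for m in caplog.messages)

    def test_group_size_errors(self):
        gebv = _gebv(np.arange(10.0).reshape(-1, 1))
        with pytest.raises(ValueError):
            select_contrast_by_trait(gebv, "t0", 0)
        with pytest.raises(ValueError):
            select_contrast_by_trait(gebv, "t0", 6)

    def test_score_contrast_symmetry(self):
        scores = pd.Series([3.0, -3.0, 1.0, -1.0, 2.0, -2.0],
                           index=[f"s{i}" for i in range(6)])
        d = select_contrast_by_score(scores, 3)
        assert set(d.high_samples) == {"s0", "s2", "s4"}
        assert set(d.low_samples) == {"s1", "s3", "s5"}

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ContrastDesign("x", ["a", "b"], ["b", "c"])


class TestPCAScores:
    def test_all_identical_samples_give_zero_scores(self):
        gebv = _gebv(np.tile([1.0, 2.0, 3.0], (5, 1)))
        assert (pca_scores(gebv) == 0).all()

    def test_single_trait_proportional_to_standardized_gebv(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(12)
        gebv = _gebv(x.reshape(-1, 1))
        s = pca_scores(gebv)
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(s.to_numpy(), z, atol=1e-10)

    def test_matches_independent_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 3))
        gebv = _gebv(X)
        s = pca_scores(gebv)
        # oracle: standardize, eigendecompose np.corrcoef, weighted PC-score sum
        Z = (X - X.mean(0)) / X.std(0)
        vals, vecs = np.linalg.eig(np.corrcoef(X, rowvar=False))
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order].real, vecs[:, order].real
        for j in range(3):
            if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
                vecs[:, j] *= -1
        expected = (Z @ vecs) @ (vals / vals.sum())
        np.testing.assert_allclose(s.to_numpy(), expected, atol=1e-8)

    def test_invariant_to_positive_affine_trait_rescaling(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 4))
        base = pca_scores(_gebv(X))
        Y = X * np.array([2.0, 0.5, 10.0, 1.0]) + np.array([5.0, -3.0, 0.0, 100.0])
        np.testing.assert_allclose(pca_scores(_gebv(Y)).to_numpy(),
                                   base.to_numpy(), atol=1e-9)

    def test_partially_constant_columns_rejected(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        with pytest.raises(ValueError, match="constant trait"):
            pca_scores(_gebv(X))

    def test_eigenvalue_weight_mode(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((15, 3))
        prop = pca_scores(_gebv(X), "proportion")
        raw = pca_scores(_gebv(X), "eigenvalue")
        # weights differ by the constant trace (= number of traits)
        np.testing.assert_allclose(raw.to_numpy(), 3.0 * prop.to_numpy(), atol=1e-9)


def _rif_inputs(n_cand=6, n=30, seed=0, n_traits=1):
    rng = np.random.default_rng(seed)
    samples = [f"s{i:02d}" for i in range(n)]
    cand = pd.DataFrame(rng.standard_normal((n_cand, n)),
                        index=[f"c{i}" for i in range(n_cand)], columns=samples)
    targ = pd.DataFrame(rng.standard_normal((n, n_traits)), index=samples,
                        columns=[f"t{j}" for j in range(n_traits)])
    design = ContrastDesign("t0", samples[:n // 2], samples[n // 2:])
    return cand, targ, design


class TestRIFScores:
    def test_symmetric_groups_give_exact_zero_raws(self):
        # identical target pattern and candidate pattern in both groups:
        # group means equal and within-group correlations equal -> RIF1=RIF2=0
        pattern = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        samples = [f"h{i}" for i in range(5)] + [f"l{i}" for i in range(5)]
        cand = pd.DataFrame(
            np.vstack([np.r_[pattern, pattern], np.r_[pattern * 2, pattern * 2],
                       np.r_[pattern[::-1], pattern[::-1]]]),
            index=["c0", "c1", "c2"], columns=samples)
        targ = pd.DataFrame({"t0": np.r_[pattern, pattern]}, index=samples)
        design = ContrastDesign("t0", samples[:5], samples[5:])
        table = RIF(cand, targ, design).fit().table
        assert (table["rif1_raw"] == 0).all()
        assert (table["rif2_raw"] == 0).all()
        assert not table["significant"].any()

    def test_z_columns_standardized(self):
        cand, targ, design = _rif_inputs(n_cand=40, seed=5)
        table = RIF(cand, targ, design).fit().table
        for col in ("rif1_z", "rif2_z"):
            assert abs(table[col].mean()) < 1e-9
            assert abs(table[col].std(ddof=0) - 1.0) < 1e-9

    def test_significance_boundary_inclusive(self):
        z = pd.Series([1.96, 1.95, -1.96, -1.95, 0.0])
        calls = significance_call(z, pd.Series([0.0] * 5))
        assert list(calls) == [True, False, True, False, False]

    def test_candidate_permutation_equivariance(self):
        cand, targ, design = _rif_inputs(n_cand=10, seed=6)
        t1 = RIF(cand, targ, design).fit().table.set_index("candidate_id")
        perm = cand.sample(frac=1, random_state=1)
        t2 = RIF(perm, targ, design).fit().table.set_index("candidate_id")
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_group_swap_negates_raws_keeps_significance(self):
        cand, targ, design = _rif_inputs(n_cand=12, seed=7)
        res = RIF(cand, targ, design).fit().table
        swapped = ContrastDesign(design.label, design.low_samples, design.high_samples)
        res2 = RIF(cand, targ, swapped).fit().table
        np.testing.assert_allclose(res2["rif1_raw"], -res["rif1_raw"], atol=1e-12)
        np.testing.assert_allclose(res2["rif2_raw"], -res["rif2_raw"], atol=1e-12)
        assert list(res2["significant"]) == list(res["significant"])

    def test_null_significance_fraction_in_sanity_band(self):
        # empirically standardized z-scores: loose band, not normal quantiles
        total = sig = 0
        for seed in range(200):
            cand, targ, design = _rif_inputs(n_cand=50, seed=seed)
            table = RIF(cand, targ, design).fit().table
            sig += int((table["rif1_z"].abs() >= 1.96).sum())
            total += len(table)
        frac = sig / total
        assert 0.005 <= frac <= 0.15

    def test_constant_candidate_warns_and_zeroes(self, caplog):
        cand, targ, design = _rif_inputs(n_cand=5, seed=8)
        cand.iloc[0] = 3.14
        with caplog.at_level("WARNING"):
            table = RIF(cand, targ, design).fit().table
        assert any("constant" in m for m in caplog.messages)
        assert table.loc[table["candidate_id"] == "c0", "rif1_raw"].iloc[0] == 0.0

    def test_fewer_than_two_candidates_rejected(self):
        cand, targ, design = _rif_inputs(n_cand=1, seed=9)
        with pytest.raises(ValueError, match="2 candidates"):
            RIF(cand, targ, design)

    def test_small_groups_rejected(self):
        cand, targ, _ = _rif_inputs(n_cand=4, n=8)
        design = ContrastDesign("t0", [f"s{i:02d}" for i in range(2)],
                                [f"s{i:02d}" for i in range(2, 8)])
        with pytest.raises(ValueError, match="need >= 3"):
            RIF(cand, targ, design)


class TestRIFWrappers:
    def test_one_table_per_trait(self, small_dataset):
        cfg, gebv, genes, mirnas, truth = small_dataset
        expr = ExpressionMatrix(pd.concat([genes.data, mirnas.data]),
                                pd.concat([genes.feature_role, mirnas.feature_role]))
        cands = {t: list(genes.feature_ids[:10]) for t in gebv.trait_ids}
        results = rif_per_trait(cands, expr, gebv, group_size=10)
        assert set(results) == set(gebv.trait_ids)
        for res in results.values():
            assert len(res.table) == 10

    def test_trait_without_candidates_gives_empty_table(self, small_dataset, caplog):
        cfg, gebv, genes, mirnas, truth = small_dataset
        cands = {gebv.trait_ids[0]: list(genes.feature_ids[:5])}
        with caplog.at_level("WARNING"):
            results = rif_per_trait(cands, genes, gebv, group_size=10)
        assert results[gebv.trait_ids[1]].table.empty

    def test_single_trait_overall_reduces_to_per_trait_with_score_groups(self):
        rng = np.random.default_rng(12)
        n = 40
        samples = [f"s{i:02d}" for i in range(n)]
        gebv = GEBVMatrix(pd.DataFrame({"t0": rng.standard_normal(n)}, index=samples))
        expr = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((6, n)), index=[f"g{i}" for i in range(6)],
            columns=samples))
        overall, scores, design = rif_overall(expr.feature_ids, expr, gebv,
                                              group_size=10)
        # one trait: the PCA score orders samples exactly like the GEBV
        by_trait = select_contrast_by_trait(gebv, "t0", 10)
        assert set(design.high_samples) == set(by_trait.high_samples)
        direct = RIF(expr.data, gebv.data, by_trait).fit().table
        pd.testing.assert_series_equal(overall.table["rif1_raw"], direct["rif1_raw"])

    def test_planted_regulator_significant_in_overall(self, small_dataset):
        cfg, gebv, genes, mirnas, truth = small_dataset
        expr = ExpressionMatrix(pd.concat([genes.data, mirnas.data]),
                                pd.concat([genes.feature_role, mirnas.feature_role]))
        overall, _, _ = rif_overall(expr.feature_ids, expr, gebv, group_size=15)
        assert set(truth.regulator_ids) <= set(overall.significant_ids)
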