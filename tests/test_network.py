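import numpy as np
import pandas as pd
import pytest

from fluidnet.model import NetworkParams
from fluidnet.network import (
    adjacency, bicor_matrix, build_network, cluster_modules,
    compute_eigenproteins, correlate_with_traits, detect_sample_outliers,
    enforce_kme_consistency, merge_close_modules, pearson_matrix,
    tom_similarity,
)


def factor_data(rng, n_samples=40, blocks=((15, 1.0), (12, 1.0)), noise=0.3,
                n_background=0):
    """Columns grouped in factor blocks plus optional independent noise."""
    cols, names, truth = [], [], []
    for b, (size, load) in enumerate(blocks, start=1):
        z = rng.standard_normal(n_samples)
        for j in range(size):
            cols.append(load * z + noise * rng.standard_normal(n_samples))
            names.append(f"b{b}_{j}")
            truth.append(b)
    for j in range(n_background):
        cols.append(rng.standard_normal(n_samples))
        names.append(f"bg_{j}")
        truth.append(0)
    X = pd.DataFrame(np.column_stack(cols), columns=names)
    return X, pd.Series(truth, index=names)


class TestBicor:
    def test_self_and_negated(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"x": x, "neg": -x, "y": rng.standard_normal(30)})
        C = bicor_matrix(X)
        assert C.loc["x", "x"] == pytest.approx(1.0)
        assert C.loc["x", "neg"] == pytest.approx(-1.0)
        assert abs(C.loc["x", "y"]) < 0.5

    def test_close_to_pearson_on_gaussian(self, rng):
        X = pd.DataFrame(rng.standard_normal((1000, 8)))
        diff = np.abs(bicor_matrix(X).to_numpy()
                      - pearson_matrix(X).to_numpy())
        assert diff.max() < 0.05

    def test_robust_to_gross_outlier(self, rng):
        z = rng.standard_normal(20)
        x = z + 0.3 * rng.standard_normal(20)
        y = z + 0.3 * rng.standard_normal(20)
        x_dirty = x.copy()
        x_dirty[0] = 30.0
        clean_r = np.corrcoef(x[1:], y[1:])[0, 1]  # leave-outlier-out oracle
        X = pd.DataFrame({"x": x_dirty, "y": y})
        bic = bicor_matrix(X).loc["x", "y"]
        pea = pearson_matrix(X).loc["x", "y"]
        assert abs(bic - clean_r) < abs(pea - clean_r)

    def test_constant_feature_error(self):
        X = pd.DataFrame({"c": np.ones(10), "x": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            bicor_matrix(X)


class TestAdjacencyAndTom:
    def test_signed_endpoints_and_value(self):
        C = pd.DataFrame([[1.0, 0.0, -1.0], [0.0, 1.0, 1.0],
                          [-1.0, 1.0, 1.0]])
        A = adjacency(C, NetworkParams(beta=6.5))
        assert A.iloc[0, 2] == pytest.approx(0.0)
        assert A.iloc[1, 2] == pytest.approx(1.0)
        assert A.iloc[0, 1] == pytest.approx(0.5 ** 6.5)
        assert A.iloc[0, 1] == pytest.approx(0.011048, abs=1e-5)

    def test_monotone_in_correlation(self):
        params = NetworkParams(beta=6.5)
        grid = np.linspace(-1, 1, 21)
        C = pd.DataFrame(np.eye(2))
        vals = []
        for r in grid:
            C.iloc[0, 1] = C.iloc[1, 0] = r
            vals.append(adjacency(C, params).iloc[0, 1])
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_tom_complete_graph_is_one(self):
        m = 6
        A = pd.DataFrame(np.ones((m, m)))
        T = tom_similarity(A)
        np.testing.assert_allclose(T.to_numpy(), 1.0, atol=1e-12)

    def test_tom_empty_graph_is_zero(self):
        A = pd.DataFrame(np.eye(5))
        T = tom_similarity(A)
        off = T.to_numpy()[~np.eye(5, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-12)

    def test_tom_three_node_half(self):
        A = pd.DataFrame(np.full((3, 3), 0.5))
        np.fill_diagonal(A.values, 1.0)
        T = tom_similarity(A)
        # (0.25 + 0.5) / (1 + 1 - 0.5) = 0.5
        assert T.iloc[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("denom", ["mean", "min"])
    def test_tom_equals_brute_force(self, rng, denom):
        for _ in range(20):
            m = rng.integers(4, 13)
            A = rng.uniform(0, 1, (m, m))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            T = tom_similarity(pd.DataFrame(A), denom=denom).to_numpy()
            A0 = A.copy()
            np.fill_diagonal(A0, 0.0)
            k = A0.sum(axis=1)
            for i in range(m):
                for j in range(m):
                    if i == j:
                        continue
                    l = sum(A0[i, q] * A0[q, j] for q in range(m)
                            if q not in (i, j))
                    mm = (k[i] + k[j]) / 2 if denom == "mean" \
                        else min(k[i], k[j])
                    expect = (l + A0[i, j]) / (mm + 1 - A0[i, j])
                    assert abs(T[i, j] - expect) < 1e-12

    def test_tom_bounds_and_symmetry(self, rng):
        A = rng.uniform(0, 1, (15, 15))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = tom_similarity(pd.DataFrame(A)).to_numpy()
        assert (T >= -1e-12).all() and (T <= 1 + 1e-12).all()
        np.testing.assert_allclose(T, T.T, atol=1e-12)


class TestClusterModules:
    def block_diag_diss(self, sizes, within=0.3, between=1.0):
        n = sum(sizes)
        D = np.full((n, n), between)
        start = 0
        truth = []
        for b, size in enumerate(sizes, start=1):
            D[start:start + size, start:start + size] = within
            truth += [b] * size
            start += size
        np.fill_diagonal(D, 0.0)
        names = [f"f{i}" for i in range(n)]
        return pd.DataFrame(D, index=names, columns=names), \
            pd.Series(truth, index=names)

    def test_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score
        diss, truth = self.block_diag_diss([15, 12, 11])
        assign, Z = cluster_modules(diss, NetworkParams(beta=6.5))
        assert len(set(assign) - {0}) == 3
        assert adjusted_rand_score(truth, assign) == pytest.approx(1.0)

    def test_small_block_never_a_module(self):
        diss, truth = self.block_diag_diss([15, 4])
        params = NetworkParams(beta=6.5, min_module_size=10, pam_stage=False)
        assign, _ = cluster_modules(diss, params)
        small = truth.index[truth == 2]
        assert set(assign[small]) == {0}

    def test_identical_features_single_module(self):
        n = 20
        diss = pd.DataFrame(np.zeros((n, n)))
        assign, _ = cluster_modules(diss, NetworkParams(beta=6.5))
        assert len(set(assign)) == 1 and set(assign) != {0}

    def test_too_few_features_all_grey(self):
        diss = pd.DataFrame(np.zeros((4, 4)))
        assign, _ = cluster_modules(diss, NetworkParams(beta=6.5,
                                                        min_module_size=10))
        assert set(assign) == {0}


class TestEigenproteins:
    def test_identical_members(self, rng):
        v = rng.standard_normal(25)
        X = pd.DataFrame({f"a{i}": v for i in range(5)})
        assign = pd.Series(1, index=X.columns)
        eig, varex = compute_eigenproteins(X, assign)
        assert varex[1] == pytest.approx(1.0)
        r = np.corrcoef(eig[1], v)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_sign_orientation_restored_after_flip(self, rng):
        z = rng.standard_normal(30)
        X = pd.DataFrame({f"a{i}": z + 0.2 * rng.standard_normal(30)
                          for i in range(6)})
        assign = pd.Series(1, index=X.columns)
        eig1, _ = compute_eigenproteins(X, assign)
        eig2, _ = compute_eigenproteins(-X, assign)
        r1 = np.mean([np.corrcoef(eig1[1], X[c])[0, 1] for c in X])
        r2 = np.mean([np.corrcoef(eig2[1], -X[c])[0, 1] for c in X])
        assert r1 > 0 and r2 > 0

    def test_two_orthogonal_pairs_explain_half(self, rng):
        a = rng.standard_normal(400)
        b = rng.standard_normal(400)
        X = pd.DataFrame({"a1": a, "a2": a + 1e-6 * rng.standard_normal(400),
                          "b1": b, "b2": b + 1e-6 * rng.standard_normal(400)})
        assign = pd.Series(1, index=X.columns)
        _, varex = compute_eigenproteins(X, assign)
        assert varex[1] == pytest.approx(0.5, abs=0.05)

    def test_singleton_module_error(self, rng):
        X = pd.DataFrame({"a": rng.standard_normal(10)})
        with pytest.raises(ValueError, match="fewer than 2"):
            compute_eigenproteins(X, pd.Series(1, index=X.columns))


class TestKmeConsistency:
    def test_consistent_assignment_is_fixpoint(self, rng):
        X, truth = factor_data(rng)
        out, kme, conv = enforce_kme_consistency(truth.copy(), X)
        assert conv
        pd.testing.assert_series_equal(out, truth, check_names=False)

    def test_planted_swap_corrected(self, rng):
        X, truth = factor_data(rng)
        wrong = truth.copy()
        wrong.iloc[0] = 2  # b1_0 planted in block 2
        out, kme, conv = enforce_kme_consistency(wrong, X)
        assert conv and out.iloc[0] == 1

    def test_uncorrelated_label_sent_to_grey(self, rng):
        X, truth = factor_data(rng, n_background=1)
        start = truth.copy()
        start[start == 0] = 1  # force the noise label into module 1
        out, kme, conv = enforce_kme_consistency(start, X)
        assert out["bg_0"] == 0


class TestMergeCloseModules:
    def _two_module_data(self, rng, cor):
        z1 = rng.standard_normal(500)
        z2 = cor * z1 + np.sqrt(1 - cor ** 2) * rng.standard_normal(500)
        cols = {}
        for j in range(10):
            cols[f"m1_{j}"] = z1 + 1e-3 * rng.standard_normal(500)
            cols[f"m2_{j}"] = z2 + 1e-3 * rng.standard_normal(500)
        X = pd.DataFrame(cols)
        assign = pd.Series([1, 2] * 10, index=X.columns)
        return X, assign

    def test_above_threshold_merged(self, rng):
        X, assign = self._two_module_data(rng, cor=0.95)
        out = merge_close_modules(assign, X, 0.07)
        assert len(set(out)) == 1

    def test_below_threshold_kept(self, rng):
        X, assign = self._two_module_data(rng, cor=0.90)
        out = merge_close_modules(assign, X, 0.07)
        assert len(set(out)) == 2

    def test_single_module_identity(self, rng):
        X = pd.DataFrame(rng.standard_normal((20, 5)))
        assign = pd.Series(1, index=X.columns)
        out = merge_close_modules(assign, X, 0.07)
        pd.testing.assert_series_equal(out, assign)


class TestSampleOutliers:
    def test_planted_outlier_flagged(self, rng):
        # samples share a common feature profile; one is replaced by noise
        mu = rng.normal(0, 2, 40)
        X = pd.DataFrame(mu + 0.4 * rng.standard_normal((30, 40)),
                         index=[f"s{i}" for i in range(30)])
        X.iloc[0] = rng.standard_normal(40) * 2
        flagged = detect_sample_outliers(X)
        assert "s0" in flagged

    def test_null_flag_rate_low(self):
        flags = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.standard_normal((20, 30)))
            flags += len(detect_sample_outliers(X))
        assert flags / (20 * 20) < 0.05

    def test_identical_samples_not_flagged(self, rng):
        row = rng.standard_normal(10)
        X = pd.DataFrame(np.tile(row, (6, 1)) + 1e-9 * rng.standard_normal((6, 10)))
        assert detect_sample_outliers(X) == []


class TestTraitCorrelation:
    def test_perfect_trait(self, rng):
        eig = pd.DataFrame({1: rng.standard_normal(30)})
        traits = pd.DataFrame({"tau": eig[1] * 2 + 5})
        rtab, ptab, r_crit = correlate_with_traits(eig, traits)
        assert rtab.loc[1, "tau"] == pytest.approx(1.0)
        assert 0 < r_crit < 1

    def test_null_traits_calibrated(self):
        """Independent noise traits exceed the critical |r| ~5% of the time."""
        hits = total = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            eig = pd.DataFrame({m: r.standard_normal(35) for m in range(1, 5)})
            traits = pd.DataFrame({f"t{k}": r.standard_normal(35)
                                   for k in range(5)})
            rtab, ptab, r_crit = correlate_with_traits(eig, traits)
            hits += (rtab.abs() > r_crit).to_numpy().sum()
            total += rtab.size
        assert hits / total < 0.10

    def test_constant_trait_reported_nan(self, rng):
        eig = pd.DataFrame({1: rng.standard_normal(20)})
        traits = pd.DataFrame({"const": np.ones(20)}, index=eig.index)
        rtab, ptab, _ = correlate_with_traits(eig, traits)
        assert np.isnan(rtab.loc[1, "const"])


class TestBuildNetwork:
    def test_recovers_planted_blocks_with_background(self, rng):
        from sklearn.metrics import adjusted_rand_score
        X, truth = factor_data(rng, n_samples=36,
                               blocks=((15, 1.0), (14, 1.0), (12, 1.0)),
                               noise=0.35, n_background=40)
        model = build_network(X, NetworkParams(beta=6.5))
        sel = truth > 0
        assert adjusted_rand_score(truth[sel], model.assignments[sel]) > 0.9

    def test_higher_beta_sharpens_tom_contrast(self, rng):
        X, truth = factor_data(rng, n_samples=36,
                               blocks=((15, 1.0), (14, 1.0)), noise=0.35,
                               n_background=20)
        contrasts = {}
        for beta in (1.5, 11.0):
            C = bicor_matrix(X)
            T = tom_similarity(adjacency(C, NetworkParams(beta=beta)))
            within = T.loc[truth == 1, truth == 1].to_numpy()
            across = T.loc[truth == 1, truth == 2].to_numpy()
            iu = np.triu_indices_from(within, k=1)
            contrasts[beta] = within[iu].mean() / across.mean()
        assert contrasts[11.0] > contrasts[1.5]

    def test_kme_invariant_at_exit(self, rng):
        X, truth = factor_data(rng, n_samples=36,
                               blocks=((15, 1.0), (14, 1.0)), noise=0.35,
                               n_background=20)
        model = build_network(X, NetworkParams(beta=6.5))
        assert model.converged
        for label, mid in model.assignments.items():
            if mid == 0:
                continue
            own = model.kme.loc[label, mid]
            assert own >= model.kme.loc[label].max() - 1e-9
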