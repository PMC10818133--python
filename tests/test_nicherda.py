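"""pRDA stack: Hellinger transform, dbMEM, ordination, selection,
permutation inference and variance partitioning."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from reefdiverge.nicherda import (PartialRDA, adjusted_r2, build_env_matrix,
                                  dbmem, forward_select,
                                  genotype_freq_matrix, hellinger,
                                  partial_rda, permutation_test,
                                  variance_partition)
from reefdiverge.simdata import SimScenario, simulate_env, simulate_pair


class TestHellinger:
    def test_closed_forms(self):
        assert np.allclose(hellinger(np.array([[4.0, 0.0]])), [[1.0, 0.0]])
        out = hellinger(np.array([[1.0, 1.0, 2.0]]))
        assert np.allclose(out, [[0.5, 0.5, np.sqrt(0.5)]])

    def test_rows_have_unit_sum_of_squares(self):
        rng = np.random.default_rng(0)
        out = hellinger(rng.random((10, 6)))
        assert np.allclose((out**2).sum(axis=1), 1.0)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            hellinger(np.array([[0.0, 0.0]]))


class TestEnvMatrix:
    def test_standardisation_and_collinearity_drop(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        df = pd.DataFrame({"a": a, "b": a * 2 + 0.01 * rng.normal(size=50),
                           "c": rng.normal(size=50)})
        em = build_env_matrix(df)
        assert em.dropped == ["b"]
        assert np.allclose(em.data.mean(), 0, atol=1e-12)
        assert np.allclose(em.data.std(ddof=1), 1, atol=1e-12)


class TestDbmem:
    def test_truncation_equals_brute_force_mst_longest_edge(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(2)
        xy = rng.random((6, 2)) * 10
        basis = dbmem(xy)
        g = nx.Graph()
        for i in range(6):
            for j in range(i + 1, 6):
                g.add_edge(i, j, weight=float(np.linalg.norm(xy[i] - xy[j])))
        mst = nx.minimum_spanning_tree(g)
        longest = max(d["weight"] for _, _, d in mst.edges(data=True))
        assert basis.truncation == pytest.approx(longest)

    def test_eigenvectors_orthonormal(self):
        rng = np.random.default_rng(3)
        basis = dbmem(rng.random((12, 2)) * 5)
        gram = basis.vectors.T @ basis.vectors
        assert np.allclose(gram, np.eye(basis.n_vectors), atol=1e-10)
        assert (basis.eigenvalues > 0).all()

    def test_1d_transect_leading_vector_is_low_frequency_sinusoid(self):
        """On an equally spaced transect the leading eigenvectors are the
        classic sinusoidal spatial modes; the top two eigenvalues are
        nearly degenerate, so the leading vector is matched against both
        lowest-frequency modes (half-period cosine, full-period sine)."""
        n = 20
        xy = np.stack([np.arange(n, dtype=float), np.zeros(n)], axis=1)
        basis = dbmem(xy)
        j = np.arange(n)
        modes = [np.cos(np.pi * j / (n - 1)),
                 np.sin(2 * np.pi * j / (n - 1))]
        best = max(abs(np.corrcoef(basis.vectors[:, 0], m)[0, 1])
                   for m in modes)
        assert best > 0.95

    def test_duplicate_coordinates_jittered(self, caplog):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with caplog.at_level("WARNING"):
            basis = dbmem(xy)
        assert "jitter" in caplog.text
        assert basis.n_vectors >= 1


class TestPartialRDAModel:
    def _xyz(self, seed=4, n=40, effect=1.0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 3))
        Z = rng.normal(size=(n, 2))
        noise = rng.normal(size=(n, 8))
        Y = noise + effect * np.outer(X[:, 0], rng.normal(size=8))
        return Y, X, Z

    def test_empty_conditioning_equals_plain_rda(self):
        Y, X, _ = self._xyz()
        a = PartialRDA(n_perm=0).fit(Y, X, None)
        b = PartialRDA(n_perm=0).fit(Y, X, np.zeros((len(Y), 0)))
        assert a.r2_ == pytest.approx(b.r2_)
        # direct multivariate regression oracle for R^2
        Yc = Y - Y.mean(axis=0)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
        r2 = ((Xc @ beta) ** 2).sum() / (Yc**2).sum()
        assert a.r2_ == pytest.approx(r2)

    def test_axis_variances_sum_to_one(self):
        Y, X, Z = self._xyz()
        m = PartialRDA(n_perm=0).fit(Y, X, Z)
        assert m.axis_variance_.sum() == pytest.approx(1.0)
        assert m.adj_r2_ <= m.r2_

    def test_aliased_predictor_dropped(self):
        Y, X, Z = self._xyz()
        X2 = np.hstack([X, X[:, [0]]])
        m = PartialRDA(n_perm=0).fit(Y, X2, Z)
        assert len(m.selected_) == 3

    def test_null_adjusted_r2_near_zero(self):
        vals = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            Y = rng.normal(size=(40, 10))
            X = rng.normal(size=(40, 3))
            vals.append(PartialRDA(n_perm=0).fit(Y, X).adj_r2_)
        assert abs(np.mean(vals)) < 0.03

    def test_single_env_effect_recovered_on_axis1(self):
        sc = SimScenario("IM", T_total=0.0, M=0.0, n1=15, n2=15,
                         n_tags=120, theta_per_tag=0.5, seed=30)
        ds = simulate_env(simulate_pair(sc), [0.4, 0, 0, 0], n_vars=4,
                          spatial_range=2.0, seed=31, loci_per_var=60)
        Y = hellinger(genotype_freq_matrix(ds.genotypes)).to_numpy()
        X = ds.env.drop(columns=["id"])
        m = PartialRDA(n_perm=0).fit(Y, X)
        r = np.corrcoef(m.sample_scores_[:, 0], X["env1"])[0, 1]
        assert abs(r) > 0.9

    def test_vegan_oracle_agreement(self, tmp_path):
        """R's vegan is the independent oracle for the constrained
        R-squared, adjusted R-squared and pseudo-F of a plain RDA."""
        Y, X, _ = self._xyz(seed=6, n=30)
        np.savetxt(tmp_path / "Y.csv", Y, delimiter=",")
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        script = textwrap.dedent("""
            suppressMessages(library(vegan))
            Y <- as.matrix(read.csv("Y.csv", header=FALSE))
            X <- as.data.frame(read.csv("X.csv", header=FALSE))
            m <- rda(Y ~ ., data=X)
            r2 <- RsquareAdj(m)
            Fv <- anova(m, permutations=2)$F[1]
            cat(r2$r.squared, r2$adj.r.squared, Fv, sep="\\n")
        """)
        (tmp_path / "rda.R").write_text(script)
        out = subprocess.run(["Rscript", "rda.R"], cwd=tmp_path,
                             capture_output=True, text=True, check=True)
        r2_v, adj_v, F_v = map(float, out.stdout.split())
        m = PartialRDA(n_perm=0).fit(Y, X)
        assert m.r2_ == pytest.approx(r2_v, rel=1e-6)
        assert m.adj_r2_ == pytest.approx(adj_v, rel=1e-6)
        assert m.F_ == pytest.approx(F_v, rel=1e-6)


class TestPermutation:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 2))
        Y = X @ rng.normal(size=(2, 6)) + 0.01 * rng.normal(size=(30, 6))
        res = permutation_test(Y, X, n_perm=999, seed=8)
        assert res["p_value"] == pytest.approx(1 / 1000)

    def test_invariant_to_joint_row_shuffle(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(25, 5))
        X = rng.normal(size=(25, 2))
        Z = rng.normal(size=(25, 2))
        res1 = permutation_test(Y, X, Z, n_perm=99, seed=10)
        order = rng.permutation(25)
        res2 = permutation_test(Y[order], X[order], Z[order], n_perm=99,
                                seed=10)
        assert res1["p_value"] == res2["p_value"]
        assert res1["F"] == pytest.approx(res2["F"])

    def test_axis_scope_returns_per_axis_values(self):
        rng = np.random.default_rng(11)
        Y = rng.normal(size=(25, 5))
        X = rng.normal(size=(25, 2))
        res = permutation_test(Y, X, n_perm=49, seed=12, scope="axis")
        assert len(res["F"]) == 2
        assert ((res["p_value"] > 0) & (res["p_value"] <= 1)).all()


class TestForwardSelect:
    def test_alpha_one_without_r2_stop_selects_all(self):
        rng = np.random.default_rng(13)
        Y = rng.normal(size=(30, 6))
        X = pd.DataFrame(rng.normal(size=(30, 4)),
                         columns=list("abcd"))
        sel = forward_select(Y, X, alpha=1.1, r2_stop=False, n_perm=19)
        assert sorted(sel) == list("abcd")

    def test_null_selects_at_most_one_variable(self):
        """Without true effects the double-stopping rule keeps the model
        empty or near-empty in at least 90% of seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            Y = rng.normal(size=(30, 8))
            X = pd.DataFrame(rng.normal(size=(30, 5)),
                             columns=[f"v{i}" for i in range(5)])
            sel = forward_select(Y, X, alpha=0.05, n_perm=99, seed=seed)
            hits += len(sel) <= 1
        assert hits >= 18

    def test_two_true_effects_found(self):
        rng = np.random.default_rng(14)
        X = pd.DataFrame(rng.normal(size=(50, 6)),
                         columns=[f"v{i}" for i in range(6)])
        Y = (np.outer(X["v1"], rng.normal(size=8))
             + np.outer(X["v4"], rng.normal(size=8))
             + 0.3 * rng.normal(size=(50, 8)))
        sel = forward_select(Y, X, alpha=0.05, n_perm=99, seed=15)
        assert {"v1", "v4"} <= set(sel)


class TestVariancePartition:
    def test_fractions_sum_to_joint_adjusted_r2(self):
        rng = np.random.default_rng(16)
        Y = rng.normal(size=(40, 6))
        X = rng.normal(size=(40, 3))
        Z = rng.normal(size=(40, 2))
        vp = variance_partition(Y, X, Z)
        assert vp["pure_env"] + vp["pure_space"] + vp["shared"] == \
            pytest.approx(vp["adj_r2_joint"], abs=1e-10)

    def test_duplicated_predictors_fully_shared(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(40, 3))
        Y = X @ rng.normal(size=(3, 6)) + 0.2 * rng.normal(size=(40, 6))
        vp = variance_partition(Y, X, X.copy())
        assert vp["pure_env"] == pytest.approx(0.0, abs=1e-8)

    def test_uninformative_space_shares_nothing(self):
        rng = np.random.default_rng(18)
        X = rng.normal(size=(60, 2))
        Z = rng.normal(size=(60, 2))
        Y = X @ rng.normal(size=(2, 6)) + 0.1 * rng.normal(size=(60, 6))
        vp = variance_partition(Y, X, Z)
        assert abs(vp["shared"]) < 0.05
        assert vp["pure_env"] > 0.5


class TestNichePartitioningEndToEnd:
    def test_taxa_with_divergent_niches_separate_on_axis1(self):
        """Two genetically diverged taxa occupying different ends of an
        environmental gradient have well-separated axis-1 scores in the
        genotype-environment ordination (rank AUC > 0.9)."""
        sc = SimScenario("SI", T_total=1.0, n1=12, n2=12, n_tags=150,
                         theta_per_tag=0.5, seed=32)
        ds = simulate_pair(sc)
        rng = np.random.default_rng(33)
        taxon2 = np.zeros(24, dtype=bool)
        taxon2[12:] = True
        # divergent niche: variable 1 tracks taxon membership, the other
        # two are noise
        X = pd.DataFrame({
            "env1": taxon2.astype(float) + 0.3 * rng.standard_normal(24),
            "env2": rng.standard_normal(24),
            "env3": rng.standard_normal(24)})
        Y = hellinger(genotype_freq_matrix(ds.genotypes)).to_numpy()
        m = PartialRDA(n_perm=0).fit(Y, X)
        s = m.sample_scores_[:, 0]
        from scipy.stats import mannwhitneyu
        u = mannwhitneyu(s[taxon2], s[~taxon2]).statistic
        auc = u / (taxon2.sum() * (~taxon2).sum())
        assert max(auc, 1 - auc) > 0.9
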