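"""Coalescent simulator: determinism, neutral closed forms, divergence
behaviour, artefact injection and environmental fields."""

import numpy as np
import pytest

from reefdiverge.genio import MISSING
from reefdiverge.popstats import wc_fst
from reefdiverge.simdata import (SimScenario, expected_jafs_mc,
                                 inject_missing_and_clones, simulate_env,
                                 simulate_pair)


def mean_fst(model, n_reps, seed0, **kw):
    vals = []
    for s in range(n_reps):
        sc = SimScenario(model, n1=4, n2=4, n_tags=80, theta_per_tag=0.5,
                         seed=seed0 + s, **kw)
        gm = simulate_pair(sc).genotypes
        vals.append(wc_fst(gm, ("pop1", "pop2")))
    return float(np.mean(vals))


class TestDeterminism:
    def test_fixed_seed_bit_identical(self):
        sc = SimScenario("IM2M", M=2.0, M_e=0.1, Q=0.3, T_total=1.0,
                         n1=4, n2=4, n_tags=60, seed=17)
        a = simulate_pair(sc)
        b = simulate_pair(sc)
        assert np.array_equal(a.genotypes.dosages, b.genotypes.dosages)
        assert a.genotypes.site_meta.equals(b.genotypes.site_meta)
        assert np.array_equal(a.tag_classes, b.tag_classes)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            SimScenario("XX")
        with pytest.raises(ValueError):
            SimScenario("IM", n1=1)
        with pytest.raises(ValueError):
            SimScenario("IM2M", M=1.0, M_e=2.0)
        with pytest.raises(ValueError):
            SimScenario("SC", T_total=1.0, T_phase=1.5)


class TestNeutralClosedForm:
    def test_single_population_folded_sfs(self):
        """A panmictic sample's folded SFS entry i is proportional to
        1/i + 1/(2n-i); checked within 3 Monte-Carlo SEs per class."""
        sc = SimScenario("IM", M=0.0, T_total=0.0, n1=4, n2=4,
                         theta_per_tag=1.0, seed=3)
        spec = expected_jafs_mc(sc, 40_000, seed=4)
        n = 16
        agg = np.zeros(n // 2 + 1)
        se2 = np.zeros(n // 2 + 1)
        for i in range(spec.counts.shape[0]):
            for j in range(spec.counts.shape[1]):
                if not spec.mask[i, j]:
                    agg[i + j] += spec.counts[i, j]
                    se2[i + j] += spec.se[i, j] ** 2
        expected = np.zeros(n // 2 + 1)
        for c in range(1, n // 2):
            expected[c] = 1 / c + 1 / (n - c)
        expected[n // 2] = 1 / (n // 2)
        expected /= expected.sum()
        z = (agg[1:] - expected[1:]) / np.sqrt(se2[1:])
        assert np.abs(z).max() < 3.0


class TestDivergenceBehaviour:
    def test_high_migration_near_panmixia(self):
        assert mean_fst("IM", 20, 1000, M=50.0, T_total=0.5) < 0.05

    def test_long_isolation_high_fst(self):
        assert mean_fst("SI", 20, 2000, T_total=5.0) > 0.5

    def test_fst_monotone_in_migration_and_time(self):
        """Mean F_ST decreases with M and increases with T on a 3x3
        grid (Spearman trend over cell means)."""
        from scipy.stats import spearmanr

        Ms = [0.2, 1.0, 5.0]
        Ts = [0.2, 1.0, 3.0]
        grid = np.zeros((3, 3))
        for i, M in enumerate(Ms):
            for j, T in enumerate(Ts):
                grid[i, j] = mean_fst("IM", 10, 3000 + 100 * (3 * i + j),
                                      M=M, T_total=T)
        for j in range(3):
            rho, _ = spearmanr(Ms, grid[:, j])
            assert rho < 0
        for i in range(3):
            rho, _ = spearmanr(Ts, grid[i, :])
            assert rho > 0


class TestExpectedJafsMC:
    def test_zero_theta_zero_spectrum(self):
        sc = SimScenario("IM", M=1.0, T_total=1.0, n1=3, n2=3,
                         theta_per_tag=0.0, seed=5)
        spec = expected_jafs_mc(sc, 200, seed=6)
        assert spec.counts.sum() == 0.0

    def test_population_swap_transposes_spectrum(self):
        kw = dict(model_name="IM", T_total=0.8, M=1.0, theta_per_tag=1.0)
        a = expected_jafs_mc(SimScenario(nu1=2.0, nu2=1.0, n1=3, n2=4, **kw,
                                         seed=0), 30_000, seed=7)
        b = expected_jafs_mc(SimScenario(nu1=1.0, nu2=2.0, n1=4, n2=3, **kw,
                                         seed=0), 30_000, seed=8)
        bt = b.transpose()
        se = np.sqrt(a.se**2 + bt.se**2)
        z = (a.counts - bt.counts) / np.where(se > 0, se, np.inf)
        z[a.mask] = 0
        assert np.abs(z).max() < 4.0

    def test_im2m_q_zero_nests_into_im(self):
        kw = dict(nu1=1.0, nu2=1.0, T_total=1.0, M=2.0, n1=3, n2=3,
                  theta_per_tag=1.0)
        a = expected_jafs_mc(SimScenario("IM2M", M_e=0.1, Q=0.0, **kw,
                                         seed=0), 30_000, seed=9)
        b = expected_jafs_mc(SimScenario("IM", **kw, seed=0), 30_000, seed=10)
        se = np.sqrt(a.se**2 + b.se**2)
        z = (a.counts - b.counts) / np.where(se > 0, se, np.inf)
        z[a.mask] = 0
        assert np.abs(z).max() < 4.0

    def test_convergence_doubling_reps_halves_se(self):
        sc = SimScenario("IM", M=1.0, T_total=1.0, n1=4, n2=4,
                         theta_per_tag=1.0, seed=11)
        s1 = expected_jafs_mc(sc, 5_000, seed=12)
        s2 = expected_jafs_mc(sc, 20_000, seed=12)
        m = ~s1.mask & (s1.se > 0) & (s2.se > 0)
        ratio = np.mean(s2.se[m] / s1.se[m])
        assert abs(ratio - 0.5) < 0.1

    def test_matches_msprime_branch_spectrum(self):
        """Independent coalescent cross-check: the simulator's expected
        folded JAFS for an asymmetric IM history agrees with msprime's
        branch-mode joint AFS."""
        msprime = pytest.importorskip("msprime")
        nu1, nu2, M, T = 1.0, 1.5, 1.0, 0.8
        n1 = n2 = 4
        N0 = 5000
        dem = msprime.Demography()
        dem.add_population(name="A", initial_size=nu1 * N0)
        dem.add_population(name="B", initial_size=nu2 * N0)
        dem.add_population(name="C", initial_size=N0)
        dem.add_population_split(time=T * 2 * N0, derived=["A", "B"],
                                 ancestral="C")
        dem.set_symmetric_migration_rate(["A", "B"], M / (2 * N0))
        h1 = h2 = 2 * n1
        tot = np.add.outer(np.arange(h1 + 1), np.arange(h2 + 1))
        hinge = (h1 + h2) / 2
        reps = 4000
        s = np.zeros((h1 + 1, h2 + 1))
        s2m = np.zeros((h1 + 1, h2 + 1))
        sims = msprime.sim_ancestry(
            samples={"A": n1, "B": n2}, demography=dem, sequence_length=1,
            num_replicates=reps, random_seed=7)
        for ts in sims:
            afs = ts.allele_frequency_spectrum(
                [ts.samples(population=0), ts.samples(population=1)],
                mode="branch", polarised=True,
                span_normalise=False) / (2 * N0)
            rev = afs[::-1, ::-1]
            f = np.where(tot < hinge, afs + rev, 0.0)
            f[tot == hinge] = 0.5 * (afs + rev)[tot == hinge]
            s += f
            s2m += f * f
        mean = s / reps
        var = np.maximum(s2m / reps - mean**2, 0) / reps
        mask = (tot > hinge)
        mask[0, 0] = True
        mask[h1, h2] = True
        scale = mean[~mask].sum()
        msp = mean / scale
        msp_se = np.sqrt(var) / scale
        mine = expected_jafs_mc(
            SimScenario("IM", nu1=nu1, nu2=nu2, T_total=T, M=M, n1=n1,
                        n2=n2, theta_per_tag=1.0, seed=0), 30_000, seed=13)
        se = np.sqrt(mine.se**2 + msp_se**2)
        z = (mine.counts - msp) / np.where(se > 0, se, np.inf)
        z[mine.mask] = 0
        assert np.abs(z).max() < 4.5


class TestArtefactInjection:
    def test_identity_when_disabled(self, divergent_dataset):
        out = inject_missing_and_clones(divergent_dataset, 0.0, 0, seed=1)
        assert np.array_equal(out.genotypes.dosages,
                              divergent_dataset.genotypes.dosages)

    def test_clone_copies_are_near_identical(self, divergent_dataset):
        from reefdiverge.genio import FilterConfig, pairwise_similarity

        out = inject_missing_and_clones(divergent_dataset, 0.05, 3, seed=2)
        gm = out.genotypes
        sim, co = pairwise_similarity(gm)
        np.fill_diagonal(sim, 0)
        n_clonal_pairs = int((sim >= 0.99).sum() // 2)
        assert n_clonal_pairs == 3

    def test_missing_rate_within_binomial_ci(self, divergent_dataset):
        out = inject_missing_and_clones(divergent_dataset, 0.2, 0, seed=3)
        n = out.genotypes.dosages.size
        observed = (out.genotypes.dosages == MISSING).mean()
        half_width = 2.58 * np.sqrt(0.2 * 0.8 / n)
        assert abs(observed - 0.2) < half_width


class TestEnvironment:
    def test_zero_effects_leave_genotypes_unchanged(self, divergent_dataset):
        out = simulate_env(divergent_dataset, [0.0, 0.0], n_vars=2,
                           spatial_range=2.0, seed=4)
        assert np.array_equal(out.genotypes.dosages,
                              divergent_dataset.genotypes.dosages)
        assert out.env.shape == (divergent_dataset.genotypes.n_individuals, 3)

    def test_env_columns_standardised(self, divergent_dataset):
        out = simulate_env(divergent_dataset, [0.0], n_vars=3,
                           spatial_range=1.0, seed=5)
        vals = out.env.drop(columns=["id"]).to_numpy()
        assert np.allclose(vals.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(vals.std(axis=0), 1, atol=1e-12)

    def test_spatial_range_controls_autocorrelation(self, divergent_dataset):
        """With many variables, the across-variable correlation between
        two nearby individuals vanishes as the range shrinks and grows
        with a long range."""
        from scipy.spatial.distance import pdist, squareform

        xy = divergent_dataset.coords[["x", "y"]].to_numpy()
        d = squareform(pdist(xy))
        np.fill_diagonal(d, np.inf)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        short = simulate_env(divergent_dataset, [0.0], n_vars=200,
                             spatial_range=0.0, seed=6)
        long = simulate_env(divergent_dataset, [0.0], n_vars=200,
                            spatial_range=20.0, seed=6)
        for ds, bound, cmp in ((short, 0.2, "lt"), (long, 0.5, "gt")):
            e = ds.env.drop(columns=["id"]).to_numpy()
            r = np.corrcoef(e[i], e[j])[0, 1]
            if cmp == "lt":
                assert abs(r) < bound
            else:
                assert r > bound
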