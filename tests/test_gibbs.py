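"""Gibbs sampler kernels against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from semsire import (
    CovStructureSpec,
    MCMCSettings,
    ModelSpec,
    RelationshipMatrix,
    UnstructuredCov,
    run_chain,
)
from semsire import gibbs as G
from semsire.cov_structures import full_mask
from semsire.synthetic_data import recovery_scenario, simulate_phenotypes
from semsire.trait_data import build_designs

from conftest import identity_A, make_table, plain_plan


def make_workspace(n, n_sires, trait_labels=("T1", "T2"), *, y=None, cg=False, seed=0):
    tbl = make_table(
        n, n_sires, trait_labels, rng=np.random.default_rng(seed), y=y,
        cg_levels=3 if cg else 1,
    )
    d = build_designs(tbl, plain_plan(tbl.traits, cg=cg))
    return G._Workspace(d, identity_A(d)), d


class TestReproducibility:
    def test_same_seed_bit_identical_chains(self, recovery_plan):
        g0 = np.array([[0.1, 0.03], [0.03, 0.12]])
        r0 = np.array([[0.9, 0.2], [0.2, 1.1]])
        sc = recovery_scenario(g0, r0, n_sires=30, progeny_per_sire=5, seed=2)
        tbl, truth = simulate_phenotypes(sc)
        d = build_designs(tbl, recovery_plan(sc.traits))
        spec = ModelSpec(mcmc=MCMCSettings(n_iter=120, burn_in=20, thin=2, seed=42))
        a = run_chain(d, truth.A, spec)
        b = run_chain(d, truth.A, spec)
        assert np.array_equal(a.G0, b.G0)
        assert np.array_equal(a.u, b.u)
        assert np.array_equal(a.loglik, b.loglik)
        c = run_chain(d, truth.A, spec.with_mcmc(seed=43))
        assert not np.array_equal(a.G0, c.G0)

    def test_stored_draw_count(self, recovery_plan):
        assert MCMCSettings(n_iter=1005, burn_in=100, thin=7).n_stored == 129


class TestBetaKernel:
    def test_flat_prior_limit_matches_gls(self):
        rng = np.random.default_rng(1)
        n = 200
        y = rng.standard_normal((n, 1)) * 2.0 + 1.0
        work, d = make_workspace(n, 4, ("T1",), y=y, cg=True, seed=1)
        spec = ModelSpec(beta_prior_var=1e10)
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        state.U[:] = 0.0
        state.r = UnstructuredCov(np.array([[1.7]]))
        state.refresh("R")
        x = work.X[0]
        gls = np.linalg.solve(x.T @ x, x.T @ work.y0[:, 0])
        draws = []
        for _ in range(2000):
            G.update_beta(state, work, hyper, rng)
            draws.append(state.beta[0].copy())
            state.U[:] = 0.0  # keep the conditioning fixed
        draws = np.array(draws)
        se = draws.std(axis=0) / np.sqrt(2000)
        assert np.all(np.abs(draws.mean(axis=0) - gls) < 5 * se + 1e-8)

    def test_no_fixed_effects_is_noop(self):
        tbl = make_table(20, 4, ("T1",))
        d0 = build_designs(tbl, plain_plan(tbl.traits, intercept=False))
        work0 = G._Workspace(d0, identity_A(d0))
        spec = ModelSpec()
        hyper = G._resolve_hyper(spec, work0.var_p)
        state = G.init_state(work0, spec, hyper)
        rng = np.random.default_rng(0)
        before = state.mu_fixed.copy()
        G.update_beta(state, work0, hyper, rng)
        assert np.array_equal(state.mu_fixed, before)
        assert state.beta[0].size == 0

    def test_degenerate_cg_data_recovers_group_means(self, recovery_plan):
        # records nearly constant within contemporary group: the fixed part
        # must reproduce the group means
        rng = np.random.default_rng(3)
        n = 120
        tbl = make_table(n, 6, ("T1",), rng=rng, cg_levels=4)
        groups = tbl.data["cg"].to_numpy()
        means = {g: float(v) for g, v in zip("abcd", [1.0, -2.0, 0.5, 3.0])}
        mapped = {f"c{k}": means[g] for k, g in enumerate("abcd")}
        y = np.array([mapped[g] for g in groups]) + 0.01 * rng.standard_normal(n)
        tbl.data["T1"] = y
        d = build_designs(tbl, plain_plan(tbl.traits, cg=True))
        spec = ModelSpec(mcmc=MCMCSettings(n_iter=600, burn_in=100, thin=1, seed=1))
        samples = run_chain(d, identity_A(d), spec)
        beta_mean = samples.beta[0].mean(axis=0)
        fitted = d.X_full["T1"] @ beta_mean
        for g in np.unique(groups):
            sel = groups == g
            assert fitted[sel].mean() == pytest.approx(y[sel].mean(), abs=0.05)


class TestSireKernel:
    def _brute_force(self, S, counts, A, G0, R0):
        s, p = S.shape
        Ainv = np.linalg.inv(A)
        P = np.kron(Ainv, np.linalg.inv(G0)) + np.kron(np.diag(counts), np.linalg.inv(R0))
        rhs = (S @ np.linalg.inv(R0)).reshape(-1)
        mean = np.linalg.solve(P, rhs)
        return mean.reshape(s, p), np.linalg.inv(P)

    def test_joint_conditional_matches_dense_oracle(self):
        rng = np.random.default_rng(8)
        A = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.25], [0.0, 0.25, 1.0]])
        G0 = np.array([[0.5, 0.2], [0.2, 0.4]])
        R0 = np.array([[1.0, -0.3], [-0.3, 0.8]])
        counts = np.array([4.0, 2.0, 6.0])
        S = rng.standard_normal((3, 2)) * 3
        mean_o, cov_o = self._brute_force(S, counts, A, G0, R0)
        draws = np.array(
            [
                G._draw_sire_effects(
                    S, counts, np.linalg.inv(G0), np.linalg.inv(R0), rng,
                    Ainv=np.linalg.inv(A),
                )
                for _ in range(40_000)
            ]
        )
        emp_mean = draws.mean(axis=0)
        se = draws.std(axis=0) / np.sqrt(40_000)
        assert np.all(np.abs(emp_mean - mean_o) < 5 * se)
        emp_cov = np.cov(draws.reshape(40_000, -1).T)
        assert np.linalg.norm(emp_cov - cov_o) / np.linalg.norm(cov_o) < 0.05

    def test_prior_only_draws_have_covariance_A_kron_G0(self):
        rng = np.random.default_rng(9)
        A = np.array([[1.0, 0.5, 0.25], [0.5, 1.0, 0.125], [0.25, 0.125, 1.0]])
        G0 = np.array([[0.6, -0.2], [-0.2, 0.5]])
        R0 = np.eye(2)
        draws = np.array(
            [
                G._draw_sire_effects(
                    np.zeros((3, 2)), np.zeros(3), np.linalg.inv(G0),
                    np.linalg.inv(R0), rng, Ainv=np.linalg.inv(A),
                )
                for _ in range(40_000)
            ]
        )
        emp = np.cov(draws.reshape(40_000, -1).T)
        target = np.kron(A, G0)
        assert np.linalg.norm(emp - target) / np.linalg.norm(target) < 0.05

    def test_single_trait_identity_A_shrunken_means(self):
        rng = np.random.default_rng(10)
        sg2, se2 = 0.5, 2.0
        counts = np.array([10.0, 3.0, 25.0])
        S = np.array([[4.0], [-1.5], [10.0]])
        expected = (S[:, 0] / se2) / (counts / se2 + 1.0 / sg2)
        draws = np.array(
            [
                G._draw_sire_effects(
                    S, counts, np.array([[1 / sg2]]), np.array([[1 / se2]]), rng
                )[:, 0]
                for _ in range(20_000)
            ]
        )
        se = draws.std(axis=0) / np.sqrt(20_000)
        assert np.all(np.abs(draws.mean(axis=0) - expected) < 5 * se)


class TestCovKernels:
    def test_uns_posterior_mean_matches_scatter(self):
        rng = np.random.default_rng(12)
        work, d = make_workspace(800, 800, ("T1", "T2"), seed=12)
        spec = ModelSpec(iw_scale_g=1e-9 * np.eye(2), iw_df_g=4.0)
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        u = rng.standard_normal((800, 2)) @ np.linalg.cholesky(
            np.array([[0.5, 0.2], [0.2, 0.7]])
        ).T
        scatter = u.T @ u
        draws = []
        for _ in range(3000):
            state.U = u
            G.update_uns_cov(state, work, hyper, "G", rng)
            draws.append(state.G0)
        mean = np.mean(draws, axis=0)
        expected = scatter / (4.0 + 800 - 2 - 1)
        assert np.allclose(mean, expected, rtol=0.03)

    def test_single_trait_reduces_to_scaled_inv_chi2(self):
        rng = np.random.default_rng(13)
        nu, s0 = 6.0, 2.0
        draws = np.array(
            [G._invwishart_rvs(nu, np.array([[s0]]), rng)[0, 0] for _ in range(30_000)]
        )
        # IW_1(nu, s0) == scaled-inv-chi2(nu, s0/nu)
        oracle = stats.invgamma(a=nu / 2, scale=s0 / 2)
        assert draws.mean() == pytest.approx(oracle.mean(), rel=0.03)
        assert np.quantile(draws, 0.9) == pytest.approx(oracle.ppf(0.9), rel=0.03)

    def test_draws_always_positive_definite(self):
        rng = np.random.default_rng(14)
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        for _ in range(2000):
            draw = G._invwishart_rvs(7.0, S, rng)
            assert np.linalg.eigvalsh(draw)[0] > 0

    def test_conjugate_single_trait_posterior_vs_grid_oracle(self, recovery_plan):
        """UNS/UNS, p=1, no fixed effects, A=I: Gibbs posterior means of the
        two variance components match 2-D grid integration of the exact
        marginal posterior."""
        sg2_true, se2_true = 0.4, 1.2
        n_j, s = 10, 40
        sc = recovery_scenario(
            np.array([[sg2_true]]), np.array([[se2_true]]),
            n_sires=s, progeny_per_sire=n_j, seed=77,
        )
        # pure y = Zu + e: switch the generator's nuisance fixed effects off
        sc.cg_sd_frac = 0.0
        sc.age_slope_frac = 0.0
        sc.dam_age_effect_frac = 0.0
        tbl, truth = simulate_phenotypes(sc)
        d = build_designs(tbl, plain_plan(sc.traits, intercept=False))
        nu, scale_g, scale_r = 5.0, 0.4, 1.0
        spec = ModelSpec(
            iw_df_g=nu, iw_scale_g=np.array([[scale_g]]),
            iw_df_r=nu, iw_scale_r=np.array([[scale_r]]),
            mcmc=MCMCSettings(n_iter=51_000, burn_in=1000, thin=1, seed=5),
        )
        samples = run_chain(d, truth.A, spec)
        est_g = samples.G0[:, 0, 0].mean()
        est_r = samples.R0[:, 0, 0].mean()

        # oracle: exact marginal posterior on a grid (u integrated analytically)
        yc = tbl.data["T1"].to_numpy()
        sire_idx = tbl.data["sire_id"].map(
            {sid: k for k, sid in enumerate(truth.sire_ids)}
        ).to_numpy()

        counts_all = np.bincount(sire_idx, minlength=s).astype(float)
        present = np.flatnonzero(counts_all > 0)  # sires without progeny drop out
        ssw = 0.0
        group_means = np.zeros(len(present))
        for k, j in enumerate(present):
            yj = yc[sire_idx == j]
            group_means[k] = yj.mean()
            ssw += ((yj - yj.mean()) ** 2).sum()
        counts = counts_all[present]

        def log_post(sg2, se2):
            ll = 0.0
            lam = se2 + counts * sg2
            ll += -0.5 * ((counts - 1) * np.log(se2)).sum() - 0.5 * ssw / se2
            ll += -0.5 * np.log(lam).sum() - 0.5 * (
                counts * group_means**2 / lam
            ).sum()
            lp = stats.invgamma.logpdf(sg2, a=nu / 2, scale=scale_g / 2)
            lp += stats.invgamma.logpdf(se2, a=nu / 2, scale=scale_r / 2)
            return ll + lp

        gs = np.linspace(0.05, 2.5, 220)
        es = np.linspace(0.6, 2.4, 220)
        lp = np.array([[log_post(g_, e_) for e_ in es] for g_ in gs])
        w = np.exp(lp - lp.max())
        w /= w.sum()
        oracle_g = float((w.sum(axis=1) * gs).sum())
        oracle_r = float((w.sum(axis=0) * es).sum())
        assert est_g == pytest.approx(oracle_g, rel=0.02)
        assert est_r == pytest.approx(oracle_r, rel=0.02)


@pytest.fixture(scope="module")
def fa_rec_fits(recovery_plan):
    g0 = np.array([[0.12, 0.04, 0.02], [0.04, 0.10, 0.03], [0.02, 0.03, 0.15]])
    r0 = np.array([[0.9, 0.2, 0.1], [0.2, 1.0, 0.25], [0.1, 0.25, 0.85]])
    sc = recovery_scenario(g0, r0, n_sires=60, progeny_per_sire=8, seed=31)
    tbl, truth = simulate_phenotypes(sc)
    d = build_designs(tbl, recovery_plan(sc.traits))
    mask = full_mask(3)
    mask[2, 0] = False
    fa = run_chain(
        d, truth.A,
        ModelSpec(
            g_structure=CovStructureSpec("FA", m=2),
            r_structure=CovStructureSpec("FA", m=1),
            mcmc=MCMCSettings(n_iter=400, burn_in=100, thin=2, seed=3),
        ),
    )
    rec = run_chain(
        d, truth.A,
        ModelSpec(
            g_structure=CovStructureSpec("REC", mask=mask),
            r_structure=CovStructureSpec("REC"),
            mcmc=MCMCSettings(n_iter=400, burn_in=100, thin=2, seed=4),
        ),
    )
    return fa, rec


class TestStructureConstraints:
    def test_echelon_cells_exactly_zero_in_all_draws(self, fa_rec_fits):
        fa, _ = fa_rec_fits
        lam = fa.g_native["lam"]
        assert np.all(lam[:, 0, 1] == 0.0)
        assert np.all(lam[:, 0, 0] >= 0.0)
        assert np.all(lam[:, 1, 1] >= 0.0)
        assert np.all(fa.g_native["psi"] > 0)

    def test_masked_pi_entries_exactly_zero(self, fa_rec_fits):
        _, rec = fa_rec_fits
        pi = rec.g_native["pi"]
        assert np.all(pi[:, 2, 0] == 0.0)
        assert np.any(pi[:, 1, 0] != 0.0)
        triu = np.triu_indices(3)
        assert np.all(pi[:, triu[0], triu[1]] == 0.0)

    def test_all_stored_covariances_positive_definite(self, fa_rec_fits):
        for samples in fa_rec_fits:
            for arr in (samples.G0, samples.R0):
                eigs = np.linalg.eigvalsh(arr)
                assert np.all(eigs[:, 0] > 0)


class TestFARecovery:
    def test_one_factor_structure_recovered_from_effects(self):
        """The FA block updates alone recover ΛΛ'+Ψ from directly observed
        effects (n=2000, A=I) within 10%."""
        rng = np.random.default_rng(55)
        lam_true = np.array([[0.9], [0.7], [0.5], [0.6]])
        psi_true = np.array([0.3, 0.4, 0.5, 0.35])
        n = 2000
        effects = (
            rng.standard_normal((n, 1)) @ lam_true.T
            + rng.standard_normal((n, 4)) * np.sqrt(psi_true)
        )
        work, d = make_workspace(n, 4, ("T1", "T2", "T3", "T4"), seed=55)
        spec = ModelSpec(g_structure=CovStructureSpec("FA", m=1))
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        target = lam_true @ lam_true.T + np.diag(psi_true)
        draws = []
        for it in range(600):
            state.U = effects  # condition the FA block on fixed effects data
            work.s = n
            G.update_fa_block(state, work, hyper, "G", rng)
            if it >= 100:
                draws.append(state.G0)
        est = np.mean(draws, axis=0)
        assert np.linalg.norm(est - target) / np.linalg.norm(target) < 0.10


class TestLoglik:
    def test_standard_normal_single_point(self):
        work, d = make_workspace(1, 1, ("T1",), y=np.array([[0.0]]))
        spec = ModelSpec()
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        state.beta[0][:] = 0.0
        state.mu_fixed[:] = 0.0
        state.U[:] = 0.0
        state.r = UnstructuredCov(np.array([[1.0]]))
        state.refresh("R")
        assert G.observed_loglik(state, work) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12
        )

    def test_matches_dense_multivariate_normal_oracle(self):
        rng = np.random.default_rng(23)
        n, p = 30, 4
        y = rng.standard_normal((n, p))
        y[rng.random((n, p)) < 0.3] = np.nan  # random missingness patterns
        work, d = make_workspace(n, 5, ("T1", "T2", "T3", "T4"), y=y, seed=23)
        spec = ModelSpec()
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        m = rng.standard_normal((p, p))
        state.r = UnstructuredCov(m @ m.T + p * np.eye(p))
        state.refresh("R")
        state.U = rng.standard_normal((5, p)) * 0.3
        for t in range(p):
            state.beta[t][:] = rng.standard_normal(state.beta[t].shape)
            state.mu_fixed[:, t] = work.X[t] @ state.beta[t]
        mu = state.mu_fixed + state.U[work.sire_index]
        expected = 0.0
        for i in range(n):
            obs = ~np.isnan(y[i])
            if not obs.any():
                continue
            expected += stats.multivariate_normal.logpdf(
                y[i, obs], mean=mu[i, obs], cov=state.R0[np.ix_(obs, obs)]
            )
        assert G.observed_loglik(state, work) == pytest.approx(expected, abs=1e-9)

    def test_additivity_over_independent_animals(self):
        y = np.array([[1.0, 2.0], [-0.5, 0.3]])
        work, d = make_workspace(2, 2, ("T1", "T2"), y=y)
        spec = ModelSpec()
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        total = G.observed_loglik(state, work)
        parts = 0.0
        for i in range(2):
            w1, _ = make_workspace(1, 1, ("T1", "T2"), y=y[i : i + 1])
            s1 = G.init_state(w1, spec, G._resolve_hyper(spec, w1.var_p))
            s1.beta = [b.copy() for b in state.beta]
            s1.mu_fixed = state.mu_fixed[i : i + 1].copy()
            s1.U = np.zeros((1, 2))
            s1.U[0] = state.U[work.sire_index[i]]
            s1.r = state.r
            s1.refresh("R")
            parts += G.observed_loglik(s1, w1)
        assert total == pytest.approx(parts, abs=1e-10)


class TestImputation:
    def test_fully_observed_is_noop(self):
        work, d = make_workspace(10, 2, ("T1", "T2"))
        spec = ModelSpec()
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        before = state.y_aug.copy()
        G.impute_missing(state, work, np.random.default_rng(0))
        assert np.array_equal(state.y_aug, before)

    def test_diagonal_r0_imputes_at_fixed_plus_sire_prediction(self):
        y = np.array([[1.0, np.nan], [0.5, 2.0], [np.nan, -1.0]])
        work, d = make_workspace(3, 2, ("T1", "T2"), y=y)
        spec = ModelSpec()
        hyper = G._resolve_hyper(spec, work.var_p)
        state = G.init_state(work, spec, hyper)
        rng = np.random.default_rng(4)
        state.U = rng.standard_normal((2, 2))
        for t in range(2):
            state.mu_fixed[:, t] = work.X[t] @ state.beta[t]
        state.r = UnstructuredCov(np.diag([0.5, 0.8]))
        state.refresh("R")
        mu = state.mu_fixed + state.U[work.sire_index]
        draws = []
        for _ in range(4000):
            G.impute_missing(state, work, rng)
            draws.append(state.y_aug.copy())
        draws = np.array(draws)
        assert draws[:, 0, 1].mean() == pytest.approx(mu[0, 1], abs=5 * np.sqrt(0.8 / 4000))
        assert draws[:, 0, 1].std() == pytest.approx(np.sqrt(0.8), rel=0.1)
        # observed cells untouched
        assert np.all(draws[:, 1, 0] == 0.5)

    def test_mcar_masked_recovery_matches_complete_data(self, recovery_plan):
        g0 = np.array([[0.12, 0.04], [0.04, 0.10]])
        r0 = np.array([[0.9, 0.25], [0.25, 1.1]])
        fits = {}
        for label, rate in (("complete", 0.0), ("masked", 0.3)):
            sc = recovery_scenario(
                g0, r0, n_sires=150, progeny_per_sire=12, seed=61,
                missing_rate=rate,
            )
            tbl, truth = simulate_phenotypes(sc)
            d = build_designs(tbl, recovery_plan(sc.traits))
            fits[label] = run_chain(
                d, truth.A,
                ModelSpec(mcmc=MCMCSettings(n_iter=1500, burn_in=400, thin=2, seed=9)),
            )
        a, b = fits["complete"], fits["masked"]
        sd = np.maximum(a.G0.std(axis=0), b.G0.std(axis=0))
        assert np.all(np.abs(a.posterior_mean_G0() - b.posterior_mean_G0()) < 4 * sd)
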