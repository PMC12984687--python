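"""Gibbs sampler for the Bayesian multi-trait sire model.

Model: ``y = Xβ + Zu + ε`` with ``u | A, G0 ~ N(0, A ⊗ G0)`` and
``ε ~ N(0, I ⊗ R0)``, fitted for any pairing of covariance structures
(unstructured, factor-analytic, recursive) on G0 and R0.  Missing trait
records are handled by data augmentation: each animal's unobserved trait
components are drawn from their conditional normal given the observed ones,
and all other kernels operate on the completed data.  The per-draw
log-likelihood stored for model comparison is the *observed-data* likelihood
conditional on (β, u, R0): the sum over animals of the normal log density of
the observed trait subvector at mean ``x'β + z'u`` and the matching R0
submatrix.

Full-conditional kernels
------------------------
* ``β`` (per-trait blocks): Gaussian, prior N(0, σ²_β I).
* ``u`` (all sires jointly): Gaussian with precision ``A⁻¹⊗G0⁻¹ + D⊗R0⁻¹``
  (D = diagonal progeny counts).  The draw uses the canonical transformation
  that simultaneously diagonalizes G0⁻¹ and R0⁻¹, splitting the s·p system
  into p independent s-dimensional ones.
* unstructured G0/R0: inverse-Wishart.
* factor-analytic blocks: latent factors (Gaussian, A-correlated on the
  genetic side), free loadings (Gaussian regressions under the echelon
  constraint, followed by a deterministic column-sign relabeling that keeps
  the pivots non-negative), specific variances (scaled inverse chi-square).
* recursive blocks: free structural coefficients row by row (Gaussian
  generalized regressions, A-weighted on the genetic side), then the
  structural variances (scaled inverse chi-square).  Masked entries stay 0.

All randomness flows through a single seeded generator consumed in a fixed
kernel order, so chains are bit-reproducible given (seed, spec, data).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, sparse

from . import cov_structures as cs
from .cov_structures import CovStructureSpec
from .pedigree import RelationshipMatrix
from .trait_data import DesignMatrices

__all__ = [
    "MCMCSettings",
    "ModelSpec",
    "PosteriorSamples",
    "run_chain",
    "observed_loglik",
    "load_samples",
]

LOG2PI = float(np.log(2.0 * np.pi))


# --------------------------------------------------------------------------
# specification


@dataclass
class MCMCSettings:
    """Chain length controls; defaults mirror the full field-study protocol."""

    n_iter: int = 1_500_000
    burn_in: int = 40_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class ModelSpec:
    """Structure choices, priors and MCMC settings for one model fit.

    Hyperparameters left at ``None`` are resolved from the data scale: with a
    prior heritability guess ``h²`` the sire-variance guess per trait is
    ``h²/4`` of the phenotypic variance and the residual guess the remainder;
    inverse-Wishart scales are diagonal with mean equal to that guess, and the
    same guesses center the scaled-inverse-chi-square priors used for
    factor-analytic specific variances and recursive structural variances.
    """

    g_structure: CovStructureSpec = field(default_factory=lambda: CovStructureSpec("UNS"))
    r_structure: CovStructureSpec = field(default_factory=lambda: CovStructureSpec("UNS"))
    beta_prior_var: float = 100.0**2
    prior_h2_guess: float = 0.4
    iw_df_g: float | None = None  # default p + 2
    iw_scale_g: np.ndarray | None = None
    iw_df_r: float | None = None
    iw_scale_r: np.ndarray | None = None
    coef_prior_var: float = 100.0**2  # FA loadings; REC coefficients if independent
    var_prior_df: float = 4.0  # scaled-inv-chi2 df for psi / gamma (independent mode)
    var_prior_scale_g: np.ndarray | None = None
    var_prior_scale_r: np.ndarray | None = None
    # 'iw-matched' gives (Π, Γ) the exact prior the inverse-Wishart induces on
    # the triangular factorization, so a full-mask recursive model is the same
    # Bayesian model as the unstructured one; 'independent' uses N(0, coef_prior_var)
    # coefficients and scaled-inv-chi2 variances.
    rec_prior: str = "iw-matched"
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)

    def with_mcmc(self, **kwargs) -> "ModelSpec":
        return replace(self, mcmc=replace(self.mcmc, **kwargs))


@dataclass
class _Hyper:
    """Resolved (numeric) hyperparameters."""

    beta_prec: float
    nu_g: float
    S_g: np.ndarray
    nu_r: float
    S_r: np.ndarray
    coef_prec: float
    nu0: float
    s0_g: np.ndarray
    s0_r: np.ndarray
    floor_g: np.ndarray
    floor_r: np.ndarray
    rec_matched: bool = True


def _resolve_hyper(spec: ModelSpec, var_p: np.ndarray) -> _Hyper:
    p = len(var_p)
    h2 = spec.prior_h2_guess
    guess_g = h2 / 4.0 * var_p
    guess_r = var_p - guess_g
    nu_g = spec.iw_df_g if spec.iw_df_g is not None else p + 2
    nu_r = spec.iw_df_r if spec.iw_df_r is not None else p + 2
    if spec.iw_scale_g is not None:
        S_g = np.atleast_2d(np.asarray(spec.iw_scale_g, dtype=float))
        if S_g.shape == (1, p):
            S_g = np.diag(S_g.ravel())
    else:
        S_g = np.diag(guess_g) * max(nu_g - p - 1, 1e-8)
    if spec.iw_scale_r is not None:
        S_r = np.atleast_2d(np.asarray(spec.iw_scale_r, dtype=float))
        if S_r.shape == (1, p):
            S_r = np.diag(S_r.ravel())
    else:
        S_r = np.diag(guess_r) * max(nu_r - p - 1, 1e-8)
    s0_g = (
        np.asarray(spec.var_prior_scale_g, dtype=float)
        if spec.var_prior_scale_g is not None
        else guess_g
    )
    s0_r = (
        np.asarray(spec.var_prior_scale_r, dtype=float)
        if spec.var_prior_scale_r is not None
        else guess_r
    )
    return _Hyper(
        beta_prec=1.0 / spec.beta_prior_var,
        nu_g=float(nu_g),
        S_g=S_g,
        nu_r=float(nu_r),
        S_r=S_r,
        coef_prec=1.0 / spec.coef_prior_var,
        nu0=float(spec.var_prior_df),
        s0_g=s0_g,
        s0_r=s0_r,
        floor_g=cs.VARIANCE_FLOOR * np.maximum(guess_g, 1e-30),
        floor_r=cs.VARIANCE_FLOOR * np.maximum(guess_r, 1e-30),
        rec_matched=spec.rec_prior == "iw-matched",
    )


# --------------------------------------------------------------------------
# workspace and state


class _Workspace:
    """Immutable per-fit quantities: designs, pedigree algebra, missingness."""

    def __init__(self, designs: DesignMatrices, A: RelationshipMatrix):
        if list(A.ids) != list(designs.sire_ids):
            if set(A.ids) >= set(designs.sire_ids):
                A = A.restrict(designs.sire_ids)
            else:
                raise ValueError(
                    "relationship matrix does not cover the sires in the designs"
                )
        self.designs = designs
        self.labels = designs.traits.labels
        self.p = designs.traits.p
        self.n = designs.n_animals
        self.s = designs.n_sires
        self.X = [designs.X_full[t] for t in self.labels]
        self.XtX = [x.T @ x for x in self.X]
        # class-effect dummies make X very sparse; sparse matvecs pay off
        self.Xop = [
            sparse.csr_matrix(x)
            if x.size and np.count_nonzero(x) < 0.4 * x.size
            else x
            for x in self.X
        ]
        self.sire_index = designs.sire_index
        self.counts = np.bincount(self.sire_index, minlength=self.s).astype(float)
        self.Zt = sparse.csr_matrix(
            (np.ones(self.n), (self.sire_index, np.arange(self.n))),
            shape=(self.s, self.n),
        )
        self.A = A
        self.a_identity = A.is_identity()
        self.Avals = A.values
        self.Ainv = np.eye(self.s) if self.a_identity else A.inverse()
        self.chol_A = np.eye(self.s) if self.a_identity else A.cholesky()

        self.y0 = designs.y.copy()
        self.miss = np.isnan(self.y0)
        self.patterns = []  # (obs_cols, mis_cols, row_idx)
        if self.p:
            keys = {}
            for row, pattern in enumerate(map(tuple, self.miss)):
                keys.setdefault(pattern, []).append(row)
            for pattern, rows in keys.items():
                mis = np.flatnonzero(pattern)
                obs = np.flatnonzero(~np.asarray(pattern))
                self.patterns.append((obs, mis, np.asarray(rows)))

        self.var_p = np.array(
            [
                np.var(self.y0[~self.miss[:, j], j], ddof=1)
                if (~self.miss[:, j]).sum() > 1
                else 1.0
                for j in range(self.p)
            ]
        )

    def sire_sums(self, mat: np.ndarray) -> np.ndarray:
        return self.Zt @ mat


@dataclass
class GibbsState:
    y_aug: np.ndarray  # n × p, missing entries imputed
    beta: list  # per-trait coefficient vectors
    mu_fixed: np.ndarray  # n × p, X beta
    U: np.ndarray  # s × p
    g: object  # covariance structure objects
    r: object
    G0: np.ndarray = None
    R0: np.ndarray = None
    G0inv: np.ndarray = None
    Rinv: np.ndarray = None

    def refresh(self, which: str | None = None) -> None:
        if which in (None, "G"):
            self.G0 = cs.assemble(self.g)
            self.G0inv = _pd_inverse(self.G0, "G0")
        if which in (None, "R"):
            self.R0 = cs.assemble(self.r)
            self.Rinv = _pd_inverse(self.R0, "R0")


def _pd_inverse(mat: np.ndarray, name: str) -> np.ndarray:
    try:
        c, low = linalg.cho_factor(mat, lower=True)
    except linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise RuntimeError(f"{name} draw is not positive definite") from exc
    return linalg.cho_solve((c, low), np.eye(mat.shape[0]))


def _init_structure(kind_spec: CovStructureSpec, guess: np.ndarray):
    p = len(guess)
    diag = np.diag(guess)
    if kind_spec.kind == "UNS":
        return cs.UnstructuredCov(diag)
    if kind_spec.kind == "FA":
        return cs.nearest_fa_start(diag, kind_spec.m)
    mask = kind_spec.resolved_mask(p)
    return cs.RecursiveCov(pi=np.zeros((p, p)), gamma=guess.copy(), mask=mask)


def init_state(work: _Workspace, spec: ModelSpec, hyper: _Hyper) -> GibbsState:
    p, n = work.p, work.n
    y_aug = work.y0.copy()
    for j in range(p):
        col = y_aug[:, j]
        observed = ~work.miss[:, j]
        fill = np.mean(col[observed]) if observed.any() else 0.0
        col[work.miss[:, j]] = fill
    beta = [np.zeros(x.shape[1]) for x in work.X]
    mu_fixed = np.zeros((n, p))
    guess_g = np.diag(hyper.S_g) / max(hyper.nu_g - p - 1, 1e-8)
    guess_r = np.diag(hyper.S_r) / max(hyper.nu_r - p - 1, 1e-8)
    state = GibbsState(
        y_aug=y_aug,
        beta=beta,
        mu_fixed=mu_fixed,
        U=np.zeros((work.s, p)),
        g=_init_structure(spec.g_structure, guess_g),
        r=_init_structure(spec.r_structure, guess_r),
    )
    state.refresh()
    return state


# --------------------------------------------------------------------------
# kernels


def impute_missing(state: GibbsState, work: _Workspace, rng: np.random.Generator) -> None:
    """Draw missing trait records from N(y_mis | y_obs, β, u, R0)."""
    if not work.miss.any():
        return
    mu = state.mu_fixed + state.U[work.sire_index]
    for obs, mis, rows in work.patterns:
        if len(mis) == 0:
            continue
        if len(obs) == 0:
            chol = np.linalg.cholesky(state.R0)
            draw = mu[rows] + rng.standard_normal((len(rows), work.p)) @ chol.T
            state.y_aug[rows] = draw
            continue
        R_oo = state.R0[np.ix_(obs, obs)]
        R_mo = state.R0[np.ix_(mis, obs)]
        R_mm = state.R0[np.ix_(mis, mis)]
        co = linalg.cho_factor(R_oo, lower=True)
        gain = linalg.cho_solve(co, R_mo.T).T  # R_mo R_oo^{-1}
        cond_cov = R_mm - gain @ R_mo.T
        chol = np.linalg.cholesky(0.5 * (cond_cov + cond_cov.T))
        dev = state.y_aug[np.ix_(rows, obs)] - mu[np.ix_(rows, obs)]
        mean = mu[np.ix_(rows, mis)] + dev @ gain.T
        state.y_aug[np.ix_(rows, mis)] = (
            mean + rng.standard_normal((len(rows), len(mis))) @ chol.T
        )


def update_beta(
    state: GibbsState, work: _Workspace, hyper: _Hyper, rng: np.random.Generator
) -> None:
    """Per-trait Gaussian block updates of the fixed effects."""
    resid = state.y_aug - state.mu_fixed - state.U[work.sire_index]
    for t in range(work.p):
        k = work.X[t].shape[1]
        if k == 0:
            continue
        x = work.Xop[t]
        # add trait t's own fixed part back: conditional excludes beta_t
        partial = resid @ state.Rinv[:, t] + state.Rinv[t, t] * (x @ state.beta[t])
        b = x.T @ partial
        prec = state.Rinv[t, t] * work.XtX[t] + hyper.beta_prec * np.eye(k)
        cl = np.linalg.cholesky(prec)
        mean = linalg.cho_solve((cl, True), b)
        draw = mean + linalg.solve_triangular(cl.T, rng.standard_normal(k), lower=False)
        delta = x @ (draw - state.beta[t])
        state.beta[t] = draw
        state.mu_fixed[:, t] += delta
        resid[:, t] -= delta


def _draw_sire_effects(
    S: np.ndarray,
    counts: np.ndarray,
    G0inv: np.ndarray,
    Rinv: np.ndarray,
    rng: np.random.Generator,
    *,
    Ainv: np.ndarray | None = None,
) -> np.ndarray:
    """Joint draw of all sire effects via the canonical transformation.

    ``S`` holds per-sire sums of (y − Xβ) rows; precision is
    ``A⁻¹⊗G0⁻¹ + diag(counts)⊗R0⁻¹``.  ``Ainv=None`` means A = I.
    """
    s = S.shape[0]
    lam, T = linalg.eigh(G0inv, Rinv)  # T' Rinv T = I, T' G0inv T = diag(lam)
    Rv = S @ Rinv @ T
    V = np.empty_like(Rv)
    z = rng.standard_normal(Rv.shape)
    if Ainv is None:
        denom = counts[:, None] + lam[None, :]
        V = Rv / denom + z / np.sqrt(denom)
    else:
        D = np.diag(counts)
        for k in range(len(lam)):
            M = lam[k] * Ainv + D
            cl = np.linalg.cholesky(M)
            mean = linalg.cho_solve((cl, True), Rv[:, k])
            V[:, k] = mean + linalg.solve_triangular(cl.T, z[:, k], lower=False)
    return V @ T.T


def update_sire_effects(
    state: GibbsState, work: _Workspace, rng: np.random.Generator
) -> None:
    S = work.sire_sums(state.y_aug - state.mu_fixed)
    state.U = _draw_sire_effects(
        S,
        work.counts,
        state.G0inv,
        state.Rinv,
        rng,
        Ainv=None if work.a_identity else work.Ainv,
    )


def _scaled_inv_chi2(df: float, scale: float, rng: np.random.Generator) -> float:
    return df * scale / rng.chisquare(df)


def _invwishart_rvs(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One inverse-Wishart draw via the Bartlett decomposition."""
    p = scale.shape[0]
    ls = np.linalg.cholesky(scale)
    a = np.zeros((p, p))
    a[np.diag_indices(p)] = np.sqrt(rng.chisquare(df - np.arange(p)))
    a[np.tril_indices(p, k=-1)] = rng.standard_normal(p * (p - 1) // 2)
    b = linalg.solve_triangular(a, ls.T, lower=True).T  # Ls A^{-T}
    return b @ b.T


def update_uns_cov(
    state: GibbsState, work: _Workspace, hyper: _Hyper, which: str, rng
) -> None:
    """Inverse-Wishart full conditional for an unstructured G0 or R0."""
    if which == "G":
        scatter = state.U.T @ work.Ainv @ state.U
        df = hyper.nu_g + work.s
        scale = hyper.S_g + scatter
    else:
        E = state.y_aug - state.mu_fixed - state.U[work.sire_index]
        df = hyper.nu_r + work.n
        scale = hyper.S_r + E.T @ E
    draw = _invwishart_rvs(df, 0.5 * (scale + scale.T), rng)
    if which == "G":
        state.g = cs.UnstructuredCov(0.5 * (draw + draw.T))
    else:
        state.r = cs.UnstructuredCov(0.5 * (draw + draw.T))
    state.refresh(which)


def _fa_free_cols(row: int, m: int) -> np.ndarray:
    return np.arange(min(row + 1, m))


def update_fa_block(
    state: GibbsState, work: _Workspace, hyper: _Hyper, which: str, rng
) -> None:
    """Factors, echelon loadings and specific variances for one FA matrix."""
    if which == "G":
        fa: cs.FactorAnalyticCov = state.g
        effects = state.U
        Ainv = None if work.a_identity else work.Ainv
        chol_rows = None if work.a_identity else work.chol_A
        n_eff = work.s
        s0 = hyper.s0_g
        floor = hyper.floor_g
    else:
        fa = state.r
        effects = state.y_aug - state.mu_fixed - state.U[work.sire_index]
        Ainv = None
        chol_rows = None
        n_eff = work.n
        s0 = hyper.s0_r
        floor = hyper.floor_r
    lam, psi, m, p = fa.lam.copy(), fa.psi.copy(), fa.m, fa.p

    # (i) latent common factors: per-row covariance C, across rows A (G side)
    psi_inv = 1.0 / psi
    C = np.linalg.inv(np.eye(m) + (lam * psi_inv[:, None]).T @ lam)
    M = effects @ (psi_inv[:, None] * lam) @ C
    z = rng.standard_normal((n_eff, m))
    chol_c = np.linalg.cholesky(0.5 * (C + C.T))
    noise = (chol_rows @ z if chol_rows is not None else z) @ chol_c.T
    F = M + noise

    # (ii) free loadings row by row under the echelon constraint
    FtAinvF = F.T @ (Ainv @ F) if Ainv is not None else F.T @ F
    FtAinv_eff = F.T @ (Ainv @ effects) if Ainv is not None else F.T @ effects
    new_lam = np.zeros_like(lam)
    for j in range(p):
        free = _fa_free_cols(j, m)
        prec = FtAinvF[np.ix_(free, free)] / psi[j] + hyper.coef_prec * np.eye(len(free))
        b = FtAinv_eff[free, j] / psi[j]
        cl = np.linalg.cholesky(prec)
        mean = linalg.cho_solve((cl, True), b)
        new_lam[j, free] = mean + linalg.solve_triangular(
            cl.T, rng.standard_normal(len(free)), lower=False
        )
    # sign relabeling: posterior is symmetric under joint column sign flips
    for k in range(m):
        if new_lam[k, k] < 0:
            new_lam[:, k] *= -1.0
            F[:, k] *= -1.0

    # (iii) specific variances
    delta = effects - F @ new_lam.T
    quad = (
        np.einsum("ij,ij->j", delta, Ainv @ delta)
        if Ainv is not None
        else np.einsum("ij,ij->j", delta, delta)
    )
    new_psi = np.empty(p)
    for j in range(p):
        df = hyper.nu0 + n_eff
        scale = (hyper.nu0 * s0[j] + quad[j]) / df
        new_psi[j] = max(_scaled_inv_chi2(df, scale, rng), floor[j])

    updated = cs.FactorAnalyticCov(lam=new_lam, psi=new_psi)
    if which == "G":
        state.g = updated
    else:
        state.r = updated
    state.refresh(which)


def update_rec_block(
    state: GibbsState, work: _Workspace, hyper: _Hyper, which: str, rng
) -> None:
    """Row-wise structural coefficients and variances for one REC matrix.

    Under the default IW-matched prior, row j carries
    ``γ_j ~ Inv-χ²(ν−p+j, S_jj/(ν−p+j))`` and
    ``π_jk | γ_j ~ N(0, γ_j / S_kk)`` — exactly the law the side's
    inverse-Wishart induces on the triangular factorization (for diagonal S),
    so the full-mask model is the unstructured model in different coordinates.
    """
    if which == "G":
        rec: cs.RecursiveCov = state.g
        effects = state.U
        Ainv = None if work.a_identity else work.Ainv
        n_eff = work.s
        s0 = hyper.s0_g
        floor = hyper.floor_g
        iw_df, iw_diag = hyper.nu_g, np.diag(hyper.S_g)
    else:
        rec = state.r
        effects = state.y_aug - state.mu_fixed - state.U[work.sire_index]
        Ainv = None
        n_eff = work.n
        s0 = hyper.s0_r
        floor = hyper.floor_r
        iw_df, iw_diag = hyper.nu_r, np.diag(hyper.S_r)
    p = rec.p
    mask = rec.mask
    W_all = Ainv @ effects if Ainv is not None else effects
    gram = effects.T @ W_all  # effects' Ainv effects
    new_pi = np.zeros((p, p))
    new_gamma = np.empty(p)
    for j in range(p):
        free = np.flatnonzero(mask[j])
        if len(free):
            if hyper.rec_matched:
                # prior precision of pi row scales with 1/gamma_j
                prior_prec = np.diag(iw_diag[free])
            else:
                prior_prec = rec.gamma[j] * hyper.coef_prec * np.eye(len(free))
            prec_scaled = gram[np.ix_(free, free)] + prior_prec
            cl = np.linalg.cholesky(prec_scaled)
            mean = linalg.cho_solve((cl, True), gram[free, j])
            coeffs = mean + np.sqrt(rec.gamma[j]) * linalg.solve_triangular(
                cl.T, rng.standard_normal(len(free)), lower=False
            )
            new_pi[j, free] = coeffs
            resid_j = effects[:, j] - effects[:, free] @ coeffs
        else:
            resid_j = effects[:, j]
        quad = resid_j @ (Ainv @ resid_j) if Ainv is not None else resid_j @ resid_j
        if hyper.rec_matched:
            pi_quad = float(new_pi[j, free] ** 2 @ iw_diag[free]) if len(free) else 0.0
            df = (iw_df - p + j + 1) + n_eff + len(free)
            scale = (iw_diag[j] + quad + pi_quad) / df
        else:
            df = hyper.nu0 + n_eff
            scale = (hyper.nu0 * s0[j] + quad) / df
        new_gamma[j] = max(_scaled_inv_chi2(df, scale, rng), floor[j])

    updated = cs.RecursiveCov(pi=new_pi, gamma=new_gamma, mask=mask)
    if which == "G":
        state.g = updated
    else:
        state.r = updated
    state.refresh(which)


def _update_structure(state, work, hyper, which, spec: CovStructureSpec, rng) -> None:
    if spec.kind == "UNS":
        update_uns_cov(state, work, hyper, which, rng)
    elif spec.kind == "FA":
        update_fa_block(state, work, hyper, which, rng)
    else:
        update_rec_block(state, work, hyper, which, rng)


def observed_loglik(state: GibbsState, work: _Workspace) -> float:
    """Observed-data log-likelihood at the current (β, u, R0)."""
    mu = state.mu_fixed + state.U[work.sire_index]
    total = 0.0
    for obs, _mis, rows in work.patterns:
        if len(obs) == 0:
            continue
        dev = work.y0[np.ix_(rows, obs)] - mu[np.ix_(rows, obs)]
        R_oo = state.R0[np.ix_(obs, obs)]
        cl = np.linalg.cholesky(R_oo)
        half = linalg.solve_triangular(cl, dev.T, lower=True)
        quad = float(np.sum(half**2))
        logdet = 2.0 * float(np.sum(np.log(np.diag(cl))))
        total += -0.5 * (len(rows) * (len(obs) * LOG2PI + logdet) + quad)
    return total


def redraw_data(state: GibbsState, work: _Workspace, rng: np.random.Generator) -> None:
    """Replace the full data y with a draw from the model at the current state.

    Used by simulator-consistency (joint-distribution) checks; all entries,
    observed or augmented, are redrawn.
    """
    mu = state.mu_fixed + state.U[work.sire_index]
    chol = np.linalg.cholesky(state.R0)
    y = mu + rng.standard_normal((work.n, work.p)) @ chol.T
    state.y_aug = y
    work.y0[~work.miss] = y[~work.miss]


# --------------------------------------------------------------------------
# output container


@dataclass
class PosteriorSamples:
    """Thinned posterior draws from one model fit."""

    trait_labels: tuple
    sire_ids: list
    spec: ModelSpec
    G0: np.ndarray  # k × p × p
    R0: np.ndarray
    beta: list  # per trait: k × k_t
    beta_columns: dict
    u: np.ndarray  # k × s × p
    loglik: np.ndarray  # k
    g_native: dict = field(default_factory=dict)
    r_native: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.loglik)

    def posterior_mean_G0(self) -> np.ndarray:
        return self.G0.mean(axis=0)

    def posterior_mean_R0(self) -> np.ndarray:
        return self.R0.mean(axis=0)

    def ebv(self, scale: float = 1.0) -> np.ndarray:
        """Posterior mean sire effects (s × p); ``scale=2`` gives the
        transmitting-ability-to-breeding-value conversion."""
        return scale * self.u.mean(axis=0)

    def save(self, outdir) -> None:
        """Write draws as labeled delimited text plus a JSON metadata sidecar."""
        import json
        import pathlib

        import pandas as pd

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p = len(self.trait_labels)
        cols = {}
        for i in range(p):
            for j in range(i + 1):
                cols[f"G0[{self.trait_labels[i]},{self.trait_labels[j]}]"] = self.G0[:, i, j]
                cols[f"R0[{self.trait_labels[i]},{self.trait_labels[j]}]"] = self.R0[:, i, j]
        for side, native in (("g", self.g_native), ("r", self.r_native)):
            for name, arr in native.items():
                arr = np.asarray(arr)
                flat = arr.reshape(arr.shape[0], -1)
                for k in range(flat.shape[1]):
                    cols[f"{side}_{name}_{k}"] = flat[:, k]
        cols["loglik"] = self.loglik
        pd.DataFrame(cols).to_csv(outdir / "samples.csv", index=False)
        ebv = pd.DataFrame(self.ebv(), index=self.sire_ids, columns=list(self.trait_labels))
        ebv.to_csv(outdir / "ebv.csv", index_label="sire_id")
        beta_rows = []
        for t, draws in zip(self.trait_labels, self.beta):
            names = self.beta_columns.get(t, [f"b{k}" for k in range(draws.shape[1])])
            means = draws.mean(axis=0) if draws.shape[1] else np.array([])
            for name, val in zip(names, means):
                beta_rows.append({"trait": t, "effect": name, "posterior_mean": val})
        pd.DataFrame(beta_rows, columns=["trait", "effect", "posterior_mean"]).to_csv(
            outdir / "beta_mean.csv", index=False
        )
        meta = {
            "traits": list(self.trait_labels),
            "n_draws": int(self.n_draws),
            "g_structure": self.spec.g_structure.kind,
            "r_structure": self.spec.r_structure.kind,
            "g_m": self.spec.g_structure.m,
            "r_m": self.spec.r_structure.m,
            "beta_columns": {t: list(c) for t, c in self.beta_columns.items()},
            "mcmc": {
                "n_iter": self.spec.mcmc.n_iter,
                "burn_in": self.spec.mcmc.burn_in,
                "thin": self.spec.mcmc.thin,
                "seed": self.spec.mcmc.seed,
            },
        }
        (outdir / "meta.json").write_text(json.dumps(meta, indent=1))


# --------------------------------------------------------------------------
# driver


def run_chain(
    designs: DesignMatrices,
    A: RelationshipMatrix,
    spec: ModelSpec,
    *,
    progress: bool = False,
) -> PosteriorSamples:
    """Fit the model by a systematic-scan Gibbs sampler.

    Update order per iteration: impute missing records → β → sire effects →
    genetic covariance structure → residual covariance structure.  Stored
    draws are the post-burn-in iterations at the thinning interval, with the
    observed-data log-likelihood evaluated at each stored state.
    """
    work = _Workspace(designs, A)
    hyper = _resolve_hyper(spec, work.var_p)
    rng = np.random.default_rng(spec.mcmc.seed)
    state = init_state(work, spec, hyper)

    k = spec.mcmc.n_stored
    p, s = work.p, work.s
    G0_draws = np.empty((k, p, p))
    R0_draws = np.empty((k, p, p))
    u_draws = np.empty((k, s, p))
    beta_draws = [np.empty((k, x.shape[1])) for x in work.X]
    ll_draws = np.empty(k)
    g_native: dict = _native_store(spec.g_structure, p, k)
    r_native: dict = _native_store(spec.r_structure, p, k)

    iterator = range(1, spec.mcmc.n_iter + 1)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="gibbs")
    stored = 0
    for it in iterator:
        impute_missing(state, work, rng)
        update_beta(state, work, hyper, rng)
        update_sire_effects(state, work, rng)
        _update_structure(state, work, hyper, "G", spec.g_structure, rng)
        _update_structure(state, work, hyper, "R", spec.r_structure, rng)
        if it > spec.mcmc.burn_in and (it - spec.mcmc.burn_in) % spec.mcmc.thin == 0:
            G0_draws[stored] = state.G0
            R0_draws[stored] = state.R0
            u_draws[stored] = state.U
            for t in range(p):
                beta_draws[t][stored] = state.beta[t]
            ll_draws[stored] = observed_loglik(state, work)
            _store_native(g_native, state.g, stored)
            _store_native(r_native, state.r, stored)
            stored += 1

    return PosteriorSamples(
        trait_labels=work.labels,
        sire_ids=list(designs.sire_ids),
        spec=spec,
        G0=G0_draws,
        R0=R0_draws,
        beta=beta_draws,
        beta_columns=dict(designs.columns),
        u=u_draws,
        loglik=ll_draws,
        g_native=g_native,
        r_native=r_native,
    )


def load_samples(outdir) -> PosteriorSamples:
    """Reload a saved fit for summary-only reruns.

    Covariance and log-likelihood chains are restored in full; β and u come
    back as their posterior means (stored as single-draw arrays), which is
    sufficient for DIC, genetic-parameter summaries and EBV comparisons.
    """
    import json
    import pathlib

    import pandas as pd

    outdir = pathlib.Path(outdir)
    meta = json.loads((outdir / "meta.json").read_text())
    labels = tuple(meta["traits"])
    p = len(labels)
    df = pd.read_csv(outdir / "samples.csv")
    k = len(df)
    G0 = np.empty((k, p, p))
    R0 = np.empty((k, p, p))
    for i in range(p):
        for j in range(i + 1):
            G0[:, i, j] = G0[:, j, i] = df[f"G0[{labels[i]},{labels[j]}]"]
            R0[:, i, j] = R0[:, j, i] = df[f"R0[{labels[i]},{labels[j]}]"]
    native = {"g": {}, "r": {}}
    for side, kind, m in (
        ("g", meta["g_structure"], meta.get("g_m")),
        ("r", meta["r_structure"], meta.get("r_m")),
    ):
        if kind == "FA":
            shapes = {"lam": (p, m), "psi": (p,)}
        elif kind == "REC":
            shapes = {"pi": (p, p), "gamma": (p,)}
        else:
            shapes = {}
        for name, shape in shapes.items():
            size = int(np.prod(shape))
            arr = np.column_stack(
                [df[f"{side}_{name}_{kk}"] for kk in range(size)]
            ).reshape((k,) + shape)
            native[side][name] = arr
    ebv = pd.read_csv(outdir / "ebv.csv", index_col="sire_id")
    beta_mean_df = pd.read_csv(outdir / "beta_mean.csv")
    beta = []
    for t in labels:
        vals = beta_mean_df.loc[beta_mean_df["trait"] == t, "posterior_mean"].to_numpy()
        beta.append(vals[None, :])
    spec = ModelSpec(
        g_structure=CovStructureSpec(meta["g_structure"], m=meta.get("g_m")),
        r_structure=CovStructureSpec(meta["r_structure"], m=meta.get("r_m")),
        mcmc=MCMCSettings(**meta["mcmc"]),
    )
    return PosteriorSamples(
        trait_labels=labels,
        sire_ids=list(ebv.index),
        spec=spec,
        G0=G0,
        R0=R0,
        beta=beta,
        beta_columns={t: list(c) for t, c in meta.get("beta_columns", {}).items()},
        u=ebv.to_numpy()[None, :, :],
        loglik=df["loglik"].to_numpy(),
        g_native=native["g"],
        r_native=native["r"],
    )


def _native_store(struct_spec: CovStructureSpec, p: int, k: int) -> dict:
    if struct_spec.kind == "FA":
        return {"lam": np.empty((k, p, struct_spec.m)), "psi": np.empty((k, p))}
    if struct_spec.kind == "REC":
        return {"pi": np.empty((k, p, p)), "gamma": np.empty((k, p))}
    return {}


def _store_native(store: dict, structure, idx: int) -> None:
    if "lam" in store:
        store["lam"][idx] = structure.lam
        store["psi"][idx] = structure.psi
    elif "pi" in store:
        store["pi"][idx] = structure.pi
        store["gamma"][idx] = structure.gamma
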