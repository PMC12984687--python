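"""Covariance parameterizations for the multi-trait sire model.

Three structures are supported for each of the genetic (G0) and residual (R0)
trait covariance matrices:

* unstructured (UNS): all ``p(p+1)/2`` entries free;
* factor-analytic (FA): ``Σ = ΛΛ' + Ψ`` with an ``p×m`` loading matrix Λ under
  the echelon identifiability constraint (``λ_jk = 0`` for ``k > j``,
  ``λ_kk ≥ 0``) and diagonal specific variances Ψ;
* recursive (REC): ``Σ = (I−Π)⁻¹ Γ (I−Π)⁻ᵀ`` with Π strictly lower triangular
  (structural coefficients along a fixed causal trait ordering, optionally
  masked to zero) and Γ diagonal.

A full-mask REC is a one-to-one reparameterization of UNS — the map is the
unit-lower-triangular (LDL-type) factorization of Σ — so it has exactly as
many free parameters as the unstructured matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "UnstructuredCov",
    "FactorAnalyticCov",
    "RecursiveCov",
    "CovStructureSpec",
    "assemble",
    "decompose_recursive",
    "count_params",
    "nearest_fa_start",
    "full_mask",
]

#: relative floor applied to specific/structural variances to keep assembled
#: matrices positive definite during sampling
VARIANCE_FLOOR = 1e-8


def _check_symmetric_pd(sigma: np.ndarray, name: str = "sigma") -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-10 * (1 + np.abs(sigma).max())):
        raise ValueError(f"{name} must be symmetric")
    eigmin = np.linalg.eigvalsh(sigma)[0]
    if eigmin <= 0:
        raise ValueError(f"{name} is not positive definite (min eig {eigmin:g})")
    return 0.5 * (sigma + sigma.T)


@dataclass
class UnstructuredCov:
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sigma = _check_symmetric_pd(self.sigma)

    @property
    def p(self) -> int:
        return self.sigma.shape[0]


@dataclass
class FactorAnalyticCov:
    """Λ (echelon-constrained) and diagonal Ψ; implied Σ = ΛΛ' + Ψ."""

    lam: np.ndarray
    psi: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.atleast_2d(np.asarray(self.lam, dtype=float))
        self.psi = np.asarray(self.psi, dtype=float).ravel()
        p, m = self.lam.shape
        if m >= p:
            raise ValueError(f"number of factors m={m} must be < p={p}")
        if self.psi.shape != (p,):
            raise ValueError("psi must have one entry per trait")
        if np.any(self.psi < 0):
            raise ValueError("specific variances must be non-negative")
        for j in range(p):
            for k in range(j + 1, m):
                if self.lam[j, k] != 0.0:
                    raise ValueError(
                        f"echelon constraint violated: lambda[{j},{k}] != 0"
                    )

    @property
    def p(self) -> int:
        return self.lam.shape[0]

    @property
    def m(self) -> int:
        return self.lam.shape[1]


@dataclass
class RecursiveCov:
    """Strictly-lower Π with free-entry mask, and diagonal Γ > 0."""

    pi: np.ndarray
    gamma: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pi = np.atleast_2d(np.asarray(self.pi, dtype=float))
        self.gamma = np.asarray(self.gamma, dtype=float).ravel()
        p = self.pi.shape[0]
        if self.pi.shape != (p, p):
            raise ValueError("pi must be square")
        if self.gamma.shape != (p,):
            raise ValueError("gamma must have one entry per trait")
        if np.any(self.gamma <= 0):
            raise ValueError("gamma entries must be positive")
        if self.mask is None:
            self.mask = full_mask(p)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (p, p):
            raise ValueError("mask must be p x p")
        if np.any(self.mask[np.triu_indices(p)]):
            raise ValueError("mask must be strictly lower triangular")
        fixed = ~self.mask
        if np.any(self.pi[np.triu_indices(p)] != 0.0):
            raise ValueError("pi must be strictly lower triangular")
        if np.any(self.pi[fixed] != 0.0):
            raise ValueError("pi has non-zero entries where the mask is fixed")

    @property
    def p(self) -> int:
        return self.pi.shape[0]


@dataclass
class CovStructureSpec:
    """Which parameterization a covariance matrix uses.

    kind: 'UNS', 'FA' (requires ``m``) or 'REC' (optional ``mask``; a missing
    mask means fully recursive).
    """

    kind: str
    m: int | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.kind = self.kind.upper()
        if self.kind not in {"UNS", "FA", "REC"}:
            raise ValueError(f"unknown covariance structure kind {self.kind!r}")
        if self.kind == "FA" and (self.m is None or self.m < 1):
            raise ValueError("FA structure requires m >= 1 factors")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def resolved_mask(self, p: int) -> np.ndarray:
        if self.kind != "REC":
            raise ValueError("mask only defined for REC structures")
        if self.mask is None:
            return full_mask(p)
        if self.mask.shape != (p, p):
            raise ValueError(f"mask shape {self.mask.shape} does not match p={p}")
        return self.mask


def full_mask(p: int) -> np.ndarray:
    """All strictly-lower entries free."""
    return np.tril(np.ones((p, p), dtype=bool), k=-1)


def assemble(structure) -> np.ndarray:
    """Implied p×p trait covariance matrix of a structure."""
    if isinstance(structure, UnstructuredCov):
        return structure.sigma.copy()
    if isinstance(structure, FactorAnalyticCov):
        return structure.lam @ structure.lam.T + np.diag(structure.psi)
    if isinstance(structure, RecursiveCov):
        p = structure.p
        # (I - Pi) is unit lower triangular, invert by triangular solve
        imp = np.eye(p) - structure.pi
        w = linalg.solve_triangular(imp, np.diag(np.sqrt(structure.gamma)), lower=True)
        return w @ w.T
    raise TypeError(f"unknown covariance structure {type(structure).__name__}")


def decompose_recursive(sigma: np.ndarray, mask: np.ndarray | None = None) -> RecursiveCov:
    """Map a PD matrix to its fully recursive parameterization.

    Row ``j`` of Π holds the regression coefficients of trait ``j`` on traits
    ``1..j-1`` and ``γ_j`` the successive conditional variances, i.e. the
    unit-lower-triangular LDL factorization ``Σ = (I−Π)⁻¹ Γ (I−Π)⁻ᵀ``.  Only
    the full mask admits this one-to-one map.
    """
    sigma = _check_symmetric_pd(sigma)
    p = sigma.shape[0]
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not np.array_equal(mask, full_mask(p)):
            raise ValueError("decompose_recursive requires the full (FRM) mask")
    chol = np.linalg.cholesky(sigma)
    gamma = np.diag(chol) ** 2
    unit_lower = chol / np.diag(chol)  # L = (I - Pi)^{-1}
    pi = np.eye(p) - np.linalg.inv(unit_lower)
    pi[np.triu_indices(p)] = 0.0
    return RecursiveCov(pi=pi, gamma=gamma, mask=full_mask(p))


def count_params(spec: CovStructureSpec, p: int) -> int:
    """Free (co)dispersion parameters of one covariance matrix.

    UNS: ``p(p+1)/2``.  FA with m factors: ``p + mp − m(m−1)/2`` (p specific
    variances plus the echelon-constrained loadings).  REC: ``p`` structural
    variances plus one per free mask entry; with a full mask this equals the
    unstructured count.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if spec.kind == "UNS":
        return p * (p + 1) // 2
    if spec.kind == "FA":
        m = spec.m
        if not 1 <= m < p:
            raise ValueError(f"FA requires 1 <= m < p, got m={m}, p={p}")
        return p + m * p - m * (m - 1) // 2
    mask = spec.resolved_mask(p)
    return p + int(mask.sum())


def nearest_fa_start(sigma: np.ndarray, m: int) -> FactorAnalyticCov:
    """Factor-analytic starting values from the leading eigenpairs of sigma.

    Λ is the leading-``m`` scaled eigenvector block rotated to the echelon
    (lower-triangular, non-negative pivot) form via QR; Ψ is the residual
    diagonal floored at a small positive value.  Used to initialize samplers.
    """
    sigma = _check_symmetric_pd(sigma)
    p = sigma.shape[0]
    if not 1 <= m < p:
        raise ValueError(f"need 1 <= m < p, got m={m}, p={p}")
    evals, evecs = np.linalg.eigh(sigma)
    idx = np.argsort(evals)[::-1][:m]
    lam = evecs[:, idx] * np.sqrt(np.maximum(evals[idx], 0.0))
    lam = _to_echelon(lam)
    psi = np.diag(sigma) - np.sum(lam**2, axis=1)
    floor = VARIANCE_FLOOR * float(np.trace(sigma)) / p
    psi = np.maximum(psi, floor)
    return FactorAnalyticCov(lam=lam, psi=psi)


def _to_echelon(lam: np.ndarray) -> np.ndarray:
    """Rotate loadings so rows above the pivot are zero and pivots >= 0.

    Any Λ can be post-multiplied by an orthogonal matrix without changing
    ΛΛ'; the LQ decomposition of the top m×m block supplies the rotation.
    """
    p, m = lam.shape
    # RQ/LQ: find orthogonal Q with lam[:m] @ Q lower triangular
    q_mat, r_mat = np.linalg.qr(lam[:m].T)
    out = lam @ q_mat
    # qr gives lam[:m] = r' q' -> lam[:m] q = r' lower triangular
    signs = np.sign(np.diag(out[:m]))
    signs[signs == 0] = 1.0
    out = out * signs
    tri = np.triu_indices(m, k=1)
    out[: m][tri] = 0.0  # clip numerical dust above the pivots
    return out
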