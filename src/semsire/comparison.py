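"""Model comparison and posterior summaries.

Implements the comparison tool-kit used to rank the covariance-structure
variants: the deviance information criterion with its effective-parameter
count (``DIC = Dbar + pD``, ``Dbar = −2·Mean(L)``, ``pD = Dbar − Dhat`` with
``Dhat`` the deviance at the posterior means of β, u and R0), posterior
mean ± SD tables of heritabilities and genetic/residual correlations on the
animal scale (sire-model conversion ``h² = 4σ²_s/(σ²_s+σ²_e)``), Pearson and
Spearman correlations between the breeding values two fitted models assign
to the same sires, and basic convergence diagnostics (effective sample size
and Geweke z) for the variance-component chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .gibbs import LOG2PI, PosteriorSamples
from .trait_data import DesignMatrices

__all__ = [
    "DICResult",
    "dic",
    "summarize_genetic_params",
    "ebv_correlations",
    "convergence_diagnostics",
    "effective_sample_size",
    "geweke_z",
    "comparison_table",
]


@dataclass
class DICResult:
    dic: float
    pd: float
    mean_l: float

    @property
    def dbar(self) -> float:
        return -2.0 * self.mean_l

    @property
    def dhat(self) -> float:
        return self.dbar - self.pd


def _observed_loglik_at(
    designs: DesignMatrices, beta_mean: list, u_mean: np.ndarray, r0: np.ndarray
) -> float:
    """Observed-data log-likelihood at plug-in (β, u, R0)."""
    labels = designs.traits.labels
    mu = np.column_stack(
        [
            designs.X_full[t] @ beta_mean[j]
            if designs.X_full[t].shape[1]
            else np.zeros(designs.n_animals)
            for j, t in enumerate(labels)
        ]
    )
    mu += u_mean[designs.sire_index]
    y = designs.y
    miss = np.isnan(y)
    groups: dict = {}
    for row, pattern in enumerate(map(tuple, miss)):
        groups.setdefault(pattern, []).append(row)
    total = 0.0
    for pattern, rows in groups.items():
        obs = np.flatnonzero(~np.asarray(pattern))
        if len(obs) == 0:
            continue
        rows = np.asarray(rows)
        dev = y[np.ix_(rows, obs)] - mu[np.ix_(rows, obs)]
        cl = np.linalg.cholesky(r0[np.ix_(obs, obs)])
        half = linalg.solve_triangular(cl, dev.T, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(cl))))
        total += -0.5 * (
            len(rows) * (len(obs) * LOG2PI + logdet) + float(np.sum(half**2))
        )
    return total


def dic(samples: PosteriorSamples, designs: DesignMatrices) -> DICResult:
    """DIC, pD and Mean(L) from stored per-draw log-likelihoods.

    ``Dhat`` plugs in the posterior means of (β, u, R0); the identity
    ``DIC = −2·Mean(L) + pD`` holds by construction.
    """
    if samples.n_draws < 10:
        raise ValueError("need at least 10 stored draws for DIC")
    mean_l = float(np.mean(samples.loglik))
    dbar = -2.0 * mean_l
    beta_mean = [b.mean(axis=0) for b in samples.beta]
    dhat = -2.0 * _observed_loglik_at(
        designs, beta_mean, samples.u.mean(axis=0), samples.posterior_mean_R0()
    )
    p_d = dbar - dhat
    return DICResult(dic=dbar + p_d, pd=p_d, mean_l=mean_l)


def summarize_genetic_params(samples: PosteriorSamples) -> dict:
    """Posterior mean ± SD of heritabilities and correlations.

    Returns the conventional triangular layout: heritability on the diagonal,
    genetic correlations above it, residual correlations below it, as two
    DataFrames ('mean', 'sd') plus the per-draw heritability array.
    """
    g, r = samples.G0, samples.R0
    k, p, _ = g.shape
    gd = np.einsum("kii->ki", g)
    rd = np.einsum("kii->ki", r)
    h2 = 4.0 * gd / (gd + rd)
    corr_g = g / np.sqrt(gd[:, :, None] * gd[:, None, :])
    corr_r = r / np.sqrt(rd[:, :, None] * rd[:, None, :])

    layout_mean = np.zeros((p, p))
    layout_sd = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    il = np.tril_indices(p, k=-1)
    layout_mean[np.diag_indices(p)] = h2.mean(axis=0)
    layout_sd[np.diag_indices(p)] = h2.std(axis=0, ddof=1)
    layout_mean[iu] = corr_g.mean(axis=0)[iu]
    layout_sd[iu] = corr_g.std(axis=0, ddof=1)[iu]
    layout_mean[il] = corr_r.mean(axis=0)[il]
    layout_sd[il] = corr_r.std(axis=0, ddof=1)[il]
    labels = list(samples.trait_labels)
    return {
        "mean": pd.DataFrame(layout_mean, index=labels, columns=labels),
        "sd": pd.DataFrame(layout_sd, index=labels, columns=labels),
        "h2_draws": h2,
    }


def ebv_correlations(
    samples_a: PosteriorSamples, samples_b: PosteriorSamples
) -> pd.DataFrame:
    """Per-trait Pearson and Spearman correlation of the two models' EBVs."""
    ids_a, ids_b = set(samples_a.sire_ids), set(samples_b.sire_ids)
    if ids_a != ids_b:
        diff = sorted(ids_a.symmetric_difference(ids_b))
        raise ValueError(f"sire sets differ between fits: {diff[:10]}")
    order = {s: k for k, s in enumerate(samples_b.sire_ids)}
    perm = np.array([order[s] for s in samples_a.sire_ids])
    ebv_a = samples_a.ebv()
    ebv_b = samples_b.ebv()[perm]
    rows = []
    for j, t in enumerate(samples_a.trait_labels):
        pearson = float(np.corrcoef(ebv_a[:, j], ebv_b[:, j])[0, 1])
        spearman = float(stats.spearmanr(ebv_a[:, j], ebv_b[:, j]).statistic)
        rows.append({"trait": t, "pearson": pearson, "spearman": spearman})
    return pd.DataFrame(rows).set_index("trait")


def effective_sample_size(x: np.ndarray) -> float:
    import arviz as az

    return float(az.ess(np.asarray(x, dtype=float)[None, :]))


def geweke_z(x: np.ndarray, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z: early-window vs late-window mean difference,
    standardized by spectral-density variance estimates at frequency zero."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = x[: max(2, int(first * n))]
    b = x[n - max(2, int(last * n)) :]

    def _spectral_var(seg: np.ndarray) -> float:
        m = len(seg)
        n_batches = max(2, int(np.sqrt(m)))
        size = m // n_batches
        means = np.array(
            [seg[i * size : (i + 1) * size].mean() for i in range(n_batches)]
        )
        return float(np.var(means, ddof=1) * size / m)

    denom = _spectral_var(a) + _spectral_var(b)
    if denom == 0:
        return np.nan
    return float((a.mean() - b.mean()) / np.sqrt(denom))


def convergence_diagnostics(samples: PosteriorSamples) -> pd.DataFrame:
    """ESS and Geweke z for every variance-component chain plus the
    log-likelihood; constant chains are flagged degenerate."""
    labels = list(samples.trait_labels)
    p = len(labels)
    chains = {}
    for i in range(p):
        for j in range(i + 1):
            chains[f"G0[{labels[i]},{labels[j]}]"] = samples.G0[:, i, j]
            chains[f"R0[{labels[i]},{labels[j]}]"] = samples.R0[:, i, j]
    chains["loglik"] = samples.loglik
    rows = []
    for name, x in chains.items():
        degenerate = bool(np.ptp(x) == 0)
        rows.append(
            {
                "chain": name,
                "ess": np.nan if degenerate else effective_sample_size(x),
                "geweke_z": np.nan if degenerate else geweke_z(x),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).set_index("chain")


def plot_traces(samples: PosteriorSamples, path) -> None:
    """Trace plots of the G0/R0 diagonal chains and the log-likelihood."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(samples.trait_labels)
    p = len(labels)
    fig, axes = plt.subplots(p + 1, 2, figsize=(9, 2 * (p + 1)), squeeze=False)
    for j in range(p):
        axes[j, 0].plot(samples.G0[:, j, j], lw=0.5)
        axes[j, 0].set_ylabel(f"G0[{labels[j]}]")
        axes[j, 1].plot(samples.R0[:, j, j], lw=0.5)
        axes[j, 1].set_ylabel(f"R0[{labels[j]}]")
    axes[p, 0].plot(samples.loglik, lw=0.5)
    axes[p, 0].set_ylabel("log L")
    axes[p, 1].axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def comparison_table(results: dict) -> pd.DataFrame:
    """Assemble a model-comparison table from {model_name: DICResult}."""
    return pd.DataFrame(
        {
            name: {"DIC": r.dic, "pD": r.pd, "MeanL": r.mean_l}
            for name, r in results.items()
        }
    ).T
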