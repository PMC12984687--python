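"""Synthetic half-sib datasets with the structure the sire model assumes.

The generator emulates the shape of the real Nellore study this package's
defaults are calibrated to: ~2942 animals from ~236 sires, ~302 single-sex
contemporary groups averaging ~10 animals, six traits on their published
scales, unequal per-trait record counts, and scrotal circumference recorded
only on males.  Phenotypes follow the generative model

    y = Xβ + Zu + ε,   u ~ N(0, A ⊗ G0),   ε ~ N(0, I ⊗ R0),

with ``u`` drawn through the Cholesky factors of A and G0.  When the true
G0 or R0 is given in its factor-analytic or recursive parameterization, the
draw goes through the native construction (factors + specifics, or the
triangular structural system), which is distributionally identical to the
assembled-covariance route but keeps the generator's conventions tied to the
inference code's.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cov_structures as cs
from .datasets import NELLORE_DESCRIPTIVES, nellore_genetic_covariances
from .pedigree import PedigreeTable, RelationshipMatrix, build_A
from .trait_data import TraitSet, PhenotypeTable, MALE_ONLY_TRAITS

__all__ = ["SimScenario", "SimTruth", "simulate_pedigree", "simulate_phenotypes",
           "table1_scenario", "recovery_scenario"]


def _default_missing_rates() -> dict:
    total = 2942
    rates = {}
    for t, (n, *_rest) in NELLORE_DESCRIPTIVES.items():
        if t in MALE_ONLY_TRAITS:
            rates[t] = 0.0  # structural sex rule accounts for the missing females
        else:
            rates[t] = 1.0 - n / total
    return rates


@dataclass
class SimScenario:
    """Study design plus true parameter values for one simulated dataset.

    Defaults reproduce the real study's shape: 2942 animals, 236 sires, 302
    contemporary groups (mean size ~9.7), 45.5% males, trait scales from the
    published descriptives, true (G0, R0) backed out of the published
    sire-model heritabilities and correlations, per-trait MCAR missingness
    matching the published record counts, and SC structurally missing for
    females.
    """

    traits: TraitSet = field(default_factory=TraitSet)
    n_animals: int = 2942
    n_sires: int = 236
    prop_sires_with_sire: float = 0.3
    n_cg: int = 302
    cg_concentration: float = 1.2
    male_fraction: float = 1340 / 2942
    trait_means: dict | None = None
    g_truth: object = None  # UnstructuredCov | FactorAnalyticCov | RecursiveCov
    r_truth: object = None
    cg_sd_frac: float = 0.35  # CG-effect SD as a fraction of the trait's phenotypic SD
    age_slope_frac: float = 0.3  # age effect over the full age range, in residual SDs
    dam_age_effect_frac: float = 0.1
    age_range: tuple[float, float] = (480.0, 629.0)
    dam_age_range: tuple[float, float] = (2.0, 15.0)
    missing_rates: dict | None = None
    male_only_traits: tuple[str, ...] = MALE_ONLY_TRAITS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_truth is None or self.r_truth is None:
            g0, r0 = nellore_genetic_covariances()
            g0 = g0[: self.traits.p, : self.traits.p]
            r0 = r0[: self.traits.p, : self.traits.p]
            # reserve part of the published phenotypic variance for the CG
            # effects so observed SDs track the configured trait scales
            budget = 1.0 - self.cg_sd_frac**2
            if self.g_truth is None:
                self.g_truth = cs.UnstructuredCov(budget * g0)
            if self.r_truth is None:
                self.r_truth = cs.UnstructuredCov(budget * r0)
        if self.trait_means is None:
            self.trait_means = {
                t: NELLORE_DESCRIPTIVES[t][1] if t in NELLORE_DESCRIPTIVES else 0.0
                for t in self.traits.labels
            }
        if self.missing_rates is None:
            defaults = _default_missing_rates()
            self.missing_rates = {t: defaults.get(t, 0.0) for t in self.traits.labels}
        self.g0 = cs.assemble(self.g_truth)
        self.r0 = cs.assemble(self.r_truth)
        if self.g0.shape[0] != self.traits.p or self.r0.shape[0] != self.traits.p:
            raise ValueError("true covariance dimension does not match the trait set")
        for name, mat in (("G0", self.g0), ("R0", self.r0)):
            if np.linalg.eigvalsh(mat)[0] <= 0:
                raise ValueError(f"implied true {name} is not positive definite")


@dataclass
class SimTruth:
    """Ground truth paired with a simulated phenotype table."""

    g0: np.ndarray
    r0: np.ndarray
    g_truth: object
    r_truth: object
    beta: dict
    u: np.ndarray  # n_sires × p
    sire_ids: list
    A: RelationshipMatrix
    pedigree: PedigreeTable
    manifest: dict

    def ebv_rank(self, trait_index: int) -> np.ndarray:
        """Sires ordered best-to-worst by true additive effect for one trait."""
        return np.argsort(-self.u[:, trait_index])


def simulate_pedigree(scenario: SimScenario) -> PedigreeTable:
    """Sire pedigree: founders plus optional paternal grandsire links."""
    rng = np.random.default_rng([scenario.seed, 1])
    sires = [f"S{k + 1:04d}" for k in range(scenario.n_sires)]
    n_gs = max(1, scenario.n_sires // 5)
    grandsires = [f"GS{k + 1:03d}" for k in range(n_gs)]
    linked = rng.random(scenario.n_sires) < scenario.prop_sires_with_sire
    sire_of: dict = {g: None for g in grandsires}
    dam_of: dict = {g: None for g in grandsires}
    for s, has_link in zip(sires, linked):
        sire_of[s] = rng.choice(grandsires) if has_link else None
        dam_of[s] = None
    return PedigreeTable(individuals=grandsires + sires, sire=sire_of, dam=dam_of)


def _native_effect_draw(structure, n: int, chol_rows: np.ndarray | None, rng) -> np.ndarray:
    """n × p draw with row covariance ``chol_rows @ chol_rows.T`` (or I) and
    column covariance given by the structure, via its native construction."""
    p = structure.p
    z = rng.standard_normal((n, p))
    if chol_rows is not None:
        z_rows = chol_rows @ z
    else:
        z_rows = z
    if isinstance(structure, cs.UnstructuredCov):
        return z_rows @ np.linalg.cholesky(structure.sigma).T
    if isinstance(structure, cs.FactorAnalyticCov):
        m = structure.m
        zf = rng.standard_normal((n, m))
        f = chol_rows @ zf if chol_rows is not None else zf
        delta = z_rows * np.sqrt(structure.psi)
        return f @ structure.lam.T + delta
    if isinstance(structure, cs.RecursiveCov):
        liab = z_rows * np.sqrt(structure.gamma)
        imp = np.eye(p) - structure.pi
        return np.linalg.solve(imp, liab.T).T
    raise TypeError(type(structure).__name__)


def simulate_phenotypes(scenario: SimScenario) -> tuple[PhenotypeTable, SimTruth]:
    """Generate one phenotype table and its ground truth."""
    rng = np.random.default_rng([scenario.seed, 2])
    traits = scenario.traits
    p = traits.p
    n = scenario.n_animals

    ped = simulate_pedigree(scenario)
    sire_ids = [i for i in ped.individuals if i.startswith("S")]
    A = build_A(ped, sire_ids)

    # animals to sires: overdispersed progeny-group sizes
    weights = rng.dirichlet(np.full(scenario.n_sires, 5.0))
    sire_index = rng.choice(scenario.n_sires, size=n, p=weights)

    sex = np.where(rng.random(n) < scenario.male_fraction, "M", "F")
    # contemporary groups are single-sex; split the CG budget by sex ratio
    n_cg_m = max(1, int(round(scenario.n_cg * scenario.male_fraction)))
    n_cg_f = max(1, scenario.n_cg - n_cg_m)
    cg = np.empty(n, dtype=object)
    for code, n_groups, prefix in (("M", n_cg_m, "CGM"), ("F", n_cg_f, "CGF")):
        idx = np.flatnonzero(sex == code)
        w = rng.dirichlet(np.full(n_groups, scenario.cg_concentration * 10))
        assignment = rng.choice(n_groups, size=len(idx), p=w)
        for k, g in zip(idx, assignment):
            cg[k] = f"{prefix}{g + 1:03d}"

    age = rng.uniform(*scenario.age_range, size=n)
    dam_age = rng.uniform(*scenario.dam_age_range, size=n)

    chol_a = A.cholesky()
    u = _native_effect_draw(scenario.g_truth, scenario.n_sires, chol_a, rng)
    eps = _native_effect_draw(scenario.r_truth, n, None, rng)

    resid_sd = np.sqrt(np.diag(scenario.r0))
    # CG spread consistent with the variance budget: observed variance is
    # diag(G0 + R0) / (1 - cg_sd_frac^2) up to the small covariate terms
    phen_sd = np.sqrt(np.diag(scenario.g0 + scenario.r0))
    frac = scenario.cg_sd_frac
    cg_sd = (frac / np.sqrt(max(1.0 - frac**2, 1e-12))) * phen_sd if frac > 0 else 0.0 * phen_sd
    means = np.array([scenario.trait_means[t] for t in traits.labels])
    age_span = scenario.age_range[1] - scenario.age_range[0]
    dam_span = scenario.dam_age_range[1] - scenario.dam_age_range[0]

    beta: dict = {"cg_effects": {}, "age_slope": {}, "dam_age_quad": {}}
    y = np.tile(means, (n, 1))
    cg_levels = pd.unique(cg)
    cg_eff = {}
    for t_idx, t in enumerate(traits.labels):
        eff = rng.normal(0.0, cg_sd[t_idx], size=len(cg_levels))
        cg_eff[t] = dict(zip(cg_levels, eff))
    for t_idx, t in enumerate(traits.labels):
        y[:, t_idx] += np.array([cg_eff[t][g] for g in cg])
        if t not in scenario.male_only_traits:
            slope = scenario.age_slope_frac * resid_sd[t_idx] / age_span
            y[:, t_idx] += slope * (age - np.mean(scenario.age_range))
            beta["age_slope"][t] = slope
        quad = scenario.dam_age_effect_frac * resid_sd[t_idx] / (dam_span / 2) ** 2
        center = np.mean(scenario.dam_age_range)
        y[:, t_idx] += -quad * (dam_age - center) ** 2
        beta["dam_age_quad"][t] = -quad
    beta["cg_effects"] = cg_eff

    y += u[sire_index] + eps

    # missingness: structural sex rule first, then MCAR per trait
    for t_idx, t in enumerate(traits.labels):
        if t in scenario.male_only_traits:
            y[sex == "F", t_idx] = np.nan
        rate = scenario.missing_rates.get(t, 0.0)
        if rate > 0:
            eligible = np.flatnonzero(~np.isnan(y[:, t_idx]))
            drop = eligible[rng.random(len(eligible)) < rate]
            y[drop, t_idx] = np.nan

    data = pd.DataFrame(
        {
            "animal_id": [f"A{k + 1:05d}" for k in range(n)],
            "sire_id": [sire_ids[s] for s in sire_index],
            "cg": cg,
            "sex": sex,
            "age_days": age,
            "dam_age": dam_age,
        }
    )
    for t_idx, t in enumerate(traits.labels):
        data[t] = y[:, t_idx]
    tbl = PhenotypeTable(data=data, traits=traits)

    summary = tbl.summary()
    manifest = {
        "seed": scenario.seed,
        "n_animals": n,
        "n_sires": scenario.n_sires,
        "n_cg": int(pd.Series(cg).nunique()),
        "traits": list(traits.labels),
        "record_counts": {t: int(summary.loc[t, "n_records"]) for t in traits.labels},
        "observed_means": {t: float(summary.loc[t, "mean"]) for t in traits.labels},
        "observed_sds": {t: float(summary.loc[t, "sd"]) for t in traits.labels},
    }
    truth = SimTruth(
        g0=scenario.g0,
        r0=scenario.r0,
        g_truth=scenario.g_truth,
        r_truth=scenario.r_truth,
        beta=beta,
        u=u,
        sire_ids=sire_ids,
        A=A,
        pedigree=ped,
        manifest=manifest,
    )
    return tbl, truth


def table1_scenario(seed: int = 0, scale: float = 1.0, **overrides) -> SimScenario:
    """The default study-shaped scenario, optionally scaled down by ``scale``."""
    kwargs = dict(
        n_animals=max(20, int(round(2942 * scale))),
        n_sires=max(5, int(round(236 * scale))),
        n_cg=max(2, int(round(302 * scale))),
        seed=seed,
    )
    kwargs.update(overrides)
    return SimScenario(**kwargs)


def recovery_scenario(
    g_truth,
    r_truth,
    *,
    n_sires: int = 200,
    progeny_per_sire: int = 20,
    trait_labels=None,
    seed: int = 0,
    missing_rate: float = 0.0,
    related_sires: bool = False,
    n_cg: int | None = None,
) -> SimScenario:
    """A plain half-sib recovery design with known (G0, R0).

    Unrelated sires by default (A = I) so the covariance estimation is
    isolated from pedigree structure; balanced progeny groups; generic trait
    labels; no sex-structured missingness.
    """
    g_truth = g_truth if hasattr(g_truth, "p") else cs.UnstructuredCov(np.asarray(g_truth))
    r_truth = r_truth if hasattr(r_truth, "p") else cs.UnstructuredCov(np.asarray(r_truth))
    p = g_truth.p
    labels = tuple(trait_labels) if trait_labels else tuple(f"T{k + 1}" for k in range(p))
    n = n_sires * progeny_per_sire
    return SimScenario(
        traits=TraitSet(labels, {t: "" for t in labels}),
        n_animals=n,
        n_sires=n_sires,
        prop_sires_with_sire=0.5 if related_sires else 0.0,
        n_cg=n_cg if n_cg is not None else max(2, n // 50),
        male_fraction=0.5,
        trait_means={t: 0.0 for t in labels},
        g_truth=g_truth,
        r_truth=r_truth,
        missing_rates={t: missing_rate for t in labels},
        male_only_traits=(),
        seed=seed,
    )


def write_dataset(tbl: PhenotypeTable, truth: SimTruth, outdir, missing: str = "NA") -> dict:
    """Write phenotype CSV, pedigree-style sire list, and a JSON manifest/truth."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pheno_path = outdir / "phenotypes.csv"
    tbl.data.to_csv(pheno_path, index=False, na_rep=missing)

    ped = truth.pedigree
    ped_rows = [
        {"id": i, "sire": ped.sire.get(i) or "0", "dam": ped.dam.get(i) or "0"}
        for i in ped.individuals
    ]
    ped_path = outdir / "pedigree.csv"
    pd.DataFrame(ped_rows).to_csv(ped_path, index=False)

    truth_path = outdir / "truth.json"
    payload = dict(truth.manifest)
    payload["g0"] = truth.g0.tolist()
    payload["r0"] = truth.r0.tolist()
    payload["u"] = truth.u.tolist()
    payload["sire_ids"] = list(truth.sire_ids)
    truth_path.write_text(json.dumps(payload, indent=1))
    return {"phenotypes": str(pheno_path), "pedigree": str(ped_path), "truth": str(truth_path)}
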