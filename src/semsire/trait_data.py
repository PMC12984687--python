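"""Phenotype records and per-trait fixed-effect design construction.

The six default traits are ultrasound carcass and growth measurements
(LMA, BF, RF, BW, HH, SC) recorded once per animal around yearling age.
Fixed effects follow the standard field recipe: contemporary group (CG —
herd × birth year × season × sex) as a class effect for every trait; animal
age at scanning as a linear covariate for every trait except SC (which is
age-standardized by construction); and dam age at calving as linear plus
quadratic covariates for BF, RF, HH and BW, or as a class effect for LMA and
SC.

Trait order is significant: it fixes the causal ordering used by recursive
covariance structures (effects flow from earlier to later labels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "DEFAULT_TRAITS",
    "TraitSet",
    "PhenotypeTable",
    "TraitPlan",
    "FixedEffectsPlan",
    "DesignMatrices",
    "read_phenotypes",
    "build_designs",
    "nellore_default_plan",
]

DEFAULT_TRAITS = ("LMA", "BF", "RF", "BW", "HH", "SC")

DEFAULT_UNITS = {
    "LMA": "cm^2",
    "BF": "mm",
    "RF": "mm",
    "BW": "kg",
    "HH": "cm",
    "SC": "mm",
}

#: traits whose records exist only for males
MALE_ONLY_TRAITS = ("SC",)


@dataclass(frozen=True)
class TraitSet:
    """Ordered trait labels; the order defines the recursive causal ordering."""

    labels: tuple[str, ...] = DEFAULT_TRAITS
    units: dict = field(default_factory=lambda: dict(DEFAULT_UNITS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("trait labels must be unique")

    @property
    def p(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels) -> "TraitSet":
        labels = tuple(labels)
        return TraitSet(labels, {t: self.units.get(t, "") for t in labels})


MANDATORY_COLUMNS = ("animal_id", "sire_id", "cg", "sex", "age_days", "dam_age")


@dataclass
class PhenotypeTable:
    """One row per animal: ids, CG, sex, covariates and trait values (NaN = missing)."""

    data: pd.DataFrame
    traits: TraitSet

    def __post_init__(self) -> None:
        for col in MANDATORY_COLUMNS:
            if col not in self.data.columns:
                raise ValueError(f"phenotype table missing mandatory column {col!r}")
        for t in self.traits.labels:
            if t not in self.data.columns:
                raise ValueError(f"phenotype table missing trait column {t!r}")
        if self.data["sire_id"].isna().any():
            raise ValueError("every record must have a sire id")
        self.data = self.data.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return len(self.data)

    @property
    def sire_ids(self) -> list[str]:
        """Sires in order of first appearance."""
        return list(dict.fromkeys(self.data["sire_id"]))

    def trait_values(self) -> np.ndarray:
        """n × p array of trait values with NaN for missing."""
        return self.data[list(self.traits.labels)].to_numpy(dtype=float)

    def record_counts(self) -> dict:
        vals = self.trait_values()
        return {
            t: int(np.sum(~np.isnan(vals[:, j])))
            for j, t in enumerate(self.traits.labels)
        }

    def summary(self) -> pd.DataFrame:
        """Per-trait record count, mean and SD of observed values."""
        vals = self.trait_values()
        rows = []
        for j, t in enumerate(self.traits.labels):
            v = vals[:, j]
            v = v[~np.isnan(v)]
            rows.append(
                {
                    "trait": t,
                    "n_records": len(v),
                    "mean": float(np.mean(v)) if len(v) else np.nan,
                    "sd": float(np.std(v, ddof=1)) if len(v) > 1 else np.nan,
                }
            )
        return pd.DataFrame(rows).set_index("trait")


@dataclass
class TraitPlan:
    """Fixed effects for one trait: class-effect columns and polynomial covariates.

    ``intercept=False`` with no other terms yields an empty block (a model
    with no fixed effects for that trait).
    """

    class_effects: tuple[str, ...] = ("cg",)
    covariates: tuple[tuple[str, int], ...] = ()  # (column, power)
    intercept: bool = True

    def __post_init__(self) -> None:
        terms = list(self.class_effects) + [f"{c}^{d}" for c, d in self.covariates]
        if len(set(terms)) != len(terms):
            raise ValueError("duplicate effect in trait plan")


@dataclass
class FixedEffectsPlan:
    """Per-trait plans plus dam-age class binning used by derived class effects.

    Dam-age classes (used for LMA and SC) are whole-year bins with the extreme
    bins pooled at ``dam_age_min``/``dam_age_max``.
    """

    plans: dict
    dam_age_min: float = 3.0
    dam_age_max: float = 10.0
    min_cg_records: int = 1

    def for_trait(self, trait: str) -> TraitPlan:
        if trait not in self.plans:
            raise ValueError(f"no fixed-effect plan for trait {trait!r}")
        return self.plans[trait]

    def dam_age_class(self, dam_age: np.ndarray) -> np.ndarray:
        binned = np.floor(np.asarray(dam_age, dtype=float))
        binned = np.clip(binned, self.dam_age_min, self.dam_age_max)
        return binned.astype(int)


def nellore_default_plan(traits: TraitSet | None = None, **kwargs) -> FixedEffectsPlan:
    """The default fixed-effect layout for the six standard traits.

    Unknown trait labels get CG plus a linear age covariate.
    """
    traits = traits or TraitSet()
    plans = {}
    for t in traits.labels:
        if t == "SC":
            plans[t] = TraitPlan(class_effects=("cg", "dam_age_class"))
        elif t == "LMA":
            plans[t] = TraitPlan(
                class_effects=("cg", "dam_age_class"), covariates=(("age_days", 1),)
            )
        elif t in ("BF", "RF", "BW", "HH"):
            plans[t] = TraitPlan(
                class_effects=("cg",),
                covariates=(("age_days", 1), ("dam_age", 1), ("dam_age", 2)),
            )
        else:
            plans[t] = TraitPlan(class_effects=("cg",), covariates=(("age_days", 1),))
    return FixedEffectsPlan(plans=plans, **kwargs)


@dataclass
class DesignMatrices:
    """Per-trait fixed-effect blocks, sire incidence and observation maps.

    ``X_full[t]`` has one row per animal (imputation-ready); the observed-row
    view required by the model likelihood is ``X_obs(t) = X_full[t][obs_idx[t]]``.
    ``sire_index`` maps each animal to a row of the relationship matrix.
    """

    traits: TraitSet
    X_full: dict
    columns: dict
    obs_idx: dict
    sire_index: np.ndarray
    sire_ids: list[str]
    y: np.ndarray  # n × p, NaN where missing

    @property
    def n_animals(self) -> int:
        return len(self.sire_index)

    @property
    def n_sires(self) -> int:
        return len(self.sire_ids)

    def X_obs(self, trait: str) -> np.ndarray:
        return self.X_full[trait][self.obs_idx[trait]]

    def Z_full(self) -> sparse.csr_matrix:
        n = self.n_animals
        return sparse.csr_matrix(
            (np.ones(n), (np.arange(n), self.sire_index)), shape=(n, self.n_sires)
        )

    def Z_obs(self, trait: str) -> sparse.csr_matrix:
        return self.Z_full()[self.obs_idx[trait]]

    def stacked(self) -> tuple[sparse.csr_matrix, sparse.csr_matrix, np.ndarray]:
        """Trait-major stacked (X, Z, y) over observed records only."""
        xs, zs, ys = [], [], []
        z = self.Z_full()
        for j, t in enumerate(self.traits.labels):
            idx = self.obs_idx[t]
            xs.append(sparse.csr_matrix(self.X_full[t][idx]))
            zs.append(z[idx])
            ys.append(self.y[idx, j])
        return (
            sparse.block_diag(xs, format="csr"),
            sparse.block_diag(zs, format="csr"),
            np.concatenate(ys),
        )


def read_phenotypes(
    path,
    traits: TraitSet | None = None,
    *,
    sep: str | None = None,
    missing: str = "NA",
    column_map: dict | None = None,
    strict: bool = False,
) -> PhenotypeTable:
    """Read a delimited phenotype file.

    ``column_map`` renames file columns to the canonical names
    (animal_id, sire_id, cg, sex, age_days, dam_age).  Non-numeric trait
    values other than the missing token are rejected with their row number.
    Trait values recorded for the wrong sex (SC on females) raise under
    ``strict`` and warn otherwise.
    """
    traits = traits or TraitSet()
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    if column_map:
        df = df.rename(columns=column_map)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"phenotype file missing mandatory column {col!r}")

    out = pd.DataFrame(
        {
            "animal_id": df["animal_id"].str.strip(),
            "sire_id": df["sire_id"].str.strip(),
            "cg": df["cg"].str.strip(),
            "sex": df["sex"].str.strip().str.upper(),
        }
    )
    for col in ("age_days", "dam_age"):
        out[col] = pd.to_numeric(df[col], errors="raise")

    for t in traits.labels:
        if t not in df.columns:
            raise ValueError(f"phenotype file missing trait column {t!r}")
        raw = df[t].str.strip()
        is_missing = (raw == missing) | (raw == "")
        numeric = pd.to_numeric(raw.where(~is_missing), errors="coerce")
        bad = (~is_missing) & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric value {raw.iloc[row]!r} for trait {t} at data row {row}"
            )
        out[t] = numeric

    for t in MALE_ONLY_TRAITS:
        if t in traits.labels:
            offending = (out["sex"] == "F") & out[t].notna()
            if offending.any():
                msg = f"{int(offending.sum())} female record(s) carry {t} values"
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg, stacklevel=2)
    return PhenotypeTable(data=out, traits=traits)


def build_designs(tbl: PhenotypeTable, plan: FixedEffectsPlan) -> DesignMatrices:
    """Assemble fixed-effect blocks and sire incidence from a phenotype table.

    Every trait block gets an explicit intercept; class effects use full-rank
    treatment coding with the first-observed level as reference; covariates
    are centered at the mean over that trait's observed records, and quadratic
    terms are the square of the centered linear column.
    """
    df = tbl.data
    n = len(df)
    y = tbl.trait_values()

    work = df.copy()
    work["dam_age_class"] = plan.dam_age_class(df["dam_age"].to_numpy())

    sire_ids = tbl.sire_ids
    sire_pos = {s: k for k, s in enumerate(sire_ids)}
    sire_index = df["sire_id"].map(sire_pos).to_numpy()

    X_full: dict = {}
    columns: dict = {}
    obs_idx: dict = {}
    for j, trait in enumerate(tbl.traits.labels):
        tplan = plan.for_trait(trait)
        observed = np.flatnonzero(~np.isnan(y[:, j]))

        if plan.min_cg_records > 1 and "cg" in tplan.class_effects:
            counts = work["cg"].iloc[observed].value_counts()
            small = set(counts[counts < plan.min_cg_records].index)
            if small:
                warnings.warn(
                    f"trait {trait}: dropping {len(small)} contemporary group(s) "
                    f"with fewer than {plan.min_cg_records} records",
                    stacklevel=2,
                )
                keep = ~work["cg"].iloc[observed].isin(small).to_numpy()
                observed = observed[keep]

        cols: list[np.ndarray] = []
        names: list[str] = []
        if tplan.intercept:
            cols.append(np.ones(n))
            names.append("intercept")
        for eff in tplan.class_effects:
            levels = list(dict.fromkeys(work[eff].iloc[observed]))
            if len(levels) < 2:
                # a single observed level is absorbed by the intercept
                continue
            vals = work[eff].to_numpy()
            for lev in levels[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{eff}[{lev}]")
        for cov, power in tplan.covariates:
            base = work[cov].to_numpy(dtype=float)
            center = float(np.mean(base[observed])) if len(observed) else 0.0
            cols.append((base - center) ** power)
            names.append(f"{cov}^{power}" if power > 1 else cov)

        X_full[trait] = np.column_stack(cols) if cols else np.zeros((n, 0))
        columns[trait] = names
        obs_idx[trait] = observed

    return DesignMatrices(
        traits=tbl.traits,
        X_full=X_full,
        columns=columns,
        obs_idx=obs_idx,
        sire_index=sire_index,
        sire_ids=sire_ids,
        y=y,
    )
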