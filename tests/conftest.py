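import numpy as np
import pandas as pd
import pytest

from semsire import (
    FixedEffectsPlan,
    PhenotypeTable,
    RelationshipMatrix,
    TraitPlan,
    TraitSet,
    build_designs,
)


def make_table(
    n: int,
    n_sires: int,
    trait_labels=("T1", "T2"),
    *,
    rng=None,
    y=None,
    cg_levels=1,
) -> PhenotypeTable:
    """A minimal deterministic phenotype table for kernel-level tests."""
    rng = rng or np.random.default_rng(0)
    traits = TraitSet(tuple(trait_labels), {t: "" for t in trait_labels})
    df = pd.DataFrame(
        {
            "animal_id": [f"A{i}" for i in range(n)],
            "sire_id": [f"S{i % n_sires}" for i in range(n)],
            "cg": [f"c{i % cg_levels}" for i in range(n)],
            "sex": ["M"] * n,
            "age_days": rng.uniform(480, 629, size=n),
            "dam_age": rng.uniform(2, 15, size=n),
        }
    )
    if y is None:
        y = rng.standard_normal((n, len(trait_labels)))
    for j, t in enumerate(trait_labels):
        df[t] = y[:, j]
    return PhenotypeTable(df, traits)


def plain_plan(traits: TraitSet, *, cg: bool = False, intercept: bool = True):
    return FixedEffectsPlan(
        plans={
            t: TraitPlan(
                class_effects=("cg",) if cg else (),
                covariates=(),
                intercept=intercept,
            )
            for t in traits.labels
        }
    )


def identity_A(designs) -> RelationshipMatrix:
    return RelationshipMatrix(
        ids=list(designs.sire_ids), values=np.eye(designs.n_sires)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def recovery_plan():
    def _plan(traits):
        return FixedEffectsPlan(
            plans={t: TraitPlan(class_effects=("cg",), covariates=()) for t in traits.labels}
        )

    return _plan
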