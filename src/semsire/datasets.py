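"""Published field-study summaries used as default inputs.

These are printed posterior summaries from a multi-trait Bayesian sire-model
analysis of ultrasound carcass and growth traits (LMA, BF, RF, BW, HH, SC)
in a Brazilian Nellore population; the underlying records are not publicly
deposited.  The package uses them in two ways:

* as the default trait scales and genetic parameters of the synthetic-data
  generator, so simulated data resemble the real study's structure;
* as the worked example for the structure-selection rules, which operate on
  exactly this kind of printed posterior-mean ± SD table of recursive
  effects.
"""

from __future__ import annotations

import numpy as np

from .trait_data import DEFAULT_TRAITS

__all__ = [
    "NELLORE_DESCRIPTIVES",
    "NELLORE_SMTM_PARAMS",
    "nellore_frm_recursive_effects",
    "nellore_genetic_covariances",
]

#: per-trait record count, phenotypic mean and SD, sires/dams with records and
#: contemporary-group count in the source population (2942 animals total)
NELLORE_DESCRIPTIVES = {
    #        n     mean     sd   sires  dams  cgs
    "LMA": (2770, 48.05, 8.36, 231, 2552, 243),
    "BF": (2577, 1.87, 1.07, 226, 2397, 253),
    "RF": (2566, 2.95, 1.94, 226, 2384, 252),
    "BW": (2942, 339.69, 65.98, 236, 2683, 302),
    "HH": (2349, 136.06, 5.04, 226, 2308, 250),
    "SC": (1340, 245.87, 30.22, 106, 1009, 88),
}

# posterior means from the baseline unstructured multi-trait sire model:
# heritability on the diagonal, genetic correlations above, residual below
# (trait order LMA, BF, RF, BW, HH, SC)
NELLORE_SMTM_PARAMS = np.array(
    [
        [0.29, 0.13, 0.05, 0.35, -0.14, 0.19],
        [0.14, 0.47, 0.62, 0.03, -0.52, 0.09],
        [0.11, 0.57, 0.35, 0.07, -0.42, 0.05],
        [0.49, 0.22, 0.15, 0.28, 0.24, 0.09],
        [0.11, -0.01, -0.03, 0.42, 0.38, -0.17],
        [0.21, -0.02, 0.02, 0.39, 0.20, 0.40],
    ]
)

# fully recursive model posterior summaries: genetic recursive effects above
# the diagonal (row trait acts on column trait), residual effects below the
# diagonal (column trait acts on row trait); entries are (mean, sd)
_FRM_TABLE = {
    "genetic": {
        ("LMA", "BF"): (0.40, 0.40),
        ("LMA", "RF"): (-0.13, 0.27),
        ("LMA", "BW"): (0.48, 0.18),
        ("LMA", "HH"): (-0.54, 0.27),
        ("LMA", "SC"): (0.23, 0.48),
        ("BF", "RF"): (0.56, 0.12),
        ("BF", "BW"): (-0.08, 0.12),
        ("BF", "HH"): (-0.23, 0.16),
        ("BF", "SC"): (-0.09, 0.32),
        ("RF", "BW"): (0.10, 0.14),
        ("RF", "HH"): (-0.24, 0.19),
        ("RF", "SC"): (-0.06, 0.30),
        ("BW", "HH"): (0.83, 0.25),
        ("BW", "SC"): (0.34, 0.49),
        ("HH", "SC"): (-0.41, 0.40),
    },
    "residual": {
        ("LMA", "BF"): (0.21, 0.03),
        ("LMA", "RF"): (0.04, 0.03),
        ("BF", "RF"): (0.55, 0.02),
        ("LMA", "BW"): (0.45, 0.02),
        ("BF", "BW"): (0.09, 0.02),
        ("RF", "BW"): (0.01, 0.02),
        ("LMA", "HH"): (-0.14, 0.03),
        ("BF", "HH"): (-0.05, 0.02),
        ("RF", "HH"): (-0.04, 0.02),
        ("BW", "HH"): (0.60, 0.03),
        ("LMA", "SC"): (0.03, 0.06),
        ("BF", "SC"): (-0.10, 0.06),
        ("RF", "SC"): (0.02, 0.05),
        ("BW", "SC"): (0.48, 0.06),
        ("HH", "SC"): (0.03, 0.06),
    },
}


def nellore_frm_recursive_effects(side: str):
    """Printed recursive-effect posterior summaries from the fully recursive fit.

    Returns a list of :class:`~semsire.structure_selection.RecEffectSummary`
    covering every strictly-lower (i, j) trait pair in the default causal
    order; ``side`` is 'G' (genetic) or 'R' (residual).
    """
    from .structure_selection import RecEffectSummary

    key = {"G": "genetic", "R": "residual"}[side.upper()]
    order = {t: k for k, t in enumerate(DEFAULT_TRAITS)}
    out = []
    for (source, target), (mean, sd) in _FRM_TABLE[key].items():
        i, j = order[target], order[source]  # effect of trait j on trait i, i > j
        out.append(RecEffectSummary(side=side.upper(), i=i, j=j, mean=mean, sd=sd))
    return sorted(out, key=lambda r: (r.i, r.j))


def nellore_genetic_covariances() -> tuple[np.ndarray, np.ndarray]:
    """(G0, R0) on the sire-model scale implied by the published summaries.

    Phenotypic variances come from the descriptive SDs; heritabilities h2 are
    converted to sire variances via the half-sib relation sigma2_s = h2/4 *
    sigma2_p, residual variances are the remainder, and the published genetic
    and residual correlations fill in the covariances.
    """
    p = len(DEFAULT_TRAITS)
    sd = np.array([NELLORE_DESCRIPTIVES[t][2] for t in DEFAULT_TRAITS])
    h2 = np.diag(NELLORE_SMTM_PARAMS)
    var_p = sd**2
    var_s = h2 / 4.0 * var_p
    var_e = var_p - var_s
    corr_g = np.eye(p)
    corr_r = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            corr_g[i, j] = corr_g[j, i] = NELLORE_SMTM_PARAMS[i, j]
            corr_r[i, j] = corr_r[j, i] = NELLORE_SMTM_PARAMS[j, i]
    g0 = corr_g * np.sqrt(np.outer(var_s, var_s))
    r0 = corr_r * np.sqrt(np.outer(var_e, var_e))
    return g0, r0
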