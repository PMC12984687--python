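"""Pruning recursive structures from a fully recursive fit.

Two parsimonious variants are derived from the posterior of the fully
recursive model (FRM):

* REC1 fixes to zero every residual structural coefficient whose posterior
  |mean|/sd ratio is below 1.96 (a two-sided 5% signal rule); the genetic
  side stays fully recursive.
* REC2 fixes to zero every coefficient, genetic or residual, whose posterior
  mean is below 0.15 in absolute value (a magnitude rule).

Both rules use strict inequality: an entry exactly at the threshold is
retained.  Thresholds are arguments with those defaults.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cov_structures import full_mask

__all__ = [
    "RecEffectSummary",
    "rec1_mask",
    "rec2_mask",
    "summaries_from_samples",
    "removal_report",
]


@dataclass(frozen=True)
class RecEffectSummary:
    """Posterior mean ± sd of one structural coefficient π_ij (i > j)."""

    side: str  # 'G' or 'R'
    i: int
    j: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.i <= self.j:
            raise ValueError("structural coefficients require i > j")
        if self.sd <= 0:
            raise ValueError("posterior sd must be positive")

    @property
    def z(self) -> float:
        return abs(self.mean) / self.sd


def _check_complete(summaries: Sequence[RecEffectSummary], p: int, side: str) -> dict:
    table = {}
    for s in summaries:
        if s.side.upper() != side:
            raise ValueError(f"expected side {side!r}, got {s.side!r}")
        table[(s.i, s.j)] = s
    expected = {(i, j) for i in range(p) for j in range(i)}
    missing = expected - set(table)
    if missing:
        raise ValueError(f"missing recursive-effect summaries for entries {sorted(missing)}")
    return table


def rec1_mask(
    residual_summaries: Sequence[RecEffectSummary],
    p: int,
    *,
    z_threshold: float = 1.96,
) -> np.ndarray:
    """Residual free-entry mask under the signal rule |mean|/sd < threshold.

    Returns the residual mask only; REC1 leaves the genetic side fully
    recursive (use :func:`~semsire.cov_structures.full_mask` for it).
    """
    table = _check_complete(residual_summaries, p, "R")
    mask = full_mask(p)
    for (i, j), s in table.items():
        if s.z < z_threshold:
            mask[i, j] = False
    return mask


def rec2_mask(
    genetic_summaries: Sequence[RecEffectSummary],
    residual_summaries: Sequence[RecEffectSummary],
    p: int,
    *,
    magnitude_threshold: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """(genetic, residual) free-entry masks under the magnitude rule."""
    masks = []
    for side, summaries in (("G", genetic_summaries), ("R", residual_summaries)):
        table = _check_complete(summaries, p, side)
        mask = full_mask(p)
        for (i, j), s in table.items():
            if abs(s.mean) < magnitude_threshold:
                mask[i, j] = False
        masks.append(mask)
    return masks[0], masks[1]


def summaries_from_samples(pi_draws: np.ndarray, side: str) -> list[RecEffectSummary]:
    """Posterior summaries of Π from stored draws (draws × p × p)."""
    pi_draws = np.asarray(pi_draws, dtype=float)
    p = pi_draws.shape[1]
    out = []
    for i in range(p):
        for j in range(i):
            draws = pi_draws[:, i, j]
            sd = float(np.std(draws, ddof=1))
            out.append(
                RecEffectSummary(
                    side=side.upper(), i=i, j=j, mean=float(np.mean(draws)), sd=max(sd, 1e-300)
                )
            )
    return out


def removal_report(
    mask: np.ndarray, trait_labels: Iterable[str], side: str
) -> list[str]:
    """Human-readable list of the trait pairs fixed to zero by a mask."""
    labels = list(trait_labels)
    p = len(labels)
    lines = []
    for i in range(p):
        for j in range(i):
            if not mask[i, j]:
                lines.append(
                    f"{side}: effect of {labels[j]} on {labels[i]} fixed to 0"
                )
    return lines
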