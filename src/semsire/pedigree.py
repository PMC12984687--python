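"""Pedigree handling and Wright's numerator relationship matrix.

The sire model treats the additive genetic covariance among sire effects as
``A ⊗ G0`` where ``A`` is Wright's numerator relationship matrix among the
sires with recorded progeny.  ``A`` is built by the tabular method over the
full ancestor closure of the requested individuals (dam links are used when
present, so maternal paths and inbreeding contribute) and then restricted to
the requested ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PedigreeError",
    "PedigreeTable",
    "RelationshipMatrix",
    "read_pedigree",
    "build_A",
]


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates)."""


@dataclass
class PedigreeTable:
    """Individuals with (possibly unknown) sire and dam.

    Parents are ``None`` when unknown.  Construction validates id uniqueness
    and acyclicity and stores individuals in a topological order (parents
    before offspring).
    """

    individuals: list[str]
    sire: dict[str, str | None] = field(repr=False)
    dam: dict[str, str | None] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            seen: set[str] = set()
            for ind in self.individuals:
                if ind in seen:
                    raise PedigreeError(f"duplicate individual id {ind!r}")
                seen.add(ind)
        self.individuals = self._toposort()

    def parents(self, ind: str) -> tuple[str | None, str | None]:
        return self.sire.get(ind), self.dam.get(ind)

    def _toposort(self) -> list[str]:
        order: list[str] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done
        known = set(self.individuals)

        for root in self.individuals:
            if state.get(root) == 1:
                continue
            stack: list[tuple[str, bool]] = [(root, False)]
            while stack:
                node, expanded = stack.pop()
                if expanded:
                    state[node] = 1
                    order.append(node)
                    continue
                if state.get(node) == 1:
                    continue
                if state.get(node) == 0:
                    raise PedigreeError(
                        f"pedigree cycle detected involving id {node!r}"
                    )
                state[node] = 0
                stack.append((node, True))
                for parent in (self.sire.get(node), self.dam.get(node)):
                    if parent is not None and parent in known:
                        if state.get(parent) == 0:
                            raise PedigreeError(
                                f"pedigree cycle detected involving id {parent!r}"
                            )
                        if state.get(parent) != 1:
                            stack.append((parent, False))
        return order

    def ancestor_closure(self, ids: Sequence[str]) -> list[str]:
        """All pedigree members that are ancestors of (or are) ``ids``."""
        known = set(self.individuals)
        wanted: set[str] = set()
        stack = [i for i in ids if i in known]
        while stack:
            node = stack.pop()
            if node in wanted:
                continue
            wanted.add(node)
            for parent in (self.sire.get(node), self.dam.get(node)):
                if parent is not None and parent in known:
                    stack.append(parent)
        return [i for i in self.individuals if i in wanted]


@dataclass
class RelationshipMatrix:
    """Additive relationship matrix restricted to an ordered id list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("relationship matrix shape does not match ids")

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_identity(self, tol: float = 0.0) -> bool:
        return bool(np.all(np.abs(self.values - np.eye(self.n)) <= tol))

    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.values)

    def restrict(self, ids: Sequence[str]) -> "RelationshipMatrix":
        """Subset/reorder to ``ids`` (all must be present)."""
        pos = {s: k for k, s in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids not in relationship matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return RelationshipMatrix(ids=list(ids), values=self.values[np.ix_(idx, idx)])

    def cholesky(self) -> np.ndarray:
        # tiny jitter guards against numerically semi-definite pedigrees
        try:
            return np.linalg.cholesky(self.values)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * np.trace(self.values) / self.n
            return np.linalg.cholesky(self.values + jitter * np.eye(self.n))


def read_pedigree(
    path,
    *,
    sep: str | None = None,
    missing: str = "0",
    id_col: str = "id",
    sire_col: str = "sire",
    dam_col: str = "dam",
) -> PedigreeTable:
    """Read a delimited pedigree file into a :class:`PedigreeTable`.

    The file must have a header naming the id/sire/dam columns (the dam column
    is optional).  ``missing`` is the unknown-parent token; empty cells are
    also treated as unknown.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    if id_col not in df.columns or sire_col not in df.columns:
        raise PedigreeError(
            f"pedigree file must contain columns {id_col!r} and {sire_col!r}; "
            f"found {list(df.columns)}"
        )

    def clean(value) -> str | None:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        value = str(value).strip()
        if value == "" or value == missing or value.lower() == "nan":
            return None
        return value

    individuals: list[str] = []
    sire: dict[str, str | None] = {}
    dam: dict[str, str | None] = {}
    has_dam = dam_col in df.columns
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ind = clean(rec[id_col])
        if ind is None:
            raise PedigreeError("pedigree row with missing individual id")
        individuals.append(ind)
        sire[ind] = clean(rec[sire_col])
        dam[ind] = clean(rec[dam_col]) if has_dam else None
    return PedigreeTable(individuals=individuals, sire=sire, dam=dam)


def build_A(ped: PedigreeTable, keep_ids: Sequence[str]) -> RelationshipMatrix:
    """Wright's numerator relationship matrix among ``keep_ids``.

    Computed by the tabular method over the ancestor closure of ``keep_ids``
    and then restricted to ``keep_ids`` in the given order.  Ids absent from
    the pedigree are treated as unrelated, non-inbred founders (with a
    warning), so phenotype files may reference unpedigreed sires.
    """
    keep_ids = list(keep_ids)
    if not keep_ids:
        raise ValueError("keep_ids must be non-empty")
    if len(set(keep_ids)) != len(keep_ids):
        raise ValueError("keep_ids contains duplicates")

    known = set(ped.individuals)
    missing = [i for i in keep_ids if i not in known]
    if missing:
        warnings.warn(
            f"{len(missing)} id(s) absent from the pedigree treated as unrelated "
            f"founders: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )

    members = ped.ancestor_closure([i for i in keep_ids if i in known])
    index = {ind: k for k, ind in enumerate(members)}
    n = len(members)
    a = np.zeros((n, n))
    # tabular method: individuals in topological order, so parents precede
    for i, ind in enumerate(members):
        s, d = ped.parents(ind)
        si = index.get(s) if s is not None else None
        di = index.get(d) if d is not None else None
        if si is not None and di is not None:
            a[i, i] = 1.0 + 0.5 * a[si, di]
        else:
            a[i, i] = 1.0
        for j in range(i):
            val = 0.0
            if si is not None:
                val += 0.5 * a[j, si]
            if di is not None:
                val += 0.5 * a[j, di]
            a[i, j] = a[j, i] = val

    out = np.eye(len(keep_ids))
    pos = {ind: k for k, ind in enumerate(keep_ids)}
    present = [i for i in keep_ids if i in index]
    if present:
        rows = np.array([pos[i] for i in present])
        cols = np.array([index[i] for i in present])
        out[np.ix_(rows, rows)] = a[np.ix_(cols, cols)]
    return RelationshipMatrix(ids=keep_ids, values=out)
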