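"""Pedigree handling and pedigree-based relationship matrices.

The polygenic covariance structure used throughout the package is
``Phi = 2 * kinship``, where the kinship coefficient ``phi(i, j)`` is the
probability that an allele sampled at random from individual ``i`` is
identical by descent to an allele sampled at random from ``j``.  ``Phi`` has
diagonal ``1 + F_i`` (``F_i`` the inbreeding coefficient) and is positive
semidefinite on any valid pedigree.

Founders are assumed non-inbred and mutually unrelated.  Individuals that
appear only as parents are materialized as founders (with a warning), so a
partially recorded pedigree still yields a valid matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Pedigree", "RelationshipMatrix", "read_pedigree", "kinship_matrix"]


class PedigreeError(ValueError):
    """Malformed pedigree input (cycles, half-specified parents, duplicates)."""


@dataclass
class Pedigree:
    """A validated pedigree.

    Attributes
    ----------
    table:
        One row per individual with columns ``family``, ``id``, ``father``,
        ``mother``, ``sex``; missing parents stored as ``None``.  Both parents
        are present or both absent (founder) — half-specified parent records
        are rejected at construction.
    """

    table: pd.DataFrame
    _order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].tolist()
            raise PedigreeError(f"duplicate individual id(s): {dups}")
        half = t[(t["father"].isna()) != (t["mother"].isna())]
        if len(half):
            raise PedigreeError(
                f"half-specified parents for individual(s): {half['id'].tolist()}"
            )
        known = set(t["id"])
        extra = []
        for col in ("father", "mother"):
            for pid in t[col].dropna():
                if pid not in known and pid not in extra:
                    extra.append(pid)
        if extra:
            warnings.warn(
                f"{len(extra)} individual(s) referenced only as parents; "
                f"materialized as founders: {extra}",
                stacklevel=2,
            )
            fam = {r.id: r.family for r in t.itertuples()}
            rows = []
            for pid in extra:
                child_fams = t.loc[
                    (t["father"] == pid) | (t["mother"] == pid), "family"
                ]
                rows.append(
                    {
                        "family": child_fams.iloc[0],
                        "id": pid,
                        "father": None,
                        "mother": None,
                        "sex": 0,
                    }
                )
            object.__setattr__(
                self, "table", pd.concat([t, pd.DataFrame(rows)], ignore_index=True)
            )
        self._order = self._toposort()

    # -- structure ---------------------------------------------------------

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    @property
    def n(self) -> int:
        return len(self.table)

    def parents(self) -> dict[str, tuple[str | None, str | None]]:
        return {
            r.id: (None, None) if pd.isna(r.father) else (r.father, r.mother)
            for r in self.table.itertuples()
        }

    def founders(self) -> list[str]:
        return [i for i, (f, _) in self.parents().items() if f is None]

    def topological_order(self) -> list[str]:
        """Individual ids with every parent preceding its children."""
        return list(self._order)

    def _toposort(self) -> list[str]:
        par = self.parents()
        state: dict[str, int] = {}  # 0 in progress, 1 done
        order: list[str] = []

        def visit(i: str) -> None:
            if state.get(i) == 1:
                return
            if state.get(i) == 0:
                raise PedigreeError(f"pedigree cycle detected at individual {i!r}")
            state[i] = 0
            f, m = par[i]
            if f is not None:
                visit(f)
                visit(m)
            state[i] = 1
            order.append(i)

        for i in par:
            visit(i)
        return order


@dataclass
class RelationshipMatrix:
    """``Phi = 2 * kinship`` with an explicit id ordering contract.

    Rows/columns follow ``ids``; downstream alignment to a phenotype table is
    an explicit step (:meth:`aligned`) and misalignment is an error, never a
    silent reorder.
    """

    phi: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        if phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("Phi shape does not match id list")
        if not np.allclose(phi, phi.T):
            raise ValueError("Phi must be symmetric")
        self.phi = phi

    def aligned(self, ids: list[str]) -> np.ndarray:
        """Return Phi reordered to ``ids``; every id must be present."""
        pos = {v: k for k, v in enumerate(self.ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"ids absent from relationship matrix: {missing[:5]}")
        idx = np.array([pos[i] for i in ids])
        return self.phi[np.ix_(idx, idx)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.phi, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id"
        )


def read_pedigree(path) -> Pedigree:
    """Read the first five columns of a PED-style whitespace-delimited file.

    Columns: family, individual id, father id, mother id, sex; ``0`` denotes
    a missing parent.  No header.
    """
    raw = pd.read_csv(path, sep=r"\s+", header=None, dtype=str, comment="#")
    if raw.shape[1] < 5:
        raise PedigreeError("PED file must have at least 5 columns")
    t = raw.iloc[:, :5].copy()
    t.columns = ["family", "id", "father", "mother", "sex"]
    t["father"] = t["father"].where(t["father"] != "0", None)
    t["mother"] = t["mother"].where(t["mother"] != "0", None)
    t["sex"] = pd.to_numeric(t["sex"], errors="coerce").fillna(0).astype(int)
    return Pedigree(t)


def kinship_matrix(ped: Pedigree) -> RelationshipMatrix:
    """Compute ``Phi = 2 * kinship`` by the standard recursive algorithm.

    phi(i, i) = (1 + phi(f_i, m_i)) / 2 and, for a non-founder ``i`` not
    ancestral to ``j``, phi(i, j) = (phi(f_i, j) + phi(m_i, j)) / 2; founders
    are mutually unrelated and non-inbred.  Processing individuals in
    topological order makes the recursion well-defined.
    """
    order = ped.topological_order()
    idx = {i: k for k, i in enumerate(order)}
    par = ped.parents()
    n = len(order)
    K = np.zeros((n, n))
    for i in order:
        a = idx[i]
        f, m = par[i]
        if f is None:
            K[a, a] = 0.5
        else:
            K[a, a] = 0.5 * (1.0 + K[idx[f], idx[m]])
        # i's kinship with every earlier j: i cannot be an ancestor of j
        # because parents precede children in topological order.  Founders
        # are unrelated to everyone placed before them.
        if f is not None:
            fa, mo = idx[f], idx[m]
            K[a, :a] = K[:a, a] = 0.5 * (K[fa, :a] + K[mo, :a])
    phi = 2.0 * K
    # restore the file's row order
    want = ped.ids
    perm = np.array([idx[i] for i in want])
    return RelationshipMatrix(phi[np.ix_(perm, perm)], want)
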