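"""Pedigree kinship coefficients and the familial adjustment score.

The kinship coefficient f(i, j) is the probability that an allele drawn
at random from i and one drawn from j are identical by descent.  It is
computed by the standard recursion over a pedigree sorted so parents
precede children:

    f(i, i) = 0.5 * (1 + f(father_i, mother_i))
    f(i, j) = 0.5 * (f(father_i, j) + f(mother_i, j))   (j earlier, j != i)

with a missing parent contributing 0 (each unknown parent is a unique,
unrelated, non-inbred founder).

The familial adjustment score (FAS) is a per-individual covariate that
absorbs the share of a continuous phenotype attributable to relatedness
within the cohort: the kinship-weighted sum of the other cohort members'
phenotype values, divided by the cohort size and by the focal
individual's own phenotype value.  Including it as a regression covariate
removes phenotypic variance due to both maternal and paternal
relationships.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, LookupError_, ParameterError, PedigreeError

FEMALE, MALE = "F", "M"


@dataclass(frozen=True)
class PedigreeMember:
    id: str
    father: str | None
    mother: str | None
    sex: str
    age: float | None = None


@dataclass
class Pedigree:
    members: list[PedigreeMember]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate individual ids in pedigree")
        known = set(ids)
        for m in self.members:
            for p in (m.father, m.mother):
                if p is not None and p not in known:
                    raise LookupError_(f"parent {p!r} of {m.id!r} not in pedigree")
        self._topological_order()  # raises on cycles

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def founders(self) -> list[str]:
        return [m.id for m in self.members if m.father is None and m.mother is None]

    def _topological_order(self) -> list[str]:
        by_id = {m.id: m for m in self.members}
        indeg = {m.id: sum(p is not None for p in (m.father, m.mother))
                 for m in self.members}
        children: dict[str, list[str]] = {m.id: [] for m in self.members}
        for m in self.members:
            for p in (m.father, m.mother):
                if p is not None:
                    children[p].append(m.id)
        order = [i for i in self.ids if indeg[i] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) != len(self.members):
            raise PedigreeError("pedigree contains a cycle (individual is its own ancestor)")
        return order

    def member(self, ind_id: str) -> PedigreeMember:
        for m in self.members:
            if m.id == ind_id:
                return m
        raise LookupError_(f"{ind_id!r} not in pedigree")


@dataclass
class KinshipMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, f(i,i) >= 0.5

    def __post_init__(self) -> None:
        self._index = {i: k for k, i in enumerate(self.ids)}

    def f(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        idx = [self._index[i] for i in ids]
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = [
            (self.ids[i], self.ids[j], self.values[i, j])
            for i in range(len(self.ids))
            for j in range(i, len(self.ids))
        ]
        return pd.DataFrame(rows, columns=["id_a", "id_b", "f"])


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Recursive kinship over the whole pedigree, O(n^2)."""
    topo = ped._topological_order()
    pos = {i: k for k, i in enumerate(topo)}
    by_id = {m.id: m for m in ped.members}
    n = len(topo)
    F = np.zeros((n, n))
    for k, ind in enumerate(topo):
        m = by_id[ind]
        fa = pos.get(m.father) if m.father is not None else None
        mo = pos.get(m.mother) if m.mother is not None else None
        if fa is not None and mo is not None:
            F[k, k] = 0.5 * (1.0 + F[fa, mo])
        else:
            F[k, k] = 0.5
        if k:
            row = np.zeros(k)
            if fa is not None:
                row += F[fa, :k]
            if mo is not None:
                row += F[mo, :k]
            row *= 0.5
            F[k, :k] = row
            F[:k, k] = row
    # return in the pedigree's input order
    order = [pos[i] for i in ped.ids]
    return KinshipMatrix(ped.ids, F[np.ix_(order, order)])


def familial_adjustment_scores(
    phenotype: Mapping[str, float] | pd.Series,
    kin: KinshipMatrix,
    include_self: bool = False,
) -> pd.Series:
    """FAS_i = sum_{j != i} y_j * f(i, j) / (N * y_i).

    ``N`` is the number of cohort individuals with a measured phenotype;
    individuals with a missing phenotype contribute nothing to other
    individuals' sums and receive a missing score.  ``include_self``
    restores the self term for sensitivity analyses.
    """
    pheno = pd.Series(dict(phenotype), dtype=float)
    missing_ids = [i for i in pheno.index if i not in kin._index]
    if missing_ids:
        raise ConsistencyError(
            f"phenotype ids absent from kinship matrix: {missing_ids[:5]}")
    measured = pheno.dropna()
    if (measured == 0).any():
        bad = list(measured.index[measured == 0])[:5]
        raise ParameterError(
            f"familial adjustment score undefined for zero phenotype: {bad}")
    n = len(measured)
    sub = kin.subset(list(measured.index))
    K = sub.values.copy()
    if not include_self:
        np.fill_diagonal(K, 0.0)
    weighted = K @ measured.to_numpy()
    scores = weighted / (n * measured.to_numpy())
    out = pd.Series(np.nan, index=pheno.index, dtype=float)
    out.loc[measured.index] = scores
    return out


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path) -> Pedigree:
    """Pedigree TSV: columns id, father, mother, sex, age ('0'/empty = unknown)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "father", "mother", "sex", "age"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")

    def parent(v: str | float) -> str | None:
        if pd.isna(v) or str(v).strip() in ("0", ""):
            return None
        return str(v)

    members = [
        PedigreeMember(
            id=str(r.id),
            father=parent(r.father),
            mother=parent(r.mother),
            sex=str(r.sex).upper(),
            age=float(r.age) if not pd.isna(r.age) and str(r.age) != "" else None,
        )
        for r in df.itertuples()
    ]
    return Pedigree(members)


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    pd.DataFrame(
        {
            "id": [m.id for m in ped.members],
            "father": [m.father or "0" for m in ped.members],
            "mother": [m.mother or "0" for m in ped.members],
            "sex": [m.sex for m in ped.members],
            "age": [("" if m.age is None else m.age) for m in ped.members],
        }
    ).to_csv(path, sep="\t", index=False)


def write_kinship(kin: KinshipMatrix, long_path: str | Path,
                  matrix_path: str | Path | None = None) -> None:
    kin.to_long().to_csv(long_path, sep="\t", index=False)
    if matrix_path is not None:
        kin.to_frame().to_csv(matrix_path)


def write_fas(scores: pd.Series, path: str | Path) -> None:
    scores.rename("score").rename_axis("id").reset_index().to_csv(
        path, sep="\t", index=False)
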