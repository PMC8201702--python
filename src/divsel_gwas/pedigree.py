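"""Pedigree handling and the numerator relationship matrix (A).

A pedigree is a pandas DataFrame with columns ``id, sire, dam, sex,
line, generation, role``; unknown parents are encoded as the string
``"0"`` (or NaN/None, normalised on validation).  The numerator
relationship matrix is built with the tabular (recursive) method over
the full ancestral pedigree; unknown parents are treated as unrelated,
non-inbred founders.  The diagonal of A is 1 + F where F is the
inbreeding coefficient of the individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "line", "generation", "role"]

UNKNOWN = "0"


class PedigreeError(ValueError):
    pass


def normalize_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with string ids and unknown parents as ``"0"``."""
    out = ped.copy()
    for col in ("id", "sire", "dam"):
        if col not in out.columns:
            raise PedigreeError(f"pedigree is missing column {col!r}")
        out[col] = out[col].astype(object)
        out[col] = out[col].where(out[col].notna(), UNKNOWN).astype(str)
        out.loc[out[col].isin(("", "nan", "None", "NA", ".")), col] = UNKNOWN
    if out["id"].duplicated().any():
        dup = out.loc[out["id"].duplicated(), "id"].iloc[0]
        raise PedigreeError(f"duplicated individual id {dup!r}")
    if (out["id"] == UNKNOWN).any():
        raise PedigreeError('"0" is reserved for unknown parents')
    return out


def read_pedigree(path) -> pd.DataFrame:
    """Read a pedigree CSV (columns id, sire, dam, sex, line, generation, role)."""
    ped = pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str})
    return normalize_pedigree(ped)


def write_pedigree(ped: pd.DataFrame, path) -> None:
    normalize_pedigree(ped).to_csv(path, index=False)


def topological_order(ped: pd.DataFrame) -> list[str]:
    """Order ids so every parent precedes its offspring.

    Raises :class:`PedigreeError` with an offending chain if the
    pedigree contains a cycle.
    """
    ids = list(ped["id"])
    idx = {i: k for k, i in enumerate(ids)}
    sire = list(ped["sire"])
    dam = list(ped["dam"])
    n = len(ids)
    children: list[list[int]] = [[] for _ in range(n)]
    indeg = [0] * n
    for k in range(n):
        for p in (sire[k], dam[k]):
            if p != UNKNOWN and p in idx:
                children[idx[p]].append(k)
                indeg[k] += 1
    queue = [k for k in range(n) if indeg[k] == 0]
    order: list[int] = []
    while queue:
        nxt: list[int] = []
        for k in queue:
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) < n:
        stuck = [ids[k] for k in range(n) if indeg[k] > 0]
        chain = _find_cycle(ids, idx, sire, dam, stuck)
        raise PedigreeError(f"pedigree contains a cycle: {' -> '.join(chain)}")
    return [ids[k] for k in order]


def _find_cycle(ids, idx, sire, dam, stuck) -> list[str]:
    seen: list[str] = []
    cur = stuck[0]
    pos = {}
    while cur not in pos:
        pos[cur] = len(seen)
        seen.append(cur)
        k = idx[cur]
        nxt = None
        for p in (sire[k], dam[k]):
            if p in idx and p in stuck:
                nxt = p
                break
        if nxt is None:  # pragma: no cover - defensive
            break
        cur = nxt
    return seen[pos.get(cur, 0):] + [cur]


def ancestors_closure(ped: pd.DataFrame, subset) -> pd.DataFrame:
    """Restrict the pedigree to ``subset`` and all their ancestors."""
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    keep: set[str] = set()
    stack = [str(s) for s in subset]
    missing = [s for s in stack if s not in sire]
    if missing:
        raise PedigreeError(f"subset ids not in pedigree: {missing[:5]}")
    while stack:
        i = stack.pop()
        if i in keep or i == UNKNOWN or i not in sire:
            continue
        keep.add(i)
        stack.append(sire[i])
        stack.append(dam[i])
    return ped[ped["id"].isin(keep)]


@dataclass
class RelationshipMatrix:
    """Numerator relationship matrix over an ordered id list."""

    ids: list[str]
    values: np.ndarray
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def inbreeding(self) -> pd.Series:
        return pd.Series(np.diag(self.values) - 1.0, index=self.ids, name="F")

    def subset(self, ids) -> "RelationshipMatrix":
        ix = [self._index[str(i)] for i in ids]
        return RelationshipMatrix([str(i) for i in ids], self.values[np.ix_(ix, ix)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    def write_triplets(self, path, tol: float = 0.0) -> None:
        """Sparse lower-triangle triplet format (i, j, a_ij)."""
        iidx, jidx = np.tril_indices(len(self.ids))
        vals = self.values[iidx, jidx]
        mask = np.abs(vals) > tol
        pd.DataFrame(
            {
                "id_i": [self.ids[k] for k in iidx[mask]],
                "id_j": [self.ids[k] for k in jidx[mask]],
                "a": vals[mask],
            }
        ).to_csv(path, sep="\t", index=False)


def build_a_matrix(ped: pd.DataFrame, subset=None) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Computed over the full ancestral pedigree of ``subset`` (all ids if
    None), then restricted to ``subset`` in the given order.
    """
    ped = normalize_pedigree(ped)
    if subset is not None:
        subset = [str(s) for s in subset]
        ped = ancestors_closure(ped, subset)
    order = topological_order(ped)
    idx = {i: k for k, i in enumerate(order)}
    sire = dict(zip(ped["id"], ped["sire"]))
    dam = dict(zip(ped["id"], ped["dam"]))
    n = len(order)
    a = np.zeros((n, n))
    for k, i in enumerate(order):
        s, d = sire[i], dam[i]
        si = idx.get(s, -1) if s != UNKNOWN else -1
        di = idx.get(d, -1) if d != UNKNOWN else -1
        row = np.zeros(k)
        if si >= 0:
            row += 0.5 * a[si, :k]
        if di >= 0:
            row += 0.5 * a[di, :k]
        a[k, :k] = row
        a[:k, k] = row
        a[k, k] = 1.0 + (0.5 * a[si, di] if (si >= 0 and di >= 0) else 0.0)
    if subset is None:
        return RelationshipMatrix(order, a)
    ix = [idx[s] for s in subset]
    return RelationshipMatrix(subset, a[np.ix_(ix, ix)])


def mean_inbreeding(ped: pd.DataFrame, generation: int, line: str | None = None) -> float:
    """Mean pedigree inbreeding coefficient of a cohort.

    The cohort is all individuals of ``generation`` (optionally of one
    line); F is diag(A) - 1 computed over the cohort's full ancestry.
    """
    ped = normalize_pedigree(ped)
    mask = ped["generation"] == generation
    if line is not None:
        mask &= ped["line"] == line
    cohort = list(ped.loc[mask, "id"])
    if not cohort:
        raise PedigreeError(
            f"no individuals in generation {generation}"
            + (f" line {line}" if line else "")
        )
    amat = build_a_matrix(ped, cohort)
    return float(np.mean(np.diag(amat.values) - 1.0))
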