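"""Pedigree handling and the numerator relationship matrix (A).

A pedigree is a list of (individual, sire, dam) records with unknown parents
coded by a reserved token.  Founders are assumed unrelated and non-inbred, the
standard base-population assumption of the tabular method.  The A-matrix is
built by the tabular recursion

    a_ii = 1 + 0.5 * a(sire_i, dam_i)          (0 if either parent unknown)
    a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))  for j earlier in the ordering

so the diagonal is 1 + F (F the inbreeding coefficient) and, for non-inbred
pedigrees, half-sibs are 0.25, full-sibs 0.50 and parent-offspring pairs 0.50.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import StructuralError

#: Reserved token for an unknown parent in pedigree records.
UNKNOWN = "UNKNOWN"

#: Relationship classes used by :func:`expected_class`.
CLASS_SELF = "self"
CLASS_FULL_SIB = "full-sib"
CLASS_HALF_SIB = "half-sib"
CLASS_PARENT_OFFSPRING = "parent-offspring"
CLASS_UNRELATED = "unrelated/other"

ALL_CLASSES = (
    CLASS_SELF,
    CLASS_FULL_SIB,
    CLASS_HALF_SIB,
    CLASS_PARENT_OFFSPRING,
    CLASS_UNRELATED,
)


def _is_unknown(parent) -> bool:
    return (
        parent is None
        or (isinstance(parent, float) and np.isnan(parent))
        or str(parent).strip() in ("", UNKNOWN, "NA", "0")
    )


@dataclass
class Pedigree:
    """Ordered pedigree records.

    Parameters
    ----------
    ids, sires, dams
        Parallel lists; unknown parents are ``UNKNOWN``.
    groups
        Optional genetic group (provenance) per individual.
    """

    ids: list[str]
    sires: list[str]
    dams: list[str]
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.sires = [UNKNOWN if _is_unknown(s) else str(s) for s in self.sires]
        self.dams = [UNKNOWN if _is_unknown(d) else str(d) for d in self.dams]
        if len(self.ids) != len(self.sires) or len(self.ids) != len(self.dams):
            raise StructuralError("ids, sires and dams must have equal length")
        dup = pd.Index(self.ids).duplicated()
        if dup.any():
            bad = sorted({self.ids[i] for i in np.flatnonzero(dup)})
            raise StructuralError(f"duplicate individual ids: {bad}")

    def __len__(self) -> int:
        return len(self.ids)

    def parents_of(self, individual: str) -> tuple[str, str]:
        try:
            k = self.ids.index(individual)
        except ValueError:
            raise KeyError(f"unknown individual: {individual!r}") from None
        return self.sires[k], self.dams[k]

    @property
    def founders(self) -> list[str]:
        return [
            i
            for i, s, d in zip(self.ids, self.sires, self.dams)
            if s == UNKNOWN and d == UNKNOWN
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.ids, "sire": self.sires, "dam": self.dams})
        if self.groups:
            df["group"] = [self.groups.get(i, "") for i in self.ids]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        groups = {}
        if "group" in df.columns:
            groups = {
                str(r["id"]): str(r["group"])
                for _, r in df.iterrows()
                if not _is_unknown(r["group"])
            }
        return cls(
            ids=list(df["id"]),
            sires=list(df["sire"]),
            dams=list(df["dam"]),
            groups=groups,
        )


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix keyed by individual ids.

    ``kind`` is ``"A"`` (pedigree expectation), ``"G"`` (genomic realized) or
    ``"blended"``.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "A"

    def __post_init__(self):
        self.ids = [str(i) for i in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise StructuralError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise StructuralError("relationship matrix is not symmetric")
        self._index = {i: k for k, i in enumerate(self.ids)}

    def loc(self, i: str, j: str) -> float:
        return float(self.values[self._index[i], self._index[j]])

    def indices(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[str(i)] for i in ids], dtype=int)
        except KeyError as exc:
            raise StructuralError(f"id not in relationship matrix: {exc}") from None

    def subset(self, ids) -> "RelationshipMatrix":
        idx = self.indices(ids)
        return RelationshipMatrix(
            ids=[str(i) for i in ids],
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
        )

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def validate_and_order(ped: Pedigree) -> Pedigree:
    """Topologically order a pedigree so parents precede offspring.

    Parents named but lacking their own record are inserted as founders.
    Cycles raise a :class:`StructuralError` naming the individuals involved.
    """
    known = set(ped.ids)
    extra = []
    for s, d in zip(ped.sires, ped.dams):
        for p in (s, d):
            if p != UNKNOWN and p not in known:
                known.add(p)
                extra.append(p)

    ids = extra + ped.ids
    sires = [UNKNOWN] * len(extra) + ped.sires
    dams = [UNKNOWN] * len(extra) + ped.dams
    parent_map = {i: (s, d) for i, s, d in zip(ids, sires, dams)}

    # Kahn-style ordering over the parent -> offspring DAG.
    ordered: list[str] = []
    state: dict[str, int] = {}  # 0 unvisited, 1 on stack, 2 done

    def visit(node: str):
        stack = [(node, False)]
        while stack:
            cur, processed = stack.pop()
            if processed:
                state[cur] = 2
                ordered.append(cur)
                continue
            if state.get(cur) == 2:
                continue
            if state.get(cur) == 1:
                cycle = sorted(k for k, v in state.items() if v == 1)
                raise StructuralError(f"pedigree cycle involving: {cycle}")
            state[cur] = 1
            stack.append((cur, True))
            s, d = parent_map[cur]
            for p in (s, d):
                if p != UNKNOWN:
                    if state.get(p) == 1:
                        cycle = sorted(k for k, v in state.items() if v == 1)
                        raise StructuralError(f"pedigree cycle involving: {cycle}")
                    if state.get(p) != 2:
                        stack.append((p, False))

    for i in ids:
        if state.get(i) != 2:
            visit(i)

    groups = dict(ped.groups)
    return Pedigree(
        ids=ordered,
        sires=[parent_map[i][0] for i in ordered],
        dams=[parent_map[i][1] for i in ordered],
        groups=groups,
    )


def _parent_indices(ped: Pedigree) -> tuple[np.ndarray, np.ndarray]:
    index = {i: k for k, i in enumerate(ped.ids)}
    n = len(ped)
    s_idx = np.full(n, -1, dtype=int)
    d_idx = np.full(n, -1, dtype=int)
    for k, (s, d) in enumerate(zip(ped.sires, ped.dams)):
        if s != UNKNOWN:
            if s not in index or index[s] >= k:
                raise StructuralError(
                    f"pedigree not ordered: parent {s!r} does not precede {ped.ids[k]!r}"
                )
            s_idx[k] = index[s]
        if d != UNKNOWN:
            if d not in index or index[d] >= k:
                raise StructuralError(
                    f"pedigree not ordered: parent {d!r} does not precede {ped.ids[k]!r}"
                )
            d_idx[k] = index[d]
    return s_idx, d_idx


def compute_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Requires a validated, topologically ordered pedigree (use
    :func:`validate_and_order` first).
    """
    s_idx, d_idx = _parent_indices(ped)
    n = len(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = s_idx[i], d_idx[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return RelationshipMatrix(ids=list(ped.ids), values=A, kind="A")


def inbreeding(ped: Pedigree) -> pd.Series:
    """Per-individual inbreeding coefficient F = diag(A) - 1."""
    A = compute_A(ped)
    return pd.Series(np.diag(A.values) - 1.0, index=A.ids, name="F")


def expected_class(ped: Pedigree, i: str, j: str) -> str:
    """Pedigree-expected relationship class for a pair of individuals.

    Classification uses recorded parents only: ``full-sib`` requires both
    parents shared and known, ``half-sib`` exactly one shared known parent.
    """
    for x in (i, j):
        if str(x) not in ped.ids:
            raise KeyError(f"unknown individual: {x!r}")
    i, j = str(i), str(j)
    if i == j:
        return CLASS_SELF
    si, di = ped.parents_of(i)
    sj, dj = ped.parents_of(j)
    shared = 0
    if si != UNKNOWN and si == sj:
        shared += 1
    if di != UNKNOWN and di == dj:
        shared += 1
    if shared == 2:
        return CLASS_FULL_SIB
    if shared == 1:
        return CLASS_HALF_SIB
    if i in (sj, dj) or j in (si, di):
        return CLASS_PARENT_OFFSPRING
    return CLASS_UNRELATED


def classify_pairs(ped: Pedigree, ids: list[str]) -> np.ndarray:
    """Vectorized pair classification over all n x n cells.

    Returns an (n, n) array of class labels following the same rules as
    :func:`expected_class`.
    """
    ids = [str(i) for i in ids]
    pmap = {i: ped.parents_of(i) for i in ids}
    sires = np.array([pmap[i][0] for i in ids], dtype=object)
    dams = np.array([pmap[i][1] for i in ids], dtype=object)
    arr = np.array(ids, dtype=object)

    same_sire = (sires[:, None] == sires[None, :]) & (sires != UNKNOWN)[:, None]
    same_dam = (dams[:, None] == dams[None, :]) & (dams != UNKNOWN)[:, None]
    shared = same_sire.astype(int) + same_dam.astype(int)
    is_parent = (arr[:, None] == sires[None, :]) | (arr[:, None] == dams[None, :])
    po = is_parent | is_parent.T

    out = np.full((len(ids), len(ids)), CLASS_UNRELATED, dtype=object)
    out[po] = CLASS_PARENT_OFFSPRING
    out[shared == 1] = CLASS_HALF_SIB
    out[shared == 2] = CLASS_FULL_SIB
    np.fill_diagonal(out, CLASS_SELF)
    return out


def relationship_summary(
    R: RelationshipMatrix, ped: Pedigree, collapse: bool = False
) -> pd.DataFrame:
    """Per-class statistics of pairwise relationship coefficients.

    Every matrix cell is counted: the diagonal plus both ordered off-diagonal
    cells, so class counts sum to n^2.  With ``collapse=True`` the
    parent-offspring class is folded into ``unrelated/other``, reducing to the
    four classic classes of open-pollinated trials.
    """
    missing = [i for i in R.ids if i not in set(ped.ids)]
    if missing:
        raise StructuralError(f"ids absent from pedigree: {missing[:5]}")
    labels = classify_pairs(ped, R.ids)
    if collapse:
        labels = labels.copy()
        labels[labels == CLASS_PARENT_OFFSPRING] = CLASS_UNRELATED
    classes = [c for c in ALL_CLASSES if not (collapse and c == CLASS_PARENT_OFFSPRING)]

    rows = []
    vals = R.values
    for cls in classes:
        mask = labels == cls
        x = vals[mask]
        if x.size:
            mean = float(x.mean())
            sd = float(x.std(ddof=0))
            rows.append(
                {
                    "class": cls,
                    "n": int(x.size),
                    "mean": mean,
                    "min": float(x.min()),
                    "max": float(x.max()),
                    "sd": sd,
                    "cv": sd / mean if mean != 0 else 0.0,
                }
            )
        else:
            rows.append(
                {
                    "class": cls,
                    "n": 0,
                    "mean": np.nan,
                    "min": np.nan,
                    "max": np.nan,
                    "sd": np.nan,
                    "cv": np.nan,
                }
            )
    out = pd.DataFrame(rows).set_index("class")
    assert int(out["n"].sum()) == len(R.ids) ** 2
    return out
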