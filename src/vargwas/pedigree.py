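"""Pedigree structure, inbreeding and the numerator relationship matrix.

The additive (numerator) relationship matrix A drives every pedigree-based
mixed model in the package: random additive effects are a ~ N(0, A sigma_a2).
Its diagonal is 1 + f_i, where f_i is the inbreeding coefficient of animal i.
Inbreeding is computed with the recursive path-tracing algorithm of
Meuwissen & Luo, which avoids materializing A; the dense tabular recursion is
also provided (``build_relationship``) and doubles as an independent oracle in
the test suite.  The sparse inverse of A, assembled from Mendelian-sampling
variances (Henderson's rules), is what the mixed-model equations consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from vargwas.errors import PedigreeError

UNKNOWN = ("", "0", ".", "NA", None)


def _is_unknown(x) -> bool:
    if x is None:
        return True
    if isinstance(x, float) and np.isnan(x):
        return True
    return str(x).strip() in ("", "0", ".", "NA", "nan")


@dataclass
class Pedigree:
    """A validated, topologically ordered pedigree.

    Internally animals are stored in an order where every parent precedes its
    offspring; ``sire`` / ``dam`` hold integer positions into ``ids`` (-1 for
    an unknown parent, i.e. a draw from the unrelated base population).
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {a: i for i, a in enumerate(self.ids)}

    # -- construction ------------------------------------------------------
    @classmethod
    def from_records(cls, entries) -> "Pedigree":
        """Build from an iterable of (animal, sire, dam); unknown parents are
        '', '0', '.', NA or None.  Raises :class:`PedigreeError` on duplicate
        ids, parents not listed as animals, or cycles.
        """
        raw = [(str(a), None if _is_unknown(s) else str(s), None if _is_unknown(d) else str(d))
               for a, s, d in entries]
        ids = [a for a, _, _ in raw]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for a in ids:
                if a in seen:
                    dup = a
                    break
                seen.add(a)
            raise PedigreeError(f"duplicate animal id {dup!r}")
        idset = set(ids)
        for a, s, d in raw:
            for p in (s, d):
                if p is not None and p not in idset:
                    raise PedigreeError(f"parent {p!r} of animal {a!r} is not listed as an animal")
        order = _topological_order(raw)
        pos = {a: k for k, a in enumerate(order)}
        sire = np.full(len(order), -1, dtype=np.int64)
        dam = np.full(len(order), -1, dtype=np.int64)
        by_id = {a: (s, d) for a, s, d in raw}
        for a, k in pos.items():
            s, d = by_id[a]
            if s is not None:
                sire[k] = pos[s]
            if d is not None:
                dam[k] = pos[d]
        return cls(ids=order, sire=sire, dam=dam)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        """Read a pedigree CSV with columns ``animal,sire,dam`` (header
        required; ``0`` or empty marks an unknown parent)."""
        df = pd.read_csv(path, dtype=str)
        required = {"animal", "sire", "dam"}
        if not required.issubset(df.columns):
            raise PedigreeError(f"pedigree CSV must have columns {sorted(required)}, got {list(df.columns)}")
        return cls.from_records(df[["animal", "sire", "dam"]].itertuples(index=False, name=None))

    def to_frame(self) -> pd.DataFrame:
        s = ["0" if k < 0 else self.ids[k] for k in self.sire]
        d = ["0" if k < 0 else self.ids[k] for k in self.dam]
        return pd.DataFrame({"animal": self.ids, "sire": s, "dam": d})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire < 0) & (self.dam < 0)))

    @property
    def generation_depth(self) -> int:
        """Longest chain of parent-offspring links."""
        depth = np.zeros(len(self), dtype=np.int64)
        for i in range(len(self)):
            for p in (self.sire[i], self.dam[i]):
                if p >= 0:
                    depth[i] = max(depth[i], depth[p] + 1)
        return int(depth.max(initial=0))

    def truncate(self, max_generations: int) -> "Pedigree":
        """Keep only ancestors within ``max_generations`` of the youngest
        generation; older parents become unknown."""
        depth = np.zeros(len(self), dtype=np.int64)
        for i in range(len(self)):
            for p in (self.sire[i], self.dam[i]):
                if p >= 0:
                    depth[i] = max(depth[i], depth[p] + 1)
        top = depth.max(initial=0)
        keep = depth > top - max_generations if top > max_generations else np.ones(len(self), bool)
        recs = []
        for i in np.flatnonzero(keep):
            s = self.ids[self.sire[i]] if self.sire[i] >= 0 and keep[self.sire[i]] else None
            d = self.ids[self.dam[i]] if self.dam[i] >= 0 and keep[self.dam[i]] else None
            recs.append((self.ids[i], s, d))
        return Pedigree.from_records(recs)


def _topological_order(raw) -> list:
    children = {}
    indeg = {}
    for a, s, d in raw:
        indeg.setdefault(a, 0)
        for p in (s, d):
            if p is not None:
                children.setdefault(p, []).append(a)
                indeg[a] = indeg.get(a, 0) + 1
    ready = [a for a, _, _ in raw if indeg[a] == 0]
    order = []
    while ready:
        a = ready.pop()
        order.append(a)
        for c in children.get(a, ()):
            indeg[c] -= 1
            if indeg[c] == 0:
                ready.append(c)
    if len(order) != len(raw):
        stuck = sorted(a for a, n in indeg.items() if n > 0)
        raise PedigreeError(f"pedigree contains a cycle involving animal {stuck[0]!r}")
    return order


@dataclass
class RelationshipMatrix:
    """Dense numerator relationship matrix with its inbreeding coefficients."""

    ids: list
    values: np.ndarray
    inbreeding: np.ndarray

    def loc(self, a, b) -> float:
        idx = {x: i for i, x in enumerate(self.ids)}
        return float(self.values[idx[str(a)], idx[str(b)]])


def compute_inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficients f_i for every animal, by recursive
    path-tracing (Meuwissen & Luo style).

    f_i = A(sire_i, dam_i)/2; the self-relationship of any animal is
    accumulated as sum_j l_j^2 d_j over its ancestors j, where d_j is the
    Mendelian-sampling variance of j.  Animals with an unknown parent get the
    base-population value f = 0.
    """
    f, _ = _inbreeding_and_mendelian(ped)
    return pd.Series(f, index=pd.Index(ped.ids, name="animal"), name="f")


def _inbreeding_and_mendelian(ped: Pedigree):
    """Return (f, d): inbreeding and Mendelian-sampling variance ratios."""
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    f = np.zeros(n)
    d = np.ones(n)
    for i in range(n):
        s, di = sire[i], dam[i]
        if s >= 0 and di >= 0:
            d[i] = 0.5 - 0.25 * (f[s] + f[di])
        elif s >= 0 or di >= 0:
            d[i] = 0.75 - 0.25 * f[max(s, di)]
        else:
            d[i] = 1.0
        if s < 0 or di < 0:
            f[i] = 0.0
            continue
        # a_ii = sum_j l_ij^2 d_j over ancestors, accumulated youngest-first
        L = {i: 1.0}
        aii = 0.0
        while L:
            j = max(L)
            lj = L.pop(j)
            aii += lj * lj * d[j]
            for p in (sire[j], dam[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
        f[i] = aii - 1.0
    return f, d


def mendelian_sampling_variance(ped: Pedigree) -> np.ndarray:
    """Diagonal d of the A = T D T' decomposition (within-family variance as
    a fraction of sigma_a2); also yields log|A| = sum log d_i."""
    _, d = _inbreeding_and_mendelian(ped)
    return d


def build_relationship(ped: Pedigree) -> RelationshipMatrix:
    """Dense A by the tabular recursion.

    A(i,j) = 0.5 (A(sire_i, j) + A(dam_i, j)) for any j older than i, and
    A(i,i) = 1 + 0.5 A(sire_i, dam_i).  Intended for desk-scale pedigrees and
    as the oracle against the sparse machinery; the mixed models use
    :func:`a_inverse` instead.
    """
    n = len(ped)
    A = np.zeros((n, n))
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return RelationshipMatrix(ids=list(ped.ids), values=A, inbreeding=np.diag(A) - 1.0)


def a_inverse(ped: Pedigree) -> sp.csr_matrix:
    """Sparse inverse of A from Mendelian-sampling variances.

    Each animal contributes alpha_i = 1/d_i on the pattern
    (i, sire, dam) x (i, sire, dam) with coefficients (1, -1/2, -1/2).
    """
    _, d = _inbreeding_and_mendelian(ped)
    n = len(ped)
    rows, cols, vals = [], [], []
    for i in range(n):
        alpha = 1.0 / d[i]
        members = [(i, 1.0)]
        for p in (ped.sire[i], ped.dam[i]):
            if p >= 0:
                members.append((int(p), -0.5))
        for a, ca in members:
            for b, cb in members:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * ca * cb)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def log_det_a(ped: Pedigree) -> float:
    _, d = _inbreeding_and_mendelian(ped)
    return float(np.sum(np.log(d)))
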