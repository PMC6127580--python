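"""Pedigree handling and relationship matrices.

A pedigree is a list of (animal, sire, dam) triplets; ``0`` (or ``None``)
codes an unknown parent.  Unknown parents are treated as draws from an
unrelated, non-inbred base population.  All downstream samplers consume the
sparse inverse of Wright's numerator relationship matrix A, assembled by
Henderson's rules with inbreeding accounted for through the Mendelian
sampling variances d_i = 0.5 - 0.25 (F_s + F_d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy import sparse

__all__ = [
    "Pedigree",
    "renumber_and_sort",
    "nrm",
    "inbreeding",
    "a_inverse",
    "read_pedigree",
    "write_pedigree",
]


@dataclass
class Pedigree:
    """Topologically ordered, consecutively renumbered pedigree.

    Attributes
    ----------
    sire, dam : int arrays of length N, 1-based indices into the pedigree
        order; 0 codes an unknown parent.  Parents always precede offspring.
    labels : original animal labels, ``labels[i]`` is the label of animal
        ``i + 1``.
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = self.n_animals
        if len(self.labels) == 0:
            self.labels = list(range(1, n + 1))
        if len(self.labels) != n:
            raise ValueError("labels length does not match pedigree size")
        for name, par in (("sire", self.sire), ("dam", self.dam)):
            if np.any(par < 0):
                raise ValueError(f"negative {name} index")
            bad = np.nonzero(par >= np.arange(1, n + 1))[0]
            if bad.size:
                raise ValueError(
                    f"{name} of animal {bad[0] + 1} does not precede it: "
                    "pedigree is not topologically ordered"
                )

    @property
    def n_animals(self) -> int:
        return len(self.sire)

    @property
    def index_of(self) -> dict:
        """Map original label -> 1-based internal index."""
        return {lab: i + 1 for i, lab in enumerate(self.labels)}

    def is_founder(self) -> np.ndarray:
        return (self.sire == 0) & (self.dam == 0)


def renumber_and_sort(raw_pedigree) -> Pedigree:
    """Turn raw (animal, sire, dam) triplets into a valid :class:`Pedigree`.

    Labels may be arbitrary hashables; ``0``, ``"0"`` and ``None`` code an
    unknown parent.  Parents that never appear in the animal column are added
    as founders.  Raises ``ValueError`` on a cycle (naming one animal on it)
    or on an animal listed twice with conflicting parents.
    """
    parents: dict = {}
    placeholder: set = set()
    order_seen: list = []

    def _known(p):
        return p not in (0, "0", None)

    for animal, sire, dam in raw_pedigree:
        if not _known(animal):
            raise ValueError("animal id 0/None is not allowed")
        trip = (sire if _known(sire) else 0, dam if _known(dam) else 0)
        if animal in parents and animal not in placeholder:
            if parents[animal] != trip:
                raise ValueError(f"animal {animal!r} listed twice with conflicting parents")
            continue
        parents[animal] = trip
        placeholder.discard(animal)
        if animal not in order_seen:
            order_seen.append(animal)
        for p in trip:
            if p != 0 and p not in parents:
                parents[p] = (0, 0)
                placeholder.add(p)
                order_seen.append(p)

    g = nx.DiGraph()
    g.add_nodes_from(order_seen)
    for child, (s, d) in parents.items():
        for p in (s, d):
            if p != 0:
                g.add_edge(p, child)
    try:
        # lexicographical-by-insertion keeps output deterministic
        topo = list(nx.topological_sort(g))
    except nx.NetworkXUnfeasible:
        cyc = nx.find_cycle(g)
        raise ValueError(f"pedigree cycle detected involving animal {cyc[0][0]!r}")

    idx = {lab: i + 1 for i, lab in enumerate(topo)}
    sire = np.array([idx[parents[a][0]] if parents[a][0] != 0 else 0 for a in topo])
    dam = np.array([idx[parents[a][1]] if parents[a][1] != 0 else 0 for a in topo])
    return Pedigree(sire=sire, dam=dam, labels=topo)


def nrm(ped: Pedigree) -> np.ndarray:
    """Wright's numerator relationship matrix A by the tabular method.

    a_ii = 1 + 0.5 a_sd, a_ij = 0.5 (a_js + a_jd) for j < i; diagonal is
    1 + F_i with F_i the inbreeding coefficient.
    """
    n = ped.n_animals
    a = np.zeros((n, n))
    s = ped.sire - 1  # -1 == unknown
    d = ped.dam - 1
    for i in range(n):
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * a[si, :i]
        if di >= 0:
            row += 0.5 * a[di, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[si, di] if si >= 0 and di >= 0 else 0.0)
    return a


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F by the Meuwissen & Luo algorithm.

    Computes diag(A) - 1 without forming the dense A, sequentially tracing
    each animal's ancestors; O(N * pedigree depth) time, O(N) memory.
    """
    import heapq

    n = ped.n_animals
    f = np.zeros(n + 1)  # 1-based; f[0] unused
    sire = ped.sire
    dam = ped.dam
    for i in range(1, n + 1):
        if sire[i - 1] == 0 and dam[i - 1] == 0:
            continue
        # trace ancestors j of i in decreasing index order, accumulating the
        # gene-flow coefficients L_ij; a_ii = sum_j L_ij^2 d_j, F_i = a_ii - 1
        contrib = {i: 1.0}
        heap = [-i]
        fi = -1.0
        while heap:
            j = -heapq.heappop(heap)
            cj = contrib.pop(j)
            for p in (sire[j - 1], dam[j - 1]):
                if p:
                    if p not in contrib:
                        heapq.heappush(heap, -p)
                        contrib[p] = 0.0
                    contrib[p] += 0.5 * cj
            fi += cj * cj * _mendelian_variance(f, sire[j - 1], dam[j - 1])
        f[i] = fi
    return f[1:]


def _mendelian_variance(f: np.ndarray, s: int, d: int) -> float:
    fs = f[s] if s else -1.0
    fd = f[d] if d else -1.0
    return 0.5 - 0.25 * (fs + fd)


def a_inverse(ped: Pedigree, f: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    For each animal i with Mendelian sampling variance
    d_i = 1 - 0.25 (1 + F_s) - 0.25 (1 + F_d) (terms dropped for unknown
    parents), add 1/d_i at (i,i), -0.5/d_i at (i, parent) and 0.25/d_i at
    (parent, parent') for each pair of known parents.
    """
    if f is None:
        f = inbreeding(ped)
    n = ped.n_animals
    rows, cols, vals = [], [], []
    for i in range(n):
        s = ped.sire[i] - 1
        d = ped.dam[i] - 1
        di = 1.0
        if s >= 0:
            di -= 0.25 * (1.0 + f[s])
        if d >= 0:
            di -= 0.25 * (1.0 + f[d])
        if di <= 0:
            raise ValueError(f"non-positive Mendelian sampling variance at animal {i + 1}")
        w = 1.0 / di
        rows.append(i); cols.append(i); vals.append(w)
        for p in (s, d):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * w, -0.5 * w]
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    rows.append(p); cols.append(q); vals.append(0.25 * w)
    ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    return ainv


def read_pedigree(path, header: bool = False) -> Pedigree:
    """Read a 3-column (animal, sire, dam) pedigree file.

    Whitespace- or comma-delimited; ``0`` = unknown parent; labels kept as
    strings unless they look integral.
    """
    triplets = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            if header and ln == 0:
                continue
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ValueError(f"line {ln + 1}: expected 3 columns, got {len(parts)}")
            triplets.append(tuple(_coerce(p) for p in parts))
    return renumber_and_sort(triplets)


def _coerce(tok: str):
    try:
        return int(tok)
    except ValueError:
        return tok


def write_pedigree(ped: Pedigree, path) -> None:
    with open(path, "w") as fh:
        lab = ped.labels
        for i in range(ped.n_animals):
            s = lab[ped.sire[i] - 1] if ped.sire[i] else 0
            d = lab[ped.dam[i] - 1] if ped.dam[i] else 0
            fh.write(f"{lab[i]} {s} {d}\n")
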