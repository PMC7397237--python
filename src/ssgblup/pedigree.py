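"""Pedigree renumbering and numerator-relationship-matrix (A) algebra.

The numerator relationship matrix A encodes expected identity-by-descent
between animals given the pedigree. Everything downstream of the pedigree —
BLUP, the genotyped-animal submatrix A22, and the combined matrix H — builds
on the machinery here:

* ``renumber`` maps arbitrary string IDs to a topological 1..n order
  (parents before offspring), adding animals that appear only as parents
  and turning negative parent codes into unknown-parent-group (UPG) slots.
* ``inbreeding`` runs the Meuwissen–Luo recursion for F = diag(A) - 1.
* ``build_A`` is the dense tabular method (test oracle, desk scale).
* ``build_Ainv`` applies Henderson's sparse rules, optionally with
  inbreeding in the Mendelian-sampling variances and with Quaas's
  unknown-parent-group columns.
* ``build_A22`` uses Colleau's indirect A·v products, so the full A is
  never formed; ``build_A22inv_indirect`` obtains A22⁻¹ from the sparse
  blocks of A⁻¹ without densely inverting the non-genotyped block.

Renumbered parent codes: 0 = unknown, 1..n = animal, -g = UPG slot g.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io_formats import RawPedigree

__all__ = [
    "Pedigree",
    "PedigreeError",
    "renumber",
    "inbreeding",
    "mendelian_variances",
    "build_A",
    "build_Ainv",
    "build_A22",
    "build_A22inv_indirect",
    "a_matvec",
]

#: dense tabular A is a desk-scale oracle; refuse to build it above this
DENSE_GUARD = 20_000


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Renumbered pedigree.

    ``sire``/``dam`` are arrays of length n with codes 0 (unknown),
    1..n (renumbered parent, always smaller than the animal's own index),
    or -g (unknown-parent group g in 1..upg_count).
    """

    n: int
    sire: np.ndarray
    dam: np.ndarray
    #: renumbered index (1-based) per original ID
    xref: dict[str, int] = field(default_factory=dict)
    upg_count: int = 0
    #: original UPG token per group slot (1-based)
    upg_codes: list[str] = field(default_factory=list)

    @property
    def original_ids(self) -> list[str]:
        ids = [""] * self.n
        for orig, idx in self.xref.items():
            ids[idx - 1] = orig
        return ids

    def write_xref(self, path) -> None:
        ids = self.original_ids
        with open(path, "w", encoding="ascii") as fh:
            for i, orig in enumerate(ids, start=1):
                fh.write(f"{orig} {i}\n")


def _is_upg(tok: str) -> bool:
    try:
        return int(tok) < 0
    except ValueError:
        return False


def renumber(raw: RawPedigree) -> Pedigree:
    """Topologically renumber a raw pedigree (founders first, ties broken by
    first appearance). Animals appearing only as parents are appended as
    founders; negative sire/dam codes become UPG slots."""
    appearance: dict[str, int] = {}
    parents: dict[str, tuple[str, str]] = {}
    upg_codes: list[str] = []

    def note(tok: str, order: int) -> None:
        if tok not in appearance:
            appearance[tok] = order

    order = 0
    for animal, sire, dam in raw.records:
        note(animal, order)
        order += 1
        parents[animal] = (sire, dam)
        for tok in (sire, dam):
            if tok == "0":
                continue
            if _is_upg(tok):
                if tok not in upg_codes:
                    upg_codes.append(tok)
            else:
                note(tok, order)
                order += 1
    for tok in appearance:
        parents.setdefault(tok, ("0", "0"))

    # Kahn's algorithm on parent->offspring edges; ties by first appearance.
    indeg = {a: 0 for a in appearance}
    children: dict[str, list[str]] = {a: [] for a in appearance}
    for animal, (sire, dam) in parents.items():
        for tok in (sire, dam):
            if tok != "0" and not _is_upg(tok):
                indeg[animal] += 1
                children[tok].append(animal)
    ready = [(appearance[a], a) for a, d in indeg.items() if d == 0]
    heapq.heapify(ready)
    topo: list[str] = []
    while ready:
        _, a = heapq.heappop(ready)
        topo.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(ready, (appearance[c], c))
    if len(topo) != len(appearance):
        cyc = sorted(a for a, d in indeg.items() if d > 0)
        raise PedigreeError(f"pedigree contains a loop involving: {cyc[:20]}")

    xref = {a: i + 1 for i, a in enumerate(topo)}
    n = len(topo)
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for a, (s, d) in parents.items():
        i = xref[a] - 1
        for arr, tok in ((sire, s), (dam, d)):
            if tok == "0":
                arr[i] = 0
            elif _is_upg(tok):
                arr[i] = -(upg_codes.index(tok) + 1)
            else:
                arr[i] = xref[tok]
    return Pedigree(n=n, sire=sire, dam=dam, xref=xref,
                    upg_count=len(upg_codes), upg_codes=list(upg_codes))


def _known(parent_codes: np.ndarray) -> np.ndarray:
    """Mask of real (known, non-UPG) parents."""
    return parent_codes > 0


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo algorithm.

    Computes, for each animal i, F(i) = sum_j L(i,j)^2 d(j) - 1 where
    A = L D L' with L the gene-flow (T) matrix and d the within-family
    (Mendelian-sampling) variances. Unknown parents and UPG contribute as
    unrelated non-inbred founders.
    """
    n = ped.n
    F = np.zeros(n)
    d = np.zeros(n)
    sire, dam = ped.sire, ped.dam
    for i in range(n):
        s, dm = sire[i], dam[i]
        ks, kd = s > 0, dm > 0
        if ks and kd:
            d[i] = 0.5 - 0.25 * (F[s - 1] + F[dm - 1])
        elif ks:
            d[i] = 0.75 - 0.25 * F[s - 1]
        elif kd:
            d[i] = 0.75 - 0.25 * F[dm - 1]
        else:
            d[i] = 1.0
        if not (ks and kd):
            F[i] = 0.0  # needs both parents to be inbred
            continue
        # row i of L over ancestors, max-heap on index so each ancestor is
        # finalized before its own parents are touched
        coeff: dict[int, float] = {i: 1.0}
        heap = [-i]
        acc = 0.0
        while heap:
            j = -heapq.heappop(heap)
            c = coeff.pop(j, 0.0)
            if c == 0.0:
                continue
            acc += c * c * d[j]
            for p in (sire[j], dam[j]):
                if p > 0:
                    pj = p - 1
                    if pj not in coeff:
                        coeff[pj] = 0.0
                        heapq.heappush(heap, -pj)
                    coeff[pj] += 0.5 * c
        F[i] = acc - 1.0
    return F


def mendelian_variances(ped: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Within-family variances d_i used by A = T D T' and Henderson's rules.

    Both real parents known: 0.5 - 0.25(F_s + F_d); one known:
    0.75 - 0.25 F_known; none: 1. UPG parents count as unknown here (they
    are non-inbred phantom founders)."""
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    d = np.empty(n)
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        ks, kd = s > 0, dm > 0
        if ks and kd:
            d[i] = 0.5 - 0.25 * (F[s - 1] + F[dm - 1])
        elif ks:
            d[i] = 0.75 - 0.25 * F[s - 1]
        elif kd:
            d[i] = 0.75 - 0.25 * F[dm - 1]
        else:
            d[i] = 1.0
    return d


def build_A(ped: Pedigree, guard: int = DENSE_GUARD) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    diag(A) = 1 + F. Desk-scale oracle only; guarded at ``guard`` animals.
    """
    n = ped.n
    if n > guard:
        raise PedigreeError(
            f"dense A for n={n} exceeds guard {guard}; use build_A22 / "
            "build_Ainv (indirect methods) instead"
        )
    A = np.zeros((n, n))
    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        ks, kd = s > 0, dm > 0
        if i:
            row = np.zeros(i)
            if ks:
                row += 0.5 * A[s - 1, :i]
            if kd:
                row += 0.5 * A[dm - 1, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s - 1, dm - 1] if ks and kd else 0.0)
    return A


def build_Ainv(
    ped: Pedigree,
    use_inbreeding: bool = True,
    upg: bool = False,
    F: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Sparse A⁻¹ by Henderson's rules, optionally Quaas's UPG columns.

    With ``use_inbreeding`` the Mendelian-sampling variances use the F of
    known parents (exact inverse of the tabular A); without it, all F are
    taken as 0 (the classical approximation, harmless in BLUP but damaging
    in single-step). With ``upg`` the matrix gains ``upg_count`` trailing
    columns; UPG parents receive the usual parent cross terms but no own
    unity diagonal. Without ``upg``, UPG parents are treated as unknown.
    """
    n = ped.n
    g = ped.upg_count if upg else 0
    order = n + g
    if use_inbreeding:
        if F is None:
            F = inbreeding(ped)
    else:
        F = np.zeros(n)

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, dm = ped.sire[i], ped.dam[i]
        ks, kd = s > 0, dm > 0
        if ks and kd:
            di = 0.5 - 0.25 * (F[s - 1] + F[dm - 1])
        elif ks:
            di = 0.75 - 0.25 * F[s - 1]
        elif kd:
            di = 0.75 - 0.25 * F[dm - 1]
        else:
            di = 1.0
        inv = 1.0 / di
        # equation indices: animal -> 0..n-1, UPG slot g -> n+g-1
        eq = []
        for code in (s, dm):
            if code > 0:
                eq.append(code - 1)
            elif code < 0 and upg:
                eq.append(n + (-code) - 1)
        add(i, i, inv)
        for p in eq:
            add(i, p, -0.5 * inv)
            add(p, i, -0.5 * inv)
        for p in eq:
            for q in eq:
                add(p, q, 0.25 * inv)
    return sp.coo_matrix((vals, (rows, cols)), shape=(order, order)).tocsr()


def a_matvec(ped: Pedigree, v: np.ndarray, d: np.ndarray | None = None) -> np.ndarray:
    """A·v by Colleau's indirect method, never forming A.

    Uses A = (I-P)^-1 D (I-P)^-T where P carries 0.5 on parent links and D
    the Mendelian-sampling variances (inbreeding fully considered)."""
    n = ped.n
    if d is None:
        d = mendelian_variances(ped)
    sire, dam = ped.sire, ped.dam
    # y = (I-P)^-T v : youngest to oldest, push halves up to parents
    y = v.astype(float).copy()
    for i in range(n - 1, -1, -1):
        yi = y[i]
        if yi != 0.0:
            s, dm = sire[i], dam[i]
            if s > 0:
                y[s - 1] += 0.5 * yi
            if dm > 0:
                y[dm - 1] += 0.5 * yi
    y *= d
    # u = (I-P)^-1 (D y) : oldest to youngest
    for i in range(n):
        s, dm = sire[i], dam[i]
        if s > 0:
            y[i] += 0.5 * y[s - 1]
        if dm > 0:
            y[i] += 0.5 * y[dm - 1]
    return y


def build_A22(ped: Pedigree, genotyped: np.ndarray) -> np.ndarray:
    """Pedigree relationships among genotyped animals (A22), via one
    Colleau A·v product per genotyped animal. ``genotyped`` holds 0-based
    renumbered indices."""
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if genotyped.size == 0:
        raise PedigreeError("empty genotyped set")
    d = mendelian_variances(ped)
    ng = genotyped.size
    A22 = np.empty((ng, ng))
    for j, col in enumerate(genotyped):
        e = np.zeros(ped.n)
        e[col] = 1.0
        A22[:, j] = a_matvec(ped, e, d)[genotyped]
    return 0.5 * (A22 + A22.T)


def build_A22inv_indirect(ainv: sp.spmatrix, genotyped: np.ndarray) -> np.ndarray:
    """A22⁻¹ from the blocks of sparse A⁻¹:
    A22⁻¹ = A²² − A²¹ (A¹¹)⁻¹ A¹², with the (A¹¹)⁻¹A¹² factor obtained by
    sparse LU solves (A¹¹ is never inverted densely). Any UPG columns in
    ``ainv`` belong to the non-genotyped block."""
    ainv = sp.csc_matrix(ainv)
    order = ainv.shape[0]
    genotyped = np.asarray(genotyped, dtype=np.int64)
    mask = np.zeros(order, dtype=bool)
    mask[genotyped] = True
    non = np.flatnonzero(~mask)
    A22b = ainv[genotyped][:, genotyped].toarray()
    if non.size == 0:
        return A22b
    A12 = ainv[non][:, genotyped].toarray()
    lu = spla.splu(sp.csc_matrix(ainv[non][:, non]))
    X = lu.solve(A12)
    out = A22b - A12.T @ X
    return 0.5 * (out + out.T)
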