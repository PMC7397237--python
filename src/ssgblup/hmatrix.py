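"""The combined relationship matrix H and its inverse.

H merges pedigree and genomic relationships: the genotyped block is G and
genomic information is propagated to non-genotyped relatives through the
pedigree,

    H = A + [ A12 A22⁻¹ (G - A22) A22⁻¹ A21   A12 A22⁻¹ (G - A22) ]
            [ (G - A22) A22⁻¹ A21             G - A22              ]

While H itself is complicated (and only built here at desk scale as a test
oracle), its inverse is simple and is what production single-step uses:

    H⁻¹ = A⁻¹ + [ 0   0                  ]
                [ 0   τ G⁻¹ - ω A22⁻¹    ]

τ and ω scale the genomic and pedigree information in the genotyped block
(both default 1; they matter when pedigree and genomic information are
incompatible, e.g. inbreeding ignored in A⁻¹). H⁻¹ is never materialized
densely: it is kept as sparse A⁻¹ plus a dense genotyped-block correction,
and matrix-vector products compose the two.

Unknown-parent groups can enter the genomic part through the Quaas–Pollak
transform: the genotyped-block correction gains group couplings through the
ancestral-group-fraction matrix Q2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .grm import Grm
from .pedigree import Pedigree

__all__ = ["HinvOptions", "Hinv", "HmatrixError", "build_H", "build_Hinv",
           "build_Q2", "apply_upg"]


class HmatrixError(ValueError):
    pass


@dataclass
class HinvOptions:
    tau: float = 1.0
    omega: float = 1.0
    #: scaling of the group-coupling terms: (1,1) = full genomic UPG,
    #: (0,1) = groups only in the A⁻¹ / A22⁻¹ parts
    tau_q2: float = 1.0
    omega_q2: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.omega <= 0:
            raise HmatrixError("tau and omega must be positive")


@dataclass
class Hinv:
    """H⁻¹ = sparse A⁻¹ + dense correction on the genotyped equations.

    ``correction`` has order n_g (+ n_groups after apply_upg) and applies
    to the equations listed in ``block_index`` (0-based positions in the
    full system of ``order`` equations).
    """

    ainv: sp.csr_matrix
    correction: np.ndarray
    block_index: np.ndarray
    order: int

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.ainv @ v
        idx = self.block_index
        out[idx] += self.correction @ v[idx]
        return out

    def to_dense(self) -> np.ndarray:
        H = self.ainv.toarray()
        H[np.ix_(self.block_index, self.block_index)] += self.correction
        return H

    def to_sparse(self) -> sp.csr_matrix:
        corr = sp.coo_matrix(self.correction)
        n_b = self.block_index.size
        expand = sp.coo_matrix(
            (np.ones(n_b), (self.block_index, np.arange(n_b))),
            shape=(self.order, n_b),
        ).tocsr()
        return (self.ainv + expand @ corr.tocsr() @ expand.T).tocsr()

    def save(self, path) -> None:
        """Triplet text export (row, column, value; 1-based renumbered IDs)."""
        from .io_formats import write_triplets

        write_triplets(self.to_sparse(), path)


def build_H(
    a: np.ndarray,
    a22: np.ndarray,
    g: Grm | np.ndarray,
    genotyped: np.ndarray,
) -> np.ndarray:
    """Dense H (test oracle, desk scale): A plus the (G - A22) propagation.

    The genotyped block of the result equals G exactly.
    """
    G = g.values if isinstance(g, Grm) else np.asarray(g, dtype=float)
    a = np.asarray(a, dtype=float)
    a22 = np.asarray(a22, dtype=float)
    genotyped = np.asarray(genotyped, dtype=np.int64)
    n = a.shape[0]
    mask = np.zeros(n, dtype=bool)
    mask[genotyped] = True
    non = np.flatnonzero(~mask)
    try:
        a22_inv = np.linalg.inv(a22)
    except np.linalg.LinAlgError as e:
        raise HmatrixError("A22 is singular") from e
    A12 = a[np.ix_(non, genotyped)]
    P = A12 @ a22_inv
    H = a.copy()
    H[np.ix_(non, non)] += P @ (G - a22) @ P.T
    H[np.ix_(non, genotyped)] += P @ (G - a22)
    H[np.ix_(genotyped, non)] = H[np.ix_(non, genotyped)].T
    H[np.ix_(genotyped, genotyped)] = G
    return 0.5 * (H + H.T)


def build_Hinv(
    ainv: sp.spmatrix,
    a22inv: np.ndarray,
    ginv: np.ndarray,
    genotyped: np.ndarray,
    opts: HinvOptions | None = None,
) -> Hinv:
    """Assemble H⁻¹ = A⁻¹ + [0 0; 0 τG⁻¹ - ωA22⁻¹] (sparse + dense block)."""
    if opts is None:
        opts = HinvOptions()
    ainv = sp.csr_matrix(ainv)
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if genotyped.size:
        ginv = np.asarray(ginv, dtype=float)
        a22inv = np.asarray(a22inv, dtype=float)
        if ginv.shape != (genotyped.size,) * 2 or a22inv.shape != ginv.shape:
            raise HmatrixError(
                f"G⁻¹ {getattr(ginv, 'shape', None)} / A22⁻¹ {a22inv.shape} do not "
                f"match the {genotyped.size} genotyped equations"
            )
        corr = opts.tau * ginv - opts.omega * a22inv
    else:
        corr = np.zeros((0, 0))
    if genotyped.size and genotyped.max() >= ainv.shape[0]:
        raise HmatrixError("genotyped index exceeds A⁻¹ order")
    return Hinv(ainv=ainv, correction=corr, block_index=genotyped,
                order=ainv.shape[0])


def build_Q2(ped: Pedigree, genotyped: np.ndarray) -> np.ndarray:
    """Ancestral unknown-parent-group fractions for genotyped animals.

    q(i) = ½ q(sire) + ½ q(dam); a UPG parent contributes its unit vector,
    a fully unknown (ungrouped) parent contributes nothing. Row sums are at
    most 1 and are exactly 1 when every ancestral path ends in a group.
    """
    if ped.upg_count == 0:
        raise HmatrixError("pedigree has no unknown-parent groups")
    q = np.zeros((ped.n, ped.upg_count))
    for i in range(ped.n):
        for code in (ped.sire[i], ped.dam[i]):
            if code > 0:
                q[i] += 0.5 * q[code - 1]
            elif code < 0:
                q[i, -code - 1] += 0.5
    genotyped = np.asarray(genotyped, dtype=np.int64)
    return q[genotyped]


def apply_upg(
    hinv: Hinv,
    ginv: np.ndarray,
    a22inv: np.ndarray,
    q2: np.ndarray,
    opts: HinvOptions | None = None,
) -> Hinv:
    """Add the Quaas–Pollak group couplings to the genomic part of H⁻¹.

    With S = tau_q2 G⁻¹ - omega_q2 A22⁻¹ the correction block becomes

        [ τG⁻¹ - ωA22⁻¹   -S Q2      ]
        [ -Q2' S           Q2' S Q2  ]

    over (genotyped equations, group equations). (tau_q2, omega_q2) = (0, 1)
    leaves groups in the pedigree terms only; Q2 = 0 changes nothing.
    ``hinv.ainv`` must already carry the Quaas UPG columns (its order is
    n animals + n groups, groups last).
    """
    if opts is None:
        opts = HinvOptions()
    q2 = np.asarray(q2, dtype=float)
    ng = hinv.block_index.size
    if q2.shape[0] != ng:
        raise HmatrixError(
            f"Q2 has {q2.shape[0]} rows for {ng} genotyped equations"
        )
    n_groups = q2.shape[1]
    n_animals = hinv.order - n_groups
    S = opts.tau_q2 * np.asarray(ginv) - opts.omega_q2 * np.asarray(a22inv)
    top = hinv.correction
    coupling = -S @ q2
    block = np.block([[top, coupling], [coupling.T, q2.T @ S @ q2]])
    idx = np.concatenate([hinv.block_index, n_animals + np.arange(n_groups)])
    return Hinv(ainv=hinv.ainv, correction=block, block_index=idx,
                order=hinv.order)
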