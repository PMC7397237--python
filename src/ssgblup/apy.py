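"""APY: the "algorithm for proven and young" sparse generalized inverse of G.

Inverting G costs O(n³) in the number of genotyped animals. APY avoids the
full inverse by splitting the genotyped set into a *core* (c) and *noncore*
(n) group and assuming noncore breeding values are linear functions of core
ones plus independent errors, u_n = P_nc u_c + Ψ_n. The resulting
generalized inverse is

    G_APY⁻¹ = [G_cc⁻¹ 0; 0 0] + [-G_cc⁻¹ G_cn; I] M_nn⁻¹ [-G_nc G_cc⁻¹, I]

with M_nn diagonal, m_nn,ii = g_ii - g_ic G_cc⁻¹ g_ci. Only the core block
is ever inverted; storage and work are linear in the noncore count, and
the noncore-noncore off-diagonals are exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .grm import Grm

__all__ = ["ApyError", "ApyPartition", "select_core", "build_Gapy_inv"]

CORE_GUARD = 20_000


class ApyError(ValueError):
    pass


@dataclass
class ApyPartition:
    core: np.ndarray
    noncore: np.ndarray
    seed: int | None = None

    @property
    def n(self) -> int:
        return self.core.size + self.noncore.size


def select_core(
    n_genotyped: int,
    n_core: int,
    strategy: str = "random",
    seed: int = 0,
) -> ApyPartition:
    """Random core/noncore split (reproducible for a fixed seed)."""
    if not 1 <= n_core <= n_genotyped:
        raise ApyError(
            f"n_core must be in [1, {n_genotyped}], got {n_core}"
        )
    if strategy != "random":
        raise ApyError(f"unknown core-selection strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_genotyped)
    core = np.sort(perm[:n_core])
    noncore = np.sort(perm[n_core:])
    return ApyPartition(core=core, noncore=noncore, seed=seed)


def build_Gapy_inv(g: Grm | np.ndarray, part: ApyPartition) -> sp.csr_matrix:
    """Assemble G_APY⁻¹ (sparse, in the original genotyped-animal order)."""
    G = g.values if isinstance(g, Grm) else np.asarray(g, dtype=float)
    c, n = part.core, part.noncore
    if c.size > CORE_GUARD:
        raise ApyError(f"core of {c.size} exceeds dense-inversion guard")
    Gcc = G[np.ix_(c, c)]
    try:
        Gcc_inv = np.linalg.inv(Gcc)
    except np.linalg.LinAlgError as e:
        raise ApyError(
            "core block of G is singular: blend G or choose a different core"
        ) from e
    order = G.shape[0]
    if n.size == 0:
        out = np.zeros((order, order))
        out[np.ix_(c, c)] = Gcc_inv
        return sp.csr_matrix(out)
    Gcn = G[np.ix_(c, n)]
    W = Gcc_inv @ Gcn  # G_cc⁻¹ G_cn
    m_nn = np.diag(G)[n] - np.einsum("ij,ij->j", Gcn, W)
    if np.any(m_nn <= 0):
        raise ApyError(
            "non-positive noncore conditional variance; blend G first"
        )
    minv = 1.0 / m_nn
    # dense blocks in partition order, then scatter to original order
    cc = Gcc_inv + W @ (minv[:, None] * W.T)
    cn = -W * minv
    rows, cols, vals = [], [], []

    def put(block, ridx, cidx):
        r, cq = np.nonzero(block)
        rows.append(ridx[r])
        cols.append(cidx[cq])
        vals.append(block[r, cq])

    put(cc, c, c)
    put(cn, c, n)
    put(cn.T, n, c)
    rows.append(n)
    cols.append(n)
    vals.append(minv)
    out = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(order, order),
    )
    return out.tocsr()
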