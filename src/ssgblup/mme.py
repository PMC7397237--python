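"""Build and solve Henderson's mixed-model equations (MME).

Single-trait animal model y = Xb + Wu + e, with u ~ N(0, K σ²u) for a
relationship structure K that is A (BLUP), G (GBLUP), H (single-step) or a
user-supplied covariance inverse. The MME are

    [ X'X     X'W            ] [b]   [X'y]
    [ W'X     W'W + K⁻¹ λ    ] [u] = [W'y],   λ = σ²e / σ²u.

Only K⁻¹ ever enters the equations; for single-step, K⁻¹ = H⁻¹ kept as
sparse A⁻¹ plus a dense genotyped-block correction, and the iterative
solver works through matrix-vector products without densifying anything.

Two solvers are provided: a dense factorization (desk-scale oracle, also
the route to the inverse-LHS block needed for SNP p-values) and Jacobi-
preconditioned conjugate gradients (the production default).

``run_evaluation`` orchestrates the whole pipeline from files (or in-memory
objects) to a solutions file: renumber -> QC -> G -> tune -> blend -> A⁻¹ /
A22⁻¹ -> H⁻¹ -> MME -> solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import grm as grm_mod
from . import io_formats as io
from . import pedigree as ped_mod
from .hmatrix import Hinv, HinvOptions, apply_upg, build_Hinv, build_Q2

logger = logging.getLogger(__name__)

__all__ = [
    "MmeError",
    "GeneticEffect",
    "ModelSpec",
    "MmeSystem",
    "Solutions",
    "build_mme",
    "solve_direct",
    "solve_pcg",
    "run_evaluation",
    "EvaluationResult",
]

DIRECT_GUARD = 20_000


class MmeError(ValueError):
    pass


@dataclass
class GeneticEffect:
    """One random genetic effect and its covariance structure.

    ``structure`` is "pedigree", "ssgblup", "gblup" or "user_file"; the
    corresponding inverse is supplied to ``build_mme`` via ``covstructs``.
    """

    structure: str
    variance: float
    user_file: str | None = None

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise MmeError(f"genetic variance must be positive, got {self.variance}")


@dataclass
class ModelSpec:
    trait: str
    fixed_effects: list[str]
    animal: str
    genetic_effects: list[GeneticEffect]
    residual_variance: float
    weight: str | None = None

    def __post_init__(self) -> None:
        if self.residual_variance <= 0:
            raise MmeError("residual variance must be positive")
        if not self.fixed_effects and not self.genetic_effects:
            raise MmeError("model needs at least one effect")


@dataclass
class Covstruct:
    """Covariance-structure inverse for one genetic effect.

    ``inv`` is a scipy sparse matrix, a dense array, or an Hinv;
    ``level_index`` maps original animal IDs to 0-based equation levels
    within the effect's block of ``order`` equations.
    """

    inv: object
    order: int
    level_index: dict[str, int]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        if isinstance(self.inv, Hinv):
            return self.inv.matvec(v)
        return np.asarray(self.inv @ v)

    def dense(self) -> np.ndarray:
        if isinstance(self.inv, Hinv):
            return self.inv.to_dense()
        if sp.issparse(self.inv):
            return self.inv.toarray()
        return np.asarray(self.inv)

    def diag(self) -> np.ndarray:
        if isinstance(self.inv, Hinv):
            d = self.inv.ainv.diagonal().copy()
            d[self.inv.block_index] += np.diag(self.inv.correction)
            return d
        if sp.issparse(self.inv):
            return np.asarray(self.inv.diagonal())
        return np.diag(self.inv).copy()


@dataclass
class MmeSystem:
    """Sparse LHS (+ dense corrections), RHS, and the equation map."""

    data_lhs: sp.csr_matrix
    rhs: np.ndarray
    #: (structure, lambda, offset) per genetic effect
    structures: list[tuple[Covstruct, float, int]]
    #: (effect_number_1based, level_1based) per equation
    eqmap: list[tuple[int, int]]
    #: human-readable labels per effect number
    effect_labels: dict[int, str]

    @property
    def order(self) -> int:
        return self.data_lhs.shape[0]

    def matvec(self, v: np.ndarray) -> np.ndarray:
        out = self.data_lhs @ v
        for struct, lam, off in self.structures:
            blk = slice(off, off + struct.order)
            out[blk] += lam * struct.matvec(v[blk])
        return out

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.data_lhs.diagonal()).copy()
        for struct, lam, off in self.structures:
            d[off : off + struct.order] += lam * struct.diag()
        return d

    def to_dense(self) -> np.ndarray:
        if self.order > DIRECT_GUARD:
            raise MmeError(f"dense LHS of order {self.order} exceeds guard")
        L = self.data_lhs.toarray()
        for struct, lam, off in self.structures:
            blk = slice(off, off + struct.order)
            L[blk, blk] += lam * struct.dense()
        return L


@dataclass
class Solutions:
    values: np.ndarray
    eqmap: list[tuple[int, int]]
    converged: bool = True
    iterations: int = 0
    final_residual: float = 0.0
    #: full inverse of the LHS (set by solve_direct(return_inverse=True))
    lhs_inverse: np.ndarray | None = None

    def effect(self, effect: int) -> np.ndarray:
        idx = [i for i, (e, _) in enumerate(self.eqmap) if e == effect]
        return self.values[idx]

    def rows(self, trait: int = 1) -> list[tuple[int, int, int, float]]:
        return [
            (trait, e, lvl, float(self.values[i]))
            for i, (e, lvl) in enumerate(self.eqmap)
        ]

    def write(self, path, trait: int = 1) -> None:
        io.write_solutions(self.rows(trait), path)


def _factor_incidence(levels: pd.Series) -> tuple[sp.csr_matrix, list[str]]:
    cats = pd.unique(levels)
    index = {c: j for j, c in enumerate(cats)}
    cols = levels.map(index).to_numpy()
    n = len(levels)
    X = sp.coo_matrix((np.ones(n), (np.arange(n), cols)), shape=(n, len(cats)))
    return X.tocsr(), list(cats)


def build_mme(
    model: ModelSpec,
    data: pd.DataFrame,
    covstructs: list[Covstruct],
) -> MmeSystem:
    """Assemble the MME. Fixed-effect levels are renumbered in order of
    first appearance; the animal factor uses each structure's level index so
    animals without records still get equations."""
    if len(covstructs) != len(model.genetic_effects):
        raise MmeError("one covariance structure required per genetic effect")
    y = data[model.trait].astype(float).to_numpy()
    w = (
        data[model.weight].astype(float).to_numpy()
        if model.weight is not None
        else np.ones(len(data))
    )
    n_rec = len(data)

    blocks: list[sp.csr_matrix] = []
    eqmap: list[tuple[int, int]] = []
    effect_labels: dict[int, str] = {}
    effect_no = 0
    for col in model.fixed_effects:
        effect_no += 1
        X, cats = _factor_incidence(data[col].astype(str))
        blocks.append(X)
        eqmap.extend((effect_no, lvl + 1) for lvl in range(len(cats)))
        effect_labels[effect_no] = col

    structures: list[tuple[Covstruct, float, int]] = []
    offset = sum(b.shape[1] for b in blocks)
    animals = data[model.animal].astype(str)
    for ge, struct in zip(model.genetic_effects, covstructs):
        effect_no += 1
        try:
            cols = animals.map(struct.level_index).to_numpy(dtype=float)
        except (KeyError, TypeError) as e:  # pragma: no cover
            raise MmeError(str(e)) from e
        if np.isnan(cols).any():
            missing = animals[pd.isna(animals.map(struct.level_index))].iloc[0]
            raise MmeError(
                f"phenotyped animal {missing!r} absent from the {ge.structure} "
                "covariance structure (not in pedigree/genotypes)"
            )
        W = sp.coo_matrix(
            (np.ones(n_rec), (np.arange(n_rec), cols.astype(int))),
            shape=(n_rec, struct.order),
        ).tocsr()
        blocks.append(W)
        eqmap.extend((effect_no, lvl + 1) for lvl in range(struct.order))
        effect_labels[effect_no] = f"animal ({ge.structure})"
        structures.append((struct, model.residual_variance / ge.variance, offset))
        offset += struct.order

    T = sp.hstack(blocks, format="csr")
    Wt = T.multiply(w[:, None]).tocsr()
    data_lhs = (T.T @ Wt).tocsr()
    rhs = T.T @ (w * y)
    return MmeSystem(
        data_lhs=data_lhs,
        rhs=np.asarray(rhs).ravel(),
        structures=structures,
        eqmap=eqmap,
        effect_labels=effect_labels,
    )


def _find_dependent_columns(L: np.ndarray, eqmap) -> str:
    # report equations whose LHS columns coincide (classic confounding)
    seen: dict[bytes, int] = {}
    pairs = []
    for j in range(L.shape[1]):
        key = np.round(L[:, j], 10).tobytes()
        if key in seen:
            pairs.append((eqmap[seen[key]], eqmap[j]))
        else:
            seen[key] = j
    if pairs:
        return "; ".join(f"(effect {a[0]}, level {a[1]}) == (effect {b[0]}, level {b[1]})"
                         for a, b in pairs[:5])
    return "no exactly duplicated columns found (near-singular LHS)"


def solve_direct(sys: MmeSystem, return_inverse: bool = False) -> Solutions:
    """Dense Cholesky solution (test oracle; also yields the inverse LHS
    needed for prediction error variances)."""
    L = sys.to_dense()
    try:
        c, low = scipy.linalg.cho_factor(L)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as e:
        raise MmeError(
            "singular LHS (confounded fixed effects?): "
            + _find_dependent_columns(L, sys.eqmap)
        ) from e
    x = scipy.linalg.cho_solve((c, low), sys.rhs)
    sol = Solutions(values=x, eqmap=sys.eqmap)
    if return_inverse:
        sol.lhs_inverse = scipy.linalg.cho_solve((c, low), np.eye(sys.order))
    return sol


def solve_pcg(
    sys: MmeSystem,
    tol: float = 1e-12,
    max_iter: int = 5000,
) -> Solutions:
    """Jacobi(diagonal)-preconditioned conjugate gradients.

    Matrix-vector products compose the sparse data part with the structure
    corrections; H⁻¹ is never formed densely. Converges when the relative
    residual ||LHS x - RHS|| / ||RHS|| drops below ``tol``."""
    n = sys.order
    rhs = sys.rhs
    if not np.any(rhs):
        return Solutions(values=np.zeros(n), eqmap=sys.eqmap)
    d = sys.diagonal()
    dinv = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 1.0)
    op = spla.LinearOperator((n, n), matvec=sys.matvec)
    M = spla.LinearOperator((n, n), matvec=lambda v: dinv * v)
    it = 0

    def cb(_xk):
        nonlocal it
        it += 1

    x, info = spla.cg(op, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=M,
                      callback=cb)
    res = float(np.linalg.norm(sys.matvec(x) - rhs) / np.linalg.norm(rhs))
    converged = info == 0
    if not converged:
        logger.warning(
            "PCG did not converge in %d iterations (relative residual %.3e)",
            max_iter, res,
        )
    return Solutions(values=x, eqmap=sys.eqmap, converged=converged,
                     iterations=it, final_residual=res)


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvaluationResult:
    """Everything an evaluation produced, for downstream GWAS/validation."""

    solutions: Solutions
    system: MmeSystem
    model: ModelSpec
    method: str
    ped: ped_mod.Pedigree | None = None
    inbreeding: np.ndarray | None = None
    gset: grm_mod.GenotypeSet | None = None
    Z: np.ndarray | None = None
    p: np.ndarray | None = None
    grm: grm_mod.Grm | None = None
    ginv: np.ndarray | None = None
    a22: np.ndarray | None = None
    a22inv: np.ndarray | None = None
    genotyped_idx: np.ndarray | None = None
    qc_report: grm_mod.QcReport | None = None
    stats: dict = field(default_factory=dict)
    #: genotyped-animal block of (LHS)⁻¹ σ²e (PEV matrix of GEBV); direct solver only
    cuu: np.ndarray | None = None

    @property
    def gebv(self) -> np.ndarray:
        """Animal-effect solutions (first genetic effect), renumbered order."""
        return self.solutions.effect(len(self.model.fixed_effects) + 1)

    @property
    def gebv_genotyped(self) -> np.ndarray:
        if self.genotyped_idx is None:
            raise MmeError("no genotyped animals in this evaluation")
        if self.method == "gblup":
            return self.gebv
        return self.gebv[self.genotyped_idx]


def _relationship_stats(name: str, M: np.ndarray) -> dict:
    d = np.diag(M)
    n = M.shape[0]
    off = (M.sum() - d.sum()) / (n * (n - 1)) if n > 1 else 0.0
    return {f"mean_diag_{name}": float(d.mean()), f"mean_offdiag_{name}": float(off)}


def run_evaluation(config: dict) -> EvaluationResult:
    """Run a full BLUP / GBLUP / ssGBLUP evaluation from a config mapping.

    Accepts file paths (``data_file``, ``ped_file``, ``snp_file``,
    ``map_file``) or in-memory objects (``data`` DataFrame, ``pedigree``
    RawPedigree, ``genotypes`` GenotypeSet). See the methods note for the
    full key list; option names mirror the classic parameter-file options
    (alpha_beta, tuned_g, tau_omega, no_quality_control, exact_upg, apy).
    """
    method = config.get("method", "ssgblup")
    if method not in ("blup", "gblup", "ssgblup", "user_file"):
        raise MmeError(f"unknown method {method!r}")

    # ---- data ----
    columns = config.get("columns")
    data = (
        config["data"].copy()
        if "data" in config
        else io.read_phenotype_file(config["data_file"], columns)
    )
    raw_ped = None
    if "pedigree" in config:
        raw_ped = config["pedigree"]
    elif config.get("ped_file"):
        raw_ped = io.read_pedigree_file(config["ped_file"])
    gset = None
    if "genotypes" in config:
        gset = config["genotypes"]
    elif config.get("snp_file"):
        gset = io.read_snp_file(config["snp_file"], config.get("map_file"))
    if method != "gblup" and raw_ped is None:
        raise MmeError(f"stage pedigree: method {method!r} requires a pedigree")
    if method not in ("blup", "user_file") and gset is None:
        raise MmeError(f"stage genotypes: method {method!r} requires genotypes")

    if method == "user_file":
        # one structure per supplied covariance-inverse file (e.g. several
        # saved H⁻¹ from different SNP sets, each its own random effect)
        user_files = config["user_files"]
        genetic_effects = [
            GeneticEffect(structure="user_file", variance=float(uf["variance"]),
                          user_file=uf["file"])
            for uf in user_files
        ]
    else:
        genetic_effects = [
            GeneticEffect(structure=method, variance=float(config["genetic_variance"]))
        ]
    model = ModelSpec(
        trait=config["trait"],
        fixed_effects=list(config.get("fixed_effects", [])),
        animal=config["animal"],
        genetic_effects=genetic_effects,
        residual_variance=float(config["residual_variance"]),
        weight=config.get("weight"),
    )

    stats: dict = {}
    ped = F = None
    if raw_ped is not None:
        ped = ped_mod.renumber(raw_ped)
        F = ped_mod.inbreeding(ped)

    use_inb = bool(config.get("inbreeding", True))
    exact_upg = bool(config.get("exact_upg", False))
    tau, omega = config.get("tau_omega", (1.0, 1.0))
    tau_q2, omega_q2 = config.get("tau_omega_q2", (1.0, 1.0))
    opts = HinvOptions(tau=tau, omega=omega, tau_q2=tau_q2, omega_q2=omega_q2)

    # ---- genomic side ----
    Z = p = G = ginv = a22 = a22inv = None
    genotyped_idx = None
    qc_report = None
    if gset is not None:
        n_snps_in = gset.n_snps
        qc = config.get("qc", {})
        gset, qc_report = grm_mod.qc_filter(
            gset,
            min_call_snp=qc.get("min_call_snp", 0.90),
            min_call_animal=qc.get("min_call_animal", 0.90),
            min_maf=qc.get("min_maf", 0.05),
            no_quality_control=bool(config.get("no_quality_control", False)),
        )
        max_snp = config.get("max_snp")
        if max_snp is not None and gset.n_snps > max_snp:
            raise MmeError(
                f"stage genotypes: {gset.n_snps} SNPs exceed max_snp={max_snp}"
            )
        if ped is not None:
            missing = [a for a in gset.ids if a not in ped.xref]
            if missing:
                raise MmeError(
                    f"stage genotypes: genotyped animals absent from pedigree: "
                    f"{missing[:5]}"
                )
            genotyped_idx = np.array([ped.xref[a] - 1 for a in gset.ids])
        p = config.get("base_frequencies")
        if p is None:
            p = grm_mod.allele_frequencies(gset)
        Z = grm_mod.center(gset, p)
        weights = config.get("snp_weights")
        if weights is not None:
            # weights given for the full SNP file are restricted to the
            # QC-surviving columns, then rescaled to sum to the SNP count
            # actually used in the model
            weights = np.asarray(weights, dtype=float)
            if weights.size == n_snps_in and n_snps_in != gset.n_snps:
                weights = weights[qc_report.kept_snps]
            elif weights.size != gset.n_snps:
                raise MmeError(
                    f"stage genotypes: {weights.size} SNP weights for "
                    f"{gset.n_snps} SNPs after quality control"
                )
            weights = weights * (gset.n_snps / weights.sum())
        G = grm_mod.build_G(Z, p, ids=gset.ids, weights=weights)

        if ped is not None:
            a22 = ped_mod.build_A22(ped, genotyped_idx)
            stats.update(_relationship_stats("A22", a22))
        stats.update(_relationship_stats("G_raw", G.values))

        tuned = config.get("tuned_g", 2)
        if tuned not in (None, "none", 0) and a22 is not None:
            G = grm_mod.tune(G, a22, method=f"type{tuned}")
        alpha, _beta = config.get("alpha_beta", (0.95, 0.05))
        if alpha < 1.0:
            target = a22 if (config.get("blend_target", "a22") == "a22"
                             and a22 is not None) else None
            G = grm_mod.blend(G, target, alpha=alpha)
        stats.update(_relationship_stats("G", G.values))

        apy_cfg = config.get("apy")
        if apy_cfg:
            from .apy import build_Gapy_inv, select_core

            part = select_core(
                G.n, int(apy_cfg["n_core"]), seed=int(apy_cfg.get("seed", 0))
            )
            ginv = build_Gapy_inv(G, part).toarray()
        else:
            ginv = G.inverse()

    # ---- covariance structure per method ----
    if method == "user_file":
        level_index = {a: i - 1 for a, i in ped.xref.items()}
        covstructs = [
            Covstruct(
                inv=io.read_triplets(ge.user_file, order=ped.n),
                order=ped.n,
                level_index=level_index,
            )
            for ge in model.genetic_effects
        ]
        system = build_mme(model, data, covstructs)
        solver = config.get("solver", "pcg")
        sol = (
            solve_direct(system)
            if solver == "direct"
            else solve_pcg(system, tol=float(config.get("tol", 1e-12)),
                           max_iter=int(config.get("max_iter", 5000)))
        )
        result = EvaluationResult(
            solutions=sol, system=system, model=model, method=method,
            ped=ped, inbreeding=F, stats=stats,
        )
        if config.get("solutions_file"):
            sol.write(config["solutions_file"])
        return result
    if method == "blup":
        ainv = ped_mod.build_Ainv(ped, use_inbreeding=use_inb, upg=ped.upg_count > 0,
                                  F=F)
        order = ainv.shape[0]
        level_index = {a: i - 1 for a, i in ped.xref.items()}
        struct = Covstruct(inv=ainv, order=order, level_index=level_index)
    elif method == "gblup":
        struct = Covstruct(
            inv=ginv,
            order=G.n,
            level_index={a: i for i, a in enumerate(gset.ids)},
        )
    else:  # ssgblup
        with_upg = exact_upg and ped.upg_count > 0
        ainv = ped_mod.build_Ainv(ped, use_inbreeding=use_inb, upg=with_upg, F=F)
        a22inv = ped_mod.build_A22inv_indirect(
            ped_mod.build_Ainv(ped, use_inbreeding=True, upg=False, F=F),
            genotyped_idx,
        )
        hinv = build_Hinv(ainv, a22inv, ginv, genotyped_idx, opts)
        if with_upg:
            q2 = build_Q2(ped, genotyped_idx)
            hinv = apply_upg(hinv, ginv, a22inv, q2, opts)
        level_index = {a: i - 1 for a, i in ped.xref.items()}
        struct = Covstruct(inv=hinv, order=hinv.order, level_index=level_index)
        stats.update(_relationship_stats("Ginv_minus_A22inv", ginv - a22inv))

    for key, val in stats.items():
        logger.info("%s = %.6f", key, val)

    system = build_mme(model, data, [struct])
    solver = config.get("solver", "pcg")
    want_cuu = bool(config.get("snp_p_value", False))
    if solver == "direct" or want_cuu:
        sol = solve_direct(system, return_inverse=want_cuu)
    else:
        sol = solve_pcg(
            system,
            tol=float(config.get("tol", 1e-12)),
            max_iter=int(config.get("max_iter", 5000)),
        )

    result = EvaluationResult(
        solutions=sol, system=system, model=model, method=method,
        ped=ped, inbreeding=F, gset=gset, Z=Z, p=np.asarray(p) if p is not None else None,
        grm=G, ginv=ginv, a22=a22, a22inv=a22inv,
        genotyped_idx=genotyped_idx, qc_report=qc_report, stats=stats,
    )
    if want_cuu:
        n_fixed_eq = sum(1 for e, _ in system.eqmap if e <= len(model.fixed_effects))
        if method == "gblup":
            rows = n_fixed_eq + np.arange(G.n)
        else:
            rows = n_fixed_eq + genotyped_idx
        result.cuu = (
            sol.lhs_inverse[np.ix_(rows, rows)] * model.residual_variance
        )
    if config.get("solutions_file"):
        sol.write(config["solutions_file"])
    return result
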