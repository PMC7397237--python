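"""SNP effects from GEBV: backsolving, weights, GWAS statistics.

GBLUP-type models never estimate SNP effects directly, but because GBLUP is
equivalent to SNP-BLUP the marker effects can be recovered from the animal
solutions:

    â = k D Z' G⁻¹ û        (k = 1/(2 Σ pq), D = diag of SNP weights)

From â one gets per-SNP variances (several formulas, including the bounded
exponential "nonlinearA" d_i = CT^(|â_i|/σ(â) - 2)), windowed variance
shares for Manhattan plots, prediction-error variances and p-values, the
iterative weighted single-step scheme, and indirect predictions Z_new â for
newly genotyped animals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grm import Grm

__all__ = [
    "SnpModelError",
    "SnpResults",
    "backsolve_snp",
    "snp_variance",
    "nonlinear_a_cap",
    "variance_shares",
    "window_variance",
    "snp_pvalues",
    "indirect_predictions",
    "weighted_iterate",
]


class SnpModelError(ValueError):
    pass


@dataclass
class SnpResults:
    """Per-SNP outputs of a backsolve/GWAS pass."""

    effects: np.ndarray
    weights: np.ndarray
    variance_share: np.ndarray
    k: float
    snp_map: pd.DataFrame | None = None
    window_share: np.ndarray | None = None
    pev: np.ndarray | None = None
    pvalues: np.ndarray | None = None
    ct: float | None = None
    variance_limit: float | None = None
    b_factor: float = 1.0

    def tables(self) -> dict[str, pd.DataFrame]:
        """Manhattan-plot data tables (chromosome, position, value)."""
        if self.snp_map is None:
            raise SnpModelError("SNP map required for plot tables")
        base = self.snp_map[["chromosome", "position"]]
        out = {
            "effect": base.assign(value=self.effects),
            "variance_share": base.assign(
                value=self.window_share
                if self.window_share is not None
                else self.variance_share
            ),
        }
        if self.pvalues is not None:
            out["pvalue"] = base.assign(value=-np.log10(self.pvalues))
        return out


def backsolve_snp(
    gebv_genotyped: np.ndarray,
    Z: np.ndarray,
    ginv: np.ndarray,
    k: float,
    d: np.ndarray | None = None,
) -> np.ndarray:
    """â = k D Z' G⁻¹ û over the genotyped animals.

    ``ginv`` must be the inverse of the same (possibly tuned/blended/
    weighted) G used in the evaluation that produced the GEBV."""
    u = np.asarray(gebv_genotyped, dtype=float)
    if Z.shape[0] != u.size or ginv.shape != (u.size, u.size):
        raise SnpModelError(
            f"dimension mismatch: {u.size} GEBV, Z {Z.shape}, G⁻¹ {ginv.shape}"
        )
    a = k * (Z.T @ (ginv @ u))
    if d is not None:
        a = np.asarray(d, dtype=float) * a
    return a


def nonlinear_a_cap(ct: float, limit_x: float) -> float:
    """Maximum nonlinearA variance multiplier, CT^(limit - 2)."""
    return float(ct ** (limit_x - 2.0))


def snp_variance(
    a_hat: np.ndarray,
    p: np.ndarray,
    method: Literal["default", "quadratic", "nonlinearA"] = "nonlinearA",
    ct: float = 1.125,
    limit_x: float = 5.0,
) -> np.ndarray:
    """Per-SNP variance/weight d from estimated effects.

    default: d_i = 2 p_i (1-p_i) â_i²; quadratic: d_i = â_i²;
    nonlinearA: d_i = CT^(min(|â_i|/σ(â), limit_x) - 2), a bounded
    departure from equal weights (cap CT^(limit_x - 2))."""
    a_hat = np.asarray(a_hat, dtype=float)
    if method == "default":
        p = np.asarray(p, dtype=float)
        return 2.0 * p * (1.0 - p) * a_hat**2
    if method == "quadratic":
        return a_hat**2
    if method == "nonlinearA":
        sd = float(np.std(a_hat))
        if sd == 0.0:
            raise SnpModelError("nonlinearA undefined: sd of SNP effects is 0")
        x = np.minimum(np.abs(a_hat) / sd, limit_x)
        return ct ** (x - 2.0)
    raise SnpModelError(f"unknown SNP-variance method {method!r}")


def normalize_weights(d: np.ndarray) -> np.ndarray:
    """Rescale weights to sum to the number of SNPs (also the rule for
    externally supplied weights)."""
    d = np.asarray(d, dtype=float)
    s = d.sum()
    if s <= 0 or not np.isfinite(s):
        raise SnpModelError("weights do not sum to a positive finite value")
    return d * (d.size / s)


def variance_shares(a_hat: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Percent of total marker variance per SNP: 100·2pq â² / Σ 2pq â²."""
    v = 2.0 * p * (1.0 - p) * np.asarray(a_hat, dtype=float) ** 2
    tot = v.sum()
    if tot == 0:
        return np.zeros_like(v)
    return 100.0 * v / tot


def window_variance(
    shares: np.ndarray,
    snp_map: pd.DataFrame,
    n_window: int,
) -> np.ndarray:
    """Sliding sums of per-SNP variance shares over ``n_window`` adjacent
    SNPs within a chromosome (window starting at each SNP, truncated at the
    chromosome end). The map must be sorted by chromosome then position."""
    if n_window < 1:
        raise SnpModelError(f"n_window must be >= 1, got {n_window}")
    shares = np.asarray(shares, dtype=float)
    chrom = snp_map["chromosome"].to_numpy()
    pos = snp_map["position"].to_numpy()
    for c in np.unique(chrom):
        pc = pos[chrom == c]
        if np.any(np.diff(pc) < 0):
            raise SnpModelError("map not sorted by chromosome, position")
    out = np.empty_like(shares)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        s = shares[idx]
        cs = np.concatenate([[0.0], np.cumsum(s)])
        n = s.size
        hi = np.minimum(np.arange(n) + n_window, n)
        out[idx] = cs[hi] - cs[np.arange(n)]
    return out


def snp_pvalues(
    a_hat: np.ndarray,
    Z: np.ndarray,
    ginv: np.ndarray,
    cuu: np.ndarray,
    k: float,
    sigma2_u: float,
    alpha: float = 1.0,
    b: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Prediction-error variances and p-values of backsolved SNP effects.

    var(â_i) = (k α b)² z_i' G⁻¹ (G σ²u - C^{u2u2}) G⁻¹ z_i, where
    C^{u2u2} is the genotyped-animal block of the inverse LHS times σ²e
    (the PEV matrix of the GEBV), so G σ²u - C^{u2u2} = Var(û). Then
    p_i = 2(1 - Φ(|â_i| / sd(â_i))). Non-positive computed variances are
    floored at 0 with p = 1 (and a warning via the returned arrays' users).

    Returns (pev, pvalues).
    """
    if cuu is None:
        raise SnpModelError(
            "C^{u2u2} missing: run the evaluation with the direct solver "
            "(snp_p_value option) to obtain the inverse-LHS genotyped block"
        )
    ng = Z.shape[0]
    if cuu.shape != (ng, ng) or ginv.shape != (ng, ng):
        raise SnpModelError("C^{u2u2}/G⁻¹ do not match the genotyped set")
    G = np.linalg.inv(ginv)
    var_u = G * sigma2_u - cuu
    c = k * alpha * b
    T = ginv @ Z  # columns G⁻¹ z_i
    pev = c * c * np.einsum("ij,ij->j", T, var_u @ T)
    a_hat = np.asarray(a_hat, dtype=float)
    pvals = np.ones_like(a_hat)
    ok = pev > 0
    z = np.abs(a_hat[ok]) / np.sqrt(pev[ok])
    pvals[ok] = 2.0 * sps.norm.sf(z)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    pev = np.maximum(pev, 0.0)
    return pev, pvals


def indirect_predictions(
    a_hat: np.ndarray,
    new_genotypes: np.ndarray,
    p: np.ndarray,
) -> np.ndarray:
    """IP = Z_new â for newly genotyped animals, centered with the
    evaluation's allele frequencies (missing entries imputed to 2p)."""
    M = np.asarray(new_genotypes, dtype=float)
    a_hat = np.asarray(a_hat, dtype=float)
    if M.shape[1] != a_hat.size:
        raise SnpModelError(
            f"{M.shape[1]} SNPs in new genotypes, {a_hat.size} SNP effects"
        )
    Z = np.nan_to_num(M - 2.0 * np.asarray(p, dtype=float), nan=0.0)
    return Z @ a_hat


def weighted_iterate(
    eval_config: dict,
    rounds: int,
    weight_method: Literal["default", "quadratic", "nonlinearA"] = "nonlinearA",
    ct: float = 1.125,
    limit_x: float = 5.0,
    external_weights: np.ndarray | None = None,
    compute_pvalues: bool = False,
):
    """Weighted single-step iteration.

    Round 0 runs the evaluation with D = I and backsolves; each further
    round recomputes d from the current effects (or applies the external
    weights once, rescaled to sum to the SNP count), rebuilds G = Z D Z' k
    and re-solves. p-values are only computed for the unweighted analysis
    (weights and p-values are statistically incompatible: the weights are
    functions of the effects being tested).

    Returns (EvaluationResult, SnpResults) from the final round.
    """
    from .mme import run_evaluation

    if rounds < 0:
        raise SnpModelError("rounds must be >= 0")
    if compute_pvalues and (rounds > 0 or external_weights is not None):
        raise SnpModelError(
            "p-values cannot be combined with weighted iteration"
        )
    cfg = dict(eval_config)
    if compute_pvalues:
        cfg["snp_p_value"] = True
    m = None
    d = None
    if external_weights is not None:
        d = normalize_weights(np.asarray(external_weights, dtype=float))
        cfg["snp_weights"] = d
    result = run_evaluation(cfg)
    for rnd in range(rounds + 1):
        grm: Grm = result.grm
        m = grm.p.size
        a_hat = backsolve_snp(
            result.gebv_genotyped, result.Z, result.ginv, grm.k, grm.weights
        )
        if rnd == rounds:
            break
        d = snp_variance(a_hat, grm.p, method=weight_method, ct=ct, limit_x=limit_x)
        if not np.all(np.isfinite(d)):
            raise SnpModelError(f"non-finite SNP weight in round {rnd + 1}")
        d = normalize_weights(d)
        cfg["snp_weights"] = d
        result = run_evaluation(cfg)

    grm = result.grm
    shares = variance_shares(a_hat, grm.p)
    results = SnpResults(
        effects=a_hat,
        weights=grm.weights,
        variance_share=shares,
        k=grm.k,
        snp_map=result.gset.snp_map if result.gset is not None else None,
        ct=ct if weight_method == "nonlinearA" else None,
        variance_limit=nonlinear_a_cap(ct, limit_x)
        if weight_method == "nonlinearA"
        else None,
        b_factor=grm.b_factor,
    )
    n_window = eval_config.get("windows_variance")
    if n_window and results.snp_map is not None:
        results.window_share = window_variance(shares, results.snp_map, int(n_window))
    if compute_pvalues:
        pev, pvals = snp_pvalues(
            a_hat, result.Z, result.ginv, result.cuu, grm.k,
            sigma2_u=float(eval_config["genetic_variance"]),
            alpha=grm.alpha, b=grm.b_factor,
        )
        results.pev = pev
        results.pvalues = pvals
    return result, results
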