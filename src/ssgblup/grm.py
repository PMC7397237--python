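"""Genomic relationship matrix (G): quality control, centering, blending, tuning.

G is built from centered allele counts, Z = M - 2p', as G = Z D Z' k with
k = 1/(2 Σ p_i(1-p_i)) and D a diagonal matrix of per-SNP weights (identity
unless a weighted analysis supplies variances). With observed allele
frequencies the mean of all elements of G is zero and the mean diagonal is
about 1 for a non-inbred population.

Because current-data allele frequencies differ from the (unobservable)
pedigree base population, G is *tuned* so its mean relationships match
those of the pedigree submatrix A22 — either Chen's regression-style
(phi, delta) adjustment ("type 2", the default) or the single mean shift
rho ("type 4") — and *blended* with a small share of A22 or I to guarantee
invertibility and model polygenic variance not captured by markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSet",
    "Grm",
    "GrmError",
    "QcReport",
    "qc_filter",
    "allele_frequencies",
    "center",
    "build_G",
    "blend",
    "tune",
]


class GrmError(ValueError):
    pass


@dataclass
class GenotypeSet:
    """Animal-by-SNP allele counts (0/1/2, NaN = missing) plus optional map."""

    ids: list[str]
    M: np.ndarray
    snp_map: pd.DataFrame | None = None

    @property
    def n_animals(self) -> int:
        return self.M.shape[0]

    @property
    def n_snps(self) -> int:
        return self.M.shape[1]

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypeSet":
        M = self.M
        ids = self.ids
        snp_map = self.snp_map
        if animal_idx is not None:
            animal_idx = np.asarray(animal_idx)
            M = M[animal_idx]
            ids = [self.ids[i] for i in animal_idx]
        if snp_idx is not None:
            snp_idx = np.asarray(snp_idx)
            M = M[:, snp_idx]
            if snp_map is not None:
                snp_map = snp_map.iloc[snp_idx].reset_index(drop=True)
        return GenotypeSet(ids=ids, M=M, snp_map=snp_map)


@dataclass
class QcReport:
    """Every removal with its reason, in the order applied."""

    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_animals: list[tuple[str, str]] = field(default_factory=list)
    #: column indices (into the input set) of the SNPs that survived
    kept_snps: np.ndarray | None = None

    def summary(self) -> str:
        return (
            f"QC removed {len(self.removed_snps)} SNPs, "
            f"{len(self.removed_animals)} animals"
        )


@dataclass
class Grm:
    """Dense genomic relationship matrix with its provenance.

    ``k`` is the 1/(2 Σ pq) scale; ``alpha`` the blending proportion (1
    before blending); ``tuning`` records none/type2/type4 with rho or
    (phi, delta); ``b_factor`` is the multiplicative part of the tuning
    (1 - rho/2 for type 4, phi for type 2, 1 untuned) used later in the
    SNP-effect prediction-error variance.
    """

    values: np.ndarray
    ids: list[str]
    k: float
    p: np.ndarray
    weights: np.ndarray
    alpha: float = 1.0
    tuning: Literal["none", "type2", "type4"] = "none"
    rho: float | None = None
    phi: float | None = None
    delta: float | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def b_factor(self) -> float:
        if self.tuning == "type4":
            return 1.0 - self.rho / 2.0
        if self.tuning == "type2":
            return self.phi
        return 1.0

    def inverse(self) -> np.ndarray:
        try:
            return np.linalg.inv(self.values)
        except np.linalg.LinAlgError as e:
            raise GrmError(
                "G is singular; blend with A22 or I before inverting"
            ) from e


def qc_filter(
    gset: GenotypeSet,
    min_call_snp: float = 0.90,
    min_call_animal: float = 0.90,
    min_maf: float = 0.05,
    no_quality_control: bool = False,
) -> tuple[GenotypeSet, QcReport]:
    """Drop SNPs with low call rate, low MAF or no variation (monomorphic
    SNPs are always dropped), then animals with low call rate over the
    retained SNPs. With ``no_quality_control`` everything passes untouched.
    """
    report = QcReport()
    if no_quality_control:
        report.kept_snps = np.arange(gset.n_snps)
        return gset, report
    M = gset.M
    snp_ids = (
        list(gset.snp_map["snp_id"])
        if gset.snp_map is not None
        else [str(j + 1) for j in range(gset.n_snps)]
    )
    call = 1.0 - np.mean(np.isnan(M), axis=0)
    p = allele_frequencies(gset)
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(gset.n_snps, dtype=bool)
    for j in range(gset.n_snps):
        if maf[j] == 0.0 or np.isnan(p[j]):
            keep[j] = False
            report.removed_snps.append((snp_ids[j], "monomorphic"))
        elif call[j] < min_call_snp:
            keep[j] = False
            report.removed_snps.append(
                (snp_ids[j], f"call rate {call[j]:.3f} < {min_call_snp}")
            )
        elif maf[j] < min_maf:
            keep[j] = False
            report.removed_snps.append((snp_ids[j], f"MAF {maf[j]:.3f} < {min_maf}"))
    if not keep.any():
        raise GrmError("quality control removed every SNP")
    report.kept_snps = np.flatnonzero(keep)
    out = gset.subset(snp_idx=report.kept_snps)
    acall = 1.0 - np.mean(np.isnan(out.M), axis=1)
    akeep = acall >= min_call_animal
    for i in np.flatnonzero(~akeep):
        report.removed_animals.append(
            (out.ids[i], f"call rate {acall[i]:.3f} < {min_call_animal}")
        )
    if not akeep.all():
        out = out.subset(animal_idx=np.flatnonzero(akeep))
    return out, report


def allele_frequencies(gset: GenotypeSet) -> np.ndarray:
    """Counted-allele frequency per SNP from the non-missing genotypes."""
    with np.errstate(invalid="ignore"):
        return np.nanmean(gset.M, axis=0) / 2.0


def center(gset: GenotypeSet, p: np.ndarray | None = None) -> np.ndarray:
    """Z = M - 2p' columnwise; missing entries become 0 after centering
    (mean imputation to 2p). With observed frequencies every column of Z
    sums to zero."""
    if p is None:
        p = allele_frequencies(gset)
    p = np.asarray(p, dtype=float)
    if p.shape != (gset.n_snps,):
        raise GrmError(
            f"frequency vector has length {p.size}, expected {gset.n_snps}"
        )
    Z = gset.M - 2.0 * p
    return np.nan_to_num(Z, nan=0.0)


def build_G(
    Z: np.ndarray,
    p: np.ndarray,
    ids: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> Grm:
    """G = Z D Z' k with k = 1/(2 Σ p(1-p)); D = diag(weights), default I."""
    p = np.asarray(p, dtype=float)
    m = Z.shape[1]
    if weights is None:
        weights = np.ones(m)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise GrmError("SNP weights must be positive")
    s = 2.0 * np.sum(p * (1.0 - p))
    if s <= 0:
        raise GrmError("all SNPs monomorphic: scale k = 1/(2 Σ pq) undefined")
    k = 1.0 / s
    G = (Z * weights) @ Z.T * k
    G = 0.5 * (G + G.T)
    if ids is None:
        ids = [str(i + 1) for i in range(Z.shape[0])]
    return Grm(values=G, ids=list(ids), k=k, p=p, weights=weights)


def blend(g: Grm, target: np.ndarray | None = None, alpha: float = 0.95) -> Grm:
    """G <- alpha G + (1-alpha) target, target = A22 (pass it) or I (None)."""
    if not 0.0 <= alpha <= 1.0:
        raise GrmError(f"alpha must be in [0,1], got {alpha}")
    if target is None:
        target = np.eye(g.n)
    target = np.asarray(target, dtype=float)
    if target.shape != g.values.shape:
        raise GrmError(
            f"blend target shape {target.shape} does not match G {g.values.shape}"
        )
    return replace(g, values=alpha * g.values + (1.0 - alpha) * target, alpha=alpha)


def tune(g: Grm, a22: np.ndarray, method: Literal["type2", "type4"] = "type2") -> Grm:
    """Match G's mean relationships to A22's.

    type 4 (single shift): rho = mean(A22) - mean(G);
        G* = (1 - rho/2) G + 11' rho.
    type 2 (Chen): phi = (mean diag A22 - mean offdiag A22) /
        (mean diag G - mean offdiag G); delta = mean diag A22 - phi mean diag G;
        G* = phi G + delta, which matches both the mean diagonal and the
        mean off-diagonal exactly.
    """
    a22 = np.asarray(a22, dtype=float)
    if a22.shape != g.values.shape:
        raise GrmError("A22 and G must have the same animal ordering/shape")
    G = g.values
    if method == "type4":
        rho = float(a22.mean() - G.mean())
        tuned = (1.0 - rho / 2.0) * G + rho
        return replace(g, values=tuned, tuning="type4", rho=rho)
    if method == "type2":
        n = g.n
        dG, dA = np.diag(G), np.diag(a22)
        mdG, mdA = dG.mean(), dA.mean()
        if n > 1:
            moG = (G.sum() - dG.sum()) / (n * (n - 1))
            moA = (a22.sum() - dA.sum()) / (n * (n - 1))
        else:
            moG = moA = 0.0
        denom = mdG - moG
        if abs(denom) < 1e-12:
            raise GrmError("type-2 tuning undefined: mean diag G == mean offdiag G")
        phi = (mdA - moA) / denom
        delta = mdA - mdG * phi
        return replace(g, values=phi * G + delta, tuning="type2",
                       phi=float(phi), delta=float(delta))
    raise GrmError(f"unknown tuning method {method!r}")
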