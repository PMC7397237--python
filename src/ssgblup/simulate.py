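"""Gene-dropping simulator with known truth.

Generates multi-generation pedigree, phenotype, genotype and map files in
the whitespace dialect the readers in this package expect, so the whole
pipeline can be exercised (and validated against truth) without any
external data.

The model: founders get haplotypes drawn at per-SNP allele frequencies
~ Uniform(0.05, 0.95); descendants inherit by Mendelian gene dropping with
recombination (Haldane — Poisson crossover counts at map distances,
1 cM ≈ 1 Mb). A random subset of loci are QTL with normal effects; true
breeding values TBV = Σ genotype·effect are scaled so Var(TBV) equals the
configured additive variance, and phenotypes are

    y = sex_effect + TBV + N(0, σ²e).

QTL are excluded from the written SNP panel by default (markers tag them
through linkage disequilibrium only), which mirrors how real chips relate
to causative variants; including them enables perfect-prediction
experiments. Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .grm import GenotypeSet
from .io_formats import (
    RawPedigree,
    write_map_file,
    write_pedigree_file,
    write_phenotype_file,
    write_snp_file,
)

__all__ = ["SimConfig", "SimDataset", "simulate_population", "mask_phenotypes",
           "companion_shape_config"]

#: 1 cM per Mb
BP_PER_MORGAN = 100_000_000


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study design for one simulated population.

    Defaults are the desk-scale preset: 3000 animals (500 founders + 5
    generations of 500), 2000 SNPs on 5 chromosomes of 100 cM, 50 QTL,
    h² = 0.4 with variances 0.4/0.6, sex effects 2.0 and 1.0.
    """

    n_founders: int = 500
    #: founder haplotypes are mosaics of this many distinct ancestral
    #: haplotypes, giving the linkage disequilibrium of a small effective
    #: population (markers then tag QTL); None = independent loci (no LD)
    n_ancestral_haplotypes: int | None = 100
    #: crossovers per Morgan when composing founder mosaics — emulates the
    #: accumulated historical recombination, so LD is local rather than
    #: chromosome-wide
    ancestral_recombination_rate: float = 10.0
    n_generations: int = 5
    n_offspring: int = 500
    n_sires: int = 50
    n_dams: int = 250
    n_snps: int = 2000
    n_qtl: int = 50
    n_chromosomes: int = 5
    chromosome_length_bp: int = BP_PER_MORGAN
    genetic_variance: float = 0.4
    residual_variance: float = 0.6
    sex_effects: tuple[float, float] = (2.0, 1.0)
    founder_freq_low: float = 0.05
    founder_freq_high: float = 0.95
    include_qtl_in_panel: bool = False
    #: rescale QTL effects so every QTL contributes the same realized
    #: variance (planted-QTL validation designs); default keeps the
    #: normal-effects polygenic architecture
    equal_qtl_variance: bool = False
    #: "generations" genotypes every animal of ``genotyped_generations``;
    #: "companion" samples parents of earlier generations plus the last one
    genotyping: str = "generations"
    genotyped_generations: tuple[int, ...] = (4, 5)
    n_genotyped_parents: int = 1020
    n_genotyped_last: int = 1004
    seed: int = 1

    def __post_init__(self) -> None:
        if self.genetic_variance <= 0.0 or self.residual_variance <= 0.0:
            raise SimulationError("variances must be positive")
        h2 = self.genetic_variance / (self.genetic_variance + self.residual_variance)
        if not 0.0 < h2 < 1.0:
            raise SimulationError(f"h² = {h2} outside (0, 1)")
        if self.n_qtl > self.n_snps:
            raise SimulationError("n_qtl cannot exceed n_snps")
        if self.n_sires + self.n_dams > max(self.n_founders, self.n_offspring):
            raise SimulationError(
                "not enough animals per generation to supply sires and dams"
            )


@dataclass
class SimDataset:
    """Simulated files plus the truth needed to score predictions."""

    pedigree: RawPedigree
    phenotypes: pd.DataFrame  # animal, sex, phenotype, tbv, generation
    genotypes: GenotypeSet
    truth: pd.DataFrame  # animal, sex, generation, tbv
    qtl: pd.DataFrame  # chromosome, position, effect
    config: SimConfig
    #: drawn allele frequency per panel SNP (the generative truth the
    #: founder genotypes were sampled at)
    founder_frequencies: np.ndarray | None = None

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pedigree": outdir / "pedigree.txt",
            "phenotypes": outdir / "phenotypes.txt",
            "genotypes": outdir / "genotypes.txt",
            "map": outdir / "gen_map.txt",
            "truth": outdir / "truth.txt",
        }
        write_pedigree_file(self.pedigree, paths["pedigree"])
        write_phenotype_file(self.phenotypes, paths["phenotypes"])
        write_snp_file(self.genotypes, paths["genotypes"], paths["map"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False, header=False)
        return paths

    def eval_config(self, method: str = "ssgblup", **overrides) -> dict:
        """Ready-to-run evaluation config on the in-memory objects."""
        cfg = {
            "method": method,
            "data": self.phenotypes,
            "columns": ["animal", "sex", "phenotype", "tbv", "generation"],
            "pedigree": self.pedigree,
            "trait": "phenotype",
            "fixed_effects": ["sex"],
            "animal": "animal",
            "genetic_variance": self.config.genetic_variance,
            "residual_variance": self.config.residual_variance,
        }
        if method != "blup":
            cfg["genotypes"] = self.genotypes
        cfg.update(overrides)
        return cfg


def _meiosis(hap: np.ndarray, chrom_slices, positions, rng) -> np.ndarray:
    """One gamete from a (2, n_loci) parent haplotype pair."""
    gamete = np.empty(hap.shape[1], dtype=hap.dtype)
    for sl, pos in zip(chrom_slices, positions):
        length_m = (pos[-1] - pos[0]) / BP_PER_MORGAN if pos.size > 1 else 0.0
        n_x = rng.poisson(length_m)
        current = rng.integers(2)
        seg = np.full(pos.size, current, dtype=np.int8)
        if n_x:
            xpos = rng.uniform(pos[0], pos[-1], size=n_x)
            for xp in np.sort(xpos):
                current = 1 - current
                seg[pos > xp] = current
        idx = np.arange(sl.start, sl.stop)
        gamete[sl] = hap[seg, idx]
    return gamete


def simulate_population(cfg: SimConfig) -> SimDataset:
    """Simulate pedigree, phenotypes, genotypes and truth per ``cfg``."""
    rng = np.random.default_rng(cfg.seed)
    n_total = cfg.n_founders + cfg.n_generations * cfg.n_offspring
    n_loci = cfg.n_snps + (0 if cfg.include_qtl_in_panel else cfg.n_qtl)

    # locus layout: even split over chromosomes, sorted random positions
    per_chrom = np.full(cfg.n_chromosomes, n_loci // cfg.n_chromosomes)
    per_chrom[: n_loci % cfg.n_chromosomes] += 1
    chrom_slices, positions, chrom_of = [], [], []
    start = 0
    for c, cnt in enumerate(per_chrom):
        pos = np.sort(
            rng.choice(
                np.arange(1, cfg.chromosome_length_bp, dtype=np.int64),
                size=cnt, replace=False,
            )
        )
        chrom_slices.append(slice(start, start + cnt))
        positions.append(pos)
        chrom_of.extend([c + 1] * cnt)
        start += cnt
    chrom_of = np.array(chrom_of)
    all_pos = np.concatenate(positions)

    qtl_loci = np.sort(rng.choice(n_loci, size=cfg.n_qtl, replace=False))
    is_qtl = np.zeros(n_loci, dtype=bool)
    is_qtl[qtl_loci] = True
    snp_loci = (
        np.arange(n_loci) if cfg.include_qtl_in_panel else np.flatnonzero(~is_qtl)
    )

    freq = rng.uniform(cfg.founder_freq_low, cfg.founder_freq_high, size=n_loci)
    haplo = np.zeros((n_total, 2, n_loci), dtype=np.int8)
    if cfg.n_ancestral_haplotypes is None:
        haplo[: cfg.n_founders] = (
            rng.random((cfg.n_founders, 2, n_loci)) < freq
        ).astype(np.int8)
    else:
        anc = (
            rng.random((cfg.n_ancestral_haplotypes, n_loci)) < freq
        ).astype(np.int8)
        for i in range(cfg.n_founders):
            for h in (0, 1):
                for sl, pos in zip(chrom_slices, positions):
                    length_m = (
                        (pos[-1] - pos[0]) / BP_PER_MORGAN if pos.size > 1 else 0.0
                    )
                    n_x = rng.poisson(cfg.ancestral_recombination_rate * length_m)
                    bounds = np.concatenate(
                        [
                            [pos[0]],
                            np.sort(rng.uniform(pos[0], pos[-1], size=n_x)),
                            [pos[-1] + 1],
                        ]
                    )
                    src = rng.integers(cfg.n_ancestral_haplotypes, size=n_x + 1)
                    seg = src[np.searchsorted(bounds, pos, side="right") - 1]
                    haplo[i, h, sl] = anc[seg, np.arange(sl.start, sl.stop)]

    sire = np.zeros(n_total, dtype=np.int64)  # 1-based, 0 unknown
    dam = np.zeros(n_total, dtype=np.int64)
    generation = np.zeros(n_total, dtype=np.int64)
    # balanced sexes within each cohort: 0 = male, 1 = female
    sex = np.zeros(n_total, dtype=np.int64)

    def assign_sex(idx):
        s = np.array([0, 1] * ((idx.size + 1) // 2))[: idx.size]
        sex[idx] = rng.permutation(s)

    cohort = np.arange(cfg.n_founders)
    assign_sex(cohort)
    nxt = cfg.n_founders
    for g in range(1, cfg.n_generations + 1):
        males = cohort[sex[cohort] == 0]
        females = cohort[sex[cohort] == 1]
        if males.size < cfg.n_sires or females.size < cfg.n_dams:
            raise SimulationError(
                f"generation {g}: cannot draw {cfg.n_sires} sires / "
                f"{cfg.n_dams} dams from {males.size}/{females.size} candidates"
            )
        sires = rng.choice(males, size=cfg.n_sires, replace=False)
        dams = rng.choice(females, size=cfg.n_dams, replace=False)
        new = np.arange(nxt, nxt + cfg.n_offspring)
        sire[new] = rng.choice(sires, size=cfg.n_offspring) + 1
        dam[new] = rng.choice(dams, size=cfg.n_offspring) + 1
        generation[new] = g
        for i in new:
            haplo[i, 0] = _meiosis(haplo[sire[i] - 1], chrom_slices, positions, rng)
            haplo[i, 1] = _meiosis(haplo[dam[i] - 1], chrom_slices, positions, rng)
        assign_sex(new)
        cohort = new
        nxt += cfg.n_offspring

    geno = haplo.sum(axis=1)  # allele counts, n_total x n_loci

    qtl_eff = rng.normal(size=cfg.n_qtl)
    if cfg.equal_qtl_variance:
        gvar = geno[:, qtl_loci].astype(float).var(axis=0)
        if np.any(gvar == 0):
            raise SimulationError("monomorphic QTL cannot carry variance")
        qtl_eff = np.sign(qtl_eff) / np.sqrt(gvar)
    raw = geno[:, qtl_loci].astype(float) @ qtl_eff
    sd = raw.std()
    if sd == 0:
        raise SimulationError("degenerate QTL genotypes: zero TBV variance")
    scale = np.sqrt(cfg.genetic_variance) / sd
    tbv = (raw - raw.mean()) * scale
    qtl_eff *= scale

    resid = rng.normal(scale=np.sqrt(cfg.residual_variance), size=n_total)
    y = np.asarray(cfg.sex_effects)[sex] + tbv + resid

    ids = [str(i + 1) for i in range(n_total)]
    ped = RawPedigree(
        [(ids[i], str(sire[i]), str(dam[i])) for i in range(n_total)]
    )
    phen = pd.DataFrame(
        {
            "animal": ids,
            "sex": (sex + 1).astype(str),
            "phenotype": np.round(y, 6),
            "tbv": np.round(tbv, 6),
            "generation": generation.astype(str),
        }
    )
    truth = pd.DataFrame(
        {"animal": ids, "sex": sex + 1, "generation": generation, "tbv": tbv}
    )

    # who gets genotyped
    if cfg.genotyping == "generations":
        g_idx = np.flatnonzero(np.isin(generation, cfg.genotyped_generations))
    elif cfg.genotyping == "companion":
        is_parent = np.zeros(n_total, dtype=bool)
        is_parent[sire[sire > 0] - 1] = True
        is_parent[dam[dam > 0] - 1] = True
        early = np.flatnonzero(
            is_parent & (generation >= 1) & (generation < cfg.n_generations)
        )
        last = np.flatnonzero(generation == cfg.n_generations)
        if early.size < cfg.n_genotyped_parents or last.size < cfg.n_genotyped_last:
            raise SimulationError(
                "companion genotyping rule: not enough parents/last-generation "
                f"animals ({early.size}/{last.size})"
            )
        g_idx = np.sort(
            np.concatenate(
                [
                    rng.choice(early, size=cfg.n_genotyped_parents, replace=False),
                    rng.choice(last, size=cfg.n_genotyped_last, replace=False),
                ]
            )
        )
    else:
        raise SimulationError(f"unknown genotyping rule {cfg.genotyping!r}")

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"M{j + 1}" for j in range(snp_loci.size)],
            "chromosome": chrom_of[snp_loci],
            "position": all_pos[snp_loci],
        }
    )
    gset = GenotypeSet(
        ids=[ids[i] for i in g_idx],
        M=geno[np.ix_(g_idx, snp_loci)].astype(float),
        snp_map=snp_map,
    )
    qtl_table = pd.DataFrame(
        {
            "chromosome": chrom_of[qtl_loci],
            "position": all_pos[qtl_loci],
            "effect": qtl_eff,
        }
    )
    return SimDataset(
        pedigree=ped, phenotypes=phen, genotypes=gset, truth=truth,
        qtl=qtl_table, config=cfg, founder_frequencies=freq[snp_loci],
    )


def companion_shape_config(seed: int = 1) -> SimConfig:
    """Preset matching the observable shape of the worked-example dataset:
    10,000 pedigreed/phenotyped animals, 1020 genotyped parents from the
    pre-final generations plus 1004 genotyped final-generation animals."""
    return SimConfig(
        n_founders=1000,
        n_generations=5,
        n_offspring=1800,
        n_sires=60,
        n_dams=300,
        genotyping="companion",
        seed=seed,
    )


def mask_phenotypes(dataset: SimDataset, rule) -> SimDataset:
    """Remove phenotype records for the animals a rule selects, keeping
    them in the pedigree and truth (so their prediction accuracy can be
    scored). ``rule`` is ("generation", g) or a boolean function of a
    truth-table row."""
    if isinstance(rule, tuple) and rule[0] == "generation":
        gsel = int(rule[1])
        mask = dataset.truth["generation"].to_numpy() == gsel
    elif callable(rule):
        mask = dataset.truth.apply(rule, axis=1).to_numpy(dtype=bool)
    else:
        raise SimulationError(f"unsupported masking rule {rule!r}")
    if not mask.any():
        warnings.warn("phenotype mask selected no animals", stacklevel=2)
        return dataset
    masked_ids = set(dataset.truth["animal"][mask])
    keep = ~dataset.phenotypes["animal"].isin(masked_ids)
    return replace(dataset, phenotypes=dataset.phenotypes[keep].reset_index(drop=True))
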