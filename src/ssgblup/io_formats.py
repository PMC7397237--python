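"""Readers and writers for the BLUPF90-dialect whitespace text files.

All files handled here are plain ASCII, whitespace-delimited, with a "."
decimal point. The dialect is deliberately forgiving about alignment: the
first token on a line is always an ID, and fields are split on any run of
whitespace. The one exception is the genotype file, where the second token
is a single contiguous digit string (one digit per SNP).

Writer/reader pairs are inverses on valid data; readers reject files that
violate the dialect with line-numbered errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "RawPedigree",
    "SolutionsFile",
    "read_pedigree_file",
    "write_pedigree_file",
    "read_phenotype_file",
    "write_phenotype_file",
    "read_snp_file",
    "write_snp_file",
    "read_map_file",
    "write_map_file",
    "read_solutions",
    "write_solutions",
    "write_snp_results",
    "read_snp_results",
    "read_triplets",
    "write_triplets",
]

SOLUTIONS_HEADER = "trait/effect level  solution"

#: sentinel digit for a missing genotype call in SNP files
MISSING_GENOTYPE = 5


class FormatError(ValueError):
    """A file violated the expected text dialect."""


@dataclass
class RawPedigree:
    """Pedigree file content as written: one (animal, sire, dam) per line.

    Tokens are kept verbatim: "0" means unknown parent, a negative integer
    token is an unknown-parent-group code, anything else is an animal ID.
    """

    records: list[tuple[str, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SolutionsFile:
    """Parsed solutions file: rows of (trait, effect, level, solution)."""

    rows: list[tuple[int, int, int, float]]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["trait", "effect", "level", "solution"])

    def effect(self, effect: int, trait: int = 1) -> np.ndarray:
        """Solutions of one effect ordered by level (levels must be 1..k)."""
        sel = sorted(
            (r for r in self.rows if r[0] == trait and r[1] == effect),
            key=lambda r: r[2],
        )
        levels = [r[2] for r in sel]
        if levels != list(range(1, len(sel) + 1)):
            raise FormatError(
                f"levels of effect {effect} are not contiguous from 1: {levels[:10]}..."
            )
        return np.array([r[3] for r in sel])


def _is_upg_token(tok: str) -> bool:
    try:
        return int(tok) < 0
    except ValueError:
        return False


def read_pedigree_file(path) -> RawPedigree:
    """Read a 3+ column pedigree file (animal, sire, dam; 0 = unknown parent,
    negative integers = unknown-parent-group codes). Extra columns ignored.
    """
    records: list[tuple[str, str, str]] = []
    seen: set[str] = set()
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 columns, got {len(toks)}"
                )
            animal, sire, dam = toks[0], toks[1], toks[2]
            if animal in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate animal id {animal!r}")
            seen.add(animal)
            records.append((animal, sire, dam))
    return RawPedigree(records)


def write_pedigree_file(ped: RawPedigree, path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for animal, sire, dam in ped.records:
            fh.write(f"{animal} {sire} {dam}\n")


def read_phenotype_file(path, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a free-column whitespace phenotype table.

    All columns come back as strings; the model layer casts the trait column
    to float. If ``columns`` is given it must match the file's column count.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    ncol = df.shape[1]
    counts = df.notna().sum(axis=1)
    bad = counts[counts != ncol]
    if len(bad):
        raise FormatError(
            f"{path}: line {bad.index[0] + 1}: ragged row "
            f"({int(bad.iloc[0])} columns, expected {ncol})"
        )
    if columns is not None:
        if len(columns) != ncol:
            raise FormatError(
                f"{path}: {ncol} columns in file, {len(columns)} names given"
            )
        df.columns = list(columns)
    return df


def write_phenotype_file(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=" ", header=False, index=False)


def read_map_file(path) -> pd.DataFrame:
    """SNP map: snp_id, chromosome, position (bp)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: map needs 3 columns (id, chromosome, position)")
    out = pd.DataFrame(
        {
            "snp_id": df[0].astype(str),
            "chromosome": df[1].astype(int),
            "position": df[2].astype(np.int64),
        }
    )
    return out


def write_map_file(snp_map: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="ascii") as fh:
        for row in snp_map.itertuples(index=False):
            fh.write(f"{row.snp_id} {row.chromosome} {row.position}\n")


def read_snp_file(path, map_path=None):
    """Read a genotype file: per line an animal ID and one contiguous digit
    string of 0/1/2 allele counts with 5 = missing. Returns a GenotypeSet.
    """
    from .grm import GenotypeSet  # local import: grm depends on io for writing

    ids: list[str] = []
    rows: list[np.ndarray] = []
    width = None
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'id genotypes', got {len(toks)} tokens"
                )
            animal, geno = toks
            codes = np.frombuffer(geno.encode("ascii"), dtype=np.uint8) - ord("0")
            bad = ~np.isin(codes, (0, 1, 2, MISSING_GENOTYPE))
            if bad.any():
                j = int(np.argmax(bad))
                raise FormatError(
                    f"{path}: line {lineno}: animal {animal}: genotype digit "
                    f"{geno[j]!r} at SNP {j + 1} not in {{0,1,2,5}}"
                )
            if width is None:
                width = codes.size
            elif codes.size != width:
                raise FormatError(
                    f"{path}: line {lineno}: animal {animal}: genotype string length "
                    f"{codes.size} differs from {width}"
                )
            ids.append(animal)
            rows.append(codes)
    if not rows:
        raise FormatError(f"{path}: no genotype records")
    M = np.array(rows, dtype=float)
    M[M == MISSING_GENOTYPE] = np.nan
    snp_map = read_map_file(map_path) if map_path is not None else None
    if snp_map is not None and len(snp_map) != M.shape[1]:
        raise FormatError(
            f"{map_path}: {len(snp_map)} map entries for {M.shape[1]} SNPs"
        )
    return GenotypeSet(ids=ids, M=M, snp_map=snp_map)


def write_snp_file(gset, path, map_path=None) -> None:
    lut = np.array([str(d) for d in range(10)])
    with open(path, "w", encoding="ascii") as fh:
        for i, animal in enumerate(gset.ids):
            row = gset.M[i]
            codes = np.where(np.isnan(row), MISSING_GENOTYPE, row).astype(int)
            fh.write(f"{animal} {''.join(lut[codes])}\n")
    if map_path is not None:
        if gset.snp_map is None:
            raise FormatError("genotype set has no map to write")
        write_map_file(gset.snp_map, map_path)


def write_solutions(solutions, path) -> None:
    """Write (trait, effect, level, value) rows under the standard header,
    values with 8 decimals. ``solutions`` is an iterable of such rows or a
    SolutionsFile. Levels of each effect must be contiguous from 1.
    """
    rows = solutions.rows if isinstance(solutions, SolutionsFile) else list(solutions)
    per_effect: dict[tuple[int, int], list[int]] = {}
    for trait, effect, level, _ in rows:
        per_effect.setdefault((trait, effect), []).append(level)
    for (trait, effect), levels in per_effect.items():
        if sorted(levels) != list(range(1, len(levels) + 1)):
            raise FormatError(
                f"trait {trait} effect {effect}: levels not contiguous from 1"
            )
    with open(path, "w", encoding="ascii") as fh:
        fh.write(SOLUTIONS_HEADER + "\n")
        for trait, effect, level, value in rows:
            fh.write(f"{trait:4d}{effect:4d}{level:8d}  {value:16.8f}\n")


def read_solutions(path) -> SolutionsFile:
    rows: list[tuple[int, int, int, float]] = []
    with open(path, "r", encoding="ascii") as fh:
        header = fh.readline()
        if header.strip() != SOLUTIONS_HEADER:
            raise FormatError(f"{path}: unexpected header {header.strip()!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 fields")
            rows.append((int(toks[0]), int(toks[1]), int(toks[2]), float(toks[3])))
    return SolutionsFile(rows)


# snp_sol column layout (9 fields): trait, effect, SNP index, chromosome,
# position, SNP effect, SNP variance (weight), window variance share,
# variance of the SNP solution (PEV). Optional fields are written as 0.
SNP_SOL_COLUMNS = [
    "trait",
    "effect",
    "snp",
    "chromosome",
    "position",
    "effect_estimate",
    "weight",
    "window_share",
    "pev",
]


def write_snp_results(results, path, trait: int = 1, effect: int = 2) -> None:
    """Write the per-SNP results table (snp_sol layout, 9 columns)."""
    m = len(results.effects)
    if results.snp_map is None:
        raise FormatError("SNP map required to write chromosome/position columns")
    chrom = results.snp_map["chromosome"].to_numpy()
    pos = results.snp_map["position"].to_numpy()
    window = results.window_share
    if window is None:
        window = results.variance_share
    pev = results.pev if results.pev is not None else np.zeros(m)
    with open(path, "w", encoding="ascii") as fh:
        for i in range(m):
            fh.write(
                f"{trait} {effect} {i + 1} {chrom[i]} {pos[i]} "
                f"{results.effects[i]:.10g} {results.weights[i]:.10g} "
                f"{window[i]:.10g} {pev[i]:.10g}\n"
            )


def read_snp_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, names=SNP_SOL_COLUMNS)
    if df.shape[1] != 9:
        raise FormatError(f"{path}: expected 9 columns in snp_sol file")
    return df


def read_triplets(path, order: int | None = None):
    """Read a symmetric sparse matrix stored as 'row col value' text
    (upper or lower triangle, renumbered 1-based IDs), as used for
    user-supplied covariance structures (saved H inverses).
    """
    import scipy.sparse as sp

    rows, cols, vals = [], [], []
    with open(path, "r", encoding="ascii") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            toks = line.split()
            if len(toks) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 'row col value'")
            rows.append(int(toks[0]) - 1)
            cols.append(int(toks[1]) - 1)
            vals.append(float(toks[2]))
    n = order if order is not None else max(max(rows), max(cols)) + 1
    upper = sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    dup = upper.copy()
    dup.sum_duplicates()
    if np.any(dup.row == dup.col):
        off = dup.copy()
        mask = off.row != off.col
        sym = sp.coo_matrix(
            (np.concatenate([dup.data, off.data[mask]]),
             (np.concatenate([dup.row, off.col[mask]]),
              np.concatenate([dup.col, off.row[mask]]))),
            shape=(n, n),
        )
    else:
        sym = dup + dup.T
    return sym.tocsr()


def write_triplets(mat, path) -> None:
    """Write the diagonal and upper triangle of a symmetric sparse/dense
    matrix as 'row col value' text with 1-based indices."""
    import scipy.sparse as sp

    coo = sp.coo_matrix(mat)
    with open(path, "w", encoding="ascii") as fh:
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if j >= i and v != 0.0:
                fh.write(f"{i + 1} {j + 1} {v:.12g}\n")
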