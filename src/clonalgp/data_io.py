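"""Genotype and phenotype I/O with marker/clone quality control.

Genotypes are biallelic pseudo-diploid SNP calls coded 0 (homozygous
reference), 1 (heterozygous) and 2 (homozygous alternate), with -1 as the
missing sentinel.  Phenotypes are spatially adjusted clone values, one record
per clone x year x crop x region x trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

CROP_LEVELS = ("plant", "ratoon1", "ratoon2")

PHENOTYPE_KEY = ["clone", "year", "crop", "region", "trial"]


@dataclass
class GenotypeMatrix:
    """Clone x SNP genotype codes plus per-locus genotype frequencies.

    ``codes`` is an integer matrix over {0, 1, 2, MISSING}.  ``genotype_freqs``
    holds per-locus triples (p_AA, p_Aa, p_aa) computed over non-missing calls;
    these frequencies are the substrate of the orthogonal (NOIA) marker coding,
    which makes no Hardy-Weinberg assumption.
    """

    clone_ids: list[str]
    snp_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.clone_ids), len(self.snp_ids)):
            raise ValueError("codes shape does not match id lists")
        if len(set(self.clone_ids)) != len(self.clone_ids):
            raise ValueError("duplicate clone ids")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} at clone "
                f"{self.clone_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_clones(self) -> int:
        return len(self.clone_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def genotype_freqs(self) -> np.ndarray:
        """Per-locus (p_AA, p_Aa, p_aa) over non-missing calls, shape (p, 3)."""
        obs = self.codes != MISSING
        n_obs = obs.sum(axis=0).astype(float)
        freqs = np.empty((self.n_snps, 3))
        for g in (0, 1, 2):
            freqs[:, g] = ((self.codes == g) & obs).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs /= n_obs[:, None]
        freqs[n_obs == 0] = np.nan
        return freqs

    def allele_freqs(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference (p) and alternate (q) allele frequencies per locus."""
        f = self.genotype_freqs
        p = f[:, 0] + 0.5 * f[:, 1]
        return p, 1.0 - p

    def imputed(self) -> np.ndarray:
        """Real-valued codes with missing cells replaced by the locus mean."""
        x = self.codes.astype(float)
        miss = self.codes == MISSING
        if miss.any():
            x[miss] = np.nan
            col_mean = np.nanmean(np.where(miss, np.nan, x), axis=0)
            col_mean = np.nan_to_num(col_mean, nan=0.0)
            idx = np.where(miss)
            x[idx] = col_mean[idx[1]]
        return x


@dataclass
class QcReport:
    """Record of SNPs and clones removed during quality control."""

    n_snps_in: int
    n_snps_out: int
    n_clones_in: int
    n_clones_out: int
    dropped_snps: list[tuple[str, str]] = field(default_factory=list)
    dropped_clones: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_snps_out == self.n_snps_in - len(self.dropped_snps)
        assert self.n_clones_out == self.n_clones_in - len(self.dropped_clones)

    def to_frame(self) -> pd.DataFrame:
        rows = [("snp", i, r) for i, r in self.dropped_snps]
        rows += [("clone", i, r) for i, r in self.dropped_clones]
        return pd.DataFrame(rows, columns=["axis", "id", "reason"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, format: str = "matrix_tsv") -> GenotypeMatrix:
    """Read genotypes from a VCF or a clone x SNP matrix file.

    VCF GT fields are mapped 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 and ./. to
    missing.  The matrix dialect is tab-separated with clone IDs in the first
    column, SNP IDs in the header, and cells in {0, 1, 2, NA}.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix_tsv":
        return _read_matrix_tsv(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    clone_ids = list(vcf.samples)
    snp_ids: list[str] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} "
                f"(ALT={','.join(rec.ALT)}); split or filter it first"
            )
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = rec.gt_types.copy()
        col = np.full(gt.shape, MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        snp_ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        columns.append(col)
    codes = np.column_stack(columns) if columns else np.empty((len(clone_ids), 0), dtype=np.int8)
    return GenotypeMatrix(clone_ids, snp_ids, codes)


def _read_matrix_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    snp_ids = [str(c) for c in df.columns]
    clone_ids = [str(i) for i in df.index]
    codes = np.full(df.shape, MISSING, dtype=np.int8)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING}
    values = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = values[i, j].strip()
            if cell not in valid:
                raise ValueError(
                    f"unknown genotype code {cell!r} at clone {clone_ids[i]!r}, "
                    f"SNP {snp_ids[j]!r}"
                )
            codes[i, j] = valid[cell]
    return GenotypeMatrix(clone_ids, snp_ids, codes)


def write_genotypes(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the matrix_tsv dialect; round-trips exactly with read_genotypes."""
    cells = np.where(g.codes == MISSING, "NA", g.codes.astype(str))
    df = pd.DataFrame(cells, index=g.clone_ids, columns=g.snp_ids)
    df.index.name = "clone"
    df.to_csv(path, sep="\t")


def apply_qc(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    locus_call_min: float = 0.90,
    clone_call_min: float = 0.90,
) -> tuple[GenotypeMatrix, QcReport]:
    """Marker and clone quality control.

    Clones with call rate below ``clone_call_min`` are removed first; locus
    filters (call rate, alternate-allele frequency) are then computed on the
    retained clones.  The frequency filter uses the alternate-allele frequency
    itself, not the folded minor-allele frequency, so an all-reference locus is
    removed while an all-alternate locus is kept.  Remaining missing calls are
    left in place; kernel construction imputes them to the locus mean.
    """
    for name, t in (("maf_min", maf_min), ("locus_call_min", locus_call_min),
                    ("clone_call_min", clone_call_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")

    obs = g.codes != MISSING
    clone_rate = obs.mean(axis=1) if g.n_snps else np.ones(g.n_clones)
    keep_clone = clone_rate >= clone_call_min
    dropped_clones = [
        (g.clone_ids[i], "low_call_rate") for i in np.where(~keep_clone)[0]
    ]

    codes = g.codes[keep_clone]
    obs = codes != MISSING
    n_kept = keep_clone.sum()
    dropped_snps: list[tuple[str, str]] = []
    keep_snp = np.ones(g.n_snps, dtype=bool)
    for j in range(g.n_snps):
        col = codes[:, j]
        o = obs[:, j]
        rate = o.mean() if n_kept else 0.0
        if rate < locus_call_min:
            keep_snp[j] = False
            dropped_snps.append((g.snp_ids[j], "low_call_rate"))
            continue
        called = col[o]
        q_alt = called.mean() / 2.0 if called.size else 0.0
        if q_alt < maf_min:
            reason = "monomorphic" if (called.size and (called == called[0]).all()) else "low_maf"
            keep_snp[j] = False
            dropped_snps.append((g.snp_ids[j], reason))

    if not keep_snp.any():
        raise ValueError("empty genotype matrix after QC")

    out = GenotypeMatrix(
        [c for c, k in zip(g.clone_ids, keep_clone) if k],
        [s for s, k in zip(g.snp_ids, keep_snp) if k],
        codes[:, keep_snp],
    )
    report = QcReport(
        n_snps_in=g.n_snps,
        n_snps_out=out.n_snps,
        n_clones_in=g.n_clones,
        n_clones_out=out.n_clones,
        dropped_snps=dropped_snps,
        dropped_clones=dropped_clones,
    )
    logger.info(
        "QC: %d/%d SNPs and %d/%d clones retained",
        report.n_snps_out, report.n_snps_in,
        report.n_clones_out, report.n_clones_in,
    )
    return out, report


def read_phenotypes(path: str | Path, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Read the adjusted-phenotype table (CSV).

    Requires columns clone, year, crop, region, trial plus one column per
    trait.  Rows with an empty trait cell are retained (the value is NaN) and
    excluded per-trait downstream.  Duplicate (clone, year, crop, region,
    trial) keys are an error.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in PHENOTYPE_KEY if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file missing required column(s): {missing_cols}")
    trait_cols = traits if traits is not None else [
        c for c in df.columns if c not in PHENOTYPE_KEY
    ]
    if not trait_cols:
        raise ValueError("phenotype file has no trait columns")
    df = df.astype({"clone": str, "region": str, "trial": str, "crop": str})
    df["year"] = df["year"].astype(int)
    dup = df.duplicated(PHENOTYPE_KEY, keep=False)
    if dup.any():
        key = tuple(df.loc[dup.idxmax(), PHENOTYPE_KEY])
        raise ValueError(f"duplicate phenotype key {key}")
    for t in trait_cols:
        df[t] = pd.to_numeric(df[t], errors="coerce")
    return df


def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
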