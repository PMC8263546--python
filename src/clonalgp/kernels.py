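"""Genomic relationship matrices from orthogonal (NOIA) marker coding.

The additive and dominance incidence matrices are built from observed
per-locus genotype frequencies rather than Hardy-Weinberg expectations, which
orthogonalises additive and dominance effects in populations out of HWE.
Epistatic kernels are Hadamard products of the first-order kernels; all
relationship matrices are standardised so their diagonal averages one.  A
Gaussian kernel over raw 0/1/2 codes supports RKHS regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: relative eigenvalue tolerance below which a kernel is considered indefinite
PSD_RTOL = 1e-8
#: diagonal jitter applied when a kernel fails the PSD check
PSD_JITTER = 1e-6


@dataclass
class IncidenceMatrix:
    """Per-clone, per-locus orthogonal coefficients (additive or dominance)."""

    kind: str  # "additive" | "dominance"
    values: np.ndarray  # n_clones x n_snps, real
    source_freqs: np.ndarray  # n_snps x 3 (p_AA, p_Aa, p_aa)
    degenerate: np.ndarray  # bool per locus: column forced to zero


@dataclass
class KernelMatrix:
    """Named symmetric clone x clone covariance matrix."""

    name: str
    values: np.ndarray
    clone_ids: list[str]
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.clone_ids)
        if self.values.shape != (n, n):
            raise ValueError("kernel shape does not match clone ids")

    @property
    def n(self) -> int:
        return len(self.clone_ids)

    def ensure_psd(self) -> "KernelMatrix":
        """Add diagonal jitter if the smallest eigenvalue is materially negative."""
        w = np.linalg.eigvalsh(self.values)
        if w[0] < -PSD_RTOL * max(w[-1], 1.0):
            logger.warning(
                "kernel %s has smallest eigenvalue %.3g; adding %.0e jitter",
                self.name, w[0], PSD_JITTER,
            )
            self.values = self.values + PSD_JITTER * np.eye(self.n)
        return self


@dataclass
class HetVector:
    """Average genome-wide heterozygosity per clone.

    ``values[k]`` is the sum over loci of the clone's dominance coefficient
    divided by the sum of 2 p_l q_l (allele frequencies), so a clone
    heterozygous everywhere in an HWE population scores exactly 1.
    """

    values: np.ndarray
    clone_ids: list[str]
    normalizer: float

    def centered(self) -> np.ndarray:
        return self.values - self.values.mean()


def noia_additive_coeffs(freqs: np.ndarray) -> np.ndarray:
    """Orthogonal additive coefficients (h_AA, h_Aa, h_aa) per locus.

    With genotype frequencies (p_AA, p_Aa, p_aa):
    h_AA = p_Aa + 2 p_aa, h_Aa = p_Aa + 2 p_aa - 1, h_aa = p_Aa + 2 p_aa - 2,
    which centres each column under the observed genotype frequencies.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    base = freqs[:, 1] + 2.0 * freqs[:, 2]
    return np.column_stack([base, base - 1.0, base - 2.0])


def noia_dominance_coeffs(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal dominance coefficients per locus, plus a degeneracy flag.

    With D = p_AA + p_aa - (p_AA - p_aa)^2 the coefficients are
    (-2 p_Aa p_aa / D, 4 p_AA p_aa / D, -2 p_AA p_Aa / D).  Loci with D = 0
    (no homozygotes, or monomorphic) get a zero column and are flagged.
    """
    freqs = np.atleast_2d(np.asarray(freqs, dtype=float))
    p_AA, p_Aa, p_aa = freqs[:, 0], freqs[:, 1], freqs[:, 2]
    denom = p_AA + p_aa - (p_AA - p_aa) ** 2
    degenerate = np.isclose(denom, 0.0, atol=1e-12) | (p_Aa <= 0) | np.isnan(denom)
    safe = np.where(degenerate, 1.0, denom)
    coeffs = np.column_stack([
        -2.0 * p_Aa * p_aa / safe,
        4.0 * p_AA * p_aa / safe,
        -2.0 * p_AA * p_Aa / safe,
    ])
    coeffs[degenerate] = 0.0
    return coeffs, degenerate


def incidence_matrix(g: GenotypeMatrix, kind: str) -> IncidenceMatrix:
    """Map genotype codes through the per-locus orthogonal coefficients.

    Missing calls receive the frequency-weighted expected coefficient, which
    is exactly zero, so every column stays centred under the observed
    genotype frequencies.  (For the additive coding this coincides with
    imputing the locus-mean code, since the coefficient is linear in the
    code and centred.)
    """
    freqs = g.genotype_freqs
    if kind == "additive":
        coeffs = noia_additive_coeffs(np.nan_to_num(freqs, nan=1 / 3))
        degenerate = (freqs[:, 0] >= 1.0) | (freqs[:, 2] >= 1.0) | np.isnan(freqs[:, 0])
    elif kind == "dominance":
        coeffs, degenerate = noia_dominance_coeffs(freqs)
    else:
        raise ValueError(f"unknown incidence kind {kind!r}")

    codes = np.clip(g.codes, 0, 2).astype(int)  # missing -> index 0, masked below
    cols = np.arange(g.n_snps)
    h = coeffs[cols[None, :], codes]
    h[g.codes == MISSING] = 0.0
    h[:, degenerate] = 0.0
    return IncidenceMatrix(kind=kind, values=h, source_freqs=freqs, degenerate=degenerate)


def build_grm(H: IncidenceMatrix, clone_ids: list[str], name: str | None = None) -> KernelMatrix:
    """Relationship matrix G = H H' / (tr(H H') / n)."""
    values = np.asarray(H.values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two clones")
    hh = values @ values.T
    scale = np.trace(hh) / values.shape[0]
    if scale <= 0:
        raise ValueError("degenerate incidence matrix (all-zero columns)")
    if name is None:
        name = "G_A" if H.kind == "additive" else "G_D"
    return KernelMatrix(name=name, values=hh / scale, clone_ids=list(clone_ids))


def hadamard_kernel(ga: KernelMatrix, gb: KernelMatrix, name: str | None = None) -> KernelMatrix:
    """Epistatic kernel: elementwise product rescaled to mean diagonal one."""
    if ga.clone_ids != gb.clone_ids:
        raise ValueError("kernels have mismatched clone order")
    prod = ga.values * gb.values
    scale = np.trace(prod) / ga.n
    if scale <= 0:
        raise ValueError("degenerate Hadamard product")
    if name is None:
        name = f"{ga.name}x{gb.name}"
    return KernelMatrix(name=name, values=prod / scale, clone_ids=list(ga.clone_ids))


def heterozygosity(g: GenotypeMatrix, hd: IncidenceMatrix | None = None) -> HetVector:
    """Average genome-wide heterozygosity Het_k = sum_l h_kl / sum_l 2 p_l q_l.

    h_kl are dominance-incidence entries; p_l, q_l the reference/alternate
    allele frequencies.  Degenerate (zero-column) loci are excluded from the
    normaliser so they contribute nothing to either side of the ratio.
    """
    if hd is None:
        hd = incidence_matrix(g, "dominance")
    if hd.kind != "dominance":
        raise ValueError("heterozygosity requires the dominance incidence matrix")
    p, q = g.allele_freqs()
    ok = ~hd.degenerate
    normalizer = float(np.sum(2.0 * p[ok] * q[ok]))
    if normalizer <= 0:
        raise ValueError("all loci monomorphic: heterozygosity undefined")
    values = hd.values.sum(axis=1) / normalizer
    return HetVector(values=values, clone_ids=list(g.clone_ids), normalizer=normalizer)


def gaussian_kernel(g: GenotypeMatrix, h: float) -> KernelMatrix:
    """Gaussian kernel K_ij = exp(-h * ||x_i - x_j||^2 / p) on raw 0/1/2 codes.

    Distances use locus-mean-imputed codes; ``h`` is the bandwidth (h = 0
    yields the all-ones kernel).
    """
    if h < 0:
        raise ValueError("bandwidth must be non-negative")
    x = g.imputed()
    sq = np.sum(x**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (x @ x.T)
    np.maximum(d2, 0.0, out=d2)
    np.fill_diagonal(d2, 0.0)
    values = np.exp(-h * d2 / g.n_snps)
    return KernelMatrix(name="K_gauss", values=values, clone_ids=list(g.clone_ids), bandwidth=h)


def standard_kernel_set(
    g: GenotypeMatrix,
    which: tuple[str, ...] = ("G_A", "G_D", "G_AA"),
) -> dict[str, KernelMatrix]:
    """Build the named relationship matrices used by the nested GBLUP models."""
    ha = incidence_matrix(g, "additive")
    hd = incidence_matrix(g, "dominance")
    out: dict[str, KernelMatrix] = {}
    ga = build_grm(ha, g.clone_ids, "G_A")
    gd = build_grm(hd, g.clone_ids, "G_D")
    available = {
        "G_A": lambda: ga,
        "G_D": lambda: gd,
        "G_AA": lambda: hadamard_kernel(ga, ga, "G_AA"),
        "G_AD": lambda: hadamard_kernel(ga, gd, "G_AD"),
        "G_DD": lambda: hadamard_kernel(gd, gd, "G_DD"),
    }
    for name in which:
        if name not in available:
            raise ValueError(f"unknown kernel {name!r}")
        out[name] = available[name]().ensure_psd()
    return out


def write_kernel(k: KernelMatrix, path: str | Path) -> None:
    """Full symmetric matrix with a clone-ID header row and column."""
    df = pd.DataFrame(k.values, index=k.clone_ids, columns=k.clone_ids)
    df.index.name = "clone"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_kernel(path: str | Path, name: str | None = None) -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = [str(i) for i in df.index]
    if [str(c) for c in df.columns] != ids:
        raise ValueError("kernel file row/column clone ids disagree")
    if name is None:
        name = Path(path).stem
    return KernelMatrix(name=name, values=df.to_numpy(float), clone_ids=ids)
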