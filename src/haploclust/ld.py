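"""Pairwise linkage-disequilibrium matrices, 1 - r² distances and LD decay.

The default r² estimator runs a two-locus EM over haplotype frequencies for
every variant pair simultaneously: only double-heterozygous genotypes are
phase-ambiguous, so the E-step reduces to a scalar coupling probability per
pair and the whole update vectorizes over the m x m pair grid.  A squared
Pearson correlation of dosages is available as a fast alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import MISSING, GenotypeDataset


@dataclass
class LDMatrix:
    """Symmetric r² matrix tied to an ordered variant table."""

    variants: pd.DataFrame
    r2: np.ndarray
    estimator: str
    monomorphic: np.ndarray = None  # bool flag per variant

    def __post_init__(self):
        m = len(self.variants)
        if self.r2.shape != (m, m):
            raise ValueError("r2 matrix does not match variant index")
        if self.monomorphic is None:
            self.monomorphic = np.zeros(m, dtype=bool)


def _pair_genotype_counts(d: np.ndarray):
    """Joint genotype count matrices for all variant pairs.

    Returns (c22, c21, c11, n2, n1, n) where ``cgh[i, j]`` counts samples with
    dosage g at variant i and h at variant j; the remaining cells of the 3x3
    joint table follow from the margins.
    """
    i2 = (d == 2).astype(np.float32)
    i1 = (d == 1).astype(np.float32)
    c22 = i2.T @ i2
    c21 = i2.T @ i1
    c11 = i1.T @ i1
    n2 = i2.sum(axis=0)
    n1 = i1.sum(axis=0)
    return c22, c21, c11, n2, n1, np.float32(d.shape[0])


def _em_r2(d: np.ndarray, tol: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """r² for all pairs via two-locus EM haplotype-frequency estimation.

    Runs in float32 over the full pair grid; haplotype frequencies converge
    well below the r² resolution that clustering consumes.
    """
    c22, c21, c11, n2, n1, n = _pair_genotype_counts(d)
    c12 = c21.T
    # unambiguous haplotype contributions (A = a1 at row variant, B = a1 at col variant)
    row2 = n2[:, None]
    row1 = n1[:, None]
    col2 = n2[None, :]
    col1 = n1[None, :]
    c20 = row2 - c22 - c21
    c10 = row1 - c11 - c12
    c02 = col2 - c22 - c12
    c01 = col1 - c21 - c11
    nAB = 2 * c22 + c21 + c12
    nAb = 2 * c20 + c21 + c10
    naB = 2 * c02 + c12 + c01
    nab = 2 * (n - row2 - row1 - c02 - c01) + c10 + c01  # c00 = n - everything else
    ndh = c11
    tot = 2.0 * n

    pA = ((n2 + 0.5 * n1) / n).astype(np.float32)  # a1 allele frequency
    pAB = pA[:, None] * pA[None, :]
    pAb = pA[:, None] * (1 - pA)[None, :]
    paB = (1 - pA)[:, None] * pA[None, :]
    pab = (1 - pA)[:, None] * (1 - pA)[None, :]
    for _ in range(max_iter):
        num = pAB * pab
        den = num + pAb * paB
        w = np.divide(num, den, out=np.full_like(num, np.float32(0.5)),
                      where=den > 0)
        new_pAB = (nAB + ndh * w) / tot
        delta = np.abs(new_pAB - pAB).max()
        pAB = new_pAB
        pAb = (nAb + ndh * (1 - w)) / tot
        paB = (naB + ndh * (1 - w)) / tot
        pab = (nab + ndh * w) / tot
        if delta < tol:
            break
    pArow = pA[:, None].astype(np.float64)
    pAcol = pA[None, :].astype(np.float64)
    D = pAB.astype(np.float64) - pArow * pAcol
    denom = pArow * (1 - pArow) * pAcol * (1 - pAcol)
    r2 = np.divide(D * D, denom, out=np.zeros_like(D), where=denom > 1e-300)
    return np.clip(r2, 0.0, 1.0)


def _dosage_corr_r2(d: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation of dosage vectors."""
    x = d.astype(np.float64)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    cov = (x.T @ x) / x.shape[0]
    denom = np.outer(sd, sd)
    r = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 1e-300)
    return np.clip(r * r, 0.0, 1.0)


def ld_matrix(ds: GenotypeDataset, estimator: str = "em") -> LDMatrix:
    """Full pairwise r² matrix for one genomic partition.

    ``estimator`` is ``"em"`` (two-locus EM haplotype frequencies, the
    default, matching what ``plink --r2 square`` computes) or
    ``"dosage_corr"`` (squared dosage correlation).  Genotypes must be
    complete — impute first.  Monomorphic variants get off-diagonal r² = 0
    and are flagged in ``monomorphic``.
    """
    if ds.n_variants < 2:
        raise ValueError("LD matrix needs at least two variants")
    if (ds.dosages == MISSING).any():
        raise ValueError("missing genotypes present: run impute_missing first")
    if estimator == "em":
        r2 = _em_r2(ds.dosages)
    elif estimator == "dosage_corr":
        r2 = _dosage_corr_r2(ds.dosages)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    mono = ds.dosages.std(axis=0) == 0
    r2[mono, :] = 0.0
    r2[:, mono] = 0.0
    r2 = (r2 + r2.T) / 2.0
    np.fill_diagonal(r2, np.where(mono, 0.0, 1.0))
    return LDMatrix(ds.variants.copy(), r2, estimator, mono)


def haplotype_r2(haplotypes: np.ndarray) -> np.ndarray:
    """r² from phased haplotypes (exact D²/(pq·pq) via allele correlation)."""
    h = haplotypes.astype(np.float64)
    h -= h.mean(axis=0)
    sd = h.std(axis=0)
    cov = (h.T @ h) / h.shape[0]
    denom = np.outer(sd, sd)
    r = np.divide(cov, denom, out=np.zeros_like(cov), where=denom > 1e-300)
    r2 = np.clip(r * r, 0.0, 1.0)
    np.fill_diagonal(r2, np.where(sd > 0, 1.0, 0.0))
    return r2


def distance_matrix(ldm: LDMatrix) -> np.ndarray:
    """The 1 - r² distance transform; zero diagonal."""
    d = 1.0 - ldm.r2
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 1.0)


@dataclass
class LDDecayProfile:
    """Median r² per bp-separation bin."""

    bin_edges: np.ndarray  # len nbins+1
    median_r2: np.ndarray  # len nbins, NaN where empty
    n_pairs: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1], "bin_end": self.bin_edges[1:],
            "median_r2": self.median_r2, "n_pairs": self.n_pairs,
        })


def ld_decay(source, bin_width: int = 5000, max_dist: int | None = None,
             estimator: str = "dosage_corr") -> LDDecayProfile:
    """LD decay: median r² of variant pairs binned by bp separation.

    ``source`` is a GenotypeDataset (r² computed with ``estimator``), an
    LDMatrix, or a ``(positions, r2_matrix)`` pair.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if isinstance(source, GenotypeDataset):
        ldm = ld_matrix(source, estimator=estimator)
        pos, r2 = ldm.variants["pos"].to_numpy(), ldm.r2
    elif isinstance(source, LDMatrix):
        pos, r2 = source.variants["pos"].to_numpy(), source.r2
    else:
        pos, r2 = source
        pos = np.asarray(pos)
    iu, ju = np.triu_indices(len(pos), k=1)
    sep = np.abs(pos[ju] - pos[iu])
    vals = r2[iu, ju]
    if max_dist is not None:
        keep = sep <= max_dist
        sep, vals = sep[keep], vals[keep]
    top = int(sep.max()) + 1 if len(sep) else bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    idx = np.digitize(sep, edges) - 1
    nbins = len(edges) - 1
    med = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            med[b] = np.median(vals[sel])
    return LDDecayProfile(edges, med, counts)


def export_square(ldm: LDMatrix, path) -> None:
    """Write the r² matrix as a PLINK-compatible tab-separated square text matrix."""
    np.savetxt(path, ldm.r2, delimiter="\t", fmt="%.6g")
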