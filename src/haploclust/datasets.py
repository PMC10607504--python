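"""Genotype containers, PLINK/VCF input-output, and quality-control filters.

The central object is :class:`GenotypeDataset`: a samples x variants matrix of
minor-allele dosages ({0,1,2}, -1 for missing) together with variant metadata
and case/control phenotype labels.  All downstream stages (single-variant
tests, LD matrices, clustering, haplotype association) operate on it.

Coordinates are 1-based and inclusive throughout, matching PLINK ``.bim``
files.  The counted allele ``a1`` follows the PLINK convention (usually the
minor allele); dosages count copies of ``a1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1
CASE = 1
CONTROL = 0
UNKNOWN = -9

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]

# PLINK 2-bit codes (SNP-major): 0b00 hom a1, 0b01 missing, 0b10 het, 0b11 hom a2
_PLINK_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _chrom_sort_key(chrom: str):
    s = str(chrom)
    return (0, int(s), "") if s.isdigit() else (1, 0, s)


@dataclass
class Region:
    """A 1-based, both-ends-inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"Region start {self.start} > end {self.end}")

    @property
    def span(self) -> int:
        """Length reported as end - start (the bp distance between boundary markers)."""
        return self.end - self.start


@dataclass
class GenotypeDataset:
    """Unphased diploid genotypes with case/control labels.

    Parameters
    ----------
    variants : pandas.DataFrame
        Columns ``id, chrom, pos, a1, a2``; sorted by (chrom, pos).
    samples : list of str
        Sample identifiers, one per dosage row.
    dosages : ndarray of int8, shape (n_samples, n_variants)
        Counts of allele ``a1`` per call; ``-1`` marks a missing genotype.
    phenotype : ndarray of int8, shape (n_samples,)
        ``1`` case, ``0`` control, ``-9`` unknown.
    """

    variants: pd.DataFrame
    samples: list
    dosages: np.ndarray
    phenotype: np.ndarray = field(default=None)

    def __post_init__(self):
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.phenotype is None:
            self.phenotype = np.full(len(self.samples), UNKNOWN, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if len(self.phenotype) != len(self.samples):
            raise ValueError("phenotype length does not match sample count")
        bad = ~np.isin(self.dosages, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        self._sort_variants()

    def _sort_variants(self):
        keys = [_chrom_sort_key(c) for c in self.variants["chrom"]]
        order = sorted(range(len(keys)), key=lambda i: (keys[i], self.variants["pos"].iat[i]))
        order = np.asarray(order)
        if not np.array_equal(order, np.arange(len(order))):
            self.variants = self.variants.iloc[order].reset_index(drop=True)
            self.dosages = np.ascontiguousarray(self.dosages[:, order])

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def case_mask(self) -> np.ndarray:
        return self.phenotype == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.phenotype == CONTROL

    def subset(self, variant_mask=None, sample_mask=None) -> "GenotypeDataset":
        vm = np.ones(self.n_variants, bool) if variant_mask is None else np.asarray(variant_mask)
        sm = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        return GenotypeDataset(
            variants=self.variants.loc[vm].reset_index(drop=True),
            samples=[s for s, keep in zip(self.samples, sm) if keep],
            dosages=np.ascontiguousarray(self.dosages[np.ix_(sm, vm)]),
            phenotype=self.phenotype[sm],
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            self.variants.equals(other.variants)
            and list(self.samples) == list(other.samples)
            and np.array_equal(self.dosages, other.dosages)
            and np.array_equal(self.phenotype, other.phenotype)
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary trio
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeDataset:
    """Read a PLINK 1 binary trio (.bed/.bim/.fam) into a GenotypeDataset.

    The .bed payload must be SNP-major (third magic byte 0x01).  Phenotype
    codes 2/1 map to case/control; 0 and -9 map to unknown.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype={"chrom": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype={"iid": str},
    )
    n, m = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise FormatError(f"{bed_path}: not a PLINK .bed file (bad magic bytes)")
    if raw[2] != 0x01:
        raise FormatError(f"{bed_path}: only SNP-major .bed files are supported")
    bytes_per_variant = (n + 3) // 4
    payload = raw[3:]
    if len(payload) != bytes_per_variant * m:
        raise FormatError(
            f"{bed_path}: payload of {len(payload)} bytes inconsistent with "
            f"{n} samples x {m} variants"
        )
    blocks = payload.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for slot in range(4):
        codes[:, slot::4] = (blocks >> (2 * slot)) & 0b11
    dosages = _PLINK_CODE_TO_DOSAGE[codes[:, :n]].T  # samples x variants

    pheno = np.full(n, UNKNOWN, dtype=np.int8)
    pheno[fam["pheno"].to_numpy() == 2] = CASE
    pheno[fam["pheno"].to_numpy() == 1] = CONTROL

    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeDataset(variants, list(fam["iid"]), dosages, pheno)


def write_plink(ds: GenotypeDataset, prefix) -> None:
    """Write a GenotypeDataset as a PLINK 1 SNP-major binary trio."""
    prefix = Path(prefix)
    n, m = ds.n_samples, ds.n_variants

    bim = pd.DataFrame({
        "chrom": ds.variants["chrom"], "id": ds.variants["id"], "cm": 0,
        "pos": ds.variants["pos"], "a1": ds.variants["a1"], "a2": ds.variants["a2"],
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    pheno_codes = np.where(ds.phenotype == CASE, 2, np.where(ds.phenotype == CONTROL, 1, -9))
    fam = pd.DataFrame({
        "fid": ds.samples, "iid": ds.samples, "father": 0, "mother": 0,
        "sex": 0, "pheno": pheno_codes,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    d = ds.dosages.T
    codes[d == 2] = 0b00
    codes[d == MISSING] = 0b01
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11

    bytes_per_variant = (n + 3) // 4
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    blocks = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for slot in range(4):
        blocks |= padded[:, slot::4] << (2 * slot)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(blocks.tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, on_multiallelic: str = "skip") -> GenotypeDataset:
    """Read bi-allelic GT records from a VCF into a GenotypeDataset.

    ALT is taken as the counted allele ``a1``; phase separators are ignored
    (the data are treated as unphased).  ``on_multiallelic`` is ``"skip"`` or
    ``"error"``.
    """
    from cyvcf2 import VCF  # local import: optional dependency

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1:
            if on_multiallelic == "error":
                raise FormatError(f"{vcf_path}: multi-allelic record at {v.CHROM}:{v.POS}")
            continue
        gt = v.gt_types  # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        if gt is None:
            raise FormatError(f"{vcf_path}: record without GT at {v.CHROM}:{v.POS}")
        dos = gt.astype(np.int8)
        dos[dos == 3] = MISSING
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        rows.append({"id": vid, "chrom": str(v.CHROM).removeprefix("chr"),
                     "pos": v.POS, "a1": v.ALT[0], "a2": v.REF})
        dosage_cols.append(dos)
    if not rows:
        raise FormatError(f"{vcf_path}: no usable bi-allelic records")
    variants = pd.DataFrame(rows)
    dosages = np.stack(dosage_cols, axis=1)
    return GenotypeDataset(variants, samples, dosages)


def write_vcf(ds: GenotypeDataset, vcf_path) -> None:
    """Write as a minimal uncompressed VCF 4.2 with unphased GT only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, ds.samples)) + "\n")
        for j, row in ds.variants.iterrows():
            calls = "\t".join(gt_map[int(d)] for d in ds.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.a2}\t{row.a1}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

def filter_missingness(ds: GenotypeDataset, max_variant_missing: float = 0.2,
                       max_sample_missing: float = 0.2) -> GenotypeDataset:
    """Drop variants, then samples, whose missing-call fraction exceeds the threshold."""
    for thr in (max_variant_missing, max_sample_missing):
        if not 0 <= thr <= 1:
            raise ValueError("missingness thresholds must lie in [0, 1]")
    miss = ds.dosages == MISSING
    vkeep = miss.mean(axis=0) <= max_variant_missing
    ds = ds.subset(variant_mask=vkeep)
    miss = ds.dosages == MISSING
    if ds.n_variants:
        skeep = miss.mean(axis=1) <= max_sample_missing
    else:
        skeep = np.ones(ds.n_samples, bool)
    out = ds.subset(sample_mask=skeep)
    if out.n_variants == 0 or out.n_samples == 0:
        warnings.warn("missingness filter removed every variant or sample")
    return out


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg p-value by enumeration of heterozygote counts.

    Enumerates every heterozygote count compatible with the observed allele
    counts, conditional on the genotype total, and sums the probabilities of
    configurations no more likely than the observed one.
    """
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic
    # unnormalized probabilities over het counts of the same parity as n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # log P(het) ∝ -log(het!) - log(((n_rare-het)/2)!) - log(((2n-n_rare-het)/2)!) + het*log(2)
    from scipy.special import gammaln
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1)
            - gammaln((n_rare - hets) / 2 + 1)
            - gammaln((2 * n - n_rare - hets) / 2 + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[hets == n_het][0]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """One-degree-of-freedom chi-square Hardy-Weinberg test."""
    from scipy.stats import chi2 as chi2_dist

    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    p = (2 * n_hom1 + n_het) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_hom1, n_het, n_hom2], dtype=float)
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2_dist.sf(stat, df=1))


def genotype_counts(ds: GenotypeDataset, sample_mask=None) -> np.ndarray:
    """Per-variant genotype counts, shape (n_variants, 3) for dosages (2, 1, 0).

    Column order is (a1a1, a1a2, a2a2); missing calls are not counted.
    """
    d = ds.dosages if sample_mask is None else ds.dosages[sample_mask]
    return np.stack([(d == 2).sum(0), (d == 1).sum(0), (d == 0).sum(0)], axis=1)


def hwe_filter(ds: GenotypeDataset, p_threshold: float = 1e-5,
               method: str = "exact") -> GenotypeDataset:
    """Remove variants failing Hardy-Weinberg equilibrium in the control group."""
    if not ds.control_mask.any():
        raise ValueError("HWE filter requires a non-empty control group")
    counts = genotype_counts(ds, ds.control_mask)
    test = hwe_exact_p if method == "exact" else hwe_chi2_p
    pvals = np.array([test(int(c[0]), int(c[1]), int(c[2])) for c in counts])
    return ds.subset(variant_mask=pvals >= p_threshold)


def exclude_region(ds: GenotypeDataset, region: Region):
    """Drop every variant inside ``region`` (inclusive ends).

    Returns ``(dataset, span)`` where span is the bp length ``end - start``
    of the excluded interval.
    """
    chrom = str(region.chrom).removeprefix("chr")
    inside = (ds.variants["chrom"].astype(str) == chrom) & \
        ds.variants["pos"].between(region.start, region.end)
    return ds.subset(variant_mask=~inside.to_numpy()), region.span


def split_partitions(ds: GenotypeDataset, arm_splits: dict | None = None) -> list:
    """Split into per-chromosome datasets, optionally into p/q arms.

    ``arm_splits`` maps chromosome name to the centromere split coordinate;
    a variant exactly at the split coordinate goes to the short (p) arm.
    Returns a list of ``(partition_name, GenotypeDataset)`` in genome order.
    """
    arm_splits = {str(k): v for k, v in (arm_splits or {}).items()}
    out = []
    chroms = sorted(ds.variants["chrom"].astype(str).unique(), key=_chrom_sort_key)
    for chrom in chroms:
        on = (ds.variants["chrom"].astype(str) == chrom).to_numpy()
        if chrom in arm_splits:
            split = arm_splits[chrom]
            if split is None:
                raise ValueError(f"arm split requested for chr{chrom} without coordinate")
            pos = ds.variants["pos"].to_numpy()
            out.append((f"{chrom}p", ds.subset(variant_mask=on & (pos <= split))))
            out.append((f"{chrom}q", ds.subset(variant_mask=on & (pos > split))))
        else:
            out.append((chrom, ds.subset(variant_mask=on)))
    return out


def impute_missing(ds: GenotypeDataset, seed: int | None = None) -> GenotypeDataset:
    """Replace missing calls by the per-variant modal genotype.

    Ties between equally frequent genotypes break toward the lower dosage.
    ``seed`` is accepted for interface stability; the default strategy is
    deterministic.
    """
    d = ds.dosages.copy()
    miss = d == MISSING
    if not miss.any():
        return ds
    counts = genotype_counts(ds)  # (m, 3) for dosages (2,1,0)
    if (counts.sum(axis=1) == 0).any():
        bad = ds.variants.loc[counts.sum(axis=1) == 0, "id"].tolist()
        raise ValueError(f"variants with all genotypes missing: {bad[:5]}")
    by_dosage = counts[:, ::-1]  # columns now dosage 0,1,2
    mode = np.argmax(by_dosage, axis=1).astype(np.int8)  # argmax takes first max -> lower dosage
    fill = np.broadcast_to(mode, d.shape)
    d[miss] = fill[miss]
    return replace(ds, dosages=d)


def orient_to_minor(ds: GenotypeDataset) -> GenotypeDataset:
    """Flip alleles so that a1 is the pooled (case+control) minor allele.

    Dominant/recessive collapses and the reported allelic odds ratio refer to
    the counted allele; orienting makes them reproducible across datasets.
    Ties (frequency exactly 0.5) keep the current orientation.
    """
    d = ds.dosages
    valid = d != MISSING
    a1 = np.where(valid, d, 0).sum(axis=0)
    total = 2 * valid.sum(axis=0)
    freq = np.where(total > 0, a1 / np.maximum(total, 1), 0.0)
    flip = freq > 0.5
    if not flip.any():
        return ds
    dosages = d.copy()
    cols = np.flatnonzero(flip)
    sub = dosages[:, cols]
    sub[sub != MISSING] = 2 - sub[sub != MISSING]
    dosages[:, cols] = sub
    variants = ds.variants.copy()
    va1 = variants.loc[flip, "a1"].copy()
    variants.loc[flip, "a1"] = variants.loc[flip, "a2"].to_numpy()
    variants.loc[flip, "a2"] = va1.to_numpy()
    return GenotypeDataset(variants, list(ds.samples), dosages, ds.phenotype.copy())


def minor_allele_frequencies(ds: GenotypeDataset) -> np.ndarray:
    """Per-variant minor allele frequency among non-missing calls, in [0, 0.5]."""
    d = ds.dosages
    valid = d != MISSING
    a1 = np.where(valid, d, 0).sum(axis=0)
    total = 2 * valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(total > 0, a1 / np.maximum(total, 1), 0.0)
    return np.minimum(f, 1 - f)
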