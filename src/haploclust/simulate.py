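"""Self-contained genotype-phenotype simulation with implanted disease SNPs.

The generator emulates a Hapgen-style validation design without external
data.  A synthetic phased reference panel carries block-wise LD: variants are
partitioned into blocks of geometric length; within a block every panel
haplotype is a noisy copy of one of a few founder haplotypes, and variants
fall into founder-pattern groups (variants in one group are near-perfect
proxies of each other, mirroring the tag-SNP structure of real haplotype
blocks).  New diploid individuals are drawn by Li-Stephens-style mosaic
resampling of the panel with template switches at recombination intervals.
Disease status follows a per-allele multiplicative odds model at the
implanted variants (heterozygote OR 1.5, homozygote OR 2.25 by default), with
the intercept solved numerically for the target prevalence, and cases and
controls are accumulated by rejection sampling to exact quotas.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datasets import CASE, CONTROL, GenotypeDataset
from .ld import LDDecayProfile, haplotype_r2, ld_decay


@dataclass
class ReferencePanel:
    """A synthetic phased haplotype panel for one chromosome."""

    variants: pd.DataFrame          # id, chrom, pos, a1, a2
    haplotypes: np.ndarray          # (n_hap, n_variants) uint8, 1 = allele a1
    genetic_map: np.ndarray         # per-interval genetic distance (Morgans), len m-1
    block_id: np.ndarray            # generating block per variant
    group_id: np.ndarray            # founder-pattern group per variant (truth labels)

    @property
    def n_hap(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    def maf(self) -> np.ndarray:
        f = self.haplotypes.mean(axis=0)
        return np.minimum(f, 1 - f)


@dataclass
class DiseaseModel:
    """Per-allele multiplicative disease model on the odds scale."""

    disease_variant_ids: list
    or_het: float = 1.5
    or_hom: float = 2.25
    prevalence: float = 0.1

    def __post_init__(self):
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if abs(self.or_hom - self.or_het ** 2) > 1e-9 * self.or_hom:
            raise ValueError("multiplicative model requires or_hom = or_het **2")


@dataclass
class SimulatedStudy:
    """A simulated case-control cohort plus its generating truth."""

    dataset: GenotypeDataset
    truth: dict


def generate_reference_panel(n_hap: int = 198, n_variants: int = 3000,
                             block_len_mean: float = 10.0,
                             founders_per_block: int = 4,
                             groups_per_block_mean: float = 2.0,
                             copy_noise: float = 0.01,
                             mean_spacing_bp: float = 1000.0,
                             base_rate_morgans_per_bp: float = 1e-8,
                             hotspot_morgans: float = 3e-3,
                             chrom: str = "22",
                             seed: int | None = None) -> ReferencePanel:
    """Generate a block-LD phased reference panel.

    Blocks have geometric variant counts (mean ``block_len_mean``).  Within a
    block, ``founders_per_block`` founder haplotypes are drawn with Dirichlet
    usage weights; each variant belongs to one of ~``1 +
    Poisson(groups_per_block_mean - 1)`` pattern groups, all variants of a
    group sharing the same founder bipartition (so same-group r² is ~1 and
    cross-group r² is moderate).  Panel haplotypes copy one founder per block
    with per-site flip probability ``copy_noise``.  The genetic map has a
    uniform background rate plus a recombination hotspot at every block
    boundary.  Deterministic for a given seed.
    """
    if n_hap < 4 or n_variants < 2:
        raise ValueError("panel needs n_hap >= 4 and n_variants >= 2")
    if founders_per_block < 2:
        raise ValueError("founders_per_block must be >= 2")
    rng = np.random.default_rng(seed)

    # block partition (geometric lengths, mean block_len_mean)
    block_id = np.empty(n_variants, dtype=int)
    b = 0
    j = 0
    while j < n_variants:
        length = rng.geometric(1.0 / block_len_mean)
        block_id[j:j + length] = b
        j += length
        b += 1
    n_blocks = block_id.max() + 1

    # positions and genetic map
    spacing = rng.exponential(mean_spacing_bp, size=n_variants).astype(int) + 1
    pos = 1_000_000 + np.cumsum(spacing)
    gmap = (pos[1:] - pos[:-1]).astype(float) * base_rate_morgans_per_bp
    boundary = block_id[1:] != block_id[:-1]
    gmap[boundary] += hotspot_morgans

    haplotypes = np.empty((n_hap, n_variants), dtype=np.uint8)
    group_id = np.empty(n_variants, dtype=int)
    next_group = 0
    F = founders_per_block
    for blk in range(n_blocks):
        cols = np.flatnonzero(block_id == blk)
        weights = rng.dirichlet(np.ones(F))
        n_groups = 1 + rng.poisson(max(groups_per_block_mean - 1.0, 0.0))
        # distinct non-trivial founder subsets, one per pattern group
        patterns = []
        seen = set()
        while len(patterns) < n_groups and len(seen) < 2 ** F - 2:
            mask = rng.integers(1, 2 ** F - 1)
            if mask in seen or ((2 ** F - 1) ^ mask) in seen:
                continue
            seen.add(mask)
            patterns.append(np.array([(mask >> f) & 1 for f in range(F)], dtype=np.uint8))
        groups = rng.integers(0, len(patterns), size=len(cols))
        group_id[cols] = next_group + groups
        next_group += len(patterns)
        founders = np.stack([patterns[g] for g in groups], axis=1)  # (F, len(cols))
        choice = rng.choice(F, size=n_hap, p=weights)
        block_haps = founders[choice]  # (n_hap, len(cols))
        noise = rng.random(block_haps.shape) < copy_noise
        block_haps = block_haps ^ noise
        haplotypes[:, cols] = block_haps

    # enforce polymorphism: flip one haplotype at monomorphic sites
    mono = np.flatnonzero((haplotypes.mean(axis=0) == 0) | (haplotypes.mean(axis=0) == 1))
    for col in mono:
        haplotypes[rng.integers(0, n_hap), col] ^= 1

    variants = pd.DataFrame({
        "id": [f"sv{j}" for j in range(n_variants)],
        "chrom": chrom, "pos": pos, "a1": "A", "a2": "G",
    })
    return ReferencePanel(variants, haplotypes, gmap, block_id, group_id)


def load_recombination_map(path, positions: np.ndarray) -> np.ndarray:
    """Per-interval genetic distances (Morgans) from a 3-column map TSV.

    The file has columns (position bp, rate cM/Mb, cumulative cM), with or
    without a header.  Cumulative cM is linearly interpolated at the variant
    ``positions``; the result can be assigned to ``ReferencePanel.genetic_map``.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if isinstance(df.iloc[0, 0], str):  # header row
        df = df.iloc[1:].astype(float)
    bp = df.iloc[:, 0].to_numpy(dtype=float)
    cum_cm = df.iloc[:, 2].to_numpy(dtype=float)
    cum_at = np.interp(np.asarray(positions, dtype=float), bp, cum_cm)
    return np.diff(cum_at) / 100.0  # cM -> Morgans


def _mosaic_haplotypes(panel: ReferencePanel, n_hap_new: int,
                       recomb_scale: float, error_rate: float,
                       rng: np.random.Generator) -> np.ndarray:
    H = panel.haplotypes
    m = panel.n_variants
    switch_p = np.minimum(1.0, recomb_scale * panel.genetic_map)
    tpl = rng.integers(0, panel.n_hap, size=n_hap_new)
    out = np.empty((n_hap_new, m), dtype=np.uint8)
    out[:, 0] = H[tpl, 0]
    for j in range(1, m):
        if switch_p[j - 1] > 0:
            sw = rng.random(n_hap_new) < switch_p[j - 1]
            if sw.any():
                tpl[sw] = rng.integers(0, panel.n_hap, size=int(sw.sum()))
        out[:, j] = H[tpl, j]
    if error_rate > 0:
        err = rng.random(out.shape) < error_rate
        out ^= err
    return out


def mosaic_resample(panel: ReferencePanel, n_individuals: int,
                    recomb_scale: float = 300.0, error_rate: float = 1e-3,
                    seed: int | None = None) -> GenotypeDataset:
    """Draw diploid individuals as segment-wise mosaics of panel haplotypes.

    Template switches occur between consecutive variants with probability
    min(1, recomb_scale x genetic distance); each copied allele flips with
    probability ``error_rate``.  With both zero, every simulated haplotype is
    an exact panel haplotype.
    """
    rng = np.random.default_rng(seed)
    haps = _mosaic_haplotypes(panel, 2 * n_individuals, recomb_scale, error_rate, rng)
    dosages = (haps[0::2] + haps[1::2]).astype(np.int8)
    return GenotypeDataset(panel.variants.copy(),
                           [f"i{i}" for i in range(n_individuals)], dosages)


def select_disease_variants(panel: ReferencePanel, k: int = 5,
                            maf_range=(0.2, 0.4), min_separation: int = 100_000,
                            ld_neighbors: int = 3, ld_r2: float = 0.8,
                            ld_window: int = 50,
                            seed: int | None = None) -> list[str]:
    """Pick k implantable disease variants: MAF in range, pairwise separation
    above ``min_separation`` bp, and at least ``ld_neighbors`` other variants
    with r² >= ``ld_r2`` within ``ld_window`` panel columns (a high-LD
    neighborhood criterion standing in for haplotype-block membership)."""
    rng = np.random.default_rng(seed)
    maf = panel.maf()
    pos = panel.variants["pos"].to_numpy()
    in_range = (maf >= maf_range[0]) & (maf <= maf_range[1])
    candidates = np.flatnonzero(in_range)
    good = []
    for j in candidates:
        lo, hi = max(0, j - ld_window), min(panel.n_variants, j + ld_window + 1)
        r2 = haplotype_r2(panel.haplotypes[:, lo:hi].astype(np.float64))
        jj = j - lo
        if (np.delete(r2[jj], jj) >= ld_r2).sum() >= ld_neighbors:
            good.append(j)
    if len(good) < k:
        raise ValueError(
            f"only {len(good)} variants satisfy MAF {maf_range} and the "
            f">= {ld_neighbors} neighbors at r2 >= {ld_r2} criterion (need {k})")
    good = np.array(good)
    order = rng.permutation(len(good))
    chosen = []
    for idx in order:
        j = good[idx]
        if all(abs(pos[j] - pos[c]) > min_separation for c in chosen):
            chosen.append(j)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError(
            f"could not place {k} variants with pairwise separation > "
            f"{min_separation} bp (panel span {pos[-1] - pos[0]} bp)")
    chosen = sorted(chosen)
    return [panel.variants["id"].iat[j] for j in chosen]


def _solve_intercept(panel_maf: np.ndarray, log_or: float, prevalence: float) -> float:
    """Intercept of the logistic disease model matching the target prevalence.

    Uses the panel allele frequencies at the disease loci under HWE and
    cross-locus independence (the loci are far apart by construction).
    """
    freqs = [np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2]) for p in panel_maf]
    scores = np.array([0.0])
    weights = np.array([1.0])
    for f in freqs:
        scores = (scores[:, None] + log_or * np.arange(3)[None, :]).ravel()
        weights = (weights[:, None] * f[None, :]).ravel()

    def mean_risk(alpha):
        return float((weights * expit(alpha + scores)).sum()) - prevalence

    return brentq(mean_risk, -30.0, 10.0)


def sample_case_control(panel: ReferencePanel, disease_model: DiseaseModel,
                        n_cases: int = 4929, n_controls: int = 652,
                        recomb_scale: float = 300.0, error_rate: float = 1e-3,
                        seed: int | None = None, batch_size: int = 8192,
                        max_draws: int = 2_000_000) -> SimulatedStudy:
    """Simulate a case-control study with the implanted disease variants.

    Individuals are drawn by mosaic resampling; disease status is Bernoulli
    with logit = intercept + log(or_het) x (risk-allele dosage summed over
    disease loci), the intercept solved for ``disease_model.prevalence``.
    Rejection sampling continues until both group quotas are met exactly.
    """
    rng = np.random.default_rng(seed)
    ids = list(panel.variants["id"])
    loci = np.array([ids.index(v) for v in disease_model.disease_variant_ids])
    if len(loci) == 0:
        raise ValueError("disease model names no variants present in the panel")
    # risk allele = minor allele in the panel
    panel_freq = panel.haplotypes.mean(axis=0)[loci]
    risk_is_a1 = panel_freq <= 0.5
    panel_maf = np.where(risk_is_a1, panel_freq, 1 - panel_freq)
    log_or = np.log(disease_model.or_het)
    alpha = _solve_intercept(panel_maf, log_or, disease_model.prevalence)

    case_rows, control_rows = [], []
    n_case_found = n_control_found = 0
    drawn = 0
    while n_case_found < n_cases or n_control_found < n_controls:
        if drawn >= max_draws:
            raise RuntimeError(
                f"quota unreachable: {drawn} draws yielded "
                f"{n_case_found}/{n_cases} cases and {n_control_found}/{n_controls} controls")
        haps = _mosaic_haplotypes(panel, 2 * batch_size, recomb_scale, error_rate, rng)
        dosages = (haps[0::2] + haps[1::2]).astype(np.int8)
        drawn += batch_size
        risk_dosage = np.where(risk_is_a1[None, :], dosages[:, loci],
                               2 - dosages[:, loci]).sum(axis=1)
        p_disease = expit(alpha + log_or * risk_dosage)
        disease = rng.random(batch_size) < p_disease
        if n_case_found < n_cases:
            take = np.flatnonzero(disease)[: n_cases - n_case_found]
            case_rows.append(dosages[take])
            n_case_found += len(take)
        if n_control_found < n_controls:
            take = np.flatnonzero(~disease)[: n_controls - n_control_found]
            control_rows.append(dosages[take])
            n_control_found += len(take)

    dosages = np.vstack([np.vstack(case_rows), np.vstack(control_rows)])
    phenotype = np.concatenate([np.full(n_cases, CASE, dtype=np.int8),
                                np.full(n_controls, CONTROL, dtype=np.int8)])
    samples = [f"case{i}" for i in range(n_cases)] + [f"ctrl{i}" for i in range(n_controls)]
    ds = GenotypeDataset(panel.variants.copy(), samples, dosages, phenotype)
    truth = {
        "disease_variant_ids": list(disease_model.disease_variant_ids),
        "or_het": disease_model.or_het, "or_hom": disease_model.or_hom,
        "prevalence": disease_model.prevalence, "intercept": float(alpha),
        "risk_is_a1": risk_is_a1.tolist(),
        "panel_maf": panel_maf.tolist(), "seed": seed,
        "n_cases": n_cases, "n_controls": n_controls, "n_drawn": drawn,
    }
    return SimulatedStudy(ds, truth)


def compare_maf(simulated: GenotypeDataset, panel: ReferencePanel) -> pd.DataFrame:
    """Per-variant MAF comparison between a simulated cohort and its panel."""
    from .datasets import minor_allele_frequencies

    if simulated.n_variants != panel.n_variants:
        raise ValueError("simulated dataset and panel cover different variants")
    sim = minor_allele_frequencies(simulated)
    ref = panel.maf()
    df = pd.DataFrame({"id": panel.variants["id"], "maf_simulated": sim,
                       "maf_panel": ref, "delta": sim - ref})
    df.attrs["mean_abs_delta"] = float(np.abs(df["delta"]).mean())
    return df


def compare_ld_decay(simulated: GenotypeDataset, panel: ReferencePanel,
                     bin_width: int = 5000, max_dist: int | None = None) -> pd.DataFrame:
    """Paired LD-decay profiles (median r² per bp bin) for cohort and panel."""
    pos = panel.variants["pos"].to_numpy()
    sim_prof = ld_decay(simulated, bin_width=bin_width, max_dist=max_dist,
                        estimator="dosage_corr")
    ref_prof = LDDecayProfile(*_decay_from_matrix(pos, haplotype_r2(panel.haplotypes),
                                                  bin_width, max_dist))
    a = sim_prof.to_frame().rename(columns={"median_r2": "median_r2_simulated",
                                            "n_pairs": "n_pairs_simulated"})
    b = ref_prof.to_frame().rename(columns={"median_r2": "median_r2_panel",
                                            "n_pairs": "n_pairs_panel"})
    return a.merge(b, on=["bin_start", "bin_end"], how="outer")


def _decay_from_matrix(pos, r2, bin_width, max_dist):
    prof = ld_decay((pos, r2), bin_width=bin_width, max_dist=max_dist)
    return prof.bin_edges, prof.median_r2, prof.n_pairs


def write_study(study: SimulatedStudy, prefix) -> None:
    """Write a simulated study as PLINK bed/bim/fam plus a truth JSON."""
    from .datasets import write_plink

    write_plink(study.dataset, prefix)
    with open(str(prefix) + ".truth.json", "w") as fh:
        json.dump(study.truth, fh, indent=2)
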