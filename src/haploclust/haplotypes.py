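"""Haplotype inference in LD-block prefixes and omnibus case-control testing.

Within each variant cluster, LD-blocks are the coordinate-sorted prefixes of
sizes 2..n.  Haplotype frequencies over a block are estimated from unphased
genotypes with an EM algorithm over the haplotype pairs compatible with each
genotype; case and control haplotype counts are fractional, posterior-weighted
under the jointly estimated frequencies.  Each block's haplotype x phenotype
table is tested with a Pearson chi-square omnibus test (df = haplotypes - 1),
one best block per cluster is selected (minimum p, ties to the largest
block), and the selected p-values are Bonferroni-adjusted across clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .datasets import MISSING, GenotypeDataset


# ---------------------------------------------------------------------------
# Block enumeration
# ---------------------------------------------------------------------------

@dataclass
class LDBlock:
    """A coordinate-sorted prefix of one cluster's variants."""

    cluster_id: int
    variant_indices: np.ndarray  # column indices into the dataset, position-sorted

    @property
    def size(self) -> int:
        return len(self.variant_indices)


def enumerate_prefix_blocks(cluster_id: int, variant_indices: np.ndarray,
                            positions: np.ndarray) -> list[LDBlock]:
    """The n-1 prefix blocks (sizes 2..n) of a cluster, in coordinate order.

    ``positions`` gives the bp coordinate of each index; blocks always follow
    coordinate order regardless of the input order of ``variant_indices``.
    Clusters with fewer than two variants yield an empty list.
    """
    idx = np.asarray(variant_indices)
    if len(idx) < 2:
        return []
    idx = idx[np.argsort(positions[idx], kind="stable")]
    return [LDBlock(cluster_id, idx[:size]) for size in range(2, len(idx) + 1)]


# ---------------------------------------------------------------------------
# EM haplotype frequency estimation
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeTable:
    """Haplotypes over a block with EM frequencies and fractional group counts."""

    haplotype_codes: np.ndarray       # ints; bit t set = allele a1 at block site t
    n_sites: int
    freq_overall: np.ndarray
    count_case: np.ndarray
    count_control: np.ndarray
    n_case: int
    n_control: int
    converged: bool
    log_likelihood: float
    alleles: list[str] | None = None  # optional a1/a2 letter strings
    loglik_trace: list | None = None  # per-iteration log-likelihood (final EM pass)

    @property
    def freq_case(self) -> np.ndarray:
        tot = self.count_case.sum()
        return self.count_case / tot if tot else self.count_case

    @property
    def freq_control(self) -> np.ndarray:
        tot = self.count_control.sum()
        return self.count_control / tot if tot else self.count_control

    def haplotype_strings(self) -> list[str]:
        return [format(int(h), f"0{self.n_sites}b")[::-1] for h in self.haplotype_codes]


def _compatible_pairs(geno: np.ndarray):
    """All unordered haplotype pairs consistent with one genotype vector.

    Haplotypes are bit codes (bit t = allele a1 at site t).  A genotype with
    h heterozygous sites has 2^(h-1) compatible unordered pairs; the first
    heterozygous site is pinned to allele a1 on the first haplotype to avoid
    double counting.
    """
    hom1 = int(sum(1 << t for t, g in enumerate(geno) if g == 2))
    hets = [t for t, g in enumerate(geno) if g == 1]
    if not hets:
        return [(hom1, hom1)]
    all_het = sum(1 << t for t in hets)
    first = hets[0]
    rest = hets[1:]
    pairs = []
    for mask in range(1 << len(rest)):
        h1_het = 1 << first
        for b, t in enumerate(rest):
            if mask >> b & 1:
                h1_het |= 1 << t
        h1 = hom1 | h1_het
        h2 = hom1 | (all_het ^ h1_het)
        pairs.append((h1, h2))
    return pairs


def _restricted_pairs(geno: np.ndarray, support: dict):
    """Compatible unordered pairs with both haplotypes in ``support`` (code->index)."""
    hom1 = int(sum(1 << t for t, g in enumerate(geno) if g == 2))
    het_mask = int(sum(1 << t for t, g in enumerate(geno) if g == 1))
    full_mask = (1 << len(geno)) - 1
    hom_mask = full_mask ^ het_mask
    pairs = []
    seen = set()
    for h1 in support:
        if (h1 & hom_mask) != hom1:
            continue
        h2 = h1 ^ het_mask  # flip het sites; hom sites already equal
        if h2 in support:
            key = (min(h1, h2), max(h1, h2))
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    return pairs


class _EMProblem:
    """Vectorized EM over unique genotype rows of a block."""

    def __init__(self, uniq_geno, w_total, w_case, w_control, pairs_per_row, hap_codes):
        # codes are arbitrary-precision Python ints (blocks can exceed 63 sites)
        self.hap_codes = np.array(sorted(int(c) for c in hap_codes), dtype=object)
        code_to_idx = {c: i for i, c in enumerate(self.hap_codes)}
        g_idx, h1, h2 = [], [], []
        for gi, pairs in enumerate(pairs_per_row):
            for a, b in pairs:
                g_idx.append(gi)
                h1.append(code_to_idx[a])
                h2.append(code_to_idx[b])
        self.g_idx = np.asarray(g_idx)
        self.h1 = np.asarray(h1)
        self.h2 = np.asarray(h2)
        self.mult = np.where(self.h1 == self.h2, 1.0, 2.0)
        self.w_total = np.asarray(w_total, dtype=float)
        self.w_case = np.asarray(w_case, dtype=float)
        self.w_control = np.asarray(w_control, dtype=float)
        self.n_rows = len(w_total)
        self.uniq_geno = uniq_geno

    def initial_freqs(self, n_sites) -> np.ndarray:
        # product of marginal allele frequencies, blended with uniform for support safety
        tot = self.w_total.sum()
        p = (self.uniq_geno * self.w_total[:, None]).sum(0) / (2 * tot)
        f = np.ones(len(self.hap_codes))
        for t in range(n_sites):
            bit = (self.hap_codes >> t) & 1
            f *= np.where(bit == 1, p[t], 1 - p[t])
        f = 0.95 * f + 0.05 / len(f)
        return f / f.sum()

    def run(self, f0, tol=1e-6, max_iter=1000):
        f = f0.copy()
        tot = 2.0 * self.w_total.sum()
        converged = False
        self.loglik_trace = []
        for _ in range(max_iter):
            lik = f[self.h1] * f[self.h2] * self.mult
            denom = np.bincount(self.g_idx, weights=lik, minlength=self.n_rows)
            denom = np.maximum(denom, 1e-300)
            w = lik / denom[self.g_idx] * self.w_total[self.g_idx]
            counts = (np.bincount(self.h1, weights=w, minlength=len(f))
                      + np.bincount(self.h2, weights=w, minlength=len(f)))
            f_new = counts / tot
            self.loglik_trace.append(float((self.w_total * np.log(denom)).sum()))
            if np.abs(f_new - f).max() < tol:
                f = f_new
                converged = True
                break
            f = f_new
        return f, self.loglik_trace[-1] if self.loglik_trace else -np.inf, converged

    def group_counts(self, f):
        lik = f[self.h1] * f[self.h2] * self.mult
        denom = np.bincount(self.g_idx, weights=lik, minlength=self.n_rows)
        denom = np.maximum(denom, 1e-300)
        post = lik / denom[self.g_idx]
        out = []
        for wg in (self.w_case, self.w_control):
            w = post * wg[self.g_idx]
            out.append(np.bincount(self.h1, weights=w, minlength=len(f))
                       + np.bincount(self.h2, weights=w, minlength=len(f)))
        return out


def _unique_rows(dosages_block, case_mask, control_mask):
    uniq, inv = np.unique(dosages_block, axis=0, return_inverse=True)
    n = len(uniq)
    w_total = np.bincount(inv, minlength=n).astype(float)
    w_case = np.bincount(inv[case_mask], minlength=n).astype(float)
    w_control = np.bincount(inv[control_mask], minlength=n).astype(float)
    return uniq, w_total, w_case, w_control


def em_haplotype_frequencies(ds: GenotypeDataset, block, tol: float = 1e-6,
                             max_iter: int = 1000, seed: int | None = None,
                             max_enum: int = 8, max_block: int = 64,
                             ligation_window: int = 8,
                             ligation_prune: float = 1e-4) -> HaplotypeTable | None:
    """EM haplotype frequencies and fractional case/control counts for a block.

    ``block`` is an :class:`LDBlock` or an array of variant column indices.
    Blocks up to ``max_enum`` variants use exhaustive haplotype-pair
    enumeration; larger blocks are solved by progressive ligation (windowed
    EM, merge, prune haplotypes below ``ligation_prune``).  Blocks above
    ``max_block`` variants are skipped with a warning (returns None).
    The default initialization (product of marginal allele frequencies) is
    deterministic; ``seed`` is reserved for stochastic restarts.
    """
    idx = block.variant_indices if isinstance(block, LDBlock) else np.asarray(block)
    k = len(idx)
    if k > max_block:
        warnings.warn(f"block of {k} variants exceeds max_block={max_block}; skipped")
        return None
    sub = ds.dosages[:, idx]
    if (sub == MISSING).any():
        raise ValueError("missing genotypes in block: impute first")
    case_mask, control_mask = ds.case_mask, ds.control_mask
    uniq, w_total, w_case, w_control = _unique_rows(sub, case_mask, control_mask)

    if k <= max_enum:
        pairs_per_row = [_compatible_pairs(g) for g in uniq]
        hap_codes = {h for pairs in pairs_per_row for pair in pairs for h in pair}
        prob = _EMProblem(uniq, w_total, w_case, w_control, pairs_per_row, hap_codes)
        f, loglik, converged = prob.run(prob.initial_freqs(k), tol, max_iter)
    else:
        f, prob, converged, loglik = _ligation_em(
            uniq, w_total, w_case, w_control, k, tol, max_iter,
            ligation_window, ligation_prune)

    cnt_case, cnt_control = prob.group_counts(f)
    alleles = None
    if isinstance(block, LDBlock):
        a1 = ds.variants["a1"].to_numpy()[idx]
        a2 = ds.variants["a2"].to_numpy()[idx]
        alleles = ["".join(a1[t] if (int(h) >> t) & 1 else a2[t] for t in range(k))
                   for h in prob.hap_codes]
    return HaplotypeTable(
        haplotype_codes=prob.hap_codes, n_sites=k, freq_overall=f,
        count_case=cnt_case, count_control=cnt_control,
        n_case=int(case_mask.sum()), n_control=int(control_mask.sum()),
        converged=converged, log_likelihood=loglik, alleles=alleles,
        loglik_trace=list(getattr(prob, "loglik_trace", [])))


def _ligation_em(uniq, w_total, w_case, w_control, k, tol, max_iter,
                 window, prune):
    """Progressive-ligation EM for blocks too large for exhaustive enumeration."""
    # initial window
    edges = list(range(0, k, window)) + [k]
    spans = list(zip(edges[:-1], edges[1:]))

    def window_support(lo, hi):
        sub = uniq[:, lo:hi]
        u, inv = np.unique(sub, axis=0, return_inverse=True)
        wt = np.bincount(inv, weights=w_total, minlength=len(u))
        pairs = [_compatible_pairs(g) for g in u]
        codes = {h for ps in pairs for pr in ps for h in pr}
        prob = _EMProblem(u, wt, wt, wt, pairs, codes)
        f, _, _ = prob.run(prob.initial_freqs(hi - lo), tol, max_iter)
        keep = f > prune
        return prob.hap_codes[keep], f[keep] / f[keep].sum()

    supp, freqs = window_support(*spans[0])
    for lo, hi in spans[1:]:
        nxt_supp, nxt_freqs = window_support(lo, hi)
        # candidate merged haplotypes: cross product, shifted into place
        cand = {}
        for h, fh in zip(supp, freqs):
            for g, fg in zip(nxt_supp, nxt_freqs):
                cand[int(h) | (int(g) << lo)] = fh * fg
        sub = uniq[:, :hi]
        u, inv = np.unique(sub, axis=0, return_inverse=True)
        wt = np.bincount(inv, weights=w_total, minlength=len(u))
        wc = np.bincount(inv, weights=w_case, minlength=len(u))
        wn = np.bincount(inv, weights=w_control, minlength=len(u))
        support = {c: i for i, c in enumerate(sorted(cand))}
        pairs = [_restricted_pairs(g, support) for g in u]
        # genotypes with no compatible pair in support: fall back to exhaustive
        for gi, ps in enumerate(pairs):
            if not ps:
                ps_all = _compatible_pairs(u[gi])
                pairs[gi] = ps_all
                for a, b in ps_all:
                    cand.setdefault(a, prune)
                    cand.setdefault(b, prune)
        prob = _EMProblem(u, wt, wc, wn, pairs, set(cand))
        f0 = np.array([cand.get(c, prune) for c in prob.hap_codes])
        f0 = np.maximum(f0, 1e-12)
        f0 /= f0.sum()
        f, loglik, converged = prob.run(f0, tol, max_iter)
        keep = f > prune
        if keep.sum() < 1:
            keep = f >= f.max()
        supp = prob.hap_codes[keep]
        freqs = f[keep] / f[keep].sum()
    # the last merge's problem carries the full block; reuse it for group counts
    return f, prob, converged, loglik


def _prefix_scan(ds: GenotypeDataset, cluster_id: int, idx_sorted: np.ndarray,
                 min_hap_freq: float, tol: float, max_iter: int,
                 max_enum: int, max_block: int,
                 prune: float = 1e-4, max_support: int = 256) -> list:
    """Omnibus results for every prefix block of one cluster, incrementally.

    Prefix k+1 differs from prefix k by one appended variant, so the unique
    genotype-row partition is refined column by column and the haplotype
    support is extended (each retained haplotype forks into its two possible
    alleles at the new site), with EM warm-started from the previous prefix.
    This keeps the per-cluster cost near-linear in cluster size where naive
    re-estimation is quadratic.  Prefixes longer than ``max_block`` are not
    scanned.
    """
    case_mask, control_mask = ds.case_mask, ds.control_mask
    n = ds.n_samples
    inv = np.zeros(n, dtype=np.int64)
    supp = freqs = None
    results = []
    for t, col_idx in enumerate(idx_sorted):
        k = t + 1
        if k > max_block:
            warnings.warn(
                f"cluster {cluster_id}: prefixes beyond {max_block} variants skipped")
            break
        col = ds.dosages[:, col_idx].astype(np.int64)
        keys = inv * 3 + col
        _, first, inv = np.unique(keys, return_index=True, return_inverse=True)
        if k == 1:
            continue
        geno = ds.dosages[np.ix_(first, idx_sorted[:k])]
        u = len(first)
        w_total = np.bincount(inv, minlength=u).astype(float)
        w_case = np.bincount(inv[case_mask], minlength=u).astype(float)
        w_control = np.bincount(inv[control_mask], minlength=u).astype(float)

        if k <= max_enum:
            pairs = [_compatible_pairs(g) for g in geno]
            codes = {h for ps in pairs for pr in ps for h in pr}
            prob = _EMProblem(geno, w_total, w_case, w_control, pairs, codes)
            f0 = prob.initial_freqs(k)
            if supp is not None:
                # warm start: previous-prefix frequencies forked on the new site
                warm = _fork_support(supp, freqs, k, geno, w_total)
                f0 = np.array([warm.get(int(c), prune) for c in prob.hap_codes])
                f0 = np.maximum(f0, 1e-12)
                f0 /= f0.sum()
        else:
            warm = _fork_support(supp, freqs, k, geno, w_total)
            support_map = {c: i for i, c in enumerate(sorted(warm))}
            pairs = [_restricted_pairs(g, support_map) for g in geno]
            for gi, ps in enumerate(pairs):
                if not ps:
                    extra = _fallback_pairs(geno[gi])
                    pairs[gi] = extra
                    for a, b in extra:
                        warm.setdefault(a, prune)
                        warm.setdefault(b, prune)
            prob = _EMProblem(geno, w_total, w_case, w_control, pairs, set(warm))
            f0 = np.array([warm.get(int(c), prune) for c in prob.hap_codes])
            f0 = np.maximum(f0, 1e-12)
            f0 /= f0.sum()

        f, loglik, converged = prob.run(f0, tol, max_iter)
        keep = f > prune
        if keep.sum() == 0:
            keep = f >= f.max()
        if keep.sum() > max_support:
            cutoff = np.sort(f[keep])[-max_support]
            keep &= f >= cutoff
        supp, fr = prob.hap_codes[keep], f[keep]
        freqs = fr / fr.sum()

        cnt_case, cnt_control = prob.group_counts(f)
        table = HaplotypeTable(
            haplotype_codes=prob.hap_codes, n_sites=k, freq_overall=f,
            count_case=cnt_case, count_control=cnt_control,
            n_case=int(case_mask.sum()), n_control=int(control_mask.sum()),
            converged=converged, log_likelihood=loglik)
        block = LDBlock(cluster_id, idx_sorted[:k])
        results.append(omnibus_test(table, block, min_hap_freq))
    return results


def _fork_support(supp, freqs, k, geno, w_total):
    """Extend a (k-1)-site haplotype support to k sites: each haplotype forks
    into both alleles at the new site, weighted by the site's marginal."""
    p_new = float((geno[:, k - 1] * w_total).sum() / (2 * w_total.sum()))
    out = {}
    bit = 1 << (k - 1)
    for h, fh in zip(supp, freqs):
        out[int(h)] = fh * (1 - p_new)
        out[int(h) | bit] = fh * p_new
    return out


def _fallback_pairs(geno_row, het_cap: int = 8):
    """Compatible pairs for a row the pruned support cannot explain."""
    n_het = int((geno_row == 1).sum())
    if n_het <= het_cap:
        return _compatible_pairs(geno_row)
    # extremely heterozygous row: a single deterministic phase assignment
    hom1 = int(sum(1 << t for t, g in enumerate(geno_row) if g == 2))
    het = int(sum(1 << t for t, g in enumerate(geno_row) if g == 1))
    return [(hom1 | het, hom1)]


# ---------------------------------------------------------------------------
# Omnibus test, block selection, multiple testing
# ---------------------------------------------------------------------------

@dataclass
class BlockResult:
    """Omnibus-test outcome for one LD-block."""

    cluster_id: int
    size: int
    variant_indices: np.ndarray
    chi2: float
    df: int
    p_unadjusted: float
    testable: bool
    converged: bool
    p_adjusted: float | None = None
    selected: bool = False
    significant: bool = False


def omnibus_chi2(table: np.ndarray):
    """Pearson chi-square of independence on an H x 2 (possibly fractional) table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = row @ col / total
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0).sum()
    df = table.shape[0] - 1
    return float(stat), int(df), float(chi2_dist.sf(stat, df))


def omnibus_test(haptable: HaplotypeTable, block=None,
                 min_hap_freq: float = 0.01) -> BlockResult:
    """Omnibus haplotype association test on one block's haplotype table.

    Haplotypes with overall frequency below ``min_hap_freq`` are dropped
    (their counts excluded).  If fewer than two haplotypes remain the block
    is untestable and gets p = 1 by convention.
    """
    keep = haptable.freq_overall >= min_hap_freq
    cluster_id = block.cluster_id if isinstance(block, LDBlock) else -1
    idx = (block.variant_indices if isinstance(block, LDBlock)
           else np.arange(haptable.n_sites))
    if keep.sum() < 2:
        return BlockResult(cluster_id, haptable.n_sites, idx, 0.0, 0, 1.0,
                           testable=False, converged=haptable.converged)
    table = np.column_stack([haptable.count_case[keep], haptable.count_control[keep]])
    stat, df, p = omnibus_chi2(table)
    return BlockResult(cluster_id, haptable.n_sites, idx, stat, df,
                       max(p, np.finfo(float).tiny), testable=True,
                       converged=haptable.converged)


def select_best_block(results: list[BlockResult]) -> BlockResult | None:
    """The cluster's representative block: minimum p, ties to the largest
    block, remaining ties to the earliest in enumeration order."""
    testable = [r for r in results if r.testable]
    if not testable:
        return None
    best = min(enumerate(testable), key=lambda ir: (ir[1].p_unadjusted, -ir[1].size, ir[0]))[1]
    best.selected = True
    return best


def bonferroni_adjust(selected: list[BlockResult], m: int | None = None,
                      mode: str = "bonferroni", alpha: float = 0.05,
                      threshold: float = 5e-8) -> list[BlockResult]:
    """Bonferroni adjustment across clusters and significance flagging.

    ``m`` defaults to the number of selected blocks (one per cluster — the
    number of clusters is the number of tests).  In ``"bonferroni"`` mode a
    block is significant when the adjusted p < alpha; in ``"fixed"`` mode
    (simulation protocol) when the unadjusted p < ``threshold``.
    """
    if m is None:
        m = len(selected)
    if m < len(selected):
        raise ValueError("m must be at least the number of selected results")
    for r in selected:
        r.p_adjusted = min(1.0, m * r.p_unadjusted)
        if mode == "bonferroni":
            r.significant = r.testable and r.p_adjusted < alpha
        elif mode == "fixed":
            r.significant = r.testable and r.p_unadjusted < threshold
        else:
            raise ValueError(f"unknown significance mode {mode!r}")
    return selected


# ---------------------------------------------------------------------------
# End-to-end cluster GWAS
# ---------------------------------------------------------------------------

def run_cluster_gwas(ds: GenotypeDataset, labels: np.ndarray,
                     min_hap_freq: float = 0.01, mode: str = "fixed",
                     alpha: float = 0.05, threshold: float = 5e-8,
                     tol: float = 1e-6, max_iter: int = 1000,
                     max_enum: int = 8, max_block: int = 64,
                     keep_all_blocks: bool = False):
    """Per-cluster prefix-block enumeration, EM, omnibus test and selection.

    Returns ``(selected, summary)`` where ``selected`` holds one
    :class:`BlockResult` per testable cluster (Bonferroni-adjusted across
    clusters) and ``summary`` is a census dict.  With ``keep_all_blocks`` the
    summary also carries every per-block result.
    """
    labels = np.asarray(labels)
    if len(labels) != ds.n_variants:
        raise ValueError("labels length must equal the variant count")
    positions = ds.variants["pos"].to_numpy()
    cluster_ids = [c for c in np.unique(labels) if c != -1]
    selected, all_blocks, dropped = [], [], 0
    for cid in cluster_ids:
        idx = np.flatnonzero(labels == cid)
        if len(idx) < 2:
            dropped += 1
            continue
        idx_sorted = idx[np.argsort(positions[idx], kind="stable")]
        results = _prefix_scan(ds, int(cid), idx_sorted, min_hap_freq,
                               tol, max_iter, max_enum, max_block)
        if keep_all_blocks:
            all_blocks.extend(results)
        best = select_best_block(results)
        if best is None:
            dropped += 1
            continue
        selected.append(best)
    m = len(cluster_ids)
    bonferroni_adjust(selected, m=max(m, len(selected)), mode=mode,
                      alpha=alpha, threshold=threshold)
    sizes = np.array([np.sum(labels == c) for c in cluster_ids]) if cluster_ids else np.array([])
    sel_sizes = np.array([r.size for r in selected])
    sig = [r for r in selected if r.significant]
    summary = {
        "n_clusters": len(cluster_ids),
        "n_noise": int((labels == -1).sum()),
        "efficiency": float((labels != -1).mean()) if len(labels) else 0.0,
        "n_untestable_clusters": dropped,
        "n_blocks_tested": int(sum(max(s - 1, 0) for s in sizes)),
        "n_significant": len(sig),
        "cluster_size_median": float(np.median(sizes)) if len(sizes) else np.nan,
        "selected_block_size_median": float(np.median(sel_sizes)) if len(sel_sizes) else np.nan,
        "significant_block_size_median": (float(np.median([r.size for r in sig]))
                                          if sig else np.nan),
    }
    if keep_all_blocks:
        summary["all_blocks"] = all_blocks
    return selected, summary


def results_frame(results: list[BlockResult], variants: pd.DataFrame) -> pd.DataFrame:
    """Stable TSV-ready table of block results."""
    ids = variants["id"].to_numpy()
    return pd.DataFrame({
        "cluster_id": [r.cluster_id for r in results],
        "block_size": [r.size for r in results],
        "variant_ids": [",".join(ids[r.variant_indices]) for r in results],
        "chi2": [r.chi2 for r in results],
        "df": [r.df for r in results],
        "p_unadjusted": [r.p_unadjusted for r in results],
        "p_adjusted": [r.p_adjusted for r in results],
        "significant": [r.significant for r in results],
    })


class HaplotypeClusterGWAS(BaseEstimator):
    """Cluster-based GWAS estimator: LD clustering + haplotype omnibus tests.

    fit(X, y) takes a samples x variants dosage matrix (or a
    :class:`GenotypeDataset`) for one genomic partition and binary phenotype
    labels (1 = case, 0 = control).  The pipeline computes the pairwise r²
    matrix, clusters variants on 1 - r² distances, enumerates prefix
    LD-blocks per cluster, EM-estimates haplotype frequencies, applies the
    omnibus chi-square test, selects one block per cluster and adjusts across
    clusters.

    Attributes
    ----------
    labels_ : ndarray          cluster label per variant (-1 noise)
    results_ : DataFrame       one selected block per testable cluster
    summary_ : dict            clusterization and testing census
    significant_clusters_ : ndarray of cluster ids flagged significant
    """

    def __init__(self, algorithm="dbscan", eps=0.35, min_samples=2,
                 min_cluster_size=None, ld_estimator="em", min_hap_freq=0.01,
                 mode="fixed", alpha=0.05, threshold=5e-8,
                 max_enum=8, max_block=64):
        self.algorithm = algorithm
        self.eps = eps
        self.min_samples = min_samples
        self.min_cluster_size = min_cluster_size
        self.ld_estimator = ld_estimator
        self.min_hap_freq = min_hap_freq
        self.mode = mode
        self.alpha = alpha
        self.threshold = threshold
        self.max_enum = max_enum
        self.max_block = max_block

    def fit(self, X, y=None):
        from .cluster import SNPClusterer
        from .ld import distance_matrix, ld_matrix

        if isinstance(X, GenotypeDataset):
            ds = X
            if y is not None:
                pheno = np.asarray(y, dtype=np.int8)
                ds = GenotypeDataset(ds.variants.copy(), list(ds.samples),
                                     ds.dosages.copy(), pheno)
        else:
            X = np.asarray(X)
            variants = pd.DataFrame({
                "id": [f"v{j}" for j in range(X.shape[1])], "chrom": "1",
                "pos": np.arange(1, X.shape[1] + 1), "a1": "A", "a2": "G",
            })
            if y is None:
                raise ValueError("y (case/control labels) is required")
            ds = GenotypeDataset(variants, [f"s{i}" for i in range(X.shape[0])],
                                 X.astype(np.int8), np.asarray(y, dtype=np.int8))
        ldm = ld_matrix(ds, estimator=self.ld_estimator)
        dist = distance_matrix(ldm)
        clusterer = SNPClusterer(self.algorithm, eps=self.eps,
                                 min_samples=self.min_samples,
                                 min_cluster_size=self.min_cluster_size)
        self.labels_ = clusterer.fit(dist).labels_
        selected, summary = run_cluster_gwas(
            ds, self.labels_, min_hap_freq=self.min_hap_freq, mode=self.mode,
            alpha=self.alpha, threshold=self.threshold,
            max_enum=self.max_enum, max_block=self.max_block)
        self.selected_ = selected
        self.results_ = results_frame(selected, ds.variants)
        self.summary_ = summary
        self.significant_clusters_ = np.array(
            [r.cluster_id for r in selected if r.significant], dtype=int)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_
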