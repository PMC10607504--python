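"""Result-set algebra, overlap probability and interval annotation.

Utilities for comparing significant-variant lists across methods: the
hypergeometric probability that independently drawn significant sets overlap,
pairwise/full set intersections, rank-sum comparison of block-size
distributions, and coordinate-overlap gene annotation against BED intervals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu


def overlap_probability(N: int, k: int, K: int) -> float:
    """P(at least one of k randomly drawn items falls in a marked subset of K).

    The hypergeometric complement 1 - C(N-K, k) / C(N, k), evaluated in log
    space: 1 - prod_{i=0}^{k-1} (N-K-i) / (N-i).
    """
    if not (0 <= k <= N and 0 <= K <= N):
        raise ValueError("need 0 <= k, K <= N")
    if K == 0 or k == 0:
        return 0.0
    if k + K > N:
        return 1.0
    i = np.arange(k)
    log_miss = np.log(N - K - i) - np.log(N - i)
    return float(1.0 - math.exp(log_miss.sum()))


def intersect_sets(result_sets: dict[str, set]) -> pd.DataFrame:
    """Census of all pairwise and the full intersection, plus the union.

    Returns a DataFrame with one row per combination (deterministic order)
    and a membership table in ``attrs["membership"]``.
    """
    names = sorted(result_sets)
    rows = []
    for a, b in itertools.combinations(names, 2):
        rows.append({"sets": f"{a}&{b}",
                     "count": len(result_sets[a] & result_sets[b])})
    if names:
        full = set.intersection(*(set(result_sets[n]) for n in names))
        union = set.union(*(set(result_sets[n]) for n in names))
        rows.append({"sets": "&".join(names), "count": len(full)})
        rows.append({"sets": "union", "count": len(union)})
    df = pd.DataFrame(rows)
    members = sorted(union) if names else []
    membership = pd.DataFrame(
        {n: [m in result_sets[n] for m in members] for n in names},
        index=members)
    df.attrs["membership"] = membership
    return df


def compare_size_distributions(sizes_a, sizes_b):
    """Two-sided Mann-Whitney U (tie-corrected) between two size samples."""
    sizes_a, sizes_b = np.asarray(sizes_a), np.asarray(sizes_b)
    if len(sizes_a) == 0 or len(sizes_b) == 0:
        raise ValueError("both samples must be non-empty")
    res = mannwhitneyu(sizes_a, sizes_b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def annotate_with_intervals(variants: pd.DataFrame, bed) -> pd.DataFrame:
    """Assign each variant every overlapping BED interval.

    BED is 0-based half-open; variant positions are 1-based, so a variant at
    1-based position p overlaps [start, end) iff start <= p - 1 < end.
    Variants with no overlap are labelled ``intergenic``.  ``bed`` is a path
    or a DataFrame with columns (chrom, start, end[, name]).
    """
    if not isinstance(bed, pd.DataFrame):
        bed = pd.read_csv(bed, sep="\t", header=None, comment="#")
        if bed.shape[1] < 3:
            raise ValueError("malformed BED: fewer than 3 columns")
        bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed.iloc[:, :3]
        bed.columns = ["chrom", "start", "end", "name"][: bed.shape[1]]
    if "name" not in bed.columns:
        bed = bed.assign(name=[f"iv{i}" for i in range(len(bed))])
    if (bed["start"] > bed["end"]).any():
        raise ValueError("malformed BED: start > end")
    rows = []
    for _, v in variants.iterrows():
        p0 = v["pos"] - 1  # 0-based coordinate of the variant
        hits = bed[(bed["chrom"].astype(str) == str(v["chrom"]))
                   & (bed["start"] <= p0) & (p0 < bed["end"])]
        if len(hits):
            for name in hits["name"]:
                rows.append({"variant_id": v["id"], "feature": name})
        else:
            rows.append({"variant_id": v["id"], "feature": "intergenic"})
    return pd.DataFrame(rows)
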