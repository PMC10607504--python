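"""Single-variant case-control association tests.

Implements the classic GWAS battery: allelic 2x2 chi-square, genotypic (2x3),
dominant and recessive collapses, the Cochran-Armitage trend test, Fisher's
exact alternatives, and an additive-dosage logistic regression scan.  No
continuity corrections are applied anywhere.  The counted allele a1 is the
dataset-wide minor allele, so the dominant model groups carriers of a1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from sklearn.base import BaseEstimator

from .datasets import GenotypeDataset, genotype_counts

GENOME_WIDE_THRESHOLD = 5e-8


@dataclass
class VariantTestResult:
    model: str
    statistic: float
    df: int
    p_unadjusted: float
    odds_ratio: float = np.nan
    testable: bool = True
    p_adjusted: float | None = None


def _chi2_2x2(table: np.ndarray):
    """Pearson chi-square on a 2x2 table: N(ad-bc)^2 / (r1 r2 c1 c2)."""
    a, b = table[0]
    c, d = table[1]
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return np.nan, np.nan
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2_dist.sf(stat, 1))


def allelic_test(case_alleles, control_alleles) -> VariantTestResult:
    """Allele-frequency 2x2 chi-square with the cross-product odds ratio.

    ``case_alleles`` and ``control_alleles`` are (a1_count, a2_count) pairs.
    """
    table = np.array([case_alleles, control_alleles], dtype=float)
    stat, p = _chi2_2x2(table)
    if np.isnan(stat):
        return VariantTestResult("allelic", np.nan, 1, np.nan, testable=False)
    a, b = table[0]
    c, d = table[1]
    orr = (a * d) / (b * c) if b * c > 0 else np.inf
    return VariantTestResult("allelic", stat, 1, p, odds_ratio=orr)


def genotypic_test(table: np.ndarray) -> VariantTestResult:
    """Chi-square of independence on the 2x3 genotype table (case/control x
    a1a1, a1a2, a2a2).  All-empty genotype columns are dropped with a
    corresponding df reduction."""
    table = np.asarray(table, dtype=float)
    nonzero = table.sum(axis=0) > 0
    t = table[:, nonzero]
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return VariantTestResult("genotypic", np.nan, 2, np.nan, testable=False)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    exp = row @ col / t.sum()
    stat = float(((t - exp) ** 2 / exp).sum())
    df = t.shape[1] - 1
    return VariantTestResult("genotypic", stat, df, float(chi2_dist.sf(stat, df)))


def dominant_test(table: np.ndarray) -> VariantTestResult:
    """Carriers of a1 (a1a1 + a1a2) versus a2a2, 2x2 chi-square."""
    t = np.asarray(table, dtype=float)
    collapsed = np.column_stack([t[:, 0] + t[:, 1], t[:, 2]])
    stat, p = _chi2_2x2(collapsed)
    if np.isnan(stat):
        return VariantTestResult("dominant", np.nan, 1, np.nan, testable=False)
    return VariantTestResult("dominant", stat, 1, p)


def recessive_test(table: np.ndarray) -> VariantTestResult:
    """a1a1 versus carriers of a2 (a1a2 + a2a2), 2x2 chi-square."""
    t = np.asarray(table, dtype=float)
    collapsed = np.column_stack([t[:, 0], t[:, 1] + t[:, 2]])
    stat, p = _chi2_2x2(collapsed)
    if np.isnan(stat):
        return VariantTestResult("recessive", np.nan, 1, np.nan, testable=False)
    return VariantTestResult("recessive", stat, 1, p)


def trend_test(table: np.ndarray) -> VariantTestResult:
    """Cochran-Armitage trend test with additive weights (2, 1, 0 copies of a1)."""
    t = np.asarray(table, dtype=float)
    w = np.array([2.0, 1.0, 0.0])
    r = t[0]           # case counts per genotype
    n = t.sum(axis=0)  # genotype totals
    N = n.sum()
    R = r.sum()
    if N == 0 or R == 0 or R == N:
        return VariantTestResult("trend", np.nan, 1, np.nan, testable=False)
    num = N * (N * (w * r).sum() - R * (w * n).sum()) ** 2
    den = R * (N - R) * (N * (w * w * n).sum() - ((w * n).sum()) ** 2)
    if den == 0:
        return VariantTestResult("trend", np.nan, 1, np.nan, testable=False)
    stat = float(num / den)
    return VariantTestResult("trend", stat, 1, float(chi2_dist.sf(stat, 1)))


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by the point-probability method."""
    from scipy.stats import hypergeom

    a, b = table[0]
    c, d = table[1]
    n = int(a + b + c + d)
    r1, c1 = int(a + b), int(a + c)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    probs = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(int(a), n, r1, c1)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-9)].sum()))


def logistic_scan(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-variant additive logistic regression (Wald test on the dosage term).

    Non-converging fits (e.g. perfect separation) are flagged and their
    p-values omitted.
    """
    import statsmodels.api as sm

    mask = ds.phenotype >= 0
    y = ds.phenotype[mask].astype(float)
    rows = []
    for j in range(ds.n_variants):
        x = sm.add_constant(ds.dosages[mask, j].astype(float))
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, x).fit(disp=0, maxiter=100)
            beta = fit.params[1]
            separated = not fit.mle_retvals.get("converged", True) or abs(beta) > 15
            rows.append({
                "id": ds.variants["id"].iat[j],
                "beta": beta, "odds_ratio": np.exp(beta),
                "p_unadjusted": np.nan if separated else fit.pvalues[1],
                "converged": not separated,
            })
        except Exception:
            rows.append({"id": ds.variants["id"].iat[j], "beta": np.nan,
                         "odds_ratio": np.nan, "p_unadjusted": np.nan,
                         "converged": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Vectorized genome scan
# ---------------------------------------------------------------------------

def _tables_from_dataset(ds: GenotypeDataset):
    case = genotype_counts(ds, ds.case_mask).astype(float)    # (m,3): a1a1,a1a2,a2a2
    ctrl = genotype_counts(ds, ds.control_mask).astype(float)
    return case, ctrl


def _vector_chi2_2x2(a, b, c, d):
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, np.nan)
    return stat


def gwas_scan(ds: GenotypeDataset,
              models=("allelic", "genotypic", "dominant", "recessive", "trend"),
              alpha: float = 0.05, mode: str = "bonferroni",
              threshold: float = GENOME_WIDE_THRESHOLD):
    """Run the requested single-variant models over every variant.

    Returns ``(results, significant)``: a long-format DataFrame with one row
    per variant x model, and a dict of per-model significant variant-id sets
    (Bonferroni-adjusted p < alpha in ``"bonferroni"`` mode, unadjusted
    p < ``threshold`` in ``"fixed"`` mode).
    """
    case, ctrl = _tables_from_dataset(ds)
    m = ds.n_variants
    ids = ds.variants["id"].to_numpy()
    frames = []

    def add(model, stat, df, orr=None):
        with np.errstate(invalid="ignore"):
            p = chi2_dist.sf(stat, df)
        frames.append(pd.DataFrame({
            "id": ids, "model": model, "statistic": stat,
            "df": df, "p_unadjusted": p,
            "odds_ratio": orr if orr is not None else np.nan,
        }))

    if "allelic" in models:
        a = 2 * case[:, 0] + case[:, 1]
        b = 2 * case[:, 2] + case[:, 1]
        c = 2 * ctrl[:, 0] + ctrl[:, 1]
        d = 2 * ctrl[:, 2] + ctrl[:, 1]
        stat = _vector_chi2_2x2(a, b, c, d)
        with np.errstate(invalid="ignore", divide="ignore"):
            orr = np.where(b * c > 0, a * d / (b * c), np.inf)
        add("allelic", stat, 1, orr)
    if "genotypic" in models:
        stat = np.full(m, np.nan)
        dfs = np.full(m, 2)
        for j in range(m):
            res = genotypic_test(np.vstack([case[j], ctrl[j]]))
            stat[j], dfs[j] = res.statistic, res.df
        with np.errstate(invalid="ignore"):
            p = chi2_dist.sf(stat, dfs)
        frames.append(pd.DataFrame({"id": ids, "model": "genotypic",
                                    "statistic": stat, "df": dfs,
                                    "p_unadjusted": p, "odds_ratio": np.nan}))
    if "dominant" in models:
        stat = _vector_chi2_2x2(case[:, 0] + case[:, 1], case[:, 2],
                                ctrl[:, 0] + ctrl[:, 1], ctrl[:, 2])
        add("dominant", stat, 1)
    if "recessive" in models:
        stat = _vector_chi2_2x2(case[:, 0], case[:, 1] + case[:, 2],
                                ctrl[:, 0], ctrl[:, 1] + ctrl[:, 2])
        add("recessive", stat, 1)
    if "trend" in models:
        w = np.array([2.0, 1.0, 0.0])
        r = case
        n = case + ctrl
        N = n.sum(axis=1)
        R = r.sum(axis=1)
        num = N * (N * (r @ w) - R * (n @ w)) ** 2
        den = R * (N - R) * (N * (n @ (w * w)) - (n @ w) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(den > 0, num / den, np.nan)
        add("trend", stat, 1)
    if "logistic" in models:
        lg = logistic_scan(ds)
        frames.append(pd.DataFrame({
            "id": lg["id"], "model": "logistic",
            "statistic": np.nan, "df": 1,
            "p_unadjusted": lg["p_unadjusted"], "odds_ratio": lg["odds_ratio"],
        }))

    results = pd.concat(frames, ignore_index=True)
    results["p_adjusted"] = np.minimum(results["p_unadjusted"] * m, 1.0)
    if mode == "bonferroni":
        results["significant"] = results["p_adjusted"] < alpha
    elif mode == "fixed":
        results["significant"] = results["p_unadjusted"] < threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    significant = {
        model: set(sub.loc[sub["significant"], "id"])
        for model, sub in results.groupby("model")
    }
    return results, significant


class SingleVariantGWAS(BaseEstimator):
    """Estimator wrapper for the classic single-variant GWAS battery.

    fit(X, y) accepts a dosage matrix (or :class:`GenotypeDataset`) and
    case/control labels, and exposes ``results_`` (per variant x model) and
    ``significant_`` (per-model significant id sets).
    """

    def __init__(self, models=("allelic", "genotypic", "dominant",
                               "recessive", "trend"),
                 alpha=0.05, mode="bonferroni", threshold=GENOME_WIDE_THRESHOLD):
        self.models = models
        self.alpha = alpha
        self.mode = mode
        self.threshold = threshold

    def fit(self, X, y=None):
        if isinstance(X, GenotypeDataset):
            ds = X
            if y is not None:
                ds = GenotypeDataset(ds.variants.copy(), list(ds.samples),
                                     ds.dosages.copy(), np.asarray(y, dtype=np.int8))
        else:
            X = np.asarray(X, dtype=np.int8)
            variants = pd.DataFrame({
                "id": [f"v{j}" for j in range(X.shape[1])], "chrom": "1",
                "pos": np.arange(1, X.shape[1] + 1), "a1": "A", "a2": "G",
            })
            ds = GenotypeDataset(variants, [f"s{i}" for i in range(X.shape[0])],
                                 X, np.asarray(y, dtype=np.int8))
        self.results_, self.significant_ = gwas_scan(
            ds, models=self.models, alpha=self.alpha,
            mode=self.mode, threshold=self.threshold)
        return self
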