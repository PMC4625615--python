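"""RNA-Seq normalization and differential expression.

Count matrices are normalized between samples by TMM (trimmed mean of
M-values) or the median-of-ratios size factors, log-transformed to
prior-count log-CPM, and tested gene-by-gene with an empirical-Bayes
moderated t-statistic (Smyth-style variance shrinkage via trigamma
inversion). Microarray-style data enters the same moderated-t engine
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "GroupLabels",
    "tmm_factors",
    "median_ratio_factors",
    "normalize_log",
    "moderated_t",
    "select_deg",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values tagged as raw counts or normalized."""

    values: pd.DataFrame  # rows = genes, columns = samples
    kind: str  # "counts" | "normalized"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "normalized"):
            raise ValueError(f"kind must be 'counts' or 'normalized', got {self.kind!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample names")
        if self.kind == "counts":
            arr = self.values.to_numpy()
            if (arr < 0).any():
                g, s = np.argwhere(arr < 0)[0]
                raise ValueError(
                    f"negative count at gene {self.values.index[g]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )
            if not np.allclose(arr, np.round(arr)):
                g, s = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValueError(
                    f"non-integer count at gene {self.values.index[g]!r}, "
                    f"sample {self.values.columns[s]!r}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GroupLabels:
    """Two-level sample grouping with a designated reference level."""

    labels: pd.Series  # index = sample names
    reference: str = ""

    def __post_init__(self) -> None:
        levels = list(dict.fromkeys(self.labels))
        if len(levels) != 2:
            raise ValueError(f"exactly two group levels required, got {levels}")
        if not self.reference:
            self.reference = levels[0]
        if self.reference not in levels:
            raise ValueError(f"reference level {self.reference!r} not among {levels}")
        for lev in levels:
            if (self.labels == lev).sum() < 2:
                raise ValueError(f"group {lev!r} has fewer than 2 samples")

    @property
    def levels(self) -> tuple[str, str]:
        other = next(l for l in dict.fromkeys(self.labels) if l != self.reference)
        return (self.reference, other)

    def masks(self, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
        lab = self.labels.reindex(samples)
        if lab.isna().any():
            missing = list(lab.index[lab.isna()])
            raise ValueError(f"samples without group label: {missing}")
        ref, other = self.levels
        return (lab == ref).to_numpy(), (lab == other).to_numpy()


# ---------------------------------------------------------------------------
# between-sample normalization
# ---------------------------------------------------------------------------


def tmm_factors(counts: ExpressionMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the column whose upper quartile of library-size-
    scaled counts is closest to the mean upper quartile. For each sample,
    over genes positive in both it and the reference, M is the log2 ratio of
    scaled proportions and A the average log2 proportion; the most extreme
    30 % of M (each tail) and 5 % of A are dropped and the factor is
    2^(weighted mean of the surviving M), weighted by inverse asymptotic
    binomial variances.
    """
    if counts.kind != "counts":
        raise ValueError("tmm_factors requires raw counts")
    y = counts.values.to_numpy(dtype=float)
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    uq = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    f = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref:
            continue
        f[j] = _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref],
                         counts.samples[j], trim_m, trim_a)
    logf = np.log2(f)
    f = 2 ** (logf - logf.mean())  # rescale to geometric mean 1
    return pd.Series(f, index=counts.samples, name="tmm_factor")


def _tmm_pair(obs, ref, n_obs, n_ref, sample_name, trim_m, trim_a) -> float:
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError(f"sample {sample_name!r} shares no positive gene with the reference")
    o, r = obs[pos], ref[pos]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    return float(2 ** (np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])))


def median_ratio_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors: s_j = median_g count_gj / geomean_g,
    over genes positive in every sample."""
    if counts.kind != "counts":
        raise ValueError("median_ratio_factors requires raw counts")
    y = counts.values.to_numpy(dtype=float)
    all_pos = (y > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError("no gene has positive counts in all samples")
    yp = y[all_pos]
    log_geomean = np.log(yp).mean(axis=1)
    s = np.exp(np.median(np.log(yp) - log_geomean[:, None], axis=0))
    return pd.Series(s, index=counts.samples, name="size_factor")


def normalize_log(
    counts: ExpressionMatrix, factors: pd.Series, prior: float = 0.5
) -> ExpressionMatrix:
    """Prior-count log2-CPM.

    With effective library size S_j = libsize_j * factor_j, the value is
    log2(count / S_j * 1e6 + prior): counts per million on the effective
    library, with the pseudo-count added on the CPM scale. This keeps zero
    counts finite and makes the transform exactly invariant to a global
    rescaling of counts and library sizes.
    """
    if counts.kind != "counts":
        raise ValueError("normalize_log requires raw counts")
    fac = factors.reindex(counts.samples).to_numpy(dtype=float)
    if np.isnan(fac).any() or (fac <= 0).any():
        raise ValueError("normalization factors must be positive and cover all samples")
    y = counts.values.to_numpy(dtype=float)
    eff = y.sum(axis=0) * fac
    vals = np.log2(y / eff[None, :] * 1e6 + prior)
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.genes, columns=counts.samples), kind="normalized"
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on a log-convex scale)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F prior to observed variances: returns (d0, s0^2).

    Uses the log-variance representation: e = log(s2) has mean
    log(s0^2) + digamma(d0/2) - log(d0/2) + [digamma(df/2) - log(df/2)] shifts
    and excess variance trigamma(d0/2) beyond trigamma(df/2).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    e = np.log(s2[ok]) - special.digamma(df / 2) + np.log(df / 2)
    e_bar = e.mean()
    e_var = e.var(ddof=1) * (ok.sum() - 1) / ok.sum()
    excess = e_var - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = np.inf
        s0sq = float(np.exp(e_bar))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0sq = float(np.exp(e_bar + special.digamma(d0 / 2) - np.log(d0 / 2)))
    return d0, s0sq


def moderated_t(
    expr: ExpressionMatrix,
    groups: GroupLabels,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test per gene.

    Residual variances are shrunk toward a common prior fitted by moment
    matching of log sample variances against a scaled-F distribution
    (closed form via trigamma inversion). The returned table has one row
    per gene: logFC (non-reference minus reference group mean), t, p
    (two-sided, d0 + df degrees of freedom) and BH-adjusted p.

    ``d0_override`` forces the prior degrees of freedom: 0 recovers the
    ordinary t-test, ``numpy.inf`` the fully pooled (z-like) test.
    """
    if expr.kind != "normalized":
        raise ValueError("moderated_t requires normalized expression values")
    stat = moderated_t_stats(
        expr.values.to_numpy(dtype=float), *groups.masks(expr.samples), d0_override
    )
    logfc, t, df_total = stat
    p = 2 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"logFC": logfc, "t": t, "p": p, "adj_p": adj}, index=expr.genes
    )


def moderated_t_stats(
    values: np.ndarray,
    mask1: np.ndarray,
    mask2: np.ndarray,
    d0_override: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core of :func:`moderated_t` on a raw array.

    mask1 = reference group columns. Returns (logFC, t, total df) arrays.
    """
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    x1, x2 = values[:, mask1], values[:, mask2]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    rss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = rss / df
    if d0_override is None:
        d0, s0sq = fit_f_dist(s2, df)
    elif np.isinf(d0_override):
        d0, s0sq = np.inf, float(np.median(s2[s2 > 0])) if (s2 > 0).any() else 1.0
    else:
        d0, s0sq = float(d0_override), 0.0
        if d0 > 0:
            _, s0sq = fit_f_dist(s2, df)
    if np.isinf(d0):
        post = np.full_like(s2, s0sq)
        df_total = np.full_like(s2, np.inf)
    else:
        post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = np.full_like(s2, d0 + df)
    logfc = m2 - m1
    denom = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, logfc / denom, 0.0)
    return logfc, t, df_total


def select_deg(
    table: pd.DataFrame, p_threshold: float = 0.05, lfc_threshold: float = 2.0
) -> pd.Series:
    """Differentially expressed genes: p < p_threshold and |logFC| > lfc_threshold.

    Returns the logFC values of selected genes indexed by gene id
    (the per-gene expression-change vector fed to SPIA/PRS).
    """
    if p_threshold < 0 or lfc_threshold < 0:
        raise ValueError("thresholds must be non-negative")
    if table.empty:
        return pd.Series(dtype=float, name="logFC")
    mask = (table["p"] < p_threshold) & (table["logFC"].abs() > lfc_threshold)
    return table.loc[mask, "logFC"]
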