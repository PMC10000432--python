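"""Gene-wise factorial linear models with empirical-Bayes moderation.

The pipeline starts from a summarised log2 gene x sample matrix:
quantile normalisation, a non-specific interquartile-range filter
(with a panel override keeping the Ca2+-transport genes regardless of
variability), a per-gene least-squares fit of

    log2 expression ~ line + treatment + line:treatment + day

with day as a blocking factor, empirical-Bayes shrinkage of the
residual variances toward a common prior (scaled-F moment matching on
log variances, as in the moderated-t approach of microarray linear
modelling), and Benjamini-Hochberg FDR per contrast.

Sign conventions: line logFC is HT29 minus NCM460; treatment logFC is
DFMO minus control (reported within each cell line); the interaction
is the difference of the two treatment effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.special import digamma, polygamma

CONTRASTS = ("line", "treatment_NCM460", "treatment_HT29", "interaction")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; tied
    values within a column share the mean reference value of their tied
    ranks.  Idempotent.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if matrix.isna().any().any():
        raise ValueError("missing values are not supported (no imputation)")
    values = matrix.to_numpy(float)
    order = np.sort(values, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        ranks = sps.rankdata(col, method="average")  # 1-based, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, len(col) + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def iqr_filter(
    matrix: pd.DataFrame, panel_genes: list[str] | None = None
) -> tuple[pd.DataFrame, dict]:
    """Keep genes whose IQR exceeds the median IQR; panel genes always stay.

    The threshold is strict (IQR > median of all IQRs), so when all
    genes share the same IQR only panel genes survive.
    """
    if matrix.empty:
        raise ValueError("empty expression matrix")
    iqr = matrix.quantile(0.75, axis=1) - matrix.quantile(0.25, axis=1)
    threshold = float(iqr.median())
    keep_var = iqr > threshold
    panel_set = set(panel_genes or [])
    keep_panel = matrix.index.to_series().isin(panel_set)
    keep = keep_var | keep_panel
    report = {
        "n_input": int(matrix.shape[0]),
        "n_kept": int(keep.sum()),
        "n_dropped": int((~keep).sum()),
        "n_panel_rescued": int((keep_panel & ~keep_var).sum()),
        "iqr_threshold": threshold,
    }
    return matrix.loc[keep], report


# ---------------------------------------------------------------------------
# gene-wise linear models
# ---------------------------------------------------------------------------


@dataclass
class GeneFits:
    """Per-gene OLS results for the factorial + day-block model."""

    genes: pd.Index
    coef: pd.DataFrame  # genes x contrasts (log2 units)
    stdev_unscaled: pd.Series  # per-contrast unscaled SE multipliers
    s2: np.ndarray  # per-gene residual variances
    df_resid: float
    n_samples: int


def _build_design(sheet: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    line = (sheet["line"] == "HT29").to_numpy(float)
    treat = (sheet["treatment"] == "DFMO").to_numpy(float)
    cols = [np.ones(len(sheet)), line, treat, line * treat]
    names = ["Intercept", "line", "treatment", "interaction"]
    days = pd.Categorical(sheet["day"])
    for level in days.categories[1:]:
        cols.append((days == level).astype(float))
        names.append(f"day[{level}]")
    X = np.column_stack(cols)
    return X, names


#: contrast rows in terms of (Intercept, line, treatment, interaction)
_CONTRAST_VECTORS = {
    "line": np.array([0.0, 1.0, 0.0, 0.0]),
    "treatment_NCM460": np.array([0.0, 0.0, 1.0, 0.0]),
    "treatment_HT29": np.array([0.0, 0.0, 1.0, 1.0]),
    "interaction": np.array([0.0, 0.0, 0.0, 1.0]),
}


def fit_gene_linear_models(matrix: pd.DataFrame, sheet: pd.DataFrame) -> GeneFits:
    """Least-squares fit of the factorial + day model for every gene.

    ``sheet`` must contain one row per matrix column (sample_id, line,
    treatment, day).  Returns contrast estimates, the per-gene residual
    variance ``s2`` with its degrees of freedom, and the design-based
    unscaled standard errors of each contrast.
    """
    sheet = sheet.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    X, names = _build_design(sheet)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("rank-deficient design: line/treatment/day columns are confounded")
    df_resid = float(n - p)
    if df_resid < 1:
        raise ValueError("design leaves no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    Y = matrix.to_numpy(float)
    beta = Y @ (X @ xtx_inv)  # genes x p
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_resid

    pad = np.zeros((p, len(CONTRASTS)))
    for k, name in enumerate(CONTRASTS):
        pad[:4, k] = _CONTRAST_VECTORS[name]
    coef = pd.DataFrame(beta @ pad, index=matrix.index, columns=list(CONTRASTS))
    stdev_unscaled = pd.Series(
        {name: float(np.sqrt(pad[:, k].T @ xtx_inv @ pad[:, k]))
         for k, name in enumerate(CONTRASTS)}
    )
    return GeneFits(
        genes=matrix.index,
        coef=coef,
        stdev_unscaled=stdev_unscaled,
        s2=s2,
        df_resid=df_resid,
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# empirical-Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float, tol: float = 1e-8, maxiter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on a log-convex scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(maxiter):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif / y) < tol:
            break
    return float(y)


@dataclass
class ModeratedFits:
    """Moderated statistics for every gene and contrast."""

    coef: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    se: pd.DataFrame
    s2_post: np.ndarray
    d0: float
    s0_sq: float
    df_total: float
    df_resid: float


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match log residual variances to a scaled-F model.

    Returns the prior degrees of freedom ``d0`` (may be inf when the
    observed variances are no more dispersed than chi-square sampling
    alone explains) and the prior variance ``s0^2``.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 10:
        raise ValueError("need >= 10 genes with positive residual variance")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = float(e.mean())
    n = e.size
    target = float(((e - e_bar) ** 2).sum() / (n - 1) * n / (n - 1)) - float(
        polygamma(1, df / 2.0)
    )
    if target <= 0:
        warnings.warn("variances underdispersed; using d0 = inf", RuntimeWarning)
        d0 = np.inf
        s0_sq = float(np.exp(e_bar))
    else:
        d0 = 2.0 * _trigamma_inverse(target)
        s0_sq = float(np.exp(e_bar + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def ebayes_moderate(fits: GeneFits, d0: float | None = None,
                    s0_sq: float | None = None) -> ModeratedFits:
    """Moderated t-statistics via shrinkage of the residual variances.

    The posterior variance is ``(d0*s0^2 + d*s2) / (d0 + d)``; the
    moderated t refers to ``d0 + d`` degrees of freedom (the standard
    normal when ``d0`` is infinite).  Passing ``d0 = 0`` recovers the
    ordinary t exactly.
    """
    if d0 is None or s0_sq is None:
        d0, s0_sq = estimate_variance_prior(fits.s2, fits.df_resid)
    d = fits.df_resid
    if np.isinf(d0):
        s2_post = np.full_like(fits.s2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s2_post = fits.s2.copy()
        df_total = d
    else:
        s2_post = (d0 * s0_sq + d * fits.s2) / (d0 + d)
        df_total = d0 + d
    se = np.sqrt(s2_post)[:, None] * fits.stdev_unscaled.to_numpy()[None, :]
    t = fits.coef.to_numpy() / se
    if np.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df_total)
    return ModeratedFits(
        coef=fits.coef.copy(),
        t=pd.DataFrame(t, index=fits.genes, columns=list(CONTRASTS)),
        p=pd.DataFrame(p, index=fits.genes, columns=list(CONTRASTS)),
        se=pd.DataFrame(se, index=fits.genes, columns=list(CONTRASTS)),
        s2_post=s2_post,
        d0=float(d0),
        s0_sq=float(s0_sq),
        df_total=float(df_total),
        df_resid=float(d),
    )


# ---------------------------------------------------------------------------
# multiple testing and result tables
# ---------------------------------------------------------------------------


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def make_contrast_tables(
    moderated: ModeratedFits,
    panel: pd.DataFrame | None = None,
    fdr: float = 0.05,
    level: float = 0.95,
) -> dict[str, pd.DataFrame]:
    """Per-contrast DE tables with logFC, CI, moderated t, p, q, flags.

    When a panel (gene/category table) is given, a ``category`` column
    is attached and rows are restricted to panel genes.
    """
    tables = {}
    for k, name in enumerate(CONTRASTS):
        logfc = moderated.coef[name]
        t = moderated.t[name]
        p = moderated.p[name]
        se_k = moderated.se[name]
        if np.isinf(moderated.df_total):
            crit = sps.norm.ppf(0.5 + level / 2)
        else:
            crit = sps.t.ppf(0.5 + level / 2, moderated.df_total)
        q = bh_fdr(p.to_numpy())
        table = pd.DataFrame(
            {
                "gene": moderated.coef.index,
                "logFC": logfc.to_numpy(),
                "CI_low": (logfc - crit * se_k).to_numpy(),
                "CI_high": (logfc + crit * se_k).to_numpy(),
                "t_mod": t.to_numpy(),
                "p": p.to_numpy(),
                "q": q,
            }
        ).set_index("gene")
        table["significant"] = table["q"] < fdr
        if panel is not None:
            cat = panel.set_index("gene")["category"]
            table = table.loc[table.index.intersection(cat.index)]
            table.insert(0, "category", cat.reindex(table.index))
        tables[name] = table
    return tables


def run_de(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    normalize: bool = True,
    filter_iqr: bool = True,
    fdr: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], ModeratedFits, dict]:
    """End-to-end DE: normalise -> filter -> fit -> moderate -> tables.

    Returns tables over ALL retained genes (not panel-restricted);
    restrict downstream via ``make_contrast_tables(..., panel=...)``.
    """
    report: dict = {}
    work = quantile_normalize(matrix) if normalize else matrix
    if filter_iqr:
        panel_genes = panel["gene"].tolist() if panel is not None else []
        work, filt_report = iqr_filter(work, panel_genes)
        report["filter"] = filt_report
    fits = fit_gene_linear_models(work, sheet)
    moderated = ebayes_moderate(fits)
    tables = make_contrast_tables(moderated, panel=None, fdr=fdr)
    report["d0"] = moderated.d0
    report["s0_sq"] = moderated.s0_sq
    return tables, moderated, report
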