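"""Sample-level quality control for expression matrices.

Samples are observations, genes variables.  The toolkit covers PCA
with retention of the leading components explaining at least 70% of
variance (PC70%), robust Mahalanobis outlier flagging within each
line x treatment class (minimum covariance determinant), Ward
hierarchical clustering on the retained components, and relative log
expression (RLE) summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.covariance import EmpiricalCovariance, MinCovDet


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x PCs
    variance_explained: np.ndarray  # fractions, descending, sums to 1
    n_retained: int  # smallest k with cumulative fraction >= threshold

    @property
    def retained(self) -> pd.DataFrame:
        return self.scores.iloc[:, : self.n_retained]


def pca_scores(matrix: pd.DataFrame, retain: float = 0.70) -> PCAResult:
    """PCA of samples on centred (unscaled) log2 expression.

    ``matrix`` is genes x samples; scores preserve the pairwise sample
    Euclidean distances when all components are kept.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    X = matrix.to_numpy(float).T  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    if not np.any(X):
        raise ValueError("constant matrix has no principal components")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    scores = u * s
    n_retained = int(np.searchsorted(np.cumsum(frac), retain) + 1)
    n_retained = min(n_retained, scores.shape[1])
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=cols),
        variance_explained=frac,
        n_retained=n_retained,
    )


def robust_outliers(
    scores: pd.DataFrame,
    class_labels: pd.Series | np.ndarray,
    coverage: float = 0.975,
    seed: int = 0,
) -> pd.DataFrame:
    """Robust Mahalanobis outlier flags within each class.

    Within each class the centre/scatter is the minimum covariance
    determinant estimate; a sample is flagged when its squared robust
    distance exceeds the chi-square quantile at ``coverage`` with
    df = number of score dimensions.  Classes too small for the MCD
    fall back to the classical estimator (with a warning).
    """
    labels = pd.Series(np.asarray(class_labels), index=scores.index)
    k = scores.shape[1]
    cutoff = sps.chi2.ppf(coverage, df=k)
    dist = pd.Series(np.nan, index=scores.index)
    estimator_used = pd.Series("", index=scores.index)
    for cls, idx in labels.groupby(labels).groups.items():
        sub = scores.loc[idx].to_numpy(float)
        n = sub.shape[0]
        if n > 2 * k and n >= 5:
            est = MinCovDet(random_state=seed).fit(sub)
            used = "mcd"
        else:
            warnings.warn(
                f"class {cls!r}: n={n} too small for MCD with {k} dims; "
                "using classical covariance",
                RuntimeWarning,
            )
            est = EmpiricalCovariance().fit(sub)
            used = "classical"
        dist.loc[idx] = est.mahalanobis(sub)
        estimator_used.loc[idx] = used
    return pd.DataFrame(
        {
            "class": labels,
            "sq_robust_distance": dist,
            "cutoff": cutoff,
            "outlier": dist > cutoff,
            "estimator": estimator_used,
        }
    )


@dataclass
class WardClustering:
    linkage_matrix: np.ndarray
    labels: pd.Series  # cluster assignment at the requested cut

    def cut(self, n_clusters: int) -> pd.Series:
        lab = fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return pd.Series(lab, index=self.labels.index)


def ward_clustering(scores: pd.DataFrame, n_clusters: int = 4) -> WardClustering:
    """Ward linkage on Euclidean distances over the given score columns."""
    if scores.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    Z = linkage(scores.to_numpy(float), method="ward", metric="euclidean")
    labels = pd.Series(
        fcluster(Z, t=n_clusters, criterion="maxclust"), index=scores.index
    )
    return WardClustering(linkage_matrix=Z, labels=labels)


def rle_stats(matrix: pd.DataFrame, flag_threshold: float = 0.1) -> pd.DataFrame:
    """Relative log expression per sample.

    RLE subtracts each gene's median across samples; per sample the
    median and IQR of the residuals are reported, and samples whose
    |median RLE| exceeds ``flag_threshold`` are flagged.
    """
    rle = matrix.sub(matrix.median(axis=1), axis=0)
    med = rle.median(axis=0)
    iqr = rle.quantile(0.75, axis=0) - rle.quantile(0.25, axis=0)
    return pd.DataFrame(
        {
            "rle_median": med,
            "rle_iqr": iqr,
            "flagged": med.abs() > flag_threshold,
        }
    )


def qc_report(
    matrix: pd.DataFrame,
    sheet: pd.DataFrame,
    retain: float = 0.70,
    coverage: float = 0.975,
    rle_threshold: float = 0.1,
    seed: int = 0,
) -> dict:
    """Run the full QC battery and return a serialisable report."""
    pca = pca_scores(matrix, retain=retain)
    classes = (
        sheet.set_index("sample_id")
        .loc[matrix.columns]
        .apply(lambda r: f"{r['line']}:{r['treatment']}", axis=1)
    )
    outliers = robust_outliers(pca.retained, classes, coverage=coverage, seed=seed)
    clustering = ward_clustering(pca.retained, n_clusters=classes.nunique())
    rle = rle_stats(matrix, flag_threshold=rle_threshold)
    return {
        "n_retained_pcs": pca.n_retained,
        "variance_explained": pca.variance_explained.tolist(),
        "outliers": outliers["outlier"].to_dict(),
        "clusters": clustering.labels.to_dict(),
        "rle_median": rle["rle_median"].to_dict(),
        "rle_flagged": rle["flagged"].to_dict(),
    }
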