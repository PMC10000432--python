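"""Relative quantification of qPCR data by the ddCt (Livak) method.

Threshold cycles are normalised against a housekeeping gene measured
in the same sample (dCt = Ct_gene - Ct_housekeeping; relative
abundance 2**(-dCt)), then compared between a test and a calibrator
group: ddCt = mean dCt(test) - mean dCt(calibrator).  The reported
log2 fold change is -ddCt, so 0 means no change, positive values mean
higher expression in the test group.  Group differences are tested by
a two-sample t-test on the dCt values with a Bonferroni correction
across the genes assayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

CT_COLUMNS = ["gene", "group", "sample", "replicate", "ct", "is_housekeeping"]


def delta_ct(table: pd.DataFrame, aggregate: str = "mean") -> pd.DataFrame:
    """Per-sample dCt for every target gene.

    Technical replicates are aggregated (mean by default, median by
    flag) before differencing against the housekeeping gene of the
    same sample.  Returns columns gene, group, sample, dct,
    rel_abundance (= 2**(-dct)).
    """
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if aggregate not in ("mean", "median"):
        raise ValueError("aggregate must be 'mean' or 'median'")
    agg = np.mean if aggregate == "mean" else np.median
    hk = table[table["is_housekeeping"]]
    if hk.empty:
        raise ValueError("no housekeeping rows in Ct table")
    hk_ct = hk.groupby(["group", "sample"])["ct"].agg(aggregate)
    rows = []
    targets = table[~table["is_housekeeping"]]
    for (gene, group, sample), sub in targets.groupby(["gene", "group", "sample"]):
        key = (group, sample)
        if key not in hk_ct.index:
            raise ValueError(f"housekeeping gene missing for sample {sample!r}")
        dct = float(agg(sub["ct"])) - float(hk_ct.loc[key])
        rows.append(
            {
                "gene": gene,
                "group": group,
                "sample": sample,
                "dct": dct,
                "rel_abundance": 2.0 ** (-dct),
            }
        )
    return pd.DataFrame(rows)


def ddct_fold_change(
    dct_test: np.ndarray, dct_calibrator: np.ndarray
) -> tuple[float, float]:
    """(ddCt, log2 fold change) between a test and a calibrator group.

    ``log2 fold = -ddCt``: the calibrator compared with itself gives
    exactly 0; a test group whose dCt is 2 cycles lower gives +2.
    """
    dct_test = np.asarray(dct_test, dtype=float)
    dct_calibrator = np.asarray(dct_calibrator, dtype=float)
    if dct_test.size == 0 or dct_calibrator.size == 0:
        raise ValueError("both groups must be non-empty")
    ddct = float(dct_test.mean() - dct_calibrator.mean())
    return ddct, -ddct


def ddct_test(
    dct_test: np.ndarray, dct_calibrator: np.ndarray, n_genes_tested: int = 1
) -> tuple[float, float]:
    """Two-sample t-test on dCt values with Bonferroni correction.

    The raw p is multiplied by the number of genes assayed in the same
    experiment and capped at 1.
    """
    dct_test = np.asarray(dct_test, dtype=float)
    dct_calibrator = np.asarray(dct_calibrator, dtype=float)
    if min(dct_test.size, dct_calibrator.size) < 2:
        raise ValueError("each group needs n >= 2")
    if n_genes_tested < 1:
        raise ValueError("n_genes_tested must be >= 1")
    # degenerate zero-variance groups: identical means are a certain
    # non-difference, distinct means an exact separation
    if np.var(dct_test) == 0.0 and np.var(dct_calibrator) == 0.0:
        p = 1.0 if dct_test.mean() == dct_calibrator.mean() else 0.0
    else:
        p = float(sps.ttest_ind(dct_test, dct_calibrator).pvalue)
    return p, min(1.0, p * n_genes_tested)


@dataclass
class QpcrResult:
    """Fold-change table across genes for one group comparison."""

    table: pd.DataFrame
    test_group: str
    calibrator_group: str


def analyze_qpcr(
    ct_table: pd.DataFrame,
    test_group: str,
    calibrator_group: str,
    aggregate: str = "mean",
) -> QpcrResult:
    """ddCt analysis of every target gene between two groups.

    The Bonferroni multiplier is the number of target genes in the
    table.  Output columns: gene, ddct, log2_fold, sem, p, p_adj.
    """
    dct = delta_ct(ct_table, aggregate=aggregate)
    genes = sorted(dct["gene"].unique())
    m = len(genes)
    rows = []
    for gene in genes:
        sub = dct[dct["gene"] == gene]
        test = sub.loc[sub["group"] == test_group, "dct"].to_numpy()
        calib = sub.loc[sub["group"] == calibrator_group, "dct"].to_numpy()
        ddct, log2_fold = ddct_fold_change(test, calib)
        sem = float(
            np.sqrt(
                np.var(test, ddof=1) / test.size
                + np.var(calib, ddof=1) / calib.size
            )
        ) if min(test.size, calib.size) > 1 else np.nan
        p, p_adj = ddct_test(test, calib, n_genes_tested=m)
        rows.append(
            {
                "gene": gene,
                "ddct": ddct,
                "log2_fold": log2_fold,
                "sem": sem,
                "p": p,
                "p_adj": p_adj,
            }
        )
    return QpcrResult(
        table=pd.DataFrame(rows).set_index("gene"),
        test_group=test_group,
        calibrator_group=calibrator_group,
    )
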