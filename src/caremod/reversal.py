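"""Cross-platform concordance calls and treatment-reversal classification.

Two independent technologies (e.g. RNA-seq and microarrays) each yield
a per-gene (q, logFC) pair for the cancer-vs-normal contrast.  The
combination rule declares a gene differentially expressed when

* at least one platform reaches q < 0.05, OR
* both platforms reach q < 0.10,

and in either case only if both platforms agree on the direction of
change.  Discordant signs veto the call; a gene measured on only one
platform is "insufficient" rather than "not DE".

A gene's cancer-associated change is *reversed* when the
cancer-vs-normal DE is significant, the treatment contrast within the
cancer line is significant, and the two effects have opposite signs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DECISIONS = ("DE_up", "DE_down", "not_DE", "insufficient")
BASES = ("single_0.05", "both_0.10", "both_0.05", "discordant_sign", "insufficient", "none")


def call_gene(
    q_a: float, logfc_a: float, q_b: float, logfc_b: float,
    alpha1: float = 0.05, alpha2: float = 0.10,
) -> tuple[str, str]:
    """Concordance decision for a single gene; returns (decision, basis)."""
    if alpha1 >= alpha2:
        raise ValueError("alpha1 must be < alpha2")
    if any(np.isnan(v) for v in (q_a, logfc_a, q_b, logfc_b)):
        return "insufficient", "insufficient"
    sign_a = np.sign(logfc_a)
    sign_b = np.sign(logfc_b)
    single = (q_a < alpha1) or (q_b < alpha1)
    both_strict = (q_a < alpha1) and (q_b < alpha1)
    both_loose = (q_a < alpha2) and (q_b < alpha2)
    if not (single or both_loose):
        return "not_DE", "none"
    if sign_a == 0 or sign_b == 0 or sign_a != sign_b:
        return "not_DE", "discordant_sign"
    basis = "both_0.05" if both_strict else ("single_0.05" if single else "both_0.10")
    return ("DE_up" if sign_a > 0 else "DE_down"), basis


def call_cross_platform_de(
    platform_a: pd.DataFrame,
    platform_b: pd.DataFrame,
    alpha1: float = 0.05,
    alpha2: float = 0.10,
) -> pd.DataFrame:
    """Apply the concordance rule over the union of both gene universes.

    Each platform table is indexed by gene with columns ``q`` and
    ``logFC``.  Genes present in only one platform are marked
    ``insufficient``.
    """
    if alpha1 >= alpha2:
        raise ValueError("alpha1 must be < alpha2")
    genes = platform_a.index.union(platform_b.index)
    a = platform_a.reindex(genes)
    b = platform_b.reindex(genes)
    rows = []
    for gene in genes:
        decision, basis = call_gene(
            float(a.loc[gene, "q"]) if not pd.isna(a.loc[gene, "q"]) else np.nan,
            float(a.loc[gene, "logFC"]) if not pd.isna(a.loc[gene, "logFC"]) else np.nan,
            float(b.loc[gene, "q"]) if not pd.isna(b.loc[gene, "q"]) else np.nan,
            float(b.loc[gene, "logFC"]) if not pd.isna(b.loc[gene, "logFC"]) else np.nan,
            alpha1,
            alpha2,
        )
        rows.append({"gene": gene, "decision": decision, "basis": basis})
    out = pd.DataFrame(rows).set_index("gene")
    out["logFC_a"] = a["logFC"]
    out["logFC_b"] = b["logFC"]
    out["q_a"] = a["q"]
    out["q_b"] = b["q"]
    return out


def classify_reversal(
    cancer_de: pd.DataFrame,
    treat_de_cancer: pd.DataFrame,
    alpha: float = 0.05,
    baseline_mode: str = "combined",
) -> pd.DataFrame:
    """Flag genes whose treatment effect undoes their cancer effect.

    Parameters
    ----------
    cancer_de : with ``baseline_mode="combined"``, a concordance-call
        table (``decision`` in DE_up/DE_down + logFC columns); with
        ``"microarray_only"``, a single-platform DE table indexed by
        gene with columns ``q`` and ``logFC``.
    treat_de_cancer : treatment contrast within the cancer line,
        indexed by gene with columns ``q`` and ``logFC``.
    """
    if baseline_mode not in ("combined", "microarray_only"):
        raise ValueError(f"unknown baseline_mode: {baseline_mode!r}")
    genes = cancer_de.index.intersection(treat_de_cancer.index)
    if baseline_mode == "combined":
        decision = cancer_de.loc[genes, "decision"]
        cancer_sig = decision.isin(["DE_up", "DE_down"])
        cancer_sign = decision.map({"DE_up": 1.0, "DE_down": -1.0}).fillna(0.0)
    else:
        cancer_sig = cancer_de.loc[genes, "q"] < alpha
        cancer_sign = np.sign(cancer_de.loc[genes, "logFC"]).where(cancer_sig, 0.0)
    treat_q = treat_de_cancer.loc[genes, "q"]
    treat_fc = treat_de_cancer.loc[genes, "logFC"]
    treat_sig = treat_q < alpha
    treat_sign = np.sign(treat_fc)
    reversed_flag = (
        cancer_sig
        & treat_sig
        & (cancer_sign != 0)
        & (treat_sign != 0)
        & (cancer_sign == -treat_sign)
    )
    return pd.DataFrame(
        {
            "cancer_sign": cancer_sign,
            "cancer_significant": cancer_sig,
            "treatment_sign": treat_sign,
            "treatment_significant": treat_sig,
            "reversed": reversed_flag,
            "baseline_mode": baseline_mode,
        },
        index=genes,
    )


def summarize_selectivity(
    treat_de_normal: pd.DataFrame,
    treat_de_cancer: pd.DataFrame,
    panel: pd.DataFrame,
    reversals: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> dict:
    """Counts of treatment-affected genes per line, total and panel-wise."""
    panel_genes = set(panel["gene"])
    def _counts(table: pd.DataFrame) -> tuple[int, int]:
        sig = table.index[table["q"] < alpha]
        return len(sig), len([g for g in sig if g in panel_genes])
    n_normal, n_normal_panel = _counts(treat_de_normal)
    n_cancer, n_cancer_panel = _counts(treat_de_cancer)
    summary = {
        "treatment_affected_normal": n_normal,
        "treatment_affected_cancer": n_cancer,
        "treatment_affected_normal_panel": n_normal_panel,
        "treatment_affected_cancer_panel": n_cancer_panel,
    }
    if reversals is not None:
        rev = reversals.index[reversals["reversed"]]
        summary["reversed_total"] = int(len(rev))
        summary["reversed_panel"] = int(len([g for g in rev if g in panel_genes]))
    return summary
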