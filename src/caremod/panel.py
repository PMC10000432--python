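"""Curated panel of genes involved in intracellular Ca2+ transport.

The panel covers 89 genes split into six functional clusters:
voltage-operated Ca2+ channels (VOCC), store-operated Ca2+ entry
machinery and its modulators (SOCE), transient receptor potential
channels (TRP), ER Ca2+ release channels, Ca2+ pumps and exchangers,
and mitochondrial Ca2+ transporters.  Channel-style aliases
(e.g. ``CAV1.2``, ``PMCA4``, ``TRPP2``) are used as gene labels.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

CATEGORIES = (
    "VOCC",
    "SOCE",
    "TRP",
    "release",
    "pump_exchanger",
    "mitochondrial",
)


def load_panel() -> pd.DataFrame:
    """Return the default Ca2+-transport gene panel.

    Returns
    -------
    DataFrame with columns ``gene`` (unique labels) and ``category``
    (one of :data:`CATEGORIES`).
    """
    ref = resources.files("caremod.data").joinpath("calcium_panel.tsv")
    with ref.open("r") as fh:
        panel = pd.read_csv(fh, sep="\t")
    return panel


def validate_panel(panel: pd.DataFrame) -> None:
    """Check panel structure: unique genes, known categories."""
    if panel["gene"].duplicated().any():
        dups = panel.loc[panel["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"duplicated panel genes: {dups}")
    unknown = set(panel["category"]) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown panel categories: {sorted(unknown)}")


def category_sizes(panel: pd.DataFrame | None = None) -> pd.Series:
    """Number of genes per functional cluster, in canonical order."""
    if panel is None:
        panel = load_panel()
    counts = panel["category"].value_counts()
    return counts.reindex(CATEGORIES).fillna(0).astype(int)
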