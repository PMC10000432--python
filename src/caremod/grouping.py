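"""Tukey pairwise comparisons and clique-based compact letter display.

Conditions that are not significantly different share a group letter.
The construction is graph-theoretic: build a similarity graph with an
edge between two conditions whenever their Tukey-adjusted p-value is
at least alpha, enumerate all maximal cliques (Bron-Kerbosch with
pivoting), order the cliques by the mean of their members' marginal
means, and assign letters a, b, c, ... in that order.  A condition
then carries the letters of every maximal clique containing it, so two
conditions share a letter iff they are co-members of some maximal
clique, i.e. iff they are connected in the similarity graph.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats as sps

from .mixed import MixedFit


def pairwise_contrasts(fit: MixedFit, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise condition differences with Tukey-adjusted p-values.

    The single-step adjustment refers |diff| / SE(diff) * sqrt(2) to the
    studentized-range distribution with k = number of conditions and the
    fit's containment degrees of freedom.  Raw p-values come from the
    two-sided t reference with the same df.
    """
    means = fit.means
    cov = fit.cov_means.to_numpy()
    conds = list(means.index)
    k = len(conds)
    if k < 2:
        raise ValueError("need >= 2 conditions")
    if not np.all(np.isfinite(cov)):
        raise ValueError("non-finite covariance of the marginal means")
    rows = []
    for i, j in combinations(range(k), 2):
        diff = float(means.iloc[j] - means.iloc[i])
        var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
        if var <= 0:
            raise ValueError("singular covariance for pair "
                             f"({conds[i]}, {conds[j]})")
        se = float(np.sqrt(var))
        tstat = diff / se
        p_raw = float(2 * sps.t.sf(abs(tstat), fit.df_contrast))
        q = abs(tstat) * np.sqrt(2.0)
        p_adj = float(sps.studentized_range.sf(q, k, fit.df_contrast))
        rows.append(
            {
                "cond_a": conds[j],
                "cond_b": conds[i],
                "comparison": f"{conds[j]} - {conds[i]}",
                "difference": diff,
                "se": se,
                "t": tstat,
                "p_raw": p_raw,
                "p_adj": min(1.0, p_adj),
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def build_similarity_graph(contrasts: pd.DataFrame, alpha: float = 0.05) -> nx.Graph:
    """Edge (i, j) iff the adjusted p-value of the pair is >= alpha."""
    conds = sorted(set(contrasts["cond_a"]) | set(contrasts["cond_b"]))
    expected = {frozenset(p) for p in combinations(conds, 2)}
    seen = {frozenset((a, b)) for a, b in zip(contrasts["cond_a"], contrasts["cond_b"])}
    if expected - seen:
        raise ValueError(f"incomplete contrast table; missing pairs: {expected - seen}")
    g = nx.Graph()
    g.add_nodes_from(conds)
    for _, row in contrasts.iterrows():
        if row["p_adj"] >= alpha:
            g.add_edge(row["cond_a"], row["cond_b"])
    return g


def bron_kerbosch(graph: nx.Graph) -> list[tuple]:
    """All maximal cliques via Bron-Kerbosch with pivoting.

    Every isolated node forms its own (singleton) maximal clique.
    Cliques are returned sorted internally and listed in canonical
    (lexicographic) order.
    """
    adj = {v: set(graph.neighbors(v)) for v in graph.nodes}
    cliques: list[tuple] = []

    def expand(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(tuple(sorted(r)))
            return
        pivot = max(p | x, key=lambda u: len(adj[u] & p))
        for v in list(p - adj[pivot]):
            expand(r | {v}, p & adj[v], x & adj[v])
            p.remove(v)
            x.add(v)

    expand(set(), set(adj), set())
    return sorted(cliques)


def assign_letters(cliques: list[tuple], means: pd.Series) -> pd.DataFrame:
    """Compact letter display from maximal cliques.

    Cliques are ordered by the ascending mean of their members'
    marginal means and lettered a, b, c, ... in that order; each
    condition collects the letters of all cliques containing it.
    """
    conds = list(means.index)
    covered = set().union(*map(set, cliques)) if cliques else set()
    missing = set(conds) - covered
    if missing:
        raise RuntimeError(f"conditions missing from every clique: {sorted(missing)}")
    order = sorted(cliques, key=lambda c: float(np.mean([means[v] for v in c])))
    letters = {c: "" for c in conds}
    for idx, clique in enumerate(order):
        letter = chr(ord("a") + idx)
        for cond in clique:
            letters[cond] += letter
    out = pd.DataFrame(
        {
            "condition": conds,
            "mean": [float(means[c]) for c in conds],
            "letters": [letters[c] for c in conds],
        }
    )
    return out


def letter_display(
    fit: MixedFit, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, list[tuple]]:
    """Full pipeline: contrasts -> similarity graph -> cliques -> letters."""
    contrasts = pairwise_contrasts(fit, alpha=alpha)
    graph = build_similarity_graph(contrasts, alpha=alpha)
    cliques = bron_kerbosch(graph)
    letters = assign_letters(cliques, fit.means)
    return letters, contrasts, cliques
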