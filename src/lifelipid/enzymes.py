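"""Enzyme-evolution analysis.

Enzymes are linked to lipid compounds; per enzyme and per phylogenetic
branch (long-living vs short-living lineage) a dN/dS value is supplied
as data.  Enzymes whose linked lipids are most enriched in MLS-predictor
compounds (top-quantile link proportion, tissue-specific cutoff) are the
*lifespan-related* set; their dN/dS distribution is compared against the
remaining lipid enzymes with a one-sided rank-sum test, and significant
functional terms form a shared-enzyme network.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .characterize import hypergeom_upper_p
from .datatypes import NONNEURAL_TISSUES

#: top-proportion quantile per tissue: 30% default, 25% heart, 35% non-neural
DEFAULT_Q = 0.30
TISSUE_Q = {"heart": 0.25, **{t: 0.35 for t in NONNEURAL_TISSUES}}


def _split(cell: str) -> list:
    return [x for x in str(cell).split(";") if x]


def link_proportions(table: pd.DataFrame, predictor_compounds) -> pd.Series:
    """Per enzyme: |links ∩ predictors| / |links|."""
    pred = set(predictor_compounds)
    props = {}
    for eid, row in table.iterrows():
        links = _split(row["linked_lipids"])
        if not links:
            continue
        props[eid] = len(pred.intersection(links)) / len(links)
    if not props:
        raise ValueError("empty enzyme link table")
    return pd.Series(props, name="predictor_proportion")


def tissue_quantile(tissue: str | None) -> float:
    """Selection quantile for a tissue (0.25 heart, 0.35 non-neural,
    else 0.30)."""
    if tissue is None:
        return DEFAULT_Q
    return TISSUE_Q.get(tissue, DEFAULT_Q)


def select_lifespan_enzymes(
    table: pd.DataFrame, predictor_compounds,
    tissue: str | None = None, q: float | None = None,
) -> list:
    """Enzymes at or above the (1−q) quantile of predictor-link proportion.

    Ties at the threshold are included.
    """
    q = tissue_quantile(tissue) if q is None else q
    props = link_proportions(table, predictor_compounds)
    thr = float(np.quantile(props.to_numpy(), 1.0 - q))
    return sorted(props.index[props >= thr])


def compare_dnds(
    table: pd.DataFrame, selected, branch: str = "long", background=None,
) -> dict:
    """One-sided rank-sum test: selected enzymes under stronger purifying
    selection (lower dN/dS) than the background on the chosen branch.

    ``background`` defaults to all other enzymes in the table.  Returns
    p, effect (median difference selected − background) and a
    significance star string (*, **, *** at 0.05/0.01/0.001).
    """
    col = {"long": "dnds_long", "short": "dnds_short"}[branch]
    selected = [e for e in selected if e in table.index]
    if background is None:
        background = table.index.difference(selected)
    else:
        background = pd.Index(background).difference(selected)
    if len(selected) == 0 or len(background) == 0:
        raise ValueError("both enzyme sets must be nonempty")
    x = table.loc[selected, col].to_numpy(dtype=float)
    y = table.loc[background, col].to_numpy(dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="less")
    effect = float(np.median(x) - np.median(y))
    p = float(res.pvalue)
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {"p": p, "effect": effect, "statistic": float(res.statistic),
            "stars": stars, "n_selected": len(selected),
            "n_background": len(background)}


def term_enrichment_network(
    table: pd.DataFrame, selected, alpha: float = 0.05,
    tissue_of: dict | None = None,
) -> tuple[pd.DataFrame, nx.Graph]:
    """Functional-term enrichment of the selected enzymes + shared-enzyme
    network.

    Per term, a hypergeometric upper-tail test of the selected set
    against all enzymes in the table.  Significant terms become nodes;
    an edge joins two terms when selected enzymes are annotated to both,
    weighted by the shared-enzyme count.  ``tissue_of`` optionally maps
    enzyme → tissue label(s) recorded on the nodes.
    """
    term_members: dict[str, set] = {}
    for eid, row in table.iterrows():
        for t in _split(row.get("terms", "")):
            term_members.setdefault(t, set()).add(eid)
    if not term_members:
        raise ValueError("no term annotations")
    selected = set(selected) & set(table.index)
    universe = len(table)
    rows = []
    for term, members in sorted(term_members.items()):
        k = len(members & selected)
        rows.append({"term_id": term, "overlap": k, "term_size": len(members),
                     "universe": universe, "n_selected": len(selected),
                     "p": hypergeom_upper_p(k, universe, len(members),
                                            len(selected))})
    res = pd.DataFrame(rows)
    res["significant"] = res["p"] < alpha

    g = nx.Graph()
    sig = res.loc[res["significant"], "term_id"].tolist()
    for term in sig:
        node_attrs = {"p": float(res.set_index("term_id").at[term, "p"])}
        if tissue_of:
            tissues = sorted({tissue_of[e] for e in term_members[term] & selected
                              if e in tissue_of})
            node_attrs["tissues"] = tissues
        g.add_node(term, **node_attrs)
    for i in range(len(sig)):
        for j in range(i + 1, len(sig)):
            shared = (term_members[sig[i]] & term_members[sig[j]] & selected)
            if shared:
                g.add_edge(sig[i], sig[j], weight=len(shared),
                           enzymes=sorted(shared))
    return res, g


def network_edges(g: nx.Graph) -> pd.DataFrame:
    """Edge list (term_a, term_b, weight) of the term network."""
    rows = [{"term_a": a, "term_b": b, "weight": d["weight"]}
            for a, b, d in g.edges(data=True)]
    return pd.DataFrame(rows, columns=["term_a", "term_b", "weight"])
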