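"""Over-representation analysis and confidence-filtered subnetworks.

ORA tests each gene set for enrichment in a foreground list against a
background universe with a one-sided Fisher exact test (hypergeometric
upper tail) and Benjamini-Hochberg adjustment across sets. Compartment
summaries are the same test run over subcellular-compartment gene sets.
Subnetwork extraction keeps interactions with experimental confidence
strictly above the cutoff among the proteins of interest.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from statsmodels.stats.multitest import multipletests


def ora(
    foreground: set,
    background: set,
    sets: dict[str, set],
) -> pd.DataFrame:
    """One-sided Fisher-exact over-representation of each gene set.

    2x2 counts per set: a = |foreground & set|, b = |foreground \\ set|,
    c = |background & set| - a, d = remainder. p is the hypergeometric
    upper tail P(X >= a); q is BH-adjusted across sets. Rows are sorted by
    (q, p).
    """
    foreground = set(foreground)
    background = set(background)
    if len(background) < 2:
        raise ValueError("background must contain >= 2 ids")
    stray = foreground - background
    if stray:
        raise ValueError(
            f"foreground not contained in background: {sorted(map(str, stray))[:5]}"
        )
    n_bg = len(background)
    n_fg = len(foreground)
    rows = []
    for name, members in sets.items():
        in_bg = set(members) & background
        a = len(foreground & in_bg)
        b = n_fg - a
        c = len(in_bg) - a
        d = n_bg - n_fg - c
        # hypergeometric upper tail: drawing n_fg from n_bg with len(in_bg)
        # successes, P(overlap >= a)
        p = float(stats.hypergeom.sf(a - 1, n_bg, len(in_bg), n_fg))
        p = min(p, 1.0)
        if b > 0 and c > 0:
            odds = (a * d) / (b * c)
        elif a == 0:
            odds = 0.0
        else:
            odds = np.inf
        rows.append(
            {"set_name": name, "a": a, "b": b, "c": c, "d": d,
             "odds_ratio": odds, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out = out.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    else:
        out["q"] = []
    return out


def compartment_summary(
    proteins: set, compartment_sets: dict[str, set], background: set | None = None
) -> pd.DataFrame:
    """Subcellular-compartment over-representation for a protein list.

    The background defaults to the union of all compartment annotations
    plus the query proteins (every quantified protein should appear in the
    universe).
    """
    proteins = set(proteins)
    if not proteins:
        raise ValueError("empty protein list")
    if background is None:
        background = set().union(*compartment_sets.values()) | proteins
    return ora(proteins, background, compartment_sets)


def subnetwork_extract(
    edges: pd.DataFrame,
    nodes_of_interest: set,
    min_confidence: float = 0.4,
    term_filter: list[str] | None = None,
    gene_sets: dict[str, set] | None = None,
) -> nx.Graph:
    """Induced subgraph on the proteins of interest.

    Edges must carry experimental confidence strictly greater than
    ``min_confidence``. If ``term_filter`` names gene sets, the node set
    is intersected with the union of those sets' members first. Nodes with
    no surviving edge are kept as isolated nodes.
    """
    nodes = set(map(str, nodes_of_interest))
    if term_filter is not None:
        if gene_sets is None:
            raise ValueError("term_filter requires gene_sets")
        members: set = set()
        for t in term_filter:
            if t not in gene_sets:
                raise ValueError(f"unknown gene set {t!r}")
            members |= set(gene_sets[t])
        nodes &= members
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for _, row in edges.iterrows():
        a, b = str(row["protein_a"]), str(row["protein_b"])
        conf = float(row["confidence"])
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"malformed edge confidence {conf} ({a}-{b})")
        if conf > min_confidence and a in nodes and b in nodes and a != b:
            g.add_edge(a, b, confidence=conf)
    return g
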