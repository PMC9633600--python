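"""Proximal (APEX2) phosphoproteome contrasts and the recycling cluster.

The proximal arm compares each APEX2 bait (receptor FGFR2b, endosome
marker RAB11) against the GFP-APEX2 spatial reference at the matched
treatment and timepoint: replicate medians of the normalized log2
intensities are subtracted, giving a site-by-(bait, treatment) log2 ratio
matrix. Hierarchical clustering of the ratios isolates the cluster of
sites upregulated upon FGF10 in *both* baits — the recycling proximal
signalling cluster — which is then intersected with other site/protein
sets (overlap analysis) and with the FGF10-responsive global sites.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .model import NormalizedMatrix, ProximalContrast


def ratio_column(bait: str, treatment: str) -> str:
    return f"{bait}|{treatment}"


def reference_normalize(
    matrix: NormalizedMatrix | pd.DataFrame,
    design: pd.DataFrame,
    reference_bait: str = "GFP_reference",
) -> ProximalContrast:
    """log2 bait-minus-reference ratios per site, bait and treatment.

    Replicates are summarised by their median; the reference median at the
    matched (treatment, timepoint) is subtracted. Adding a constant to all
    log2 intensities leaves the ratios unchanged.
    """
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix
    prox = design[design["compartment"] == "proximal"]
    ref = prox[prox["bait"] == reference_bait]
    baits = [b for b in pd.unique(prox["bait"]) if b != reference_bait]
    if ref.empty:
        raise ValueError(f"design has no {reference_bait!r} samples")
    ratios = pd.DataFrame(index=values.index)
    for bait in baits:
        sub = prox[prox["bait"] == bait]
        for (treatment, tp), grp in sub.groupby(["treatment", "timepoint_min"]):
            match = ref[(ref["treatment"] == treatment) & (ref["timepoint_min"] == tp)]
            if match.empty:
                raise ValueError(
                    f"no {reference_bait!r} samples matching treatment="
                    f"{treatment!r}, timepoint={tp}"
                )
            bait_med = values[list(grp.index)].median(axis=1)
            ref_med = values[list(match.index)].median(axis=1)
            ratios[ratio_column(bait, treatment)] = bait_med - ref_med
    return ProximalContrast(ratios=ratios)


def extract_recycling_cluster(
    contrast: ProximalContrast,
    k_cut: int,
    linkage: str = "ward",
    min_up: float = 0.0,
    fgf10_cols: tuple[str, str] = ("FGFR2b|FGF10", "RAB11|FGF10"),
    ut_cols: tuple[str, str] = ("FGFR2b|UT", "RAB11|UT"),
) -> ProximalContrast:
    """Cut the ratio dendrogram and flag the up-in-both-baits clusters.

    Site rows are clustered agglomeratively (Euclidean distance) and cut
    into ``k_cut`` clusters. A cluster is part of the recycling proximal
    signalling set iff its centroid exceeds ``min_up`` in both FGF10 bait
    columns and exceeds the matching UT centroid in both baits. The
    returned flag covers whole dendrogram clusters only.
    """
    ratios = contrast.ratios
    if ratios.isna().any().any():
        raise ValueError("ratio matrix must be complete")
    n = len(ratios)
    if k_cut < 2 or k_cut > n:
        raise ValueError(f"k_cut must be in [2, {n}]")
    for col in (*fgf10_cols, *ut_cols):
        if col not in ratios.columns:
            raise ValueError(f"ratio matrix lacks column {col!r}")
    z = hierarchy.linkage(ratios.to_numpy(dtype=float), method=linkage,
                          metric="euclidean")
    assign = hierarchy.fcluster(z, t=k_cut, criterion="maxclust")
    flag = pd.Series(False, index=ratios.index)
    for cl in np.unique(assign):
        rows = ratios.loc[assign == cl]
        cen = rows.mean(axis=0)
        up_both = all(cen[c] > min_up for c in fgf10_cols)
        above_ut = all(
            cen[f] > cen[u] for f, u in zip(fgf10_cols, ut_cols)
        )
        if up_both and above_ut:
            flag.loc[rows.index] = True
    return ProximalContrast(
        ratios=ratios,
        linkage=z,
        k_cut=k_cut,
        in_recycling_cluster=flag,
    )


def overlap_analysis(sets: dict[str, set]) -> pd.DataFrame:
    """All pairwise intersections/differences with counts and percentages.

    Fractions are reported relative to each of the two sets so asymmetric
    overlaps (e.g. sites within a cluster) are explicit.
    """
    rows = []
    for name_a, name_b in combinations(sets, 2):
        a, b = set(sets[name_a]), set(sets[name_b])
        inter = a & b
        rows.append(
            {
                "set_a": name_a,
                "set_b": name_b,
                "n_a": len(a),
                "n_b": len(b),
                "n_intersection": len(inter),
                "n_a_only": len(a - b),
                "n_b_only": len(b - a),
                "pct_of_a": 100.0 * len(inter) / len(a) if a else 0.0,
                "pct_of_b": 100.0 * len(inter) / len(b) if b else 0.0,
                "members_intersection": ";".join(sorted(map(str, inter))),
            }
        )
    return pd.DataFrame(rows)


def global_fgf10_up(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    min_log2fc: float = 1.0,
    alpha: float = 0.05,
    prior_df: float = 4.0,
) -> tuple[pd.Index, pd.DataFrame]:
    """Sites upregulated upon FGF10 in the global phosphoproteome.

    Moderated two-sample t-test (FGF10 vs UT) per site on the global
    samples: the pooled per-site variance is shrunk towards the mean
    variance across sites with ``prior_df`` prior degrees of freedom
    (empirical-Bayes moderation in the limma style), which restores power
    at the few replicates typical of these designs. BH adjustment across
    sites; keep sites with mean difference >= min_log2fc and q < alpha.
    """
    glob = design[design["compartment"] == "global"]
    ut_cols = list(glob.index[glob["treatment"] == "UT"])
    fgf_cols = list(glob.index[glob["treatment"] == "FGF10"])
    if not ut_cols or not fgf_cols:
        raise ValueError("need global UT and FGF10 samples")
    a = matrix[fgf_cols].to_numpy(dtype=float)
    b = matrix[ut_cols].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates per treatment")
    df_resid = n1 + n2 - 2
    s2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / df_resid
    s2_prior = float(np.nanmean(s2))
    s2_mod = (prior_df * s2_prior + df_resid * s2) / (prior_df + df_resid)
    diff = a.mean(axis=1) - b.mean(axis=1)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df=prior_df + df_resid)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {"log2fc": diff, "t": t, "p": p, "q": q}, index=matrix.index
    )
    kept = matrix.index[(diff >= min_log2fc) & (q < alpha)]
    return kept, table
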