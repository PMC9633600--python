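"""Trafficking-response clustering and cross-cell-line label transfer.

Sites that respond differentially across the four trafficking conditions
(ANOVA gate) are grouped by Bezdek fuzzy c-means on their condition
median z-profiles. Cluster centroids are mapped to a response taxonomy —
membrane (FGF10-regulated, unaffected by either dominant negative),
internalisation (dysregulated by DnDNM2 only) and recycling (dysregulated
by both DnRAB11 and DnDNM2). A Parzen-window (kernel density) classifier
trained on the labelled clusters transfers cluster identity to a second
cell line's z-profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

from .model import ClusterModel, TRAFFICKING_CONDITIONS


def anova_gate(
    replicate_z: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 1e-4,
    adjust: str = "bh",
) -> tuple[pd.Index, pd.DataFrame]:
    """One-way ANOVA per site across conditions; keep adjusted p < alpha.

    Returns the retained site index and a per-site table of p and q
    values. ``adjust='none'`` thresholds the raw p values instead.
    """
    conds = design.loc[replicate_z.columns, "condition"]
    groups = [
        replicate_z[list(conds.index[conds == c])].to_numpy(dtype=float)
        for c in pd.unique(conds)
    ]
    if len(groups) < 2:
        raise ValueError("ANOVA gate needs >= 2 conditions")
    for g, c in zip(groups, pd.unique(conds)):
        if g.shape[1] < 2:
            raise ValueError(f"condition {c!r} has < 2 replicates")
    f, p = stats.f_oneway(*groups, axis=1)
    p = np.where(np.isnan(p), 1.0, p)
    if adjust == "bh":
        q = multipletests(p, method="fdr_bh")[1]
    elif adjust == "none":
        q = p
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    table = pd.DataFrame({"F": f, "p": p, "q": q}, index=replicate_z.index)
    kept = replicate_z.index[q < alpha]
    return kept, table


# ------------------------------------------------------------ fuzzy c-means


def _fcm_memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """Bezdek update: u_ik = 1 / sum_j (d_ik / d_jk)^(2/(m-1))."""
    d2 = np.maximum(d2, 0.0)
    zero = d2 <= 1e-300
    # normalise by the row minimum before exponentiation so small
    # fuzzifiers (large exponents) cannot overflow
    dmin = np.maximum(d2.min(axis=1, keepdims=True), 1e-300)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        w = (d2 / dmin) ** (-1.0 / (m - 1.0))
        u = np.where(
            zero.any(axis=1, keepdims=True),
            zero / np.maximum(zero.sum(axis=1, keepdims=True), 1),
            w / w.sum(axis=1, keepdims=True),
        )
    return u


def fcm_objective(x: np.ndarray, u: np.ndarray, v: np.ndarray, m: float) -> float:
    """J(U, V) = sum_i sum_k u_ik^m ||x_i - v_k||^2."""
    d2 = cdist(x, v, "sqeuclidean")
    return float((u**m * d2).sum())


def fuzzy_cmeans(
    x: pd.DataFrame,
    c: int = 11,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    n_restarts: int = 10,
    seed: int = 0,
) -> ClusterModel:
    """Bezdek fuzzy c-means with Euclidean distance, best of n_restarts.

    Centroids are initialised from distinct data rows; the run whose
    converged objective is smallest wins. Deterministic given the seed.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    xa = x.to_numpy(dtype=float)
    n = xa.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds the number of sites ({n})")
    if np.isnan(xa).any():
        raise ValueError("fuzzy c-means requires a complete matrix")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        v = xa[rng.choice(n, size=c, replace=False)].copy()
        v += rng.normal(0, 1e-9, size=v.shape)  # split coincident rows
        history = []
        for _ in range(max_iter):
            d2 = cdist(xa, v, "sqeuclidean")
            u = _fcm_memberships(d2, m)
            um = u**m
            v_new = (um.T @ xa) / um.sum(axis=0)[:, None]
            history.append(float((um * d2).sum()))
            if np.abs(v_new - v).max() < tol:
                v = v_new
                break
            v = v_new
        d2 = cdist(xa, v, "sqeuclidean")
        u = _fcm_memberships(d2, m)
        obj = fcm_objective(xa, u, v, m)
        if best is None or obj < best[0]:
            best = (obj, u, v, np.asarray(history))
    obj, u, v, history = best
    clusters = [f"c{k + 1}" for k in range(c)]
    return ClusterModel(
        centroids=pd.DataFrame(v, index=clusters, columns=x.columns),
        memberships=pd.DataFrame(u, index=x.index, columns=clusters),
        fuzzifier=m,
        objective=obj,
        objective_history=history,
    )


def label_responses(
    model: ClusterModel,
    condition_order: tuple = TRAFFICKING_CONDITIONS,
    reg_margin: float = 0.5,
    preserve_frac: float = 0.5,
) -> dict[str, str]:
    """Assign the trafficking-response taxonomy to each cluster centroid.

    With delta = centroid(FGF10_GFP) - centroid(UT): a cluster is
    FGF10-regulated iff |delta| >= reg_margin; a perturbation *preserves*
    the response iff its same-direction change retains at least
    ``preserve_frac * |delta|``, otherwise it *dysregulates* it.
    membrane = regulated, both preserve; internalisation = DnDNM2
    dysregulates, DnRAB11 preserves; recycling = both dysregulate.
    """
    ut, gfp, dnrab11, dndnm2 = condition_order
    for cond in condition_order:
        if cond not in model.centroids.columns:
            raise ValueError(f"centroids lack condition {cond!r}")
    labels = {}
    for k, row in model.centroids.iterrows():
        delta = row[gfp] - row[ut]
        if abs(delta) < reg_margin:
            labels[k] = "other"
            continue
        sign = np.sign(delta)
        pres_rab11 = sign * (row[dnrab11] - row[ut]) >= preserve_frac * abs(delta)
        pres_dnm2 = sign * (row[dndnm2] - row[ut]) >= preserve_frac * abs(delta)
        if pres_rab11 and pres_dnm2:
            labels[k] = "membrane"
        elif pres_rab11 and not pres_dnm2:
            labels[k] = "internalisation"
        elif not pres_rab11 and not pres_dnm2:
            labels[k] = "recycling"
        else:
            labels[k] = "other"
    model.response_labels = labels
    return labels


# ------------------------------------------------------ Parzen classifier


@dataclass
class ParzenClassifier:
    """Class-conditional Gaussian product-kernel density classifier.

    Each class holds its training points and a per-dimension bandwidth;
    posteriors combine the kernel densities with class-frequency priors.
    """

    classes: list
    train: dict  # class -> (n_k, d) array
    bandwidths: dict  # class -> (d,) array, all > 0
    priors: np.ndarray  # simplex over classes
    feature_names: list

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """log f_k(x) for every class; x is (n, d)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], len(self.classes)))
        for j, k in enumerate(self.classes):
            t = self.train[k]  # (n_k, d)
            h = self.bandwidths[k]  # (d,)
            diff = (x[:, None, :] - t[None, :, :]) / h
            logk = -0.5 * (diff**2).sum(axis=2) - np.log(h).sum() \
                - 0.5 * t.shape[1] * np.log(2 * np.pi)
            out[:, j] = logsumexp(logk, axis=1) - np.log(t.shape[0])
        return out

    def posteriors(self, x) -> pd.DataFrame:
        xa = np.atleast_2d(np.asarray(x, dtype=float))
        logp = self.log_density(xa) + np.log(self.priors)[None, :]
        logp -= logsumexp(logp, axis=1, keepdims=True)
        idx = x.index if isinstance(x, pd.DataFrame) else pd.RangeIndex(len(xa))
        return pd.DataFrame(np.exp(logp), index=idx, columns=self.classes)

    def predict(self, x) -> pd.Series:
        post = self.posteriors(x)
        arr = post.to_numpy()
        best = np.argmax(arr, axis=1)  # first max: lowest class index on ties
        return pd.Series(
            [self.classes[i] for i in best], index=post.index, name="label"
        )


def fit_parzen(
    train: pd.DataFrame,
    labels: pd.Series,
    bandwidth: str | float = "scott",
    min_bandwidth: float = 1e-3,
) -> ParzenClassifier:
    """Fit the Parzen classifier on labelled z-profiles.

    ``bandwidth`` is Scott's rule per class per dimension
    (sd * n^(-1/(d+4))), Silverman's rule, or a fixed float. Every class
    needs >= 2 training points.
    """
    labels = labels.reindex(train.index)
    classes = sorted(pd.unique(labels.dropna()))
    if not classes:
        raise ValueError("no labelled training points")
    d = train.shape[1]
    tr, bw = {}, {}
    counts = []
    for k in classes:
        xk = train.loc[labels == k].to_numpy(dtype=float)
        if xk.shape[0] < 2:
            raise ValueError(f"class {k!r} has < 2 training points")
        n_k = xk.shape[0]
        sd = xk.std(axis=0, ddof=1)
        if bandwidth == "scott":
            h = sd * n_k ** (-1.0 / (d + 4))
        elif bandwidth == "silverman":
            h = sd * (n_k * (d + 2) / 4.0) ** (-1.0 / (d + 4))
        else:
            h = np.full(d, float(bandwidth))
        h = np.maximum(h, min_bandwidth)
        tr[k] = xk
        bw[k] = h
        counts.append(n_k)
    priors = np.asarray(counts, dtype=float)
    priors /= priors.sum()
    return ParzenClassifier(
        classes=classes,
        train=tr,
        bandwidths=bw,
        priors=priors,
        feature_names=list(train.columns),
    )


def classify(clf: ParzenClassifier, x_new: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Labels and posteriors for new z-profiles (dimensions must match)."""
    if list(x_new.columns) != clf.feature_names:
        raise ValueError(
            f"feature mismatch: classifier saw {clf.feature_names}, "
            f"got {list(x_new.columns)}"
        )
    post = clf.posteriors(x_new)
    labels = clf.predict(x_new)
    return labels, post
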