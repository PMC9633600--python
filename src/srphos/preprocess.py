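"""Filtering, normalization, imputation and summarisation.

The analysis-ready matrix is built in the order the experiments demand:
decoy/localisation filtering on the raw site table, log2 transform,
group-wise quantile normalization (global and proximal samples are never
co-normalized), a valid-values filter requiring full quantification in at
least one condition, missing-value imputation (downshifted-normal for the
trafficking arm, QRILC-style truncated draws for the proximal arm), and
finally per-site z-scores collapsed to condition medians.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .model import NormalizedMatrix, PhosphoSiteTable

log = logging.getLogger(__name__)


def filter_sites(
    table: PhosphoSiteTable, min_loc_prob: float = 0.75
) -> tuple[PhosphoSiteTable, dict]:
    """Drop reverse/contaminant rows and low-confidence localisations.

    The localisation threshold is inclusive: a site at exactly
    ``min_loc_prob`` (Class I at the default 0.75) is retained. Returns the
    filtered table and a per-rule removal report.
    """
    sites = table.sites
    rev = sites["reverse"].astype(bool)
    con = sites["contaminant"].astype(bool) & ~rev
    low = (sites["localisation_prob"] < min_loc_prob) & ~rev & ~con
    keep = ~(rev | con | low)
    report = {
        "n_input": len(sites),
        "removed_reverse": int(rev.sum()),
        "removed_contaminant": int(con.sum()),
        "removed_low_localisation": int(low.sum()),
        "n_kept": int(keep.sum()),
    }
    log.info("filter_sites: %s", report)
    return table.subset(sites.index[keep]), report


def log2_intensities(table: PhosphoSiteTable) -> pd.DataFrame:
    """log2-transform the raw intensity matrix (missing stays missing)."""
    return np.log2(table.intensities)


def quantile_normalize(
    matrix: pd.DataFrame, groups: pd.Series | None = None
) -> NormalizedMatrix:
    """Quantile-normalize a log2 site-by-sample matrix within sample groups.

    Within a group, the value at rank r in every column is replaced by the
    mean over columns of the rank-r values; tied values receive the average
    of their tied ranks' means. Missing cells are excluded from the rank
    computation (each column is mapped through its own observed quantiles)
    and remain missing. Columns from different groups are never mixed.
    """
    if groups is None:
        groups = pd.Series("all", index=matrix.columns)
    groups = groups.reindex(matrix.columns)
    out = matrix.copy().astype(float)
    for g in pd.unique(groups):
        cols = list(groups.index[groups == g])
        if len(cols) < 2:
            raise ValueError(f"normalization group {g!r} has < 2 samples")
        out[cols] = _qnorm_block(matrix[cols].to_numpy(dtype=float))
    return NormalizedMatrix(out, groups)


def _qnorm_block(x: np.ndarray) -> np.ndarray:
    obs = ~np.isnan(x)
    counts = obs.sum(axis=0)
    if (counts < 1).any():
        raise ValueError("a sample column has no observed values")
    nmax = int(counts.max())
    grid = np.linspace(0.0, 1.0, nmax) if nmax > 1 else np.array([0.0])
    # reference distribution: each column's sorted values interpolated onto
    # a common quantile grid, then averaged across columns
    interp_cols = []
    for j in range(x.shape[1]):
        v = np.sort(x[obs[:, j], j])
        if len(v) == 1:
            interp_cols.append(np.full(nmax, v[0]))
        else:
            interp_cols.append(np.interp(grid, np.linspace(0, 1, len(v)), v))
    ref = np.mean(interp_cols, axis=0)
    out = x.copy()
    for j in range(x.shape[1]):
        mask = obs[:, j]
        v = x[mask, j]
        n = len(v)
        if n == 1:
            out[mask, j] = ref[len(ref) // 2]
            continue
        targets = np.interp(np.linspace(0, 1, n), grid, ref)
        ranks = stats.rankdata(v, method="average")  # ties -> mean rank
        out[mask, j] = np.interp(ranks, np.arange(1, n + 1), targets)
    return out


def valid_value_filter(
    matrix: pd.DataFrame, design: pd.DataFrame, min_reps: int = 3
) -> pd.DataFrame:
    """Keep sites observed in >= min_reps replicates of at least one condition."""
    cond_sizes = design.groupby("condition").size()
    if min_reps > cond_sizes.max():
        raise ValueError(
            f"min_reps={min_reps} exceeds the largest condition ({cond_sizes.max()})"
        )
    keep = pd.Series(False, index=matrix.index)
    for cond, sub in design.groupby("condition"):
        cols = [c for c in sub.index if c in matrix.columns]
        if not cols:
            continue
        keep |= matrix[cols].notna().sum(axis=1) >= min_reps
    return matrix.loc[keep]


def impute_downshift(
    matrix: NormalizedMatrix | pd.DataFrame,
    width: float = 0.3,
    shift: float = 1.8,
    seed: int = 0,
) -> NormalizedMatrix:
    """Impute missing cells from a downshifted per-column normal.

    Each missing cell in column c is drawn from
    ``Normal(mean_c - shift * sd_c, (width * sd_c)^2)`` where mean/sd are
    the column's observed moments. This is the conventional MNAR
    imputation for left-censored label-free data.
    """
    nm = _as_normalized(matrix)
    rng = np.random.default_rng(seed)
    vals = nm.values.to_numpy(dtype=float).copy()
    mask = np.isnan(vals)
    for j, col in enumerate(nm.values.columns):
        obs = vals[~mask[:, j], j]
        if mask[:, j].any():
            if len(obs) < 3:
                raise ValueError(f"column {col!r} has < 3 observed values")
            mu, sd = obs.mean(), obs.std(ddof=1)
            n_miss = int(mask[:, j].sum())
            vals[mask[:, j], j] = rng.normal(mu - shift * sd, width * sd, n_miss)
    out = nm.copy()
    out.values = pd.DataFrame(vals, index=nm.values.index, columns=nm.values.columns)
    out.imputed_mask = pd.DataFrame(
        mask, index=nm.values.index, columns=nm.values.columns
    )
    return out


def impute_qrilc(
    matrix: NormalizedMatrix | pd.DataFrame,
    tune_sigma: float = 1.0,
    seed: int = 0,
) -> NormalizedMatrix:
    """Impute missing cells by draws from a left-truncated normal (QRILC-style).

    Per column, the latent normal's mean and sd are estimated by regressing
    the sorted observed values on standard-normal quantiles, placing the
    observed data in the upper ``1 - miss_frac`` tail (quantile regression
    on the observed distribution under left-censoring). Draws come from
    that normal truncated above at the censoring point.
    """
    nm = _as_normalized(matrix)
    rng = np.random.default_rng(seed)
    vals = nm.values.to_numpy(dtype=float).copy()
    mask = np.isnan(vals)
    for j, col in enumerate(nm.values.columns):
        mcol = mask[:, j]
        if not mcol.any():
            continue
        obs = np.sort(vals[~mcol, j])
        n_obs = len(obs)
        if n_obs < 3:
            raise ValueError(f"column {col!r} has < 3 observed values")
        miss_frac = mcol.mean()
        # plotting positions of the observed order statistics within the
        # full (censored) latent distribution
        p = miss_frac + (1 - miss_frac) * (np.arange(1, n_obs + 1) - 0.375) / (
            n_obs + 0.25
        )
        q = stats.norm.ppf(p)
        sd, mu = np.polyfit(q, obs, 1)
        sd = abs(sd) * tune_sigma
        upper = mu + sd * stats.norm.ppf(max(miss_frac, 1e-6))
        a = -np.inf
        b = (upper - mu) / sd if sd > 0 else 0.0
        n_miss = int(mcol.sum())
        if sd <= 0:
            draws = np.full(n_miss, upper)
        else:
            draws = stats.truncnorm.rvs(
                a, b, loc=mu, scale=sd, size=n_miss, random_state=rng
            )
        vals[mcol, j] = draws
    out = nm.copy()
    out.values = pd.DataFrame(vals, index=nm.values.index, columns=nm.values.columns)
    out.imputed_mask = pd.DataFrame(
        mask, index=nm.values.index, columns=nm.values.columns
    )
    return out


def _as_normalized(matrix: NormalizedMatrix | pd.DataFrame) -> NormalizedMatrix:
    if isinstance(matrix, NormalizedMatrix):
        return matrix
    return NormalizedMatrix(
        matrix.copy(), pd.Series("all", index=matrix.columns)
    )


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each site row to mean 0, sd 1 (sample sd, n-1).

    Zero-variance rows cannot be standardized and are dropped with a
    warning.
    """
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        log.warning("zscore_rows: dropping %d zero-variance sites", int(flat.sum()))
    z = matrix.loc[~flat].sub(mu[~flat], axis=0).div(sd[~flat], axis=0)
    return z


def median_zscore(
    matrix: pd.DataFrame, design: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site z-scores collapsed to per-condition medians.

    Returns (condition-median z matrix, replicate-level z matrix). The
    replicate-level matrix feeds the ANOVA gate; the median matrix feeds
    clustering.
    """
    if matrix.isna().any().any():
        raise ValueError("median_zscore requires a complete (imputed) matrix")
    z = zscore_rows(matrix)
    conds = design.loc[matrix.columns, "condition"]
    med = pd.DataFrame(index=z.index)
    for cond in pd.unique(conds):
        cols = list(conds.index[conds == cond])
        med[cond] = z[cols].median(axis=1)
    return med, z


def qc_summaries(matrix: pd.DataFrame, n_components: int = 2) -> dict:
    """Pairwise Pearson correlations between samples and a sample-level PCA."""
    if matrix.shape[1] < 2:
        raise ValueError("QC needs at least 2 samples")
    corr = matrix.corr(method="pearson")  # pairwise-complete
    complete = matrix.dropna(axis=0)
    x = complete.to_numpy(dtype=float).T  # samples as observations
    x = x - x.mean(axis=0, keepdims=True)
    n_comp = min(n_components, min(x.shape))
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    coords = u[:, :n_comp] * s[:n_comp]
    total_var = (s**2).sum()
    evr = (s[:n_comp] ** 2 / total_var) if total_var > 0 else np.zeros(n_comp)
    pca = pd.DataFrame(
        coords,
        index=matrix.columns,
        columns=[f"PC{i + 1}" for i in range(n_comp)],
    )
    return {"pearson": corr, "pca": pca, "explained_variance_ratio": evr}
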