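"""Synthetic data with known ground truth for every pipeline stage.

The phosphoproteome generator emulates the structure of a label-free
phosphosite experiment: log-normal site intensities, condition-structured
effects following the trafficking response archetypes (membrane /
internalisation / recycling / null), left-censored (MNAR) missingness that
grows as latent intensity falls, a global downshift of APEX2-proximal
samples relative to whole-lysate samples, localisation probabilities, and
contaminant/reverse decoy rows. The image generator draws Gaussian puncta
with analytic overlap truth for the colocalization statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import PhosphoSiteTable, validate_design

ARCHETYPES = ("membrane", "internalisation", "recycling", "null")

#: conditions (perturbations) under which each archetype keeps its FGF10
#: response; a dominant-negative that is absent from the set "dysregulates"
#: the archetype back to baseline.
_SURVIVES_PERTURBATION = {
    "membrane": {"GFP", "DnRAB11", "DnDNM2"},
    "internalisation": {"GFP", "DnRAB11"},
    "recycling": {"GFP"},
    "null": set(),
}

#: APEX2 baits near which each archetype is enriched upon FGF10; the
#: recycling archetype sits near both the receptor and the endosome marker.
_PROXIMAL_BAITS = {
    "membrane": {"RAB11"},
    "internalisation": {"FGFR2b"},
    "recycling": {"FGFR2b", "RAB11"},
    "null": set(),
}


def _perturbation_of(condition: str) -> str:
    """Map a condition name to its trafficking perturbation tag."""
    for tag in ("DnRAB11", "DnDNM2"):
        if tag in condition:
            return tag
    return "GFP"


@dataclass
class OmicsTruth:
    """Ground truth for one generated phosphoproteome."""

    table: pd.DataFrame  # per-site: archetype, base_log2, effect, cluster_id,
    # proximal-enrichment flags, decoy flags
    latent: pd.DataFrame  # noiseless+noise latent log2 values before censoring
    missing_latent_mean: float
    observed_latent_mean: float


def gen_phospho_dataset(
    design: pd.DataFrame,
    n_sites: int = 2000,
    archetype_fractions: dict[str, float] | None = None,
    effect_size: float = 2.0,
    missing_rate: float = 0.1,
    proximal_shift: float = 1.0,
    noise_sd: float = 0.3,
    base_mean: float = 23.0,
    base_sd: float = 1.5,
    contaminant_frac: float = 0.05,
    low_locprob_frac: float = 0.1,
    missing_steepness: float = 0.5,
    seed: int = 0,
) -> tuple[PhosphoSiteTable, OmicsTruth]:
    """Generate a site table with planted trafficking/proximal structure.

    Parameters mirror the experiment being emulated: ``effect_size`` is the
    FGF10 response in log2 units, ``noise_sd`` the replicate noise,
    ``proximal_shift`` the left-shift of double-enriched proximal samples,
    and ``missing_rate`` the overall fraction of left-censored cells
    (missingness is logistic in the latent log2 intensity).
    """
    design = validate_design(design)
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if archetype_fractions is None:
        archetype_fractions = {
            "membrane": 0.1,
            "internalisation": 0.1,
            "recycling": 0.1,
            "null": 0.7,
        }
    fracs = np.array([archetype_fractions.get(a, 0.0) for a in ARCHETYPES])
    if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("archetype_fractions must be a simplex over archetypes")
    bad_treat = set(design["treatment"]) - {"UT", "FGF10"}
    if bad_treat:
        raise ValueError(f"unknown treatment in design: {sorted(bad_treat)}")
    n_cond = design.groupby("condition")["replicate"].nunique()
    if len(n_cond) < 2 or (n_cond < 3).all():
        # at least two conditions, three replicates somewhere
        if len(n_cond) < 2:
            raise ValueError("design needs >= 2 conditions")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_sites, fracs)
    archetype = np.repeat(ARCHETYPES, counts)
    rng.shuffle(archetype)

    site_ids = [f"site{i:05d}" for i in range(n_sites)]
    base = rng.normal(base_mean, base_sd, size=n_sites)
    effect = np.where(archetype == "null", 0.0, effect_size)
    cluster_id = np.array([ARCHETYPES.index(a) for a in archetype])

    samples = list(design.index)
    latent = np.empty((n_sites, len(samples)))
    for j, s in enumerate(samples):
        row = design.loc[s]
        up = np.zeros(n_sites, dtype=bool)
        if row["treatment"] == "FGF10":
            if row["compartment"] == "global":
                pert = _perturbation_of(str(row["condition"]))
                up = np.array(
                    [pert in _SURVIVES_PERTURBATION[a] for a in archetype]
                )
            else:  # proximal: enrichment near the matching bait
                up = np.array(
                    [row["bait"] in _PROXIMAL_BAITS[a] for a in archetype]
                )
        latent[:, j] = base + up * effect + rng.normal(0, noise_sd, n_sites)
        if row["compartment"] == "proximal":
            latent[:, j] -= proximal_shift

    # left-censored missingness: logistic in latent log2 intensity; the
    # midpoint is solved numerically so the expected rate equals the request
    if missing_rate > 0:
        lo, hi = latent.min() - 10, latent.max() + 10
        for _ in range(60):  # bisection on E[p_miss]
            mid = 0.5 * (lo + hi)
            rate = expit((mid - latent) / missing_steepness).mean()
            if rate < missing_rate:
                lo = mid
            else:
                hi = mid
        p_miss = expit((mid - latent) / missing_steepness)
        missing = rng.random(latent.shape) < p_miss
    else:
        missing = np.zeros(latent.shape, dtype=bool)

    intensities = np.power(2.0, latent)
    intensities[missing] = np.nan

    n_decoy = int(round(contaminant_frac * n_sites))
    decoy_idx = rng.choice(n_sites, size=n_decoy, replace=False)
    reverse = np.zeros(n_sites, dtype=bool)
    contaminant = np.zeros(n_sites, dtype=bool)
    reverse[decoy_idx[: n_decoy // 2]] = True
    contaminant[decoy_idx[n_decoy // 2:]] = True

    loc_prob = 0.75 + 0.25 * rng.beta(2.0, 1.0, size=n_sites)
    low = rng.random(n_sites) < low_locprob_frac
    loc_prob[low] = rng.uniform(0.3, 0.7499, size=low.sum())

    sites = pd.DataFrame(
        {
            "protein_id": [f"P{(i // 3):05d}" for i in range(n_sites)],
            "gene": [f"GENE{(i // 3):05d}" for i in range(n_sites)],
            "position": rng.integers(1, 1200, size=n_sites),
            "residue": rng.choice(["S", "T", "Y"], size=n_sites, p=[0.8, 0.15, 0.05]),
            "multiplicity": rng.choice([1, 2, 3], size=n_sites, p=[0.7, 0.25, 0.05]),
            "localisation_prob": np.round(loc_prob, 6),
            "reverse": reverse,
            "contaminant": contaminant,
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    inten = pd.DataFrame(intensities, index=sites.index, columns=samples)
    table = PhosphoSiteTable(sites, inten, design)

    truth_table = pd.DataFrame(
        {
            "archetype": archetype,
            "base_log2": base,
            "effect": effect,
            "cluster_id": cluster_id,
            "proximal_enriched_FGFR2b": [
                "FGFR2b" in _PROXIMAL_BAITS[a] for a in archetype
            ],
            "proximal_enriched_RAB11": [
                "RAB11" in _PROXIMAL_BAITS[a] for a in archetype
            ],
            "reverse": reverse,
            "contaminant": contaminant,
        },
        index=sites.index,
    )
    latent_df = pd.DataFrame(latent, index=sites.index, columns=samples)
    truth = OmicsTruth(
        table=truth_table,
        latent=latent_df,
        missing_latent_mean=float(latent[missing].mean()) if missing.any() else np.nan,
        observed_latent_mean=float(latent[~missing].mean()),
    )
    return table, truth


# ---------------------------------------------------------------- designs


def trafficking_design(
    cell_line: str = "HeLa_FGFR2b", n_replicates: int = 3
) -> pd.DataFrame:
    """The four-condition trafficking-perturbation design (global arm)."""
    rows = []
    for cond in ("UT", "FGF10_GFP", "FGF10_DnRAB11", "FGF10_DnDNM2"):
        treatment = "UT" if cond == "UT" else "FGF10"
        for r in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{cell_line}_{cond}_r{r}",
                    "cell_line": cell_line,
                    "condition": cond,
                    "replicate": r,
                    "compartment": "global",
                    "bait": "none",
                    "treatment": treatment,
                    "timepoint_min": 0 if treatment == "UT" else 40,
                }
            )
    return validate_design(pd.DataFrame(rows))


def srp_design(cell_line: str = "HeLa_FGFR2b", n_replicates: int = 3,
               include_global: bool = True) -> pd.DataFrame:
    """APEX2 proximal design: FGFR2b / RAB11 / GFP-reference baits x UT/FGF10,
    optionally alongside matched global (whole-lysate) samples."""
    rows = []
    for bait in ("FGFR2b", "RAB11", "GFP_reference"):
        for treatment in ("UT", "FGF10"):
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cell_line}_prox_{bait}_{treatment}_r{r}",
                        "cell_line": cell_line,
                        "condition": f"{bait}_{treatment}",
                        "replicate": r,
                        "compartment": "proximal",
                        "bait": bait,
                        "treatment": treatment,
                        "timepoint_min": 0 if treatment == "UT" else 40,
                    }
                )
    if include_global:
        for treatment in ("UT", "FGF10"):
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{cell_line}_glob_{treatment}_r{r}",
                        "cell_line": cell_line,
                        "condition": f"global_{treatment}",
                        "replicate": r,
                        "compartment": "global",
                        "bait": "none",
                        "treatment": treatment,
                        "timepoint_min": 0 if treatment == "UT" else 40,
                    }
                )
    return validate_design(pd.DataFrame(rows))


# ----------------------------------------------------------------- images


@dataclass
class ImageTruth:
    """Analytic ground truth for one generated puncta image pair."""

    centres_a: np.ndarray
    centres_b: np.ndarray
    psf_sigma: float
    noise_sd: float
    true_overlap_fraction: float
    true_m1: float
    true_m2: float
    noiseless: np.ndarray  # (2, h, w) float images in [0, 1]


def _render_puncta(shape, centres, amplitudes, sigma) -> np.ndarray:
    """Sum of isotropic Gaussians truncated at 3 sigma, clipped to [0, 1]."""
    img = np.zeros(shape, dtype=float)
    rad = int(np.ceil(3 * sigma))
    yy, xx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    r2 = yy**2 + xx**2
    kern = np.exp(-r2 / (2 * sigma**2))
    kern[r2 > (3 * sigma) ** 2] = 0.0
    for (cy, cx), amp in zip(centres, amplitudes):
        y0, y1 = cy - rad, cy + rad + 1
        x0, x1 = cx - rad, cx + rad + 1
        img[max(y0, 0) : y1, max(x0, 0) : x1] += (
            amp * kern[max(y0, 0) - y0 :, max(x0, 0) - x0 :][
                : shape[0] - max(y0, 0), : shape[1] - max(x0, 0)
            ]
        )
    return np.clip(img, 0.0, 1.0)


def gen_coloc_images(
    shape: tuple[int, int] = (128, 128),
    n_puncta: int = 25,
    overlap_target: float = 0.5,
    psf_sigma: float = 2.0,
    noise_sd: float = 0.0,
    bit_depth: int = 8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, ImageTruth]:
    """Generate a two-channel puncta image pair with known overlap truth.

    A fraction ``overlap_target`` of channel-B puncta share centres with
    channel-A puncta; the remainder are placed at least 6 sigma + 1 px away
    from every A punctum so their supports are disjoint. True M1/M2/OF are
    computed from the noiseless images at zero threshold.
    """
    if not 0.0 <= overlap_target <= 1.0:
        raise ValueError("overlap_target must lie in [0, 1]")
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    if shape[0] < 32 or shape[1] < 32:
        raise ValueError("image must be at least 32x32")
    rng = np.random.default_rng(seed)
    rad = int(np.ceil(3 * psf_sigma))
    margin = rad + 1
    h, w = shape
    if (h - 2 * margin) <= 0 or (w - 2 * margin) <= 0:
        raise ValueError("psf_sigma too large for image shape")
    capacity = ((h - 2 * margin) * (w - 2 * margin)) // max(1, (2 * rad + 1) ** 2)
    if n_puncta > capacity:
        raise ValueError(f"n_puncta={n_puncta} exceeds image capacity ~{capacity}")

    min_dist = 2 * rad + 1  # puncta supports never touch

    def draw(n, avoid):
        pts = []
        tries = 0
        while len(pts) < n:
            tries += 1
            if tries > 50000:
                raise ValueError("could not place puncta; image too crowded")
            p = (rng.integers(margin, h - margin), rng.integers(margin, w - margin))
            others = list(avoid) + pts
            if others:
                d2 = ((np.asarray(others) - p) ** 2).sum(axis=1)
                if (d2 < min_dist**2).any():
                    continue
            pts.append(p)
        return np.asarray(pts, dtype=int).reshape(n, 2)

    centres_a = draw(n_puncta, [])
    n_shared = int(round(overlap_target * n_puncta))
    shared = centres_a[rng.choice(n_puncta, size=n_shared, replace=False)]
    free = draw(n_puncta - n_shared, centres_a)
    centres_b = (
        np.vstack([shared, free]) if len(free) else shared.copy()
    )

    amps_a = rng.uniform(0.6, 1.0, size=len(centres_a))
    amps_b = rng.uniform(0.6, 1.0, size=len(centres_b))
    a0 = _render_puncta(shape, centres_a, amps_a, psf_sigma)
    b0 = _render_puncta(shape, centres_b, amps_b, psf_sigma)

    # truth from the noiseless images at zero threshold
    both = (a0 > 0) & (b0 > 0)
    sa, sb = a0.sum(), b0.sum()
    true_m1 = float(a0[both].sum() / sa) if sa > 0 else 0.0
    true_m2 = float(b0[both].sum() / sb) if sb > 0 else 0.0
    true_of = float(((a0 * b0) > 0).sum() / a0.size)

    maxval = 2**bit_depth - 1
    channels = []
    for img in (a0, b0):
        noisy = img + (rng.normal(0, noise_sd, size=shape) if noise_sd > 0 else 0.0)
        q = np.round(np.clip(noisy, 0.0, 1.0) * maxval)
        channels.append(q.astype(np.uint16 if bit_depth > 8 else np.uint8))
    stack = np.stack(channels)
    roi = np.ones(shape, dtype=np.uint16)

    truth = ImageTruth(
        centres_a=centres_a,
        centres_b=centres_b,
        psf_sigma=psf_sigma,
        noise_sd=noise_sd,
        true_overlap_fraction=true_of,
        true_m1=true_m1,
        true_m2=true_m2,
        noiseless=np.stack([a0, b0]),
    )
    return stack, roi, truth


# -------------------------------------------------------------- gene sets


def gen_genesets(
    n_sets: int,
    universe: list[str],
    planted: set[str] | None = None,
    planted_name: str = "planted_set",
    set_size: tuple[int, int] = (10, 60),
    seed: int = 0,
) -> dict[str, set]:
    """Random gene sets drawn from a universe, optionally with a planted set."""
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    rng = np.random.default_rng(seed)
    sets: dict[str, set] = {}
    if planted is not None:
        extra = set(planted) - set(universe)
        if extra:
            raise ValueError(f"planted members outside universe: {sorted(extra)[:5]}")
        sets[planted_name] = set(planted)
    lo, hi = set_size
    hi = min(hi, len(universe))
    lo = min(lo, hi)
    for i in range(n_sets):
        k = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=k, replace=False)
        sets[f"set{i:03d}"] = set(members.tolist())
    return sets
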