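"""Confocal colocalization statistics for puncta-style markers.

Implements the quantification chain used on multi-channel confocal
images: an a-trous (stationary) B3-spline wavelet bandpass to suppress
high-frequency speckle, [0, 1] normalization from the 8-bit range,
per-ROI expression fractions, the overlap fraction (OF) of the channel
product image, Costes automatic thresholding, Manders colocalization
coefficients M1/M2, a three-marker overlap statistic, thresholded vesicle
counting, and receptor internalisation/recycling percentages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d
from skimage import measure

from .model import ColocResult

# B3-spline scaling kernel for the a-trous transform
_B3 = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def atrous_decompose(image: np.ndarray, n_levels: int = 4) -> tuple[list, np.ndarray]:
    """A-trous B3-spline decomposition into detail planes and a smooth rest.

    Level j smooths with the B3 kernel dilated by 2^j (holes), mirror
    boundary; detail plane w_{j+1} = c_j - c_{j+1}. The planes plus the
    final smooth reconstruct the input exactly.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    support = 4 * 2 ** (n_levels - 1) + 1
    if min(img.shape) < support:
        raise ValueError(
            f"image {img.shape} smaller than kernel support {support} at "
            f"level {n_levels}"
        )
    c = img
    planes = []
    for j in range(n_levels):
        step = 2**j
        kern = np.zeros(4 * step + 1)
        kern[::step] = _B3
        cs = convolve1d(c, kern, axis=0, mode="mirror")
        cs = convolve1d(cs, kern, axis=1, mode="mirror")
        planes.append(c - cs)
        c = cs
    return planes, c


def atrous_bandpass(
    image: np.ndarray, n_levels: int = 4, drop_finest: int = 1
) -> np.ndarray:
    """Bandpass: sum of detail planes above the finest ``drop_finest``.

    The finest plane(s) carry the single-pixel speckle; the residual
    smooth carries the background. Both are discarded.
    """
    planes, _ = atrous_decompose(image, n_levels=n_levels)
    if not 0 <= drop_finest < len(planes):
        raise ValueError("drop_finest out of range")
    return np.sum(planes[drop_finest:], axis=0)


def normalize01(image: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Map integer pixel values from [0, 2^bit_depth - 1] to [0, 1]."""
    img = np.asarray(image)
    maxval = 2**bit_depth - 1
    if img.min() < 0 or img.max() > maxval:
        raise ValueError(f"pixel values outside [0, {maxval}]")
    return img.astype(float) / maxval


def _roi_bool(roi, shape) -> np.ndarray:
    roi = np.asarray(roi)
    if roi.shape != tuple(shape):
        raise ValueError(f"ROI shape {roi.shape} != image shape {tuple(shape)}")
    mask = roi.astype(bool)
    if not mask.any():
        raise ValueError("empty ROI")
    return mask


def expression_fraction(channel: np.ndarray, roi: np.ndarray) -> float:
    """Fraction of ROI pixels with strictly positive intensity."""
    mask = _roi_bool(roi, np.asarray(channel).shape)
    vals = np.asarray(channel, dtype=float)[mask]
    return float((vals > 0).sum() / mask.sum())


def overlap_fraction(ch_a: np.ndarray, ch_b: np.ndarray, roi: np.ndarray) -> float:
    """OF: fraction of ROI pixels where the channel product is positive."""
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    mask = _roi_bool(roi, a.shape)
    prod = a[mask] * b[mask]
    return float((prod > 0).sum() / mask.sum())


def costes_threshold(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    roi: np.ndarray,
    step: float = 1.0 / 255.0,
) -> tuple[float, float]:
    """Costes automatic thresholds for a channel pair within an ROI.

    Channel B is regressed on channel A by orthogonal (total least
    squares) regression; the threshold pair (T, a*T + b) is scanned
    downward from max(A) in 8-bit steps until the Pearson correlation of
    the below-threshold pixels drops to <= 0. An empty, near-empty or
    zero-variance below-threshold subset counts as uncorrelated and stops
    the scan. Returns thresholds clamped to [0, 1].
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    mask = _roi_bool(roi, a.shape)
    av, bv = a[mask], b[mask]
    if av.std() == 0 or bv.std() == 0:
        raise ValueError("Costes threshold needs variance in both channels")

    # orthogonal regression: principal axis of the centred (A, B) cloud
    cov = np.cov(av, bv)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, np.argmax(evals)]
    if abs(v[0]) < 1e-12:
        raise ValueError("degenerate regression (vertical principal axis)")
    slope = v[1] / v[0]
    intercept = bv.mean() - slope * av.mean()

    pos = av[av > 0]
    floor = float(pos.min()) if len(pos) else 0.0
    t = float(av.max())
    t_a = floor
    while t > floor:
        sel = (av < t) & (bv < slope * t + intercept)
        # an empty or degenerate below-threshold subset counts as
        # uncorrelated, so the scan stops (anti-correlated channels stop
        # at the very first step)
        if sel.sum() < 2:
            t_a = t
            break
        sa, sb = av[sel], bv[sel]
        if sa.std() == 0 or sb.std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(sa, sb)[0, 1])
        if r <= 0:
            t_a = t
            break
        t -= step
    t_b = slope * t_a + intercept
    return float(np.clip(t_a, 0.0, 1.0)), float(np.clip(t_b, 0.0, 1.0))


def manders(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    roi: np.ndarray,
    t_a: float = 0.0,
    t_b: float = 0.0,
) -> tuple[float, float]:
    """Manders colocalization coefficients above the given thresholds.

    M1 = sum of A over pixels with A > t_a and B > t_b, divided by the sum
    of A over pixels with A > t_a; M2 symmetric. 0/0 is defined as 0.
    """
    a = np.asarray(ch_a, dtype=float)
    b = np.asarray(ch_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    mask = _roi_bool(roi, a.shape)
    av, bv = a[mask], b[mask]
    a_on = av > t_a
    b_on = bv > t_b
    denom1 = av[a_on].sum()
    denom2 = bv[b_on].sum()
    m1 = float(av[a_on & b_on].sum() / denom1) if denom1 > 0 else 0.0
    m2 = float(bv[a_on & b_on].sum() / denom2) if denom2 > 0 else 0.0
    return m1, m2


def coloc_stats(
    ch_a: np.ndarray,
    ch_b: np.ndarray,
    roi: np.ndarray,
    roi_label: int = 1,
    use_costes: bool = True,
) -> ColocResult:
    """Full colocalization record for one ROI: EF, OF, Costes, M1/M2."""
    mask = _roi_bool(roi, np.asarray(ch_a).shape)
    ef_a = expression_fraction(ch_a, mask)
    ef_b = expression_fraction(ch_b, mask)
    of = overlap_fraction(ch_a, ch_b, mask)
    if use_costes:
        t_a, t_b = costes_threshold(ch_a, ch_b, mask)
    else:
        t_a = t_b = 0.0
    m1, m2 = manders(ch_a, ch_b, mask, t_a, t_b)
    return ColocResult(
        roi_label=roi_label,
        roi_pixels=int(mask.sum()),
        ef={"A": ef_a, "B": ef_b},
        of=of,
        m1=m1,
        m2=m2,
        t_a=t_a,
        t_b=t_b,
    )


def triple_overlap(
    ch_r: np.ndarray,
    ch_f: np.ndarray,
    ch_g: np.ndarray,
    roi: np.ndarray,
    use_costes: bool = True,
) -> float:
    """Three-marker colocalization: M1 of the R*F product image against G.

    The red/far-red overlap image C = R (elementwise) F is formed first;
    Costes thresholds for (C, G) are then applied and the M1 fraction of C
    residing in G-positive pixels is returned.
    """
    r = np.asarray(ch_r, dtype=float)
    f = np.asarray(ch_f, dtype=float)
    g = np.asarray(ch_g, dtype=float)
    if not (r.shape == f.shape == g.shape):
        raise ValueError("channel shapes differ")
    combined = r * f
    if use_costes and combined.std() > 0 and g.std() > 0:
        t_c, t_g = costes_threshold(combined, g, roi)
    else:
        t_c = t_g = 0.0
    m1, _ = manders(combined, g, roi, t_c, t_g)
    return m1


def count_vesicles(
    channel: np.ndarray,
    nuclei_count: int,
    threshold: int = 50,
    min_size: int = 1,
) -> dict:
    """Count thresholded particles and express them per nucleus.

    Pixels strictly above ``threshold`` (8-bit scale) are binarised and
    8-connected components of at least ``min_size`` pixels are counted;
    the ratio divides by the DAPI nuclei count.
    """
    if nuclei_count < 1:
        raise ValueError("nuclei_count must be >= 1")
    binary = np.asarray(channel) > threshold
    labels = measure.label(binary, connectivity=2)
    if min_size > 1:
        sizes = np.bincount(labels.ravel())
        n_objects = int((sizes[1:] >= min_size).sum())
    else:
        n_objects = int(labels.max())
    return {"n_objects": n_objects, "ratio_per_nucleus": n_objects / nuclei_count}


def trafficking_percentages(counts: pd.DataFrame) -> pd.DataFrame:
    """Receptor-positive cell percentages referred to time zero.

    ``counts`` needs columns timepoint_min, positive, nuclei. pct(t) =
    100 * positive / nuclei; relative(t) = 100 * pct(t) / pct(0).
    """
    df = counts.copy()
    for col in ("timepoint_min", "positive", "nuclei"):
        if col not in df.columns:
            raise ValueError(f"counts table lacks column {col!r}")
    if (df["nuclei"] <= 0).any():
        raise ValueError("nuclei counts must be positive")
    df["pct_positive"] = 100.0 * df["positive"] / df["nuclei"]
    t0 = df.loc[df["timepoint_min"] == 0, "pct_positive"]
    if t0.empty:
        raise ValueError("no timepoint 0 row")
    if float(t0.iloc[0]) == 0:
        raise ValueError("pct at time zero is 0; relative values undefined")
    df["relative_pct"] = 100.0 * df["pct_positive"] / float(t0.iloc[0])
    return df
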