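"""Readers and writers for the pipeline's on-disk formats.

The phosphosite table follows the tab-separated dialect of MaxQuant's
"Phospho (STY)Sites" output: one row per site isoform, ``+`` flags for
reverse/contaminant rows, and zero-filled intensities for absent
quantifications (read back as missing). Gene sets are standard GMT;
interaction edges are a three-column TSV; images are multi-page TIFF with
one page per channel plus an integer ROI label mask.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .model import DESIGN_COLUMNS, PhosphoSiteTable, validate_design

log = logging.getLogger(__name__)

# site-table column headers, MaxQuant dialect
_SITE_COLUMNS = {
    "id": "id",
    "protein_id": "Protein",
    "gene": "Gene names",
    "position": "Position",
    "residue": "Amino acid",
    "multiplicity": "Multiplicity",
    "localisation_prob": "Localization prob",
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
}
_INTENSITY_PREFIX = "Intensity "


def write_design(design: pd.DataFrame, path) -> None:
    validate_design(design)[DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    return validate_design(df)


def write_sites(table: PhosphoSiteTable, path) -> None:
    """Write a site table in the MaxQuant-style TSV dialect.

    Missing intensities are written as 0 (the MaxQuant convention);
    ``read_sites`` restores them to missing.
    """
    out = pd.DataFrame({"id": table.sites.index})
    for field, col in _SITE_COLUMNS.items():
        if field == "id":
            continue
        vals = table.sites[field]
        if field in ("reverse", "contaminant"):
            vals = np.where(vals.astype(bool), "+", "")
        out[col] = np.asarray(vals)
    # floats are written via repr so values survive a parse round trip
    # bit-exactly (pandas' default float formatting does not)
    out["Localization prob"] = [repr(float(v)) for v in out["Localization prob"]]
    inten = table.intensities.fillna(0.0)
    for s in table.design.index:
        out[_INTENSITY_PREFIX + s] = [repr(float(v)) for v in inten[s]]
    out.to_csv(path, sep="\t", index=False)


def read_sites(path, design: pd.DataFrame) -> PhosphoSiteTable:
    """Parse a site table against a sample design.

    Intensity columns are reordered to the design order regardless of file
    order; zeros become missing; unknown extra columns are ignored with a
    warning. A design sample absent from the header is a hard error.
    """
    design = validate_design(design)
    df = pd.read_csv(path, sep="\t", dtype={"id": str},
                     float_precision="round_trip")
    required = list(_SITE_COLUMNS.values())
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    for s in design.index:
        col = _INTENSITY_PREFIX + s
        if col not in df.columns:
            raise ValueError(f"{path}: design sample {s!r} has no column {col!r}")
    known = set(required) | {_INTENSITY_PREFIX + s for s in design.index}
    extras = [c for c in df.columns if c not in known]
    if extras:
        log.warning("%s: ignoring %d unknown columns: %s", path, len(extras), extras)

    sites = pd.DataFrame(index=pd.Index(df["id"], name="site_id"))
    for field, col in _SITE_COLUMNS.items():
        if field == "id":
            continue
        vals = df[col]
        if field in ("reverse", "contaminant"):
            sites[field] = vals.fillna("").astype(str).str.strip().eq("+").to_numpy()
        else:
            sites[field] = vals.to_numpy()
    sites["position"] = sites["position"].astype(int)
    sites["multiplicity"] = sites["multiplicity"].astype(int)
    sites["localisation_prob"] = sites["localisation_prob"].astype(float)

    inten = pd.DataFrame(index=sites.index)
    for s in design.index:
        col = df[_INTENSITY_PREFIX + s].astype(float)
        if col.isna().any():
            raise ValueError(f"{path}: non-numeric intensity in sample {s!r}")
        if (col < 0).any():
            raise ValueError(f"{path}: negative intensity in sample {s!r}")
        inten[s] = col.replace(0.0, np.nan).to_numpy()
    return PhosphoSiteTable(sites, inten, design)


# ---------------------------------------------------------------- gene sets


def read_gmt(path, category: str | None = None) -> dict[str, set]:
    """Read a GMT gene-set collection: name, description, members per line."""
    sets: dict[str, set] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(parts)} fields)"
                )
            name = parts[0]
            members = {m for m in parts[2:] if m}
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, set], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ------------------------------------------------------------------- edges


def read_edges(path) -> pd.DataFrame:
    """Read an interaction edge list TSV (protein_a, protein_b, confidence).

    Undirected: endpoint order is canonicalised, duplicate edges keep the
    highest confidence, self-loops are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    needed = ["protein_a", "protein_b", "confidence"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: edge list missing columns {missing}")
    conf = df["confidence"].astype(float)
    bad = conf[(conf < 0) | (conf > 1)]
    if len(bad):
        raise ValueError(
            f"{path}: confidence outside [0,1] at rows {bad.index.tolist()[:5]}"
        )
    a = df["protein_a"].astype(str)
    b = df["protein_b"].astype(str)
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    out = pd.DataFrame({"protein_a": lo, "protein_b": hi, "confidence": conf})
    out = out[out["protein_a"] != out["protein_b"]]
    out = (
        out.groupby(["protein_a", "protein_b"], as_index=False)["confidence"].max()
    )
    return out.reset_index(drop=True)


def write_edges(edges: pd.DataFrame, path) -> None:
    edges[["protein_a", "protein_b", "confidence"]].to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------ images


def write_image(channels: np.ndarray, path, roi: np.ndarray | None = None,
                roi_path=None) -> None:
    """Write a (n_channels, h, w) stack as multi-page TIFF, ROI mask alongside."""
    channels = np.asarray(channels)
    if channels.ndim != 3:
        raise ValueError("expected a (n_channels, h, w) array")
    tifffile.imwrite(path, channels)
    if roi is not None:
        if roi_path is None:
            roi_path = Path(path).with_name(Path(path).stem + "_roi.tif")
        tifffile.imwrite(roi_path, np.asarray(roi).astype(np.uint16))


def read_image(path, roi_path) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-page TIFF and its ROI label mask; shapes must agree."""
    img = tifffile.imread(path)
    if img.ndim == 2:
        img = img[None, :, :]
    roi = tifffile.imread(roi_path)
    if roi.ndim != 2:
        raise ValueError(f"{roi_path}: ROI mask must be 2-D")
    if img.shape[1:] != roi.shape:
        raise ValueError(
            f"shape mismatch: image {img.shape[1:]} vs ROI {roi.shape}"
        )
    return img, roi
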