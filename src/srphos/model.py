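"""Shared data model for the phosphoproteomics pipeline.

Containers are thin wrappers around pandas objects so every stage can be
inspected, sliced and serialised with ordinary DataFrame tooling. The two
experimental arms share one site-table layout; they differ only in the
sample design (``compartment`` global vs proximal, and the APEX2 ``bait``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: residues that can carry a phosphate in this assay
RESIDUES = ("S", "T", "Y")

#: canonical trafficking-perturbation conditions, in plotting order
TRAFFICKING_CONDITIONS = ("UT", "FGF10_GFP", "FGF10_DnRAB11", "FGF10_DnDNM2")

#: APEX2 baits; GFP_reference is the spatial background control
BAITS = ("FGFR2b", "RAB11", "GFP_reference", "none")

COMPARTMENTS = ("global", "proximal")

DESIGN_COLUMNS = [
    "sample_id",
    "cell_line",
    "condition",
    "replicate",
    "compartment",
    "bait",
    "treatment",
    "timepoint_min",
]

SITE_META_COLUMNS = [
    "protein_id",
    "gene",
    "position",
    "residue",
    "multiplicity",
    "localisation_prob",
    "reverse",
    "contaminant",
]


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-design table and return it indexed by sample_id.

    Raises ``ValueError`` on missing columns, duplicate
    (condition, replicate) pairs within a compartment, or a proximal
    sample without a bait.
    """
    df = design.copy()
    if df.index.name == "sample_id":
        df = df.reset_index(drop="sample_id" in df.columns)
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"design is missing columns: {missing}")
    bad_comp = set(df["compartment"]) - set(COMPARTMENTS)
    if bad_comp:
        raise ValueError(f"unknown compartment values: {sorted(bad_comp)}")
    bad_bait = set(df["bait"]) - set(BAITS)
    if bad_bait:
        raise ValueError(f"unknown bait values: {sorted(bad_bait)}")
    dup = df.duplicated(subset=["compartment", "condition", "replicate"])
    if dup.any():
        raise ValueError(
            "duplicate (condition, replicate) within a compartment: "
            f"{df.loc[dup, 'sample_id'].tolist()}"
        )
    prox = df[df["compartment"] == "proximal"]
    if (prox["bait"] == "none").any():
        raise ValueError("every proximal sample must declare a bait")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in design")
    return df.set_index("sample_id", drop=False)


@dataclass
class PhosphoSiteTable:
    """A site-by-sample intensity matrix with site metadata and design.

    ``intensities`` holds raw (linear) LFQ intensities with ``NaN`` for
    missing quantifications; columns follow the design order exactly.
    """

    sites: pd.DataFrame
    intensities: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.design = validate_design(self.design)
        if list(self.intensities.columns) != list(self.design.index):
            raise ValueError("intensity columns must match design sample order")
        if not self.sites.index.equals(self.intensities.index):
            raise ValueError("site metadata and intensity rows disagree")
        lp = self.sites["localisation_prob"]
        if ((lp < 0) | (lp > 1)).any():
            raise ValueError("localisation_prob outside [0, 1]")
        if (self.sites["position"] < 1).any():
            raise ValueError("positions are 1-based; found position < 1")
        bad = set(self.sites["residue"]) - set(RESIDUES)
        if bad:
            raise ValueError(f"unknown residues: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def subset(self, site_ids) -> "PhosphoSiteTable":
        return PhosphoSiteTable(
            self.sites.loc[site_ids].copy(),
            self.intensities.loc[site_ids].copy(),
            self.design.copy(),
        )


@dataclass
class NormalizedMatrix:
    """log2 site-by-sample matrix after group-wise quantile normalization.

    ``groups`` maps each sample to its normalization group (global /
    proximal samples are never co-normalized). ``imputed_mask`` marks the
    cells that were missing before imputation; it is all-False until an
    imputation step runs.
    """

    values: pd.DataFrame
    groups: pd.Series
    imputed_mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.imputed_mask is None:
            self.imputed_mask = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        if list(self.groups.index) != list(self.values.columns):
            raise ValueError("groups must be indexed by the sample columns")

    def copy(self) -> "NormalizedMatrix":
        return NormalizedMatrix(
            self.values.copy(), self.groups.copy(), self.imputed_mask.copy()
        )


@dataclass
class ClusterModel:
    """Fuzzy c-means result over condition median z-profiles."""

    centroids: pd.DataFrame  # cluster x condition
    memberships: pd.DataFrame  # site x cluster, rows sum to 1
    fuzzifier: float
    objective: float
    objective_history: np.ndarray
    response_labels: dict = field(default_factory=dict)  # cluster -> label

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    @property
    def assigned_cluster(self) -> pd.Series:
        """Hard assignment: argmax membership, ties broken by lowest index."""
        arr = self.memberships.to_numpy()
        idx = np.argmax(arr, axis=1)  # np.argmax takes the first maximum
        return pd.Series(
            self.memberships.columns.to_numpy()[idx],
            index=self.memberships.index,
            name="cluster",
        )


@dataclass
class ProximalContrast:
    """Per-site log2 bait-minus-reference ratios and the recycling flag."""

    ratios: pd.DataFrame  # site x "bait|treatment" columns
    linkage: np.ndarray | None = None
    k_cut: int | None = None
    in_recycling_cluster: pd.Series | None = None


@dataclass
class ColocResult:
    """Colocalization statistics for one ROI of one image."""

    roi_label: int
    roi_pixels: int
    ef: dict  # channel name -> expression fraction
    of: float
    m1: float
    m2: float
    t_a: float
    t_b: float

    def as_dict(self) -> dict:
        out = {"roi_label": self.roi_label, "roi_pixels": self.roi_pixels}
        out.update({f"EF_{k}": v for k, v in self.ef.items()})
        out.update(
            {"OF": self.of, "M1": self.m1, "M2": self.m2, "t_A": self.t_a, "t_B": self.t_b}
        )
        return out
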