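"""End-to-end orchestration of the two analysis arms.

The trafficking arm mirrors the global-phosphoproteome analysis: filter,
quantile-normalize, valid-value filter, downshifted imputation, median
z-scores, ANOVA gate, fuzzy c-means, response labelling, and Parzen
transfer to a second cell line. The SRP arm mirrors the proximal
analysis: separate normalization of global and proximal samples, QRILC
imputation, replicate-median bait-vs-reference ratios, hierarchical
extraction of the recycling proximal signalling cluster, and overlap/ORA
summaries. Both arms run from one config and write a manifest with a
SHA-256 hash of every output so reruns can be checked for bit-identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, enrichment, preprocess, srp, synthetic
from .model import NormalizedMatrix

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunable parameters of both arms, serialisable to YAML."""

    seed: int = 0
    # synthetic generation
    n_sites: int = 2000
    archetype_fractions: dict = field(
        default_factory=lambda: {
            "membrane": 0.1,
            "internalisation": 0.1,
            "recycling": 0.1,
            "null": 0.7,
        }
    )
    effect_size: float = 2.0
    noise_sd: float = 0.3
    missing_rate: float = 0.1
    proximal_shift: float = 1.0
    n_replicates: int = 3
    # preprocessing
    min_loc_prob: float = 0.75
    min_reps: int = 3
    impute: str = "downshift"  # trafficking arm; SRP arm uses qrilc
    downshift_width: float = 0.3
    downshift_shift: float = 1.8
    # clustering
    anova_alpha: float = 1e-4
    anova_adjust: str = "none"  # the raw-p reading of the gate; 'bh' available
    n_clusters: int = 3
    fuzzifier: float = 2.0
    n_restarts: int = 10
    reg_margin: float = 0.5
    preserve_frac: float = 0.5
    parzen_bandwidth: str = "scott"
    # SRP arm
    k_cut: int = 8
    srp_linkage: str = "ward"
    srp_min_up: float = 0.0
    global_min_log2fc: float = 1.0
    global_alpha: float = 0.05
    # enrichment
    min_confidence: float = 0.4

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Path, config: PipelineConfig, files: list[Path]) -> Path:
    """Record config, a parameter hash and a SHA-256 per output file."""
    cfg = dataclasses.asdict(config)
    param_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "parameters": cfg,
        "parameter_hash": param_hash,
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(files)},
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def _write(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, sep="\t", **kw)
    return path


def preprocess_trafficking(table, config: PipelineConfig):
    """Raw site table -> (condition-median z, replicate z) for one arm."""
    filtered, report = preprocess.filter_sites(table, config.min_loc_prob)
    logm = preprocess.log2_intensities(filtered)
    groups = filtered.design["compartment"]
    norm = preprocess.quantile_normalize(logm, groups)
    kept = preprocess.valid_value_filter(
        norm.values, filtered.design, config.min_reps
    )
    norm = NormalizedMatrix(kept, norm.groups)
    if config.impute == "downshift":
        imputed = preprocess.impute_downshift(
            norm, config.downshift_width, config.downshift_shift, seed=config.seed
        )
    elif config.impute == "qrilc":
        imputed = preprocess.impute_qrilc(norm, seed=config.seed)
    else:
        raise ValueError(f"unknown imputation {config.impute!r}")
    med_z, rep_z = preprocess.median_zscore(imputed.values, filtered.design)
    return med_z, rep_z, filtered, report


def run_trafficking_arm(
    config: PipelineConfig,
    outdir,
    gene_sets: dict[str, set] | None = None,
    compartment_sets: dict[str, set] | None = None,
) -> dict:
    """Simulate (or load) the trafficking experiment and run the full arm.

    Returns the in-memory artifacts; writes TSVs plus a hashed manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = synthetic.trafficking_design("HeLa_FGFR2b", config.n_replicates)
    table, truth = synthetic.gen_phospho_dataset(
        design,
        n_sites=config.n_sites,
        archetype_fractions=config.archetype_fractions,
        effect_size=config.effect_size,
        missing_rate=config.missing_rate,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    med_z, rep_z, filtered, filter_report = preprocess_trafficking(table, config)

    kept, anova_table = clustering.anova_gate(
        rep_z, filtered.design, config.anova_alpha, config.anova_adjust
    )
    model = clustering.fuzzy_cmeans(
        med_z.loc[kept],
        c=config.n_clusters,
        m=config.fuzzifier,
        n_restarts=config.n_restarts,
        seed=config.seed,
    )
    labels = clustering.label_responses(
        model, reg_margin=config.reg_margin, preserve_frac=config.preserve_frac
    )

    # transfer to a second cell line: same archetypes, fresh noise
    design2 = synthetic.trafficking_design("T47D", config.n_replicates)
    table2, truth2 = synthetic.gen_phospho_dataset(
        design2,
        n_sites=config.n_sites,
        archetype_fractions=config.archetype_fractions,
        effect_size=config.effect_size,
        missing_rate=config.missing_rate,
        noise_sd=config.noise_sd,
        seed=config.seed + 1,
    )
    med_z2, rep_z2, filtered2, _ = preprocess_trafficking(table2, config)
    kept2, _ = clustering.anova_gate(
        rep_z2, filtered2.design, config.anova_alpha, config.anova_adjust
    )
    clf = clustering.fit_parzen(
        med_z.loc[kept],
        model.assigned_cluster,
        bandwidth=config.parzen_bandwidth,
    )
    transfer_labels, posteriors = clustering.classify(clf, med_z2.loc[kept2])

    enrich_tables = {}
    if gene_sets is not None:
        site2prot = filtered.sites["protein_id"]
        background = set(site2prot)
        for resp in ("membrane", "internalisation", "recycling"):
            members = [k for k, v in labels.items() if v == resp]
            if not members:
                continue
            fg_sites = model.assigned_cluster.index[
                model.assigned_cluster.isin(members)
            ]
            fg = set(site2prot.loc[fg_sites])
            enrich_tables[resp] = enrichment.ora(fg, background, gene_sets)
    compartment_table = None
    if compartment_sets is not None and "recycling" in set(labels.values()):
        members = [k for k, v in labels.items() if v == "recycling"]
        fg_sites = model.assigned_cluster.index[
            model.assigned_cluster.isin(members)
        ]
        fg = set(filtered.sites["protein_id"].loc[fg_sites])
        compartment_table = enrichment.compartment_summary(fg, compartment_sets)

    files = []
    files.append(_write(med_z, outdir / "median_z.tsv"))
    files.append(_write(anova_table, outdir / "anova.tsv"))
    files.append(_write(model.memberships, outdir / "memberships.tsv"))
    files.append(_write(model.centroids, outdir / "centroids.tsv"))
    files.append(
        _write(
            pd.DataFrame(
                {"cluster": list(labels), "response": list(labels.values())}
            ),
            outdir / "cluster_labels.tsv",
            index=False,
        )
    )
    files.append(
        _write(
            pd.concat([transfer_labels, posteriors], axis=1),
            outdir / "transfer.tsv",
        )
    )
    for resp, tab in enrich_tables.items():
        files.append(_write(tab, outdir / f"ora_{resp}.tsv", index=False))
    if compartment_table is not None:
        files.append(_write(compartment_table, outdir / "compartments.tsv",
                            index=False))
    manifest = write_manifest(outdir, config, files)
    return {
        "median_z": med_z,
        "anova": anova_table,
        "gated": kept,
        "model": model,
        "response_labels": labels,
        "truth": truth,
        "truth2": truth2,
        "transfer_labels": transfer_labels,
        "posteriors": posteriors,
        "enrichment": enrich_tables,
        "compartments": compartment_table,
        "filter_report": filter_report,
        "manifest": manifest,
    }


def run_srp_arm(config: PipelineConfig, outdir) -> dict:
    """Simulate (or load) the proximal experiment and run the SRP arm."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = synthetic.srp_design("HeLa_FGFR2b", config.n_replicates)
    table, truth = synthetic.gen_phospho_dataset(
        design,
        n_sites=config.n_sites,
        archetype_fractions=config.archetype_fractions,
        effect_size=config.effect_size,
        missing_rate=config.missing_rate,
        noise_sd=config.noise_sd,
        proximal_shift=config.proximal_shift,
        seed=config.seed,
    )
    filtered, filter_report = preprocess.filter_sites(table, config.min_loc_prob)
    logm = preprocess.log2_intensities(filtered)
    groups = filtered.design["compartment"]  # global/proximal never co-normalized
    norm = preprocess.quantile_normalize(logm, groups)
    kept = preprocess.valid_value_filter(
        norm.values, filtered.design, config.min_reps
    )
    norm = NormalizedMatrix(kept, norm.groups)
    imputed = preprocess.impute_qrilc(norm, seed=config.seed)

    contrast = srp.reference_normalize(imputed, filtered.design)
    contrast = srp.extract_recycling_cluster(
        contrast,
        k_cut=config.k_cut,
        linkage=config.srp_linkage,
        min_up=config.srp_min_up,
    )
    up_sites, up_table = srp.global_fgf10_up(
        imputed.values,
        filtered.design,
        min_log2fc=config.global_min_log2fc,
        alpha=config.global_alpha,
    )
    site2prot = filtered.sites["protein_id"]
    cluster_sites = set(
        contrast.in_recycling_cluster.index[contrast.in_recycling_cluster]
    )
    overlap = srp.overlap_analysis(
        {
            "recycling_cluster_sites": cluster_sites,
            "global_fgf10_up_sites": set(up_sites),
            "proximal_phospho_proteins": set(site2prot.loc[list(cluster_sites)])
            if cluster_sites
            else set(),
        }
    )

    files = []
    files.append(_write(contrast.ratios, outdir / "ratios.tsv"))
    files.append(
        _write(
            contrast.in_recycling_cluster.rename("in_recycling_cluster").to_frame(),
            outdir / "recycling_cluster.tsv",
        )
    )
    files.append(_write(up_table, outdir / "global_fgf10_up.tsv"))
    files.append(_write(overlap, outdir / "overlap.tsv", index=False))
    manifest = write_manifest(outdir, config, files)
    return {
        "contrast": contrast,
        "truth": truth,
        "global_up": up_sites,
        "global_up_table": up_table,
        "overlap": overlap,
        "filter_report": filter_report,
        "manifest": manifest,
    }
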