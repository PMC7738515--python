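"""End-to-end pipeline: simulate -> process -> integrate -> cluster -> map
-> correlate -> differential, with a validated configuration and a run
manifest.  One top-level seed deterministically derives every per-stage
seed, so a configuration reproduces its outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .antigen_map import build_antigen_map, score_concordance
from .cluster import pca, two_dimensional_cluster
from .corrstats import compare_median_correlations, pairwise_correlations, split_and_summarise
from .differential import DifferentialConfig, permutation_fdr, volcano_table
from .exceptions import ConfigError
from .integration import annotate_panels, integrate
from .io import write_json, write_tsv
from .processing import process_platform
from .synthetic import (
    DEFAULT_SYNONYMS,
    default_antigen_config,
    default_platforms,
    derive_seed,
    simulate_study,
)
from .treefiles import write_cluster_files

__all__ = ["PipelineConfig", "run_pipeline"]

_DEFAULT_CONTRASTS = [
    {"cell_line": "SKBR3", "treatment": "lapatinib", "timepoint_min": 20},
    {"cell_line": "MDA-MB-231", "treatment": "selumetinib", "timepoint_min": 20},
]


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration.  Unknown keys are rejected on load."""

    seed: int = 7
    out_dir: str = "results"
    subset: str = "all"  # "all" (108 samples) or "control" (DMSO, 20 min)
    metric: str = "spearman"
    normalisation: str = "dilution_fit"
    normalisation_overrides: dict = field(default_factory=lambda: {"edinburgh": "total_protein"})
    centring: str = "analysed"  # "analysed" or "control": sample set used for medians
    concordance_rule: str = "sibling"
    concordance_k: int = 3
    s0: float = 1.0
    fdr_threshold: float = 0.05
    n_permutations: int = 1000
    replicate_sd: float = 0.25
    antibody_noise_sd: float = 0.15
    noise_free: bool = False
    n_eff: int | None = None  # Fisher-test sample count; default = n samples
    contrasts: list = field(default_factory=lambda: [dict(c) for c in _DEFAULT_CONTRASTS])
    figures: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        cfg = cls(**data)
        if cfg.subset not in ("all", "control"):
            raise ConfigError("subset must be 'all' or 'control'")
        if cfg.centring not in ("analysed", "control"):
            raise ConfigError("centring must be 'analysed' or 'control'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "figures")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: PipelineConfig, stage: str) -> dict:
    return {
        "generator": f"crossrppa {__version__}",
        "stage": stage,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artefacts; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stages": {},
    }

    # --- simulate -----------------------------------------------------
    platforms = default_platforms(
        noise_sd=config.antibody_noise_sd, noise_free=config.noise_free
    )
    study = simulate_study(
        derive_seed(config.seed, "study"),
        antigen_config=default_antigen_config(
            replicate_sd=0.0 if config.noise_free else config.replicate_sd
        ),
        platforms=platforms,
    )
    write_tsv(study.sample_table, out / "samples.tsv", _provenance(config, "simulate"))
    for pid, render in study.renders.items():
        write_tsv(
            render.spots, out / f"spots_{pid}.tsv",
            _provenance(config, "simulate"), index=False,
        )
    manifest["stages"]["simulate"] = {
        pid: r.provenance for pid, r in study.renders.items()
    }

    # --- process ------------------------------------------------------
    processed = []
    for pcfg in study.platforms:
        method = config.normalisation_overrides.get(pcfg.platform_id, config.normalisation)
        render = study.renders[pcfg.platform_id]
        mat = process_platform(
            render.spots,
            pcfg.platform_id,
            method=method,
            total_protein=render.total_protein,
            detection_floor=pcfg.detection_floor,
        )
        processed.append(mat)
        write_tsv(mat.values, out / f"processed_{pcfg.platform_id}.tsv",
                  _provenance(config, "process"))
    manifest["stages"]["process"] = {
        m.platform_id: {"method": m.method, "n_readings": m.n_readings} for m in processed
    }

    # --- integrate ----------------------------------------------------
    annotations = annotate_panels(study.raw_annotations, DEFAULT_SYNONYMS)
    write_tsv(annotations, out / "antibody_annotations.tsv",
              _provenance(config, "integrate"), index=False)
    controls = study.sample_table.query("treatment == 'DMSO' and timepoint_min == 20").index
    if config.subset == "control":
        subset = list(controls)
        processed = [
            dataclasses.replace(m, values=m.values.loc[subset], qc=m.qc.loc[subset])
            for m in processed
        ]
    centring = list(controls) if config.centring == "control" else None
    integrated = integrate(processed, annotations, centring_samples=centring)
    write_tsv(integrated.values, out / "integrated.tsv", _provenance(config, "integrate"))
    write_json({"provenance": _provenance(config, "integrate"), **integrated.manifest},
               out / "integration_manifest.json")
    manifest["stages"]["integrate"] = integrated.manifest

    # --- cluster ------------------------------------------------------
    row_dend, col_dend, reordered = two_dimensional_cluster(
        integrated.values, metric=config.metric
    )
    write_cluster_files(integrated.values, row_dend, col_dend, out / "clustered")
    pca_res = pca(
        integrated.values,
        n_components=min(5, integrated.values.shape[0] - 1, integrated.values.shape[1]),
    )
    write_tsv(pca_res.scores, out / "pca_scores.tsv", _provenance(config, "cluster"))
    manifest["stages"]["cluster"] = {
        "metric": config.metric,
        "row_inversions": row_dend.n_inversions,
        "col_inversions": col_dend.n_inversions,
        "pc1_variance_fraction": float(pca_res.variance_fraction[0]),
    }

    # --- antigen map + concordance ------------------------------------
    amap = build_antigen_map(col_dend.leaf_order, integrated.column_annotations)
    amap.to_tsv(out / "antigen_map.tsv")
    report = score_concordance(
        col_dend, integrated.column_annotations,
        rule=config.concordance_rule, k=config.concordance_k,
    )
    write_tsv(report.per_class, out / "concordance.tsv", _provenance(config, "map"))
    manifest["stages"]["map"] = report.summary()

    # --- correlations -------------------------------------------------
    pairs = pairwise_correlations(integrated)
    write_tsv(pairs, out / "pairwise_correlations.tsv",
              _provenance(config, "correlate"), index=False)
    groups = split_and_summarise(pairs, "like_vs_all")
    n_eff = config.n_eff or integrated.values.shape[0]
    comparison = compare_median_correlations(
        groups["like_antigen"].values, groups["all_antibodies"].values, n_eff
    )
    manifest["stages"]["correlate"] = {
        "n_pairs": int(len(pairs)),
        "median_like_antigen": groups["like_antigen"].median,
        "median_all_antibodies": groups["all_antibodies"].median,
        "fisher_z": comparison.z,
        "fisher_p": comparison.p,
        "n_eff": n_eff,
    }

    # --- differential -------------------------------------------------
    if config.subset == "all":
        diff_manifest = {}
        for contrast in config.contrasts:
            cell, drug, tp = (
                contrast["cell_line"], contrast["treatment"], contrast["timepoint_min"],
            )
            sel = study.sample_table.query(
                "cell_line == @cell and timepoint_min == @tp and treatment in [@drug, 'DMSO']"
            )
            dcfg = DifferentialConfig(
                s0=config.s0,
                n_permutations=config.n_permutations,
                fdr_threshold=config.fdr_threshold,
                seed=derive_seed(config.seed, f"fdr:{cell}:{drug}:{tp}"),
            )
            result = permutation_fdr(
                integrated.values.loc[sel.index], sel["treatment"], drug, "DMSO", dcfg
            )
            tag = f"{cell}_{drug}_{tp}min".replace("/", "-")
            write_tsv(volcano_table(result), out / f"differential_{tag}.tsv",
                      _provenance(config, "differential"), index=False)
            diff_manifest[tag] = {
                "n_significant": int(result.table["significant"].sum()),
                "n_perm_used": result.n_perm_used,
                "cut": None if result.cut == float("inf") else result.cut,
            }
        manifest["stages"]["differential"] = diff_manifest

    if config.figures:
        from . import plots

        plots.plot_correlation_densities(groups, out / "correlation_densities.png")
        plots.plot_antigen_map(amap, out / "antigen_map.png")

    write_json(manifest, out / "manifest.json")
    return manifest
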