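"""End-to-end pipeline orchestration.

Stages run in dependency order: input synthesis (or loading) -> profile
normalisation -> diversity/ordination -> per-rank differential abundance ->
marker selection -> co-abundance gene groups -> viral presence calls ->
SCFA comparison and species correlation. Every stochastic stage derives its
randomness from the single pipeline seed, so a re-run with the same
configuration reproduces every output file byte for byte. A stage whose
dependency yields nothing (e.g. no significant species for the marker
stage) is skipped cleanly with a logged reason rather than failing.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cag, diffabund, ecology, markers, profile_io, scfa, synthdata
from .exceptions import ConfigurationError, DataError

log = logging.getLogger("mgmwas")


@dataclass
class PipelineConfig:
    """Single configuration object for a full run.

    Exactly one of ``inputs`` (paths to existing profile tables) or
    ``synth`` (a SynthConfig block) must be active. Every study constant
    surfaces as a named key with its conventional default: q < 0.05
    significance, depth > 2 viral presence, AChRAb > 0.5 nmol/L positivity,
    CAG network edge thresholds 0.5 / -0.2, inclusive 80% species
    annotation, 500 trees, 5 folds, 5 trials.
    """

    outdir: str = "out"
    seed: int = 0
    synth: synthdata.SynthConfig | None = None
    inputs: dict | None = None  # paths: taxa, gene_families, metadata, depths, scfa
    q_threshold: float = 0.05
    depth_threshold: float = 2.0
    achrab_cutoff: float = 0.5
    canopy: dict = field(default_factory=lambda: {"t_gather": 0.9, "t_merge": 0.97, "min_size": 3})
    edge_pos: float = 0.5
    edge_neg: float = -0.2
    rf_params: dict = field(default_factory=lambda: {"n_estimators": 500})
    n_folds: int = 5
    n_trials: int = 5
    n_control_holdout: int = 12
    contrast: str = "case-vs-control"

    def __post_init__(self) -> None:
        if (self.synth is None) == (self.inputs is None):
            raise ConfigurationError("exactly one of synth/inputs must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw and raw["synth"] is not None:
            synth_raw = dict(raw["synth"])
            if "cag_size_range" in synth_raw:
                synth_raw["cag_size_range"] = tuple(synth_raw["cag_size_range"])
            raw["synth"] = synthdata.SynthConfig(**synth_raw)
        return cls(**raw)


_CONTRASTS = {
    "case-vs-control": diffabund.ContrastSpec.case_vs_control,
    "achrab-pos-vs-control": diffabund.ContrastSpec.achrab_positive_vs_control,
    "achrab-neg-vs-control": diffabund.ContrastSpec.achrab_negative_vs_control,
}


@dataclass
class RunReport:
    """Per-stage record of parameters and counts, serialisable to JSON."""

    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"version": self.version, "seed": self.seed, "stages": self.stages},
            indent=2,
            sort_keys=True,
        )


def _load_inputs(config: PipelineConfig):
    if config.synth is not None:
        synth_cfg = dataclasses.replace(config.synth, seed=config.seed)
        dataset = synthdata.generate_dataset(synth_cfg)
        return dataset
    paths = config.inputs
    for key in ("taxa", "metadata"):
        if key not in paths or not Path(paths[key]).exists():
            raise DataError(f"missing required input: {paths.get(key, key)}")
    taxa = profile_io.read_taxonomic_table(paths["taxa"])
    metadata = profile_io.read_metadata(paths["metadata"])
    genes = (
        profile_io.read_gene_family_table(paths["gene_families"])
        if paths.get("gene_families")
        else None
    )
    depths = (
        profile_io.read_depth_table(paths["depths"]) if paths.get("depths") else None
    )
    panel = (
        scfa.SCFAPanel(pd.read_csv(paths["scfa"], sep="\t", index_col="sample"))
        if paths.get("scfa")
        else None
    )
    return synthdata.SynthDataset(None, taxa, metadata, genes, depths, panel, None)


def run_pipeline(config: PipelineConfig) -> RunReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    contrast = _CONTRASTS[config.contrast](config.q_threshold)

    dataset = _load_inputs(config)
    taxa, metadata = dataset.taxa, dataset.metadata
    if config.synth is not None:
        synthdata.write_dataset(dataset, outdir / "inputs")
    report.stages["inputs"] = {
        "n_samples": len(metadata.samples),
        "n_case": len(metadata.case_ids()),
        "n_control": len(metadata.control_ids()),
        "n_species_features": len(taxa.features),
    }

    # --- diversity -------------------------------------------------------
    rel = taxa if taxa.normalization == "relative" else profile_io.renormalize(taxa)
    shannon = ecology.shannon_index(rel)
    shannon.to_frame().to_csv(outdir / "shannon.tsv", sep="\t")
    dist = ecology.bray_curtis(rel)
    dist.to_frame().to_csv(outdir / "bray_curtis.tsv", sep="\t")
    ordination = ecology.pcoa(dist, n_axes=2)
    ordination.coordinates.to_csv(outdir / "pcoa.tsv", sep="\t")
    stat, p = ecology.diversity_group_test(shannon, metadata)
    report.stages["diversity"] = {
        "shannon_mean": float(shannon.mean()),
        "shannon_group_p": float(p),
        "pcoa_axis1_fraction": float(ordination.proportion_explained[0]),
    }

    # --- differential abundance across taxonomic ranks -------------------
    combined = profile_io.aggregate_to_ranks(rel)
    diff = diffabund.differential_features(combined, metadata, contrast, per_rank=True)
    diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    sig_species = diff[(diff["rank"] == "species") & diff["significant"]]
    report.stages["differential"] = {
        "n_tested": int(len(diff)),
        "n_significant": int(diff["significant"].sum()),
        "n_significant_species": int(len(sig_species)),
        "contrast": contrast.name,
    }

    # --- marker selection -------------------------------------------------
    candidates = sorted(sig_species["feature"])
    if "cohort" in metadata.data.columns:
        discovery = metadata.data.index[metadata.data["cohort"] == "discovery"]
    else:
        discovery = metadata.data.index
    validation_cases = [s for s in metadata.case_ids() if s not in set(discovery)]
    if len(candidates) < 2:
        log.warning("marker stage skipped: %d significant species", len(candidates))
        report.stages["markers"] = {"skipped": True, "n_candidates": len(candidates)}
    else:
        species_rel = profile_io.filter_by_rank(combined, "species")
        disc_cases = [s for s in metadata.case_ids() if s in set(discovery)]
        controls = metadata.control_ids()
        if validation_cases:
            split = markers.make_train_test_split(
                disc_cases, controls, validation_cases,
                min(config.n_control_holdout, len(controls)), seed=config.seed,
            )
        else:
            split = markers.TrainTestSplit(
                tuple(disc_cases), tuple(controls), (), (), config.seed
            )
        labels = metadata.group()
        train_table = species_rel.subset_samples(split.train)
        result = markers.select_markers(
            train_table, labels.loc[split.train], candidates,
            n_folds=config.n_folds, n_trials=config.n_trials,
            rf_params=config.rf_params, seed=config.seed,
        )
        result.curve_set.to_frame().to_csv(outdir / "error_curves.tsv", sep="\t", index=False)
        pd.Series(result.markers, name="marker").to_csv(outdir / "markers.tsv", sep="\t", index=False)
        result.probabilities.rename("probability").to_frame().assign(
            set="train", label=result.labels
        ).to_csv(outdir / "probabilities_train.tsv", sep="\t")
        result.roc_points.to_csv(outdir / "roc_train.tsv", sep="\t", index=False)
        stage = {
            "n_candidates": len(candidates),
            "k_min": result.curve_set.k_min,
            "k_star": result.curve_set.k_star,
            "selected_markers": result.markers,
            "train_auc_oob": result.auc,
            "train_n_case": len(split.train_case),
            "train_n_control": len(split.train_control),
        }
        if split.test:
            test_table = species_rel.subset_samples(split.test)
            test_probs = result.model.predict_probability(test_table)
            test_probs.rename("probability").to_frame().assign(
                set="test", label=labels.loc[split.test]
            ).to_csv(outdir / "probabilities_test.tsv", sep="\t")
            roc_points, test_auc = markers.roc_auc(test_probs, labels.loc[split.test])
            roc_points.to_csv(outdir / "roc_test.tsv", sep="\t", index=False)
            stage.update(
                {
                    "test_auc": test_auc,
                    "test_n_case": len(split.test_case),
                    "test_n_control": len(split.test_control),
                }
            )
        report.stages["markers"] = stage

    # --- co-abundance gene groups ----------------------------------------
    if dataset.gene_families is None:
        report.stages["cag"] = {"skipped": True}
    else:
        genes = dataset.gene_families
        _, strat = profile_io.split_stratified(genes)
        gene_diff = diffabund.differential_features(strat, metadata, contrast, per_rank=False)
        sig_families = gene_diff[gene_diff["significant"]]["feature"].tolist()
        pool = strat.subset_features(sig_families) if len(sig_families) >= 2 else strat
        cags = cag.canopy_cluster(pool, seed=config.seed, **config.canopy)
        for c in cags:
            cag.annotate_cag(c)
        cag.cag_enrichment(cags, metadata, contrast)
        cag.membership_frame(cags).to_csv(outdir / "cag_membership.tsv", sep="\t", index=False)
        stage = {
            "n_stratified_families": len(strat.features),
            "n_significant_families": len(sig_families),
            "n_cags": len(cags),
        }
        if len(cags) >= 2:
            network = cag.build_network(cags, config.edge_pos, config.edge_neg)
            network.edges.to_csv(outdir / "cag_network_edges.tsv", sep="\t", index=False)
            network.write_graphml(outdir / "cag_network.graphml")
            stage["n_edges"] = int(network.n_edges)
        report.stages["cag"] = stage

    # --- virome -----------------------------------------------------------
    if dataset.depths is None:
        report.stages["virome"] = {"skipped": True}
    else:
        calls = profile_io.call_viral_presence(dataset.depths, config.depth_threshold)
        pd.DataFrame(sorted(calls), columns=["sample", "reference"]).to_csv(
            outdir / "viral_presence.tsv", sep="\t", index=False
        )
        groups = metadata.group()
        report.stages["virome"] = {
            "n_positive": len(calls),
            "n_positive_case": sum(groups.get(s) == "case" for s, _ in calls),
            "n_positive_control": sum(groups.get(s) == "control" for s, _ in calls),
        }

    # --- SCFA -------------------------------------------------------------
    if dataset.scfa_panel is None:
        report.stages["scfa"] = {"skipped": True}
    else:
        panel = dataset.scfa_panel
        tests = scfa.compare_groups(panel, metadata)
        tests.to_csv(outdir / "scfa_tests.tsv", sep="\t")
        species_rel = profile_io.filter_by_rank(rel, "species") if rel.has_lineages else rel
        r, p = scfa.species_scfa_correlation(species_rel, panel)
        long = (
            r.stack().rename("r").to_frame().join(p.stack().rename("p"))
            .reset_index().rename(columns={"level_0": "species", "level_1": "acid"})
        )
        long.to_csv(outdir / "species_scfa_correlation.tsv", sep="\t", index=False)
        report.stages["scfa"] = {
            "butyric_p": float(tests.loc["butyric", "p"]),
            "isobutyric_p": float(tests.loc["isobutyric", "p"]),
            "n_acids": len(panel.acids),
        }

    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
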