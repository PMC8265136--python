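"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates a two-cohort case/control metagenomic study: a
log-normal compositional taxonomic profile with planted differential
species, stratified gene-family profiles with planted co-abundant blocks
attributable to a species, sparse viral alignment depth confined to the
case group, and an SCFA panel whose concentrations couple to selected
species through the centred log-ratio (CLR) of their abundance, so coupling
is scale-free on compositional data.

Defaults mirror the study design the pipeline targets: 53 cases vs 46
controls, 25 planted differential species, a case-group adenovirus
prevalence of 10/53, and a seropositive AChRAb fraction of 34/53. Effect
size and dispersion are calibration choices on the natural-log scale, not
inferences from any cohort. Every emitted table is a pure function of the
seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import profile_io
from .exceptions import ConfigurationError
from .profile_io import AbundanceTable, DepthTable, SampleMetadata
from .scfa import ACIDS, SCFAPanel

#: per-acid baseline serum concentration, μg/ml
_ACID_BASELINES = {
    "acetic": 30.0,
    "propanoic": 10.0,
    "butyric": 10.0,
    "isobutyric": 6.0,
    "n_valeric": 4.0,
    "isovaleric": 4.0,
    "caproic": 3.0,
}

#: acids carrying the planted case/control shift (the deficits the panel is
#: built to detect)
_SHIFTED_ACIDS = ("butyric", "isobutyric")


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of the synthetic study.

    All rates and sizes default to the emulated cohort structure; effect
    sizes are natural-log fold changes and dispersion is the log-scale SD.
    """

    n_case: int = 53
    n_control: int = 46
    n_validation_case: int = 0  # extra cases sharing feature baselines
    n_features: int = 200
    n_differential: int = 25
    effect_size: float = 2.0
    dispersion: float = 1.0
    zero_inflation: float = 0.3
    n_gene_families: int = 200
    n_cags: int = 5
    cag_size_range: tuple[int, int] = (10, 20)
    within_cag_correlation: float = 0.95
    cag_group_effect: float = 0.0  # log-scale case/control shift of CAG latents
    n_species_labels: int = 12
    viral_prevalence_case: float = 10 / 53
    viral_depth_mean: float = 5.0
    scfa_group_shift: float = -2.0  # μg/ml, applied to butyric & isobutyric in cases
    scfa_noise_sd: float = 2.0
    scfa_species_coupling: float = 1.0  # μg/ml per CLR unit of the coupled species
    scfa_coupled_species: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_differential > self.n_features:
            raise ConfigurationError("n_differential exceeds n_features")
        for name in ("zero_inflation", "viral_prevalence_case"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if not 0.0 <= self.within_cag_correlation <= 1.0:
            raise ConfigurationError("within_cag_correlation must be in [0, 1]")
        if self.cag_size_range[0] < 2:
            raise ConfigurationError("CAG sizes must be >= 2")
        if self.n_cags and self.cag_size_range[1] * self.n_cags > self.n_gene_families:
            raise ConfigurationError("planted CAG sizes exceed n_gene_families")


@dataclass
class SynthTruth:
    """Ground truth of the planted structure."""

    differential_features: dict[str, str] = field(default_factory=dict)  # id -> case/control
    cag_membership: dict[str, tuple[str, str]] = field(default_factory=dict)  # family -> (cag, species)
    viral_positive_samples: set[str] = field(default_factory=set)
    scfa_true_params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "differential_features": dict(sorted(self.differential_features.items())),
            "cag_membership": {k: list(v) for k, v in sorted(self.cag_membership.items())},
            "viral_positive_samples": sorted(self.viral_positive_samples),
            "scfa_true_params": self.scfa_true_params,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([stage, seed]))


def _species_lineage(i: int) -> str:
    phylum = i % 6 + 1
    return (
        f"k__Bacteria|p__Phylum{phylum}|c__Class{phylum}|o__Order{phylum}"
        f"|f__Family{i % 20 + 1}|g__Genus{i % 40 + 1}|s__Species_{i + 1:03d}"
    )


def generate_taxonomic_profiles(
    config: SynthConfig,
) -> tuple[AbundanceTable, SampleMetadata, SynthTruth]:
    """Log-normal compositional species profiles with planted group shifts.

    Per-sample feature value = exp(baseline + direction * effect_size *
    group_indicator + Normal(0, dispersion)); zero-inflation hits
    low-baseline features preferentially; each sample is closed to relative
    abundances summing to one. Metadata mirrors the emulated cohort table:
    group, AChRAb titre (seropositives strictly above 0.5 nmol/L), age,
    gender and birth mode.
    """
    rng = _rng(1, config.seed)
    n_case_all = config.n_case + config.n_validation_case
    case_ids = [f"MG{i + 1:03d}" for i in range(config.n_case)]
    val_ids = [f"MGV{i + 1:03d}" for i in range(config.n_validation_case)]
    control_ids = [f"HC{i + 1:03d}" for i in range(config.n_control)]
    samples = case_ids + val_ids + control_ids
    group_ind = np.array([1] * n_case_all + [0] * config.n_control)

    features = [_species_lineage(i) for i in range(config.n_features)]
    baseline = rng.normal(0.0, 2.0, size=config.n_features)

    directions = np.zeros(config.n_features)
    truth = SynthTruth()
    if config.n_differential > 0 and config.effect_size != 0.0:
        diff_idx = rng.choice(config.n_features, size=config.n_differential, replace=False)
        signs = np.ones(config.n_differential)
        signs[config.n_differential // 2 :] = -1.0  # balanced directions
        directions[diff_idx] = signs
        for i, s in zip(diff_idx, signs):
            truth.differential_features[features[i]] = "case" if s > 0 else "control"

    log_mu = (
        baseline[:, None]
        + directions[:, None] * config.effect_size * group_ind[None, :]
    )
    values = np.exp(log_mu + rng.normal(0.0, config.dispersion, size=log_mu.shape))

    if config.zero_inflation > 0:
        # zeros emulate a detection limit: each feature's lowest values are
        # censored to zero, with an expected zero fraction that is higher for
        # low-baseline features (mean fraction = zero_inflation). The
        # top-baseline feature is never censored so no sample can become
        # all-zero.
        rank_frac = np.argsort(np.argsort(baseline)) / max(config.n_features - 1, 1)
        p_zero = np.clip(2.0 * config.zero_inflation * (1.0 - rank_frac), 0.0, 0.95)
        p_zero[np.argmax(baseline)] = 0.0
        thresholds = np.array(
            [np.quantile(values[i], p_zero[i]) for i in range(config.n_features)]
        )
        values = np.where(values < thresholds[:, None], 0.0, values)

    values = values / values.sum(axis=0, keepdims=True)
    table = AbundanceTable(
        pd.DataFrame(values, index=features, columns=samples),
        normalization="relative",
        has_lineages=True,
    )

    # metadata emulating the cohort's demographic structure
    seropos = rng.random(n_case_all) < 34 / 53
    achrab_case = np.where(
        seropos, rng.uniform(0.6, 15.0, n_case_all), rng.uniform(0.0, 0.5, n_case_all)
    )
    achrab = np.concatenate([achrab_case, rng.uniform(0.0, 0.4, config.n_control)])
    age = np.clip(rng.normal(7.0, 3.8, len(samples)), 2.9, 18.0)
    p_male = np.where(group_ind == 1, 0.302, 0.543)
    gender = np.where(rng.random(len(samples)) < p_male, "M", "F")
    p_vd = np.where(group_ind == 1, 0.547, 0.717)
    birth = np.where(rng.random(len(samples)) < p_vd, "VD", "CS")
    meta = pd.DataFrame(
        {
            "group": ["case"] * n_case_all + ["control"] * config.n_control,
            "cohort": ["discovery"] * config.n_case
            + ["validation"] * config.n_validation_case
            + ["discovery"] * config.n_control,
            "achrab": np.round(achrab, 3),
            "age": np.round(age, 2),
            "gender": gender,
            "birth_mode": birth,
        },
        index=pd.Index(samples, name="sample"),
    )
    return table, SampleMetadata(meta), truth


def generate_gene_family_profiles(
    config: SynthConfig, metadata: SampleMetadata
) -> tuple[AbundanceTable, SynthTruth]:
    """Stratified gene-family profiles with planted co-abundant blocks.

    Each planted block shares a per-sample latent log-factor; member values
    are the exponential of that latent plus independent noise calibrated on
    the log scale so pairwise Pearson r is close to
    ``within_cag_correlation``. At least 80% of each block's members carry
    the block's species tag; the remaining families and all non-block
    families get other labels. Non-block families are independent noise.
    """
    rng = _rng(2, config.seed)
    samples = metadata.samples
    n = len(samples)
    group_ind = (metadata.group() == "case").to_numpy().astype(float)

    r = config.within_cag_correlation
    # members share a unit-variance log-latent; independent log-noise of SD s
    # attenuates the value-scale (log-normal) Pearson correlation to
    # (e - 1) / (exp(1 + s^2) - 1), so s is chosen to hit the target r on the
    # scale the clustering actually sees
    noise_sd = np.sqrt(np.log(1.0 + (np.e - 1.0) / r) - 1.0) if r > 0 else None

    truth = SynthTruth()
    rows, ids = [], []
    if config.n_cags > 0:
        sizes = rng.integers(
            config.cag_size_range[0], config.cag_size_range[1] + 1, size=config.n_cags
        )
        if sizes.sum() > config.n_gene_families:
            raise ConfigurationError("planted CAG sizes exceed n_gene_families")
    else:
        sizes = np.array([], dtype=int)

    for k, size in enumerate(sizes):
        species = f"Blockspecies_{k + 1}"
        direction = 1.0 if k % 2 == 0 else -1.0
        latent = rng.normal(0.0, 1.0, n) + config.cag_group_effect * direction * group_ind
        n_tagged = int(np.ceil(0.9 * size))
        for m in range(size):
            tag = species if m < n_tagged else f"Otherspecies_{(m % config.n_species_labels) + 1}"
            fid = f"UniRef90_B{k + 1:02d}M{m + 1:02d}|g__GenusB{k + 1}.s__{tag}"
            a = rng.normal(0.0, 0.5)
            if noise_sd is None:
                log_v = a + latent * 0.0 + rng.normal(0.0, 1.0, n)  # r == 0: pure noise
            elif noise_sd == 0.0:
                log_v = a + latent
            else:
                log_v = a + latent + rng.normal(0.0, noise_sd, n)
            rows.append(np.exp(log_v))
            ids.append(fid)
            truth.cag_membership[fid] = (f"block_{k + 1}", species)

    n_noise = config.n_gene_families - len(ids)
    for j in range(n_noise):
        tag = f"Otherspecies_{(j % config.n_species_labels) + 1}"
        fid = f"UniRef90_N{j + 1:04d}|g__GenusN.s__{tag}"
        rows.append(np.exp(rng.normal(0.0, 1.0, n) + rng.normal(0.0, 0.5)))
        ids.append(fid)

    table = AbundanceTable(
        pd.DataFrame(np.asarray(rows), index=ids, columns=samples), normalization="raw"
    )
    return table, truth


def generate_viral_depths(
    config: SynthConfig, metadata: SampleMetadata, reference: str = "human_adenovirus_F"
) -> tuple[DepthTable, SynthTruth]:
    """Sparse viral alignment depth confined to the case group.

    Controls always have depth 0; each case is positive with probability
    ``viral_prevalence_case`` and positive depths are 2 + Exponential(mean
    ``viral_depth_mean``) fold-coverage, so every true positive clears the
    over-2x presence cutoff.
    """
    rng = _rng(3, config.seed)
    truth = SynthTruth()
    rows = []
    for sample in metadata.samples:
        depth = 0.0
        if metadata.group().loc[sample] == "case" and rng.random() < config.viral_prevalence_case:
            depth = 2.0 + rng.exponential(config.viral_depth_mean)
            truth.viral_positive_samples.add(sample)
        rows.append({"sample": sample, "reference": reference, "mean_depth": depth})
    return DepthTable(pd.DataFrame(rows)), truth


def _clr(column: np.ndarray, pseudocount: float) -> np.ndarray:
    x = column + pseudocount
    return np.log(x) - np.log(x).mean()


def generate_scfa_panel(
    config: SynthConfig, taxa: AbundanceTable, metadata: SampleMetadata
) -> tuple[SCFAPanel, SynthTruth]:
    """SCFA concentrations coupled to selected species.

    Per acid: baseline + group shift (butyric and isobutyric only, so the
    planted deficit mirrors the acids the panel is built to detect) + the
    coupling coefficient times the CLR abundance of the coupled species +
    Gaussian noise. Coupled species default to the two most abundant
    features of the taxonomic table (butyric and isobutyric respectively).
    """
    rng = _rng(4, config.seed)
    samples = [s for s in metadata.samples if s in taxa.data.columns]
    if len(samples) != len(metadata.samples):
        raise ConfigurationError("taxa table and metadata sample ids differ")
    group_ind = (metadata.group().loc[samples] == "case").to_numpy().astype(float)

    if config.scfa_coupled_species is None:
        by_abundance = taxa.data[samples].mean(axis=1).sort_values(ascending=False)
        coupled = tuple(by_abundance.index[:2])
    else:
        coupled = config.scfa_coupled_species
        missing = [s for s in coupled if s not in taxa.data.index]
        if missing:
            raise ConfigurationError(f"coupled species absent from table: {missing}")

    positive = taxa.data[samples].to_numpy()
    positive = positive[positive > 0]
    pseudo = positive.min() / 2.0 if positive.size else 1e-6
    clr_profiles = {
        sp: _clr(taxa.data.loc[sp, samples].to_numpy(dtype=float), pseudo) for sp in coupled
    }
    coupling_map = dict(zip(_SHIFTED_ACIDS, coupled))

    truth = SynthTruth()
    truth.scfa_true_params = {
        "group_shift": config.scfa_group_shift,
        "shifted_acids": list(_SHIFTED_ACIDS),
        "coupling": {acid: {"species": sp, "coefficient": config.scfa_species_coupling}
                     for acid, sp in coupling_map.items()},
        "noise_sd": config.scfa_noise_sd,
    }

    data = {}
    for acid in ACIDS:
        conc = np.full(len(samples), _ACID_BASELINES[acid])
        if acid in _SHIFTED_ACIDS:
            conc = conc + config.scfa_group_shift * group_ind
        if acid in coupling_map:
            conc = conc + config.scfa_species_coupling * clr_profiles[coupling_map[acid]]
        conc = conc + rng.normal(0.0, config.scfa_noise_sd, len(samples))
        data[acid] = np.clip(conc, 0.0, None)
    panel = SCFAPanel(pd.DataFrame(data, index=pd.Index(samples, name="sample")))
    return panel, truth


@dataclass
class SynthDataset:
    """A fully generated study: tables, metadata, depths, SCFA panel, truth."""

    config: SynthConfig
    taxa: AbundanceTable
    metadata: SampleMetadata
    gene_families: AbundanceTable
    depths: DepthTable
    scfa_panel: SCFAPanel
    truth: SynthTruth


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate every input table of one synthetic study with a shared truth."""
    taxa, metadata, truth = generate_taxonomic_profiles(config)
    genes, gene_truth = generate_gene_family_profiles(config, metadata)
    depths, viral_truth = generate_viral_depths(config, metadata)
    panel, scfa_truth = generate_scfa_panel(config, taxa, metadata)
    truth.cag_membership = gene_truth.cag_membership
    truth.viral_positive_samples = viral_truth.viral_positive_samples
    truth.scfa_true_params = scfa_truth.scfa_true_params
    return SynthDataset(config, taxa, metadata, genes, depths, panel, truth)


def write_dataset(dataset: SynthDataset, outdir: str | Path) -> dict[str, Path]:
    """Write all tables in the pipeline's TSV dialects, plus truth JSON and
    config YAML. Byte-for-byte deterministic for a fixed config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxa": outdir / "taxa_species.tsv",
        "gene_families": outdir / "gene_families.tsv",
        "metadata": outdir / "metadata.tsv",
        "depths": outdir / "viral_depths.tsv",
        "scfa": outdir / "scfa_panel.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    profile_io.write_taxonomic_table(dataset.taxa, paths["taxa"], units="percent")
    profile_io.write_gene_family_table(dataset.gene_families, paths["gene_families"])
    profile_io.write_metadata(dataset.metadata, paths["metadata"])
    profile_io.write_depth_table(dataset.depths, paths["depths"])
    dataset.scfa_panel.data.to_csv(paths["scfa"], sep="\t")
    paths["truth"].write_text(dataset.truth.to_json() + "\n")
    cfg = dataclasses.asdict(dataset.config)
    cfg["cag_size_range"] = list(cfg["cag_size_range"])
    if cfg["scfa_coupled_species"] is not None:
        cfg["scfa_coupled_species"] = list(cfg["scfa_coupled_species"])
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
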