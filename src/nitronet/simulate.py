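"""Synthetic soil-microbiome experiment with known ground truth.

Emulates a fertilization time-course: 2-4 treatments (zero-N control,
fulvic acid, controlled-release urea, and their combination) sampled on
days 1/7/30/60 with 3 replicates, ~20,000 reads per sample.  Taxa are
organized into correlated modules via a log-normal module-factor model:

    z_t(s) = sqrt(rho_w) * f_{m(t)}(s) + sqrt(1 - rho_w) * eps_t(s)

where f_m is a per-sample module factor (unit-variance Gaussian around a
treatment-by-day shift) and rho_w the target within-module latent
correlation.  Log-abundances b_t + sigma * z_t are softmax-normalized to
expected relative abundances, perturbed by a Dirichlet draw (concentration
= dispersion x expectation, modelling replicate-level compositional
noise), and closed by a multinomial draw of ``depth`` reads, so every
sample total equals the configured depth exactly.

Environmental covariates are linear combinations of per-sample module
relative abundances plus Gaussian noise; agronomic records are
per-replicate Gaussians around stated treatment means.  Everything is
driven by one seed with deterministic per-stage substreams.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import to_relative_abundance

TREATMENT_SETS = {
    2: ("CRU", "CRU+FA"),
    3: ("control", "CRU", "CRU+FA"),
    4: ("control", "FA", "CRU", "CRU+FA"),
}

# genera repeatedly implicated in soil N cycling, plus their guilds
GUILD_GENERA = {
    "Sphingomonas": "ammonia-oxidizer",
    "Lysobacter": "nitrifier",
    "Nitrospira": "nitrifier",
    "Nocardioides": "denitrifier",
    "Gaiella": "denitrifier",
    "Ensifer": "N-fixer",
    "Blastococcus": "N-fixer",
    "Pseudolabrys": "N-fixer",
}

_GENUS_PHYLUM = {
    "Sphingomonas": "Proteobacteria",
    "Lysobacter": "Proteobacteria",
    "Nitrospira": "Nitrospirae",
    "Nocardioides": "Actinobacteria",
    "Gaiella": "Actinobacteria",
    "Ensifer": "Proteobacteria",
    "Blastococcus": "Actinobacteria",
    "Pseudolabrys": "Proteobacteria",
}

_FILLER_PHYLA = (
    "Actinobacteria", "Proteobacteria", "Chloroflexi", "Acidobacteria",
    "Bacteroidetes", "Firmicutes", "Gemmatimonadetes", "Planctomycetes",
)

ENV_FACTORS = (
    "NO3-_L", "NH4+_L", "HO3-_L", "pH_L",
    "NO3-_S", "NH4+_S", "pH_S",
    "NO3-_P", "NH4+_P", "pH_P",
    "NUE", "Yield",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults follow the emulated design: 3 treatments x 4 sampling days x
    3 replicates = 36 samples at 20,000 reads each, five correlated
    modules, within-module latent correlation 0.8.  ``module_effect`` is
    the treatment-by-day shift applied to module log-abundance (0 = null
    community); ``dispersion`` is the Dirichlet concentration controlling
    replicate-level compositional noise (larger = less noise).
    """

    n_taxa: int = 300
    n_modules: int = 5
    n_treatments: int = 3
    days: tuple = (1, 7, 30, 60)
    n_replicates: int = 3
    depth: int = 20_000
    module_effect: float = 1.0
    env_noise_sd: float = 0.2
    dispersion: float = 2000.0
    within_module_corr: float = 0.8
    log_abundance_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_taxa, self.n_modules, self.n_treatments, self.n_replicates) < 1:
            raise ValueError("counts must be >= 1")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if list(self.days) != sorted(set(self.days)):
            raise ValueError("days must be strictly increasing")
        if self.n_modules > self.n_taxa:
            raise ValueError("n_modules cannot exceed n_taxa")
        if not 0 <= self.within_module_corr < 1:
            raise ValueError("within_module_corr must lie in [0, 1)")
        if self.n_treatments not in TREATMENT_SETS:
            raise ValueError("n_treatments must be 2, 3 or 4")

    @property
    def treatments(self) -> tuple:
        return TREATMENT_SETS[self.n_treatments]


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated community.

    ``module_of`` maps each taxon to its planted module id (1..K);
    ``differential_taxa`` holds the signed log-abundance effect per day
    between the two fertilized comparison treatments; ``env_loadings``
    maps each environmental factor to its module-weight vector;
    ``guild_of`` maps genus names to N-cycle guilds; ``latent`` stores the
    taxon x sample latent Gaussian matrix so correlation structure can be
    checked directly.
    """

    module_of: pd.Series
    differential_taxa: pd.DataFrame
    env_loadings: pd.DataFrame
    guild_of: pd.Series
    latent: pd.DataFrame = field(repr=False, default=None)


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[stage])


def sample_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Sample table (treatment, day, replicate) with deterministic ids."""
    rows = []
    for trt in config.treatments:
        for day in config.days:
            for rep in range(1, config.n_replicates + 1):
                rows.append((f"{trt}_d{day}_r{rep}", trt, day, rep))
    frame = pd.DataFrame(rows, columns=["sample", "treatment", "day", "replicate"])
    return frame.set_index("sample")


def _module_shift(config: SimulationConfig, module: int, trt_index: int, day_index: int) -> float:
    """Treatment-by-day shift of a module's log-abundance.

    Modules alternate direction; the shift grows with sampling day and
    with treatment intensity (control = 0).  Zero ``module_effect`` makes
    every taxon null.
    """
    direction = 1.0 if module % 2 == 1 else -1.0
    day_weight = (day_index + 1) / len(config.days)
    intensity = float(trt_index) if config.treatments[0] == "control" else float(trt_index + 1)
    return config.module_effect * direction * day_weight * intensity


def _taxonomy(config: SimulationConfig) -> tuple[pd.DataFrame, pd.Series]:
    named = list(GUILD_GENERA)
    n_genera = max(len(named), min(config.n_taxa, max(config.n_taxa // 5, len(named))))
    genera = list(named)
    i = 1
    while len(genera) < n_genera:
        genera.append(f"Genus{i:03d}")
        i += 1
    taxa = [f"OTU{i:04d}" for i in range(1, config.n_taxa + 1)]
    rows = []
    for k, taxon in enumerate(taxa):
        genus = genera[k % len(genera)]
        phylum = _GENUS_PHYLUM.get(genus, _FILLER_PHYLA[k % len(_FILLER_PHYLA)])
        rows.append(
            (taxon, "Bacteria", phylum, f"{phylum}_cls", f"{phylum}_ord", f"{genus}aceae", genus)
        )
    taxonomy = pd.DataFrame(
        rows, columns=["taxon", "domain", "phylum", "class", "order", "family", "genus"]
    ).set_index("taxon")
    guild_of = pd.Series(
        {g: GUILD_GENERA.get(g, "none") for g in genera}, name="guild"
    )
    return taxonomy, guild_of


def simulate_community(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a count table, taxonomy, and the planted ground truth."""
    rng = _stage_rng(config.seed, 0)
    metadata = sample_metadata(config)
    samples = list(metadata.index)
    taxa = [f"OTU{i:04d}" for i in range(1, config.n_taxa + 1)]
    modules = 1 + (np.arange(config.n_taxa) % config.n_modules)
    module_of = pd.Series(modules, index=taxa, name="module")

    base = rng.normal(0.0, 1.0, size=config.n_taxa)
    rho = config.within_module_corr
    n_samples = len(samples)
    factors = rng.normal(0.0, 1.0, size=(config.n_modules, n_samples))
    for si, sample in enumerate(samples):
        trt = metadata.loc[sample, "treatment"]
        trt_index = config.treatments.index(trt)
        day_index = list(config.days).index(metadata.loc[sample, "day"])
        for m in range(config.n_modules):
            factors[m, si] += _module_shift(config, m + 1, trt_index, day_index)
    eps = rng.normal(0.0, 1.0, size=(config.n_taxa, n_samples))
    latent = np.sqrt(rho) * factors[modules - 1, :] + np.sqrt(1.0 - rho) * eps
    log_abund = base[:, None] + config.log_abundance_sd * latent
    expected = np.exp(log_abund - log_abund.max(axis=0))
    expected /= expected.sum(axis=0)

    counts = np.empty((config.n_taxa, n_samples), dtype=np.int64)
    for si in range(n_samples):
        p = rng.dirichlet(config.dispersion * expected[:, si])
        counts[:, si] = rng.multinomial(config.depth, p)
    table = pd.DataFrame(counts, index=taxa, columns=samples)

    taxonomy, guild_of = _taxonomy(config)

    ref_idx, cmp_idx = config.n_treatments - 2, config.n_treatments - 1
    diff = {
        day: [
            _module_shift(config, m, cmp_idx, di) - _module_shift(config, m, ref_idx, di)
            for m in modules
        ]
        for di, day in enumerate(config.days)
    }
    differential = pd.DataFrame(diff, index=taxa)

    loadings = np.zeros((len(ENV_FACTORS), config.n_modules))
    for fi in range(len(ENV_FACTORS)):
        loadings[fi, fi % config.n_modules] = 1.0 if fi % 2 == 0 else -1.0
    env_loadings = pd.DataFrame(
        loadings, index=list(ENV_FACTORS), columns=[f"Mod{m}" for m in range(1, config.n_modules + 1)]
    )

    truth = GroundTruth(
        module_of=module_of,
        differential_taxa=differential,
        env_loadings=env_loadings,
        guild_of=guild_of,
        latent=pd.DataFrame(latent, index=taxa, columns=samples),
    )
    return table, taxonomy, truth


def simulate_environment(
    truth: GroundTruth, counts: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Environmental covariates coupled to module abundances.

    Each factor is its loading vector dotted with the per-sample module
    relative abundances plus N(0, env_noise_sd) noise.  Raises if a
    loading refers to a module absent from the ground truth.
    """
    rng = _stage_rng(config.seed, 1)
    known = {f"Mod{m}" for m in sorted(truth.module_of.unique())}
    unknown = set(truth.env_loadings.columns) - known
    if unknown:
        raise ValueError(f"loadings refer to unknown module(s): {sorted(unknown)}")
    rel = to_relative_abundance(counts)
    module_abund = rel.groupby(
        truth.module_of.reindex(rel.index).map(lambda m: f"Mod{m}").values
    ).sum()
    module_abund = module_abund.reindex(truth.env_loadings.columns).fillna(0.0)
    signal = truth.env_loadings.to_numpy() @ module_abund.to_numpy()
    noise = rng.normal(0.0, config.env_noise_sd, size=signal.shape)
    env = pd.DataFrame(
        (signal + noise).T, index=list(counts.columns), columns=list(truth.env_loadings.index)
    )
    env.index.name = "sample"
    return env


# Treatment means for the agronomic generator: grain yield, aboveground
# biomass and 1000-grain weight follow a wheat pot experiment with
# controlled-release urea; the N dose (6.3 g pot-1) and uptake values are
# chosen so the NUE/NAE indices land in the realistic 30-50% / 7-10 kg kg-1
# range for such trials.
AGRONOMY_MEANS = {
    "control": {"grain_yield": 37.6, "biomass": 82.6, "thousand_grain": 53.6,
                "n_uptake": 1.0, "n_dose": 0.0},
    "FA": {"grain_yield": 45.0, "biomass": 95.0, "thousand_grain": 54.0,
           "n_uptake": 1.2, "n_dose": 0.0},
    "CRU": {"grain_yield": 81.6, "biomass": 168.8, "thousand_grain": 47.1,
            "n_uptake": 3.2302, "n_dose": 6.3},
    "CRU+FA": {"grain_yield": 99.6, "biomass": 196.2, "thousand_grain": 59.3,
               "n_uptake": 4.15, "n_dose": 6.3},
}


def simulate_agronomy(
    config: SimulationConfig,
    means: dict | None = None,
    residual_cv: float = 0.03,
) -> pd.DataFrame:
    """Per-replicate agronomic records with treatment effects.

    ``means`` maps treatment -> column -> mean (defaults above); replicate
    values are Gaussian with SD = ``residual_cv`` x mean (zero CV gives
    replicates exactly equal to their means).  The N dose column is a
    design constant, never perturbed.  Requires a zero-N control among the
    treatments.
    """
    rng = _stage_rng(config.seed, 2)
    means = dict(AGRONOMY_MEANS if means is None else means)
    treatments = [t for t in config.treatments if t in means]
    if "control" not in treatments:
        treatments = ["control"] + treatments
    if len(treatments) < 2:
        raise ValueError("need >= 2 treatments including a zero-N control")
    rows = []
    for trt in treatments:
        treatment_means = means[trt]
        for rep in range(1, config.n_replicates + 1):
            row = {"treatment": trt, "replicate": rep}
            for column, mu in treatment_means.items():
                if column == "n_dose":
                    row[column] = mu
                else:
                    row[column] = mu if residual_cv == 0 else rng.normal(mu, residual_cv * abs(mu))
            rows.append(row)
    return pd.DataFrame(rows)
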