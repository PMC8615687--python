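"""Synthetic MRM experiment generator with attached ground truth.

The generator emulates the statistical structure the analysis assumes:
a two-group design with five biological samples per group measured in
technical triplicates over the 240-species panel, with class-specific
internal standards spiked at fixed amounts.

Generative model (all noise multiplicative log-normal, mean 1):

* each species has a baseline ratio-scale abundance ``a_s`` drawn once
  per species, log-normal across the panel;
* a non-reference sample's true value is ``a_s`` x class effect x a
  species-specific effect jitter; reference samples use ``a_s``;
* biological noise (CV ``biological_cv``) is one shared draw per
  (sample, species), so averaging technical replicates is meaningful;
* each technical replicate's species intensity is the sample value x
  the standard's spiked intensity x technical noise (CV
  ``technical_cv``); the standard row itself is the spiked intensity x
  the group's matrix-effect factor x its own technical noise.

Randomness is organized as one master seed with per-species (and
per-standard) substreams keyed by the analyte name, so adding or
removing panel species never reshuffles the draws of the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import default_panel
from .quantify import RAW_COLUMNS, StandardMap
from .species import LipidClass, LipidSpecies

__all__ = ["SimulationConfig", "GroundTruth", "simulate", "null_simulation"]


def _cv_to_sigma(cv: float) -> float:
    """Log-sd of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def _lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 multiplicative noise (exactly 1 everywhere when cv = 0)."""
    if cv == 0.0:
        return np.ones(size)
    sigma = _cv_to_sigma(cv)
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _stream(seed: int, tag: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(tag, key)))


@dataclass
class SimulationConfig:
    """Full generative description of one synthetic experiment.

    Defaults encode the emulated study design: two groups (first label
    is the reference), five biological samples each, technical
    triplicates, biological CV 0.10 and technical CV 0.05.
    ``class_effects`` multiplies the non-reference group's true values
    per lipid class (1.0 = null); ``matrix_effects`` biases the
    non-reference group's standard intensities per standard name.
    """

    panel: list[LipidSpecies] = field(default_factory=default_panel)
    n_per_group: int = 5
    n_technical: int = 3
    groups: tuple[str, str] = ("control", "deficient")
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.0
    biological_cv: float = 0.10
    technical_cv: float = 0.05
    class_effects: dict[LipidClass, float] = field(default_factory=dict)
    species_effect_jitter_sd: float = 0.0
    standard_intensity: float = 2.0e4
    matrix_effects: dict[str, float] = field(default_factory=dict)
    standards: StandardMap = field(default_factory=StandardMap)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")
        if len(self.groups) != 2 or self.groups[0] == self.groups[1]:
            raise ValueError("groups must be two distinct labels")
        for cv in (self.biological_cv, self.technical_cv,
                   self.species_effect_jitter_sd):
            if cv < 0:
                raise ValueError("CVs must be >= 0")
        if self.baseline_log_sd < 0:
            raise ValueError("baseline_log_sd must be >= 0")
        if self.standard_intensity <= 0:
            raise ValueError("standard_intensity must be > 0")
        for eff in self.class_effects.values():
            if eff <= 0:
                raise ValueError("class effects must be > 0")
        for eff in self.matrix_effects.values():
            if eff <= 0:
                raise ValueError("matrix effects must be > 0")
        if not self.panel:
            raise ValueError("panel must be non-empty")

    @property
    def reference_group(self) -> str:
        return self.groups[0]


@dataclass
class GroundTruth:
    """Injected truth for parameter-recovery checks.

    ``species_percent`` is the true percent of reference per species
    (100 x class effect x species jitter); ``matrix_percent`` the true
    per-standard matrix-effect change in percent; ``class_effects`` the
    injected multiplicative effects.
    """

    species_percent: dict[str, float]
    matrix_percent: dict[str, float]
    class_effects: dict[LipidClass, float]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"species": list(self.species_percent),
             "true_percent_of_reference": list(self.species_percent.values())}
        ).to_csv(path, index=False)


def simulate(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format raw intensity table plus its ground truth.

    Deterministic given ``config.seed``; rows are ordered species-major
    (panel order), then sample, then technical replicate, with all
    standard rows appended afterwards in the same sample-major order.
    """
    ref_label, other_label = config.groups
    n, t = config.n_per_group, config.n_technical
    sample_ids = ([f"{ref_label}_{i + 1}" for i in range(n)]
                  + [f"{other_label}_{i + 1}" for i in range(n)])
    sample_groups = [ref_label] * n + [other_label] * n
    is_other = np.array([g == other_label for g in sample_groups])

    frames: list[pd.DataFrame] = []
    truth_percent: dict[str, float] = {}

    rep_ids = np.arange(1, t + 1)
    for spec in config.panel:
        name = spec.canonical_name
        rng = _stream(config.seed, 0, name)
        log_a = rng.normal(config.baseline_log_mean, config.baseline_log_sd)
        jitter = float(np.exp(rng.normal(0.0, config.species_effect_jitter_sd)
                              if config.species_effect_jitter_sd > 0 else 0.0))
        effect = config.class_effects.get(spec.lipid_class, 1.0) * jitter
        truth_percent[name] = 100.0 * effect

        bio = _lognormal(rng, config.biological_cv, 2 * n)
        tech = _lognormal(rng, config.technical_cv, (2 * n, t))
        sample_value = math.exp(log_a) * np.where(is_other, effect, 1.0) * bio
        intensity = (sample_value[:, None] * config.standard_intensity
                     * tech)
        frames.append(pd.DataFrame({
            "sample_id": np.repeat(sample_ids, t),
            "group": np.repeat(sample_groups, t),
            "bio_replicate": np.repeat(
                [f"b{i % n + 1}" for i in range(2 * n)], t),
            "tech_replicate": np.tile(rep_ids, 2 * n),
            "analyte": name,
            "role": "species",
            "lipid_class": spec.lipid_class.value,
            "intensity": intensity.ravel(),
        }))

    truth_matrix: dict[str, float] = {}
    for std_name in config.standards.standard_names():
        rng = _stream(config.seed, 1, std_name)
        factor = config.matrix_effects.get(std_name, 1.0)
        truth_matrix[std_name] = (factor - 1.0) * 100.0
        tech = _lognormal(rng, config.technical_cv, (2 * n, t))
        intensity = (config.standard_intensity
                     * np.where(is_other, factor, 1.0)[:, None] * tech)
        frames.append(pd.DataFrame({
            "sample_id": np.repeat(sample_ids, t),
            "group": np.repeat(sample_groups, t),
            "bio_replicate": np.repeat(
                [f"b{i % n + 1}" for i in range(2 * n)], t),
            "tech_replicate": np.tile(rep_ids, 2 * n),
            "analyte": std_name,
            "role": "standard",
            "lipid_class": config.standards.class_of_standard(std_name).value,
            "intensity": intensity.ravel(),
        }))

    records = pd.concat(frames, ignore_index=True)[RAW_COLUMNS]
    truth = GroundTruth(truth_percent, truth_matrix,
                        {c: config.class_effects.get(c, 1.0)
                         for c in LipidClass})
    return records, truth


def null_simulation(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """:func:`simulate` with every effect forced to 1 (type-I harness)."""
    null_config = replace(config, class_effects={}, matrix_effects={},
                          species_effect_jitter_sd=0.0)
    return simulate(null_config)
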