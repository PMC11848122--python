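"""Synthetic multitrophic survey and trait-measurement generator.

Produces long-format survey tables and per-individual trait measurements
with the statistical structure the downstream analysis assumes:

* a species pool split over four trophic feeding modes, with a tunable
  degree of within-mode trait *redundancy* (one-to-many species->trait
  mapping);
* pond-level log-abundance offsets that persist across years (spatial
  filters);
* interannual lognormal abundance fluctuations with optional *compensatory*
  (negatively covarying) dynamics within feeding modes;
* per-individual fork lengths, and trait values that depend linearly on
  length around each species' mean.

All randomness flows through one :class:`numpy.random.Generator` seeded from
the config, so identical configs yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    FEEDING_MODES,
    SURVEY_COLUMNS,
    TRAIT_MEASUREMENT_COLUMNS,
    TRAIT_NAMES,
    ConfigurationError,
)

N_TRAITS = len(TRAIT_NAMES)


@dataclass(frozen=True)
class SpeciesSpec:
    """Generating parameters for one species."""

    name: str
    feeding_mode: str
    trait_means: np.ndarray          # (13,) strictly positive
    trait_length_slopes: np.ndarray  # (13,) trait units per mm
    length_mean: float               # mm
    length_sd: float                 # mm
    base_abundance: float            # expected count per station haul
    family: str = ""

    def __post_init__(self) -> None:
        if self.feeding_mode not in FEEDING_MODES:
            raise ConfigurationError(
                f"unknown feeding mode {self.feeding_mode!r} for {self.name}"
            )
        tm = np.asarray(self.trait_means, dtype=float)
        sl = np.asarray(self.trait_length_slopes, dtype=float)
        if tm.shape != (N_TRAITS,) or sl.shape != (N_TRAITS,):
            raise ConfigurationError(
                f"{self.name}: trait vectors must have length {N_TRAITS}"
            )
        if not np.all(tm > 0):
            raise ConfigurationError(f"{self.name}: trait_means must be positive")
        if self.length_sd <= 0 or self.length_mean <= 0:
            raise ConfigurationError(f"{self.name}: length parameters must be positive")
        if self.base_abundance <= 0:
            raise ConfigurationError(f"{self.name}: base_abundance must be positive")
        object.__setattr__(self, "trait_means", tm)
        object.__setattr__(self, "trait_length_slopes", sl)
        if not self.family:
            object.__setattr__(self, "family", f"fam_{self.name}")


@dataclass(frozen=True)
class SynthConfig:
    """Dimensions and knobs for one synthetic survey."""

    n_ponds: int = 6
    n_years: int = 6
    n_months: int = 6
    n_stations: int = 2
    species_pool: tuple[SpeciesSpec, ...] = ()
    redundancy: float = 0.5
    spatial_filter_strength: float = 0.5
    temporal_cv: float = 0.5
    compensation: float = 0.0
    measure_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ponds < 2:
            raise ConfigurationError("n_ponds must be >= 2")
        if self.n_years < 3:
            raise ConfigurationError("n_years must be >= 3")
        if self.n_months < 1 or self.n_stations < 1:
            raise ConfigurationError("n_months and n_stations must be >= 1")
        if not self.species_pool:
            raise ConfigurationError("species_pool must be nonempty")
        if not 0.0 <= self.redundancy <= 1.0:
            raise ConfigurationError("redundancy must be in [0, 1]")
        if not 0.0 <= self.compensation <= 1.0:
            raise ConfigurationError("compensation must be in [0, 1]")
        if self.spatial_filter_strength < 0 or self.temporal_cv < 0:
            raise ConfigurationError(
                "spatial_filter_strength and temporal_cv must be >= 0"
            )
        if not 0.0 < self.measure_fraction <= 1.0:
            raise ConfigurationError("measure_fraction must be in (0, 1]")
        object.__setattr__(self, "species_pool", tuple(self.species_pool))

    def replace(self, **kwargs) -> "SynthConfig":
        return dataclasses.replace(self, **kwargs)


def generate_species_pool(
    n_species: int, redundancy: float, seed: int,
    mode_split: tuple[int, int, int, int] | None = None,
) -> list[SpeciesSpec]:
    """Draw a species pool with controllable within-mode trait overlap.

    Each species' ``trait_means`` is the convex mixture
    ``redundancy * mode_archetype + (1 - redundancy) * independent_draw``,
    so ``redundancy == 1`` makes all species within a feeding mode
    functionally identical and ``redundancy == 0`` makes them independent.
    Consecutive pairs of species within a mode share a family.  Feeding
    modes are assigned round-robin unless ``mode_split`` gives explicit
    per-mode counts (summing to ``n_species``).
    """
    if n_species < 4:
        raise ConfigurationError("n_species must be >= 4 (one per feeding mode)")
    if not 0.0 <= redundancy <= 1.0:
        raise ConfigurationError("redundancy must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if mode_split is None:
        modes = [FEEDING_MODES[i % 4] for i in range(n_species)]
    else:
        if len(mode_split) != 4 or sum(mode_split) != n_species or min(mode_split) < 1:
            raise ConfigurationError(
                "mode_split must give 4 positive counts summing to n_species"
            )
        modes = [m for m, c in zip(FEEDING_MODES, mode_split) for _ in range(c)]
    archetype_mean = {m: rng.uniform(0.5, 3.0, N_TRAITS) for m in FEEDING_MODES}
    archetype_slope = {m: rng.normal(0.0, 0.004, N_TRAITS) for m in FEEDING_MODES}

    within_mode_index: dict[str, int] = {m: 0 for m in FEEDING_MODES}
    pool: list[SpeciesSpec] = []
    for i, mode in enumerate(modes):
        j = within_mode_index[mode]
        within_mode_index[mode] += 1
        indep_mean = rng.uniform(0.5, 3.0, N_TRAITS)
        indep_slope = rng.normal(0.0, 0.004, N_TRAITS)
        means = redundancy * archetype_mean[mode] + (1.0 - redundancy) * indep_mean
        slopes = redundancy * archetype_slope[mode] + (1.0 - redundancy) * indep_slope
        pool.append(
            SpeciesSpec(
                name=f"sp{i:02d}_{mode[:4]}",
                feeding_mode=mode,
                trait_means=means,
                trait_length_slopes=slopes,
                length_mean=float(rng.uniform(60.0, 140.0)),
                length_sd=float(rng.uniform(5.0, 20.0)),
                base_abundance=float(rng.lognormal(np.log(8.0), 0.5)),
                family=f"{mode[:4]}_fam{j // 2}",
            )
        )
    return pool


def _log_sigma(temporal_cv: float) -> float:
    # lognormal sd on the log scale matching a target coefficient of variation
    return float(np.sqrt(np.log1p(temporal_cv**2)))


def draw_year_effects(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw the (n_years, n_species) matrix of log-scale year fluctuations.

    Within each feeding mode the yearly shocks are ``z - c * mean(z)`` with
    ``c = compensation``, rescaled to unit variance and multiplied by the
    lognormal sigma implied by ``temporal_cv``.  At ``c = 1`` the shocks sum
    to zero within the mode, so pairwise correlations are ``-1/(m-1)``.
    """
    n_sp = len(config.species_pool)
    eff = np.zeros((config.n_years, n_sp))
    sigma = _log_sigma(config.temporal_cv)
    mode_members = {
        m: [i for i, sp in enumerate(config.species_pool) if sp.feeding_mode == m]
        for m in FEEDING_MODES
    }
    for _m, idx in mode_members.items():
        if not idx:
            continue
        m_size = len(idx)
        z = rng.standard_normal((config.n_years, m_size))
        if m_size == 1:
            mixed = z
        else:
            c = config.compensation
            mixed = z - c * z.mean(axis=1, keepdims=True)
            var = 1.0 - c * (2.0 - c) / m_size
            mixed = mixed / np.sqrt(var)
        eff[:, idx] = sigma * mixed
    return eff


def simulate_survey(config: SynthConfig) -> pd.DataFrame:
    """Simulate a long-format survey table.

    Counts are Poisson with lognormal mean
    ``base_abundance * exp(pond_offset + year_effect)``; pond offsets are
    fixed per species x pond across years.  A ``measure_fraction`` of
    individuals carry a measured fork length (one row each, ``count == 1``);
    the unmeasured remainder of each haul is emitted as a single count-only
    row with an empty ``fork_length_mm``.
    """
    rng = np.random.default_rng(config.seed)
    species = config.species_pool
    n_sp = len(species)
    ponds = [f"pond{p}" for p in range(config.n_ponds)]
    years = list(range(2010, 2010 + config.n_years))
    months = list(range(5, 5 + config.n_months))
    stations = [f"st{s}" for s in range(config.n_stations)]

    pond_off = rng.normal(0.0, config.spatial_filter_strength, (n_sp, config.n_ponds))
    year_eff = draw_year_effects(config, rng)  # (n_years, n_sp)
    base = np.array([sp.base_abundance for sp in species])

    # expected count per haul: (pond, year, species)
    lam = base[None, None, :] * np.exp(pond_off.T[:, None, :] + year_eff[None, :, :])

    rows: list[tuple] = []
    for pi, pond in enumerate(ponds):
        for yi, year in enumerate(years):
            for month in months:
                for station in stations:
                    counts = rng.poisson(lam[pi, yi])
                    for si, n in enumerate(counts):
                        if n == 0:
                            continue
                        sp = species[si]
                        n_meas = int(rng.binomial(n, config.measure_fraction))
                        if n_meas:
                            a = -sp.length_mean / sp.length_sd
                            lengths = stats.truncnorm.rvs(
                                a, np.inf, loc=sp.length_mean, scale=sp.length_sd,
                                size=n_meas, random_state=rng,
                            )
                            for ln in lengths:
                                rows.append(
                                    (pond, year, month, station, sp.name, 1,
                                     round(float(ln), 2))
                                )
                        if n - n_meas > 0:
                            rows.append(
                                (pond, year, month, station, sp.name,
                                 int(n - n_meas), np.nan)
                            )
    return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))


def simulate_trait_measurements(
    config: SynthConfig, n_per_species: int, noise_sd: float
) -> pd.DataFrame:
    """Simulate per-individual trait measurements for model fitting.

    Lengths span each species' +/- 2 sd range evenly; each trait value is
    ``trait_mean + slope * (length - length_mean) + Normal(0, noise_sd)``.
    """
    if n_per_species < 2:
        raise ConfigurationError(
            "n_per_species must be >= 2 (length effect unidentifiable otherwise)"
        )
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    rng = np.random.default_rng(config.seed + 1)
    rows: list[tuple] = []
    for sp in config.species_pool:
        lo = max(1.0, sp.length_mean - 2.0 * sp.length_sd)
        hi = sp.length_mean + 2.0 * sp.length_sd
        lengths = np.linspace(lo, hi, n_per_species)
        for ln in lengths:
            noise = rng.normal(0.0, noise_sd, N_TRAITS) if noise_sd > 0 else np.zeros(N_TRAITS)
            vals = sp.trait_means + sp.trait_length_slopes * (ln - sp.length_mean) + noise
            for t, v in zip(TRAIT_NAMES, vals):
                rows.append((sp.name, sp.family, round(float(ln), 2), t, float(v)))
    return pd.DataFrame(rows, columns=list(TRAIT_MEASUREMENT_COLUMNS))


def feeding_mode_lookup(pool: list[SpeciesSpec] | tuple[SpeciesSpec, ...]) -> pd.DataFrame:
    """Species -> feeding mode (and family) lookup table."""
    return pd.DataFrame(
        {
            "species": [sp.name for sp in pool],
            "feeding_mode": [sp.feeding_mode for sp in pool],
            "family": [sp.family for sp in pool],
        }
    )


def write_survey_csv(survey: pd.DataFrame, path) -> None:
    survey.to_csv(path, index=False, float_format="%.2f")


def write_trait_measurements_csv(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, index=False)


def write_feeding_mode_csv(lookup: pd.DataFrame, path) -> None:
    lookup.to_csv(path, index=False)
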