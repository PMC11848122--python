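"""Trait imputation: fit per-trait additive models and predict traits for
every surveyed individual.

Morphometric traits are modelled at species level; nutrient-recycling traits
(NH4, PO4, N:P) at family level, because they are measured per family.
Surveyed individuals without a measured fork length receive their species'
survey-wide mean length; lengths outside the training range are clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    FAMILY_LEVEL_TRAITS,
    TRAIT_NAMES,
    DataError,
)
from .gam import PenalizedAdditiveModel

logger = logging.getLogger(__name__)

#: Output columns of :func:`impute_survey_traits`. ``weight`` is the number
#: of individuals the row represents (1 for measured individuals).
PREDICTION_COLUMNS = ("pond", "year", "species", "trait", "value", "weight")


@dataclass
class TraitModel:
    """A fitted per-trait additive model plus its fitting metadata."""

    trait: str
    taxon_level: str  # "species" or "family"
    model: PenalizedAdditiveModel
    n_records: int = 0
    length_range: tuple[float, float] = (np.nan, np.nan)

    @property
    def taxon_effects(self) -> dict[str, float]:
        return self.model.taxon_effects_

    @property
    def penalty(self) -> float:
        return self.model.lambda_

    @property
    def edf(self) -> float:
        return self.model.edf_

    @property
    def resid_sd(self) -> float:
        return self.model.resid_sd_

    def predict(self, taxa, lengths) -> np.ndarray:
        return self.model.predict(taxa, lengths)


def fit_trait_model(
    measurements: pd.DataFrame,
    trait: str,
    taxon_level: str | None = None,
    basis_dim: int = 10,
    per_taxon_smooth: bool = False,
) -> TraitModel:
    """Fit ``value ~ taxon + s(fork_length)`` for one trait.

    ``taxon_level`` defaults to "family" for nutrient-recycling traits and
    "species" otherwise.
    """
    if trait not in TRAIT_NAMES:
        raise DataError(f"unknown trait {trait!r}; expected one of {TRAIT_NAMES}")
    if taxon_level is None:
        taxon_level = "family" if trait in FAMILY_LEVEL_TRAITS else "species"
    if taxon_level not in ("species", "family"):
        raise DataError("taxon_level must be 'species' or 'family'")
    sub = measurements.loc[measurements["trait"] == trait]
    if sub.empty:
        raise DataError(f"no measurements for trait {trait!r}")
    if (sub["fork_length_mm"] <= 0).any():
        raise DataError(f"non-positive fork lengths in measurements for {trait!r}")
    engine = PenalizedAdditiveModel(
        basis_dim=basis_dim, per_taxon_smooth=per_taxon_smooth
    )
    engine.fit(
        sub[taxon_level].to_numpy(),
        sub["fork_length_mm"].to_numpy(float),
        sub["value"].to_numpy(float),
    )
    return TraitModel(
        trait=trait,
        taxon_level=taxon_level,
        model=engine,
        n_records=len(sub),
        length_range=(float(sub["fork_length_mm"].min()),
                      float(sub["fork_length_mm"].max())),
    )


def fit_all_trait_models(
    measurements: pd.DataFrame,
    basis_dim: int = 10,
    per_taxon_smooth: bool = False,
) -> dict[str, TraitModel]:
    """Fit the full set of 13 trait models."""
    return {
        t: fit_trait_model(
            measurements, t, basis_dim=basis_dim, per_taxon_smooth=per_taxon_smooth
        )
        for t in TRAIT_NAMES
    }


def species_to_family_map(measurements: pd.DataFrame) -> dict[str, str]:
    """Derive the species -> family mapping from a measurement table."""
    pairs = measurements[["species", "family"]].drop_duplicates()
    dup = pairs["species"][pairs["species"].duplicated()]
    if not dup.empty:
        raise DataError(f"species mapped to multiple families: {sorted(set(dup))}")
    return dict(zip(pairs["species"], pairs["family"]))


def impute_survey_traits(
    models: dict[str, TraitModel],
    survey: pd.DataFrame,
    species_to_family: dict[str, str],
) -> pd.DataFrame:
    """Predict all 13 traits for every surveyed individual.

    Returns a tidy frame with one row per (survey row, trait); ``weight``
    carries the number of individuals the row stands for, so measured
    individuals (count == 1) appear one-per-row and count-only rows keep
    their multiplicity.  Individuals lacking a length get their species'
    survey-wide mean measured length (logged).
    """
    missing_traits = [t for t in TRAIT_NAMES if t not in models]
    if missing_traits:
        raise DataError(f"missing trait models: {missing_traits}")
    if survey.empty:
        raise DataError("empty survey")

    surveyed_species = sorted(survey["species"].unique())
    # resolve the taxon key per (trait, species) up front; fail loudly
    unmapped: set[str] = set()
    for t, tm in models.items():
        for sp in surveyed_species:
            key = sp if tm.taxon_level == "species" else species_to_family.get(sp)
            if key is None or key not in tm.taxon_effects:
                unmapped.add(sp)
    if unmapped:
        raise DataError(
            f"surveyed species without a model taxon: {sorted(unmapped)}"
        )

    work = survey.copy()
    measured = work["fork_length_mm"].notna()
    mean_len = (
        work.loc[measured]
        .groupby("species")["fork_length_mm"]
        .mean()
    )
    n_filled = int((~measured).sum())
    if n_filled:
        logger.info(
            "%d count-only rows assigned species mean lengths", n_filled
        )
    fallback = float(work.loc[measured, "fork_length_mm"].mean())
    fill = work["species"].map(mean_len)
    if fill.isna().any() and (~measured & fill.isna()).any():
        bad = sorted(work.loc[~measured & fill.isna(), "species"].unique())
        logger.warning(
            "species with no measured lengths anywhere, using survey mean: %s", bad
        )
        fill = fill.fillna(fallback)
    work["length_filled"] = work["fork_length_mm"].where(measured, fill)

    # predict on unique (species, length) pairs, then broadcast back
    pairs = work[["species", "length_filled"]].drop_duplicates().reset_index(drop=True)
    out_frames = []
    for t in TRAIT_NAMES:
        tm = models[t]
        if tm.taxon_level == "species":
            taxa = pairs["species"].to_numpy(object)
        else:
            taxa = pairs["species"].map(species_to_family).to_numpy(object)
        vals = tm.predict(taxa, pairs["length_filled"].to_numpy(float))
        pred = pairs.assign(trait=t, value=vals)
        merged = work.merge(pred, on=["species", "length_filled"], how="left")
        out_frames.append(
            pd.DataFrame(
                {
                    "pond": merged["pond"],
                    "year": merged["year"],
                    "species": merged["species"],
                    "trait": t,
                    "value": merged["value"],
                    "weight": merged["count"].astype(float),
                }
            )
        )
    out = pd.concat(out_frames, ignore_index=True)
    return out[list(PREDICTION_COLUMNS)]


def model_summary(models: dict[str, TraitModel]) -> pd.DataFrame:
    """Per-trait fitting report: penalty, effective df, residual SD."""
    rows = [
        {
            "trait": t,
            "taxon_level": m.taxon_level,
            "n_records": m.n_records,
            "lambda": m.penalty,
            "edf": m.edf,
            "resid_sd": m.resid_sd,
            "length_min": m.length_range[0],
            "length_max": m.length_range[1],
        }
        for t, m in models.items()
    ]
    return pd.DataFrame(rows)
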