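"""Fixed vocabularies shared across the pipeline.

Trait columns are always emitted in :data:`TRAIT_NAMES` order; feeding modes
in :data:`FEEDING_MODES` order.  Three trait groups partition the 13 traits:
energy acquisition (5), locomotion (5) and nutrient recycling (3).
"""

from __future__ import annotations

#: Canonical trait column order.
TRAIT_NAMES: tuple[str, ...] = (
    "Osf", "Osh", "Ops", "Pro", "ES",        # energy acquisition
    "EP", "Bsf", "Bsh", "Pfp", "Cpt",        # locomotion
    "NH4", "PO4", "N_P",                      # nutrient recycling
)

ENERGY_TRAITS: tuple[str, ...] = TRAIT_NAMES[:5]
LOCOMOTION_TRAITS: tuple[str, ...] = TRAIT_NAMES[5:10]
NUTRIENT_TRAITS: tuple[str, ...] = TRAIT_NAMES[10:]

#: Trait -> functional group.
TRAIT_GROUPS: dict[str, str] = {
    **{t: "energy" for t in ENERGY_TRAITS},
    **{t: "locomotion" for t in LOCOMOTION_TRAITS},
    **{t: "nutrient" for t in NUTRIENT_TRAITS},
}

#: Trophic feeding modes assigned per species.
FEEDING_MODES: tuple[str, ...] = (
    "detritivore",
    "planktivore",
    "hunting_meiofauna",
    "hunting_macrofauna",
)

#: Traits modelled at family level (measured per family, not per species).
FAMILY_LEVEL_TRAITS: tuple[str, ...] = NUTRIENT_TRAITS

#: Survey CSV column order (one row per measured individual plus
#: count-only rows carrying the unmeasured remainder).
SURVEY_COLUMNS: tuple[str, ...] = (
    "pond", "year", "month", "station", "species", "count", "fork_length_mm",
)

#: Trait-measurement CSV column order.
TRAIT_MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "species", "family", "fork_length_mm", "trait", "value",
)


class TraitstabError(Exception):
    """Base class for configuration and data errors raised by this package."""


class ConfigurationError(TraitstabError):
    """Invalid configuration values."""


class DataError(TraitstabError):
    """Invalid or inconsistent input data."""
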