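"""Aggregate survey records into pond x year community matrices.

Two matrices share one row index of (pond, year) pairs: the species
abundance matrix (counts averaged stations-within-month first, then across
months) and the community-weighted trait matrix (abundance-weighted mean of
per-individual trait predictions).
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd

from .constants import FEEDING_MODES, TRAIT_NAMES, DataError

logger = logging.getLogger(__name__)


def build_abundance_matrix(
    survey: pd.DataFrame, averaging: str = "two_stage"
) -> pd.DataFrame:
    """Pond x year by species matrix of averaged counts.

    ``two_stage`` (default): counts are averaged over stations within each
    month, then averaged over the months surveyed in that pond-year.
    ``grand``: single mean over all station x month hauls.  Species absent
    from a haul contribute zero.  Rows are a (pond, year) MultiIndex; columns
    are species sorted alphabetically.
    """
    if survey.empty:
        raise DataError("empty survey")
    if averaging not in ("two_stage", "grand"):
        raise DataError("averaging must be 'two_stage' or 'grand'")

    key = ["pond", "year", "month", "station", "species"]
    count_only = survey[survey["fork_length_mm"].isna()] if "fork_length_mm" in survey else survey
    dup = count_only.duplicated(subset=key)
    if dup.any():
        warnings.warn(
            f"{int(dup.sum())} duplicate count-only rows per haul x species; "
            "counts summed",
            stacklevel=2,
        )
    counts = survey.groupby(key, sort=True)["count"].sum()

    haul_counts = counts.groupby(["pond", "year", "month", "species"]).sum()
    n_stations = (
        survey.groupby(["pond", "year", "month"])["station"].nunique()
    )
    if averaging == "two_stage":
        month_mean = haul_counts / n_stations.reindex(
            haul_counts.index.droplevel("species")
        ).to_numpy()
        n_months = survey.groupby(["pond", "year"])["month"].nunique()
        cell = month_mean.groupby(["pond", "year", "species"]).sum()
        cell = cell / n_months.reindex(cell.index.droplevel("species")).to_numpy()
    else:
        n_hauls = (
            survey.assign(haul=lambda d: d["month"].astype(str) + "/" + d["station"].astype(str))
            .groupby(["pond", "year"])["haul"]
            .nunique()
        )
        cell = counts.groupby(["pond", "year", "species"]).sum()
        cell = cell / n_hauls.reindex(cell.index.droplevel("species")).to_numpy()

    mat = cell.unstack("species", fill_value=0.0)
    mat = mat[sorted(mat.columns)]
    mat = mat.sort_index()
    mat.columns.name = None
    return mat


def build_trait_matrix(
    predictions: pd.DataFrame,
    clamp_negative: bool = True,
    rescale: bool = False,
) -> pd.DataFrame:
    """Pond x year by 13-trait community-weighted mean matrix.

    Cell = weighted mean of per-individual predicted trait values in that
    pond-year (weights = individuals represented).  Negative cells are
    clamped to 0 by default (Bray-Curtis requires non-negative data);
    ``rescale`` min-max scales each trait column to [0, 1].
    """
    if predictions.empty:
        raise DataError("empty predictions")
    wsum = (
        predictions.assign(wv=lambda d: d["value"] * d["weight"])
        .groupby(["pond", "year", "trait"])[["wv", "weight"]]
        .sum()
    )
    cwm = (wsum["wv"] / wsum["weight"]).unstack("trait")
    missing = [t for t in TRAIT_NAMES if t not in cwm.columns]
    if missing:
        raise DataError(f"predictions missing traits: {missing}")
    cwm = cwm[list(TRAIT_NAMES)].sort_index()
    if cwm.isna().any().any():
        bad = cwm.index[cwm.isna().any(axis=1)].tolist()
        warnings.warn(f"dropping pond-years without individuals: {bad}", stacklevel=2)
        cwm = cwm.dropna()
    if clamp_negative:
        n_neg = int((cwm < 0).to_numpy().sum())
        if n_neg:
            logger.info("clamped %d negative CWM cells to 0", n_neg)
            cwm = cwm.clip(lower=0.0)
    if rescale:
        rng_ = cwm.max() - cwm.min()
        rng_ = rng_.replace(0.0, 1.0)
        cwm = (cwm - cwm.min()) / rng_
    cwm.columns.name = None
    return cwm


def aggregate_by_feeding_mode(
    abundance: pd.DataFrame, lookup: dict[str, str] | pd.DataFrame
) -> pd.DataFrame:
    """Collapse species columns into feeding-mode columns (column sums).

    Row totals are conserved exactly.
    """
    if isinstance(lookup, pd.DataFrame):
        lookup = dict(zip(lookup["species"], lookup["feeding_mode"]))
    unmapped = [s for s in abundance.columns if s not in lookup]
    if unmapped:
        raise DataError(f"species without a feeding mode: {unmapped}")
    modes = [m for m in FEEDING_MODES if m in set(lookup[s] for s in abundance.columns)]
    extra = sorted(
        set(lookup[s] for s in abundance.columns) - set(FEEDING_MODES)
    )
    out = pd.DataFrame(index=abundance.index, columns=modes + extra, dtype=float)
    for m in modes + extra:
        members = [s for s in abundance.columns if lookup[s] == m]
        out[m] = abundance[members].sum(axis=1)
    return out
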