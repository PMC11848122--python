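"""Community stability metrics and their two-way ANOVA comparison.

Two per-pond metrics on a pond x year distance matrix: year-to-centroid
distance (each year's composition to the pond's multi-year centroid, by
default computed in PCoA space, betadisper-style, with negative-eigenvalue
correction) and year-to-year distance (consecutive-year dissimilarities).
Relative stability divides every distance by the maximum observed within its
composition type, so species and trait metrics share a [0, 1] scale.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .constants import DataError
from .multivariate import DistanceMatrix, bray_curtis, pcoa

logger = logging.getLogger(__name__)


def _split_labels(D: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    try:
        ponds = np.array([l[0] for l in D.labels], dtype=object)
        years = np.array([l[1] for l in D.labels])
    except (TypeError, IndexError) as exc:
        raise DataError(
            "distance labels must be (pond, year) pairs for stability metrics"
        ) from exc
    return ponds, years


def _signed_sq_dist(pos: np.ndarray, neg: np.ndarray,
                    cpos: np.ndarray, cneg: np.ndarray) -> np.ndarray:
    sq = ((pos - cpos) ** 2).sum(axis=1) - ((neg - cneg) ** 2).sum(axis=1)
    return sq


def year_to_centroid(
    D: DistanceMatrix,
    mode: str = "pcoa_centroid",
    M: pd.DataFrame | None = None,
    centroid: str = "mean",
) -> pd.DataFrame:
    """Distance of each pond-year to its pond's multi-year centre.

    ``pcoa_centroid`` (default) works in PCoA space with squared distance =
    (positive-axis part) - (negative-axis part), floored at 0 before the
    square root; ``centroid`` may be the group ``mean`` or the geometric
    ``median``.  ``raw_to_mean`` computes Bray-Curtis between each year's
    composition row of ``M`` and the pond's time-averaged row.
    """
    ponds, years = _split_labels(D)
    out_rows = []
    if mode == "pcoa_centroid":
        pc = pcoa(D)
        pos, neg = pc.pos_coords, pc.neg_coords
        n_floored = 0
        for pond in pd.unique(ponds):
            idx = np.where(ponds == pond)[0]
            if idx.size < 2:
                warnings.warn(f"pond {pond!r} has < 2 years; dropped", stacklevel=2)
                continue
            if centroid == "mean":
                cpos = pos[idx].mean(axis=0)
                cneg = neg[idx].mean(axis=0)
            elif centroid == "median":
                cpos, cneg = _spatial_median(pos[idx], neg[idx])
            else:
                raise DataError("centroid must be 'mean' or 'median'")
            sq = _signed_sq_dist(pos[idx], neg[idx], cpos, cneg)
            n_floored += int((sq < 0).sum())
            d = np.sqrt(np.maximum(sq, 0.0))
            for i, di in zip(idx, d):
                out_rows.append({"pond": pond, "year": years[i], "distance": float(di)})
        if n_floored:
            logger.info("floored %d negative squared distances at 0", n_floored)
    elif mode == "raw_to_mean":
        if M is None:
            raise DataError("raw_to_mean mode requires the composition matrix M")
        if list(M.index) != list(D.labels):
            raise DataError("M rows must align with the distance labels")
        X = np.asarray(M, dtype=float)
        for pond in pd.unique(ponds):
            idx = np.where(ponds == pond)[0]
            if idx.size < 2:
                warnings.warn(f"pond {pond!r} has < 2 years; dropped", stacklevel=2)
                continue
            mean_row = X[idx].mean(axis=0)
            for i in idx:
                pair = pd.DataFrame([X[i], mean_row])
                d = bray_curtis(pair).data[0, 1]
                out_rows.append({"pond": pond, "year": years[i], "distance": float(d)})
    else:
        raise DataError("mode must be 'pcoa_centroid' or 'raw_to_mean'")
    if not out_rows:
        raise DataError("no pond has >= 2 years")
    return pd.DataFrame(out_rows)


def _spatial_median(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geometric median in the signed PCoA metric (numeric minimization)."""
    from scipy import optimize

    np_, nn = pos.shape[1], neg.shape[1]

    def objective(c):
        cpos, cneg = c[:np_], c[np_:]
        sq = _signed_sq_dist(pos, neg, cpos, cneg)
        return np.sqrt(np.maximum(sq, 0.0)).sum()

    c0 = np.concatenate([pos.mean(axis=0), neg.mean(axis=0)])
    res = optimize.minimize(objective, c0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return res.x[:np_], res.x[np_:]


def year_to_year(D: DistanceMatrix) -> pd.DataFrame:
    """Consecutive-year dissimilarities per pond.

    Only calendar-adjacent year pairs are used; a missing intermediate year
    is logged as a gap, never bridged.
    """
    ponds, years = _split_labels(D)
    rows = []
    for pond in pd.unique(ponds):
        idx = np.where(ponds == pond)[0]
        if idx.size < 2:
            warnings.warn(f"pond {pond!r} has < 2 years; no transitions", stacklevel=2)
            continue
        order = idx[np.argsort(years[idx])]
        ys = years[order]
        for a, b in zip(order[:-1], order[1:]):
            if years[b] - years[a] != 1:
                logger.info(
                    "pond %s: gap between years %s and %s; transition skipped",
                    pond, years[a], years[b],
                )
                continue
            rows.append(
                {
                    "pond": pond,
                    "year_from": years[a],
                    "year_to": years[b],
                    "distance": float(D.data[a, b]),
                }
            )
        del ys
    return pd.DataFrame(rows, columns=["pond", "year_from", "year_to", "distance"])


def relative_stability(distances: pd.DataFrame, composition_type: str) -> pd.DataFrame:
    """Max-normalize distances within one composition type.

    Input needs a ``distance`` column plus ``pond`` and either ``year`` or
    (``year_from``, ``year_to``) unit columns.
    """
    if distances.empty:
        raise DataError("no distances to normalize")
    d = distances["distance"].to_numpy(float)
    dmax = d.max()
    if dmax <= 0:
        warnings.warn("all distances are zero; relative distances set to 0",
                      stacklevel=2)
        rel = np.zeros_like(d)
    else:
        rel = d / dmax
    out = distances.copy()
    if "year" in out.columns:
        out["unit"] = out["year"].astype(str)
    else:
        out["unit"] = out["year_from"].astype(str) + "-" + out["year_to"].astype(str)
    out["composition_type"] = composition_type
    out["relative_distance"] = rel
    return out[["pond", "composition_type", "unit", "distance", "relative_distance"]]


def stability_table(
    by_type: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Concatenate per-composition-type relative-stability tables."""
    return pd.concat(
        [relative_stability(df, ct) for ct, df in by_type.items()],
        ignore_index=True,
    )


def stability_anova(table: pd.DataFrame, response: str = "relative_distance") -> pd.DataFrame:
    """Crossed two-way fixed-effects ANOVA: pond x composition type.

    Type I sums of squares on a balanced design (the orderings coincide
    there); unbalanced input triggers a warning and Type II.
    """
    needed = {"pond", "composition_type", response}
    if not needed.issubset(table.columns):
        raise DataError(f"stability table must have columns {sorted(needed)}")
    cells = table.groupby(["pond", "composition_type"]).size()
    n_ponds = table["pond"].nunique()
    n_types = table["composition_type"].nunique()
    if len(cells) < n_ponds * n_types:
        raise DataError("empty pond x composition-type cells; design must be complete")
    balanced = cells.nunique() == 1
    typ = 1
    if not balanced:
        warnings.warn("unbalanced design; using Type II sums of squares",
                      stacklevel=2)
        typ = 2
    df = table.rename(columns={response: "resp"})
    if n_ponds == 1:
        # degenerate design: only the composition-type contrast remains
        fit = smf.ols("resp ~ C(composition_type)", data=df).fit()
    else:
        fit = smf.ols("resp ~ C(pond) * C(composition_type)", data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=typ)
    name_map = {
        "C(pond)": "pond",
        "C(composition_type)": "composition_type",
        "C(pond):C(composition_type)": "interaction",
        "Residual": "residual",
    }
    aov = aov.rename(index=name_map)
    out = pd.DataFrame(
        {
            "term": aov.index,
            "df": aov["df"].to_numpy(float),
            "sum_sq": aov["sum_sq"].to_numpy(float),
            "F": aov["F"].to_numpy(float),
            "p": aov["PR(>F)"].to_numpy(float),
        }
    ).reset_index(drop=True)
    # a constant response has 0/0 F ratios: define them as 0, p = 1
    resp = df["resp"].to_numpy(float)
    if np.var(resp) <= 1e-24 * max(1.0, np.mean(resp) ** 2):
        model_terms = out["term"] != "residual"
        out.loc[model_terms, "F"] = 0.0
        out.loc[model_terms, "p"] = 1.0
    return out


def stability_report(table: pd.DataFrame) -> str:
    """Compact text summary: mean relative distance per pond and per type."""
    lines = ["relative stability (smaller distance = more stable)", ""]
    by_type = table.groupby("composition_type")["relative_distance"].mean()
    lines.append("mean relative distance by composition type:")
    for k, v in by_type.items():
        lines.append(f"  {k:>10s}: {v:.4f}")
    lines.append("")
    lines.append("mean relative distance by pond:")
    by_pond = table.groupby("pond")["relative_distance"].mean()
    for k, v in by_pond.items():
        lines.append(f"  {k!s:>10s}: {v:.4f}")
    return "\n".join(lines) + "\n"
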