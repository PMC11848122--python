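"""Permutational inference on community matrices.

* :func:`permanova` — sequential (Type I) partition of a Gower-centered
  distance matrix by ``pond + year + pond:year`` with a numeric year
  covariate by default, pseudo-F by hat-matrix traces, p by free row
  permutation.
* SIMPER decompositions restricted to the two bespoke comparison sets:
  each year against its pond's time-mean composition, and consecutive-year
  pairs within ponds.
* :func:`envfit` — least-squares vector fitting of external variables onto
  ordination scores with a permutation test on R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DataError
from .multivariate import DistanceMatrix, Ordination, gower_center


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------
def _projector(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T


def adonis(
    D: DistanceMatrix,
    terms: list[tuple[str, np.ndarray]],
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Sequential PERMANOVA over arbitrary design-term column blocks.

    Each entry of ``terms`` is ``(name, columns)``; columns are added to the
    design in order after an intercept.  Returns a table with df, SS,
    pseudo-F and permutation p per term plus the residual row.
    """
    if n_perm < 99:
        raise DataError("n_perm must be >= 99")
    n = D.n
    G = gower_center(D)
    X = np.ones((n, 1))
    H_prev = _projector(X)
    increments: list[tuple[str, np.ndarray, int]] = []
    rank_prev = 1
    for name, cols in terms:
        cols = np.atleast_2d(np.asarray(cols, dtype=float))
        if cols.shape[0] != n:
            cols = cols.T
        X = np.column_stack([X, cols])
        H_cur = _projector(X)
        rank_cur = int(round(np.trace(H_cur)))
        df_t = rank_cur - rank_prev
        if df_t == 0:
            raise DataError(f"term {name!r} is aliased with preceding terms")
        increments.append((name, H_cur - H_prev, df_t))
        H_prev, rank_prev = H_cur, rank_cur
    R = np.eye(n) - H_prev
    df_res = n - rank_prev
    if df_res <= 0:
        raise DataError("saturated design: no residual degrees of freedom")

    def stats_for(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float((H * Gm).sum()) for _, H, _ in increments])
        ss_res = float((R * Gm).sum())
        return ss, ss_res

    ss_obs, ss_res_obs = stats_for(G)
    dfs = np.array([df for _, _, df in increments], dtype=float)
    F_obs = (ss_obs / dfs) / (ss_res_obs / df_res)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(increments))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Gp = G[np.ix_(perm, perm)]
        ss_p, ss_res_p = stats_for(Gp)
        F_p = (ss_p / dfs) / (ss_res_p / df_res)
        exceed += F_p >= F_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = [
        {
            "term": name,
            "df": int(df),
            "sum_sq": ss,
            "F": F,
            "p": p,
        }
        for (name, _, df), ss, F, p in zip(increments, ss_obs, F_obs, pvals)
    ]
    rows.append(
        {"term": "residual", "df": int(df_res), "sum_sq": ss_res_obs,
         "F": np.nan, "p": np.nan}
    )
    rows.append(
        {"term": "total", "df": n - 1, "sum_sq": float(np.trace(G)),
         "F": np.nan, "p": np.nan}
    )
    return pd.DataFrame(rows)


def permanova(
    D: DistanceMatrix,
    pond,
    year,
    n_perm: int = 999,
    seed: int = 0,
    year_numeric: bool = True,
    interaction: bool = True,
) -> pd.DataFrame:
    """``pond + year + pond:year`` PERMANOVA on a labelled distance matrix.

    Year enters as a centered numeric covariate (df = 1) by default; pass
    ``year_numeric=False`` for a categorical year (note a categorical year
    with the full interaction saturates a complete pond x year design, so
    that combination needs ``interaction=False``).
    """
    pond = np.asarray(pond, dtype=object)
    year = np.asarray(year, dtype=float)
    if pond.size != D.n or year.size != D.n:
        raise DataError("pond/year labels must align with the distance matrix")
    levels = pd.unique(pond)
    P = np.column_stack([(pond == l).astype(float) for l in levels[1:]])
    if year_numeric:
        Y = (year - year.mean())[:, None]
    else:
        ylev = pd.unique(year)
        Y = np.column_stack([(year == l).astype(float) for l in ylev[1:]])
    terms = [("pond", P), ("year", Y)]
    if interaction:
        inter = np.column_stack([P[:, j:j + 1] * Y for j in range(P.shape[1])])
        terms.append(("pond:year", inter))
    return adonis(D, terms, n_perm=n_perm, seed=seed)


# --------------------------------------------------------------------------
# SIMPER
# --------------------------------------------------------------------------
@dataclass
class SimperResult:
    """Per-comparison contributions plus a grouped pond-level summary."""

    comparisons: pd.DataFrame   # long: one row per comparison x column
    summary: pd.DataFrame       # pond-level average percent per column/group
    grouping: str


def simper_pair(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-column contribution to the Bray-Curtis dissimilarity of two rows:
    ``|x_i - y_i| / sum(x + y)``.  Contributions sum to BC(x, y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise DataError("simper_pair requires non-negative rows")
    denom = float((x + y).sum())
    if denom == 0:
        warnings.warn("all-zero row pair; contributions set to 0", stacklevel=2)
        return np.zeros_like(x)
    return np.abs(x - y) / denom


def _percent(contrib: np.ndarray) -> np.ndarray:
    total = contrib.sum()
    if total == 0:
        warnings.warn("zero total dissimilarity; percents set to 0", stacklevel=2)
        return np.zeros_like(contrib)
    return 100.0 * contrib / total


def _split_index(M: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    try:
        ponds = np.array([i[0] for i in M.index], dtype=object)
        years = np.array([i[1] for i in M.index])
    except (TypeError, IndexError) as exc:
        raise DataError("matrix rows must be (pond, year) pairs") from exc
    return ponds, years


def simper_year_to_centroid(M: pd.DataFrame) -> SimperResult:
    """SIMPER of each year's composition against its pond's time-mean row."""
    ponds, years = _split_index(M)
    X = np.asarray(M, dtype=float)
    cols = list(M.columns)
    rows = []
    for pond in pd.unique(ponds):
        idx = np.where(ponds == pond)[0]
        if idx.size < 2:
            warnings.warn(f"pond {pond!r} has < 2 years; skipped", stacklevel=2)
            continue
        mean_row = X[idx].mean(axis=0)
        for i in idx:
            contrib = simper_pair(X[i], mean_row)
            pct = _percent(contrib)
            for c, cv, pv in zip(cols, contrib, pct):
                rows.append(
                    {"pond": pond, "year": years[i], "column": c,
                     "contribution": cv, "percent": pv}
                )
    comparisons = pd.DataFrame(rows)
    summary = (
        comparisons.groupby(["pond", "column"], sort=False)[["contribution", "percent"]]
        .mean()
        .reset_index()
    )
    return SimperResult(comparisons, summary, grouping="year_to_centroid")


def simper_year_to_year(
    M: pd.DataFrame, group_map: dict[str, str] | None = None
) -> SimperResult:
    """SIMPER restricted to consecutive-year comparisons within each pond.

    With ``group_map`` (column -> group) the summary additionally averages
    group-summed percents over transitions per pond (the pie-chart numbers).
    """
    ponds, years = _split_index(M)
    X = np.asarray(M, dtype=float)
    cols = list(M.columns)
    rows = []
    for pond in pd.unique(ponds):
        idx = np.where(ponds == pond)[0]
        order = idx[np.argsort(years[idx])]
        for a, b in zip(order[:-1], order[1:]):
            if years[b] - years[a] != 1:
                continue
            contrib = simper_pair(X[a], X[b])
            pct = _percent(contrib)
            for c, cv, pv in zip(cols, contrib, pct):
                rows.append(
                    {"pond": pond, "year_from": years[a], "year_to": years[b],
                     "column": c, "contribution": cv, "percent": pv}
                )
    comparisons = pd.DataFrame(rows)
    if comparisons.empty:
        raise DataError("no consecutive-year comparisons available")
    if group_map is not None:
        unmapped = [c for c in cols if c not in group_map]
        if unmapped:
            raise DataError(f"columns without a group: {unmapped}")
        g = comparisons.assign(group=comparisons["column"].map(group_map))
        per_transition = (
            g.groupby(["pond", "year_from", "year_to", "group"], sort=False)["percent"]
            .sum()
            .reset_index()
        )
        summary = (
            per_transition.groupby(["pond", "group"], sort=False)["percent"]
            .mean()
            .reset_index()
        )
    else:
        summary = (
            comparisons.groupby(["pond", "column"], sort=False)[["contribution", "percent"]]
            .mean()
            .reset_index()
        )
    return SimperResult(comparisons, summary, grouping="year_to_year")


def simper_all_pairs(M: pd.DataFrame, groups) -> pd.DataFrame:
    """Classic SIMPER: average contributions over *all* between-group pairs."""
    groups = np.asarray(groups, dtype=object)
    X = np.asarray(M, dtype=float)
    cols = list(M.columns)
    rows = []
    levels = pd.unique(groups)
    for gi in range(len(levels)):
        for gj in range(gi + 1, len(levels)):
            ia = np.where(groups == levels[gi])[0]
            ib = np.where(groups == levels[gj])[0]
            acc = np.zeros(len(cols))
            n_pairs = 0
            for a in ia:
                for b in ib:
                    acc += simper_pair(X[a], X[b])
                    n_pairs += 1
            acc /= n_pairs
            pct = _percent(acc)
            for c, cv, pv in zip(cols, acc, pct):
                rows.append(
                    {"group_a": levels[gi], "group_b": levels[gj], "column": c,
                     "contribution": cv, "percent": pv}
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# envfit
# --------------------------------------------------------------------------
def envfit(
    ordination: Ordination | np.ndarray,
    V: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Vector fitting of each column of ``V`` onto ordination scores.

    Per variable: least-squares regression of the centered variable on the
    centered scores; R^2 = 1 - SSE/SST; the arrow is the coefficient vector
    normalized to unit length; p from free permutation of the variable.
    """
    scores = ordination.scores if isinstance(ordination, Ordination) else np.asarray(ordination, float)
    n, k = scores.shape
    if k < 2:
        raise DataError("envfit requires at least 2 ordination axes")
    if len(V) != n:
        raise DataError("variable rows must align with ordination scores")
    Xc = scores - scores.mean(axis=0)
    Q, _ = np.linalg.qr(Xc)
    rng = np.random.default_rng(seed)
    rows = []
    for name in V.columns:
        v = V[name].to_numpy(float)
        vc = v - v.mean()
        sst = float(vc @ vc)
        if sst == 0:
            warnings.warn(f"constant variable {name!r}: R^2 = 0", stacklevel=2)
            rows.append(
                {"variable": name, **{f"nMDS{i+1}": 0.0 for i in range(k)},
                 "R2": 0.0, "p": 1.0}
            )
            continue
        coef, *_ = np.linalg.lstsq(Xc, vc, rcond=None)
        r2 = float((Q.T @ vc) @ (Q.T @ vc) / sst)
        norm = np.linalg.norm(coef)
        direction = coef / norm if norm > 0 else np.zeros(k)
        perm_r2 = np.empty(n_perm)
        for b in range(n_perm):
            vp = vc[rng.permutation(n)]
            proj = Q.T @ vp
            perm_r2[b] = (proj @ proj) / sst
        p = (1.0 + float((perm_r2 >= r2 - 1e-12).sum())) / (1.0 + n_perm)
        rows.append(
            {"variable": name,
             **{f"nMDS{i+1}": float(direction[i]) for i in range(k)},
             "R2": r2, "p": p}
        )
    return pd.DataFrame(rows)
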