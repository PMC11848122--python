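"""From-scratch multivariate engines: Bray-Curtis, PCoA and non-metric MDS.

These are deliberately self-contained implementations (no vegan/scikit-bio
delegation): Bray-Curtis by direct formula, principal coordinates via the
Gower double-centered eigendecomposition (keeping negative-eigenvalue axes),
and nMDS by alternating pool-adjacent-violators monotone regression with
Guttman-transform configuration updates, minimizing Kruskal stress-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DataError


# --------------------------------------------------------------------------
# distance matrix container
# --------------------------------------------------------------------------
@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with row labels."""

    labels: list
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise DataError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DataError("distance matrix not symmetric (tol 1e-12)")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise DataError("distance matrix diagonal not zero")
        self.data = 0.5 * (d + d.T)
        np.fill_diagonal(self.data, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        idx = pd.Index([str(l) for l in self.labels])
        return pd.DataFrame(self.data, index=idx, columns=idx)

    def submatrix(self, idx: np.ndarray) -> "DistanceMatrix":
        idx = np.asarray(idx)
        return DistanceMatrix(
            [self.labels[i] for i in idx], self.data[np.ix_(idx, idx)]
        )

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.data[iu]


def bray_curtis(M: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between matrix rows.

    ``d(j, k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik)``.  A pair of
    all-zero rows gets distance 0 with a warning.
    """
    X = np.asarray(M, dtype=float)
    if np.isnan(X).any():
        raise DataError("matrix contains NaN")
    neg = np.argwhere(X < 0)
    if neg.size:
        i, j = neg[0]
        raise DataError(
            f"negative entry at row {M.index[i]!r}, column {M.columns[j]!r}: "
            f"{X[i, j]}"
        )
    n = X.shape[0]
    numer = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    denom = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    zero = denom == 0
    np.fill_diagonal(zero, False)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum()) // 2} all-zero row pairs; distance set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, numer / np.where(denom == 0, 1.0, denom), 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(M.index), d)


# --------------------------------------------------------------------------
# principal coordinates
# --------------------------------------------------------------------------
@dataclass
class PCoAResult:
    """Eigendecomposition of the Gower-centered squared-distance matrix.

    ``pos_coords`` / ``neg_coords`` are the coordinates on the positive- and
    negative-eigenvalue axes; for any pair ``j, k``:
    ``d(j,k)^2 = ||pos_j - pos_k||^2 - ||neg_j - neg_k||^2``.
    """

    labels: list
    eigenvalues: np.ndarray       # all, sorted descending
    pos_coords: np.ndarray        # (n, n_pos)
    neg_coords: np.ndarray        # (n, n_neg)


def gower_center(D: DistanceMatrix) -> np.ndarray:
    """Return G = -1/2 J D^2 J (double-centered squared distances)."""
    A = -0.5 * D.data**2
    n = D.n
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def pcoa(D: DistanceMatrix) -> PCoAResult:
    G = gower_center(D)
    G = 0.5 * (G + G.T)
    ev, U = np.linalg.eigh(G)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    tol = max(1e-12, np.abs(ev).max() * 1e-9) if ev.size else 1e-12
    pos = ev > tol
    negm = ev < -tol
    pos_coords = U[:, pos] * np.sqrt(ev[pos])
    neg_coords = U[:, negm] * np.sqrt(-ev[negm])
    return PCoAResult(list(D.labels), ev, pos_coords, neg_coords)


# --------------------------------------------------------------------------
# non-metric MDS
# --------------------------------------------------------------------------
@dataclass
class Ordination:
    """nMDS scores (column-centered) with Kruskal stress-1."""

    labels: list
    scores: np.ndarray
    stress: float
    converged: bool
    n_starts: int
    stress_trace: list = field(default_factory=list, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [f"nMDS{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(
            self.scores, index=pd.Index([str(l) for l in self.labels]), columns=cols
        )


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators: least-squares nondecreasing fit (equal weights)."""
    n = y.size
    fitted = y.astype(float).copy()
    weights = np.ones(n)
    # block representation
    vals: list[float] = []
    wts: list[float] = []
    sizes: list[int] = []
    for i in range(n):
        vals.append(fitted[i])
        wts.append(weights[i])
        sizes.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            w = wts[-2] + wts[-1]
            s = sizes[-2] + sizes[-1]
            vals = vals[:-2] + [v]
            wts = wts[:-2] + [w]
            sizes = sizes[:-2] + [s]
    out = np.empty(n)
    pos = 0
    for v, s in zip(vals, sizes):
        out[pos: pos + s] = v
        pos += s
    return out


def _disparities(d_obs: np.ndarray, d_conf: np.ndarray) -> np.ndarray:
    """Monotone (primary-tie) regression of configuration distances on the
    rank order of observed dissimilarities."""
    order = np.lexsort((d_conf, d_obs))
    fitted = np.empty_like(d_conf)
    fitted[order] = _pava(d_conf[order])
    return fitted


def _pair_distances(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    full = np.sqrt((diff**2).sum(axis=2))
    iu = np.triu_indices(X.shape[0], k=1)
    return full[iu]


def kruskal_stress(D: DistanceMatrix, X: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    d_obs = D.condensed()
    d_conf = _pair_distances(np.asarray(X, dtype=float))
    dhat = _disparities(d_obs, d_conf)
    denom = float((d_conf**2).sum())
    if denom == 0:
        return 1.0
    return float(np.sqrt(((d_conf - dhat) ** 2).sum() / denom))


def _nmds_single(
    d_obs: np.ndarray, X0: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, float, bool, list]:
    n, _k = X0.shape
    iu = np.triu_indices(n, k=1)
    X = X0 - X0.mean(axis=0)
    prev_stress = np.inf
    converged = False
    trace: list[float] = []
    for _ in range(max_iter):
        d_conf = _pair_distances(X)
        dhat = _disparities(d_obs, d_conf)
        denom = float((d_conf**2).sum())
        stress = np.sqrt(((d_conf - dhat) ** 2).sum() / denom) if denom else 1.0
        if stress > prev_stress + 1e-15:
            # Guttman step overshot the normalized criterion: keep previous
            X = X_prev
            stress = prev_stress
            converged = True
            break
        trace.append(float(stress))
        if prev_stress - stress < tol:
            prev_stress = stress
            converged = True
            break
        prev_stress = stress
        X_prev = X
        # Guttman transform toward the disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_conf > 0, dhat / d_conf, 0.0)
        B = np.zeros((n, n))
        B[iu] = -ratio
        B = B + B.T
        np.fill_diagonal(B, -B.sum(axis=1))
        X = (B @ X) / n
        X = X - X.mean(axis=0)
        if stress < 1e-12:
            converged = True
            break
    return X - X.mean(axis=0), float(prev_stress), converged, trace


def nmds(
    D: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> Ordination:
    """Best-of-n-starts non-metric MDS (random starts plus one PCoA start)."""
    if k < 1:
        raise DataError("k must be >= 1")
    if D.n < k + 2:
        raise DataError(f"need at least k + 2 = {k + 2} objects, got {D.n}")
    rng = np.random.default_rng(seed)
    d_obs = D.condensed()
    scale = d_obs.max() if d_obs.max() > 0 else 1.0

    starts: list[np.ndarray] = []
    pc = pcoa(D)
    X0 = np.zeros((D.n, k))
    m = min(k, pc.pos_coords.shape[1])
    X0[:, :m] = pc.pos_coords[:, :m]
    starts.append(X0)
    for _ in range(n_starts):
        starts.append(rng.normal(0.0, scale, (D.n, k)))

    best: tuple[np.ndarray, float, bool, list] | None = None
    for X0 in starts:
        X, stress, conv, trace = _nmds_single(d_obs, X0, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, conv, trace)
    X, stress, conv, trace = best
    return Ordination(list(D.labels), X, stress, conv, len(starts), trace)
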