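"""Penalized thin-plate regression spline engine.

Fits the additive model ``value = alpha_taxon + s(length)`` where ``s`` is a
low-rank 1-D thin-plate spline (radial basis ``|x - t|^3`` on quantile knots,
null space {1, x} projected out) with ridge penalty on the wiggly part.  The
penalty weight lambda is selected by minimizing the Gaussian restricted
maximum likelihood (REML) score with a coarse grid plus golden-section
refinement on log(lambda).

As lambda -> infinity the smooth shrinks to zero and the model degenerates to
additive taxon intercepts plus a linear length term.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .constants import DataError

logger = logging.getLogger(__name__)

_LOG_LAMBDA_BOUNDS = (-14.0, 20.0)  # natural log; wide enough for both limits


def _tps_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Radial thin-plate basis |x - t|^3 evaluated at x for each knot."""
    return np.abs(x[:, None] - knots[None, :]) ** 3


@dataclass
class PenalizedAdditiveModel:
    """``value ~ taxon + s(length)`` with a REML-selected penalty.

    Parameters
    ----------
    basis_dim:
        Number of spline knots (upper bound; reduced if there are fewer
        distinct length values).
    per_taxon_smooth:
        If True, fit one smooth per taxon (shared knots and lambda) instead
        of a single shared smooth.
    """

    basis_dim: int = 10
    per_taxon_smooth: bool = False
    lambda_fixed: float | None = None  # skip REML selection when set

    # populated by fit()
    taxa_: list[str] = field(default_factory=list, repr=False)
    taxon_effects_: dict[str, float] = field(default_factory=dict, repr=False)
    lambda_: float = np.nan
    edf_: float = np.nan
    resid_sd_: float = np.nan
    n_clamped_: int = 0

    # ------------------------------------------------------------------ fit
    def fit(self, taxa, lengths, values) -> "PenalizedAdditiveModel":
        taxa = np.asarray(taxa, dtype=object)
        x = np.asarray(lengths, dtype=float)
        y = np.asarray(values, dtype=float)
        if x.size == 0:
            raise DataError("empty input")
        if not (taxa.shape == x.shape == y.shape):
            raise DataError("taxa, lengths and values must have equal length")
        if np.unique(x).size < 2:
            raise DataError("need >= 2 distinct lengths to fit a length effect")

        self.taxa_ = sorted(set(taxa.tolist()))
        for t in self.taxa_:
            mask = taxa == t
            if mask.sum() < 2 and np.unique(x[mask]).size < 2:
                warnings.warn(
                    f"taxon {t!r} has < 2 records; its prediction reduces to "
                    "the taxon intercept at any length",
                    stacklevel=2,
                )

        self._x_min, self._x_max = float(x.min()), float(x.max())
        xr = (x - self._x_min) / (self._x_max - self._x_min)
        self._xr_mean = float(xr.mean())

        # knots at quantiles of the scaled lengths
        uniq = np.unique(xr)
        k = min(self.basis_dim, uniq.size)
        if k >= 3:
            qs = np.linspace(0.0, 1.0, k)
            knots = np.unique(np.quantile(uniq, qs))
            k = knots.size
        else:
            knots = np.empty(0)
        self._knots = knots

        n = x.size
        taxon_index = {t: i for i, t in enumerate(self.taxa_)}
        ti = np.array([taxon_index[t] for t in taxa])
        D = np.zeros((n, len(self.taxa_)))
        D[np.arange(n), ti] = 1.0
        xc = xr - self._xr_mean

        if k >= 3:
            E = _tps_basis(knots, knots)
            T = np.column_stack([np.ones(k), knots])
            Q, _ = np.linalg.qr(T, mode="complete")
            Z = Q[:, 2:]                       # (k, k-2)
            S = Z.T @ E @ Z
            S = 0.5 * (S + S.T)
            self._Z = Z
            Phi = _tps_basis(xr, knots)
            if self.per_taxon_smooth:
                B = np.concatenate(
                    [(Phi @ Z) * (ti == i)[:, None] for i in range(len(self.taxa_))],
                    axis=1,
                )
                S_blocks = [S] * len(self.taxa_)
            else:
                B = Phi @ Z
                S_blocks = [S]
            X = np.column_stack([D, xc, B])
            p_fixed = len(self.taxa_) + 1
            Sf = np.zeros((X.shape[1], X.shape[1]))
            off = p_fixed
            for Sb in S_blocks:
                m = Sb.shape[0]
                Sf[off:off + m, off:off + m] = Sb
                off += m
            # log|S|_+ : sum of log positive eigenvalues of the penalty block
            ev = np.concatenate([np.linalg.eigvalsh(Sb) for Sb in S_blocks])
            ev = ev[ev > 1e-12 * ev.max()]
            self._rank_S = ev.size
            self._logdet_S = float(np.sum(np.log(ev)))
        else:
            X = np.column_stack([D, xc])
            p_fixed = X.shape[1]
            Sf = np.zeros((X.shape[1], X.shape[1]))
            self._rank_S = 0
            self._logdet_S = 0.0

        self._X, self._y, self._Sf, self._p_fixed = X, y, Sf, p_fixed
        XtX, Xty = X.T @ X, X.T @ y

        def fit_at(lam: float):
            A = XtX + lam * Sf
            try:
                c, low = linalg.cho_factor(A)
                beta = linalg.cho_solve((c, low), Xty)
                logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
            except linalg.LinAlgError:
                A = A + 1e-10 * np.eye(A.shape[0]) * max(1.0, np.trace(A))
                c, low = linalg.cho_factor(A)
                beta = linalg.cho_solve((c, low), Xty)
                logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
            return beta, logdet_A

        def reml(lam: float) -> float:
            beta, logdet_A = fit_at(lam)
            resid = y - X @ beta
            rss = float(resid @ resid)
            pen = float(lam * beta @ Sf @ beta)
            nm = n - p_fixed
            sigma2 = max((rss + pen) / nm, 1e-300)
            logdet_Slam = self._rank_S * np.log(lam) + self._logdet_S
            return 0.5 * (
                nm * (np.log(2.0 * np.pi * sigma2) + 1.0)
                + logdet_A - logdet_Slam
            )

        self._reml_fn = reml

        if self.lambda_fixed is not None:
            self.lambda_ = float(self.lambda_fixed)
        elif self._rank_S > 0:
            lo, hi = _LOG_LAMBDA_BOUNDS
            grid = np.linspace(lo, hi, 18)
            scores = [reml(np.exp(g)) for g in grid]
            i = int(np.argmin(scores))
            if 0 < i < len(grid) - 1:
                res = optimize.minimize_scalar(
                    lambda g: reml(np.exp(g)),
                    bracket=(grid[i - 1], grid[i], grid[i + 1]),
                    method="golden",
                    options={"xtol": 1e-4},
                )
                log_lam = float(res.x)
            else:
                log_lam = float(grid[i])
            self.lambda_ = float(np.exp(log_lam))
        else:
            self.lambda_ = np.inf

        lam_eff = self.lambda_ if np.isfinite(self.lambda_) else 0.0
        A = XtX + lam_eff * Sf
        beta = np.linalg.solve(A, Xty)
        self._beta = beta
        self.edf_ = float(np.trace(np.linalg.solve(A, XtX)))
        resid = y - X @ beta
        rss = float(resid @ resid)
        self.resid_sd_ = float(np.sqrt(rss / max(n - self.edf_, 1.0)))
        self.taxon_effects_ = {
            t: float(beta[i]) for i, t in enumerate(self.taxa_)
        }
        self._taxon_index = taxon_index
        return self

    # -------------------------------------------------------------- predict
    def reml(self, lam: float) -> float:
        """REML score at an arbitrary penalty (for diagnostics/tests)."""
        return self._reml_fn(lam)

    def predict(self, taxa, lengths) -> np.ndarray:
        """Predict trait values; lengths are clamped to the training range."""
        taxa = np.asarray(taxa, dtype=object)
        x = np.asarray(lengths, dtype=float)
        missing = sorted({t for t in taxa.tolist() if t not in self._taxon_index})
        if missing:
            raise DataError(f"taxa without a fitted effect: {missing}")
        clamped = (x < self._x_min) | (x > self._x_max)
        self.n_clamped_ += int(clamped.sum())
        if clamped.any():
            logger.info("clamped %d lengths to the training range", clamped.sum())
        x = np.clip(x, self._x_min, self._x_max)
        xr = (x - self._x_min) / (self._x_max - self._x_min)

        n = x.size
        p = self._X.shape[1]
        Xp = np.zeros((n, p))
        ti = np.array([self._taxon_index[t] for t in taxa])
        Xp[np.arange(n), ti] = 1.0
        n_taxa = len(self.taxa_)
        Xp[:, n_taxa] = xr - self._xr_mean
        if self._rank_S > 0:
            Phi = _tps_basis(xr, self._knots)
            BZ = Phi @ self._Z
            m = BZ.shape[1]
            off = n_taxa + 1
            if self.per_taxon_smooth:
                for i in range(n_taxa):
                    rows = ti == i
                    Xp[rows, off + i * m: off + (i + 1) * m] = BZ[rows]
            else:
                Xp[:, off: off + m] = BZ
        return Xp @ self._beta
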