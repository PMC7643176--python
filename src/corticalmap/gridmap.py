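"""Standardized thickness maps: min-max scaling, penalized thin-plate
smoothing onto the fixed K x M grid, consensus maps scored by GCV, and
deformation (difference) maps.

The smoother is a low-rank thin-plate spline regression: a grid of knots
carries the radial basis r^2 log r, the polynomial null space (1, x, y)
is unpenalized, and the bending-energy penalty acts on the kernel
coefficients projected onto the polynomial-orthogonal complement.  The
smoothing parameter is selected by generalized cross-validation.  The
circumferential coordinate is circular: points near the seam are
duplicated one period away before fitting, so a thickening straddling
y = 0/1 is reconstructed as one contiguous feature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, qr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import FitError, GridMismatchError, ParameterError
from .thickness import ThicknessCloud

__all__ = ["GridSpec", "StandardMap", "ConsensusMap", "ThinPlateSmoother",
           "normalize_thickness", "fit_map", "consensus_map", "deformation_map"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Regular evaluation grid: M columns along the shaft (x), K rows around
    the circumference (y); nodes at cell centers ((j - 1/2)/M, (i - 1/2)/K)."""

    M: int = 100
    K: int = 200

    def __post_init__(self):
        if self.M < 4 or self.K < 4:
            raise ParameterError("grid needs M, K >= 4")

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.M) + 0.5) / self.M

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.K) + 0.5) / self.K

    def nodes(self) -> np.ndarray:
        """(K*M, 2) node coordinates, row-major (y outer, x inner)."""
        gx, gy = np.meshgrid(self.x, self.y)
        return np.column_stack([gx.ravel(), gy.ravel()])


def _long_form(grid: np.ndarray, gridspec: GridSpec) -> pd.DataFrame:
    nodes = gridspec.nodes()
    return pd.DataFrame({"x": nodes[:, 0], "y": nodes[:, 1],
                         "z": grid.ravel()})


@dataclass
class StandardMap:
    """K x M grid of (standardized) thickness plus its long form."""

    grid: np.ndarray
    gridspec: GridSpec
    gcv: float
    specimen_id: str = ""
    standardized: bool = True
    n_clipped: int = 0

    @property
    def long_form(self) -> pd.DataFrame:
        return _long_form(self.grid, self.gridspec)

    def to_csv(self, path):
        self.long_form.to_csv(path, index=False)

    def to_png(self, path, **kwargs):
        heatmap(self.grid, path, **kwargs)


@dataclass
class ConsensusMap:
    """Pooled smooth map for a group of specimens, scored by GCV."""

    grid: np.ndarray
    gridspec: GridSpec
    gcv: float
    specimen_ids: tuple = ()

    @property
    def long_form(self) -> pd.DataFrame:
        return _long_form(self.grid, self.gridspec)

    def to_csv(self, path):
        self.long_form.to_csv(path, index=False)


def _tps_kernel(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Thin-plate radial basis r^2 log r between two 2D point sets."""
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        k = 0.5 * d2 * np.log(d2)   # = r^2 log r
    k[d2 == 0.0] = 0.0
    return k


class ThinPlateSmoother(BaseEstimator, RegressorMixin):
    """Penalized thin-plate-spline regression z ~ s(x, y) with GCV.

    Parameters
    ----------
    n_knots : int
        Approximate size of the knot grid (basis dimension); large by
        default to preserve spatial resolution, with the penalty doing
        the regularization.
    circular : bool
        Treat y as periodic with period 1 (the shaft is a closed tube).
    wrap_margin : float
        Width of the duplicated band on each side of the seam.
    lambdas : array-like or None
        Grid of smoothing parameters searched by GCV (per-point scaling).
    lam : float or None
        Fixed smoothing parameter; bypasses GCV selection.

    Attributes
    ----------
    coef_ : fitted coefficients; gcv_ : GCV score of the selected fit;
    lambda_ : selected smoothing parameter; edof_ : effective degrees of
    freedom of the smoother.
    """

    def __init__(self, n_knots: int = 300, circular: bool = True,
                 wrap_margin: float = 0.15, lambdas=None, lam=None):
        self.n_knots = n_knots
        self.circular = circular
        self.wrap_margin = wrap_margin
        self.lambdas = lambdas
        self.lam = lam

    def _augment(self, X, z):
        if not self.circular:
            return X, z
        y = X[:, 1]
        lo = y < self.wrap_margin
        hi = y > 1.0 - self.wrap_margin
        X_aug = np.vstack([X,
                           np.column_stack([X[lo, 0], y[lo] + 1.0]),
                           np.column_stack([X[hi, 0], y[hi] - 1.0])])
        z_aug = np.concatenate([z, z[lo], z[hi]])
        return X_aug, z_aug

    def _knot_grid(self):
        y_lo = -self.wrap_margin if self.circular else 0.0
        y_hi = 1.0 + self.wrap_margin if self.circular else 1.0
        height = y_hi - y_lo
        ky = max(4, int(round(np.sqrt(self.n_knots * height))))
        kx = max(4, int(round(self.n_knots / ky)))
        xs = (np.arange(kx) + 0.5) / kx
        ys = y_lo + (np.arange(ky) + 0.5) / ky * height
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def fit(self, X, z):
        X = np.asarray(X, dtype=float)
        z = np.asarray(z, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise FitError("X must be (n, 2) coordinates")
        if len(X) < 10:
            raise FitError(f"too few points to fit a surface ({len(X)})")
        Xa, za = self._augment(X, z)
        # collapse exactly repeated observations into frequency weights so a
        # pooled fit of duplicated clouds equals the single-cloud fit (the
        # GCV below counts distinct observations)
        rows = np.column_stack([Xa, za])
        uniq, counts = np.unique(rows, axis=0, return_counts=True)
        Xa, za = uniq[:, :2], uniq[:, 2]
        w = counts.astype(float)
        n = len(za)
        w_mean = w.mean()

        knots = self._knot_grid()
        k = len(knots)
        T_k = np.column_stack([np.ones(k), knots])          # (k, 3)
        Q, _ = qr(T_k, mode="full")
        Z = Q[:, 3:]                                        # null space of T_k'
        K_kk = _tps_kernel(knots, knots)
        S = Z.T @ K_kk @ Z
        S = (S + S.T) / 2.0
        # scale-normalize the penalty so lambda is comparable across fits
        S /= np.trace(S) / S.shape[0]

        B = _tps_kernel(Xa, knots) @ Z                      # (n, k-3)
        T = np.column_stack([np.ones(n), Xa])               # (n, 3)
        C = np.hstack([B, T])
        p = C.shape[1]
        P = np.zeros((p, p))
        P[:k - 3, :k - 3] = S

        Cw = C * w[:, None]
        G = C.T @ Cw
        b = Cw.T @ za
        zz = float((w * za) @ za)
        w_total = float(w.sum())

        lambdas = (np.asarray([self.lam], dtype=float) if self.lam is not None
                   else np.asarray(self.lambdas if self.lambdas is not None
                                   else np.logspace(-8, 2, 25), dtype=float))
        best = None
        jitter = 1e-10 * np.trace(G) / p
        for lam in lambdas:
            A = G + lam * w_total * P
            A[np.diag_indices_from(A)] += jitter
            try:
                cf = cho_factor(A)
            except np.linalg.LinAlgError:
                continue
            theta = cho_solve(cf, b)
            rss = max(zz - 2.0 * theta @ b + theta @ (G @ theta), 0.0)
            edof = float(np.trace(cho_solve(cf, G)))
            denom = max(n - edof, 1e-8)
            gcv = n * (rss / w_mean) / denom ** 2
            if best is None or gcv < best[0]:
                best = (gcv, lam, theta, edof)
        if best is None:
            raise FitError("rank-deficient design: smoothing system singular")
        self.gcv_, self.lambda_, self.coef_, self.edof_ = best
        self.knots_ = knots
        self.Z_ = Z
        self.n_points_ = n
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        Xp = X.copy()
        if self.circular:
            Xp[:, 1] = Xp[:, 1] % 1.0
        B = _tps_kernel(Xp, self.knots_) @ self.Z_
        T = np.column_stack([np.ones(len(Xp)), Xp])
        return np.hstack([B, T]) @ self.coef_


# ---------------------------------------------------------------------------
# module-level operations


def normalize_thickness(cloud: ThicknessCloud) -> ThicknessCloud:
    """Min-max standardize thickness to [0, 1] (per specimen).

    A constant field is degenerate: every value maps to 0.5 with a
    prominent warning.
    """
    z = cloud.z
    lo, hi = float(z.min()), float(z.max())
    if hi == lo:
        warnings.warn(
            f"specimen {cloud.specimen_id!r} has a constant thickness field; "
            "standardized values set to 0.5", stacklevel=2)
        z_std = np.full_like(z, 0.5)
    else:
        z_std = (z - lo) / (hi - lo)
    return ThicknessCloud(x=cloud.x, y=cloud.y, z=z_std,
                          specimen_id=cloud.specimen_id,
                          laterality=cloud.laterality, standardized=True)


MIN_POINTS = 50


def _fit_grid(x, y, z, gridspec, clip, **smoother_kwargs):
    if len(z) < MIN_POINTS:
        raise FitError(f"need at least {MIN_POINTS} points, got {len(z)}")
    sm = ThinPlateSmoother(**smoother_kwargs)
    sm.fit(np.column_stack([x, y]), z)
    grid = sm.predict(gridspec.nodes()).reshape(gridspec.K, gridspec.M)
    n_clipped = 0
    if clip:
        outside = (grid < 0.0) | (grid > 1.0)
        n_clipped = int(outside.sum())
        if n_clipped:
            log.info("clipped %d of %d grid values to [0, 1]",
                     n_clipped, grid.size)
            grid = np.clip(grid, 0.0, 1.0)
    return grid, float(sm.gcv_), n_clipped


def fit_map(cloud: ThicknessCloud, gridspec: GridSpec = GridSpec(),
            **smoother_kwargs) -> StandardMap:
    """Regress a scattered cloud onto the K x M grid.

    Standardized clouds are clipped back to [0, 1] where the smoother
    overshoots (count logged); clouds in mm are left on their scale.
    """
    grid, gcv, n_clipped = _fit_grid(cloud.x, cloud.y, cloud.z, gridspec,
                                     clip=cloud.standardized, **smoother_kwargs)
    return StandardMap(grid=grid, gridspec=gridspec, gcv=gcv,
                       specimen_id=cloud.specimen_id,
                       standardized=cloud.standardized, n_clipped=n_clipped)


def consensus_map(clouds, gridspec: GridSpec = GridSpec(),
                  **smoother_kwargs) -> ConsensusMap:
    """Single pooled fit over the concatenation of all clouds, with its GCV."""
    clouds = list(clouds)
    if not clouds:
        raise ParameterError("consensus_map needs at least one cloud")
    x = np.concatenate([c.x for c in clouds])
    y = np.concatenate([c.y for c in clouds])
    z = np.concatenate([c.z for c in clouds])
    clip = all(c.standardized for c in clouds)
    grid, gcv, _ = _fit_grid(x, y, z, gridspec, clip=clip, **smoother_kwargs)
    return ConsensusMap(grid=grid, gridspec=gridspec, gcv=gcv,
                        specimen_ids=tuple(c.specimen_id for c in clouds))


def deformation_map(a, b) -> np.ndarray:
    """Cell-wise difference grid between two consensus (or standard) maps."""
    if a.gridspec != b.gridspec:
        raise GridMismatchError(
            f"grid mismatch: {a.gridspec} vs {b.gridspec}")
    return a.grid - b.grid


def heatmap(grid: np.ndarray, path, title: str = "", entheses=None):
    """PNG heatmap of a map grid; optional enthesis ellipses as visual cues."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(grid, origin="lower", aspect="auto", cmap="inferno",
                   extent=(0, 1, 0, 1))
    ax.set_xlabel("x (diaphysis length)")
    ax.set_ylabel("y (circumference)")
    if title:
        ax.set_title(title)
    for ell in entheses or ():
        ax.add_patch(Ellipse(ell[:2], *ell[2:4], fill=False, color="white"))
    fig.colorbar(im, ax=ax, label="standardized thickness")
    fig.savefig(path, dpi=120)
    plt.close(fig)
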