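"""Multivariate statistics on morphometric maps and life-history traits.

The map matrix (one standardized K*M map per specimen row) feeds a
distance-based factorial permutation MANOVA/MANCOVA with residual
randomization, PCA dimension reduction, canonical variate analysis with
theoretical extreme maps, and two-block partial least squares against
trait blocks; scalar traits get factorial ANOVA, Pearson tests,
per-group regressions and Bonferroni pairwise comparisons.  Muscle force
is proxied by anatomical cross-sectional area, ACSA = (mass / 1.06
g cm^-3) / fascicle length.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .errors import ParameterError

__all__ = ["acsa", "add_acsa", "MUSCLE_DENSITY",
           "PermutationMANOVA", "perm_manova",
           "MapPCA", "pca_reduce",
           "CanonicalVariates", "cva",
           "TwoBlockPLS", "pls2b",
           "trait_models", "TraitModelResults"]

#: density of mammalian muscle, g / cm^3
MUSCLE_DENSITY = 1.06


def acsa(mass_g, fascicle_length_cm):
    """Anatomical cross-sectional area (cm^2), a proxy for muscle force.

    ACSA = (mass / density) / fascicle length with density 1.06 g/cm^3.
    """
    mass_g = np.asarray(mass_g, dtype=float)
    fascicle_length_cm = np.asarray(fascicle_length_cm, dtype=float)
    if np.any(mass_g <= 0) or np.any(fascicle_length_cm <= 0):
        raise ParameterError("mass and fascicle length must be positive")
    out = (mass_g / MUSCLE_DENSITY) / fascicle_length_cm
    return float(out) if out.ndim == 0 else out


def add_acsa(muscles: pd.DataFrame) -> pd.DataFrame:
    """Return the muscle table with an ``acsa_cm2`` column appended."""
    out = muscles.copy()
    out["acsa_cm2"] = acsa(out["mass_g"].to_numpy(),
                           out["fascicle_length_cm"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# design-matrix helpers (sequential / Type I decomposition)


def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric design columns for one model term ('a', 'x', or 'a:b')."""
    blocks = []
    for part in term.split(":"):
        if part not in data.columns:
            raise ParameterError(f"term {part!r} not in metadata columns")
        col = data[part]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True)
            if dummies.shape[1] == 0:
                raise ParameterError(f"factor {part!r} has a single level")
            blocks.append(dummies.to_numpy(dtype=float))
        else:
            v = col.to_numpy(dtype=float)
            blocks.append((v - v.mean())[:, None])
    cols = blocks[0]
    for nxt in blocks[1:]:
        cols = np.einsum("ij,ik->ijk", cols, nxt).reshape(len(cols), -1)
    return cols


def _orthonormal_increments(data: pd.DataFrame, terms) -> list:
    """Sequential orthonormal bases: intercept, then one block per term.

    Each block spans the part of a term's column space not already spanned
    by earlier terms (QR with rank filtering); confounded directions are
    dropped with a warning.
    """
    n = len(data)
    basis = [np.full((n, 1), 1.0 / np.sqrt(n))]
    for term in terms:
        cols = _term_columns(data, term)
        Q_prev = np.hstack(basis)
        resid = cols - Q_prev @ (Q_prev.T @ cols)
        q, r = np.linalg.qr(resid)
        keep = np.abs(np.diag(r)) > 1e-8 * max(1.0, np.abs(r).max())
        if keep.sum() < cols.shape[1]:
            warnings.warn(f"term {term!r} is partially confounded with earlier "
                          f"terms; dropped {cols.shape[1] - int(keep.sum())} "
                          "column(s)")
        basis.append(q[:, keep])
    return basis


@dataclass
class PermutationManovaResult:
    """Sequential (Type I) decomposition with permutation p-values."""

    table: pd.DataFrame
    n_perm: int
    seed: int | None

    def __repr__(self):
        return f"PermutationManovaResult(n_perm={self.n_perm})\n{self.table}"


class PermutationMANOVA(BaseEstimator):
    """Distance-based factorial MANOVA/MANCOVA with residual permutation.

    Sums of squares come from sequential linear-model fits on the
    high-dimensional response (Goodall-style pseudo-F on the Euclidean
    geometry of the maps, the same statistic geometric morphometrics
    applies to shapes already in a common frame); p-values come from
    randomization of reduced-model residuals (RRPP), seed-reproducible,
    with the (b + 1)/(B + 1) convention.
    """

    def __init__(self, terms, n_perm: int = 1000, seed: int | None = None):
        self.terms = terms
        self.n_perm = n_perm
        self.seed = seed

    def fit(self, X, data: pd.DataFrame):
        Y = np.asarray(X, dtype=float)
        n = len(Y)
        if len(data) != n:
            raise ParameterError("metadata rows must align with map rows")
        terms = list(self.terms)
        total_df = sum(_term_columns(data, t).shape[1] for t in terms)
        if n < total_df + 2:
            raise ParameterError(
                f"n = {n} too small for model with {total_df} df")
        basis = _orthonormal_increments(data, terms)
        Q_all = np.hstack(basis)
        ss_total = float(np.sum(Y ** 2) - np.sum((basis[0].T @ Y) ** 2))
        ss_terms = [float(np.sum((q.T @ Y) ** 2)) for q in basis[1:]]
        dfs = [q.shape[1] for q in basis[1:]]
        ss_res = float(np.sum(Y ** 2) - np.sum((Q_all.T @ Y) ** 2))
        df_res = n - Q_all.shape[1]
        if df_res <= 0:
            raise ParameterError("saturated model: no residual df")

        def f_stat(ss_t, df_t, ss_r):
            return (ss_t / df_t) / (ss_r / df_res)

        rng = np.random.default_rng(self.seed)
        rows = []
        for i, term in enumerate(terms):
            q_term = basis[i + 1]
            df_t = dfs[i]
            if df_t == 0:
                warnings.warn(f"term {term!r} fully confounded; skipped")
                continue
            f_obs = f_stat(ss_terms[i], df_t, ss_res)
            Q_red = np.hstack(basis[:i + 1])
            fitted_red = Q_red @ (Q_red.T @ Y)
            resid_red = Y - fitted_red
            count = 0
            for _ in range(self.n_perm):
                perm = rng.permutation(n)
                Y_star = fitted_red + resid_red[perm]
                ss_t_star = float(np.sum((q_term.T @ Y_star) ** 2))
                ss_res_star = float(np.sum(Y_star ** 2)
                                    - np.sum((Q_all.T @ Y_star) ** 2))
                if f_stat(ss_t_star, df_t, max(ss_res_star, 1e-300)) >= f_obs:
                    count += 1
            rows.append({"term": term, "df": df_t, "SS": ss_terms[i],
                         "R2": ss_terms[i] / ss_total, "F": f_obs,
                         "p_perm": (count + 1) / (self.n_perm + 1)})
        rows.append({"term": "Residuals", "df": df_res, "SS": ss_res,
                     "R2": ss_res / ss_total, "F": np.nan, "p_perm": np.nan})
        self.results_ = PermutationManovaResult(pd.DataFrame(rows),
                                                self.n_perm, self.seed)
        return self


def perm_manova(maps, data, terms, n_perm: int = 1000,
                seed: int | None = None) -> PermutationManovaResult:
    """Functional wrapper over :class:`PermutationMANOVA`."""
    est = PermutationMANOVA(terms=terms, n_perm=n_perm, seed=seed)
    est.fit(np.asarray(maps, dtype=float), data)
    return est.results_


# ---------------------------------------------------------------------------
# PCA reduction


class MapPCA(BaseEstimator, TransformerMixin):
    """Centered PCA retaining the smallest number of components whose
    cumulative explained variance reaches ``variance_kept`` (default 95%)."""

    def __init__(self, variance_kept: float = 0.95):
        self.variance_kept = variance_kept

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if len(X) < 3:
            raise ParameterError("PCA reduction needs n >= 3")
        pca = PCA(svd_solver="full")
        scores = pca.fit_transform(X)
        evr = pca.explained_variance_ratio_
        cum = np.cumsum(evr)
        q = int(np.searchsorted(cum, self.variance_kept - 1e-12) + 1)
        q = min(q, len(evr))
        self.n_components_ = q
        self.components_ = pca.components_[:q]
        self.explained_variance_ratio_ = evr[:q]
        self.mean_ = pca.mean_
        self.scores_ = scores[:, :q]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T

    def inverse_transform(self, scores):
        check_is_fitted(self, "components_")
        return np.asarray(scores, dtype=float) @ self.components_ + self.mean_


def pca_reduce(maps, variance_kept: float = 0.95) -> MapPCA:
    """Fit and return a :class:`MapPCA` on the map matrix."""
    return MapPCA(variance_kept=variance_kept).fit(np.asarray(maps, dtype=float))


# ---------------------------------------------------------------------------
# CVA


class CanonicalVariates(BaseEstimator, TransformerMixin):
    """Canonical variate analysis on (PCA-reduced) scores.

    Axes maximize the between-group to within-group variance ratio
    (generalized eigenproblem of the between and pooled-within covariance);
    at most ``n_groups - 1`` axes.  A singular within-group covariance is
    ridge-regularized with a warning.
    """

    def __init__(self, ridge: float = 0.0):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        labels, counts = np.unique(y, return_counts=True)
        if len(labels) < 2:
            raise ParameterError("CVA needs at least 2 groups")
        if (counts < 2).any():
            raise ParameterError("every group needs at least 2 members")
        n, p = X.shape
        g = len(labels)
        grand = X.mean(axis=0)
        W = np.zeros((p, p))
        B = np.zeros((p, p))
        centroids = np.empty((g, p))
        for i, lab in enumerate(labels):
            Xi = X[y == lab]
            centroids[i] = Xi.mean(axis=0)
            W += (Xi - centroids[i]).T @ (Xi - centroids[i])
            B += len(Xi) * np.outer(centroids[i] - grand, centroids[i] - grand)
        W /= (n - g)
        B /= (g - 1)
        ridge = self.ridge
        for attempt in range(2):
            try:
                evals, evecs = scipy.linalg.eigh(
                    B, W + ridge * np.eye(p))
                break
            except scipy.linalg.LinAlgError:
                ridge = max(ridge, 1e-8) * np.trace(W) / p + 1e-12
                warnings.warn("singular within-group covariance; "
                              f"ridge {ridge:.2e} added")
        else:  # pragma: no cover
            raise ParameterError("within-group covariance not factorizable")
        order = np.argsort(evals)[::-1][:min(g - 1, p)]
        self.eigenvalues_ = evals[order]
        A = evecs[:, order]
        # scale so that a' W a = 1 (Mahalanobis convention)
        norms = np.sqrt(np.einsum("ij,jk,ki->i", A.T, W, A))
        self.axes_ = A / norms
        self.mean_ = grand
        self.classes_ = labels
        self.scores_ = (X - grand) @ self.axes_
        self.centroids_ = (centroids - grand) @ self.axes_
        return self

    def transform(self, X):
        check_is_fitted(self, "axes_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.axes_

    def extreme_maps(self, map_pca: MapPCA, gridspec):
        """Theoretical min/max morphometric map for each canonical axis.

        The observed extreme score on an axis is back-projected to PC-score
        space (pseudo-inverse of the axis matrix) and then through the PCA
        loadings into a K x M grid.
        """
        check_is_fitted(self, "axes_")
        back = np.linalg.pinv(self.axes_)          # (n_axes, p_scores)
        out = []
        for k in range(self.axes_.shape[1]):
            maps = []
            for s in (self.scores_[:, k].min(), self.scores_[:, k].max()):
                pc = self.mean_ + s * back[k]
                grid = map_pca.inverse_transform(pc[None])[0]
                maps.append(grid.reshape(gridspec.K, gridspec.M))
            out.append(tuple(maps))
        return out


def cva(scores, groups, ridge: float = 0.0) -> CanonicalVariates:
    """Fit and return a :class:`CanonicalVariates` on score matrix + labels."""
    return CanonicalVariates(ridge=ridge).fit(np.asarray(scores, dtype=float),
                                              groups)


# ---------------------------------------------------------------------------
# two-block PLS


class TwoBlockPLS(BaseEstimator):
    """Two-block partial least squares between maps and a trait block.

    SVD of the between-block cross-covariance of the centered map block
    and the standardized trait block; the first-dimension correlation is
    tested by permutation of trait-block rows ((b+1)/(B+1) convention).
    """

    def __init__(self, n_perm: int = 1000, seed: int | None = None,
                 scale_traits: bool = True):
        self.n_perm = n_perm
        self.seed = seed
        self.scale_traits = scale_traits

    def _prepare(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if len(X) != len(Y):
            raise ParameterError("blocks must have the same number of rows")
        if np.isnan(X).any() or np.isnan(Y).any():
            raise ParameterError("blocks must be complete cases")
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        if self.scale_traits:
            sd = Yc.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Yc = Yc / sd
        return Xc, Yc

    @staticmethod
    def _first_corr(Xc, Yc):
        C = Xc.T @ Yc / (len(Xc) - 1)
        u, s, vt = np.linalg.svd(C, full_matrices=False)
        xs = Xc @ u[:, 0]
        ys = Yc @ vt[0]
        if xs.std() == 0 or ys.std() == 0:
            return 0.0, u, s, vt
        return abs(np.corrcoef(xs, ys)[0, 1]), u, s, vt

    def fit(self, X, Y):
        Xc, Yc = self._prepare(X, Y)
        if len(Xc) < 4:
            raise ParameterError("2B-PLS needs n >= 4")
        r1, u, s, vt = self._first_corr(Xc, Yc)
        q = int(min(Xc.shape[1], Yc.shape[1], len(Xc) - 1))
        self.x_weights_ = u[:, :q]
        self.y_weights_ = vt[:q].T
        self.singular_values_ = s[:q]
        self.x_scores_ = Xc @ self.x_weights_
        self.y_scores_ = Yc @ self.y_weights_
        corrs = []
        for k in range(q):
            xs, ys = self.x_scores_[:, k], self.y_scores_[:, k]
            corrs.append(abs(np.corrcoef(xs, ys)[0, 1])
                         if xs.std() > 0 and ys.std() > 0 else 0.0)
        self.correlations_ = np.asarray(corrs)
        rng = np.random.default_rng(self.seed)
        count = 0
        for _ in range(self.n_perm):
            perm = rng.permutation(len(Xc))
            r_star, *_ = self._first_corr(Xc, Yc[perm])
            if r_star >= r1:
                count += 1
        self.p_value_ = (count + 1) / (self.n_perm + 1)
        self.r_pls_ = r1
        return self

    def extreme_maps(self, gridspec, mean_map=None, scale: float = 1.0):
        """Map-block deformation along the first PLS axis (mean +/- scale*w1)."""
        check_is_fitted(self, "x_weights_")
        w = self.x_weights_[:, 0]
        base = np.zeros_like(w) if mean_map is None else np.asarray(mean_map).ravel()
        return ((base - scale * w).reshape(gridspec.K, gridspec.M),
                (base + scale * w).reshape(gridspec.K, gridspec.M))


def pls2b(maps, traits, n_perm: int = 1000, seed: int | None = None,
          scale_traits: bool = True) -> TwoBlockPLS:
    """Fit and return a :class:`TwoBlockPLS` between a map and a trait block."""
    return TwoBlockPLS(n_perm=n_perm, seed=seed,
                       scale_traits=scale_traits).fit(maps, traits)


# ---------------------------------------------------------------------------
# scalar trait models


@dataclass
class TraitModelResults:
    anova: pd.DataFrame | None = None
    pearson: dict = dc_field(default_factory=dict)
    regressions: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None


def _pairwise_bonferroni(data, response, by):
    counts = data.groupby(by)[response].count()
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"groups excluded from pairwise tests (n = 1): "
                      f"{singletons}")
    levels = counts[counts >= 2].index.tolist()
    pairs = list(itertools.combinations(levels, 2))
    k = len(pairs)
    rows = []
    for a, b in pairs:
        xa = data.loc[data[by] == a, response]
        xb = data.loc[data[by] == b, response]
        t, p = scipy.stats.ttest_ind(xa, xb)
        rows.append({"group_a": a, "group_b": b, "t": t, "p_raw": p,
                     "p_bonferroni": min(1.0, p * k)})
    return pd.DataFrame(rows)


def _group_regressions(data, response, covariate, by):
    rows = []
    for name, sub in data.groupby(by):
        if len(sub) < 3:
            warnings.warn(f"group {name!r} too small for regression; skipped")
            continue
        model = smf.ols(f"{response} ~ {covariate}", data=sub).fit()
        lo, hi = model.conf_int().loc[covariate]
        rows.append({by: name, "n": len(sub),
                     "slope": model.params[covariate],
                     "intercept": model.params["Intercept"],
                     "r_squared": model.rsquared,
                     "p": model.pvalues[covariate],
                     "slope_ci_low": lo, "slope_ci_high": hi})
    return pd.DataFrame(rows)


def trait_models(data: pd.DataFrame, response: str, factors=(), covariates=(),
                 pairwise_by: str | None = None,
                 regress_on: str | None = None,
                 regress_by: str | None = None) -> TraitModelResults:
    """Scalar-trait battery: factorial ANOVA, Pearson tests, per-group
    regressions with confidence intervals, Bonferroni pairwise comparisons.

    ``factors`` are crossed (factorial design); ``covariates`` enter
    additively.  ``regress_on``/``regress_by`` fit a per-group simple
    regression of the response on one covariate.
    """
    out = TraitModelResults()
    terms = [f"C({f})" for f in factors]
    if terms:
        rhs_full = "*".join(terms)
        rhs_additive = "+".join(terms)
        for rhs in ([rhs_full, rhs_additive] if rhs_full != rhs_additive
                    else [rhs_full]):
            formula = f"{response} ~ {rhs}"
            if covariates:
                formula += " + " + " + ".join(covariates)
            model = smf.ols(formula, data=data).fit()
            if model.df_resid >= 1:
                break
            warnings.warn(f"model {formula!r} is saturated; simplifying")
        if model.df_resid < 1:
            warnings.warn("too few specimens for any factorial ANOVA; skipped")
        else:
            try:
                out.anova = sm.stats.anova_lm(model, typ=2)
            except ValueError:
                out.anova = sm.stats.anova_lm(model, typ=1)
    for cov in covariates:
        sub = data[[response, cov]].dropna()
        r, p = scipy.stats.pearsonr(sub[response], sub[cov])
        out.pearson[cov] = {"r": float(r), "p": float(p), "n": len(sub)}
    if regress_on is not None:
        if regress_by is not None:
            out.regressions = _group_regressions(data.dropna(
                subset=[response, regress_on]), response, regress_on, regress_by)
        else:
            tmp = data.dropna(subset=[response, regress_on]).copy()
            tmp["_all"] = "all"
            out.regressions = _group_regressions(tmp, response, regress_on,
                                                 "_all")
    if pairwise_by is not None:
        out.pairwise = _pairwise_bonferroni(
            data.dropna(subset=[response]), response, pairwise_by)
    return out
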