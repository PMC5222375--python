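"""Genomic-prediction regressors.

Five whole-genome regression models over a complete {0,1,2} marker
matrix, all exposed as scikit-learn estimators:

* :class:`RidgeBLUP` — ridge-regression BLUP.  Every marker receives an
  effect shrunken by the ridge parameter lambda = s2e/s2u, estimated by
  REML through a spectral decomposition of the marker kernel GG' so each
  candidate lambda costs O(n).  Effects solve
  u = G'(GG' + lambda I)^-1 (y - mu).
* :class:`BayesA` — marker-specific effect variances, scaled
  inverse-chi-square prior, Gibbs sampling.
* :class:`BayesB` — Bayes A plus a point mass at zero with prior
  inclusion probability 1 - pi_zero.
* :class:`BayesianLasso` — double-exponential effect prior via the
  exponential scale mixture, gamma hyperprior on lambda^2.
* :class:`LinearSVRGS` — linear epsilon-insensitive support vector
  regression with (C, epsilon) chosen by grid search on a 10% tuning
  subset.

Marker columns are centered (no variance standardisation).  Default
sampler settings: 3,000 iterations, burn-in 500, thinning 5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from ._samplers import bayes_ab_kernel, bayesian_lasso_kernel


@dataclass
class SamplerConfig:
    """Gibbs chain settings."""

    n_iter: int = 3000
    burn_in: int = 500
    thinning: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class SvrGrid:
    """Grid-search space for the linear SVR."""

    cost_values: tuple[float, ...] = (2.0, 4.0, 8.0, 16.0, 32.0, 64.0)
    epsilon_values: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))
    tuning_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not self.cost_values or not self.epsilon_values:
            raise ValueError("grid must be non-empty")
        if not 0.0 < self.tuning_fraction < 1.0:
            raise ValueError("tuning_fraction must be in (0, 1)")

    @property
    def n_candidates(self) -> int:
        return len(self.cost_values) * len(self.epsilon_values)


@dataclass
class GsFit:
    """Serialisable snapshot of a fitted genomic-prediction model."""

    model_tag: str
    intercept: float
    marker_effects: np.ndarray
    col_means: np.ndarray
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + (X - self.col_means) @ self.marker_effects

    def to_json(self, path) -> None:
        payload = {
            "model_tag": self.model_tag,
            "intercept": self.intercept,
            "marker_effects": np.asarray(self.marker_effects).tolist(),
            "col_means": np.asarray(self.col_means).tolist(),
            "hyperparameters": self.hyperparameters,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GsFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["model_tag"],
            d["intercept"],
            np.asarray(d["marker_effects"]),
            np.asarray(d["col_means"]),
            d.get("hyperparameters", {}),
            d.get("seed"),
        )


def _validate_xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y have mismatched sample counts")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values; impute first")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    return X, y


class RidgeBLUP(RegressorMixin, BaseEstimator):
    """Ridge-regression BLUP with REML lambda via spectral decomposition.

    Parameters
    ----------
    ridge_lambda : float or None, default=None
        Fixed ridge parameter lambda = s2e/s2u.  ``None`` estimates it
        by maximising the REML likelihood of the single-kernel model
        (kernel GG'), profiled over the genetic variance so that each
        lambda evaluation after the eigendecomposition costs O(n).
    lambda_bounds : pair of floats
        Search interval for lambda (default 1e-6 .. 1e6, searched in
        log space with bracketed bounded minimisation, xatol 1e-8).
    """

    def __init__(self, ridge_lambda=None, lambda_bounds=(1e-6, 1e6)):
        self.ridge_lambda = ridge_lambda
        self.lambda_bounds = lambda_bounds

    def fit(self, X, y):
        X, y = _validate_xy(X, y)
        n = X.shape[0]
        if n < 3:
            raise ValueError("need >= 3 samples")
        self.n_features_in_ = X.shape[1]
        self.col_means_ = X.mean(axis=0)
        Xc = X - self.col_means_
        self.degenerate_ = bool(np.ptp(y) == 0.0)
        if self.degenerate_:
            # constant response: REML lambda is unbounded; full shrinkage
            self.lambda_ = np.inf
            self.intercept_ = float(y[0])
            self.marker_effects_ = np.zeros(X.shape[1])
            self.sigma2_u_, self.sigma2_e_ = 0.0, 0.0
            self._alpha = np.zeros(n)
            self._Xc_train = Xc
            return self

        K = Xc @ Xc.T
        if self.ridge_lambda is None:
            ones = np.ones((n, 1))
            qfull, _ = np.linalg.qr(ones, mode="complete")
            Q = qfull[:, 1:]  # orthonormal basis of the intercept complement
            A = Q.T @ K @ Q
            theta, W = np.linalg.eigh((A + A.T) / 2.0)
            theta = np.clip(theta, 0.0, None)
            eta = W.T @ (Q.T @ y)
            m = n - 1

            def neg_restricted_ll(log_lam: float) -> float:
                d = theta + np.exp(log_lam)
                return m * np.log((eta**2 / d).sum()) + np.log(d).sum()

            lo, hi = np.log(self.lambda_bounds[0]), np.log(self.lambda_bounds[1])
            res = minimize_scalar(
                neg_restricted_ll, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-8},
            )
            lam = float(np.exp(res.x))
            self.sigma2_u_ = float((eta**2 / (theta + lam)).sum() / m)
            self.sigma2_e_ = lam * self.sigma2_u_
        else:
            lam = float(self.ridge_lambda)
            if lam <= 0:
                raise ValueError("ridge_lambda must be > 0")
            self.sigma2_u_ = None
            self.sigma2_e_ = None
        self.lambda_ = lam

        V = K + lam * np.eye(n)
        a = np.linalg.solve(V, np.ones(n))
        b = np.linalg.solve(V, y)
        self.intercept_ = float(b.sum() / a.sum())  # GLS mean
        self._alpha = np.linalg.solve(V, y - self.intercept_)
        self._Xc_train = Xc
        self.marker_effects_ = Xc.T @ self._alpha
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "marker_effects_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker count mismatch with the fitted model")
        return self.intercept_ + (X - self.col_means_) @ self.marker_effects_

    def predict_kernel(self, X) -> np.ndarray:
        """GBLUP (kernel-form) predictions; algebraically identical to
        :meth:`predict` and exposed for cross-checking."""
        check_is_fitted(self, "_alpha")
        Xc = np.asarray(X, dtype=float) - self.col_means_
        return self.intercept_ + (Xc @ self._Xc_train.T) @ self._alpha


class _GibbsRegressor(RegressorMixin, BaseEstimator):
    """Shared plumbing for the Gibbs-sampled whole-genome regressions."""

    _tag = "gibbs"

    def __init__(self, n_iter=3000, burn_in=500, thinning=5, seed=None,
                 df_prior=5.0, r2_prior=0.5):
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.thinning = thinning
        self.seed = seed
        self.df_prior = df_prior
        self.r2_prior = r2_prior

    def _kernel_seed(self) -> int:
        ss = np.random.SeedSequence(self.seed)
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))

    def _prepare(self, X, y):
        SamplerConfig(self.n_iter, self.burn_in, self.thinning, self.seed)
        X, y = _validate_xy(X, y)
        self.n_features_in_ = X.shape[1]
        self.col_means_ = X.mean(axis=0)
        Xc = X - self.col_means_
        Xt = np.ascontiguousarray(Xc.T)
        vy = float(np.var(y))
        msx = float((Xc**2).mean(axis=0).sum())  # sum of marker variances
        return Xt, y, vy, max(msx, 1e-12)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "marker_effects_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker count mismatch with the fitted model")
        return self.intercept_ + (X - self.col_means_) @ self.marker_effects_


class BayesA(_GibbsRegressor):
    """Bayes A: marker-specific effect variances, no point mass at zero.

    Priors: effect variances ~ scaled-inv-chi-square(df_prior, S0) with
    S0 chosen so the prior explains ``r2_prior`` of the phenotypic
    variance; residual variance likewise anchored at 1 - r2_prior.
    """

    _tag = "bayesA"

    def fit(self, X, y):
        Xt, y, vy, msx = self._prepare(X, y)
        nu0, nue = self.df_prior, self.df_prior
        S0 = self.r2_prior * vy * (nu0 + 2.0) / msx
        Se = (1.0 - self.r2_prior) * vy * (nue + 2.0)
        beta_s, mu_s, s2e_s, _, kept, fail = bayes_ab_kernel(
            Xt, y.astype(float), self.n_iter, self.burn_in, self.thinning,
            nu0, S0, nue, Se, 1.0, self._kernel_seed(),
        )
        if fail:
            raise RuntimeError(f"Gibbs chain diverged at iteration {fail}")
        self.marker_effects_ = beta_s / kept
        self.intercept_ = float(mu_s / kept)
        self.sigma2_e_ = float(s2e_s / kept)
        return self


class BayesB(_GibbsRegressor):
    """Bayes B: Bayes A with a point mass at zero (pi_zero prior mass)."""

    _tag = "bayesB"

    def __init__(self, n_iter=3000, burn_in=500, thinning=5, seed=None,
                 df_prior=5.0, r2_prior=0.5, pi_zero=0.5):
        super().__init__(n_iter, burn_in, thinning, seed, df_prior, r2_prior)
        self.pi_zero = pi_zero

    def fit(self, X, y):
        if not 0.0 <= self.pi_zero < 1.0:
            raise ValueError("pi_zero must be in [0, 1)")
        Xt, y, vy, msx = self._prepare(X, y)
        pi_incl = 1.0 - self.pi_zero
        nu0, nue = self.df_prior, self.df_prior
        S0 = self.r2_prior * vy * (nu0 + 2.0) / (msx * pi_incl)
        Se = (1.0 - self.r2_prior) * vy * (nue + 2.0)
        beta_s, mu_s, s2e_s, incl_s, kept, fail = bayes_ab_kernel(
            Xt, y.astype(float), self.n_iter, self.burn_in, self.thinning,
            nu0, S0, nue, Se, pi_incl, self._kernel_seed(),
        )
        if fail:
            raise RuntimeError(f"Gibbs chain diverged at iteration {fail}")
        self.marker_effects_ = beta_s / kept
        self.intercept_ = float(mu_s / kept)
        self.sigma2_e_ = float(s2e_s / kept)
        self.inclusion_prob_ = incl_s / kept
        return self


class BayesianLasso(_GibbsRegressor):
    """Bayesian Lasso: double-exponential prior via its normal scale
    mixture, with a gamma hyperprior on the regularisation lambda^2."""

    _tag = "blasso"

    def __init__(self, n_iter=3000, burn_in=500, thinning=5, seed=None,
                 df_prior=5.0, r2_prior=0.5, lambda2_shape=1.1):
        super().__init__(n_iter, burn_in, thinning, seed, df_prior, r2_prior)
        self.lambda2_shape = lambda2_shape

    def fit(self, X, y):
        Xt, y, vy, msx = self._prepare(X, y)
        nue = self.df_prior
        Se = (1.0 - self.r2_prior) * vy * (nue + 2.0)
        lambda2_init = 2.0 * (1.0 - self.r2_prior) / self.r2_prior * msx
        gamma_rate = max((self.lambda2_shape - 1.0), 1e-4) / lambda2_init
        beta_s, mu_s, s2e_s, lam2_s, kept, fail = bayesian_lasso_kernel(
            Xt, y.astype(float), self.n_iter, self.burn_in, self.thinning,
            lambda2_init, self.lambda2_shape, gamma_rate, nue, Se,
            self._kernel_seed(),
        )
        if fail:
            raise RuntimeError(f"Gibbs chain diverged at iteration {fail}")
        self.marker_effects_ = beta_s / kept
        self.intercept_ = float(mu_s / kept)
        self.sigma2_e_ = float(s2e_s / kept)
        self.lambda2_ = float(lam2_s / kept)
        return self


class LinearSVRGS(RegressorMixin, BaseEstimator):
    """Linear epsilon-insensitive SVR with grid-tuned (C, epsilon).

    The 6 x 10 grid (C in 2^1..2^6, epsilon in 0, 0.1, ..., 0.9) is
    scored by 5-fold mean-squared-error cross-validation on a seeded
    random subset of ``tuning_fraction`` (10%) of the training data; the
    winning pair is refit on the full training data.  The response is
    standardised internally (the epsilon grid is on the standardised
    scale); marker effects are reported in original trait units.
    """

    def __init__(self, grid: SvrGrid | None = None, inner_folds: int = 5,
                 seed: int | None = None):
        self.grid = grid
        self.inner_folds = inner_folds
        self.seed = seed

    def fit(self, X, y):
        grid = self.grid or SvrGrid()
        X, y = _validate_xy(X, y)
        n = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self.col_means_ = X.mean(axis=0)
        Xc = X - self.col_means_
        self.y_mean_ = float(y.mean())
        y_sd = float(y.std())
        if y_sd == 0.0:
            self.y_scale_ = 1.0
            self.marker_effects_ = np.zeros(X.shape[1])
            self.intercept_ = self.y_mean_
            self.best_params_ = {"C": None, "epsilon": None}
            return self
        self.y_scale_ = y_sd
        ys = (y - self.y_mean_) / self.y_scale_

        rng = np.random.default_rng(self.seed)
        n_sub = max(int(round(grid.tuning_fraction * n)), 1)
        if n_sub < 2 * self.inner_folds:
            warnings.warn(
                "tuning subset too small for internal CV; tuning on the full "
                "training data",
                stacklevel=2,
            )
            sub = np.arange(n)
        else:
            sub = rng.choice(n, size=n_sub, replace=False)
        Xs, yss = Xc[sub], ys[sub]
        folds = min(self.inner_folds, len(sub))
        kf = KFold(
            n_splits=folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        best, best_mse = None, np.inf
        for c in grid.cost_values:
            for eps in grid.epsilon_values:
                mse = 0.0
                for tr, te in kf.split(Xs):
                    model = SVR(kernel="linear", C=c, epsilon=eps)
                    model.fit(Xs[tr], yss[tr])
                    resid = yss[te] - model.predict(Xs[te])
                    mse += float(resid @ resid)
                if mse < best_mse - 1e-12:
                    best, best_mse = (c, eps), mse
        self.best_params_ = {"C": best[0], "epsilon": best[1]}
        svr = SVR(kernel="linear", C=best[0], epsilon=best[1])
        svr.fit(Xc, ys)
        w = np.asarray(svr.coef_).ravel()
        self.marker_effects_ = w * self.y_scale_
        self.intercept_ = float(svr.intercept_[0]) * self.y_scale_ + self.y_mean_
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "marker_effects_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("marker count mismatch with the fitted model")
        return self.intercept_ + (X - self.col_means_) @ self.marker_effects_


MODEL_REGISTRY = {
    "rrblup": RidgeBLUP,
    "bayesA": BayesA,
    "bayesB": BayesB,
    "blasso": BayesianLasso,
    "svrlin": LinearSVRGS,
}


def _as_gsfit(est, tag: str, hyper: dict, seed=None) -> GsFit:
    return GsFit(
        model_tag=tag,
        intercept=float(est.intercept_),
        marker_effects=np.asarray(est.marker_effects_),
        col_means=np.asarray(est.col_means_),
        hyperparameters=hyper,
        seed=seed,
    )


def fit_rrblup(G, y, ridge_lambda=None) -> GsFit:
    est = RidgeBLUP(ridge_lambda=ridge_lambda).fit(G, y)
    return _as_gsfit(est, "rrblup", {
        "lambda": est.lambda_, "sigma2_u": est.sigma2_u_, "sigma2_e": est.sigma2_e_,
    })


def fit_bayes_a(G, y, cfg: SamplerConfig | None = None) -> GsFit:
    cfg = cfg or SamplerConfig()
    est = BayesA(cfg.n_iter, cfg.burn_in, cfg.thinning, cfg.seed).fit(G, y)
    return _as_gsfit(est, "bayesA", {"sigma2_e": est.sigma2_e_,
                                     "sampler": cfg.__dict__}, seed=cfg.seed)


def fit_bayes_b(G, y, cfg: SamplerConfig | None = None, pi_zero: float = 0.5) -> GsFit:
    cfg = cfg or SamplerConfig()
    est = BayesB(cfg.n_iter, cfg.burn_in, cfg.thinning, cfg.seed, pi_zero=pi_zero).fit(G, y)
    return _as_gsfit(est, "bayesB", {"sigma2_e": est.sigma2_e_, "pi_zero": pi_zero,
                                     "sampler": cfg.__dict__}, seed=cfg.seed)


def fit_bayesian_lasso(G, y, cfg: SamplerConfig | None = None) -> GsFit:
    cfg = cfg or SamplerConfig()
    est = BayesianLasso(cfg.n_iter, cfg.burn_in, cfg.thinning, cfg.seed).fit(G, y)
    return _as_gsfit(est, "blasso", {"sigma2_e": est.sigma2_e_, "lambda2": est.lambda2_,
                                     "sampler": cfg.__dict__}, seed=cfg.seed)


def fit_svr_linear(G, y, grid: SvrGrid | None = None, seed: int | None = None) -> GsFit:
    est = LinearSVRGS(grid=grid, seed=seed).fit(G, y)
    return _as_gsfit(est, "svrlin", dict(est.best_params_), seed=seed)


def predict(fit: GsFit, G_new) -> np.ndarray:
    """Predict phenotypes from a serialised fit: mu + (G - centering) u."""
    G_new = np.asarray(G_new, dtype=float)
    if G_new.shape[1] != fit.marker_effects.shape[0]:
        raise ValueError("marker count mismatch with the fitted model")
    return fit.predict(G_new)
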