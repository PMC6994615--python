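"""Sparse Bayesian linear regression (relevance-vector style) with
automatic feature selection.

The model is linear in the (internally standardized) features with an
intercept: y = w0 + sum_i w_i x_i + eps, eps ~ N(0, sigma^2), with an
independent zero-mean Gaussian prior of precision alpha_i on each
weight.  Hyperparameters are estimated by type-II maximum likelihood
(evidence maximization):

    Sigma = (sigma^-2 Phi' Phi + A)^-1,   mu = sigma^-2 Sigma Phi' y
    gamma_i = 1 - alpha_i Sigma_ii
    alpha_i <- gamma_i / mu_i^2
    sigma^2 <- ||y - Phi mu||^2 / (n - sum_i gamma_i)

Features whose precision exceeds the pruning ceiling are removed (their
posterior collapses onto zero); the intercept is never pruned.  The
iteration is deterministic, and pruned features never re-enter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lidarstands import fieldparams
from lidarstands.fieldparams import ErrorStats, RSquared


@dataclass(frozen=True)
class RVMConfig:
    max_iter: int = 500
    tol: float = 1e-6  # convergence on max |delta log alpha|
    #: weights whose prior precision exceeds this are pruned; 1e4 is the
    #: customary ARD threshold (irrelevant features settle at large but
    #: finite precisions, so a looser ceiling under-prunes)
    alpha_ceiling: float = 1e4
    alpha_init: float = 1e-6
    sigma2_init: float | None = None  # default: 0.1 * var(y)
    prune: bool = True
    fixed_alpha: bool = False  # keep alpha at alpha_init (ridge/OLS limit)
    seed: int = 0  # reserved for degenerate tie-breaking only

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if self.alpha_ceiling <= self.alpha_init:
            raise ValueError("pruning ceiling must exceed the initial alpha")


@dataclass
class RVMModel:
    """A fitted sparse Bayesian linear model.

    ``weights``/``alpha``/``sigma_diag`` are indexed like
    ``["intercept"] + retained_features`` and live on the standardized
    feature scale; predictions are returned in response units.
    """

    feature_names: list[str]  # all input features, fit order
    retained: list[str]  # retained features (subset, order preserved)
    weights: np.ndarray
    alpha: np.ndarray
    sigma_diag: np.ndarray
    sigma2: float
    x_mean: np.ndarray  # standardization over all input features
    x_sd: np.ndarray
    covariance: np.ndarray = field(repr=False, default=None)  # posterior cov, retained basis
    fit_log: list[dict] = field(default_factory=list)
    marginal_log_likelihood: float = float("nan")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "feature_names": self.feature_names,
            "retained": self.retained,
            "weights": self.weights.tolist(),
            "alpha": self.alpha.tolist(),
            "sigma_diag": self.sigma_diag.tolist(),
            "sigma2": self.sigma2,
            "x_mean": self.x_mean.tolist(),
            "x_sd": self.x_sd.tolist(),
            "covariance": np.asarray(self.covariance).tolist(),
            "fit_log": self.fit_log,
            "marginal_log_likelihood": self.marginal_log_likelihood,
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str | None = None, path: str | Path | None = None) -> "RVMModel":
        if text is None:
            text = Path(path).read_text()  # type: ignore[arg-type]
        doc = json.loads(text)
        return cls(
            feature_names=doc["feature_names"],
            retained=doc["retained"],
            weights=np.asarray(doc["weights"]),
            alpha=np.asarray(doc["alpha"]),
            sigma_diag=np.asarray(doc["sigma_diag"]),
            sigma2=doc["sigma2"],
            x_mean=np.asarray(doc["x_mean"]),
            x_sd=np.asarray(doc["x_sd"]),
            covariance=np.asarray(doc["covariance"]),
            fit_log=doc["fit_log"],
            marginal_log_likelihood=doc["marginal_log_likelihood"],
        )


def _as_matrix(X: pd.DataFrame | np.ndarray, feature_names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            missing = set(feature_names) - set(X.columns)
            if missing:
                raise ValueError(f"missing feature columns: {sorted(missing)}")
            X = X[feature_names]
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-D")
    names = feature_names or [f"x{i}" for i in range(arr.shape[1])]
    if len(names) != arr.shape[1]:
        raise ValueError("feature name count does not match X width")
    return arr, list(names)


def rvm_fit(X: pd.DataFrame | np.ndarray, y: np.ndarray, config: RVMConfig = RVMConfig()) -> RVMModel:
    """Fit the sparse Bayesian linear model by evidence maximization."""
    arr, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n, p = arr.shape
    if n != y.size:
        raise ValueError("X and y disagree on the sample count")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(arr)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in the inputs")

    x_mean = arr.mean(axis=0)
    x_sd = arr.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Z = (arr - x_mean) / x_sd

    var_y = float(np.var(y))
    sigma2 = config.sigma2_init if config.sigma2_init is not None else max(0.1 * var_y, 1e-8)
    active = np.arange(p + 1)  # 0 = intercept, i+1 = feature i
    alpha = np.full(p + 1, config.alpha_init, dtype=float)
    Phi_full = np.column_stack([np.ones(n), Z])
    fit_log: list[dict] = []
    log_alpha_old = np.log(alpha)
    mu = np.zeros(active.size)
    Sigma = np.eye(active.size)

    for iteration in range(config.max_iter):
        Phi = Phi_full[:, active]
        A = np.diag(alpha[active])
        H = Phi.T @ Phi / sigma2 + A
        H.flat[:: H.shape[0] + 1] += 1e-10  # jitter
        Sigma = np.linalg.inv(H)
        mu = Sigma @ Phi.T @ y / sigma2
        gamma = 1.0 - alpha[active] * np.diag(Sigma)
        gamma = np.clip(gamma, 1e-12, None)
        new_alpha = gamma / np.maximum(mu**2, 1e-300)
        resid = y - Phi @ mu
        denom = max(n - float(gamma.sum()), 1e-9)
        sigma2 = max(float(resid @ resid) / denom, 1e-12)

        if not config.fixed_alpha:
            alpha[active] = new_alpha
        pruned: list[str] = []
        if config.prune:
            # relevance test (quality^2 <= sparsity): the evidence would
            # not decrease by deleting the basis function.  With the
            # in-model identities S = alpha*gamma, Q = alpha*mu the test
            # q^2 <= s collapses to mu^2 <= gamma * Sigma_ii, which is
            # numerically stable.  Only the single least relevant
            # function is deleted per iteration: with correlated
            # features the statistics are only valid one removal at a
            # time (the posterior is refit before the next deletion).
            margin = gamma * np.diag(Sigma) - mu**2
            margin[active == 0] = -np.inf  # intercept never deleted
            worst = int(np.argmax(margin))
            irrelevant = np.zeros(active.size, dtype=bool)
            if margin[worst] >= 0:
                irrelevant[worst] = True
            keep = ((alpha[active] < config.alpha_ceiling) & ~irrelevant) | (active == 0)
            if not np.all(keep):
                pruned = [
                    ("intercept" if a == 0 else names[a - 1])
                    for a in active[~keep]
                ]
                active = active[keep]
        delta = float(np.max(np.abs(np.log(alpha[active]) - log_alpha_old[active])))
        log_alpha_old = np.log(np.clip(alpha, 1e-300, None))
        fit_log.append(
            {"iteration": iteration, "active": int(active.size), "pruned": pruned, "sigma2": sigma2}
        )
        if delta < config.tol and not pruned:
            break

    # final posterior on the surviving basis
    Phi = Phi_full[:, active]
    A = np.diag(alpha[active])
    H = Phi.T @ Phi / sigma2 + A
    H.flat[:: H.shape[0] + 1] += 1e-10
    Sigma = np.linalg.inv(H)
    mu = Sigma @ Phi.T @ y / sigma2

    sign, logdet_Sinv = np.linalg.slogdet(H)
    log_c = float(logdet_Sinv - np.sum(np.log(alpha[active])) + n * np.log(sigma2))
    quad = float((y @ y - y @ (Phi @ mu)) / sigma2)
    mll = -0.5 * (n * np.log(2 * np.pi) + log_c + quad)

    retained = [names[a - 1] for a in active if a != 0]
    return RVMModel(
        feature_names=names,
        retained=retained,
        weights=mu,
        alpha=alpha[active],
        sigma_diag=np.diag(Sigma).copy(),
        sigma2=sigma2,
        x_mean=x_mean,
        x_sd=x_sd,
        covariance=Sigma,
        fit_log=fit_log,
        marginal_log_likelihood=mll,
    )


def rvm_predict(
    model: RVMModel, X: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior predictive mean and variance per row (response units)."""
    arr, _ = _as_matrix(X, model.feature_names)
    Z = (arr - model.x_mean) / model.x_sd
    idx = [model.feature_names.index(f) for f in model.retained]
    Phi = np.column_stack([np.ones(arr.shape[0]), Z[:, idx]])
    mean = Phi @ model.weights
    cov = np.asarray(model.covariance)
    var = model.sigma2 + np.einsum("ij,jk,ik->i", Phi, cov, Phi)
    return mean, var


@dataclass
class LOOResult:
    predictions: np.ndarray
    rmse: ErrorStats
    bias: ErrorStats
    r2: RSquared
    n_fits: int


def loo_validate(
    X: pd.DataFrame | np.ndarray, y: np.ndarray, config: RVMConfig = RVMConfig()
) -> LOOResult:
    """Leave-one-out validation: n refits, each predicting its held-out
    row; accuracy summarized as RMSE%, Bias% and squared Pearson r."""
    arr, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("LOO needs at least 4 observations")
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        model = rvm_fit(pd.DataFrame(arr[mask], columns=names), y[mask], config)
        preds[i] = rvm_predict(model, pd.DataFrame(arr[[i]], columns=names))[0][0]
    return LOOResult(
        predictions=preds,
        rmse=fieldparams.rmse(y, preds),
        bias=fieldparams.bias(y, preds),
        r2=fieldparams.r_squared(y, preds),
        n_fits=n,
    )
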