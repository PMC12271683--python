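"""Transfer-learning ridge estimator across environments.

The estimator borrows strength from a fully phenotyped *proxy* environment to
improve prediction in a sparsely phenotyped *goal* environment:

1. fit ridge coefficients β̂_p on the complete proxy data (λ_p tuned by
   inner CV on the proxy);
2. adjust the goal-training response: y* = y_g − (β₀_p + X_g β̂_p);
3. fit a ridge correction γ̂ of y* on X_g (λ_g tuned by inner CV on the
   goal training subset with the adjusted response);
4. combine: β̂_g = β̂_p + γ̂ (and intercepts likewise);
5. predict goal-test phenotypes with the combined coefficients.

When γ̂'s penalty is driven to infinity the estimator falls back to the
proxy model; when β̂_p = 0 it reduces exactly to plain ridge on the goal
training data. Between those poles, the correction learns only the
environment-specific deviation, which is the transfer-learning gain — and,
for an unrelated proxy, the potential source of negative transfer.

λ_p and λ_g are tuned independently, each by the same inner-CV procedure.
The proxy intercept is carried into the adjusted response; after centering
this is algebraically equivalent to subtracting X_g β̂_p alone and keeps the
proxy-mean shift out of the γ stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import AlignedDesign
from .ridge import (
    InnerCVResult,
    LambdaGrid,
    RidgeFit,
    fit_ridge_analytic,
    fit_ridge_iterative,
    make_lambda_grid,
    predict,
    tune_lambda,
)

__all__ = [
    "TransferFit",
    "fit_proxy",
    "adjust_response",
    "fit_transfer",
    "predict_transfer",
    "TransferRidgeModel",
    "TransferResults",
]


@dataclass(frozen=True)
class TransferFit:
    """Proxy coefficients, ridge correction, and their combination."""

    proxy_fit: RidgeFit
    gamma_fit: RidgeFit
    combined_coefficients: np.ndarray
    combined_intercept: float

    def __post_init__(self):
        object.__setattr__(
            self, "combined_coefficients",
            np.asarray(self.combined_coefficients, dtype=float),
        )


def _check_columns(goal: AlignedDesign, proxy_fit: RidgeFit,
                   proxy_markers: tuple[str, ...] = ()) -> None:
    if goal.p != proxy_fit.p:
        raise ValueError(
            f"goal design has {goal.p} markers; proxy fit expects {proxy_fit.p}"
        )
    if goal.marker_ids and proxy_markers and goal.marker_ids != proxy_markers:
        for a, b in zip(goal.marker_ids, proxy_markers):
            if a != b:
                raise ValueError(f"marker mismatch between environments: {a!r} vs {b!r}")


def _solve(d: AlignedDesign, lam: float, solver: str) -> RidgeFit:
    if solver == "analytic":
        return fit_ridge_analytic(d, lam)
    if solver == "iterative":
        return fit_ridge_iterative(d, lam)
    raise ValueError(f"unknown solver {solver!r}")


def fit_proxy(proxy: AlignedDesign, grid: LambdaGrid | None = None,
              lam: float | None = None, n_splits: int = 10,
              val_fraction: float = 0.2, seed: int = 0,
              solver: str = "analytic", grid_n_values: int = 100,
              grid_min_ratio: float = 1e-6) -> RidgeFit:
    """Fit β̂_p on the complete proxy-environment data, tuning λ_p by inner CV."""
    if lam is None:
        if grid is None:
            grid = make_lambda_grid(proxy, grid_n_values, grid_min_ratio)
        lam = tune_lambda(proxy, grid, n_splits=n_splits, val_fraction=val_fraction,
                          seed=seed, solver=solver).lambda_star
    return _solve(proxy, lam, solver)


def adjust_response(goal: AlignedDesign, proxy_fit: RidgeFit) -> np.ndarray:
    """Proxy-adjusted goal response y* = y_g − (β₀_p + X_g β̂_p)."""
    _check_columns(goal, proxy_fit)
    return goal.y - predict(proxy_fit, goal.X)


def fit_transfer(proxy: AlignedDesign | None, goal_train: AlignedDesign,
                 proxy_fit: RidgeFit | None = None,
                 grid: LambdaGrid | None = None,
                 lam_proxy: float | None = None, lam_gamma: float | None = None,
                 n_splits: int = 10, val_fraction: float = 0.2,
                 seed: int = 0, solver: str = "analytic",
                 grid_n_values: int = 100, grid_min_ratio: float = 1e-6) -> TransferFit:
    """Full transfer estimator: proxy fit, adjusted-response correction, combination.

    ``goal_train`` must be only the goal environment's training subset; the
    goal test rows never enter either stage. A precomputed ``proxy_fit`` may
    be supplied (the proxy stage does not depend on the goal partition, so
    evaluation protocols fit it once and reuse it).
    """
    if proxy_fit is None:
        if proxy is None:
            raise ValueError("either proxy design or a precomputed proxy_fit is required")
        proxy_fit = fit_proxy(proxy, lam=lam_proxy, n_splits=n_splits,
                              val_fraction=val_fraction, seed=seed, solver=solver,
                              grid_n_values=grid_n_values,
                              grid_min_ratio=grid_min_ratio)
        _check_columns(goal_train, proxy_fit, proxy.marker_ids)
    else:
        _check_columns(goal_train, proxy_fit)
    y_star = adjust_response(goal_train, proxy_fit)
    adjusted = AlignedDesign(goal_train.X, y_star, goal_train.line_ids,
                             goal_train.marker_ids)
    if lam_gamma is None:
        gamma_grid = grid if grid is not None else make_lambda_grid(
            adjusted, grid_n_values, grid_min_ratio)
        lam_gamma = tune_lambda(adjusted, gamma_grid, n_splits=n_splits,
                                val_fraction=val_fraction, seed=seed,
                                solver=solver).lambda_star
    gamma_fit = _solve(adjusted, lam_gamma, solver)
    combined = proxy_fit.coefficients + gamma_fit.coefficients
    intercept = proxy_fit.intercept + gamma_fit.intercept
    return TransferFit(proxy_fit, gamma_fit, combined, intercept)


def predict_transfer(tf: TransferFit, X_tst: np.ndarray) -> np.ndarray:
    """Goal-environment prediction with the combined coefficients β̂_g."""
    X_tst = np.atleast_2d(np.asarray(X_tst, dtype=float))
    if X_tst.shape[1] != len(tf.combined_coefficients):
        raise ValueError(
            f"X_tst has {X_tst.shape[1]} columns; fit expects {len(tf.combined_coefficients)}"
        )
    return tf.combined_intercept + X_tst @ tf.combined_coefficients


class TransferRidgeModel:
    """Transfer ridge regression from a proxy to a goal environment.

    Parameters
    ----------
    proxy : AlignedDesign
        Complete (X, y) of the proxy environment.
    goal_train : AlignedDesign
        Training subset of the goal environment (same markers, same order).
    """

    def __init__(self, proxy: AlignedDesign, goal_train: AlignedDesign):
        self.proxy = proxy
        self.goal_train = goal_train

    def fit(self, solver: str = "analytic", lam_proxy: float | None = None,
            lam_gamma: float | None = None, n_splits: int = 10,
            val_fraction: float = 0.2, seed: int = 0) -> "TransferResults":
        tf = fit_transfer(self.proxy, self.goal_train, lam_proxy=lam_proxy,
                          lam_gamma=lam_gamma, n_splits=n_splits,
                          val_fraction=val_fraction, seed=seed, solver=solver)
        return TransferResults(self, tf)


class TransferResults:
    """Fitted transfer estimator: β̂_p, γ̂ and β̂_g = β̂_p + γ̂."""

    def __init__(self, model: TransferRidgeModel, fit: TransferFit):
        self.model = model
        self._fit = fit

    @property
    def transfer_fit(self) -> TransferFit:
        return self._fit

    @property
    def proxy_params(self) -> np.ndarray:
        return self._fit.proxy_fit.coefficients

    @property
    def gamma_params(self) -> np.ndarray:
        return self._fit.gamma_fit.coefficients

    @property
    def params(self) -> np.ndarray:
        return self._fit.combined_coefficients

    @property
    def intercept(self) -> float:
        return self._fit.combined_intercept

    def predict(self, X_new=None) -> np.ndarray:
        if X_new is None:
            X_new = self.model.goal_train.X
        return predict_transfer(self._fit, X_new)

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Transfer Ridge Regression Results",
            "=" * 44,
            f"{'Proxy observations:':<28}{f.proxy_fit.training_n}",
            f"{'Goal training observations:':<28}{f.gamma_fit.training_n}",
            f"{'No. markers (p):':<28}{f.proxy_fit.p}",
            f"{'Solver:':<28}{f.gamma_fit.solver}",
            f"{'Lambda (proxy):':<28}{f.proxy_fit.lam:.6g}",
            f"{'Lambda (correction):':<28}{f.gamma_fit.lam:.6g}",
            f"{'||beta_p||_2:':<28}{np.linalg.norm(f.proxy_fit.coefficients):.6g}",
            f"{'||gamma||_2:':<28}{np.linalg.norm(f.gamma_fit.coefficients):.6g}",
            f"{'||beta_g||_2:':<28}{np.linalg.norm(f.combined_coefficients):.6g}",
            f"{'Combined intercept:':<28}{f.combined_intercept:.6g}",
            "=" * 44,
        ]
        return "\n".join(lines)
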