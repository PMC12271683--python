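"""Outer cross-validation, prediction metrics, and model comparisons.

Prediction accuracy is assessed the way the genomic-selection literature
reports it: repeated random 80/20 partitions of the goal environment's
lines, Pearson correlation (Cor) and normalized RMSE (NRMSE) on each test
split, then means and standard deviations across partitions. Conventional
ridge models see only the goal training split; transfer models additionally
receive proxy coefficients fitted on the complete proxy environment. The
regularization parameter is re-tuned by inner CV on every partition's
training data, so no test row ever influences a fit.

Transfer-vs-conventional comparisons use relative efficiencies:
``[(AvgCor_transfer / AvgCor_conventional) − 1] × 100`` for Cor and the
inverted ratio for NRMSE (lower NRMSE is better).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import AlignedDesign, EnvironmentPair, MarkerMatrix, PhenotypeTable, align
from .ridge import fit_ridge_analytic, fit_ridge_iterative, make_lambda_grid, predict, tune_lambda
from .transfer import fit_proxy, fit_transfer, predict_transfer

__all__ = [
    "MODELS",
    "pearson_cor",
    "nrmse",
    "PartitionScheme",
    "make_partitions",
    "FoldMetrics",
    "AggregateResult",
    "evaluate_pair",
    "EvaluationResult",
    "aggregate",
    "relative_efficiency_cor",
    "relative_efficiency_nrmse",
    "relative_efficiencies",
]

#: estimator names → (pathway, solver); the iterative pathway emulates the
#: library-optimized route, the analytic pathway the closed-form solution.
MODELS = {
    "RR": ("conventional", "iterative"),
    "ARR": ("conventional", "analytic"),
    "Transfer_RR": ("transfer", "iterative"),
    "Transfer_ARR": ("transfer", "analytic"),
}

# seed offsets decoupling the independent randomness sources within one run
_INNER_SEED_OFFSET = 10_000
_PROXY_SEED_OFFSET = 20_000


def pearson_cor(y, yhat) -> float:
    """Sample Pearson correlation; NaN (undefined) when either side is constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(y) == 0 or np.ptp(yhat) == 0:
        return float("nan")
    return float(stats.pearsonr(y, yhat).statistic)


def nrmse(y, yhat, normalization: str = "mean") -> float:
    """Root mean square error normalized by a statistic of the observed values.

    ``mean`` divides by |mean(y)|, ``range`` by max(y)−min(y), ``sd`` by the
    sample SD of y. A zero (or numerically zero) normalizer is an error.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    rmse = float(np.sqrt(((y - yhat) ** 2).mean()))
    if normalization == "mean":
        denom = abs(float(y.mean()))
        if denom <= 1e-12:
            raise ValueError("mean of observed values is ~0; mean-normalized NRMSE undefined")
    elif normalization == "range":
        denom = float(np.ptp(y))
        if denom <= 0:
            raise ValueError("observed values constant; range-normalized NRMSE undefined")
    elif normalization == "sd":
        denom = float(y.std(ddof=1))
        if denom <= 0:
            raise ValueError("observed values constant; sd-normalized NRMSE undefined")
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    return rmse / denom


@dataclass(frozen=True)
class PartitionScheme:
    """Repeated random train/test partitions over the goal lines.

    These are independent random splits, not a disjoint-fold decomposition;
    partition k is drawn with seed ``seed + k``.
    """

    n: int
    n_partitions: int
    train_fraction: float
    seed: int
    assignments: tuple  # tuple of (train_idx, test_idx) index-array pairs

    def __iter__(self):
        return iter(self.assignments)


def make_partitions(n: int, n_partitions: int = 10, train_fraction: float = 0.8,
                    seed: int = 0) -> PartitionScheme:
    if n < 5:
        raise ValueError("need at least 5 observations to partition")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n_train = int(round(train_fraction * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError(f"train size {n_train} of {n} leaves no usable split")
    assignments = []
    for k in range(n_partitions):
        perm = np.random.default_rng(seed + k).permutation(n)
        assignments.append((np.sort(perm[:n_train]), np.sort(perm[n_train:])))
    return PartitionScheme(n, n_partitions, train_fraction, seed, tuple(assignments))


@dataclass(frozen=True)
class FoldMetrics:
    """Test-split metrics of one model on one outer partition."""

    dataset: str
    pair: EnvironmentPair
    trait: str
    model: str
    partition: int
    cor: float  # NaN when undefined (zero-variance predictions)
    nrmse: float
    n_test: int

    @property
    def cor_defined(self) -> bool:
        return not np.isnan(self.cor)


@dataclass(frozen=True)
class AggregateResult:
    """Mean/SD of Cor and NRMSE over the cells of one group."""

    labels: dict
    cor_mean: float
    cor_sd: float
    nrmse_mean: float
    nrmse_sd: float
    n_cells: int
    n_undefined_dropped: int


class EvaluationResult(list):
    """A list of :class:`FoldMetrics` with aggregation and reporting helpers.

    ``partitions`` retains the outer train/test index sets so that train/test
    hygiene (no goal test line in any fit that predicts it) can be audited.
    """

    def __init__(self, metrics=(), partitions: PartitionScheme | None = None):
        super().__init__(metrics)
        self.partitions = partitions

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": m.dataset,
                "proxy_env": m.pair.proxy_env,
                "goal_env": m.pair.goal_env,
                "trait": m.trait,
                "model": m.model,
                "partition": m.partition,
                "cor": m.cor,
                "nrmse": m.nrmse,
                "n_test": m.n_test,
            }
            for m in self
        )

    def aggregate(self, group_by=("dataset", "model")) -> list[AggregateResult]:
        return aggregate(self, group_by)

    def aggregate_frame(self, group_by=("dataset", "model")) -> pd.DataFrame:
        rows = []
        for a in self.aggregate(group_by):
            row = dict(a.labels)
            row.update(NRMSE=a.nrmse_mean, NRMSE_SD=a.nrmse_sd,
                       Cor=a.cor_mean, Cor_SD=a.cor_sd)
            rows.append(row)
        return pd.DataFrame(rows)

    def relative_efficiencies(self) -> dict:
        return relative_efficiencies(self.aggregate_frame(group_by=("model",)))

    def summary(self) -> str:
        df = self.aggregate_frame()
        cols = [c for c in ("dataset", "model", "NRMSE", "NRMSE_SD", "Cor", "Cor_SD")
                if c in df.columns]
        out = df[cols].to_string(index=False, float_format=lambda v: f"{v:.3f}")
        try:
            re = self.relative_efficiencies()
            out += (f"\n\nRelative efficiency (transfer vs conventional): "
                    f"Cor {re['re_cor']:+.2f}%, NRMSE {re['re_nrmse']:+.2f}%")
        except (KeyError, ValueError):
            pass
        return out


def _conventional_fit(d: AlignedDesign, solver: str, seed: int,
                      grid_n_values: int, grid_min_ratio: float,
                      n_splits: int, val_fraction: float):
    grid = make_lambda_grid(d, grid_n_values, grid_min_ratio)
    lam = tune_lambda(d, grid, n_splits=n_splits, val_fraction=val_fraction,
                      seed=seed, solver=solver).lambda_star
    if solver == "analytic":
        return fit_ridge_analytic(d, lam)
    return fit_ridge_iterative(d, lam)


def evaluate_pair(m: MarkerMatrix, pt: PhenotypeTable, pair: EnvironmentPair,
                  models=("RR", "ARR", "Transfer_RR", "Transfer_ARR"),
                  scheme: PartitionScheme | None = None, n_partitions: int = 10,
                  train_fraction: float = 0.8, seed: int = 0,
                  nrmse_norm: str = "mean", dataset: str = "dataset",
                  inner_n_splits: int = 10, inner_val_fraction: float = 0.2,
                  grid_n_values: int = 100, grid_min_ratio: float = 1e-6,
                  ) -> EvaluationResult:
    """Outer-CV evaluation of the requested estimators on one environment pair.

    Per partition: conventional models are tuned and fitted on the goal
    training split alone; transfer models reuse the same split plus proxy
    coefficients fitted once on the complete proxy environment, with the
    correction's λ re-tuned per partition on the adjusted response.
    """
    unknown = [mo for mo in models if mo not in MODELS]
    if unknown:
        raise ValueError(f"unknown models: {unknown}")
    goal = align(m, pt, pair.goal_env, pair.trait)
    if scheme is None:
        scheme = make_partitions(goal.n, n_partitions, train_fraction, seed)
    elif scheme.n != goal.n:
        raise ValueError(f"partition scheme is over {scheme.n} lines; goal has {goal.n}")

    proxy_fits = {}
    transfer_models = [mo for mo in models if MODELS[mo][0] == "transfer"]
    if transfer_models:
        proxy = align(m, pt, pair.proxy_env, pair.trait)
        for mo in transfer_models:
            solver = MODELS[mo][1]
            proxy_fits[solver] = fit_proxy(
                proxy, n_splits=inner_n_splits, val_fraction=inner_val_fraction,
                seed=seed + _PROXY_SEED_OFFSET, solver=solver,
                grid_n_values=grid_n_values, grid_min_ratio=grid_min_ratio)

    result = EvaluationResult(partitions=scheme)
    for k, (tr_idx, te_idx) in enumerate(scheme):
        goal_tr = goal.subset(tr_idx)
        goal_te = goal.subset(te_idx)
        inner_seed = seed + _INNER_SEED_OFFSET + k
        for mo in models:
            pathway, solver = MODELS[mo]
            if pathway == "conventional":
                fit = _conventional_fit(goal_tr, solver, inner_seed,
                                        grid_n_values, grid_min_ratio,
                                        inner_n_splits, inner_val_fraction)
                pred = predict(fit, goal_te.X)
            else:
                tf = fit_transfer(None, goal_tr, proxy_fit=proxy_fits[solver],
                                  n_splits=inner_n_splits,
                                  val_fraction=inner_val_fraction,
                                  seed=inner_seed, solver=solver,
                                  grid_n_values=grid_n_values,
                                  grid_min_ratio=grid_min_ratio)
                pred = predict_transfer(tf, goal_te.X)
            result.append(FoldMetrics(
                dataset=dataset, pair=pair, trait=pair.trait, model=mo,
                partition=k, cor=pearson_cor(goal_te.y, pred),
                nrmse=nrmse(goal_te.y, pred, nrmse_norm), n_test=goal_te.n))
    return result


def aggregate(metrics, group_by=("dataset", "model")) -> list[AggregateResult]:
    """Equal-weight mean/SD of Cor and NRMSE over all cells within each group.

    Undefined-Cor cells are excluded from the Cor aggregation (and counted),
    never coerced to 0.
    """
    metrics = list(metrics)
    if not metrics:
        raise ValueError("no metrics to aggregate")
    df = EvaluationResult(metrics).to_frame()
    group_by = list(group_by)
    out = []
    for key, g in df.groupby(group_by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        cor = g["cor"].dropna()
        out.append(AggregateResult(
            labels=dict(zip(group_by, key)),
            cor_mean=float(cor.mean()) if len(cor) else float("nan"),
            cor_sd=float(cor.std(ddof=1)) if len(cor) > 1 else 0.0,
            nrmse_mean=float(g["nrmse"].mean()),
            nrmse_sd=float(g["nrmse"].std(ddof=1)) if len(g) > 1 else 0.0,
            n_cells=len(g),
            n_undefined_dropped=int(g["cor"].isna().sum()),
        ))
    return out


def relative_efficiency_cor(avg_conventional: float, avg_transfer: float) -> float:
    """Percentage Cor gain of transfer over conventional models."""
    if avg_conventional <= 0:
        raise ValueError("conventional average Cor must be positive")
    return (avg_transfer / avg_conventional - 1.0) * 100.0


def relative_efficiency_nrmse(avg_conventional: float, avg_transfer: float) -> float:
    """Percentage NRMSE improvement (inverted ratio: lower NRMSE is better)."""
    if avg_transfer <= 0:
        raise ValueError("transfer average NRMSE must be positive")
    return (avg_conventional / avg_transfer - 1.0) * 100.0


def relative_efficiencies(per_model: pd.DataFrame) -> dict:
    """Cor and NRMSE relative efficiencies from a per-model aggregate table.

    ``per_model`` needs columns ``model``, ``Cor``, ``NRMSE``; conventional
    and transfer averages are simple means over the models present on each
    side.
    """
    conv = per_model[per_model["model"].isin(["RR", "ARR"])]
    tran = per_model[per_model["model"].isin(["Transfer_RR", "Transfer_ARR"])]
    if conv.empty or tran.empty:
        raise ValueError("need at least one conventional and one transfer model")
    return {
        "avg_cor_conventional": float(conv["Cor"].mean()),
        "avg_cor_transfer": float(tran["Cor"].mean()),
        "avg_nrmse_conventional": float(conv["NRMSE"].mean()),
        "avg_nrmse_transfer": float(tran["NRMSE"].mean()),
        "re_cor": relative_efficiency_cor(float(conv["Cor"].mean()),
                                          float(tran["Cor"].mean())),
        "re_nrmse": relative_efficiency_nrmse(float(conv["NRMSE"].mean()),
                                              float(tran["NRMSE"].mean())),
    }
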