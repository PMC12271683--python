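"""Synthetic multi-environment genotype/phenotype datasets.

The generator emulates the structure of multi-environment variety-trial
datasets: a p >> n dosage matrix over a panel of lines, two environments
("proxy" and "goal") that share a controllable fraction of those lines, and
quantitative traits driven by environment-specific marker effects. Two dials
matter for transfer learning:

* ``effect_correlation`` ρ — the correlation between proxy and goal marker
  effects, drawn at shared causal positions from a bivariate standard
  normal. This is the generative stand-in for the degree of relatedness
  between environments (genetic + environmental similarity): ρ near 1 makes
  the proxy informative, ρ near 0 makes transfer useless or harmful
  (negative transfer).
* ``h2`` per environment — the fraction of phenotypic variance explained by
  the marker effects; the noise variance is solved against the realized
  genetic variance so var(Xβ)/var(y) hits the target.

Markers are sampled independently (no linkage disequilibrium) with allele
frequencies uniform on ``maf_range`` and dosages Binomial(2, freq). Every
operation is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import MarkerMatrix, PhenotypeTable, EnvironmentPair
from .evaluation import EvaluationResult, evaluate_pair, relative_efficiencies

__all__ = [
    "SimConfig",
    "SimulatedDataset",
    "simulate_genotypes",
    "simulate_effect_pair",
    "simulate_dataset",
    "transfer_gain_experiment",
    "GainExperimentResult",
]

PROXY_ENV = "proxy"
GOAL_ENV = "goal"
TRAIT = "trait"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated two-environment dataset.

    Defaults reproduce the package's reference transfer-gain condition:
    480 lines, 1000 markers, 2/3 of lines phenotyped in both environments
    (so each environment carries 400 lines), a fully polygenic architecture
    (every marker causal), effect correlation 0.9 and heritability 0.5 in
    both environments.
    """

    n_lines_total: int = 480
    p_markers: int = 1000
    shared_line_fraction: float = 2.0 / 3.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_correlation: float = 0.9
    n_causal: int | None = None  # None → all markers causal
    h2_proxy: float = 0.5
    h2_goal: float = 0.5
    base_value: float = 20.0  # trait mean; real traits are far from zero
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shared_line_fraction <= 1:
            raise ValueError("shared_line_fraction must be in [0, 1]")
        if not -1 <= self.effect_correlation <= 1:
            raise ValueError("effect_correlation must be in [-1, 1]")
        for h2 in (self.h2_proxy, self.h2_goal):
            if not 0 < h2 <= 1:
                raise ValueError("heritabilities must be in (0, 1]")
        nc = self.p_markers if self.n_causal is None else self.n_causal
        if not 1 <= nc <= self.p_markers:
            raise ValueError("n_causal must be in [1, p_markers]")

    @property
    def resolved_n_causal(self) -> int:
        return self.p_markers if self.n_causal is None else self.n_causal


@dataclass(frozen=True)
class SimulatedDataset:
    """Simulated genotypes, two-environment phenotypes, and their ground truth."""

    genotypes: MarkerMatrix
    phenotypes: PhenotypeTable
    true_effects_proxy: np.ndarray
    true_effects_goal: np.ndarray
    realized_h2: dict
    config: SimConfig

    @property
    def pair(self) -> EnvironmentPair:
        return EnvironmentPair(PROXY_ENV, GOAL_ENV, TRAIT)


def simulate_genotypes(n: int, p: int, maf_range=(0.05, 0.5), seed: int = 0) -> MarkerMatrix:
    """Independent biallelic markers: freq ~ U(maf_range), dosage ~ Binomial(2, freq)."""
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n < 1 or p < 1:
        raise ValueError("n and p must be positive")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(lo, hi, size=p)
    dosages = rng.binomial(2, freqs, size=(n, p)).astype(float)
    width = max(4, len(str(n)))
    line_ids = tuple(f"L{i + 1:0{width}d}" for i in range(n))
    marker_ids = tuple(f"M{j + 1:0{max(4, len(str(p)))}d}" for j in range(p))
    return MarkerMatrix(line_ids, marker_ids, dosages)


def simulate_effect_pair(p: int, n_causal: int, rho: float, seed: int = 0):
    """Correlated proxy/goal marker effects at shared causal positions.

    At each of ``n_causal`` positions, (b_proxy, b_goal) is bivariate
    standard normal with correlation ``rho``; all other positions are zero.
    """
    if not -1 <= rho <= 1:
        raise ValueError("rho must be in [-1, 1]")
    if not 1 <= n_causal <= p:
        raise ValueError("n_causal must be in [1, p]")
    rng = np.random.default_rng(seed)
    causal = np.sort(rng.choice(p, size=n_causal, replace=False))
    z1 = rng.standard_normal(n_causal)
    z2 = rng.standard_normal(n_causal)
    beta_proxy = np.zeros(p)
    beta_goal = np.zeros(p)
    beta_proxy[causal] = z1
    beta_goal[causal] = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * z2
    return beta_proxy, beta_goal


def _environment_lines(n: int, shared_fraction: float):
    """Deterministic line layout: the first round(f·n) lines are phenotyped in
    both environments; the remaining lines alternate proxy, goal, proxy, ..."""
    n_shared = int(round(shared_fraction * n))
    shared = list(range(n_shared))
    rest = list(range(n_shared, n))
    proxy_only = rest[0::2]
    goal_only = rest[1::2]
    return shared + proxy_only, shared + goal_only


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Compose genotypes, correlated effects and per-environment phenotypes.

    Noise variance per environment is solved so that the realized genetic
    variance over that environment's lines accounts for the target h² of the
    phenotypic variance; ``realized_h2`` records var(g)/var(y) actually
    achieved on the finite sample. Phenotypes sit on ``base_value`` so that
    trait means are far from zero, as for real quantitative traits.
    """
    geno = simulate_genotypes(cfg.n_lines_total, cfg.p_markers, cfg.maf_range, cfg.seed)
    beta_p, beta_g = simulate_effect_pair(
        cfg.p_markers, cfg.resolved_n_causal, cfg.effect_correlation, cfg.seed + 1)
    proxy_rows, goal_rows = _environment_lines(cfg.n_lines_total, cfg.shared_line_fraction)

    records = []
    realized = {}
    for env, rows, beta, h2, noise_seed in (
        (PROXY_ENV, proxy_rows, beta_p, cfg.h2_proxy, cfg.seed + 2),
        (GOAL_ENV, goal_rows, beta_g, cfg.h2_goal, cfg.seed + 3),
    ):
        X = geno.values[rows]
        g = X @ beta
        var_g = float(g.var())
        if var_g == 0:
            raise ValueError(f"zero genetic variance in environment {env!r}")
        sigma = np.sqrt(var_g * (1.0 - h2) / h2)
        eps = np.random.default_rng(noise_seed).standard_normal(len(rows)) * sigma
        y = cfg.base_value + g + eps
        realized[env] = var_g / float(y.var()) if y.var() > 0 else 1.0
        for i, r in enumerate(rows):
            records.append((geno.line_ids[r], env, TRAIT, y[i]))
    pt = PhenotypeTable(pd.DataFrame(records, columns=["line", "environment", "trait", "value"]))
    return SimulatedDataset(geno, pt, beta_p, beta_g, realized, cfg)


@dataclass(frozen=True)
class GainExperimentResult:
    """Monte-Carlo summary of the transfer-vs-conventional contrast."""

    per_model: pd.DataFrame       # model, Cor, Cor_SD, NRMSE, NRMSE_SD over all cells
    per_replicate: pd.DataFrame   # replicate x model mean Cor/NRMSE (for paired tests)
    efficiencies: dict            # avg_cor_*, avg_nrmse_*, re_cor, re_nrmse
    config: SimConfig
    n_replicates: int

    def paired_cor(self, model_a: str, model_b: str):
        """Per-replicate mean-Cor arrays of two models, aligned for a paired test."""
        wide = self.per_replicate.pivot(index="replicate", columns="model", values="cor")
        return wide[model_a].to_numpy(), wide[model_b].to_numpy()

    def summary(self) -> str:
        out = self.per_model.to_string(index=False, float_format=lambda v: f"{v:.3f}")
        e = self.efficiencies
        out += (f"\n\nRelative efficiency over {self.n_replicates} replicates "
                f"(rho={self.config.effect_correlation}): "
                f"Cor {e['re_cor']:+.2f}%, NRMSE {e['re_nrmse']:+.2f}%")
        return out


def transfer_gain_experiment(cfg: SimConfig, n_replicates: int = 30,
                             models=("RR", "ARR", "Transfer_RR", "Transfer_ARR"),
                             n_partitions: int = 10, train_fraction: float = 0.8,
                             nrmse_norm: str = "mean") -> GainExperimentResult:
    """Monte-Carlo experiment: simulate, evaluate all models, compare.

    Each replicate simulates a fresh dataset (replicate r uses the master
    seed offset by 101·r) and runs the full outer-CV evaluation; cells are
    pooled with equal weight for the per-model table and the relative
    efficiencies, while per-replicate means are retained for paired
    contrasts.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    all_metrics = []
    rep_rows = []
    for r in range(n_replicates):
        rep_cfg = replace(cfg, seed=cfg.seed + 101 * r)
        ds = simulate_dataset(rep_cfg)
        res = evaluate_pair(ds.genotypes, ds.phenotypes, ds.pair, models=models,
                            n_partitions=n_partitions, train_fraction=train_fraction,
                            seed=rep_cfg.seed, nrmse_norm=nrmse_norm,
                            dataset=f"rep{r}")
        all_metrics.extend(res)
        df = res.to_frame()
        for mo, g in df.groupby("model"):
            rep_rows.append({"replicate": r, "model": mo,
                             "cor": float(g["cor"].mean()),
                             "nrmse": float(g["nrmse"].mean())})
    pooled = EvaluationResult(all_metrics)
    per_model = pooled.aggregate_frame(group_by=("model",))
    eff = relative_efficiencies(per_model)
    return GainExperimentResult(per_model, pd.DataFrame(rep_rows), eff, cfg, n_replicates)
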