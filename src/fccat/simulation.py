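"""Simulation harness: adaptive-vs-static by desirability-constraint experiments.

The experimental design crosses item selection (adaptive vs nonadaptive-but-
optimal/static) with social-desirability balancing (strict T=0.5, lenient
T=1.0, or none) and administers 120-pair forced-choice tests to simulees drawn
from the multivariate normal trait prior.  Precision is summarized per scale
and checkpoint by the mean directional SEM, the correlation between true and
estimated scores (COR) and the root-mean-square error (RMSE), with
Monte-Carlo standard errors from a leave-one-simulee-out jackknife.

Conditions share simulees and response-noise streams (matched seeds), so
between-condition contrasts are paired and far more precise than the
marginal Monte-Carlo error would suggest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bank import BankRecipe, ItemBank, synthesize_bank
from .cat import (
    DesirabilityConstraint,
    SessionResult,
    administer_form,
    assemble_static_test,
    run_adaptive_session,
)
from .information import PriorSpec, default_trait_prior

__all__ = [
    "Condition",
    "SimulationConfig",
    "ConditionResult",
    "SimulationResult",
    "generate_simulees",
    "run_condition",
    "run_simulation",
    "compute_metrics",
    "compare_conditions",
    "DEFAULT_CONDITIONS",
]


@dataclass(frozen=True)
class Condition:
    """One cell of the design: selection mode x desirability balancing."""

    selection: str  # "adaptive" | "static"
    balancing: str  # "strict" | "lenient" | "none"

    def __post_init__(self) -> None:
        if self.selection not in ("adaptive", "static"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        DesirabilityConstraint.from_spec(self.balancing)

    @property
    def constraint(self) -> DesirabilityConstraint:
        return DesirabilityConstraint.from_spec(self.balancing)

    @property
    def name(self) -> str:
        return f"{self.selection}-{self.balancing}"

    @classmethod
    def parse(cls, name) -> "Condition":
        if isinstance(name, Condition):
            return name
        sel, _, bal = str(name).partition("-")
        return cls(sel, bal)


#: The empirical 2x2 design (AL, AS, NL, NS).
DEFAULT_CONDITIONS: tuple[Condition, ...] = (
    Condition("adaptive", "lenient"),
    Condition("adaptive", "strict"),
    Condition("static", "lenient"),
    Condition("static", "strict"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for one simulation experiment (defaults mirror the study design)."""

    n_simulees: int = 2000
    test_length: int = 120
    conditions: tuple[Condition, ...] = DEFAULT_CONDITIONS
    prior: PriorSpec = field(default_factory=default_trait_prior)
    bank: ItemBank | None = None
    bank_recipe: BankRecipe | None = None
    bank_seed: int = 1
    seed: int = 0
    checkpoints: tuple[int, ...] = tuple(range(10, 121, 10))

    def __post_init__(self) -> None:
        if self.n_simulees < 1:
            raise ValueError("n_simulees must be >= 1")
        if self.test_length < 0:
            raise ValueError("test_length must be >= 0")
        if any(c < 1 or c > self.test_length for c in self.checkpoints):
            raise ValueError("checkpoints must lie in [1, test_length]")
        if tuple(self.checkpoints) != tuple(sorted(self.checkpoints)):
            raise ValueError("checkpoints must be increasing")

    def resolve_bank(self) -> ItemBank:
        if self.bank is not None:
            return self.bank
        return synthesize_bank(self.bank_recipe, seed=self.bank_seed)


@dataclass
class ConditionResult:
    """Per-simulee trajectories of one condition at the configured checkpoints."""

    condition: Condition
    checkpoints: tuple[int, ...]
    scales: tuple[str, ...]
    true_eta: np.ndarray  # (n, S)
    eta_hat: np.ndarray  # (n, C, S)
    sem: np.ndarray  # (n, C, S)
    final_eta: np.ndarray  # (n, S)
    final_sem: np.ndarray  # (n, S)
    n_completed: np.ndarray  # (n,) blocks completed per session
    truncated: np.ndarray  # (n,) bool

    @property
    def n_simulees(self) -> int:
        return self.true_eta.shape[0]


@dataclass
class SimulationResult:
    config: SimulationConfig
    conditions: dict[str, ConditionResult]
    metrics: pd.DataFrame

    def to_csv(self, path) -> None:
        self.metrics.to_csv(path, index=False, float_format="%.10g")


def generate_simulees(n: int, prior: PriorSpec, seed) -> np.ndarray:
    """Draw ``n`` true trait profiles from the MVN prior; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return prior.rvs(n, rng)


def _simulee_rng(master_seed: int, index: int) -> np.random.Generator:
    # Same stream for simulee `index` in every condition (matched-seed design).
    return np.random.default_rng([master_seed, 1, index])


def run_condition(config: SimulationConfig, condition: Condition | str) -> ConditionResult:
    """Run one design cell for all simulees of the configured experiment."""
    condition = Condition.parse(condition)
    bank = config.resolve_bank()
    prior = config.prior
    n = config.n_simulees
    S = bank.n_scales
    cps = tuple(config.checkpoints)
    true_eta = generate_simulees(n, prior, [config.seed, 0])

    eta_hat = np.full((n, len(cps), S), np.nan)
    sem = np.full((n, len(cps), S), np.nan)
    final_eta = np.empty((n, S))
    final_sem = np.empty((n, S))
    n_completed = np.zeros(n, dtype=int)
    truncated = np.zeros(n, dtype=bool)

    static_form = None
    if condition.selection == "static":
        static_form = assemble_static_test(
            bank, prior, condition.constraint, config.test_length, seed=config.seed
        )

    cp_idx = np.array(cps, dtype=int) - 1
    for i in range(n):
        rng = _simulee_rng(config.seed, i)
        if condition.selection == "adaptive":
            res: SessionResult = run_adaptive_session(
                bank, prior, condition.constraint, config.test_length, true_eta=true_eta[i], rng=rng
            )
        else:
            res = administer_form(static_form, bank, prior, true_eta=true_eta[i], rng=rng)
        L = len(res.responses)
        n_completed[i] = L
        truncated[i] = res.truncated
        ok = cp_idx < L
        if ok.any():
            eta_hat[i, ok] = res.interim_trajectory[cp_idx[ok]]
            sem[i, ok] = res.sem_trajectory[cp_idx[ok]]
        final_eta[i] = res.estimate.eta_hat
        final_sem[i] = res.estimate.sem
    return ConditionResult(
        condition, cps, bank.scales, true_eta, eta_hat, sem, final_eta, final_sem, n_completed, truncated
    )


# ---------------------------------------------------------------------------
# Metrics with leave-one-out jackknife Monte-Carlo standard errors.
# ---------------------------------------------------------------------------


def _jackknife_se(loo: np.ndarray) -> float:
    n = loo.size
    return float(math.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


def _loo_mean(x: np.ndarray) -> np.ndarray:
    n = x.size
    return (x.sum() - x) / (n - 1)


def _loo_rmse(err: np.ndarray) -> np.ndarray:
    n = err.size
    sq = err**2
    return np.sqrt(np.maximum((sq.sum() - sq) / (n - 1), 0.0))


def _loo_corr(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized leave-one-out Pearson correlations."""
    n = x.size
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    m = n - 1
    mx = (sx - x) / m
    my = (sy - y) / m
    cxy = (sxy - x * y) / m - mx * my
    vx = (sxx - x * x) / m - mx * mx
    vy = (syy - y * y) / m - my * my
    denom = np.sqrt(np.maximum(vx * vy, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return cxy / denom


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def compute_metrics(result: ConditionResult) -> pd.DataFrame:
    """Long-format precision table: per scale x checkpoint x metric, with MC SEs.

    Metrics: ``mean_sem``, ``cor`` (Pearson true-vs-estimated; missing when the
    estimates have zero variance) and ``rmse``.
    """
    rows = []
    n = result.n_simulees
    for ci, cp in enumerate(result.checkpoints):
        for si, scale in enumerate(result.scales):
            est = result.eta_hat[:, ci, si]
            tru = result.true_eta[:, si]
            sems = result.sem[:, ci, si]
            err = est - tru
            cor = _pearson(tru, est) if n > 1 else float("nan")
            rows.extend(
                [
                    {
                        "condition": result.condition.name,
                        "scale": scale,
                        "checkpoint": cp,
                        "metric": "mean_sem",
                        "value": float(np.mean(sems)),
                        "mc_se": _jackknife_se(_loo_mean(sems)) if n > 1 else float("nan"),
                    },
                    {
                        "condition": result.condition.name,
                        "scale": scale,
                        "checkpoint": cp,
                        "metric": "cor",
                        "value": cor,
                        "mc_se": _jackknife_se(_loo_corr(tru, est)) if n > 2 and not math.isnan(cor) else float("nan"),
                    },
                    {
                        "condition": result.condition.name,
                        "scale": scale,
                        "checkpoint": cp,
                        "metric": "rmse",
                        "value": float(np.sqrt(np.mean(err**2))),
                        "mc_se": _jackknife_se(_loo_rmse(err)) if n > 1 else float("nan"),
                    },
                ]
            )
    return pd.DataFrame(rows)


def _loo_metric(result: ConditionResult, metric: str, ci: int, si: int) -> np.ndarray:
    est = result.eta_hat[:, ci, si]
    tru = result.true_eta[:, si]
    if metric == "mean_sem":
        return _loo_mean(result.sem[:, ci, si])
    if metric == "rmse":
        return _loo_rmse(est - tru)
    if metric == "cor":
        return _loo_corr(tru, est)
    raise ValueError(f"unknown metric {metric!r}")


def compare_conditions(
    results: Mapping[str, ConditionResult] | Sequence[ConditionResult],
    contrasts: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Paired per-scale contrasts between conditions with jackknife MC SEs.

    Requires matched simulees (same true profiles in every condition).  By
    default all adaptive-minus-static and lenient/none-minus-strict contrasts
    present in ``results`` are reported; each row flags the sign of the
    difference (-1: first condition smaller).
    """
    if not isinstance(results, Mapping):
        results = {r.condition.name: r for r in results}
    names = list(results)
    if len(names) < 2:
        raise ValueError("need at least two conditions to compare")
    base = next(iter(results.values()))
    for r in results.values():
        if r.checkpoints != base.checkpoints or r.scales != base.scales:
            raise ValueError("conditions have mismatched checkpoints or scales")
        if r.true_eta.shape != base.true_eta.shape or not np.allclose(r.true_eta, base.true_eta):
            raise ValueError("conditions are not matched (different simulees)")

    if contrasts is None:
        contrasts = []
        for a in names:
            for b in names:
                ca, cb = Condition.parse(a), Condition.parse(b)
                if ca.selection == "adaptive" and cb.selection == "static" and ca.balancing == cb.balancing:
                    contrasts.append((a, b))
                if (
                    ca.selection == cb.selection
                    and (ca.balancing, cb.balancing) in (("lenient", "strict"), ("none", "strict"), ("none", "lenient"))
                ):
                    contrasts.append((a, b))

    rows = []
    for a, b in contrasts:
        ra, rb = results[a], results[b]
        for ci, cp in enumerate(base.checkpoints):
            for si, scale in enumerate(base.scales):
                for metric in ("mean_sem", "cor", "rmse"):
                    la = _loo_metric(ra, metric, ci, si)
                    lb = _loo_metric(rb, metric, ci, si)
                    va = compute_single(ra, metric, ci, si)
                    vb = compute_single(rb, metric, ci, si)
                    diff = va - vb
                    se = _jackknife_se(la - lb)
                    rows.append(
                        {
                            "contrast": f"{a} - {b}",
                            "scale": scale,
                            "checkpoint": cp,
                            "metric": metric,
                            "diff": diff,
                            "mc_se": se,
                            "sign": int(np.sign(diff)) if not math.isnan(diff) else 0,
                        }
                    )
    return pd.DataFrame(rows)


def compute_single(result: ConditionResult, metric: str, ci: int, si: int) -> float:
    est = result.eta_hat[:, ci, si]
    tru = result.true_eta[:, si]
    if metric == "mean_sem":
        return float(np.mean(result.sem[:, ci, si]))
    if metric == "rmse":
        return float(np.sqrt(np.mean((est - tru) ** 2)))
    if metric == "cor":
        return _pearson(tru, est)
    raise ValueError(f"unknown metric {metric!r}")


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run every configured condition and assemble the combined metrics table."""
    results: dict[str, ConditionResult] = {}
    frames = []
    for cond in config.conditions:
        res = run_condition(config, cond)
        results[cond.name] = res
        frames.append(compute_metrics(res))
    metrics = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return SimulationResult(config, results, metrics)


def plot_metric_trajectories(metrics: pd.DataFrame, metric: str, path) -> None:
    """One panel per scale: metric vs test length, one line per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = metrics[metrics["metric"] == metric]
    scales = list(dict.fromkeys(sub["scale"]))
    fig, axes = plt.subplots(2, (len(scales) + 1) // 2, figsize=(3.2 * ((len(scales) + 1) // 2), 6), squeeze=False)
    for ax, scale in zip(axes.ravel(), scales):
        for cond, grp in sub[sub["scale"] == scale].groupby("condition"):
            grp = grp.sort_values("checkpoint")
            ax.plot(grp["checkpoint"], grp["value"], marker="o", ms=3, label=cond)
        ax.set_title(scale)
        ax.set_xlabel("test length (pairs)")
        ax.set_ylabel(metric)
    axes.ravel()[0].legend(fontsize=7)
    for ax in axes.ravel()[len(scales):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
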