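"""One-way and probabilistic sensitivity analysis.

One-way analysis re-evaluates the full model at each bound of a single
parameter (all others at base case) and reports the incremental net
monetary benefit of a strategy pair; the tornado ordering sorts bars by
width.  The probabilistic analysis draws every uncertain parameter from
its moment-matched distribution (beta for probabilities and utilities,
gamma for costs), re-evaluates all strategies per draw, and summarizes
the preferred-strategy frequency as a cost-effectiveness acceptability
curve over a willingness-to-pay grid.

Sampling assumptions: parameters are drawn independently (no correlation
information is available); sampled 30-day disposition rows are
renormalized to sum to one after drawing each entry independently (a
Dirichlet row draw is available behind a flag); annual rows whose exits
sum above one are redrawn, capped at 100 attempts per iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import compute_nmb
from .cohort import (
    DEFAULT_CONVENTION,
    Convention,
    ModelArrays,
    _evaluate_one,
    compile_arrays,
)
from .distributions import BetaDistribution, PointMass
from .parameters import ModelBundle, ModelValidationError
from .states import (
    HEALTH_STATES,
    PERMITTED_ANNUAL_EXITS,
    STATE_INDEX,
    STATE_SPACE,
    HealthState,
    StratifiedState,
)

__all__ = ["OwsaResult", "PsaRun", "run_owsa", "run_full_owsa", "tornado", "run_psa", "ceac"]

MAX_REDRAWS = 100


@dataclass(frozen=True)
class OwsaResult:
    """Incremental NMB of a strategy pair at both bounds of one parameter."""

    parameter: str
    low: float
    high: float
    nmb_low: float
    nmb_high: float
    nmb_base: float

    @property
    def width(self) -> float:
        return abs(self.nmb_high - self.nmb_low)


def _incremental_nmb(
    bundle: ModelBundle, pair: tuple[str, str], wtp: float, convention: Convention
) -> float:
    arrays = compile_arrays(bundle)
    nmbs = {}
    for name in pair:
        i = arrays.strategy_names.index(name)
        cost, qaly, _ = _evaluate_one(arrays, arrays.p_aki[i], arrays.upfront[i], convention)
        nmbs[name] = compute_nmb(qaly, cost, wtp)
    return nmbs[pair[0]] - nmbs[pair[1]]


def run_owsa(
    bundle: ModelBundle,
    parameter: str,
    low: float,
    high: float,
    pair: tuple[str, str],
    wtp: float,
    convention: Convention = DEFAULT_CONVENTION,
) -> OwsaResult:
    """Re-evaluate the model at each bound of one parameter."""
    if low > high:
        raise ValueError(f"{parameter}: low {low} exceeds high {high}")
    if pair[0] == pair[1]:
        raise ValueError("strategy pair must be distinct")
    base = _incremental_nmb(bundle, pair, wtp, convention)
    bounds = []
    for value in (low, high):
        try:
            varied = bundle.with_parameter(parameter, value)
        except ModelValidationError as exc:
            raise ModelValidationError(
                f"{parameter}: bound {value} makes the model invalid ({exc})"
            ) from exc
        bounds.append(_incremental_nmb(varied, pair, wtp, convention))
    return OwsaResult(
        parameter=parameter, low=low, high=high,
        nmb_low=bounds[0], nmb_high=bounds[1], nmb_base=base,
    )


def run_full_owsa(
    bundle: ModelBundle,
    pair: tuple[str, str],
    wtp: float,
    convention: Convention = DEFAULT_CONVENTION,
) -> list[OwsaResult]:
    """One-way analysis over every parameter that has a range."""
    results = []
    for name, ref in bundle.parameters().items():
        if not ref.has_range:
            continue
        results.append(run_owsa(bundle, name, ref.low, ref.high, pair, wtp, convention))
    return results


def tornado(results: Sequence[OwsaResult]) -> pd.DataFrame:
    """Stable descending sort by bar width; ties broken by parameter name."""
    if not results:
        raise ValueError("tornado needs at least one one-way result")
    df = pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "nmb_low": r.nmb_low,
                "nmb_high": r.nmb_high,
                "nmb_base": r.nmb_base,
                "width": r.width,
            }
            for r in results
        ]
    )
    return df.sort_values(
        ["width", "parameter"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def plot_tornado(df: pd.DataFrame, path, top: int = 15) -> None:
    """Horizontal-bar tornado plot of the widest ``top`` parameters."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = df.head(top).iloc[::-1]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(sub) + 1.5))
    left = np.minimum(sub["nmb_low"], sub["nmb_high"])
    ax.barh(sub["parameter"], sub["width"], left=left, color="#4477aa")
    ax.axvline(sub["nmb_base"].iloc[0], color="k", lw=1)
    ax.set_xlabel("Incremental net monetary benefit, $")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ----------------------------------------------------------------------
# probabilistic sensitivity analysis
# ----------------------------------------------------------------------


@dataclass
class PsaRun:
    """Per-iteration strategy outcomes from a seeded PSA."""

    n_samples: int
    seed: int
    strategies: tuple[str, ...]
    costs: np.ndarray  # (n_samples, n_strategies)
    qalys: np.ndarray  # (n_samples, n_strategies)
    redraws: int = 0

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, name in enumerate(self.strategies):
            frames.append(
                pd.DataFrame(
                    {
                        "iteration": np.arange(self.n_samples),
                        "strategy": name,
                        "cost": self.costs[:, j],
                        "qaly": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def preferred(self, wtp: float) -> np.ndarray:
        """Index of the NMB-maximizing strategy per iteration.

        Ties are broken by lower cost, then by strategy name order.
        """
        nmb = self.qalys * wtp - self.costs
        best = np.argmax(nmb, axis=1)
        # resolve exact ties explicitly (measure-zero but cheap to honor)
        tied = (nmb == nmb[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
        for i in np.nonzero(tied)[0]:
            cand = np.nonzero(nmb[i] == nmb[i].max())[0]
            cand = cand[np.argsort(self.costs[i, cand], kind="stable")]
            best[i] = cand[0]
        return best

    def preferred_fraction(self, strategy: str, wtp: float) -> float:
        j = self.strategies.index(strategy)
        return float(np.mean(self.preferred(wtp) == j))


def _draw_row(
    rng: np.random.Generator,
    dists: list,
    dirichlet: bool,
) -> np.ndarray:
    """Draw one categorical row and renormalize it to sum to one."""
    if dirichlet:
        betas = [d for d in dists if isinstance(d, BetaDistribution)]
        conc = np.mean([b.alpha + b.beta for b in betas]) if betas else 1.0
        alphas = np.array([max(d.mean * conc, 1e-12) for d in dists])
        draw = rng.dirichlet(alphas)
        # zero-mean entries stay structural zeroes
        draw = np.where([d.mean == 0.0 for d in dists], 0.0, draw)
        return draw / draw.sum()
    draw = np.array([d.sample(rng) for d in dists], dtype=float)
    total = draw.sum()
    if total <= 0.0:
        raise ModelValidationError("sampled disposition row sums to zero")
    return draw / total


def run_psa(
    bundle: ModelBundle,
    n_samples: int = 1000,
    seed: int = 0,
    convention: Convention = DEFAULT_CONVENTION,
    dirichlet_rows: bool = False,
) -> PsaRun:
    """Second-order Monte Carlo over all uncertain parameters.

    Deterministic given ``seed``.  Each iteration draws every parameter
    once, renormalizes the 30-day disposition rows, rejects annual rows
    with exit sums above one (redraw, capped), and evaluates all four
    strategies under ``convention``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    base = compile_arrays(bundle)
    dists = bundle.psa_distributions()
    names = base.strategy_names
    n_strat = len(names)
    costs = np.empty((n_samples, n_strat))
    qalys = np.empty((n_samples, n_strat))
    total_redraws = 0

    d30_dists = {
        status: [dists[f"thirty_day.{status}.{s.value}"] for s in HEALTH_STATES]
        for status in ("aki", "no_aki")
    }
    annual_rows = [
        (hist, origin, [dists[f"annual.{hist}.{origin.value}.{d.value}"] for d in perm], perm)
        for hist in ("after_aki", "no_aki")
        for origin, perm in PERMITTED_ANNUAL_EXITS.items()
    ]

    for it in range(n_samples):
        arrays = ModelArrays(
            strategy_names=names,
            p_aki=np.array([dists[f"p_aki.{n}"].sample(rng) for n in names]),
            upfront=np.array([dists[f"upfront_cost.{n}"].sample(rng) for n in names]),
            d30_aki=_draw_row(rng, d30_dists["aki"], dirichlet_rows),
            d30_no_aki=_draw_row(rng, d30_dists["no_aki"], dirichlet_rows),
            transition=np.zeros_like(base.transition),
            utilities=np.zeros_like(base.utilities),
            state_costs=np.zeros_like(base.state_costs),
            aki_episode_cost=float(dists["cost.aki_episode"].sample(rng)),
            discount_rate=base.discount_rate,
            horizon=base.horizon,
            wtp=base.wtp,
        )
        P = arrays.transition
        for hist_key, origin, row_dists, perm in annual_rows:
            hist = hist_key == "after_aki"
            for attempt in range(MAX_REDRAWS + 1):
                exits = np.array([d.sample(rng) for d in row_dists], dtype=float)
                if exits.sum() <= 1.0:
                    break
                total_redraws += 1
            else:
                raise ModelValidationError(
                    f"annual.{hist_key}.{origin.value}: exit sum stayed above 1 "
                    f"after {MAX_REDRAWS} redraws"
                )
            i = STATE_INDEX[StratifiedState(origin, hist)]
            P[i, i] = 1.0 - exits.sum()
            for dest, p in zip(perm, exits):
                P[i, STATE_INDEX[StratifiedState(dest, hist)]] = p
        for hist in (True, False):
            i = STATE_INDEX[StratifiedState(HealthState.DEATH, hist)]
            P[i, i] = 1.0

        util = {
            s: float(dists[f"utility.{s.value}"].sample(rng))
            for s in (HealthState.NORMAL, HealthState.CKD, HealthState.ESRD)
        }
        util[HealthState.DEATH] = 0.0
        cost_by_state = {
            HealthState.NORMAL: 0.0,
            HealthState.DEATH: 0.0,
            HealthState.CKD: float(dists["cost.CKD"].sample(rng)),
            HealthState.ESRD: float(dists["cost.ESRD"].sample(rng)),
        }
        arrays.utilities = np.array([util[s.state] for s in STATE_SPACE])
        arrays.state_costs = np.array([cost_by_state[s.state] for s in STATE_SPACE])

        for j in range(n_strat):
            c, q, _ = _evaluate_one(arrays, arrays.p_aki[j], arrays.upfront[j], convention)
            costs[it, j] = c
            qalys[it, j] = q

    return PsaRun(
        n_samples=n_samples, seed=seed, strategies=names,
        costs=costs, qalys=qalys, redraws=total_redraws,
    )


def ceac(run: PsaRun, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Acceptability: fraction of iterations each strategy maximizes NMB."""
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("willingness-to-pay grid is empty")
    if any(w < 0 for w in grid):
        raise ValueError("willingness-to-pay values must be non-negative")
    rows = []
    for w in grid:
        best = run.preferred(w)
        for j, name in enumerate(run.strategies):
            rows.append(
                {
                    "wtp": w,
                    "strategy": name,
                    "acceptability": float(np.mean(best == j)),
                }
            )
    return pd.DataFrame(rows)


def plot_ceac(df: pd.DataFrame, path) -> None:
    """Line plot of acceptability against willingness to pay."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for name, sub in df.groupby("strategy"):
        ax.plot(sub["wtp"], sub["acceptability"], marker="o", label=name)
    ax.set_xlabel("Willingness to pay, $/QALY")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
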