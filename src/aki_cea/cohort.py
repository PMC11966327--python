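"""Decision tree and yearly-cycle Markov cohort engine.

Each strategy is evaluated in two phases.  The decision-tree phase covers
the first 30 days: a Bernoulli AKI event at 7 days, followed by a 30-day
disposition over the four health states conditional on AKI status.  The
cohort then enters a Markov model with yearly cycles over the stratified
state space (health state x AKI history) for the remaining horizon.

Accrual conventions
-------------------
The tree phase accrues the upfront intervention cost plus the expected
AKI episode cost at time zero, undiscounted.  State costs and utilities
accrue once per Markov cycle, discounted at ``(1 + r)^-t`` for cycle
``t = 1..H``.  Which occupancy vector carries the accrual is a toggle:

* ``accrual="pre"`` (default): the distribution at the *start* of the
  cycle — a patient earns the reward of the state they spend the year in.
* ``accrual="post"``: the distribution after the transition.
* ``half_cycle=True``: the average of the two.

The shipped default (pre-transition, no half-cycle correction) is the
combination closest to the published base-case estimates for this model;
see the methods note.  The first 30 days contribute no QALYs, and 30-day
CKD/ESRD dispositions accrue their first annual state cost at cycle 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Literal, Mapping

import numpy as np
import pandas as pd

from .parameters import ModelBundle, StrategySpec, TransitionTables, EconomicInputs
from .states import (
    HEALTH_STATES,
    PERMITTED_ANNUAL_EXITS,
    STATE_INDEX,
    STATE_SPACE,
    HealthState,
    StratifiedState,
)

__all__ = [
    "Convention",
    "ModelArrays",
    "StrategyOutcome",
    "compile_arrays",
    "run_decision_tree",
    "step_markov",
    "evaluate_strategy",
    "evaluate_all",
    "DEFAULT_CONVENTION",
]

N_STATES = len(STATE_SPACE)


@dataclass(frozen=True)
class Convention:
    """Cycle accrual toggles for the Markov phase."""

    accrual: Literal["pre", "post"] = "pre"
    half_cycle: bool = False

    def weights(self) -> tuple[float, float]:
        """(weight on pre-transition occupancy, weight on post-transition)."""
        if self.half_cycle:
            return 0.5, 0.5
        return (1.0, 0.0) if self.accrual == "pre" else (0.0, 1.0)


DEFAULT_CONVENTION = Convention()


@dataclass
class ModelArrays:
    """Dense numeric view of a model bundle for fast repeated evaluation.

    Mutable by design: the PSA overwrites entries draw by draw.  Strategy
    order follows ``strategy_names``.
    """

    strategy_names: tuple[str, ...]
    p_aki: np.ndarray            # (S,)
    upfront: np.ndarray          # (S,)
    d30_aki: np.ndarray          # (4,) over HEALTH_STATES
    d30_no_aki: np.ndarray       # (4,)
    transition: np.ndarray       # (8, 8) stratified transition matrix
    utilities: np.ndarray        # (8,)
    state_costs: np.ndarray      # (8,)
    aki_episode_cost: float
    discount_rate: float
    horizon: int
    wtp: float


def _row_vector(row: Mapping[HealthState, object]) -> np.ndarray:
    return np.array([row[s].mean for s in HEALTH_STATES])


def build_transition_matrix(tables: TransitionTables) -> np.ndarray:
    """Stratified yearly transition matrix over the 8-state space.

    AKI history never changes; death is absorbing; stay probabilities are
    the residual of each row's exits.
    """
    P = np.zeros((N_STATES, N_STATES))
    for hist in (True, False):
        key = "after_aki" if hist else "no_aki"
        for origin in HEALTH_STATES:
            i = STATE_INDEX[StratifiedState(origin, hist)]
            if origin is HealthState.DEATH:
                P[i, i] = 1.0
                continue
            exits = tables.annual[key][origin]
            stay = 1.0 - sum(p.mean for p in exits.values())
            if stay < 0.0:
                raise ValueError(
                    f"annual.{key}.{origin.value}: negative stay residual {stay:.6g}"
                )
            P[i, i] = stay
            for dest, p in exits.items():
                P[i, STATE_INDEX[StratifiedState(dest, hist)]] = p.mean
    return P


def compile_arrays(bundle: ModelBundle) -> ModelArrays:
    """Flatten a validated bundle into dense arrays."""
    names = tuple(sorted(bundle.strategies))
    econ = bundle.economics
    utilities = np.array([econ.utilities[s.state].mean for s in STATE_SPACE])
    state_costs = np.array([econ.annual_state_costs[s.state].mean for s in STATE_SPACE])
    return ModelArrays(
        strategy_names=names,
        p_aki=np.array([bundle.strategies[n].p_aki.mean for n in names]),
        upfront=np.array([bundle.strategies[n].upfront_cost.mean for n in names]),
        d30_aki=_row_vector(bundle.transitions.thirty_day["aki"]),
        d30_no_aki=_row_vector(bundle.transitions.thirty_day["no_aki"]),
        transition=build_transition_matrix(bundle.transitions),
        utilities=utilities,
        state_costs=state_costs,
        aki_episode_cost=econ.aki_episode_cost.mean,
        discount_rate=econ.discount_rate,
        horizon=econ.horizon_years,
        wtp=econ.wtp,
    )


def _initial_occupancy(p_aki: float, d30_aki: np.ndarray, d30_no: np.ndarray) -> np.ndarray:
    occ = np.empty(N_STATES)
    occ[:4] = p_aki * d30_aki
    occ[4:] = (1.0 - p_aki) * d30_no
    return occ


def run_decision_tree(
    strategy: StrategySpec,
    transitions: TransitionTables,
    economics: EconomicInputs,
) -> tuple[Dict[StratifiedState, float], float]:
    """30-day occupancy over the stratified state space, and the tree cost.

    The tree cost is the upfront per-person intervention cost plus the
    expected AKI episode cost, ``upfront + p_aki * aki_episode_cost``,
    accrued at time zero.
    """
    p = strategy.p_aki.mean
    occ = _initial_occupancy(
        p,
        _row_vector(transitions.thirty_day["aki"]),
        _row_vector(transitions.thirty_day["no_aki"]),
    )
    tree_cost = strategy.upfront_cost.mean + p * economics.aki_episode_cost.mean
    return dict(zip(STATE_SPACE, occ)), tree_cost


def step_markov(occupancy: np.ndarray, transition: np.ndarray) -> np.ndarray:
    """Advance the cohort one yearly cycle."""
    occupancy = np.asarray(occupancy, dtype=float)
    if occupancy.shape != (N_STATES,):
        raise ValueError(f"occupancy must have shape ({N_STATES},)")
    if abs(occupancy.sum() - 1.0) > 1e-9:
        raise ValueError(f"occupancy sums to {occupancy.sum():.12g}, not 1")
    return occupancy @ transition


def _evaluate_one(
    arrays: ModelArrays, p_aki: float, upfront: float, convention: Convention
) -> tuple[float, float, np.ndarray]:
    """(total discounted cost, total discounted QALYs, occupancy history)."""
    occ = _initial_occupancy(p_aki, arrays.d30_aki, arrays.d30_no_aki)
    history = np.empty((arrays.horizon + 1, N_STATES))
    history[0] = occ
    w_pre, w_post = convention.weights()
    cost = upfront + p_aki * arrays.aki_episode_cost
    qaly = 0.0
    r = arrays.discount_rate
    for t in range(1, arrays.horizon + 1):
        nxt = occ @ arrays.transition
        history[t] = nxt
        acc = w_pre * occ + w_post * nxt
        d = (1.0 + r) ** (-t)
        cost += d * float(acc @ arrays.state_costs)
        qaly += d * float(acc @ arrays.utilities)
        occ = nxt
    return cost, qaly, history


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected discounted totals and the cohort trace for one strategy."""

    strategy: str
    total_cost: float
    total_qaly: float
    trace: pd.DataFrame = field(repr=False)


def _make_trace(
    arrays: ModelArrays, history: np.ndarray, convention: Convention
) -> pd.DataFrame:
    """Tidy per-cycle trace: occupancy plus discounted accruals."""
    w_pre, w_post = convention.weights()
    r = arrays.discount_rate
    rows = []
    for t in range(arrays.horizon + 1):
        if t == 0:
            disc_cost = np.zeros(N_STATES)
            disc_qaly = np.zeros(N_STATES)
        else:
            acc = w_pre * history[t - 1] + w_post * history[t]
            d = (1.0 + r) ** (-t)
            disc_cost = d * acc * arrays.state_costs
            disc_qaly = d * acc * arrays.utilities
        for i, s in enumerate(STATE_SPACE):
            rows.append(
                {
                    "cycle": t,
                    "state": s.state.value,
                    "aki_history": s.aki_history,
                    "occupancy": history[t, i],
                    "disc_cost": disc_cost[i],
                    "disc_qaly": disc_qaly[i],
                }
            )
    return pd.DataFrame(rows)


def evaluate_strategy(
    bundle: ModelBundle,
    strategy: str,
    convention: Convention = DEFAULT_CONVENTION,
) -> StrategyOutcome:
    """Expected discounted cost and QALYs for one strategy."""
    arrays = compile_arrays(bundle)
    i = arrays.strategy_names.index(strategy)
    cost, qaly, history = _evaluate_one(
        arrays, arrays.p_aki[i], arrays.upfront[i], convention
    )
    return StrategyOutcome(
        strategy=strategy,
        total_cost=cost,
        total_qaly=qaly,
        trace=_make_trace(arrays, history, convention),
    )


def evaluate_all(
    bundle_or_arrays: ModelBundle | ModelArrays,
    convention: Convention = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Expected (cost, qaly) per strategy, indexed by strategy name."""
    arrays = (
        bundle_or_arrays
        if isinstance(bundle_or_arrays, ModelArrays)
        else compile_arrays(bundle_or_arrays)
    )
    records = {}
    for i, name in enumerate(arrays.strategy_names):
        cost, qaly, _ = _evaluate_one(
            arrays, arrays.p_aki[i], arrays.upfront[i], convention
        )
        records[name] = {"cost": cost, "qaly": qaly}
    return pd.DataFrame.from_dict(records, orient="index").rename_axis("strategy")
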