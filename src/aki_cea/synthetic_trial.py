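"""Synthetic patient-level trial data and parameter re-estimation.

The generator emulates the data-generating process the cohort model
assumes: per-arm cohorts with Bernoulli 7-day AKI events, categorical
30-day dispositions conditional on AKI status, and yearly categorical
state transitions stratified by AKI history (using the single averaged
annual table).  ``estimate_parameters`` closes the loop by re-estimating
every transition probability from the records as an empirical proportion
with a Wald 95% confidence interval, yielding a new model bundle.

Seeding: one master seed; each arm gets a deterministic substream keyed
by its name, so adding or removing an arm leaves the others unchanged.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import DEFAULT_CONVENTION, Convention, build_transition_matrix, compile_arrays
from .parameters import ModelBundle, ProbEstimate
from .states import HEALTH_STATES, PERMITTED_ANNUAL_EXITS, STATE_INDEX, HealthState, StratifiedState

__all__ = [
    "simulate_trial",
    "estimate_parameters",
    "pooled_aki_estimate",
    "wald_ci",
    "patient_outcomes",
    "write_records",
    "read_records",
    "EmptyCellError",
]

RECORD_COLUMNS = ["patient_id", "strategy", "aki_at_7d", "state_30d"]


class EmptyCellError(ValueError):
    """A conditioning cell required for estimation contains no patients."""


def _arm_substream(seed: int, arm: str) -> np.random.Generator:
    """Deterministic per-arm RNG substream keyed by the arm name."""
    digest = hashlib.sha256(arm.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _draw_categorical(rng: np.random.Generator, probs: np.ndarray, n: int) -> np.ndarray:
    """Vectorized categorical draw; returns indices into ``probs``."""
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(n), side="right")


def simulate_trial(bundle: ModelBundle, n_per_arm: int, seed: int) -> pd.DataFrame:
    """Patient-level records for all four arms.

    Columns: ``patient_id``, ``strategy``, ``aki_at_7d`` (bool),
    ``state_30d`` and ``state_year1..H`` (health-state labels).  Once a
    patient dies all later entries are DEATH.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    arrays = compile_arrays(bundle)
    horizon = arrays.horizon
    P = arrays.transition
    cum_rows = np.cumsum(P, axis=1)
    cum_rows[:, -1] = 1.0

    frames = []
    labels = np.array([s.value for s in HEALTH_STATES])
    for arm_idx, arm in enumerate(arrays.strategy_names):
        rng = _arm_substream(seed, arm)
        n = n_per_arm
        aki = rng.random(n) < arrays.p_aki[arm_idx]
        state30 = np.empty(n, dtype=int)
        n_aki = int(aki.sum())
        state30[aki] = _draw_categorical(rng, arrays.d30_aki, n_aki)
        state30[~aki] = _draw_categorical(rng, arrays.d30_no_aki, n - n_aki)

        # stratified state indices: AKI-history block first (offset 0), else 4
        current = state30 + np.where(aki, 0, 4)
        yearly = np.empty((horizon, n), dtype=int)
        for t in range(horizon):
            u = rng.random(n)
            nxt = np.empty(n, dtype=int)
            for s in np.unique(current):
                mask = current == s
                nxt[mask] = np.searchsorted(cum_rows[s], u[mask], side="right")
            yearly[t] = nxt
            current = nxt

        frame = pd.DataFrame(
            {
                "patient_id": [f"{arm}-{i:07d}" for i in range(n)],
                "strategy": arm,
                "aki_at_7d": aki,
                "state_30d": labels[state30],
            }
        )
        for t in range(horizon):
            frame[f"state_year{t + 1}"] = labels[yearly[t] % 4]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def wald_ci(successes: int, n: int) -> ProbEstimate:
    """Empirical proportion with a Wald 95% CI truncated to [0, 1]."""
    if n <= 0:
        raise EmptyCellError("cannot estimate a proportion from zero observations")
    p = successes / n
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return ProbEstimate(mean=p, ci_low=max(0.0, p - half), ci_high=min(1.0, p + half))


def pooled_aki_estimate(records: pd.DataFrame) -> ProbEstimate:
    """AKI proportion pooled over all arms."""
    return wald_ci(int(records["aki_at_7d"].sum()), len(records))


def _year_columns(records: pd.DataFrame) -> list[str]:
    cols = sorted(
        (c for c in records.columns if c.startswith("state_year")),
        key=lambda c: int(c.removeprefix("state_year")),
    )
    if not cols:
        raise ValueError("records contain no yearly state columns")
    return cols


def estimate_parameters(records: pd.DataFrame, template: ModelBundle) -> ModelBundle:
    """Re-estimate all probability parameters from patient records.

    AKI probabilities are per arm; 30-day dispositions condition on AKI
    status; annual transitions pool the yearly moves, stratified by AKI
    history, with the stay probability left as the residual.  Economic
    inputs and upfront costs are copied from ``template`` (they are not
    identifiable from outcome records).  Raises :class:`EmptyCellError`
    naming any conditioning cell with no patients.
    """
    data = template.model_dump(mode="json")
    year_cols = _year_columns(records)

    for arm in sorted(template.strategies):
        sub = records[records["strategy"] == arm]
        if sub.empty:
            raise EmptyCellError(f"arm {arm!r} has no patients")
        est = wald_ci(int(sub["aki_at_7d"].sum()), len(sub))
        data["strategies"][arm]["p_aki"] = est.model_dump()

    for status, mask in (("aki", records["aki_at_7d"]), ("no_aki", ~records["aki_at_7d"])):
        sub = records[mask]
        if sub.empty:
            raise EmptyCellError(f"thirty_day.{status}: no patients")
        counts = sub["state_30d"].value_counts()
        for state in HEALTH_STATES:
            est = wald_ci(int(counts.get(state.value, 0)), len(sub))
            data["transitions"]["thirty_day"][status][state.value] = est.model_dump()

    # annual transitions pooled over cycles, stratified by AKI history
    for hist_key, hist_mask in (("after_aki", records["aki_at_7d"]), ("no_aki", ~records["aki_at_7d"])):
        sub = records[hist_mask]
        prev_cols = ["state_30d"] + year_cols[:-1]
        origins = pd.concat([sub[c] for c in prev_cols], ignore_index=True)
        dests = pd.concat([sub[c] for c in year_cols], ignore_index=True)
        for origin, permitted in PERMITTED_ANNUAL_EXITS.items():
            at_risk = origins == origin.value
            n_risk = int(at_risk.sum())
            if n_risk == 0:
                raise EmptyCellError(
                    f"annual.{hist_key}.{origin.value}: no patients at risk"
                )
            moved = dests[at_risk]
            for dest in permitted:
                est = wald_ci(int((moved == dest.value).sum()), n_risk)
                data["transitions"]["annual"][hist_key][origin.value][dest.value] = (
                    est.model_dump()
                )
    return ModelBundle.model_validate(data)


def patient_outcomes(
    records: pd.DataFrame,
    bundle: ModelBundle,
    convention: Convention = DEFAULT_CONVENTION,
) -> pd.DataFrame:
    """Per-patient discounted cost and QALY accrual (microsimulation view).

    Applies the same accrual convention as the cohort engine: upfront and
    AKI episode costs at time zero, then per-cycle state costs and
    utilities on the pre- and/or post-transition state.
    """
    arrays = compile_arrays(bundle)
    econ = bundle.economics
    year_cols = _year_columns(records)
    w_pre, w_post = convention.weights()
    r = arrays.discount_rate

    util = {s.value: econ.utilities[s].mean for s in HEALTH_STATES}
    cost = {s.value: econ.annual_state_costs[s].mean for s in HEALTH_STATES}
    upfront = {n: bundle.strategies[n].upfront_cost.mean for n in bundle.strategies}

    total_cost = records["strategy"].map(upfront).to_numpy(dtype=float)
    total_cost += records["aki_at_7d"].to_numpy() * econ.aki_episode_cost.mean
    total_qaly = np.zeros(len(records))
    path_cols = ["state_30d"] + year_cols
    for t in range(1, len(path_cols)):
        pre = records[path_cols[t - 1]].map(util).to_numpy()
        post = records[path_cols[t]].map(util).to_numpy()
        pre_c = records[path_cols[t - 1]].map(cost).to_numpy()
        post_c = records[path_cols[t]].map(cost).to_numpy()
        d = (1.0 + r) ** (-t)
        total_qaly += d * (w_pre * pre + w_post * post)
        total_cost += d * (w_pre * pre_c + w_post * post_c)
    return pd.DataFrame(
        {
            "patient_id": records["patient_id"],
            "strategy": records["strategy"],
            "cost": total_cost,
            "qaly": total_qaly,
        }
    )


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """CSV export with the documented header (round-trips with read_records)."""
    records.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file missing columns {missing}")
    df["aki_at_7d"] = df["aki_at_7d"].astype(bool)
    return df
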