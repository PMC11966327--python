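"""Validated model inputs and the declarative model file.

The model bundle collects everything the analysis needs: one AKI
probability and per-person upfront cost per implementation strategy,
30-day disposition distributions conditional on AKI status, annual
transition probabilities stratified by AKI history, and the economic
inputs (utilities, costs, discount rate, horizon, willingness to pay).

Probabilities are stored as fractions.  The canonical fixture shipped
with the package (``data/transcatheter_aki_model.yaml``) reproduces the
trial-derived inputs verbatim; ``units: percent`` in a model file is
accepted and converted at load.
"""

from __future__ import annotations

import importlib.resources
import warnings
from pathlib import Path
from typing import Dict, Iterator, Literal, Mapping, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .distributions import (
    PointMass,
    PsaDistribution,
    beta_from_mean_ci,
    gamma_from_mean_range,
)
from .states import HEALTH_STATES, PERMITTED_ANNUAL_EXITS, HealthState

__all__ = [
    "ProbEstimate",
    "CostEstimate",
    "StrategySpec",
    "TransitionTables",
    "EconomicInputs",
    "ModelBundle",
    "ModelValidationError",
    "ParameterRef",
    "STRATEGY_NAMES",
    "load_model",
    "write_model",
    "default_model_path",
]

StrategyName = Literal[
    "assistance",
    "assistance_surveillance",
    "collaborative",
    "collaborative_surveillance",
]

STRATEGY_NAMES: tuple[str, ...] = (
    "assistance",
    "assistance_surveillance",
    "collaborative",
    "collaborative_surveillance",
)

AkiStatus = Literal["aki", "no_aki"]
HistKey = Literal["after_aki", "no_aki"]

#: A 30-day disposition row may sum to 1 +/- this before it is an error;
#: within the tolerance it is renormalized proportionally with a warning
#: (the printed no-AKI row sums to 0.999, a rounding artifact).
THIRTY_DAY_SUM_TOL = 0.005


class ModelValidationError(ValueError):
    """A model input violates an invariant; the message names the parameter."""


class ProbEstimate(BaseModel):
    """A probability with a (possibly degenerate) 95% confidence interval."""

    model_config = ConfigDict(frozen=True)

    mean: float
    ci_low: float | None = None
    ci_high: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "ProbEstimate":
        lo = self.mean if self.ci_low is None else self.ci_low
        hi = self.mean if self.ci_high is None else self.ci_high
        object.__setattr__(self, "ci_low", lo)
        object.__setattr__(self, "ci_high", hi)
        if not (0.0 <= lo <= self.mean <= hi <= 1.0):
            raise ValueError(
                f"probability estimate violates 0 <= ci_low <= mean <= ci_high <= 1: "
                f"mean={self.mean}, ci=({lo}, {hi})"
            )
        return self

    def scaled(self, factor: float) -> "ProbEstimate":
        return ProbEstimate(
            mean=self.mean * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
        )

    def psa_distribution(self) -> PsaDistribution:
        if self.ci_low == self.ci_high or self.mean in (0.0, 1.0):
            return PointMass(self.mean)
        return beta_from_mean_ci(self.mean, self.ci_low, self.ci_high)


class CostEstimate(BaseModel):
    """A money amount (2020 USD) with a low/high sensitivity range."""

    model_config = ConfigDict(frozen=True)

    mean: float = Field(ge=0.0)
    low: float | None = None
    high: float | None = None

    @model_validator(mode="after")
    def _check(self) -> "CostEstimate":
        lo = self.mean if self.low is None else self.low
        hi = self.mean if self.high is None else self.high
        object.__setattr__(self, "low", lo)
        object.__setattr__(self, "high", hi)
        if not (0.0 <= lo <= self.mean <= hi):
            raise ValueError(
                f"cost estimate violates 0 <= low <= mean <= high: "
                f"mean={self.mean}, range=({lo}, {hi})"
            )
        return self

    def psa_distribution(self) -> PsaDistribution:
        if self.low == self.high or self.mean == 0.0:
            return PointMass(self.mean)
        return gamma_from_mean_range(self.mean, self.low, self.high)


class StrategySpec(BaseModel):
    """One implementation strategy: AKI probability and upfront cost."""

    model_config = ConfigDict(frozen=True)

    name: StrategyName
    p_aki: ProbEstimate
    upfront_cost: CostEstimate


class TransitionTables(BaseModel):
    """30-day dispositions by AKI status and annual transitions by history.

    ``thirty_day[status][state]`` is the probability of occupying ``state``
    at day 30 given AKI status; each row must sum to one within
    ``THIRTY_DAY_SUM_TOL`` and is renormalized proportionally at load.

    ``annual[hist][origin][dest]`` are yearly exit probabilities; the stay
    probability is the residual and must be non-negative.  Backward
    transitions (e.g. CKD to normal) are structurally absent.
    """

    model_config = ConfigDict(frozen=True)

    thirty_day: Dict[AkiStatus, Dict[HealthState, ProbEstimate]]
    annual: Dict[HistKey, Dict[HealthState, Dict[HealthState, ProbEstimate]]]

    @model_validator(mode="after")
    def _check(self) -> "TransitionTables":
        for status in ("aki", "no_aki"):
            if status not in self.thirty_day:
                raise ValueError(f"thirty_day.{status}: missing disposition row")
            row = self.thirty_day[status]
            missing = [s.value for s in HEALTH_STATES if s not in row]
            if missing:
                raise ValueError(f"thirty_day.{status}: missing states {missing}")
            total = sum(p.mean for p in row.values())
            if abs(total - 1.0) > THIRTY_DAY_SUM_TOL:
                raise ValueError(
                    f"thirty_day.{status}: disposition probabilities sum to "
                    f"{total:.6g}, outside 1 +/- {THIRTY_DAY_SUM_TOL}"
                )
            if total != 1.0:
                if abs(total - 1.0) > 1e-9:
                    warnings.warn(
                        f"thirty_day.{status}: row sums to {total:.6g}; "
                        "renormalizing proportionally",
                        stacklevel=2,
                    )
                object.__setattr__(
                    self,
                    "thirty_day",
                    {
                        **self.thirty_day,
                        status: {s: p.scaled(1.0 / total) for s, p in row.items()},
                    },
                )
        for hist in ("after_aki", "no_aki"):
            if hist not in self.annual:
                raise ValueError(f"annual.{hist}: missing transition table")
            table = self.annual[hist]
            for origin, permitted in PERMITTED_ANNUAL_EXITS.items():
                if origin not in table:
                    raise ValueError(f"annual.{hist}.{origin.value}: missing row")
                exits = table[origin]
                for dest in exits:
                    if dest not in permitted:
                        raise ValueError(
                            f"annual.{hist}.{origin.value}->{dest.value}: "
                            "structurally forbidden transition"
                        )
                for dest in permitted:
                    if dest not in exits:
                        raise ValueError(
                            f"annual.{hist}.{origin.value}->{dest.value}: missing"
                        )
                exit_sum = sum(p.mean for p in exits.values())
                if exit_sum > 1.0:
                    raise ValueError(
                        f"annual.{hist}.{origin.value}: exit probabilities sum to "
                        f"{exit_sum:.6g} > 1 (negative stay residual)"
                    )
        return self

    def stay_probability(self, origin: HealthState, aki_history: bool) -> float:
        """Residual probability of remaining in ``origin`` for one cycle."""
        hist = "after_aki" if aki_history else "no_aki"
        return 1.0 - sum(p.mean for p in self.annual[hist][origin].values())


class EconomicInputs(BaseModel):
    """Utilities, costs, discounting, horizon and willingness to pay."""

    model_config = ConfigDict(frozen=True)

    utilities: Dict[HealthState, ProbEstimate]
    aki_episode_cost: CostEstimate
    annual_state_costs: Dict[HealthState, CostEstimate]
    discount_rate: float = Field(ge=0.0)
    horizon_years: int = Field(ge=1)
    wtp: float = Field(gt=0.0)

    @model_validator(mode="after")
    def _check(self) -> "EconomicInputs":
        utilities = dict(self.utilities)
        utilities.setdefault(HealthState.DEATH, ProbEstimate(mean=0.0))
        if utilities[HealthState.DEATH].mean != 0.0:
            raise ValueError("utilities.DEATH must be 0")
        for s in (HealthState.NORMAL, HealthState.CKD, HealthState.ESRD):
            if s not in utilities:
                raise ValueError(f"utilities.{s.value}: missing")
        object.__setattr__(self, "utilities", utilities)
        costs = dict(self.annual_state_costs)
        for s in (HealthState.NORMAL, HealthState.DEATH):
            costs.setdefault(s, CostEstimate(mean=0.0))
            if costs[s].mean != 0.0:
                raise ValueError(f"annual_state_costs.{s.value} must be 0")
        for s in (HealthState.CKD, HealthState.ESRD):
            if s not in costs:
                raise ValueError(f"annual_state_costs.{s.value}: missing")
        object.__setattr__(self, "annual_state_costs", costs)
        return self


class ParameterRef(BaseModel):
    """Addressable uncertain parameter with its base value and range."""

    model_config = ConfigDict(frozen=True)

    name: str
    kind: Literal["probability", "utility", "cost"]
    base: float
    low: float
    high: float

    @property
    def has_range(self) -> bool:
        return self.low != self.high


class ModelBundle(BaseModel):
    """The full declarative model: strategies, transitions, economics."""

    model_config = ConfigDict(frozen=True)

    strategies: Dict[str, StrategySpec]
    transitions: TransitionTables
    economics: EconomicInputs

    @model_validator(mode="after")
    def _check(self) -> "ModelBundle":
        if set(self.strategies) != set(STRATEGY_NAMES):
            raise ValueError(
                f"strategies must be exactly {sorted(STRATEGY_NAMES)}, "
                f"got {sorted(self.strategies)}"
            )
        for name, spec in self.strategies.items():
            if spec.name != name:
                raise ValueError(f"strategies.{name}: name field is {spec.name!r}")
        return self

    # ------------------------------------------------------------------
    # parameter addressing (used by OWSA and PSA)
    # ------------------------------------------------------------------
    def parameters(self) -> Dict[str, ParameterRef]:
        """Flat registry of every uncertain parameter, keyed by dotted path."""
        out: Dict[str, ParameterRef] = {}

        def add(name: str, kind: str, base: float, low: float, high: float) -> None:
            out[name] = ParameterRef(name=name, kind=kind, base=base, low=low, high=high)

        for sname, spec in sorted(self.strategies.items()):
            add(f"p_aki.{sname}", "probability",
                spec.p_aki.mean, spec.p_aki.ci_low, spec.p_aki.ci_high)
            add(f"upfront_cost.{sname}", "cost",
                spec.upfront_cost.mean, spec.upfront_cost.low, spec.upfront_cost.high)
        for status in ("aki", "no_aki"):
            for state in HEALTH_STATES:
                p = self.transitions.thirty_day[status][state]
                add(f"thirty_day.{status}.{state.value}", "probability",
                    p.mean, p.ci_low, p.ci_high)
        for hist in ("after_aki", "no_aki"):
            for origin, permitted in PERMITTED_ANNUAL_EXITS.items():
                for dest in permitted:
                    p = self.transitions.annual[hist][origin][dest]
                    add(f"annual.{hist}.{origin.value}.{dest.value}", "probability",
                        p.mean, p.ci_low, p.ci_high)
        for state in (HealthState.NORMAL, HealthState.CKD, HealthState.ESRD):
            u = self.economics.utilities[state]
            add(f"utility.{state.value}", "utility", u.mean, u.ci_low, u.ci_high)
        c = self.economics.aki_episode_cost
        add("cost.aki_episode", "cost", c.mean, c.low, c.high)
        for state in (HealthState.CKD, HealthState.ESRD):
            cc = self.economics.annual_state_costs[state]
            add(f"cost.{state.value}", "cost", cc.mean, cc.low, cc.high)
        return out

    def with_parameter(self, name: str, value: float) -> "ModelBundle":
        """Copy of the bundle with one parameter's base value replaced.

        Setting a 30-day disposition probability rescales the other three
        entries of its row proportionally so the row still sums to one.
        Annual rows keep their other exits; a resulting negative stay
        residual is a :class:`ModelValidationError`.
        """
        if name not in self.parameters():
            raise ModelValidationError(f"unknown parameter {name!r}")
        data = self.model_dump()
        parts = name.split(".")
        try:
            if parts[0] == "p_aki":
                _set_prob(data["strategies"][parts[1]]["p_aki"], value, name)
            elif parts[0] == "upfront_cost":
                _set_cost(data["strategies"][parts[1]]["upfront_cost"], value, name)
            elif parts[0] == "thirty_day":
                status, state = parts[1], parts[2]
                row = data["transitions"]["thirty_day"][status]
                _set_prob(row[state], value, name)
                others = [s for s in row if s != state]
                rest = sum(row[s]["mean"] for s in others)
                target = 1.0 - value
                if target < 0.0:
                    raise ModelValidationError(f"{name}: value {value} exceeds 1")
                if rest > 0.0:
                    for s in others:
                        factor = target / rest
                        row[s]["mean"] *= factor
                        row[s]["ci_low"] *= factor
                        row[s]["ci_high"] *= factor
            elif parts[0] == "annual":
                hist, origin, dest = parts[1], parts[2], parts[3]
                _set_prob(data["transitions"]["annual"][hist][origin][dest], value, name)
            elif parts[0] == "utility":
                _set_prob(data["economics"]["utilities"][parts[1]], value, name)
            elif parts[0] == "cost":
                key = parts[1]
                if key == "aki_episode":
                    _set_cost(data["economics"]["aki_episode_cost"], value, name)
                else:
                    _set_cost(data["economics"]["annual_state_costs"][key], value, name)
            return ModelBundle.model_validate(data)
        except (ValueError, KeyError) as exc:
            if isinstance(exc, ModelValidationError):
                raise
            raise ModelValidationError(f"setting {name}={value} failed: {exc}") from exc

    def psa_distributions(self) -> Dict[str, PsaDistribution]:
        """Moment-matched sampling distribution for every parameter."""
        dists: Dict[str, PsaDistribution] = {}
        for name, ref in self.parameters().items():
            if not ref.has_range:
                dists[name] = PointMass(ref.base)
            elif ref.kind == "cost":
                dists[name] = gamma_from_mean_range(ref.base, ref.low, ref.high)
            else:
                dists[name] = beta_from_mean_ci(ref.base, ref.low, ref.high)
        return dists

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        data = self.model_dump(mode="json")
        data["units"] = "fraction"
        return data


def _set_prob(node: dict, value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ModelValidationError(f"{name}: probability {value} outside [0, 1]")
    node["mean"] = value
    node["ci_low"] = min(node["ci_low"], value)
    node["ci_high"] = max(node["ci_high"], value)


def _set_cost(node: dict, value: float, name: str) -> None:
    if value < 0.0:
        raise ModelValidationError(f"{name}: cost {value} is negative")
    node["mean"] = value
    node["low"] = min(node["low"], value)
    node["high"] = max(node["high"], value)


def _convert_percent(data: dict) -> dict:
    """Convert probability fields from percent to fractions in place."""

    def conv(node: dict) -> None:
        for key in ("mean", "ci_low", "ci_high"):
            if node.get(key) is not None:
                node[key] /= 100.0

    for spec in data.get("strategies", {}).values():
        conv(spec["p_aki"])
    for row in data.get("transitions", {}).get("thirty_day", {}).values():
        for node in row.values():
            conv(node)
    for table in data.get("transitions", {}).get("annual", {}).values():
        for row in table.values():
            for node in row.values():
                conv(node)
    return data


def default_model_path() -> Path:
    """Path of the packaged canonical model fixture."""
    return Path(
        importlib.resources.files("aki_cea").joinpath(
            "data/transcatheter_aki_model.yaml"
        )
    )


def load_model(path: str | Path | None = None) -> ModelBundle:
    """Load and validate a declarative model file (YAML or JSON).

    ``units: percent`` at the top level converts all probability entries
    (AKI rates, 30-day dispositions, annual transitions) from percent;
    utilities and costs are never rescaled.
    """
    path = default_model_path() if path is None else Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ModelValidationError(f"model file {path} does not contain a mapping")
    units = data.pop("units", "fraction")
    if units == "percent":
        data = _convert_percent(data)
    elif units != "fraction":
        raise ModelValidationError(f"unknown units {units!r} (use fraction|percent)")
    try:
        return ModelBundle.model_validate(data)
    except ValueError as exc:
        raise ModelValidationError(str(exc)) from exc


def write_model(bundle: ModelBundle, path: str | Path) -> None:
    """Write a bundle back to YAML with full numeric precision."""
    with open(path, "w") as fh:
        yaml.safe_dump(bundle.to_dict(), fh, sort_keys=True)
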