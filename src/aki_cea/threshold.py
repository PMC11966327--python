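"""Break-even analysis on the upfront intervention cost.

Finds the per-person upfront cost of a strategy at which a comparator
attains equal net monetary benefit at a given willingness to pay.  NMB is
affine in the upfront cost with slope -1 (the cost enters the total once,
undiscounted, and nothing else depends on it), so the threshold has the
closed form ``c* = c_base + NMB_varied(base) - NMB_comparator``.  A
bisection solver is shipped alongside to validate the affine assumption
and to generalize should the cost ever enter nonlinearly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .cea import compute_nmb
from .cohort import DEFAULT_CONVENTION, Convention, _evaluate_one, compile_arrays
from .parameters import ModelBundle

__all__ = ["ThresholdResult", "threshold_cost"]

#: Agreement tolerance between the closed form and the bisection, in USD.
TOL_USD = 1e-6

#: Upper bracket width for the bisection search.
SEARCH_SPAN = 1e6


class NoHeadroomError(ValueError):
    """The varied strategy is not preferred at base case."""


@dataclass(frozen=True)
class ThresholdResult:
    varied: str
    comparator: str
    wtp: float
    threshold: float
    method: Literal["closed_form", "bisection"]
    residual: float  # NMB difference at the reported threshold


def _nmb_at_upfront(arrays, idx: int, upfront: float, wtp: float, convention) -> float:
    cost, qaly, _ = _evaluate_one(arrays, arrays.p_aki[idx], upfront, convention)
    return compute_nmb(qaly, cost, wtp)


def threshold_cost(
    bundle: ModelBundle,
    varied: str,
    comparator: str,
    wtp: float,
    convention: Convention = DEFAULT_CONVENTION,
    method: Literal["closed_form", "bisection"] = "closed_form",
) -> ThresholdResult:
    """Upfront cost of ``varied`` equating its NMB with ``comparator``'s.

    Raises :class:`NoHeadroomError` if the varied strategy does not have
    the higher NMB at its base-case cost.
    """
    if varied == comparator:
        raise ValueError("varied strategy and comparator must be distinct")
    arrays = compile_arrays(bundle)
    iv = arrays.strategy_names.index(varied)
    ic = arrays.strategy_names.index(comparator)
    c_base = arrays.upfront[iv]
    nmb_comp = _nmb_at_upfront(arrays, ic, arrays.upfront[ic], wtp, convention)

    def gap(c: float) -> float:
        return _nmb_at_upfront(arrays, iv, c, wtp, convention) - nmb_comp

    headroom = gap(c_base)
    if headroom < 0.0:
        raise NoHeadroomError(
            f"{varied} is not preferred over {comparator} at its base-case "
            f"upfront cost (NMB gap {headroom:.2f} $)"
        )

    if method == "closed_form":
        # NMB_varied is affine in the upfront cost with slope -1
        threshold = float(c_base + headroom)
    else:
        lo, hi = float(c_base), float(c_base + SEARCH_SPAN)
        if gap(hi) > 0.0:
            raise ValueError(
                f"no sign change within [{lo:.2f}, {hi:.2f}]; threshold above bracket"
            )
        while hi - lo > TOL_USD / 4.0:
            mid = 0.5 * (lo + hi)
            if gap(mid) >= 0.0:
                lo = mid
            else:
                hi = mid
        threshold = 0.5 * (lo + hi)
    return ThresholdResult(
        varied=varied,
        comparator=comparator,
        wtp=wtp,
        threshold=threshold,
        method=method,
        residual=gap(threshold),
    )
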