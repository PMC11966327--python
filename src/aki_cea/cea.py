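"""Cost-effectiveness league table: increments, dominance, ICERs, NMB."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["compute_nmb", "build_cea_table", "render_cea_table"]


def compute_nmb(effect: float, cost: float, wtp: float) -> float:
    """Net monetary benefit: effectiveness x willingness-to-pay - cost."""
    return effect * wtp - cost


def _strongly_dominated(df: pd.DataFrame) -> pd.Series:
    """True where some other strategy costs no more and yields no fewer QALYs,
    with at least one strict inequality."""
    dominated = pd.Series(False, index=df.index)
    for a in df.index:
        for b in df.index:
            if a == b:
                continue
            le_cost = df.loc[b, "cost"] <= df.loc[a, "cost"]
            ge_qaly = df.loc[b, "qaly"] >= df.loc[a, "qaly"]
            strict = (df.loc[b, "cost"] < df.loc[a, "cost"]) or (
                df.loc[b, "qaly"] > df.loc[a, "qaly"]
            )
            if le_cost and ge_qaly and strict:
                dominated[a] = True
                break
    return dominated


def _frontier(df: pd.DataFrame) -> list[str]:
    """Efficiency frontier after removing strong and extended dominance.

    Candidates are sorted by cost; extended dominance removes strategies
    whose ICER exceeds that of the next more effective option.
    """
    cand = df[~_strongly_dominated(df)].sort_values(["cost", "qaly"]).index.tolist()
    changed = True
    while changed and len(cand) > 2:
        changed = False
        for k in range(1, len(cand) - 1):
            lo, mid, hi = cand[k - 1], cand[k], cand[k + 1]
            icer_mid = _icer(df, lo, mid)
            icer_hi = _icer(df, mid, hi)
            if icer_mid is not None and icer_hi is not None and icer_mid > icer_hi:
                cand.pop(k)
                changed = True
                break
    return cand


def _icer(df: pd.DataFrame, a: str, b: str) -> float | None:
    dq = df.loc[b, "qaly"] - df.loc[a, "qaly"]
    if dq == 0:
        return None
    return (df.loc[b, "cost"] - df.loc[a, "cost"]) / dq


def build_cea_table(
    results: Mapping[str, tuple[float, float]] | pd.DataFrame,
    reference: str,
    wtp: float,
) -> pd.DataFrame:
    """League table with increments vs the reference, dominance labels and NMB.

    Increments are reported as (strategy - reference), so when the reference
    is the dominant strategy the dominated rows show positive incremental
    cost and negative incremental effect.  ICERs are reported only between
    adjacent strategies on the efficiency frontier.
    """
    if isinstance(results, pd.DataFrame):
        df = results[["cost", "qaly"]].copy()
    else:
        names = list(results)
        if len(set(names)) != len(names):
            raise ValueError("duplicate strategy names")
        df = pd.DataFrame(
            [{"strategy": n, "cost": c, "qaly": q} for n, (c, q) in results.items()]
        ).set_index("strategy")
    if df.index.duplicated().any():
        raise ValueError("duplicate strategy names")
    if len(df) < 2:
        raise ValueError("need at least two strategies")
    if reference not in df.index:
        raise ValueError(f"reference strategy {reference!r} not in results")

    df = df.sort_values(["cost", "qaly"], ascending=[True, False])
    df["incremental_cost"] = df["cost"] - df.loc[reference, "cost"]
    df["incremental_qaly"] = df["qaly"] - df.loc[reference, "qaly"]
    df["nmb"] = compute_nmb(df["qaly"], df["cost"], wtp)

    dominated = _strongly_dominated(df)
    labels = pd.Series("non-dominated", index=df.index)
    labels[dominated] = "dominated"
    for a in df.index:
        if dominated[a]:
            continue
        # dominant = dominates every other strategy pairwise
        if all(
            df.loc[a, "cost"] <= df.loc[b, "cost"]
            and df.loc[a, "qaly"] >= df.loc[b, "qaly"]
            and (
                df.loc[a, "cost"] < df.loc[b, "cost"]
                or df.loc[a, "qaly"] > df.loc[b, "qaly"]
            )
            for b in df.index
            if b != a
        ):
            labels[a] = "dominant"
    df["dominance"] = labels

    frontier = _frontier(df)
    df["icer"] = np.nan
    for prev, cur in zip(frontier, frontier[1:]):
        icer = _icer(df, prev, cur)
        if icer is not None:
            df.loc[cur, "icer"] = icer

    # preferred strategy for reporting: max NMB, ties by cost then name
    order = df.sort_values(["nmb", "cost"], ascending=[False, True]).index
    ties = df.loc[order, "nmb"] == df.loc[order[0], "nmb"]
    preferred = sorted(order[ties.values])[0] if ties.sum() > 1 else order[0]
    df.attrs["preferred"] = preferred
    df.attrs["reference"] = reference
    df.attrs["wtp"] = wtp
    return df


def render_cea_table(table: pd.DataFrame) -> str:
    """Aligned text rendering: money to 2 d.p., QALYs to 3 d.p."""
    lines = [
        f"{'Strategy':28s} {'Dominance':13s} {'Cost, $':>10s} "
        f"{'Incr cost, $':>12s} {'QALYs':>7s} {'Incr QALYs':>10s} {'NMB, $':>12s}"
    ]
    for name, row in table.iterrows():
        inc_c = "NA" if name == table.attrs.get("reference") else f"{row.incremental_cost:.2f}"
        inc_q = "NA" if name == table.attrs.get("reference") else f"{row.incremental_qaly:.3f}"
        lines.append(
            f"{name:28s} {row.dominance:13s} {row.cost:10.2f} "
            f"{inc_c:>12s} {row.qaly:7.3f} {inc_q:>10s} {row.nmb:12.2f}"
        )
    return "\n".join(lines)
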