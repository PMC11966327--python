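"""Threshold (break-even) analysis on the upfront intervention cost.

Solves for the per-person upfront cost of collaborative-with-
surveillance at which each assistance comparator attains equal net
monetary benefit, at willingness-to-pay $50,000 and $100,000 per QALY,
by closed form with bisection cross-validation.  Writes the table to
results/threshold/.
"""

from pathlib import Path

from aki_cea import load_model, threshold_cost

OUT = Path(__file__).resolve().parents[1] / "results" / "threshold"
VARIED = "collaborative_surveillance"


def main() -> None:
    bundle = load_model()
    OUT.mkdir(parents=True, exist_ok=True)
    lines = ["comparator,wtp,threshold_cost,bisection_agreement"]
    print(f"{'Comparator':26s} {'WTP':>9s} {'Threshold, $':>13s}")
    for comparator in ("assistance_surveillance", "assistance"):
        for wtp in (50_000.0, 100_000.0):
            closed = threshold_cost(bundle, VARIED, comparator, wtp)
            bisect = threshold_cost(bundle, VARIED, comparator, wtp, method="bisection")
            gap = abs(closed.threshold - bisect.threshold)
            lines.append(f"{comparator},{wtp:.0f},{closed.threshold:.6f},{gap:.2e}")
            print(f"{comparator:26s} {wtp:9,.0f} {closed.threshold:13.2f}")
    (OUT / "threshold.csv").write_text("\n".join(lines) + "\n")
    print(f"\nwrote {OUT / 'threshold.csv'}")


if __name__ == "__main__":
    main()
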