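"""Base-case evaluation: expected 3-year cost and QALYs per strategy.

Runs the decision tree + Markov cohort model on the canonical inputs
under the shipped accrual convention and writes the league table
(costs, QALYs, increments vs the dominant strategy, dominance labels,
NMB at $100,000/QALY) to results/basecase/.
"""

from pathlib import Path

from aki_cea import build_cea_table, evaluate_all, load_model, render_cea_table

OUT = Path(__file__).resolve().parents[1] / "results" / "basecase"


def main() -> None:
    bundle = load_model()
    results = evaluate_all(bundle)
    table = build_cea_table(results, reference="collaborative_surveillance",
                            wtp=bundle.economics.wtp)
    OUT.mkdir(parents=True, exist_ok=True)
    table.to_csv(OUT / "league_table.csv", float_format="%.6f")
    (OUT / "league_table.txt").write_text(render_cea_table(table) + "\n")
    print(render_cea_table(table))
    print(f"\npreferred strategy: {table.attrs['preferred']}")
    print(f"wrote {OUT / 'league_table.csv'}")


if __name__ == "__main__":
    main()
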