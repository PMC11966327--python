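"""One-way and probabilistic sensitivity analysis."""

import copy

import numpy as np
import pytest

from aki_cea import ModelBundle, ceac, run_full_owsa, run_owsa, run_psa, tornado
from aki_cea.sensitivity import OwsaResult

PAIR = ("collaborative_surveillance", "assistance")
WTP = 100_000.0


def test_owsa_upfront_cost_is_exactly_linear(bundle):
    """NMB is affine in upfront cost with slope -1, so a +/-delta variation
    moves the incremental NMB by exactly -/+ delta (bar width 2*delta)."""
    delta = 5.0
    base = 12.74
    res = run_owsa(bundle, "upfront_cost.collaborative_surveillance",
                   base - delta, base + delta, PAIR, WTP)
    assert res.nmb_low - res.nmb_base == pytest.approx(delta, abs=1e-8)
    assert res.nmb_base - res.nmb_high == pytest.approx(delta, abs=1e-8)
    assert res.width == pytest.approx(2 * delta, abs=1e-8)


def test_owsa_degenerate_range_has_zero_width(bundle):
    res = run_owsa(bundle, "cost.CKD", 25322.0, 25322.0, PAIR, WTP)
    assert res.width == 0.0


def test_owsa_invalid_bound_names_the_bound(bundle):
    from aki_cea.parameters import ModelValidationError

    with pytest.raises(ModelValidationError, match="annual.after_aki.CKD.DEATH"):
        run_owsa(bundle, "annual.after_aki.CKD.DEATH", 0.223, 0.99, PAIR, WTP)


@pytest.fixture(scope="module")
def full_tornado(bundle):
    return tornado(run_full_owsa(bundle, PAIR, WTP))


def test_owsa_preferred_strategy_never_flips_within_ranges(full_tornado):
    """The dominant strategy keeps positive incremental NMB at every bound."""
    assert (full_tornado["nmb_low"] > 0).all()
    assert (full_tornado["nmb_high"] > 0).all()


def test_tornado_top_bars_are_aki_rates_and_downstream_costs(full_tornado):
    ordered = list(full_tornado["parameter"])
    assert set(ordered[:2]) == {"p_aki.assistance", "p_aki.collaborative_surveillance"}
    widths = full_tornado.set_index("parameter")["width"]
    downstream = widths[["cost.aki_episode", "cost.CKD", "cost.ESRD"]].min()
    upfront = widths[widths.index.str.startswith("upfront_cost.")]
    assert (upfront < downstream).all()


def test_owsa_parameters_outside_the_pair_have_zero_width(full_tornado):
    widths = full_tornado.set_index("parameter")["width"]
    for name in ("p_aki.collaborative", "upfront_cost.collaborative",
                 "p_aki.assistance_surveillance"):
        assert widths[name] == pytest.approx(0.0, abs=1e-9)


def test_tornado_sorts_descending_with_name_ties():
    mk = lambda name, w: OwsaResult(name, 0, 1, 0.0, w, w / 2)
    df = tornado([mk("b", 3.0), mk("a", 5.0), mk("c", 3.0)])
    assert list(df["parameter"]) == ["a", "b", "c"]
    assert list(df["width"]) == [5.0, 3.0, 3.0]


def test_tornado_requires_results():
    with pytest.raises(ValueError):
        tornado([])


# ----------------------------------------------------------------------
# probabilistic sensitivity analysis
# ----------------------------------------------------------------------


def test_psa_reproducible_given_seed(bundle):
    a = run_psa(bundle, n_samples=40, seed=7)
    b = run_psa(bundle, n_samples=40, seed=7)
    assert np.array_equal(a.costs, b.costs) and np.array_equal(a.qalys, b.qalys)
    c = run_psa(bundle, n_samples=40, seed=8)
    assert not np.array_equal(a.costs, c.costs)


def _point_mass_bundle(bundle_dict) -> ModelBundle:
    data = copy.deepcopy(bundle_dict)

    def collapse(node, keys):
        for k in keys[1:]:
            node[k] = node[keys[0]]

    for spec in data["strategies"].values():
        collapse(spec["p_aki"], ["mean", "ci_low", "ci_high"])
        collapse(spec["upfront_cost"], ["mean", "low", "high"])
    for row in data["transitions"]["thirty_day"].values():
        for node in row.values():
            collapse(node, ["mean", "ci_low", "ci_high"])
    for table in data["transitions"]["annual"].values():
        for row in table.values():
            for node in row.values():
                collapse(node, ["mean", "ci_low", "ci_high"])
    for node in data["economics"]["utilities"].values():
        collapse(node, ["mean", "ci_low", "ci_high"])
    collapse(data["economics"]["aki_episode_cost"], ["mean", "low", "high"])
    for node in data["economics"]["annual_state_costs"].values():
        collapse(node, ["mean", "low", "high"])
    return ModelBundle.model_validate(data)


def test_degenerate_psa_reproduces_base_case(bundle, bundle_dict):
    from aki_cea import evaluate_all

    point = _point_mass_bundle(bundle_dict)
    run = run_psa(point, n_samples=20, seed=3)
    base = evaluate_all(point)
    for j, name in enumerate(run.strategies):
        assert np.allclose(run.costs[:, j], base.loc[name, "cost"], rtol=1e-12)
        assert np.allclose(run.qalys[:, j], base.loc[name, "qaly"], rtol=1e-12)
    assert run.preferred_fraction("collaborative_surveillance", WTP) == 1.0


def test_ceac_frequencies_sum_to_one(bundle):
    run = run_psa(bundle, n_samples=200, seed=11)
    curve = ceac(run, [0, 25_000, 50_000, 100_000, 200_000])
    sums = curve.groupby("wtp")["acceptability"].sum()
    assert np.allclose(sums, 1.0)


def test_ceac_dominant_strategy_highly_acceptable(bundle):
    run = run_psa(bundle, n_samples=500, seed=5)
    curve = ceac(run, [50_000, 100_000]).set_index(["wtp", "strategy"])
    for w in (50_000, 100_000):
        assert curve.loc[(w, "collaborative_surveillance"), "acceptability"] >= 0.95


def test_ceac_rejects_bad_grid(bundle):
    run = run_psa(bundle, n_samples=10, seed=1)
    with pytest.raises(ValueError):
        ceac(run, [])
    with pytest.raises(ValueError):
        ceac(run, [-5.0])


def test_psa_samples_long_frame_shape(bundle):
    run = run_psa(bundle, n_samples=25, seed=2)
    df = run.to_frame()
    assert len(df) == 25 * 4
    assert set(df.columns) == {"iteration", "strategy", "cost", "qaly"}


def test_psa_dirichlet_rows_preserve_structural_zero(bundle):
    run = run_psa(bundle, n_samples=30, seed=4, dirichlet_rows=True)
    # evaluable and deterministic; structural zero checked via estimator elsewhere
    again = run_psa(bundle, n_samples=30, seed=4, dirichlet_rows=True)
    assert np.array_equal(run.costs, again.costs)
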