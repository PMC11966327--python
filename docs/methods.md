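# Methods

## Model structure

The analysis evaluates four implementation strategies for an AKI-prevention
protocol in patients undergoing cardiac catheterization: assistance,
assistance with surveillance, collaborative, and collaborative with
surveillance. A strategy enters the model through exactly two quantities —
its per-person upfront implementation cost and its 7-day AKI probability —
so the model isolates the economic value of reducing AKI.

The first 30 days are a decision tree: AKI (Bernoulli, probability
*p*<sub>s</sub>) followed by a 30-day disposition over {normal kidney
function, CKD, ESRD, death} conditional on AKI status. The cohort then runs
through a Markov model with yearly cycles for 3 years over the disposition
states *stratified by AKI history* (eight states; death carried per
stratum), because the observed annual transition probabilities differ
markedly after AKI (e.g. CKD→ESRD 4.7%/y vs 1.8%/y). Permitted annual
transitions are NORMAL→{CKD, ESRD, DEATH}, CKD→{ESRD, DEATH}, ESRD→{DEATH};
the stay probability is the residual of each row, and recovery transitions
are structurally absent. The annual table is a single 3-year average; no
per-year tables are modelled.

The horizon is deliberately short (3 years, matching the trial's follow-up);
no lifetime extrapolation is attempted.

## Parameters

All inputs live in one declarative YAML file
(`src/aki_cea/data/transcatheter_aki_model.yaml`; pydantic models are the
schema, with a generated JSON schema alongside). Probabilities are stored as
fractions (`units: percent` converts at load); money is 2020 USD.

Key defaults: AKI probabilities 13.3/11.4/12.7/7.9% (assistance,
assistance+surveillance, collaborative, collaborative+surveillance) with
their trial 95% CIs; upfront costs $2.69/$3.36/$3.97/$12.74 per person
(±25%); utilities 0.85 (normal), 0.80 (CKD), 0.70 (ESRD), 0 (death); AKI
episode cost $14,000; annual CKD cost $25,322 and ESRD cost $78,537;
discount rate 3%/y; WTP $100,000/QALY.

Two input quirks are handled explicitly:

* The printed 30-day no-AKI disposition row sums to 0.999 (a rounding
  artifact); rows within ±0.005 of 1 are renormalized proportionally at load
  with a warning, anything further off is an error.
* The AKI episode cost's published interval ($8,200–$13,750) is inconsistent
  with its published base case ($14,000). The base case is kept at $14,000
  and the sensitivity range set to ±25% of it, matching the convention used
  for the other cost inputs. This choice materially affects how closely the
  published cost totals can be reproduced (see "Calibration" below).

## Accrual and discounting conventions

The source model was built in commercial decision-tree software whose
cycle-accrual convention is not stated, so the engine exposes toggles rather
than asserting one: accrual on the pre- or post-transition occupancy, with
or without half-cycle correction. In all cases the tree phase (upfront +
expected AKI episode cost) accrues undiscounted at time zero, the first 30
days contribute no QALYs, 30-day CKD/ESRD dispositions accrue their first
annual cost at cycle 1, and cycle *t* accruals are discounted by
(1+r)<sup>−t</sup>, t = 1..3.

**Calibration.** Golden tests evaluate all four toggle combinations against
the published league table. Pre-transition accrual without half-cycle
correction is uniformly closest and is the shipped default. Two residual
discrepancies with the published table remain under *every* toggle
combination, and the acceptance tests document them as failures rather than
papering over them:

* The published QALY totals for all four strategies coincide (to <0.04%)
  with *undiscounted* pre-transition accrual, although the stated method
  discounts QALYs at 3%. This package follows the stated method, so its QALY
  totals are ~5.6% below the published ones.
* The published cost totals imply downstream state costs that *decrease*
  with the AKI rate, which no propagation of the stated transition tables
  can produce; they are reconcilable only with an AKI episode cost of about
  $10,450 (inside the published $8,200–$13,750 interval) rather than the
  published $14,000 base case. This package keeps $14,000.

Dominance ordering, incremental signs, the PSA conclusion and the
$100,000-WTP break-even costs (within ~1.3%) are insensitive to all of this.

## Ranking and sensitivity analyses

Strategies are ranked by strong dominance (no more cost, no fewer QALYs,
one strict), with extended dominance implemented for generality; ICERs are
reported only between adjacent efficiency-frontier strategies (the base case
has a single non-dominated strategy, so none). Increments are reported as
(strategy − reference). NMB ties are broken by lower cost, then name.

One-way analysis varies a parameter to each bound with everything else at
base case; varying one 30-day disposition entry rescales the other three
proportionally so the row stays a distribution; an annual bound that drives
an exit sum above 1 is an error naming the bound. Tornado bars are
|NMB(high) − NMB(low)| of the pair's incremental NMB, sorted descending with
name tie-breaks.

The PSA draws each parameter independently (no correlation information
exists): beta for probabilities and utilities, gamma for costs, all
moment-matched to the base-case mean and sd = (high − low)/3.92 — a
deliberately conservative normal-approximation reading of the printed 95%
intervals, applied uniformly (including the asymmetric CKD-utility interval,
preserving the mean but not the printed bounds). Point estimates without a
range (e.g. the structural zero for no-AKI→ESRD) stay fixed. Sampled 30-day
rows are renormalized after independent draws (a Dirichlet row-draw
alternative sits behind a flag); annual rows with exit sums above 1 are
redrawn, capped at 100 attempts. 1000 draws per run by default.

Threshold analysis exploits that NMB is affine in the upfront cost with
slope −1, giving the closed form c\* = c_base + [NMB_varied − NMB_comparator];
a bisection solver over [c_base, c_base + 10⁶] must agree within $10⁻⁶ and
guards the affinity assumption.

## Synthetic trials

`simulate_trial` emulates the assumed data-generating process patient by
patient: Bernoulli AKI, categorical 30-day disposition, yearly categorical
transitions from the averaged annual table stratified by AKI history. One
master seed; each arm draws from a substream keyed by a hash of its name, so
adding an arm never perturbs another. `estimate_parameters` recovers every
probability as an empirical proportion with a Wald 95% CI (chosen to match
the symmetric printed intervals; swappable), raising a named error on any
empty conditioning cell.

What this does and does not show: the generator reproduces the model's own
statistical structure, so recovery and microsimulation-agreement tests
validate the estimator, the engine's expected-value arithmetic and the
seeding contract — they cannot detect misspecification relative to real
trial data (site-level clustering, per-year transition drift, covariate
effects are all absent by design; the trial's cluster randomization across
20 sites is deliberately not modelled, as no site-level parameters are
available).

## Problem sizes and numerics

Default problem sizes: PSA 1000 draws (10 seeds in the acceptance script);
microsimulation cross-check 25,000 patients/arm (10⁵ total, agreement within
3 Monte Carlo SE); parameter-recovery coverage 50,000 patients/arm over 20
seeds (Wald coverage within 5 points of nominal). Occupancy conservation is
enforced at 10⁻⁹ per cycle; threshold solver agreement at $10⁻⁶; PSA
distribution means reproduce base-case means within 10⁻⁶ relative.

Known limitations: 3-year horizon only; no correlation structure in the
PSA; Wald CIs undercover for very rare transitions at small n; the
first-30-day window accrues neither QALYs nor CKD/ESRD state costs; AKI
survivors accrue no extra first-year cost beyond the episode cost.
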