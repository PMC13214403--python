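# Methods

## Model structure

The analysis is a discrete-time Markov cohort model with year-long cycles.
Two strategies are evaluated with the same background mortality:

**No treatment.** States `NormalLife, Death`; the alive row is
`[1 − dp, dp]` with `dp` the cycle's background death probability.

**Surgical limb lengthening.** States `LLL, LLComp, ULL, ULComp,
NormalLifeLLLOnly, NormalLifeFull, Death`. The printed transition structure
uses a single lifelong "normal life" destination, but the two surgical
pathways carry different lifelong utilities (0.888 after lower-limb-only
lengthening, 0.944 after full lengthening). We therefore split the lifelong
state into two bookkeeping states with identical transition rows
(`[1 − dp, dp]`): path-dependent utility becomes assignable in a memoryless
chain, and the two states' columns sum to the single original column, so the
transition structure is unchanged. Surgical-state death outflows are
`dp + surg_dp`, adding the elective-surgery mortality (0.013% per surgical
cycle); transitions out of `LLL`/`LLComp` split the surviving,
non-complicated mass between continuing to `ULL` (fraction `1 − p_withdraw`)
and withdrawing to `NormalLifeLLLOnly` (fraction `p_withdraw`).

The cohort starts wholly in `NormalLife` or `LLL` at cycle 0. Occupancy at
cycle *t* is the distribution *lived* during that cycle; the cycle-*t*
matrix applies at cycle end. Rewards (utility × year, plus state costs)
accrue on the occupancy rows 0…n−1, discounted by (1 + r)^−t; the terminal
row after the last transition earns nothing. This convention is pinned by
two limits: a single lived cycle at utility 0.711 yields exactly 0.711
QALYs, and constant mortality `dp` with u = 1, r = 0 yields 1/dp QALYs in
the long-horizon limit. No half-cycle correction is applied; the accrual
convention is isolated in `valuation.accumulate` so one could be added.

### Feasibility outside the surgical window

The printed surgical rows require `p_LL_comp + dp + surg_dp ≤ 1`. With the
base-case `p_LL_comp = 0.8` this is violated once background mortality
exceeds ≈0.2 — which any realistic life table reaches at high ages, i.e. at
late cycles of the 90-year horizon. The resolution is structural: a cohort
starting in `LLL` provably vacates all four surgical states within 4
transitions (the longest path is LLL → LLComp → ULL → ULComp → normal
life), for *any* parameter values. The as-printed surgical rows are built
and validated only for cycles 0–3; at later cycles the unreachable surgical
rows are replaced by a valid absorbing placeholder, keeping every matrix
row-stochastic. A test proves the trace is bit-identical under any other
valid placeholder. Consequently the PSA's feasibility check also applies
only to the surgical window, where background mortality is small and
rejections are rare.

## Parameters

| symbol | meaning | default | PSA distribution |
|---|---|---|---|
| u_base | lifelong utility, untreated | 0.711 (sd 0.266) | beta, moment-matched |
| u_lll | lifelong utility, lower limbs lengthened | 0.888 (sd 0.111) | beta, moment-matched |
| u_full | lifelong utility, fully lengthened | 0.944 (sd 0.078) | beta, moment-matched |
| m_lll / m_ull / m_llc / m_ulc | utility multipliers during surgery/complication years | 0.7 / 0.8 / 0.8 / 0.75 | beta, ess = 50 |
| p_ll_comp / p_ul_comp | complication (reoperation) probabilities | 0.8 / 0.1 | beta, ess = 50 |
| p_withdraw | withdrawal after the lower-limb stage | 0.1 | beta, ess = 50 |
| surg_dp | per-cycle surgical mortality | 0.00013 | fixed |
| c_lll / c_ull / c_comp | procedure costs (€) | 28,539 / 10,834 / 6,275 | gamma, cv = 30% |
| r_cost, r_health | annual discount rates | 0.03 | fixed |
| wtp | decision threshold (€/QALY) | 25,000 | fixed |
| start_age / n_cycles | cohort entry age / horizon | 12 / 90 | fixed |
| age_shift | life-expectancy reduction (years) | 10 | fixed |

Two conventions were genuinely open and are configurable:

- **Multiplier base** (`multiplier_base`). The disutility multipliers are
  described as applying "during surgery" without naming the utility they
  scale. Default `pathway` multiplies the post-stage utility of that pathway
  (u_lll for lower-limb states, u_full for upper-limb states), keeping each
  pathway internally consistent; `baseline` multiplies u_base instead. Both
  are tested.
- **Age shift.** The reduced life expectancy of achondroplasia is
  implemented as an age shift in the mortality lookup — dp at age a is the
  general-population qₓ(a + 10) — the simplest operationalization; it is
  isolated behind `dp_at` so a hazard-multiplier alternative could be
  substituted. The table is unisex.

## Synthetic life table

Real national period tables are not redistributable, so the default
mortality input is synthesized from a Gompertz–Makeham hazard
h(x) = a + b·cˣ with annual death probability
qₓ = 1 − exp(−(a + b·cˣ·(c − 1)/ln c)) (the exact one-year hazard integral),
closed with qₓ(120) = 1. Defaults a = 5·10⁻⁴, b = 3.5·10⁻⁵, c = 1.095 give a
life expectancy at birth of ≈78.7 years, in the contemporary
western-European range. The synthetic table reproduces the *shape* of human
all-cause mortality (low child/adult mortality, exponential senescence) but
not the accident hump of young adulthood, cohort effects, or any specific
country's level. Passing tests on it therefore validate the machinery and
the qualitative decision findings, not country-specific absolute values;
reproducing a published national analysis requires supplying that country's
table (`life_table: {path: ...}` in the config).

With the synthetic table the base case gives 19.52 vs 25.08 discounted
QALYs (Δ = 5.56), an incremental cost of €43,163 and an ICER of
€7,763/QALY; these are the numbers the test suite and
`scripts/acceptance.py` actually compute, and they shift with the mortality
input.

On cost accrual: costs attach to state occupancy in the cycle the procedure
state is lived and are discounted at that cycle; with the printed
per-procedure costs and probabilities the per-patient undiscounted maximum
is ≈€44.7k, so analyses that report higher per-patient totals must include
cost components or timing conventions beyond the per-procedure figures
used here. The budget module's discounting convention is likewise
configurable (`bia_discounting: program_start | none`) because aggregate
budget figures depend on it.

## PSA, decision curves, budget impact

Each of the 1,000 iterations draws the 13 sampled parameters in a fixed,
documented order from a seeded `numpy.random.Generator` (so a seed fully
determines the stream), rebuilds matrices and state values, and reruns both
strategies. Draws making a surgical-window row infeasible are rejected and
redrawn — never clamped, which would distort the sampled marginals — and the
rejection count is kept in the result and run manifest. The published
utility moments (e.g. 0.711 ± 0.266 → beta(1.354, 0.550)) sit near the
feasibility edge and produce U-adjacent betas; they are used as given, with
a log warning rather than silent truncation. The PSA ICER is the ratio of
mean increments (mean-of-ratios is unstable when incremental effects cross
zero).

CEAC, CEAF and EVPI are computed from the same per-iteration NMB matrix over
a λ grid (default €0–50,000 in €500 steps, always containing the €25,000
threshold): CEAC is the per-λ win frequency (NMB ties awarded to the
reference strategy — conservative toward the intervention and measure-zero
for continuous draws); CEAF selects the strategy with maximal mean NMB,
switching exactly at the ICER of means; EVPI(λ) = E[maxₛ NMBₛ] − maxₛ
E[NMBₛ] ≥ 0, reported per patient. Since maxₛ E[NMBₛ] is piecewise linear
with its kink at the expected-NMB crossing, EVPI's second difference spikes
there — a property the tests exploit to localize the kink.

The budget impact adds one incident cohort per year (15 patients; 7 in the
50% scenario) for 15 years; each cohort generates the expected per-patient
incremental cost stream (exhausted within the 4-year surgical window),
yearly totals are discounted to program start at 3%, and costs beyond the
horizon are truncated. The result is exactly homogeneous of degree 1 in
patients per year, so the 50% scenario is 7/15 of the full scenario year by
year.

## Numerical and testing notes

- Row-stochasticity is enforced at 10⁻¹² and trace mass conservation at
  10⁻¹⁰; Death occupancy is checked monotone; with qₓ(max_age) = 1 and a
  horizon outliving the table, terminal Death occupancy exceeds 1 − 10⁻⁹.
- The cohort engine is validated against an independent individual-level
  microsimulation (10⁵ simulated patients, fixed seed): per-state occupancy
  agrees within 3 binomial standard errors at cycles 1, 2, 5 and 50.
- Distribution builders are cross-checked against closed-form moments
  (scipy) and against sample moments of 10⁶ draws within 4 standard errors.
- The default suite and the full pipeline (1,000-iteration PSA, curves,
  budget) each run in seconds on one CPU; problem sizes (90 cycles, 10³ PSA
  iterations, 10⁵ microsimulated individuals, 10⁶ distribution draws) are
  the analysis's own configured sizes.

## Known limitations

- The synthetic mortality default is a stand-in: absolute QALY, cost and
  budget outputs are only as country-specific as the table supplied.
- The lifelong utility gain from lengthening is assumed to persist for life;
  complications are single-cycle states; no tunnel states or half-cycle
  correction.
- Parameter draws are independent (no correlation structure); per-parameter
  value of information (EVPPI) is not computed, though per-iteration
  parameter sets are retained to enable it.
- Only the two shipped strategies are modelled; pharmacological comparators
  are out of scope.
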