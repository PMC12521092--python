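# Methods

This note records the modelling conventions, numerical choices and known
limitations of `deaequity`, in the order the pipeline runs.

## Panel model

A `PanelDataset` is a balanced DMU × period × indicator table. Balance is a
hard requirement (a missing cell raises `UnbalancedPanelError`); input and
output cells must be strictly positive, because the input-oriented envelopment
model assumes positive data and the indicators modelled here are counts with
published minima well above zero. Zero or negative input/output cells are
rejected rather than ε-shifted: shifting silently changes every efficiency
score, and the caller should decide how to treat such data. Environment, area
and population indicators may be zero.

Descriptive statistics use the sample (n−1) standard deviation, matching the
convention of the statistical bulletins the generator is calibrated to.
Periods are opaque ordered labels; Malmquist adjacency is list order, never
arithmetic on year numbers.

## Envelopment (stage 1)

* **Orientation.** Input-oriented throughout; projections reduce inputs at
  fixed outputs. Output orientation, super-efficiency, FDH and weight
  restrictions are out of scope.
* **Two-phase LP.** The non-Archimedean ε of the classic single-LP
  formulation is replaced by a lexicographic pair: minimise θ, then maximise
  total slack at fixed θ*. Phase 2 is solved over λ only — the slacks are
  affine in λ once θ is fixed — which avoids equality constraints and is
  noticeably more robust at the 1e−7 feasibility tolerances of HiGHS
  (`scipy.optimize.linprog`).
* **Normalisation.** Both phases run on column-mean-normalised data. θ and λ
  are mathematically invariant to column scaling, so this only improves
  conditioning; it also makes the phase-2 objective "total slack in
  mean-relative units", a deliberate choice that keeps slack maximisation
  unit-free. Slacks are rescaled to raw units on output.
* **Tolerances.** All "= 1" classifications (efficient, RTS ties, VRS λ-sum)
  use 1e−6. Scores are reported at full precision; display rounding to 3
  decimals happens only in the report layer.
* **Degeneracy.** Multiple optimal λ are possible; any optimal vertex is
  accepted. Everything reported (θ, TE/PTE/SE, RTS label via Σλ, slack
  totals) is either unique or tolerance-stable in practice at this problem
  size.
* **Ideal values.** Input targets are θx − s⁻ (radial contraction plus slack
  removal). The alternative convention x − s⁻ (slack removal only) exists in
  the literature; we use the former because the stage-2 dependent variable is
  defined as actual minus target input, which then cleanly equals radial plus
  non-radial excess.

## Slack frontier (stage 2)

* **Model.** One independent regression per input (no joint estimation), with
  dependent S = (1−θ)x + s⁻ from the BCC results and design = intercept +
  environment covariates. The composed error is v + u with half-normal u ≥ 0 —
  the cost-frontier orientation, since inefficiency inflates slack. The
  half-normal (rather than truncated-normal or exponential) inefficiency is
  the convention whose output signature is (β, σ², γ, one-sided LR).
* **Estimation.** ML in the (σ², γ) parameterisation; multi-start L-BFGS-B
  over the γ grid 0.05…0.95 (step 0.1), each start using modified-OLS values
  (OLS intercept shifted down by σ_u√(2/π), moment-matched σ²). γ is bounded
  to [1e−6, 1−1e−6] during optimisation to keep the likelihood finite and
  reported unclamped (0 or 1) at the boundary. Non-convergence falls back to
  the OLS (γ=0) fit with `converged=False` — with 14 DMUs and 3 covariates
  the MLE is genuinely fragile, and a fragile fit that degrades to OLS leaves
  stage 3 well-defined (zero inefficiency, pure luck-levelling).
* **Testing γ = 0.** The one-sided LR statistic 2(ℓ − ℓ_OLS), clamped at 0,
  is referred to the 50:50 mixed χ²₀/χ²₁ distribution (5% critical value
  2.706), the correct reference for a boundary null.
* **JLMS.** Observation-level inefficiency is E[u|ε] =
  σ\*[φ(z)/Φ(z) + z], z = ελ/σ. The Mills ratio is computed via
  `scipy.special.log_ndtr`, which is accurate in the deep lower tail where a
  naive φ/Φ underflows; u is clipped at 0 against round-off.
* **Adjustment.** x^A = x + [max f − f] + [max v̂ − v̂]. Both terms are
  nonnegative, so x^A ≥ x cell-wise and the max-attaining DMUs are left
  unchanged — these are exact invariants, tested as such. Only inputs are
  adjusted; outputs pass to stage 3 untouched. Inputs whose stage-1 slack
  column is identically zero (e.g. an all-efficient panel) raise a degenerate
  frontier internally and pass through unadjusted with a warning; if every
  input is degenerate, stage 3 equals stage 1.

## Malmquist

* **Decomposition.** CRS distances define TFP, EC and TC; PECT is the ratio
  of own-period VRS distances; SEC = EC/PECT residually — the standard Färe
  convention (as implemented in DEAP). This avoids every cross-period VRS LP,
  and with it the classic infeasibility problem; `cross_distance` still
  exposes cross-period VRS evaluation for diagnostics and raises a named
  error when infeasible. Cross-period CRS scores may exceed 1 and are never
  clipped.
* **Averaging.** All "average" rows/columns are geometric means — the only
  mean under which TFP = EC × TC survives aggregation, and the convention the
  published average rows actually satisfy (their arithmetic means do not).
* **Raw vs adjusted inputs.** Malmquist runs on the panel as supplied; the
  dynamic analysis defaults to raw inputs, and a caller wanting
  adjusted-input dynamics can feed stage-3 adjusted frames back in.

## Concentration indices

Computed from raw shares (the ×100% in the textbook formulas cancels).
Parent totals default to sums over the supplied regions and can be overridden
for non-exhaustive region lists (a province scored against national totals).
Zero-resource regions get HRAD = 0 and the "scarce" verdict rather than an
error. Exact algebraic identities — area-weighted mean HRAD = 1, PAD = 1,
population-weighted mean ratio = 1, area-invariance of HRAD/PAD — are tested
to 1e−12.

## Synthetic generator

The generator emulates the published study conditions: 14 DMUs × 7 periods,
with every indicator's marginal distribution lognormal and moment-matched to
the published mean/sd (means land within a few percent; a 25% band is asserted
since inflation terms and cross-correlations shift them slightly). A per-city
size factor (correlation 0.9) links indicators, so large cities have more of
everything, as in real panels. Defaults that neither the bulletins nor the
summary tables state, chosen once as realistic for this setting:

| parameter | default | why |
|---|---|---|
| σ_u (log-scale inefficiency) | 0.15 | mean TE ≈ 0.93–0.96, matching observed provincial cross-sections |
| σ_v (log-scale noise) | 0.05 | measurement noise well below the inefficiency signal |
| drift (frontier shift/period) | 0.955 | the published mean TFP, i.e. mild technical regress |
| env effects (per 1 sd of covariate score) | +0.08 GDP, +0.05 population, −0.04 TCM share | sign pattern of the published slack regressions, modest magnitude |
| city areas | lognormal, mean 3.04e4 km², sd 4e4 | resembles the real prefecture spread; not published in the summary table |

Outputs are efficient (Cobb-Douglas CRS frontiers, exponents summing to 1,
calibrated so output means hit the published targets exactly on each draw);
all inefficiency enters as input inflation exp(u + η + v). A noiseless
configuration therefore yields an all-CRS-efficient panel — points on a
concave CRS surface are DEA-efficient — which is itself a test. One seed
sequence per indicator, split in fixed order, so appending an indicator does
not perturb earlier draws; the same seed reproduces the panel bit for bit.

What the generator does **not** emulate: serial correlation of inefficiency
within a city over time, integer-valued counts, reporting artefacts,
COVID-style structural breaks, and the multiplicative-vs-linear mismatch
between how slack is generated (log-scale) and how stage 2 models it
(linear). Passing tests therefore show the pipeline recovers structure it can
represent, not that the linear SFA is the true model of any real bulletin.

## Problem sizes and test design

Unit and property tests run on 2–6 DMU instances with exhaustive
vertex-enumeration oracles; Monte-Carlo suites use the sizes their claims
state (SFA recovery: 50 replicates at n = 500; environment-levelling: 100
replicates at n = 14; end-to-end rank recovery: 50 seeds), which keeps the
whole suite in the minutes range on one CPU. Published tables are used as
*inputs* to arithmetic consistency checks (column means, row products,
geometric-mean averages, ratio recomputation) at the bounds their 3-decimal
printing supports; the raw city panel behind them was never deposited, so
cell-level reproduction is out of scope by design.

## Known limitations

* Efficiency scores from 14-DMU cross-sections with 4 inputs and 3 outputs
  are generously dimensioned (many units sit on the frontier); that is a
  property of the emulated study design, not of the implementation.
* The SFA stage at n = 14 frequently returns boundary γ̂ = 1 — visible in the
  synthetic runs exactly as in published provincial analyses — and its
  standard errors (numerical Hessian) should be read as descriptive.
* `aggregate`'s geometric means require strictly positive indices, which the
  model guarantees but degenerate hand-made records (component = 0) would
  break.
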