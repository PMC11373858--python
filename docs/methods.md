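# Methods

## Model

The Maintenance-Growth Model (MGM) treats individual growth under ad
libitum feeding as an energy balance (units fixed package-wide: mass mg
fresh weight, energy J, time days):

```
(E_M + E_S)·dW/dt = e·S(W) − R_F(S) − R_M(W)
```

* `e` — assimilation efficiency (J assimilated per J ingested);
* `E_M` — energy bound per mg of new tissue; `E_S` — synthesis overhead
  lost as heat per mg (so `R_G = E_S·dW/dt` is the growth-overhead rate);
* `S(W)` — ad libitum ingestion: `α·W^β` for `W ≤ W_mat`; beyond imago
  emergence the branch with derivative `k·W^(β−1)(W* − W)`, continuous at
  `W_mat`, peaking at `W*` and declining after;
* `R_F(S)` — continuous piecewise-linear ("hockey-stick") feeding costs
  with slopes `kF1 ≤ kF2` and breakpoint `S1`;
* `R_M(W) = γ·W/(1 − a_N·W)` — maintenance; the numerator-linear part
  `γ·(mass)` is basal, the remainder negotiable, and the negotiable share
  equals `a_N·(mass)` by construction.  Mature females split maintenance
  between somatic tissue (frozen at `W_mat`, coefficient `γ_BS`) and
  reproductive tissue (`W − W_mat`, coefficient `γ_BR`), continuously at
  `W_mat`.

Masses at or beyond the maintenance pole (`a_N·mass ≥ 1`) raise a typed
`ValidityDomainError`: a trial parameter set that reaches the pole is
structurally invalid, and silent infinities corrupt optimizers.

Deliberately out of scope: temperature dependence, food limitation
(`φ < 1` is rejected), mass-dependent `E_M`/`E_S`, and cell-size-dependent
basal maintenance.

Two companion forms are provided: the **resting form**
`dW/dt = (a_R·W^b_R − R_M)/E_S` (resting metabolism approximated by a
power allometry; the basis of inverse calibration) and the **compact
form** `a·W^β − c·W/(1 − a_N·W)`, which reduces to the Generalized
Standard Growth Model (GSGM, `a·W^b − c·W^d`) when `a_N = 0`.

## Numerical choices

* Integration: `scipy.solve_ivp` (LSODA, stiff-capable), `rtol 1e-8`,
  `atol 1e-10` mg by default.  The model is continuous but not smooth at
  its branch boundaries, so the maturity crossing is located by a
  terminal event and the integration restarted — the derivative kink
  never sits inside an adaptive step.  Masses exactly at a boundary take
  the closed lower branch (both branches agree there).
* Asymptotic mass: geometric bracketing scan over the validity domain plus
  Brent's method on `a_R·W^b_R − R_M(W)`; `None` when no root exists
  (e.g. `a_N = 0, b_R = 1, γ < a_R`, where the rate grows without bound).
* Negative growth rates are admitted by the right-hand side (the balance
  may go negative) but flagged with a warning, since ad libitum data are
  not expected to show mass loss.
* Log-log allometry fits (`R_tot ≈ a_T·W^b_T`) are ordinary least squares
  on `log10` via statsmodels, restricted to an explicit mass window; the
  two windows used are the whole juvenile interval `W ≤ W_mat` and the
  short interval below the feeding-cost break (`S ≤ S1`).

## Synthetic experiment

The generator emulates the study design the calibration assumes: 42
nymphs reared individually (17♂ + 25♀ by default), 7 lost to attrition
(leaving 14♂ + 21♀), weighed and fed twice weekly (3.5-day spacing) for
72 days; food remains (mixed with faeces except on every 4th occasion,
when faeces are separated) are recovered at each occasion and the imago
date recorded.

**Latent dynamics.** Each individual's trajectory follows the resting
form exactly, with ingestion the exact broken allometry.  The three
structures the calibration assumes — power-law resting metabolism,
allometric ingestion, hockey-stick feeding costs — are mutually
over-determined: they cannot all hold exactly along one trajectory.  The
generator therefore satisfies the first two exactly and lets feeding
costs be *implied* by the energy balance; the template's `S1/kF1/kF2`
values are the least-squares hockey-stick projection of that implied
relation over the rising-ingestion domain (`W ≤ W*`, where `S(W)` is
single-valued).  This mirrors the empirical situation, where the
feeding-cost relation is itself an inferred, approximately-piecewise
construct.  A consequence worth knowing: ingestion random effects do not
feed back on growth (an individual that eats more has higher implied
feeding costs instead), which real animals need not obey.

**Templates** (chosen once for a cricket-like regime; synthetic defaults,
not literature estimates): `e = 0.8`, `E_M = 6.0`, `E_S = 2.7` J/mg
(growth overhead 31% of total growth costs), `α = 4.0`, `β = 0.8`,
`b_R = 0.9` (the resting exponent reported for crickets), `a_R = 0.75`
(keeps implied feeding costs nonnegative); maintenance `γ_B = 0.18`,
`a_N = 0.0010` (males), `γ_BS = 0.15`, `γ_BR = 0.26`, `a_N = 0.0012`
(females), giving maturity near day 45, asymptotes ≈ 550 (♂) / 806 (♀)
mg, peak growth ≈ 18–21 mg/day, and activity scopes within 1.1–2.3.

**Observation model** (invented defaults, config-overridable): 3%
multiplicative Gaussian noise on every weighing; moisture uptake inflates
recovered remains by `(1+m)` with `m = 0.15`; faecal dry output is a
fraction `r = 1 − e` of ingested dry mass (equal energy density of food
and faeces assumed); food energy density `E_f = 17` J/mg dry; provision
1.6× expected consumption plus a 50 mg floor (ad libitum guaranteed).

**Random effects**: lognormal multipliers with mean exactly 1 on
{α, γ (sex-appropriate basal coefficient), W_mat (with `W*` co-scaled to
preserve the adult-branch geometry), W_0}, log-SD 0.15 each — exponents
shared, normalizations individually variable.

What passing tests on these data do **not** show about real data: no
mortality or moulting dynamics, no temperature fluctuation, noise and
moisture magnitudes are placeholders, and the resting-form latency means
the feeding-cost component is exactly as identifiable as its projection —
no more.

## Preprocessing

Dry recovered mass is `recovered/(1+m)`; unseparated remains are
corrected with the pooled egestion fraction
`r = Σ faeces_dry / Σ ingested_dry` over separated occasions; ingestion
rates are interval quantities assigned to interval midpoints with
companion mass (mean of adjacent smoothed masses) and growth rate (exact
interval mean difference).  Mass and ingestion series are smoothed with a
centered 3-occasion moving average (truncated at the edges; window
configurable); growth rates at occasions use central differences.
Maturity is taken from the recorded imago flag only, with the maturity
age/mass estimated at the midpoint of the interval in which the flag
first appears.  Negative corrected ingestion is flagged, never clipped.

## Calibration

Stages run per sex, in dependency order:

1. **Juvenile ingestion** — per-individual OLS of `log10 S` on `log10 W`,
   precision-weighted pooling of slopes into a shared `β`, per-individual
   intercepts at the pooled slope (`α` fixed effect and random-effect
   spread).  Individuals with < 3 juvenile records are dropped.
2. **Adult ingestion** — bounded nonlinear least squares for `(k, W*)`
   with `α, β` fixed and each record using its individual's maturity
   mass; multi-start over a `W*` grid that includes the empirical
   ingestion peak.
3. **Feeding costs** — per-record
   `R_F = e·S − E_M·dW/dt − a_R·W^b_R`, restricted to each individual's
   rising-ingestion phase (up to the empirical ingestion peak; beyond it
   the S ↦ R_F relation is multivalued), then a constrained hockey-stick
   fit: breakpoint profiled over observed S values (ties toward smaller
   `S1`), slopes by nonnegative least squares on
   `R_F = kF1·S + (kF2−kF1)·(S−S1)₊`, per-individual slopes with a shared
   breakpoint (the two-stage analog of a random-slopes mixed model —
   pooled fitting is confounded by individuals whose whole record cloud
   sits higher or lower).
4. **Inverse calibration** — `(E_S, γ_B, a_N)` (♂) or
   `(E_S, γ_BS, γ_BR, a_N)` (♀) by least squares between the resting-form
   solution and observed mass curves.  Stage 1: sex-averaged raw mass
   curve, 16 Latin-hypercube starts (seeded), bounds
   `E_S ∈ (0, 10·E_M]`, `γ ∈ (0, a_R·W_mat^(b_R−1)]`,
   `a_N ∈ [0, 0.9/W_max)`, objective ties broken toward smaller `a_N`;
   female maturity mass additionally profiled over ±8% (the growth-curve
   kink identifies it more sharply than the twice-weekly imago flag).
   Stage 2: per-individual refits warm-started at the stage-1 optimum.
   When refits run, the reported fixed effects are the means of the
   individual estimates — the classical two-stage estimator; the average
   of nonlinear trajectories is not itself a trajectory of any parameter
   set, so the averaged-curve fit alone is biased under individual
   variation (it is retained as `extras["stage1_params"]`).  A full
   likelihood-based nonlinear mixed-effects backend can be plugged in
   behind the same `FitResult` surface.
   The raw (unsmoothed) averaged masses are used here because the
   truncated moving-average windows bias the curve ends, drastically so
   at birth mass.

Individual variation is reported as the standardized random effect
`SRE = sd(RE)/|FE|`, a coefficient-of-variation analogue for
hierarchical parameters.

## Evaluation

Goodness of fit is the efficiency statistic
`GF = 1 − SS_res/SS_tot` (1 = perfect, 0 = mean predictor, negative
reported as-is).  Sex-averaged GF compares the fixed-effects full-form
trajectory with the averaged empirical mass curve; per-individual GF uses
each individual's raw masses (predictions restarted from that
individual's first mass).  Empirical total metabolic rate is computed
indirectly as `R_tot = e·S − E_M·dW/dt`; model-predicted `R_tot` comes
from the integrated decomposition `R_F + R_G + R_M`; both are fitted with
log-log allometries on the two juvenile windows.  The activity scope is
`R_tot/R_R` with its extrema.

## Known limitations

* The recovery target for the feeding-cost group is a *projection* of a
  smooth implied curve onto a broken line; its value shifts by roughly
  10% between the dense latent curve and records sampled at the
  twice-weekly design, so breakpoint parameters are recoverable to ~10%,
  not to the sub-5% level the other groups reach in the deterministic
  limit.
* `γ_BR` and `a_N` shape the same post-maturity deceleration and are
  partially confounded; their individual estimates are wider than their
  joint effect on `R_M`.
* The generator draws no mortality, moulting cycles or temperature
  effects; attrition simply removes individuals.
* Parameter-set serialization is flat YAML with unit comments; unknown
  keys are rejected rather than ignored.
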