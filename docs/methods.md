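# Methods

## Model

The vessel is an ideally mixed chemostat: volume $V$ (default 125 mL),
flow $F$ (default 2.6 mL/h), dilution rate $D = F/V \approx 0.0208$/h,
hydraulic residence time $V/F \approx 48$ h. Perchlorate obeys the
concentration balance $dP/dt = D(P_{in}(t) - P)$ with a
piecewise-constant inflow schedule; within a segment this has the exact
solution $P(t) = P_{in} + (P_0 - P_{in})e^{-D\Delta t}$.

Inhibition is purely phenomenological: a normalized variable-slope
dose-response curve $y(P) = 1/(1 + 10^{(\log IC_{50} - \log_{10}P)h})$
multiplies the maximal growth rate, $\mu = \mu_{max} y(P)$. There is no
mechanistic representation of sulfate-pathway de-repression, transport,
or perchlorate-reducing competitors, and perchlorate is not consumed.

SRM biomass is carried as *percent of community* (0–100), never a 0–1
fraction. Two non-exchanging pools grow logistically against separate
carrying capacities: planktonic ($K_p$, default 40%), which is diluted
at $D$, and surface-attached ($K_A$, default 0.5%), which is not. In
reality the pools interconvert; the model omits attachment/detachment
terms because both pools are assumed inhibited identically, so the
omission does not change the steady-state structure. $K_A = 0$ models a
purely planktonic vessel (and then requires a zero attached inoculum).

Total SRM converts to effluent sulfide through the empirical log-log
regression $[\mathrm{sulfide}] = 10^{a\log_{10}N_t + b}$ with preset
$a = 0.6786$, $b = -0.7375$ ($R^2 = 0.79$ in the source data). The
conversion is evaluated on $\max(N_t, 10^{-6}\,\%)$ to keep the
logarithm defined after deep washout.

### Units inside the dose-response log

The API carries perchlorate in mM throughout, but the logarithm in the
dose-response curve is taken on **mol/L**, so the community preset
$\log IC_{50} = -1.914$ means an IC50 of $10^{-1.914}$ M $\approx
12.2$ mM. This is the only reading under which 20 mM is marginally
inhibitory and 50 mM strongly suppressive, consistent with the critical
concentration $\mu(P^\*) = D$ landing at $\approx 30$ mM for the
community preset. The Hill slope is stored signed (negative for an
inhibitor) rather than as a magnitude plus orientation. $y(0) := 1$ by
the continuous limit.

## Parameter presets

| parameter | community | BMSR isolate | units |
|---|---|---|---|
| $\mu_{max}$ | 0.13 | 0.2 | 1/h |
| $\log IC_{50}$ | −1.914 | −2.099 | log10 mol/L |
| Hill slope | −1.813 | −1.108 | — |

$K_p = 40\%$, $K_A = 0.5\%$, $V = 125$ mL, $F = 2.6$ mL/h accompany
them as the default vessel. Presets ship in
`src/sulfostat/data/presets.yaml`.

## Numerics

* Integration: LSODA with rtol $10^{-8}$ / atol $10^{-10}$, hard
  restarts at every schedule breakpoint (the inflow is discontinuous
  there, and the breakpoints are known a priori, so restarting beats
  event detection). Perchlorate is not co-integrated: it decouples from
  the biology and is evaluated by its exact segment-wise exponential,
  so $\mu(t)$ carries no solver error and the trajectory matches the
  closed form identically.
* Planktonic floor: $N_p$ is clipped at $10^{-9}\%$ (configurable) at
  segment boundaries and in output, so rebound after deep washout
  remains possible. Rebound timing depends on this floor for very long
  treatments; the dependence is a model artefact, not biology, and the
  floor is therefore exposed as a config knob rather than hidden.
* Default initial state: the untreated steady state
  $(K_p(1 - D/\mu_{max}),\, K_A,\, 0)$, matching a protocol of treating
  only after sulfide production has stabilised.
* `critical_perchlorate` brackets the monotone curve in $\log_{10} P$
  over $[10^{-12}, 10^{12}]$ mM and solves $\mu(P) = D$ with Brent's
  method to $|\mu - D| < 10^{-10}$. The tie $\mu(P) = D$ in the
  steady-state formula is assigned to washout (a measure-zero boundary).
* Dose-response fitting: nonlinear least squares on log-molar
  concentration with top/bottom fixed at 1/0 (the normalized-response
  variant; 4-parameter plateaus are out of scope). Initialisation: the
  log-concentration nearest response 0.5 and slope −1; on failure a
  grid search over $\log IC_{50} \in [-4, 0]$, $h \in [-5, -0.1]$
  restarts the solver. 0 mM wells are used only for normalisation
  (their log-concentration is undefined) and at least 4 distinct
  nonzero concentrations are required. 95% CIs come from the linearised
  covariance with a $t$ quantile (asymptotic, as curve-fitting packages
  report them); a case-resampling bootstrap is available.
* Growth rates: the slope of ln(measurement) vs time over a sliding
  window (all contiguous runs of ≥4 time points, replicates pooled).
  Among windows within $10^{-6}$ of the best $R^2$ the steepest is
  taken — ties are common in clean data, and the tie-break stops a flat
  saturated tail (also nearly log-linear) from shadowing the
  exponential phase. Windows never reaching $R^2 = 0.9$ yield a flagged
  estimate with a warning. In the growth-rate dose-response pipeline,
  slightly negative rate estimates from flat noisy curves are floored
  at zero (a batch culture cannot shrink in this model). How the source
  study extracted rates from curves is not stated; the sliding-window
  rule is this package's choice.
* Calibration regression: OLS of $\log_{10}$ sulfide on $\log_{10}$
  %SRM via statsmodels; $R^2$ is computed (and reported) in log space.
  Whether the original regression used replicate means or all points is
  unknown, so both modes exist (`on_means`) and the result records
  which was used. Replicate points are equally weighted everywhere.
* Batch mixtures share one logistic ceiling (strains compete for a
  single donor niche) rather than having independent ceilings.

## Synthetic data

The generator emulates the study's three input classes with known
ground truth: replicated chemostat sulfide/%SRM series under on/off
schedules (default sampling every 12 h, roughly daily manual sampling),
two-fold serial-dilution endpoint plates from 500 mM down, and batch
logistic growth curves with optional lag. Chemostat and plate noise is
multiplicative-lognormal by default because observed replicate scatter
scales with the mean (e.g. ±0.57 on 2.0 mM but ±0.076 on 0.17 mM);
additive Gaussian noise is available. A toy genus-level
relative-abundance table embeds the $N_t$ signal across four SRM genera
(Desulfovibrio-dominant fixed split) with exchangeable Dirichlet filler
taxa; only the summed SRM fraction is meaningful — no attempt is made
to mimic real community structure, 16S read-level data, or qPCR-scale
outputs.

What passing tests show: the pipeline recovers its own generating
parameters under the stated noise (self-consistency), and the model
reproduces the published steady-state/washout/rebound numbers from the
published constants. They do not show that real plates or chemostats
satisfy the model's assumptions (fixed $\mu_{max}$ and $K$, no
adaptation, no donor effects, no interconversion of pools).

## Problem sizes

Simulations run on 1 h output grids over 2000–3000 h horizons
(steady-state and treatment runs); the washout-dichotomy grid check
uses 50 inflow levels with a $10^5$ h horizon and coarse output so
near-critical levels have converged. Monte-Carlo recovery envelopes use
100 seeds at the stated noise (plate sd 0.05; calibration log-space
sd 0.19, chosen to land near the calibration's published $R^2$). The
whole suite runs in well under a minute on one CPU.

## Known limitations

* The rebound window depends on treatment duration and the washout
  floor; the acceptance script defines "inhibition stabilised"
  (treatment cessation) as predicted sulfide declining < 1% over the
  preceding 7 days, mirroring the stable-sulfide steady-state
  definition, and reports the model's own rebound rather than
  calibrating to the observed one.
* No DPRB/bio-competition, nitrate/nitrite chemistry, sulfide
  oxidation, spatial structure or diffusion limitation, and no
  adaptation of IC50 over time (fold-change comparison of two fits is
  provided instead).
* The two-parameter normalized dose-response cannot represent partial
  inhibition plateaus.
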