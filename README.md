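# sulfostat

Chemostat modelling of perchlorate inhibition of sulfate-reducing
microorganisms (SRM).

Hydrogen sulfide produced by SRM ("souring") is a major problem in oil
reservoirs and other engineered anaerobic systems, and perchlorate is a
candidate souring-control amendment: it competitively inhibits the
sulfate-reduction pathway, slowing SRM growth rather than killing cells.
In a continuous-flow vessel that slowdown has a sharp consequence —
once the inhibited growth rate falls below the dilution rate, the
planktonic SRM population washes out. `sulfostat` implements a compact
quantitative model of this process for microbial ecologists and
corrosion/souring engineers who want to predict inhibition, washout and
rebound from a handful of batch-measurable parameters.

## The model

Perchlorate in a well-mixed vessel of volume $V$ fed at flow $F$
(dilution rate $D = F/V$) follows the linear balance

$$\frac{dP}{dt} = D\,(P_{in}(t) - P),$$

with $P_{in}$ a piecewise-constant treatment schedule. Its effect on
growth is a variable-slope dose-response curve

$$y(P) = \frac{1}{1 + 10^{(\log IC_{50} - \log_{10} P)\,h}},
\qquad \mu(P) = \mu_{max}\, y(P),$$

with $h < 0$ the Hill slope and the log taken on molar concentration
(the community preset's $\log IC_{50} = -1.914$ is an IC50 of
$\approx 12.2$ mM). SRM biomass (as percent of the community) is split
into a planktonic pool, which grows logistically and washes out, and a
surface-attached pool, which grows logistically and does not:

$$\frac{dN_p}{dt} = \mu N_p\Big(1 - \frac{N_p}{K_p}\Big) - D N_p,
\qquad
\frac{dN_A}{dt} = \mu N_A\Big(1 - \frac{N_A}{K_A}\Big),
\qquad N_t = N_p + N_A.$$

Total SRM is converted to effluent sulfide through an empirical log-log
calibration $[\mathrm{sulfide}] = 10^{\,a \log_{10} N_t + b}$
(preset: $a = 0.6786$, $b = -0.7375$).

Key analytics fall out in closed form: the untreated steady state
$N_p^\* = K_p(1 - D/\mu_{max})$, the washout criterion $\mu(P) < D$, the
critical perchlorate concentration solving $\mu(P) = D$, and the
"inhibited" sulfide floor set by the attached pool alone. The package
also re-implements the parameterisation steps: normalized variable-slope
dose-response fitting (endpoint plates or growth rates), sliding-window
exponential growth-rate estimation, the log-log sulfide calibration
regression, and IC50 fold-change comparison — plus a seed-deterministic
synthetic-data generator for all of these inputs.

## Worked example

```python
import sulfostat as ss

community = ss.get_strain_preset("community")   # mu_max 0.13/h, logIC50 -1.914, Hill -1.813
comp = ss.get_compartment_preset()              # K_p 40 %, K_A 0.5 %
calib = ss.get_calibration_preset()

cfg = ss.ChemostatConfig(
    strain=community, compartments=comp, calib=calib,
    schedule=((0.0, 0.0), (200.0, 50.0), (1200.0, 0.0)),  # 50 mM from 200-1200 h
    t_end_h=2500.0,
)
res = ss.simulate(cfg)
print(f"D = {cfg.dilution:.4f} /h, residence time = {cfg.residence_time_h:.1f} h")
print(f"pre-treatment sulfide:  {res.sulfide[res.times == 200.0][0]:.2f} mM")
print(f"inhibited sulfide:      {res.sulfide[res.times == 1200.0][0]:.3f} mM")
print(f"critical perchlorate:   {ss.critical_perchlorate(community, cfg.dilution):.1f} mM")
t_reb = ss.rebound_time(res, float(res.sulfide[0]), tolerance=0.1)
print(f"rebound after cessation: {t_reb:.0f} h "
      f"({t_reb / cfg.residence_time_h:.1f} residence times)")
```

prints

```
D = 0.0208 /h, residence time = 48.1 h
pre-treatment sulfide:  2.01 mM
inhibited sulfide:      0.114 mM
critical perchlorate:   30.4 mM
rebound after cessation: 205 h (4.3 residence times)
```

The untreated vessel settles at ~2 mM sulfide (total SRM ~34% of the
community). Sustained 50 mM perchlorate pushes $\mu$ below $D$, the
planktonic pool washes out, and sulfide falls to the ~0.11 mM floor
sustained by the attached pool; 20 mM would sit below the ~30 mM
critical concentration and only partially suppress. After treatment
stops, sulfide recovers to 90% of its pre-treatment level in a few
residence times.

Fitting a noisy synthetic plate recovers the inhibition constants:

```python
plate = ss.gen_plate_gradient(community, noise=ss.NoiseModel(sd=0.05, seed=1), replicates=3)
print(ss.DoseResponse.from_plate(plate).fit().summary())
```

```
Dose-response fit (normalized, variable slope)
======================================================
source:        endpoint
n points:      36
LogIC50:       -1.8883  (95% CI -1.9206, -1.8561)  [log10 M]
IC50:           12.932 mM
HillSlope:     -2.0513  (95% CI -2.3260, -1.7765)
residual SSE:   0.06703
```

A `sulfostat` console script exposes the same pipeline from the shell
(`simulate`, `steady-state`, `fit-dr`, `fit-growth`, `calibrate`,
`synth`); run `sulfostat --help`.

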