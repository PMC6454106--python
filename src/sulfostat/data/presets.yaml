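# Published parameter presets for the sulfidogenic chemostat model.
#
# Strain inhibition constants are on the variable-slope dose-response scale:
# log_ic50 is log10 of the half-inhibitory perchlorate concentration in mol/L
# (the community IC50 of 10^-1.914 M is ~12.2 mM); hill_slope is signed and
# negative for an inhibitor; mu_max is the uninhibited specific growth rate
# in 1/h.
strains:
  community:
    name: community
    mu_max: 0.13
    log_ic50: -1.914
    hill_slope: -1.813
  bmsr:
    name: bmsr
    mu_max: 0.2
    log_ic50: -2.099
    hill_slope: -1.108

# Log-log regression converting total SRM (% of community) to sulfide (mM):
# [sulfide] = 10^(slope * log10(Nt) + intercept)
calibrations:
  default:
    slope: 0.6786
    intercept: -0.7375
    r_squared: 0.79

# Two-compartment carrying capacities (% of community) and vessel geometry.
compartments:
  default:
    k_p: 40.0
    k_a: 0.5

vessel:
  default:
    volume_ml: 125.0
    flow_ml_per_h: 2.6
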