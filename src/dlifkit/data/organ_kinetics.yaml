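# Default irreversible two-tissue-compartment parameters for the digital
# mouse phantom, FDG-like, units: K1 [ml/g/min], k2, k3 [1/min], vB [-].
# Plausible fixture values for fasted mice, deliberately chosen inside the
# validity regime of Patlak graphical analysis: fast tissue equilibration
# (k2 + k3 well above the late input-function decay rate) and small
# fractional blood volume, since the Patlak slope of a simulated voxel is
# (1 - vB) * K1*k3/(k2+k3) plus a transient tilt that grows as k2+k3
# shrinks.  They are simulation inputs, not measured claims.
# version: 2
body:        {K1: 0.06, k2: 0.80, k3: 0.055, vB: 0.02}   # muscle-like bulk, Ki ~ 0.0039
liver:       {K1: 0.50, k2: 0.80, k3: 0.040, vB: 0.02}   # Ki ~ 0.0238
myocardium:  {K1: 0.55, k2: 1.20, k3: 0.350, vB: 0.03}   # Ki ~ 0.124
brain:       {K1: 0.18, k2: 0.60, k3: 0.065, vB: 0.02}   # Ki ~ 0.0176
bladder:     {K1: 0.03, k2: 0.80, k3: 0.160, vB: 0.01}   # Ki ~ 0.0051
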