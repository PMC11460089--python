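# dlifkit

Quantitative dynamic [¹⁸F]FDG PET of mice needs the arterial input function
(AIF) — the tracer concentration in arterial blood over time — to turn
time–activity curves into physiology.  Measuring it by arterial cannulation
is terminal surgery in mice, which rules out longitudinal studies.  `dlifkit`
is a toolkit for the non-invasive alternatives: it provides an image-derived
input function (IDIF) pipeline with standardized volume-of-interest rules, a
convolutional sequence-regression network that predicts a 41-point input
function directly from the 4-D PET image, Patlak graphical analysis for net
influx quantification, a digital mouse phantom with known ground truth to
validate all of it, and the comparison statistics (orthogonal regression,
signed average error, paired t-tests) used to judge agreement between input
functions and the influx values they produce.

It is aimed at preclinical imaging scientists and methods developers who
want a tested, fully seeded reference implementation they can run end to end
on synthetic data and apply to their own NIfTI + CSV exports.

## The models

**Kinetics.** Tissue uptake follows the irreversible two-tissue compartment
model with rate constants K₁ [ml/g/min], k₂, k₃ [1/min] and fractional blood
volume v_B:

    Ct(t) = (1 − v_B) · h(t) ∗ Cp(t) + v_B · Cp(t),
    h(t)  = K₁/(k₂+k₃) · [k₃ + k₂ e^{−(k₂+k₃)t}]

For an irreversible tracer, plotting Ct/Cp against (∫₀ᵗ Cp dτ)/Cp is linear
after a steady-state time t*; the slope is the net influx rate constant
Ki = K₁k₃/(k₂+k₃) (Patlak analysis), which for FDG is proportional to the
metabolic rate of glucose.  The parametric input function is the Feng bolus
model: Cp(t) = (A₁t − A₂ − A₃)e^{λ₁t} + A₂e^{λ₂t} + A₃e^{λ₃t} with
λ₁ ≤ λ₂ ≤ λ₃ < 0.

**Network.** A shared per-frame encoder — four blocks of 3-D convolution,
batch normalization, ReLU and 2×2×2 max pooling, doubling filters
(2→4→8→16) while halving each spatial dimension — reduces every 64×48×48
frame to 4×3×3×16 = 576 features, which two dense layers compress to a
32-vector per frame.  A 1-D convolution with 16 filters mixes neighbouring
time frames, and a final dense layer maps the 16×41 features to the 41-point
input function through a non-negative rectifier.  Training minimizes the
mean squared error with Adam (learning rate 2·10⁻⁴); k-fold cross-validation
and multi-seed ensembling are built in.  The network is implemented in a
compact, fully deterministic numpy engine with explicit backpropagation.

## Worked example

```python
import dataclasses
import numpy as np
from dlifkit import (default_phantom, simulate_scan, extract_idif, patlak_fit,
                     TimeActivityCurve, deming_fit)

spec = dataclasses.replace(default_phantom(seed=7), noise_scale=0.05)
scan = simulate_scan(spec)                      # 41-frame, 64x48x48 dynamic scan
idif = extract_idif(scan.image)                 # image-derived input function

brain = scan.labels == [o.name for o in spec.organs].index("brain") + 1
tac = TimeActivityCurve(scan.image.schedule.midpoint_s,
                        scan.image.voxels[:, brain].mean(axis=1))
ki_idif = patlak_fit(tac, idif.curve).Ki        # influx with the IDIF
ki_true = patlak_fit(tac, scan.cp).Ki           # influx with the true input
```

prints (via the analogous `print` lines):

```
IDIF peak:            20.73 SUV (ground truth 20.77)
curve agreement:      slope 0.998, r 1.000
brain Ki (IDIF):      0.01705 ml/g/min
brain Ki (true input):0.01710 ml/g/min
simulated truth Ki:   0.01759 ml/g/min
```

The IDIF chain (peak-voxel vena-cava sphere + left-ventricle cavity core +
Feng-model fit) recovers the bolus peak to within 1% despite the simulated
partial-volume blur, and the brain influx computed with the IDIF differs
from the true-input result by well under 1%; the remaining ~3% gap to the
simulated truth is the known finite-t*/blood-volume bias of Patlak analysis
itself.

A command-line interface wires the same pieces into reproducible runs:

```bash
dlifkit simulate --config toy.yaml --outdir sim/
dlifkit idif sim/scan_000.nii.gz sim/schedule.csv --out idif.csv
dlifkit patlak sim/scan_000.nii.gz sim/schedule.csv idif.csv --mip
dlifkit train sim/ --epochs 50
dlifkit evaluate pred/ sim/ --outdir report/
```

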