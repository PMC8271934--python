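# megloc

Dipole source localization for simulated MEG: a physics-based simulator
(spherical-conductor forward model), deep regression networks that map
sensor snapshots directly to source coordinates, and a from-scratch
RAP-MUSIC scanning baseline, with Monte-Carlo drivers that measure
accuracy across SNR, inter-source correlation, and forward-model
misregistration.

## The problem

MEG measures, at M sensors around the head, the magnetic field of
synchronously active cortical patches modeled as equivalent current
dipoles.  With Q active dipoles the sampled data follow

```
Y = A(P) S + N,          A(P) = [ l(p_1), ..., l(p_Q) ],   l(p) = L(p) q
```

where `Y` is M×N (N time samples), `L(p)` is the M×3 lead field at
location `p`, `q` the dipole moment, `S` the Q×N source time courses and
`N` sensor noise.  The inverse problem — recover `P` from `Y` — is the
bottleneck for real-time applications: classical scanning methods such
as RAP-MUSIC search a dense source grid at every time window, degrade
for correlated sources, and cost hundreds of milliseconds per estimate.

`megloc` implements the alternative: train a feedforward network on
simulated `(Y, P)` pairs so that inference is a single forward pass.
Two families are provided, each for Q ∈ {1, 2, 3} sources:

* **mlp-1/2/3** — single-snapshot input (M-vector):
  FC(3000) → FC(2500) → FC(1200) → FC(3Q), sigmoid hidden units, linear output;
* **cnn-1/2/3** — multi-snapshot input (M×16):
  Conv1D(32 kernels × 5 samples over all M channels, valid padding) →
  the same FC stack.

Parameter counts of all six are reproduced exactly (e.g. mlp-1:
11,428,303; cnn-3: 11,718,501), which pins the architecture wiring.
The RAP-MUSIC baseline estimates the signal subspace from the SVD of
`Y` and recursively finds one source per step by maximizing the
subspace correlation (largest canonical correlation between `span L(p)`
and the signal subspace), out-projecting found topographies.

In place of real anatomy, the forward model is the analytic
spherical-conductor (Sarvas) solution: exact, fast, and it preserves
the properties the experiments depend on (linearity in the moment,
radial-source silence).  The source space is a quasi-uniform shell grid
of tangential dipoles; sensor geometry is a synthetic radial-
magnetometer helmet (a user-supplied sensor table or precomputed lead
field can replace both).

## Worked example

```python
import numpy as np
from megloc import (SphereModel, helmet_array, build_source_space, make_sample,
                    rap_music_scan)
from megloc.forward import SphereLeadField
from megloc.evaluation import localization_error

sphere  = SphereModel(center=np.zeros(3), radius=0.09)   # 9 cm conductor
sensors = helmet_array(306, sphere)                      # synthetic helmet
space   = build_source_space(sphere, 2000)               # shell grid, 72 mm
G = SphereLeadField(sensors, sphere)(space.points)

sample = make_sample(space, sensors, sphere, q=2, snr_db=0.0, rho=0.5,
                     n_times=16, rng=np.random.default_rng(7))
result = rap_music_scan(sample.Y, space, None, q=2, lead_fields=G)
print(localization_error(sample.true_locations, result.locations))
```

prints `2.89` — the mean matched error in millimeters of the two
recovered dipoles at 0 dB; rerun with `snr_db=300.0` (effectively
noiseless) and it prints `0.0`, the exact on-grid recovery the MUSIC
theory guarantees.  The scripts in `examples/` walk through each
capability (forward fields, simulation contracts, scanning, network
training, misregistration robustness) and print what the numbers mean.

A thin CLI wraps the same library for shell use:

```
megloc simulate --config cfg.yaml --n 100 --out data.h5
megloc train    --config cfg.yaml --out model.h5
megloc evaluate --config cfg.yaml --experiment exp3 --checkpoint model.h5 --out exp3.csv
```

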