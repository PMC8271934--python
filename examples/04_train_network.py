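"""Train a width-reduced single-snapshot MLP and localize with it.

Uses on-the-fly simulated data (one source, 10 dB SNR).  A short run
for illustration; the shipped evaluation budgets train for 20k steps.
"""

import numpy as np

from megloc import (
    CoordinateScaler,
    SphereModel,
    StreamConfig,
    batch_stream,
    build_mlp,
    build_source_space,
    count_parameters,
    helmet_array,
    make_sample,
    predict_locations,
    train,
)
from megloc.evaluation import localization_error, random_guess_baseline
from megloc.training import TrainConfig

sphere = SphereModel(center=np.zeros(3), radius=0.09)
sensors = helmet_array(306, sphere)
space = build_source_space(sphere, 2000)
scaler = CoordinateScaler(scale=0.8 * sphere.radius, center=sphere.center)

spec = build_mlp(q=1, m=306, width_scale=0.1)
print(f"{spec.name} at width scale 0.1: {count_parameters(spec):,} parameters "
      f"(full-width version has {count_parameters(build_mlp(1)):,})")

stream = batch_stream(space, sensors, sphere,
                      StreamConfig(batch_size=32, q=1, n_times=1, snr_db=10.0),
                      master_seed=0)
model, report = train(spec, TrainConfig(n_steps=4000, master_seed=0, momentum=0.9,
                                        log_every=1000), scaler, stream)
print("minibatch loss:", [f"{l:.3f}" for _, l in report.loss_history])

errors = []
for rep in range(100):
    rng = np.random.default_rng((55, rep))
    s = make_sample(space, sensors, sphere, 1, 10.0, 0.0, 1, rng)
    est = predict_locations(model.spec, model.params, s.Y[:, 0], model.scaler)
    errors.append(localization_error(s.true_locations, est[0]))
baseline = random_guess_baseline(space, np.random.default_rng(9))
print(f"held-out mean error: {np.mean(errors):.1f} mm "
      f"(random-guess baseline {baseline:.1f} mm; longer training drives this lower)")
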