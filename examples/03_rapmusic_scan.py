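"""Locate two dipoles with the recursive subspace scan.

Simulates a noiseless and a noisy two-source trial and runs RAP-MUSIC
over the full grid; on-grid noiseless sources are recovered exactly.
"""

import numpy as np

from megloc import SphereModel, build_source_space, helmet_array, make_sample, rap_music_scan
from megloc.evaluation import localization_error
from megloc.forward import SphereLeadField

sphere = SphereModel(center=np.zeros(3), radius=0.09)
sensors = helmet_array(306, sphere)
space = build_source_space(sphere, 2000)
provider = SphereLeadField(sensors, sphere)
G = provider(space.points)  # precompute once, scan many trials

for snr_db in (300.0, 0.0):
    rng = np.random.default_rng(7)
    sample = make_sample(space, sensors, sphere, q=2, snr_db=snr_db, rho=0.5,
                         n_times=16, rng=rng)
    result = rap_music_scan(sample.Y, space, provider, q=2, lead_fields=G)
    err = localization_error(sample.true_locations, result.locations)
    label = "noiseless" if snr_db > 100 else f"{snr_db:g} dB"
    print(f"{label}: matched error {err:.2f} mm; "
          f"subspace correlations {[f'{d.subcorr:.4f}' for d in result.dipoles]}")
print("(exact 0 mm recovery in the noiseless on-grid case is a MUSIC-theory guarantee)")
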