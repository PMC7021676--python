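"""Generate a synthetic dyadic recording with full ground truth.

Two mice wander a 76 x 76 cm arena; their vocal emission hazard rises
when they are close.  Prints how often the pair was within 20 cm and at
what distances emissions happened — on synthetic data the generator's
hazard structure should be visible directly.
"""

import numpy as np

from squeaktrace import (
    ArenaConfig,
    BehaviorParams,
    interanimal_distance,
    simulate_dyad,
)

arena = ArenaConfig(duration=120.0)  # 2 minutes at 30 Hz
behavior = BehaviorParams(emission_hazard_near=0.01, emission_hazard_far=5e-4)
tracks, truth = simulate_dyad(arena, behavior, seed=42)

dist = interanimal_distance(tracks)
at_emission = [dist[int(ev.time * 30)] for ev in truth.events]

print(f"frames simulated        : {tracks.n_frames}")
print(f"emissions               : {len(truth.events)}")
print(f"fraction of time < 20 cm: {np.mean(dist < 20):.2f}")
print(f"median distance overall : {np.median(dist):.1f} cm")
print(f"median distance at call : {np.median(at_emission):.1f} cm")
# Emissions should cluster at short range: the near/far hazard contrast
# concentrates calls in close-proximity frames, as in real dyads.
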