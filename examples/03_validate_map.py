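"""Validate a predicted suitability map with independent sign transects.

Transect segments are labelled presence (sign found) or confirmed absence
(no sign at the segment nor at any segment within 1 km); ambiguous
segments are dropped.  AUC is the probability that a random presence
outscores a random absence on the map.
"""

from corridorscape import (
    LandscapeConfig, TrueModel, generate_landscape, simulate_truth,
    simulate_validation_transects, validate_map,
)

stack, _ = generate_landscape(LandscapeConfig(n_rows=80, n_cols=100, seed=7))
psi = simulate_truth(stack, TrueModel.panda_like())

segments = simulate_validation_transects(psi, 216, seed=3,
                                         low_psi_fraction=0.5)
print(f"surveyed {len(segments)} segments on "
      f"{segments['transect_id'].nunique()} transects; "
      f"raw sign rate {segments['sign'].mean():.2f}")

res = validate_map(psi, segments)
print(f"labelled: {res['n_presence']} presences, {res['n_absence']} absences "
      f"({res['n_dropped']} ambiguous segments dropped)")
print(f"AUC of the (true) suitability map: {res['auc']:.2f}")
# scoring the map that generated the data bounds what any fitted map can do
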