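"""Detect a spiral core whose true position is known exactly.

Builds an analytic spiral movie with an orbiting core, embeds the phase
with a 2 ms delay, runs both detectors and scores them against the exact
core trajectory. The line integral reports every frame; the temporal-jump
criterion fires whenever the moving core crosses a pixel, and wherever it
fires it pins the core.
"""

from psmap import (DetectorConfig, SimGrid, analytic_spiral_movie,
                   compute_phase, default_orbit_spec, detect_movie,
                   score_against_truth)

grid = SimGrid.from_cm(3, 3)              # 120 x 120 pixels at 0.25 mm
spec = default_orbit_spec(grid)           # core orbits at ~0.7 px/frame
movie, truth = analytic_spiral_movie(spec, grid, duration_ms=400.0)
phase = compute_phase(movie, tau_ms=2.0)

for method in ("iyer_gray", "location_centric"):
    ps = detect_movie(phase, DetectorConfig(method=method))
    score = score_against_truth(ps, truth, lag_frames=1)
    print(f"{method:17s}: {len(ps):5d} detections in "
          f"{ps.points['frame'].nunique():3d}/{phase.n_frames} frames, "
          f"{100 * score['fraction_within']:.1f}% of reporting frames "
          f"within 1 pixel of the true core")

print()
print("Both detectors localize the known core wherever they report;")
print("the temporal-jump criterion is an event detector on smooth fields.")
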