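"""The full ionic-model agreement experiment for one remodeling scenario.

Simulates the 0.3 x ICaL (stable rotor) scenario on the desk-scale sheet
with adaptive cross-field initiation, then measures the agreement between
the two detectors across the location-centric threshold sweep. Takes a few
minutes of CPU.
"""

import numpy as np

from psmap.experiments import plateau_hausdorff, run_study, study_compare

movie = run_study("0.3xICaL")
print(f"S2 fired at {movie.meta['s2_time_ms']:.0f} ms; "
      f"{movie.n_frames} frames of {movie.shape} at {movie.dx_mm} mm")

res = plateau_hausdorff(movie)
print("\nthreshold sweep (M / pi -> H, mm):")
for m, h in zip(res["thresholds"], res["H_mm"]):
    tag = " (plateau)" if m in res["plateau_thresholds"] else ""
    print(f"  {m / np.pi:5.1f}  ->  {h:5.2f}{tag}")
print(f"\nplateau agreement: {res['mean_H_mm']:.2f} +/- {res['std_H_mm']:.2f} mm")

h40 = study_compare(movie, tau_ms=40.0).H_mm
print(f"agreement at tau = 40 ms: {h40:.2f} mm (about one display pixel)")
print()
print("Tight thresholds admit only the deep phase discontinuities at the")
print("rotor core and agreement is flat; loose thresholds admit conduction")
print("events far from the rotor and the distance diverges.")
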