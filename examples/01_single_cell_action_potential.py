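"""Pace a single atrial myocyte and report its action-potential metrics.

Runs the human atrial membrane model for one paced beat using the same
compiled stepper as the tissue solver, and prints the resting potential,
peak and APD90 — the numbers one checks first against the published model
behaviour (rest near -81 mV, amplitude ~104 mV, APD90 ~300 ms).
"""

from psmap import ap_metrics, pace_single_cell

t, V = pace_single_cell(n_beats=1, cl_ms=600.0, stim_amp_pA_per_pF=20.0)
m = ap_metrics(t, V)

print(f"resting potential : {m['V_rest_mV']:.1f} mV")
print(f"peak potential    : {m['V_peak_mV']:.1f} mV")
print(f"amplitude         : {m['amplitude_mV']:.1f} mV")
print(f"APD90             : {m['APD90_ms']:.0f} ms")
print()
print("APD90 is the time from the maximal upstroke to 90% repolarisation;")
print("it sets the reentry wavelength together with conduction velocity.")
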