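# psmap — phase-singularity mapping for cardiac fibrillation

During atrial or ventricular fibrillation, electrical activation organises
around rotors: spiral waves pivoting about a **phase singularity** (PS) — a
point with no defined phase whose neighbourhood spans the full −π…π cycle.
Rotor cores are candidate ablation targets, so locating PS fast and
reliably, frame by frame, matters both for mechanistic simulation studies
and for clinical mapping pipelines.

`psmap` is a library (plus a thin CLI) for people who work with 2D
transmembrane-voltage movies — from monodomain simulations or optical
mapping — and need to detect, compare and benchmark PS detectors:

* **phase construction** by time-delay embedding,
  θ(x, y, t) = atan2(V(t+τ) − V̄, V(t) − V̄), with per-pixel fibrillation-state
  mean V̄ and delay τ (default 30 ms);
* **two detectors**: the classic *line-integral* (Iyer–Gray) criterion
  (winding number ±1 on the 8-neighbour loop — needs neighbours, gives
  chirality) and the fast *location-centric* criterion (raw temporal phase
  jump θₙ₊₁ − θₙ < M, default M = −π — needs no neighbours, touches each
  pixel once);
* **agreement metrics**: symmetric Hausdorff distance
  H(A,B) = max(h(A,B), h(B,A)), h(A,B) = maxₚ minᵩ ‖p − q‖, between pooled
  PS trajectories at 0.5 mm display resolution, with threshold/delay/
  sampling-interval sweeps and wall-clock benchmarks;
* **synthetic data**: a 2D monodomain solver with the Courtemanche human
  atrial membrane model and electrical-remodeling scenarios (0.3×I_CaL,
  0.7×I_Na, a seven-multiplier chronic-AF set, gap-junction scaling), a fast
  two-variable surrogate, and analytic spiral fixtures with exactly known
  cores.

## Worked example

Detect a spiral core whose position is known exactly
(`examples/02_detect_on_analytic_spiral.py`):

```python
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
    ...
```

prints

```
iyer_gray        :  1592 detections in 398/398 frames, 100.0% of reporting frames within 1 pixel of the true core
location_centric :    83 detections in  71/398 frames, 100.0% of reporting frames within 1 pixel of the true core
```

— the line-integral criterion flags a small cluster at the core in every
frame; the temporal-jump criterion fires only when the moving core crosses
a pixel (it keys on temporal phase discontinuities), and wherever it fires
it pins the core exactly. On the same machine the temporal-jump pass over a
500 ms surrogate movie takes ~29 ms against ~1.7 s for the line integral
(`examples/03_surrogate_spiral_comparison.py`). For the full ionic-model
agreement experiment — remodeling scenarios, threshold plateau, Hausdorff
statistics — see `examples/04_remodeling_study.py`; `examples/01_...` checks
the single-cell action potential against its published behaviour.

## CLI

```bash
psmap simulate --scenario 0.3xICaL --size-cm 12 --duration 1060 --out movie.h5
psmap detect --method location-centric --tau 30 --threshold -3.14159 \
             --in movie.h5 --out ps.csv
psmap compare --in movie.h5 --window 450 1450
psmap fixtures --kind analytic-spiral --out spiral.h5 --truth truth.csv
```

Subcommands: `simulate`, `phase`, `detect`, `compare`, `sweep`,
`benchmark`, `fixtures`. Exit codes: 0 ok, 2 usage, 1 runtime error.
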