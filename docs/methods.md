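# Methods

This note documents the models, algorithms and numerical choices behind
`psmap`, and what the synthetic data do and do not establish about real
recordings.

## Problem

During atrial or ventricular fibrillation, electrical activation organises
around rotors — spiral waves whose pivot is a *phase singularity* (PS): a
point with no defined phase around which the neighbouring phase covers the
full −π…π cycle. Locating PS quickly matters because rotor cores are
candidate ablation targets, and because 3D/organ-scale maps contain millions
of nodes per frame. The package implements and compares two per-frame PS
detectors on 2D transmembrane-voltage movies:

* **line-integral (Iyer–Gray) criterion** — a pixel is a PS when the phase
  accumulated along its closed 8-neighbour loop is ±2π (winding number ±1);
  the sign gives the rotor's chirality;
* **location-centric criterion** — a pixel is a PS when its *raw* phase
  difference between successive frames drops below a negative threshold
  M (default −π). No neighbour information is used, which removes the
  neighbour-gather memory traffic and makes the criterion embarrassingly
  parallel; chirality is not determined.

## Phase construction

Phase is built per pixel by time-delay embedding around the pixel's temporal
mean:

    θ(x, y, t) = atan2(V(t+τ) − V̄, V(t) − V̄),   θ ∈ (−π, π]

* **Delay τ** — default 30 ms, swept over {10, 20, 30, 40} ms in the
  sensitivity analyses. τ must be an integer multiple of the frame interval;
  no temporal interpolation is performed (misalignment is an error).
* **Argument order** — the delayed signal is the ordinate (phase-plane
  V(t) vs V(t+τ)); the bracket order is ambiguous in parts of the
  literature, and flipping it only reverses the rotation sense, so it is a
  config switch (`delayed_first`).
* **V̄ (embedding origin)** — the per-pixel temporal mean *over the
  fibrillation state*. On records where the induced reentry terminates
  before the record ends, averaging the quiescent tail would drag V̄ to the
  resting potential and the embedded trajectory would no longer encircle the
  origin (verified: the temporal-jump detector goes silent); the study
  pipeline therefore averages over the active span of the record
  (`fibrillation_window`: frames with any pixel above −40 mV). Shorter
  windows (single action potential) or a fixed empirical map are supported
  for streaming use.
* **Degenerate pixels** — pixels whose trace never departs from V̄ have no
  defined phase; they get θ = 0, are flagged, and are excluded from PS
  candidacy.

A property both detectors inherit from this construction: the embedded
singularity lives where *both* V(t) and V(t+τ) cross V̄, i.e. between the
true core positions at t and t+τ. For moving cores the apparent PS lags the
instantaneous core by up to the core displacement over τ; accuracy tests on
moving-core fixtures compare against the truth half a delay later.

A second structural property: the location-centric criterion is an *event*
detector. On a perfectly smooth, rigidly rotating spiral with a stationary
core every pixel's phase advances by −ω·Δt per frame and the only
discontinuities are the positive 2π wraps, so the criterion never fires —
a stationary, phase-static core is its stated blind spot. Detection requires
the core to move across pixels (fibrillatory rotors always meander), and the
temporal jumps it keys on are then genuinely below −π while depolarisation
upstrokes give *positive* jumps, which is why only negative jumps are
singular and why the difference is deliberately not wrapped (wrapping would
fold every jump into (−π, π] and empty the criterion).

## Detectors — numerical conventions

* 8-neighbour loop traversed counter-clockwise in display coordinates (row
  axis down), starting east: E, SE, S, SW, W, NW, N, NE. With this
  traversal, `atan2(row−r0, col−c0)` has winding +1.
* Wrapped differences map to the half-open interval (−π, π]; ties at ±π
  resolve to +π.
* Winding numbers outside {−1, 0, +1} indicate an under-resolved phase
  field and raise a warning.
* The line-integral detector needs a 1-cell border margin; the
  location-centric detector needs none (one of its practical advantages).
* Both detectors report *all* flagged pixels — a rotor core typically shows
  as a small cluster (often ~4 pixels) under the line integral and a single
  pixel under the temporal jump; an optional connected-component centroid
  reducer exists but is off by default.
* A temporal-jump detection between frames n and n+1 is stamped at n+1 (the
  frame where the new phase holds); configurable.

## Agreement metric

Detections are pooled over the analysis window into two planar point sets,
snapped to the 0.5 mm display resolution (twice the historical 0.25 mm
compute grid; results are *reported* at display resolution), and compared
with the symmetric Hausdorff distance

    H(A,B) = max(h(A,B), h(B,A)),  h(A,B) = max_{p∈A} min_{q∈B} ‖p−q‖  (mm).

Distance to an empty set is an error, never NaN. The implementation uses a
k-d tree and is tested for exact agreement with the defining double loop.
A per-frame variant exists; the pooled-trajectory form is the default
because the comparison targets trajectories.

**Threshold plateau.** Sweeping the location-centric threshold M over
{−1.8π … −0.2π} produces a characteristic curve: for tight (very negative)
M only the deep singularity jumps are admitted and H is flat — the
*plateau*; loose thresholds start admitting conduction events (wavefront
collisions, stimulus edges) far from any rotor and H diverges. The plateau
is identified operationally as the maximal run of consecutive thresholds
from the tight end whose H stays within 1 mm of the tight-end value; the
plateau mean ± spread is the study's agreement statistic. On the desk-scale
runs the divergence typically begins around M = −0.6π, one bin earlier than
on full-size maps.

## Tissue model

Monodomain reaction–diffusion on a uniform 2D sheet:

    ∂V/∂t = −(I_ion + I_stim)/C_m + D (∂²V/∂x² + ∂²V/∂y²)

with D = 0.001 cm²/ms, C_m = 1 µF/cm², 5-point Laplacian, no-flux boundaries
by ghost-node mirroring (the spatial mean is conserved exactly under pure
diffusion), no fibre anisotropy. I_ion is the Courtemanche–Ramirez–Nattel
human atrial membrane model (21 states: V, 12 Hodgkin–Huxley gates, the SR
release machinery u/v/w/fCa, and Na⁺/K⁺/Ca²⁺ concentrations), implemented
from its published description and validated against an independent stiff
integration (SciPy LSODA) of the same right-hand side: resting potential
−81.2 mV, amplitude ~104 mV, APD90 ≈ 308 ms at the first paced beat.

**Electrical remodeling scenarios** are named multiplier sets on
conductances/fluxes (applied functionally; the base parameters are never
mutated): `0.3xICaL` (70 % I_CaL reduction — the stable-rotor condition),
`0.7xINa`, the seven-multiplier chronic-AF set (I_Na −10 %, I_to −70 %,
I_CaL −70 %, I_Kur −50 %, SR Ca leak +25 %, I_K1 +100 %, I_NaCa,max +40 %),
and gap-junction scenarios `0.7xD` and `0.3xD` scaling D.

**Integration.** Operator splitting: diffusion advances explicitly at the
coarse step dt_max = 0.1 ms (stability factor D·dt/dx² ≤ 0.25 is enforced);
each cell's ionic ODEs advance by Rush–Larsen for the gates (exact for
frozen V) and forward Euler for concentrations, substepping to
dt_min = 0.01 ms whenever that cell's reaction rate |dV/dt| exceeded
1 mV/ms on the previous step. A global time step pinned to dt_min by the
ever-present wavefronts would make desk-scale runs infeasible; per-cell
substepping is the standard alternative and respects the same bounds.
Voltage-dependent rates, steady states and Rush–Larsen factors are
tabulated on a 0.05 mV lookup grid with linear interpolation; the inner
loop is compiled (numba) and the solver is deterministic — identical
configurations give bit-identical movies. Halving both step bounds changes
a paced single-cell trace by < 0.5 mV. Leaving |V| > 300 mV or non-finite
aborts with the failing time and cell.

**Stimulation.** Cross-field S1–S2: S1 is a left-edge stripe (vertical
wavefront), S2 the bottom half-plane, both 2 ms injections of 40 pA/pF
(~2–4× diastolic threshold; the single-cell threshold for a 2 ms pulse is
~10–20 pA/pF and edge stripes face electrotonic load). `run_monodomain`
uses a fixed coupling interval (default 300 ms, the full-size convention).
The study runner `run_study` instead *times S2 adaptively*: it fires when
40 % of the sheet is excited-and-recovered (below −70 mV) while refractory
tissue remains — the protocol's structural intent (S2 into the partially
recovered repolarisation tail), robust across scenarios whose APD ranges
from ~100 to ~310 ms. The firing time is recorded in the movie metadata.

## Desk-scale study conditions

* **Domain 12 × 12 cm, grid 0.5 mm (240 × 240).** The agreement statistic
  requires reentry that survives the 1-s analysis window. The unremodeled
  wavelength (~10 cm) cannot re-enter on a 5 cm sheet — probes showed every
  long-wavelength scenario terminating 100–250 ms after S2 with pooled sets
  of ~10 display pixels. Keeping a near-full-size sheet and coarsening the
  grid to 0.5 mm preserves the wavelength physics and the millimetre scale
  of the Hausdorff values at a quarter of the cost; 12 cm is the smallest
  size that sustained control reentry through the window. Waves remain well
  resolved (≥ 60 grid points per wavelength). The 0.5 mm *reporting*
  resolution is unchanged.
* **Analysis window**: 1 s starting 200 ms (≈ one rotor period) after S2,
  so the statistic describes the *established* reentry. The immediate
  post-S2 wavebreaks are short-lived and asymmetrically visible to the two
  detectors (the temporal-jump criterion needs a moving, cycling core),
  so including them measures initiation debris rather than rotor-tracking
  agreement; the full-size experiment likewise analyses a window starting
  hundreds of milliseconds after S2.
* **Fine-sampling comparison** (0.1 ms vs 1 ms phase sampling): measured on
  a 500 ms window of the same record, fine first, then decimated ×10 — the
  difference isolates the sampling-interval effect. (A full-second 0.1 ms
  240×240 float32 movie plus its phase would not fit comfortably in memory
  alongside the rest of the pipeline.)

## Synthetic fixtures

* **Analytic spiral** — `V = offset + amp·cos(atan2(Δy, Δx) + k·dist − ωt)`
  with a core that is static or orbits a circle; the core pixel per frame is
  exact ground truth. The accuracy fixture orbits at ~0.7 pixel/frame with a
  2 ms embedding delay, balancing the location-centric detector's need for
  core motion against the embedding lag (above). It contains no wavefront
  curvature, restitution, meander or noise — passing it shows correct
  geometry/topology handling, not robustness to real-signal artefacts.
* **Two-variable surrogate** (Aliev–Panfilov kinetics) — a phenomenological
  excitable medium that sustains a rotor on a 3 cm sheet in seconds of
  compute; used for fast integration tests and benchmarks. Its time unit is
  mapped to 12.5 ms so frames land exactly on a 1 ms grid (rotor period
  ≈ 140 ms). It reproduces spiral topology and meander but not atrial
  electrophysiology (no restitution detail, no remodeling pharmacology), so
  it never stands in for the ionic model in the agreement experiments.

## Benchmarks

Wall-clock comparisons share one phase computation, exclude I/O, discard a
warm-up pass, and report the median of ≥3 repeats on a monotonic clock.
Only the *direction* of the difference (location-centric faster) is treated
as meaningful; fold-changes are hardware- and language-specific. Complexity:
the temporal-jump criterion touches each pixel once per frame pair; the
line integral touches each interior pixel plus its 8 neighbours.

## Known limitations

* The location-centric criterion cannot detect a core whose phase is static
  in time, and assigns no chirality. The flip side also occurs: the
  line-integral criterion reports every topological defect of the embedded
  phase field, including quasi-static ones — e.g. the endpoint of a V ≈ V̄
  contour inside a large, slowly repolarising region — which the
  temporal-jump criterion then never confirms. Under strong gap-junction
  reduction such episodes can dominate the *symmetric* worst-case Hausdorff
  distance even though every temporal-jump detection still lies on the
  line-integral trajectory; the directed distances disambiguate the two
  failure modes.
* 2D homogeneous tissue only: no fibre orientation, fibrosis, 3D or
  irregular meshes.
* Desk-scale runs coarsen the grid 2× relative to the historical 0.25 mm
  convention; Hausdorff values are quantized by the 0.5 mm snap and
  scenario-level agreement values carry that granularity.
* The S1–S2 geometry and stimulus strength are conventions; exact PS birth
  sites are protocol-dependent and only the statistical/structural
  behaviour of the agreement measures is reproducible.
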