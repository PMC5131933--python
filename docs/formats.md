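# File formats

## Voltage / phase movies

**HDF5** (`.h5`, `.hdf5`):

| object | content |
| --- | --- |
| `/frames` | `float32`, `T x H x W`, mV (or radians for phase carriers) |
| attr `dx_mm` | pixel spacing, mm (required) |
| attr `frame_interval_ms` | sampling interval, ms (required) |
| attr `t0_ms` | time of the first frame, ms |
| attrs `meta_*` | provenance: solver, scenario, stimulus geometry/timing, ... (JSON-encoded when structured) |

**NPZ fallback** (`.npz`): arrays `frames`, `dx_mm`, `frame_interval_ms`,
`t0_ms` and a JSON string `meta`.

Reading a movie without `dx_mm` or `frame_interval_ms` is a hard error; no
defaults are assumed.

Pixel `(row, col)` sits at physical position `x = col * dx_mm`,
`y = row * dx_mm` (row-major, origin at the top-left pixel).

## Phase-singularity tables (`.csv`)

Header comments carry grid metadata, then one detection per line:

```
# dx_mm=0.5
# frame_interval_ms=1.0
# config={"method": "iyer_gray", ...}
method,frame,t_ms,row,col,x_mm,y_mm,chirality
iyer_gray,12,463.0,118,92,46.0,59.0,1
```

* `frame` indexes the *phase* movie; `t_ms` is absolute time.
* `row`, `col` are 0-based compute-grid indices; `x_mm`, `y_mm` the physical
  position.
* `chirality` is the winding sign (+1 / -1) for the line-integral detector
  and 0 (unknown) for the location-centric detector.
* Rows are unique in `(frame, row, col)` and sorted by frame, then row-major.
* All angles anywhere in the package are radians.

## Run configurations (`.yaml`)

Plain YAML mappings (see `psmap.io.save_config` / `load_config`); they
round-trip losslessly and every solver/phase/detector default can be
overridden.
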