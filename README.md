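# sfxprep

Desk-scale pre-processing pipeline for serial femtosecond crystallography
(SFX) detector data, exercised entirely on synthetically generated
diffraction frames with known ground truth:

* **calibration** — dark-reference construction and conversion of raw
  multi-module ADU frames to 16-bit integer "deci-photon" images
  (`value = round((ADU − dark) · gain · 3.65 / photon_energy · 10)`;
  ten units = one photon),
* **spot finding** — inclusive thresholding, connected components (4/8
  connectivity), area and local-SNR filters, saturation flags,
* **hit classification** — a cheap ROI max/mean blank-rejection pre-filter
  plus the accepted-spot-count rule (default: ≥ 20 spots), and pump–probe
  light/dark classification from photodiode readouts,
* **multi-event HDF5 output** — one `tag-N` group per event, deflate
  compression (default level 5), transparent decompression,
* **monitoring** — per-frame spot / saturated-spot counts, rolling hit
  rate, per-run summary tables, optional trace plot,
* **orchestration** — the eight-watermark producer–consumer tag dispatch
  contract (`TagTracker`), run splitting into parallel-style jobs, and
  crash recovery from the monitor log,
* **parameter tuning** — exhaustive grid search over spot-finder
  parameters scored by precision/recall/F1 against synthetic ground truth,
  including beam-center-offset recovery via a ring-exclusion mask,
* **synthetic data** — a deterministic generator producing runs laid out
  as a dark block (default 150 frames) followed by exposed frames
  (default 5000), with planted Gaussian Bragg spots, a carrier-medium
  scattering ring, saturation, and per-frame ground truth.

## Conventions

The detector is 8 modules of 512 (fast) × 1024 (slow) pixels.  In memory
the modules are stacked along the slow axis into an `(8192, 512)` array:
rows are the stacking dimension, module *m* occupies rows
`m·1024 … (m+1)·1024 − 1`; panel arrays are indexed `[slow, fast]`,
0-based, pixel centers at integer coordinates.  Default metrology: panels
stacked contiguously, beam center at the array center, 0.05 mm pixels,
50 mm camera length, per-module gain 10 e⁻/ADU (one 7300 eV photon =
2000 electrons = 200 ADU).

## CLI

```sh
sfx-prep simulate --out runs/ --n-dark 150 --n-exposed 5000 --mini --seed 1
sfx-prep process  --out out/  --raw runs/run-1.raw.h5 --n-dark 150 --n-exposed 5000 --mini
sfx-prep monitor  --log out/monitor.tsv --n-dark 150 --plot trace.png
sfx-prep tune     --out grid.csv --grid grid.yaml --mini
sfx-prep geom     --out detector.geom
```

`--mini` selects the 8×(64×128) test geometry; `--full` the 512×1024
panels.  `process` writes `dark.h5`, `hits.h5` (or `hits_light.h5` /
`hits_dark.h5` for pump–probe runs), `monitor.tsv`, `summary.json` and a
full `config.yaml` parameter snapshot.  A tuning grid file looks like:

```yaml
axes:
  pixel_threshold: [30.0, 50.0, 100.0]
  min_snr: [3.0, 5.0]
subset_size: 100
```

## Event-store schema

```
/metadata                  file-level attributes (run id, parameter snapshot)
/tag-N/data                int16 stacked image, deflate, one chunk per panel
/tag-N/peaks               float64 (n_spots, 5): fast, ss, panel, intensity, snr
/tag-N@photon_energy_ev    /tag-N@spectrum_mean_ev
/tag-N@photodiode          /tag-N@n_spots
```

Group names derive from the pulse tag, so re-processing a run reproduces
identical names.  Readers ignore unknown extra members.

## Tutorial: simulate → process → tune

```python
import sfxprep as sp
from sfxprep.fixtures import mini_geometry, mini_params

geom = mini_geometry()
manifest = sp.RunManifest(n_dark=15, n_exposed=200)
config = sp.PipelineConfig(geometry=geom, sim=mini_params(seed=1))
summary, paths = sp.process_run(manifest, config, "out/")
print(summary.hit_rate, sp.list_tags(paths["hits"]))
```

then tune the spot finder against ground truth:

```python
frames, truths = sp.simulate_run(manifest, config.sim, geom)
dark = sp.compute_dark(frames[:15])
calib = sp.CalibrationParams(gains=geom.gains)
pairs = [(sp.calibrate(f, dark, calib), t) for f, t in zip(frames[15:], truths[15:])]
grid = sp.ParamGrid(axes={"pixel_threshold": (30.0, 50.0, 100.0)}, subset_size=100)
result = sp.grid_search(pairs, grid, sp.SpotFindParams())
print(result.best, result.config_snippet())
```

Named seeded fixtures (`mini-run`, `standard-run`, `pump-probe-run`) are
regenerated deterministically with
`sfxprep.fixtures.make_fixture(name, out_dir)`.

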