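# Session file format

One session = one exercise trial, stored as a JSON envelope plus a side-car
CSV of raw samples next to it. All angles are degrees; all times are seconds
since trial start. `read_session(write_session(record))` is bit-exact.

## JSON envelope (`<name>.json`)

```json
{
  "schema": "vestkit-session/1",
  "subject_id": "S017",
  "condition": "app",
  "prescription": {
    "exercise": "vor_yaw",
    "amplitude_deg": 20.0,
    "frequency_hz": 1.0,
    "duration_s": 60.0,
    "angular_velocity_deg_s": null
  },
  "series": {
    "sample_rate_hz": 50.0,
    "frame": "head",
    "reference": "absolute",
    "samples_csv": "<name>.samples.csv"
  },
  "metrics": null,
  "errors": null,
  "game_result": null
}
```

Field rules:

* `subject_id` — non-empty, caller-supplied, opaque (no identifier
  generation or hashing is performed).
* `condition` — `"app"` or `"no_app"`.
* `prescription.exercise` — one of `vor_yaw`, `vor_pitch`, `ws_ml`,
  `ws_ap`, `ws_omni`, `sls_left`, `sls_right`. `amplitude_deg` must be
  positive except for single-leg exercises; `duration_s` positive;
  `angular_velocity_deg_s` optional (must agree with `frequency_hz` to 1 %
  when both are set, under the sweep model `v = 4 A f`).
* `series.frame` — `"head"` for VOR exercises, `"pelvis"` otherwise
  (validated against the exercise). `reference` is `"absolute"` or
  `"neutral-relative"`.
* `metrics` — written by the analysis: either
  `{"kind": "cycle", "rom_mean_deg": ..., "rom_var_deg2": ...,
  "freq_mean_hz": ..., "freq_var_hz2": ..., "n_cycles": ...}` or
  `{"kind": "balance", "resultant_rom_deg": ..., "fluency": ...}`
  (`fluency` is `null` for a motionless trial).
* `errors` — written by detection:
  `{"events": [...], "summary": {...}, "thresholds": {...}}` with events
  `{window_index, t_start, t_end, error_type, severity}` and the summary
  carrying per-type `made` / `corrected` / `not_corrected` booleans plus the
  per-window boolean raster (`window_grid`).
* `game_result` —
  `{game, coins, opportunities, max_coins, fraction, trophy}`.
* Unknown top-level keys are preserved on a read/write round trip but
  otherwise ignored; the toolkit itself uses `truth` (injected-error ground
  truth of synthetic sessions) and `provenance` (seeds and generator
  settings).

## Sample CSV (`<name>.samples.csv`)

Header `t,roll_deg,pitch_deg,yaw_deg`, one row per sample. Optional
quaternion columns `qw,qx,qy,qz` (unit norm within 1e-6) follow when the
device supplied them. Timestamps must be non-negative, strictly increasing,
with a median interval within 10 % of `1 / sample_rate_hz`; all values must
be finite — a non-numeric or non-finite cell is reported with its line
number.
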