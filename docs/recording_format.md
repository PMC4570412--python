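# Recording container format

A *recording* stores one performance of one test movement by one subject.
Two layouts are accepted by `fmakit.read_recording` / written by
`fmakit.write_recording`; both round-trip all values to at least 9
significant digits. All timestamps are seconds relative to recording start.

## JSON document (`*.json`)

One JSON object per recording:

```json
{
  "format_version": 1,
  "test_id": "forearm_supination",
  "subject_id": "S01",
  "side": "right",
  "true_score": 2,
  "streams": {
    "skeleton": {
      "nominal_rate": 30.0,
      "frames": [
        {
          "t": 0.0,
          "pos": {"neck": [0.0, 0.55, 2.0], "wrist_r": [0.1, 0.2, 1.9]},
          "status": {"neck": "tracked", "wrist_r": "tracked"}
        }
      ]
    },
    "imu": {
      "placement": "wrist",
      "nominal_rate": 100.0,
      "samples": [[0.0, 0.01, -0.02, -1.0, 0.5, -0.1, 0.0]]
    },
    "glove": {
      "nominal_rate": 100.0,
      "raw_max": 1023,
      "samples": [[0.0, 120.0, 131.5, 118.0, 110.2, 105.9]]
    },
    "pressure": {
      "nominal_rate": 30.0,
      "samples": [[0.0, 5.2]]
    }
  }
}
```

* `side` is `left` or `right`; `true_score` is 0/1/2 or `null` (unknown).
* Joint names: `neck`, `shoulder_l/r`, `elbow_l/r`, `wrist_l/r`, `hand_l/r`.
  Unknown names are rejected. Joint status is `tracked`, `inferred` or
  `missing`; positions of `missing` joints are stored as `[null, null, null]`.
* `imu.samples` rows are `[t, accel_x, accel_y, accel_z, gyro_x, gyro_y,
  gyro_z]` — accelerometer in g, gyroscope in deg/s.
* `glove.samples` rows are `[t, thumb, index, middle, ring, little]` raw
  counts in `[0, raw_max]`; larger = more flexed. A glove with an embedded
  IMU carries an `imu` object inside the glove block.
* `pressure.samples` rows are `[t, value]`, raw counts ≥ 0.
* Streams the recording lacks are absent, never empty. If `test_id` names a
  registry test, the streams that test requires must be present.

## CSV directory

A directory with a `meta.json` sidecar (same metadata keys as above plus
per-stream rates) and one CSV per stream, each with a header row
`timestamp,<channel...>`:

| file           | columns                                                        |
|----------------|----------------------------------------------------------------|
| `skeleton.csv` | `timestamp`, then `<joint>_x,<joint>_y,<joint>_z,<joint>_status` per joint |
| `imu.csv`      | `timestamp,accel_x,accel_y,accel_z,gyro_x,gyro_y,gyro_z`       |
| `glove.csv`    | `timestamp,flex_thumb,flex_index,flex_middle,flex_ring,flex_little` |
| `glove_imu.csv`| as `imu.csv` (embedded glove IMU, if any)                      |
| `pressure.csv` | `timestamp,value`                                              |

Occluded skeleton samples have empty position cells and status `missing`.
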