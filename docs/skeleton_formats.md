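# Skeleton file formats

## Canonical joint numbering

| index | joint          | group |
|------:|----------------|-------|
| 1     | head           | P3    |
| 2     | neck           | P3    |
| 3     | spine          | P3    |
| 4     | left_shoulder  | P1    |
| 5     | left_elbow     | P1    |
| 6     | left_wrist     | P1    |
| 7     | right_shoulder | P2    |
| 8     | right_elbow    | P2    |
| 9     | right_wrist    | P2    |
| 10    | left_hip       | P4    |
| 11    | left_knee      | P4    |
| 12    | left_ankle     | P4    |
| 13    | right_hip      | P5    |
| 14    | right_knee     | P5    |
| 15    | right_ankle    | P5    |

Coordinates are x, y, z in meters in the sensor camera frame. The
encoding is scale- and translation-invariant, so units cancel.

## Long-format CSV (`skeletons.csv`)

One row per frame per joint:

```
sample_id,frame,joint_index,joint_name,x,y,z
s01_CLAP_front0,0,1,head,0.012,0.713,-0.004
...
```

- `frame` is 0-based and contiguous within a sample.
- `joint_index` is the canonical 1–15 index above; `joint_name` is
  informative and must agree with it.
- All 15 joints must be present for every frame; values must be finite.

A dataset directory also carries `manifest.csv` with one row per sample:
`sample_id, subject, class, viewpoint` (and optionally `seed`).

## JSONL

One frame object per line:

```json
{"sample_id": "s01_CLAP_front0", "frame": 0,
 "joints": {"head": [0.012, 0.713, -0.004], "neck": [...], ...}}
```

Extra joints beyond the canonical 15 (e.g. hands) are silently
discarded on read; missing required joints are an error.

## KARD per-sample text files (optional reader)

Each line is `x y z` for one joint, 15 lines per frame, frames
concatenated, in the KARD order: head, neck, torso, right shoulder,
right elbow, right hand, left shoulder, left elbow, left hand, right
hip, right knee, right foot, left hip, left knee, left foot. The reader
maps hand→wrist and foot→ankle onto the canonical numbering.
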