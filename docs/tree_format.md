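# Coronary tree file format

Trees serialise to JSON (`CoronaryTree.to_json` / `from_json`); the CLI
writes one file per cohort lesion (`tree_001.json`, ...) next to
`cohort_manifest.json`. All geometric fields carry their unit in the name.

```json
{
  "inlet_id": 0,
  "segments": [
    {
      "segment_id": 0,
      "parent_id": null,          // null marks the root (inlet) segment
      "length_cm": 1.62,
      "radius_cm": 0.15,          // healthy lumen radius
      "wire_present": false,
      "stenosis": null            // or the object below
    },
    {
      "segment_id": 1,
      "parent_id": 0,
      "length_cm": 1.21,
      "radius_cm": 0.126,
      "wire_present": false,
      "stenosis": {
        "degree": 0.7,            // fractional AREA reduction, 1 - A_s/A_0
        "stenosis_length_cm": 0.6,
        "position": 0.5           // fractional offset along the segment
      }
    }
  ],
  "measurement": {
    "lesion_segment_id": 1,
    "distal_offset_cm": 2.5,      // nominal sensor distance past the lesion
    "segment_id": 3               // resolved segment whose distal node is p_d
  },
  "wire": {                       // present only on wire-included trees
    "path": [0, 1, 3],            // ordered segment ids from inlet to sensor
    "wire_diameter_cm": 0.036
  }
}
```

Constraints: segment ids unique; every non-root segment names an existing
parent; the graph is a rooted tree (one inlet, no cycles); `degree` lies in
[0, 1) (total occlusion is rejected); a wire must fit every lumen on its
path, stenotic throats included.
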