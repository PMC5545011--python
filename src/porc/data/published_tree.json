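{
  "name": "published-muscle-function-pathway",
  "version": "1",
  "comment": "Fixed decision pathway over bedside muscle-function tests. Node ids follow the published figure's preorder numbering; terminals are 3, 5, 6, 8, 10, 11. Thresholds use the 'score >= t goes right' convention. The interior eye-opening split (nodes 4-6) is an encoding choice consistent with the validated four-test battery (arm lift, head lift, swallowing, eye opening); re-encode via JSON if a different interior is wanted.",
  "nodes": [
    {"id": 1, "kind": "internal", "variable": "arm_lift", "threshold": 5, "left": 2, "right": 7},
    {"id": 2, "kind": "internal", "variable": "head_lift", "threshold": 2, "left": 3, "right": 4},
    {"id": 3, "kind": "terminal", "block_lt_07": true, "block_lt_09": true, "tofr_band": "<0.3"},
    {"id": 4, "kind": "internal", "variable": "open_eyes", "threshold": 5, "left": 5, "right": 6},
    {"id": 5, "kind": "terminal", "block_lt_07": true, "block_lt_09": true, "tofr_band": "0.3-0.7"},
    {"id": 6, "kind": "terminal", "block_lt_07": true, "block_lt_09": true, "tofr_band": "0.3-0.7"},
    {"id": 7, "kind": "internal", "variable": "head_lift", "threshold": 5, "left": 8, "right": 9},
    {"id": 8, "kind": "terminal", "block_lt_07": true, "block_lt_09": true, "tofr_band": "0.4-0.9"},
    {"id": 9, "kind": "internal", "variable": "swallow", "threshold": 3, "left": 10, "right": 11},
    {"id": 10, "kind": "terminal", "block_lt_07": true, "block_lt_09": true, "tofr_band": "0.5-0.9"},
    {"id": 11, "kind": "terminal", "block_lt_07": false, "block_lt_09": false, "tofr_band": ">0.7"}
  ]
}
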