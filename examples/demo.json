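{
  "scene": "demo",
  "room": "room2",
  "viewpoint": {
    "place": [0.0, 0.0, 1.2],
    "head": [-0.7853981633974483, 0.0],
    "eyes": [0.0, 0.0],
    "convergence": 0.0,
    "baseline": 0.06
  },
  "light": {
    "direction": [0.2, -0.2, 0.95],
    "ambient": 0.1,
    "diffuse": 0.6,
    "specular": 0.3,
    "exponent": 8.0
  },
  "imaging": {"n_rows": 32, "n_cols": 32, "extent_deg": 40.0},
  "plant": {"inertia": 1.0, "damping": 2.0, "convergence": 0.1,
            "phi": [0.3, 0.2], "dt": 0.001, "T": 2.0},
  "planner": {
    "policies": [
      {"label": "southeast", "head": [-0.7853981633974483, 0.0]},
      {"label": "northeast", "head": [0.7853981633974483, 0.0]},
      {"label": "southwest", "head": [-2.356194490192345, 0.0]},
      {"label": "northwest", "head": [2.356194490192345, 0.0]}
    ]
  },
  "outdir": "demo_out"
}
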