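# gazesim

A desk-scale simulator of *active vision as a generative model*, for
computational neuroscientists studying how looking and seeing interact.
Instead of analysing images bottom-up, `gazesim` generates binocular
retinal images top-down — from a categorical prior over rooms, through
recursively assembled object geometry and a gaze-dependent field of
view, down to ray-cast, Blinn–Phong-shaded, DCT-blurred retinal
intensity grids — then simulates the saccadic dynamics that move the
eyes and selects fixations by expected information gain.

## The model in brief

**Seeing.**  A room x^a draws objects, each assembled by a recursive
affine chain applied to sphere-mesh parts: vertices v ↦ T + R(θ,φ,ϕ)·S(e^α,e^β,e^γ)·v.
The viewer's allocentric gaze is p = d + e (head direction plus
egocentric eye direction); each eye carries a uniform pinhole retina
whose cell (i, j) looks along a fixed angular offset from the gaze.  A
cell's intensity is the shaded nearest surface hit of its line of sight,

    I = α + η_light · ( c₁ max(0, n·z) + c₂ max(0, n·h)^{c₃} ),

with z the light direction, n the surface normal, h the half-vector,
and η_light a cast-shadow indicator; the image is retinally inverted and
low-pass filtered in the 2-D DCT domain.

**Looking.**  Saccades follow a damped second-order plant
J·θ̈ = φ − θ − κ·θ̇ toward an equilibrium point φ, read out by II
(position) and Ia (velocity) proprioceptive afferents whose heading
channels are offset ±ω/2 by the vergence angle.  A candidate fixation π
is scored by the mutual information between room identity X and
predicted images Y,

    I[X, Y | π] = H[P(y|π)] − E_{P(x|π)} H[P(y|x,π)],

i.e. predictive entropy minus expected ambiguity, and beliefs over
rooms are updated by exact Bayes against rendered observations.

## Worked example

The built-in world has three equiprobable rooms in a shared 5×5×3 m
shell.  The southeast corner holds a stacked-sphere object in rooms 2
and 3 but is empty in room 1; the northeast corner is empty everywhere;
rooms 2 and 3 differ at the southwest/northwest corners.

```python
import gazesim as gz
from gazesim.planner import demo_context, demo_policy

library = gz.build_demo_library()
ctx = demo_context()                      # 32x32 retina, 40 deg field
corners = {c: demo_policy(c) for c in
           ("southeast", "northeast", "southwest", "northwest")}

report = gz.rank_policies(library.prior,
                          [corners["southeast"], corners["northeast"]],
                          library, ctx)
for s in report.scores:
    print(f"{s.label:10s} entropy={s.predictive_entropy:.4f} "
          f"gain={s.info_gain:.4f} bits")

obs = ctx.render(library.rooms[1], corners["southeast"])   # see object 1
posterior = gz.update_belief(library.prior, obs, corners["southeast"],
                             library, ctx)
print("posterior:", posterior)
print("southwest gain now:",
      gz.expected_information_gain(posterior, corners["southwest"],
                                   library, ctx))
```

prints

```
southeast  entropy=0.9183 gain=0.9183 bits
northeast  entropy=0.0000 gain=0.0000 bits
posterior: [0.  0.5 0.5]
southwest gain now: 1.0
```

A southeast fixation could reveal either an empty corner (room 1,
probability 1/3) or object 1 (rooms 2–3, probability 2/3), so its
predictive entropy is H(1/3, 2/3) ≈ 0.918 bits; the northeast view is
the same in every room and teaches nothing.  Having seen object 1, only
rooms 2 and 3 remain, the original views drop to zero gain, and the
southwest/northwest corners — where the surviving rooms differ — become
the salient fixations (1 bit each).

The same scenario is available from the shell:

```sh
gazesim plan -c examples/demo.json --out plan_out \
    --update southeast --observed-room room2
# best policy: northwest (info gain 0.9183 bits); report in plan_out/report.csv
```

(Under the *uniform* prior all three object-bearing corners tie at
0.918 bits and the tie breaks alphabetically; `posterior.csv` holds the
updated belief (0, 0.5, 0.5).)  `gazesim render` writes per-eye shaded
and blurred images as 16-bit PGM/PNG, `gazesim saccade` writes the
plant trajectory CSV and a proprioception plot, and `gazesim
lesion-demo` renders the intact, monocular and hemianopic conditions.

## Layout

- `src/gazesim/scene.py` — mesh primitives, affine hierarchy, room
  library, lesions, scene-file I/O
- `src/gazesim/viewpoint.py` — gaze arithmetic, retinal arrays,
  binocular field of view
- `src/gazesim/render.py` — ray casting, shading, blurring, lesion
  modes, image output
- `src/gazesim/oculomotor.py` — saccade plant, closed form, RK4,
  proprioception
- `src/gazesim/planner.py` — outcome clustering, entropies, information
  gain, belief updates
- `src/gazesim/config.py`, `src/gazesim/cli.py` — run configuration and
  the `gazesim` command

See `docs/methods.md` for modelling assumptions, parameter defaults and
numerical choices.
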