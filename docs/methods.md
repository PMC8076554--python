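# Methods

## The model

`gazesim` implements a top-down (generative) account of foveal vision at
desk scale.  Sensory images are *generated* from latent causes rather
than analysed from pixels, in four stages:

1. **Scene** (`gazesim.scene`).  A categorical prior selects one of a
   library of rooms.  A room is a list of placed objects; an object is a
   recursive configuration of parts bottoming out in a unit-sphere
   primitive.  Every level of the hierarchy applies the same
   deterministic affine chain — anisotropic scaling, rotation,
   translation, in that fixed order — to a triangulated surface mesh.
   Scales are parameterized on a log scale, so the realized factors are
   positive by construction; the deterministic maps are the zero-variance
   limit of Gaussian factors, i.e. all uncertainty is carried by the
   priors over transform parameters rather than injected into geometry.
2. **Viewpoint** (`gazesim.viewpoint`).  The allocentric gaze is the sum
   of head direction and egocentric eye direction, per axis; heading
   wraps to (−π, π].  Each eye carries a uniformly spaced array of
   retinal cells behind a pinhole lens — a deliberate foveal
   simplification that ignores the eccentricity-dependent fall-off of
   receptor density.  The two eyes sit half an interocular baseline to
   either side of the head position, and the convergence angle ω splits
   their gaze headings symmetrically (±ω/2).
3. **Rendering** (`gazesim.render`).  For each cell a ray is traced from
   the lens along the cell's preferred incidence direction; the nearest
   surface hit is shaded as ambient + shadowed Blinn–Phong
   (diffuse + specular with a half-vector), a *single-bounce*
   simplification in which surfaces reflect the directional source to the
   retina but do not illuminate one another.  Intensities are written at
   the retinally inverted grid location (both image axes flipped, as in a
   pinhole eye), then low-pass filtered by attenuating 2-D DCT
   coefficients with a Gaussian centred on the DC term — compensating
   for the artificial high frequencies of a point-lens model.
4. **Action** (`gazesim.oculomotor`, `gazesim.planner`).  Saccades relax
   the conjugate eye angle θ toward an equilibrium point φ under
   J·θ̈ = φ − θ − κ·θ̇ (an equilibrium-point reading of motor control);
   proprioceptive II/Ia afferents report position and velocity per eye,
   with the ω offset applied to heading only.  Candidate fixations are
   scored by expected information gain — the mutual information between
   room identity and predicted images — and beliefs over rooms are
   updated by exact Bayes against rendered observations.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| sphere `resolution` | latitude bands | 8 | ~224 faces: resolves the demo objects at 32×32 pixels at interactive cost |
| retinal array | cells | 32 × 32 | small enough for exact outcome enumeration, large enough that a ~9° object spans several cells |
| angular extent | rad | 40° | a generous foveal/parafoveal field |
| interocular baseline | m | 0.06 | adult human; set 0 for a cyclopean viewer in symmetry tests |
| light (α, c1, c2, c3) | — | 0.1, 0.6, 0.3, 8 | ambient floor, dominant diffuse, modest highlight; all configurable |
| blur σ | DCT index | min(rows, cols)/6 | attenuates the top ~⅔ of the spectrum while leaving object-scale structure |
| plant J | a.u. | 1 | sets the time scale only |
| plant κ | a.u. | 2 | critical damping at J=1: fast settling with no overshoot oscillation |
| Π_f, Π_g | a.u. | 10⁴ | small but visible noise when a seed is supplied |
| cluster tol | intensity | 1e-6 | far below any physical contrast, far above float error |

## The demonstration world

`build_demo_library()` realizes the qualitative layout the planning
story needs: three equiprobable rooms sharing a 5×5×3 m shell (walls kept
as an open-top box so the overhead directional light reaches the
interior — a closed box under a directional source would be uniformly in
shadow), with two objects per room at corner sites at eye height
(1.2 m).  The southeast site holds a stacked-sphere object ("object1")
in rooms 2 and 3 and is empty in room 1; the northeast site is empty
everywhere; rooms 2 and 3 differ only in whether a twin-sphere object
("object2") occupies the southwest or northwest corner.  Under a uniform
prior a southeast fixation therefore predicts two outcomes with
probabilities (1/3, 2/3) — entropy ≈ 0.918 bits — while a northeast
fixation predicts a single outcome (0 bits); after seeing object1 the
southwest/northwest corners become the only informative views (1 bit
each between the two surviving rooms).

What the fixture does *not* emulate: textured or coloured surfaces,
cluttered scenes with partial occlusion between objects, distance-scaled
illumination, or observation noise.  Tests passing on this world show
the machinery is exact on a discrete, noiseless instance; they do not
certify behaviour under continuous real-image ambiguity.

## Numerical choices

- **Rotation convention.**  Intrinsic rotations composed as
  R = R_z(varphi)·R_y(phi)·R_x(theta).  Tests validate against an
  independent composition of single-axis matrices, orthogonality and
  unit determinant at 1e-12.
- **Ray casting.**  Möller–Trumbore, vectorized over faces in chunks of
  256 rays; hits closer than 1e-9 are discarded (self-intersection
  guard); zero-area faces are skipped with a logged warning; equal-
  distance ties resolve to the lowest face index, making renders fully
  deterministic.  Shadow rays start 1e-6 along the face normal.
- **Shading clamps.**  Both the diffuse and specular dot products clamp
  at zero, so intensities are non-negative for any geometry and any
  (even) exponent.
- **Blur linearity.**  `blur_image` performs only DCT → Gaussian
  attenuation → inverse DCT and is therefore exactly linear and
  mean-preserving; the small negative ringing it can produce is clamped
  to zero one stage later, in `render_binocular`, so the linearity and
  DC-preservation invariants hold at 1e-9 on the operator itself.
- **Retinal grid.**  Cell directions sit on an endpoint grid
  (linspace over ±extent/2): corner cells lie exactly half the extent
  off-axis, and the angular step is extent/(n−1).
- **Plant integration.**  Fixed-step RK4; the exact closed form of the
  damped linear oscillator (per characteristic-root regime, with the
  critical case taken when |κ² − 4J| < 1e-12) serves as the oracle.
  Process noise, when seeded, enters the velocity rows only — position
  is the integral of velocity, so driving velocity alone keeps the state
  differentiable — with per-step covariance dt/Π_f.
- **Outcome discretization.**  Noiseless renders are clustered greedily
  in room order by max-abs pixel difference; with tol = 1e-6 this is an
  exact partition because distinct scenes differ at the 1e-2 intensity
  level while identical scenes agree to machine precision.  Entropies
  are reported in bits.
- **Seeding.**  A single global seed fans out to named substreams via a
  CRC32 of the consumer's name mixed into a `SeedSequence`, so adding a
  consumer never perturbs existing streams; `seed=None` means noiseless
  everywhere.

## Design choices where the design was open

- The ambient term inside the reflected component of the shading
  equation is read as a unit source intensity: shade = ambient +
  lit·(diffuse + specular).
- `hemianopia` is implemented as generative-model surface removal (all
  faces whose egocentric lateral coordinate lies on the stated side are
  deleted before rendering), not as an image mask; it is therefore an
  alias of `scene_side_removal`.  Monocular lesions, by contrast, blank
  the affected eye's image after rendering and blurring.
- Convergence ω is treated as a fixed parameter of the viewer, not a
  latent variable with its own prior.
- Policy scores are reported as a deterministic ranking (ties broken by
  label); no softmax selection distribution over policies is asserted.
- The salience machinery exposes both the noiseless reading (ambiguity
  exactly 0) and a pluggable discrete sensory channel; the bundled
  eyes-closed channel (every intensity bin equiprobable) yields the
  maximal ambiguity log₂K and zero information gain, whatever the prior.

## Limitations

- Single-bounce lighting: no interreflection, no emissive surfaces, no
  falloff; one directional source.
- Greyscale only; surface reflectance constants are global, not
  per-surface (no texture).
- The retina is a uniform grid; no log-polar organization, no receptor
  noise, no temporal dynamics of the image.
- One conjugate plant drives both eyes; head dynamics and vestibular
  signals are out of scope, as are generalized coordinates of motion
  and pulse-step innervation profiles.
- Exact-match Bayes over rendered images is appropriate for the
  deterministic renderer; with observation noise it would need a proper
  likelihood, which is only sketched here via the discrete channel
  interface.
- Model inversion (inferring scenes from images by message passing) is
  deliberately not implemented; the package is the forward model plus
  the decision layer.
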