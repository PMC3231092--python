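# Methods

## Problem and model

A longitudinal B-mode view of the common carotid artery shows, from the
transducer downward: tissue, the near wall (bright adventitia band, dark
media, bright intima band), the dark lumen, and the far wall (bright intima
band, dark media, bright adventitia band).  The quantities of interest are
the four interface curves — intima and adventitia of each wall — per frame,
and the lumen diameter LD (distance between the two intima curves) over the
cardiac cycle.

Interface coordinates follow the standard reading conventions of vascular
ultrasound: the far-wall interfaces are the *leading* (upper) edges of its
bright bands (lumen–intima and media–adventitia), while the near-wall
interfaces are the *trailing* (lower) edges (adventitia–media and
intima–lumen).  Rows increase downward and are 0-based; all public outputs
use full-frame coordinates.

## Feature images

`F = Σ_θ |I ∗ f_M(θ)| + I · f_x`, computed on the min–max-normalized ROI
sub-image:

* The MacLeod kernel
  `f_M(x, y) = exp(−(x²+y²)/d_c²) · [exp(−((d_xy+d_pk)/d_pk)²) − exp(−((d_xy−d_pk)/d_pk)²)]`
  with `d_xy = x·sinθ − y·cosθ` is evaluated at integer offsets at the four
  orientations 0, π/4, π/2, 3π/4.  The absolute responses are summed
  (a max-combine variant is available via `combine="max"`); the kernel sums
  to zero exactly by point symmetry.
* `f_x` is the 7 × 7 intima-media enhancement kernel: a −1 triplet stacked
  above the anchor and a +1 triplet below, one column apart; the near-wall
  kernel is its 180° rotation.  Kernels are applied by **correlation** with
  replicate padding, under which the far-wall kernel peaks at dark-above /
  bright-below transitions (the far wall's leading edges) and its negation —
  used for the near wall — at bright-above / dark-below transitions (the
  near wall's trailing edges).  `flip_fx=True` switches to convolution
  orientation for data with the opposite polarity convention.

For the near wall only, the outer wall `y_outer` is first found by a single
dynamic program maximizing the signed response of the 9 × 1 column kernel
(−1,−1,−1,−1,0,1,1,1,1); then
`H(y, x) = 1 − (1/r) Σ_{i=y+1}^{y+r} I(i, x)` for rows strictly between
`y_outer(x)` and `M − r` (neutral value 1 elsewhere), and the DDP cost is
the normalized `1 − F + c·H`.  `H` is low where the tissue beneath a row is
bright.  This separates the true (adventitia, intima) pair — whose upper
curve sits above media *followed by the bright intima band* — from a bright
sub-intima noise layer in the lumen: a curve pair resting on the noise layer
pays two full "dark-below" penalties against roughly 1.6 for the true pair,
a systematic margin of ~0.4·c per column that a noise-gradient advantage in
`F` cannot normally overcome.  For the far wall the cost is simply `1 − F`.

Min–max normalization maps every feature to [0, 1]; an exactly flat raw map
normalizes to all zeros when the response is identically zero (no evidence)
and to the constant 0.5 otherwise, so degenerate inputs keep every
downstream contract.

## Dual dynamic programming

States are pairs `(y1, y2)` with `d_min ≤ y2 − y1 ≤ d_max`; the recursion

`J(x, y1, y2) = min_{j1,j2 ∈ [−k,k]} { J(x−1, y1+j1, y2+j2) + α·|j2−j1| + β·(|j1|+|j2|) } + cost(x, y1) + cost(x, y2)`

is initialized with the first column's costs on feasible states, infeasible
states and transitions carry +∞, and the optimum is recovered by
backtracking through stored predecessor coordinates — exact by
construction, verified against an independent graph-shortest-path solver
and literal path enumeration.  Tie-breaking is deterministic: among
equal-cost predecessors, (0, 0) first, then smallest |j1|+|j2|, then
lexicographic; among equal-cost terminal states the lexicographically
smallest pair.  A single curve (the outer wall) is extracted by the same
machinery with the degenerate band `d_min = 0, d_max = 1`, returning the
upper curve.

The cost tables are stored in full (`N × M × M`); half-ROIs are a few tens
of rows, so this stays within a few megabytes.

## Tracking and smoothing

Each half-ROI is registered per frame by maximizing the Pearson correlation
between the fixed first-frame template and the candidate patch over integer
vertical shifts `s ∈ [−Δs, Δs]` relative to the previous frame's position
(`y_i = y_{i−1} + s*`).  The template is never updated; ties go to the
smallest |s|, then the negative shift; sub-pixel refinement is deliberately
not performed (integer shifts suffice since the dual program re-localizes
the curves within the ROI).  The near and far halves are tracked
independently because the two walls move differently.  Detected traces are
finally smoothed along columns by a moving average with shrinking edge
windows; no temporal (across-frame) smoothing is applied.

## Parameters

| name | default | meaning / rationale |
|---|---|---|
| `d_c`, `d_pk` | 2 px, 2 px | MacLeod radial decay and lobe distance; matched to the ~5-px intima-media thickness at ~0.1 mm/px that also fixes the 7 × 7 kernel size |
| `r` | 5 px | depth of the below-darkness window H (≈0.5 mm) |
| `c` | 0.5 | weight of H in the near-wall cost; large enough that the ~0.4·c margin dominates typical noise-edge contrast differences |
| `α`, `β` | 0.25, 0.15 | smoothness weights on a [0, 1] cost scale: a 1-px single-line step must be justified by ~0.15 of feature contrast |
| `k` | 1 px | per-column step bound |
| `d_min`, `d_max` | 4 px, 0.9·M | thickness band (≈0.42 mm minimum at 0.106 mm/px); both configurable |
| `Δs` | 10 px | tracking half-range (≈1 mm, the typical near-wall excursion) |
| `smooth_window` | 5 columns | trace smoothing |
| `pixel_size_mm` | 0.106 | scanner calibration |

## The phantom

The generator emulates the image structure the detector assumes: layer
levels lumen 15 < media 45 < intima = adventitia 205, tissue 75 (8-bit);
intima band 3.2 px, adventitia band 6 px; interfaces rendered as steps
convolved with a Gaussian of σ = 0.7 px so sub-pixel truth is meaningful.
The intima band width is matched to the 3-element lobe of the enhancement
kernel — with much thinner bands the neighbouring interface pulls the
response peak and biases any edge detector of this family outward by
roughly half a pixel.  The lumen diameter follows
`baseline + amplitude·sin(2πt/P)` (defaults 40 ± 4 px, P = 40 frames) and
the wall complex drifts by `1 px·sin(2πt/P + π/4)`.  Speckle is a
multiplicative mean-one Rayleigh factor blended by `speckle_scale`
(default 0.5, i.e. ~26 % intensity deviation — moderate, emulating
post-compression B-mode texture) and clamped to [0, 255].

A plaque is a raised-cosine extra-thickness bump bulging into the lumen
over a column range.  The sub-intima noise layer is a bright band (default
at the intima's intensity, 3 px thick, 2 px below the intima) rendered only
during configured systolic frame ranges, with a column-patchy amplitude
profile (smoothed seeded random field): patchiness matters, because a
coherent full-width bright band would also defeat the outer-wall detector,
which contradicts the clinical picture of blob-like lumen echoes.  The
noise intensity default makes the noise–lumen gradient exceed the
media–adventitia gradient — exactly the regime in which an edge feature
alone mis-tracks and the H term is needed.

What the phantom does **not** model: physically simulated point-spread
functions, attenuation or time-gain compensation; horizontal wall motion;
calcification shadows; heterogeneous tissue texture.  Passing phantom tests
therefore demonstrates the correctness and noise behaviour of the
optimization machinery under the stated image model, not clinical-grade
accuracy on arbitrary scanners.

## Validation protocol and numerical choices

The validation runs (80 frames = two cardiac cycles, 200 × 160-px frames)
were sized to exercise tracking, pulsation and the systolic noise layer
while completing in seconds; errors are pooled over intima and adventitia,
averaged per frame over all ROI columns, then over frames (unsigned and
signed variants).  Sparse references are linearly interpolated onto the
detected columns before comparison.  Reports round pixels to 2 decimals and
millimetres to 4.

Degenerate inputs are defined behaviour throughout: constant patches raise
in NCC (correlation undefined), constant ROIs yield the constant-0.5 cost
map and any feasible trace, empty inputs raise with the offending item
named.

## Known limitations

* Traces are integer-valued before smoothing (no sub-pixel interpolation of
  the DDP optimum), bounding per-frame accuracy near ±0.5 px; the ~0.3-px
  phantom errors are close to this floor.
* Only vertical motion is tracked and only two curves are optimized
  jointly; near- and far-wall detections are independent.
* The H mechanism assumes the outer wall is detectable; a full-width bright
  artifact above the near wall would corrupt `y_outer` and thus H.
* Parameter defaults target ~0.1 mm/px linear-array carotid imaging;
  other probes or depths require re-scaling the kernel and band parameters.
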