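# Methods

## Model

`afterglow` predicts the afterimage perceived when a brief chromatic
inducer I₀ is replaced by an achromatic remaining-contour image I₁.  The
model treats perceived surface color as the steady state of a diffusion
(filling-in) process whose *sources* are sign-reversed chromatic edge
signals; contours never act as explicit barriers — blocking emerges when
opposing sources collide.

The computation per prediction:

1. I₀ is transformed to opponent space by the orthonormal map
   `O_RG = (R−G)/√2`, `O_YB = (R+G−2B)/√6`, `O_BW = (R+G+B)/√3`.  The
   forward transform is computed with explicit channel arithmetic rather
   than a matrix product so gray pixels land exactly on the achromatic
   axis (BLAS reassociation otherwise leaves ~1e−18 chroma).
2. Each opponent channel is convolved with the discrete Laplace kernel
   `L = [[0,−¼,0],[−¼,1,−¼],[0,−¼,0]]` with replicate padding, giving the
   double-opponent edge response `DO`; the off (rebound) response at
   stimulus offset is `−DO`.
3. Pixels are partitioned into the chromatic zone Ω (opponent chroma
   magnitude √(O_RG²+O_YB²) strictly above `chroma_threshold`) and its
   complement Ω̄.  The contour mask is luminance strictly below
   `contour_threshold` in I₁ (which must be achromatic).
4. The Poisson right-hand side is the weighted off response,
   `−DO · (α·𝟙_contour + β)`, split into a negative-effect source (zeroed
   outside Ω) and a positive-effect source (zeroed outside Ω̄).  Both
   solves then run on the *full* grid: only the sources are
   zone-restricted, so color can spread into regions that were never
   induced, which is the defining property of these effects.  (The
   alternative reading — restricting the PDE *domain* per zone — would
   make complementary color unable to enter the achromatic interior of a
   ring, contradicting the negative-effect demonstrations.)
5. Each of the six fields (3 channels × 2 effects) solves `∇²u = f` with
   the standard 5-point discretization, unit grid spacing, and zero
   Dirichlet borders *in deviation-from-white space*: the percept is
   computed as a deviation and white is added at rendering, which realizes
   the white-border/white-initial-image convention exactly (a blank
   inducer renders bit-exactly white).
6. The two effect fields are combined as
   `O_p = (pos + neg) / (max|pos| + max|neg|)` (maxima over all channels
   and pixels; a zero denominator yields the zero field), then rendered as
   `clip(white + display_gain · O⁻¹{O_p})`.

### Sign convention

The printed Laplace kernel is −¼ times the standard 5-point Laplacian, so
`DO = I ∗ L = −¼∇²I`.  The model equation "the perceived field's Laplacian
equals the reversed weighted gradient" is therefore implemented as
`poisson_solve(−source)` with `source = (−DO)·w`; this is the sign under
which the chromatic side of an edge fills with the complementary color and
the achromatic side with the inducer color.  Global sign correctness is
enforced by the figure-level polarity tests rather than by trusting any
single symbolic form.

## Parameters

| parameter           | default | meaning |
|---------------------|---------|---------|
| `alpha`             | 1.3     | source weight of the remaining contour (dimensionless; must exceed beta) |
| `beta`              | 0.1     | source weight of bare chromatic edges |
| `chroma_threshold`  | 0.05    | opponent-chroma magnitude separating Ω from Ω̄; small and positive so interpolation noise and grays stay achromatic |
| `contour_threshold` | 0.5     | luminance below which a contour-image pixel counts as contour |
| `display_gain`      | 1.0     | scale of the normalized percept at rendering (the model publishes no radiometric output scale) |
| solver `tolerance`  | 1e−6    | max-abs update per Gauss–Seidel sweep at which iteration stops |
| solver `max_iterations` | 50,000 | sweep cap; a 128×128 solve at 1e−6 needs ≈ 12–15k sweeps, so the cap indicates misconfiguration, not slow convergence |

α and β are the published values and are held fixed across every
demonstration.  The cap of 50,000 sweeps was chosen because the asymptotic
Gauss–Seidel contraction at 128×128 is ≈ 6×10⁻⁴ per sweep, which puts
worst-case convergence to 1e−6 slightly above a 20,000-sweep budget.

## Solver

Production solves use lexicographic Gauss–Seidel (numba-compiled; sweep
order fixed for bit-stable reproducibility).  An exact direct solve of the
same discretization (sparse LU on the assembled 5-point system, guarded to
≤ 64×64) serves as the independent oracle in tests; the two agree to
≤ 1e−5 max-abs on random 32×32 sources at tolerance 1e−8.  Interior
residuals of every solve are recorded in the prediction diagnostics.

## Synthetic stimuli

All stimuli are generated programmatically on a white 128×128 canvas
(geometry scales to smaller canvases).  Shapes use analytic membership
functions — annuli and circles by Euclidean distance (half-open
`[r_inner, r_outer)`), four-point stars as L^p balls with `p = 0.7`
(concave "astroid" stars), spirals by signed radial offset from an
Archimedean centerline — rather than polygon rasterization, because the
model's predictions turn on exactly which pixel rows beside an edge a
contour covers, and polygon rasterizers assign those rows inconsistently
around a shape.

A central finding of the implementation, documented here deliberately: the
predicted dominance is controlled by which side of a chromatic edge the
remaining contour's pixels cover.  Covering the chromatic-side rows floods
the surround with the complementary color; covering the achromatic-side
rows floods it with the inducer color; covering both symmetrically leaves
only a weak curvature-driven residual (complementary inside a closed
contour, same-hue outside).  Published stimuli exist only as printed
figures, so each fixture family fixes one rasterization convention,
matching the qualitative outcome its demonstration reports:

- **Rings** (`ring_outer`, `ring_inner`): the drawn circle straddles the
  faded edge (band `[r−t/2, r+t/2)`).  Cyan inducer `(0,1,1)` — the
  complement is red — chosen for maximal chroma relative to luminance
  contrast so the interior percepts (±0.016–0.018 in normalized units)
  sit clearly above the τ = 0.01 classification threshold.
- **Stars** (`stars_vanlier`, `stars_rect_overlap`, `stars_rect_apart`):
  a red diagonal star under a cyan axis-aligned star with a white central
  square (standing in for the central transparency region of the two-star
  stimulus).  A drawn outline of a *filled* shape occupies the shape's own
  boundary pixels, so star outlines cover the interior (chromatic) side;
  this produces the strong complementary fill inside the remaining
  contour.  The added small square of the rect variants either straddles
  the white square's chromatic border (overlap — weakens the interior
  fill from −0.99 to −0.62) or sits strictly inside the uniform white
  center (apart — bit-identical fields to the no-square case).
- **Single-color star** (`star_single_color`): the two-star stimulus with
  one color removed — only the diagonal star keeps its cyan; the contour
  still traces the axis star.  That contour runs almost entirely through
  white and is inert; the model's filling-in collapses (all regions below
  τ), leaving a faint complementary response that is strongest at the
  star's vertices (−0.0082) and weaker in the central polygon (−0.0052).
- **Spirals** (`spiral_full/outer/inner`): strip of width 8 px, start
  radius 14 px, pitch 15 px, 2.25 turns; contour bands occupy `[edge,
  edge+t)` in signed offset — the same half-open convention as strip
  membership `[−w/2, +w/2)`, so the inner contour coincides with the
  innermost strip rows and the outer contour with the first background
  rows.  This yields the reversed dominance the spiral demonstrations
  report: outer contour → inducer hue dominates (+0.33 over the gap),
  inner contour → complement dominates (−0.30), full contour → both
  polarities coexist (outer gap +0.028, core −0.018).
- **Averaging** (`averaging_negative_a/b`, `averaging_positive`):
  half-red/half-blue disk under one enclosing circle (with an added
  dividing contour in variant b), and a two-color annulus with the inner
  circle remaining.  The region-mean chromatic angle lands on the
  bisector of the two complementary hues (negative case) or the two
  inducer hues (positive case), strictly inside the respective arc.

What the generator emulates: the topology of the classic demonstrations —
which chromatic edge each remaining contour overlaps, closed vs open
contours, one- vs two-color inducers.  What it does not: the published
artwork (proportions, hues where unstated, anti-aliasing), luminance
manipulations of contours or interiors, and any temporal structure.
Passing tests therefore show that the model reproduces the *polarity
logic* of the phenomena under controlled geometry, not that it reproduces
pixel-accurate published figures or psychophysical magnitudes.

## Metrics

Percepts are quantified on the pre-rendering normalized opponent field
(clipping never biases them).  The *hue projection* of a region is the dot
product of its mean (O_RG, O_YB) with the unit chroma direction of the
inducer color; classification uses τ = 0.01 in normalized units (positive
/ negative / none), separating genuine percepts from solver residue.
Color averaging is summarized by the region-mean chromatic angle and its
position relative to the minor arc between two reference hue angles.

## Limitations

- Steady state only: the diffusion coefficient and all temporal structure
  (exposure duration, decay) drop out and are not represented.
- α and β are constants; spatially varying weights are out of scope.
- Polarity predictions for hand-drawn stimuli inherit the edge-side
  sensitivity described above; users supplying their own PNGs should
  ensure drawn contours cover the intended side of the faded edges.
- Input PNGs are treated as linear RGB in [0, 1]; no color management.
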