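# Methods

## Scope and model

`wingmorph` implements a theoretical-morphospace workflow for 2D wing
planform outlines. The core assumption is that a planform's flight-relevant
geometry is captured by a low-order elliptical Fourier (EF) description of
its closed outline, and that performance proxies computed directly on
reconstructed outlines define meaningful adaptive surfaces over the first two
principal components of EF coefficient space. Shapes are compared free of
size: every outline is standardised so the semi-major axis of its
first-harmonic ellipse equals 1. Mass, wing loading and any size-dependent
quantity are deliberately out of reach — theoretical shapes have no mass —
so all four metrics are functions of outline geometry alone (pitch agility
uses a dimensionless mass constant, default 1).

### Coordinate and orientation conventions

- *x* spanwise, root at minimum *x*, tip at maximum *x*; *y* chordwise with
  the leading edge on the +*y* side. Left wings are mirrored about mid-span.
- Canonical outlines are counterclockwise with consecutive duplicates
  removed; closure is implicit.
- No rotation or EF starting-point normalisation is applied. Input data are
  assumed consistently oriented (as photographed wings are); normalising
  rotation would destroy the anterior–posterior tip-position variation that
  higher PCs capture. This is a convention of this package, and analyses of
  externally digitised data should verify their outlines obey it.
- Rightmost-point ties (bifurcated, emarginated tips) resolve to the
  greatest-*y* (leading-edge) landmark, within a tolerance of 1e−9 × span.

## Pipeline stages and tunable parameters

| parameter | default | meaning |
|---|---|---|
| `landmarks` | 1200 | equal-arc-length landmarks per outline (past convergence for smooth outlines) |
| `harmonics` | 5 | EF harmonics; low order keeps most of the expanded grid free of self-intersection |
| `grid_nx × grid_ny` | 23 × 22 | lattice nodes along PC1 × PC2 (506 theoretical shapes) |
| `expansion` | 0.20 | total PC-range growth (10% added per side, 120% of observed variation) |
| `n_strips` | 100 | spanwise strips for the agility metric; 100 vs 200 differ by <0.5% |
| `tip_offset` | 500 | landmark offset for the tip angle; scales proportionally with `landmarks` |

PCA is centred and unscaled (covariance of coefficients): after size
standardisation all coefficients share one dimensionless scale, so
correlation-weighting would distort the variance structure. The DC
(centroid) terms are excluded from the feature vector — translation is not
shape. Scores reproduce inputs exactly (full SVD), and the grid bounds per
axis are `[min − e·range/2, max + e·range/2]` with `e = expansion`, i.e. the
total range grows by exactly `expansion`, split symmetrically; the larger
node count sits on PC1, the larger-variance axis.

Reconstruction of a grid node sets all PCs above the second to zero and
re-standardises the resulting coefficient vector, keeping every theoretical
shape identically size-scaled. Nodes whose reconstructed outline
self-intersects ("impossible space") are excluded from every functional
computation; a shape touching itself at a single point counts as
self-intersecting, being the limit of the split-tip morphology. The test is
delegated to exact geometric predicates (GEOS via shapely) and is verified
against an all-pairs segment-intersection brute force in the test suite.

### Performance metrics

- **Aspect ratio** `R²/S`: spanwise extent squared over polygon area.
- **Second moment of area**: polygon (Green's-theorem) formula for
  `∫ x² dA` about the chordwise axis through the root, with the root
  translated to `x = 0`; non-dimensionalised as `√(r₂/(S R²))`. Any rectangle
  gives `√(1/3)`; a linearly tapering triangle gives `√(1/6)` (both verified
  against brute-force integration).
- **Pitch agility**: the planform is cut into `n_strips` equal-width
  spanwise strips; at each strip midline the boundary crossings give the
  local chord (outermost extent), the material chord (summed in-polygon
  intervals, used as the area weight) and the leading-edge offset from the
  global leading edge. The mean quarter-chord position `x̃_c/4` is the
  area-weighted mean of (leading-edge offset + chord/4), `c_r,max` the
  maximum strip chord, the rotation point and centre of gravity the minimum
  spanwise coordinate (0 after rooting), `I_yy` the dimensional second
  moment about the rotation axis, and
  `PA = [ ((x̃_c/4/c_r,max)^0.8) c_r,max − x_CG ] (m^0.12)² S / I_yy`.
  This takes the spanwise axis literally as the reference axis. The
  aerodynamically conventional chordwise frame is available via
  `AgilityParams(axis="chordwise")`; the default is anchored by a hand-
  evaluated rectangle oracle in the tests. Only relative values across one
  identically scaled grid are meaningful — the metric is not scale-invariant.
- **Tip angle**: interior angle at the tip between the vectors to the
  landmarks `tip_offset` positions away along the loop, in degrees. With the
  canonical 1200 landmarks and offset 500 this is a *global* pointedness
  measure (the probe points lie well down the span), not a local vertex
  angle. The default optimality direction treats acute tips as optimal
  (drag reduction); styles rewarded for lift ("TA(LOW)") invert it.

Surfaces are min–max normalised over valid nodes only and oriented so 1 is
always optimal; a constant surface is flagged degenerate (all zeros, no
meaningful peak). Peak ties break deterministically to the lowest PC1, then
PC2, index. Taxa are assigned surface values by bilinear interpolation in
their grid cell, falling back to the nearest valid node when the cell
touches impossible space; taxa that project into impossible space are
flagged but still scored by the fallback.

### Pareto trade-offs

Goldberg ranking peels successive nondominated fronts (weak dominance; exact
ties share a front). Each valid node gets an optimal rank `R_o` (objectives
maximised) and suboptimal rank `R_s` (minimised); `PRR = 1` when `R_o = 0`,
else `R_s/(R_o+R_s)`. Fronts are computed over valid nodes only. Duplicate
objective vectors receive identical PRR; no jitter is injected. The standard
combinations shipped (2MA+TA, AR+TA, 2MA+PA, 2MA+PA+TA(LOW)) mirror the
per-flight-style proxy table in `src/wingmorph/data/flight_styles.toml`,
which users can replace; a four-metric generalist combination is the same
operation with four surfaces.

### Group statistics

Distance from optimum is measured in performance value, not Euclidean PC
distance: surfaces are non-isotropic, so equal PC displacements are not
equal performance losses. On normalised surfaces
`similarity = 1 − distance` holds exactly, which is what makes "percentage
similarity to the optimal shape" well defined. Group membership comes only
from the supplied label table; no style inference is attempted.

## Synthetic data

The generator emulates the axes of planform variation the analysis assumes:
chord profile `c(x) = c_r [taper + (1−taper)(1 − (x/R)^p)]` with
`p = 2/(1+tip_sharpness)` (sharpness 0 → rounded near-elliptic tip, 1 →
linear taper, large → slender pointed tip); an area-shift factor
`1 + tip_weight (x/R − ½)`; sinusoidal emargination clefts carved from the
trailing side of the distal quarter of the span (the leading edge stays
smooth so the leading-edge tip rule is exercised); radial Gaussian boundary
noise applied before resampling, with redraws on self-intersection. All
randomness flows from a single generator per call; no global state.

Per-style parameter presets (`STYLE_PRESETS`) place the seven flight styles
at morphologically sensible means — high-span slender marine soarers,
emarginated broad thermal soarers, low-taper broad burst flappers, short
pointed hoverers, and so on — with modest within-style spreads
(`DEFAULT_SDS`). No quantitative within-style variance estimates exist to
calibrate against, so these spreads are free choices of the generator, made
once. Consequently, passing tests demonstrate that the pipeline recovers the
structure the generator puts in (taper → PC1 separation, tip weight → its
own PC, near-peak cohorts reporting >90% similarity); they do not
demonstrate that real wing datasets have that structure. The generator omits
allometry, camber, feather microstructure and any 3D effect.

## Numerical choices

- Arc-length resampling interpolates linearly between landmarks (no
  spline): matches outline-tracing precision and keeps the perimeter
  well defined.
- EF coefficients use the cumulative-chord-length parametrisation. A
  consequence worth knowing: only a circle is *exactly* captured by the
  first harmonic of its own forward transform; an ellipse is exactly
  *representable* at H = 1 (reconstruction from exact first-harmonic
  coefficients reproduces it to machine precision) but its forward
  transform leaks ~1% of perimeter into the third harmonic via the
  arc-length reparametrisation.
- The first elliptic's "size" is its semi-major axis — the largest singular
  value of the 2×2 first-harmonic coefficient matrix; standardisation is
  idempotent and commutes with uniform scaling of the input.
- Strip scanlines use a half-open crossing rule so vertices lying exactly
  on a strip midline are counted once.
- Agility strips with fewer than two boundary crossings (off the planform)
  are skipped; a planform crossed by no strip is degenerate and errors.
- Zero-area, zero-perimeter or sub-3-point outlines raise
  `DegenerateOutlineError` before any metric is attempted.

## Test and report problem sizes

The shipped test suite and the acceptance script run entirely on synthetic
data at deliberately modest sizes — cohorts of tens of wings, grids from
8 × 7 up to the full 23 × 22, 200–1200 landmarks — chosen as the smallest
sizes at which each property is cleanly exercised. The reproduction check
against the deposited 1139-wing empirical dataset requires staging that
dataset under `data/empirical/` (see `tests/test_acceptance.py`); without
it the corresponding test reports failure rather than silently passing.

## Known limitations

- Performance proxies are geometric stand-ins, not aerodynamic simulation;
  the drag-reducing effect of slotted tips is represented only through the
  leading-edge tip-angle rule and is likely understated.
- The 2D grid discards PC3+ variation; shapes projected from higher
  dimensions can land in formally impossible space.
- The pitch-agility frame ambiguity (spanwise vs chordwise reference axis)
  is unresolved in principle; both are implemented, and conclusions that
  depend on PA should be checked under both.
- Percentage-similarity values depend on min–max normalisation over the
  particular grid; they are comparable within one fitted space, not across
  differently fitted spaces.
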