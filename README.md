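# wingmorph

Theoretical morphospace analysis of wing planforms: how close do real (or
simulated) wing shapes come to the shapes that would perform best?

Rather than assuming that observed wings are optimal, the package builds a
*theoretical* shape space — a grid of computationally generated planforms that
extends beyond the range of observed variation — scores every theoretical
shape with flight-performance proxies, and only then asks where empirical
shapes fall on those performance surfaces. It is aimed at evolutionary
morphologists and biomechanists working with 2D outline data (bird wings are
the motivating system, but nothing is bird-specific).

## Method

1. **Shape capture.** Each closed planform outline (CSV or TPS landmarks) is
   canonicalised (counterclockwise, root at minimum *x*, leading edge on +*y*),
   resampled to 1200 equal-arc-length landmarks, and decomposed by elliptical
   Fourier analysis (Kuhl–Giardina) into `H = 5` harmonics. Size is removed by
   standardising the semi-major axis of the first elliptic to 1.
2. **Morphospace.** Centred PCA over the 4H coefficient vectors. A regular
   23 × 22 lattice (506 nodes) spans the PC1–PC2 score range expanded by 20%;
   each node is inverse-mapped to an outline (higher PCs at zero). Nodes whose
   outlines self-intersect are geometrically impossible and masked out.
3. **Performance surfaces.** Four proxies per valid node, min–max normalised:
   - aspect ratio `AR = R²/S` (cost of transport),
   - non-dimensional second moment of area `r̂₂ = √(r₂ / S R²)` with
     `r₂ = (1/12) Σ (xᵢyᵢ₊₁ − xᵢ₊₁yᵢ)(xᵢ² + xᵢxᵢ₊₁ + xᵢ₊₁²)` (manoeuvrability),
   - pitch agility `[ ((x̃_c/4 / c_r,max)^0.8 c_r,max) − x_CG ] (m^0.12)² S / I_yy`
     (capacity to initiate manoeuvres),
   - tip angle: the interior angle at the rightmost landmark measured 500
     landmarks away in either direction (drag vs lift trade-off; the
     leading-edge point is used for bifurcated tips).
4. **Trade-offs.** Metric combinations are scored with iterative Goldberg
   Pareto ranking: optimal rank `R_o` (fronts peeled maximising) and
   suboptimal rank `R_s` (minimising) give the Pareto Rank Ratio
   `PRR = 1` if `R_o = 0`, else `R_s / (R_o + R_s)` ∈ [0, 1].
5. **Group optimality.** Labelled taxa are projected into the space; a
   group's distance from a surface's optimum is measured in performance value
   (peak minus the taxon's interpolated value), so `similarity = 1 − distance`
   reads directly as percentage similarity to the optimal shape.

A synthetic-data module generates wing-like outlines (chord breadth, tip–base
weighting, tip pointedness, trailing-edge emargination, boundary noise) and
flight-style-labelled cohorts, so the whole pipeline is testable without any
download.

## Worked example

```sh
wingmorph run-all --workspace demo --seed 42 --landmarks 400 \
    --grid-nx 12 --grid-ny 11 --n-per-style 6
```

simulates six wings for each of seven flight styles, fits the space, builds a
12 × 11 grid and prints:

```
42 specimens; grid 132 nodes (7 impossible); PC1-3 variance ['0.8687', '0.0972', '0.0249']
                  style        surface  n  mean_distance  mean_similarity  top_decile_fraction
       aerial_predation 2MA+PA+TA(LOW)  6       0.833960         0.166040                  0.0
         burst_flapping        TA(LOW)  6       0.225479         0.774521                  0.0
                 diving         2MA+PA  6       0.690325         0.309675                  0.0
               hovering         2MA+PA  6       0.920823         0.079177                  0.0
long_distance_migration          AR+TA  6       0.183606         0.816394                  0.0
         marine_soaring         2MA+TA  6       1.000000         0.000000                  0.0
        thermal_soaring             TA  6       0.290359         0.709641                  0.0
```

Reading the output: 7 of the 132 theoretical shapes self-intersected and were
excluded; PC1 carries 87% of synthetic shape variance (chord breadth). Each
row scores one flight style against its hypothesised metric combination —
e.g. simulated burst flappers sit 0.225 below the peak of the inverted
(broad-tip-optimal) tip-angle surface, i.e. 77% similar to the optimal shape,
while this particular synthetic marine-soaring cohort is maximally distant
from its trade-off optimum. With such small cohorts these numbers
characterise the simulation, not real birds. The workspace directory holds
every intermediate artifact (manifest, harmonics, scores, grid nodes, one CSV
per surface, projections, report) as plain CSV/JSON.

Stages can equally be run separately (`simulate`, `efa`, `build-space`,
`metrics`, `pareto`, `project`, `report`), or from Python:

```python
from wingmorph import PipelineConfig, run_pipeline
arts = run_pipeline(PipelineConfig(seed=42, workspace="demo"))
arts["report"], arts["grid"].n_invalid
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the synthetic-data
generator, numerical choices and known limitations.
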