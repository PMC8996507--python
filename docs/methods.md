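# Methods

This note documents the models, conventions and numerical choices behind
`wingmorph`, and what the synthetic generator does and does not establish.

## Synthetic wing worlds

The generator (`wingmorph.simulate`) states a small world modelled on a
museum-scale comparative wing study:

| parameter | default | meaning / rationale |
|---|---|---|
| `n_species` | 27 | species count typical of a genus-level comparative sample |
| `n_per_species` | 10 | specimens per species (museum-collection scale) |
| `tree_depth` | 10 time units | a ~10 Ma basal-node calibration |
| `bm_sigma2` | 2.5e-6 / coordinate / time unit | tip sd per coordinate √(σ²·depth) = 0.005 of wing length — visible but subtle interspecific shape scatter |
| `habitat_effect_size` | 0.01 | multiplies the unit-max deformation template; 2× the within-species noise, giving imperfect (realistic) group separation at defaults |
| `habitat_concordance` | 0.75 | fraction of species whose water-body class matches the concordant pairing with landscape |
| `within_species_sd` | 0.005 | iid coordinate noise, same order as the Brownian tip scatter |
| `pigment_intensity_range` | (40, 100) grey levels | proximal patch darkening on standing-water species' wings |
| frames | 200×56 / 200×81 px | forewing / hindwing standard frames |

Construction: a pure-birth (Yule) topology is rescaled to exact ultrametric
depth; species mean shapes are the 38-point reference wing plus Brownian
deviations (each coordinate ~ MVN(0, σ²C)); landscape labels come from a
latent Brownian trait split at its median, so they form phylogenetic
*grades*; the water-body label copies the concordant pairing with
probability `habitat_concordance`.  Specimens add a signed habitat
deformation (the fixed "narrowing + anal-corner" template, exposed as
`wingmorph.template.NARROWING_TEMPLATE`) and iid coordinate noise.  Images
are rasterized from a smooth dense outline interpolated through the
specimen's boundary points, with vein polylines and an optional proximal
pigment patch; background is white (255), origin top-left, row-major.

What the generator does **not** emulate: photographic artifacts, venation
detail beyond a fixed 13-edge graph, allometry, sexual dimorphism and
intra-wing modularity.  A green end-to-end test therefore establishes that
the analysis chain recovers group structure of the stated geometric kind at
the stated effect size — not that it would perform identically on real
photographs.

Two deliberate consequences of the stated world are worth flagging:

* **Zero direct effect is not chance-level.**  Because habitat labels are
  phylogenetic grades and shapes evolve by Brownian motion on the same
  tree, shape similarity predicts habitat above chance even with
  `habitat_effect_size = 0`.  Chance-level calibration checks therefore
  permute specimen labels (which is also how the null examples for the
  discriminant operations are defined), rather than merely zeroing the
  effect.
* **Pigment is informative for the water-body factor by construction**, so
  null checks disable it via `pigment_intensity_range=(0, 0)`.

### Outline repair at rasterization

Iid noise can fold the interpolated outline microscopically at the wing
tip, where the two margins approach each other.  The renderer repairs
hairline folds (`buffer(0)`, keeping the dominant lobe) and raises a render
error only when a secondary lobe exceeds 1% of the outline area — i.e. for
genuinely crossed outlines such as exchanged distant points.

## Eigenshape outline sampling

Zone accuracy is the canonical perimeter ratio: length of the equally
spaced m+1-point polyline divided by the digitized zone length.  It is
scale- and rotation-invariant and non-decreasing in m for convex arcs.  The
per-zone count is the smallest m whose accuracy exceeds the threshold
(default 0.95) for *every* specimen; the plan records the binding specimen.
Interpolation is linear along the digitized boundary with anchors preserved
exactly; there is no subsequent semilandmark sliding.  Re-sampling an
already-sampled polyline is an exact fixed point only on constant-curvature
(straight or circular) zones; elsewhere chord lengths differ at second
order in the spacing, which is why the idempotence test uses circles.

## Procrustes superimposition

Classical GPA: unit centroid-size scaling (not variance-weighted),
rotation by SVD with reflections disallowed (wings are pre-mirrored to left
pose), convergence when the consensus moves < 1e-8.  The final consensus is
rotated to its principal axes with a third-moment sign convention, making
results invariant (to 1e-7) under arbitrary similarity transforms of the
input batch.  Analyses run on Procrustes coordinates directly; an
orthogonal tangent-space projection is available (`tangent_project=True`)
but off by default.

## Multivariate phylogenetic signal

K_mult follows the distance-based formulation (see README for the
formula).  Numerical choices: C^(−1/2) via symmetric eigendecomposition
with eigenvalues clipped at 1e-12 (stable for near-singular C; a singular C
falls back to the pseudo-inverse with a warning).  The permutation null
shuffles rows of Y (equivalently tip labels) with C fixed, using a seeded
generator.  The primary verdict is two-tailed against the 2.5/97.5
percentiles of the permuted K distribution; a one-tailed permutation
p-value (1 + #{K* ≥ K_obs})/(B + 1) is reported alongside.  With finite B
and interpolated percentiles the realized two-tailed type-I rate sits
slightly above nominal (≈ 0.06–0.07 at B = 199 in our calibration), inside
the accepted 5% ± 3 band.

Ancestral states solve the normal equations of Σ(Δ²/branch length) over
internal-node values — the GLS/ML Brownian estimate, valid for polytomies.
Phylomorphospace branch crossings are counted as proper interior
intersections of branch segments in the PC1–PC2 plane (shared endpoints
excluded).

## PCA–CVA discrimination

* PCA is covariance-based, computed by SVD of the centered matrix
  (efficient for p ≫ n, e.g. 11 200 pixel variables); retention is the
  smallest k reaching the variance threshold; component signs are fixed by
  making the largest-magnitude loading positive.
* Two-group CVA uses the Fisher form w ∝ S_w⁻¹(m_A − m_B) — equivalent to
  the single nonzero canonical axis while avoiding generalized-eigenproblem
  edge cases.  A singular within-group covariance is refused explicitly
  (retain fewer components) rather than silently regularized.
* LD score conventions (verdict-neutral, documented because they are not
  forced by the method): grand mean 0, unit pooled within-group variance,
  group A (first label in sorted order) positive.
* Classification is the unweighted midpoint rule between group mean scores
  (no priors; confusion tables report raw counts).
* The "bootstrapped" Hotelling T² is a label-permutation test (B = 1000 by
  default, seeded); its p-value is uniform under the null by construction.
* Back-projection maps an LD score to PC coordinates along the unit
  discriminant direction, calibrated so group mean scores round-trip to the
  projections of the group means, then through the retained basis to the
  original variables.  Score 0 maps exactly to the grand mean.
* The leave-one-out jackknife refits the *entire* PCA + CVA pipeline per
  fold, including PC retention (no leakage); folds that would leave a
  singleton group are skipped with a warning.  Under shuffled labels the
  jackknife is pessimistically biased (below 0.5 for overfit folds), and
  single-split estimates at n ≈ 40 have sd ≈ 0.12, so chance-level checks
  average a few label shuffles.
* SMA regression: slope = sign(r)·sd_y/sd_x, intercept through the means,
  permutation p on |r|.

## Embedded image-contrast CNN

The contrast encoding is the absolute pixel-difference image rescaled to
[0, 1] — the simplest encoding consistent with a single-channel input; it
is isolated behind `make_contrast_input` so stacked-channel or squared
variants can be swapped in.  The 2-vector output is read as {same-group,
different-group}; single-image identification aggregates P(same) against
grouped references (mean difference of group means, ties to the first group
with a warning).

The default input side is 28, which reproduces the published layer tensors
bit-exactly (flatten 320); 40×40 thumbnails are supported (flatten 980).
Optimizer details are deliberately plain: SGD, fixed learning rate 0.01,
He-scaled seeded initialization, softmax cross-entropy; no momentum or
scheduling.  Nothing downstream depends on optimizer specifics.  Default
iteration counts per epoch are ceil(3 · n_contrasts / batch 64), which
reconstructs the published per-round consumption; reduced schedules (1
epoch × 200 iterations) are used in tests to fit a CPU budget.  All
randomness (initialization, batch order, jackknife target choice, per-fold
training seeds) flows from named seeds, so training is bitwise
reproducible.

The implementation is pure numpy (im2col convolutions); at 28×28 with two
small convolution stages this trains in a few milliseconds per batch on one
CPU, and GPU-scale experiments are out of scope.

## Known limitations

* The generator's habitat deformation is a single fixed template shared by
  both wing types; real wings differ in fore/hindwing displacement detail.
* `standardize_image` normalizes brightness/contrast over non-background
  pixels with package-default targets (mean 200, sd 40); it is idempotent
  only up to clipping and integer rounding (≤ 1 grey level).
* The jackknife for the CNN retrains a reduced schedule per fold; it
  measures stability of the discriminant rule, not asymptotic accuracy.
* Star phylogenies make K ≡ 1; near-star trees make the K permutation test
  powerless by construction, which is a property of the statistic, not a
  defect of the implementation.
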