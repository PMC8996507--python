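# wingmorph

Ecomorphological analysis of insect wing form: does wing shape track the
environment ("push") or phylogeny ("pull")?  The package implements, as a
tested and reusable pipeline, the comparative toolkit used to ask that
question for dragonfly wings — classic geometric morphometrics on
landmark/semilandmark configurations, a parallel "every pixel is a variable"
analysis of standardized wing images, and an embedded image-contrast
convolutional discriminator — together with a synthetic wing generator so
the whole chain is exercisable without any external data.

It is aimed at quantitative morphologists and evolutionary biologists who
want these analyses as composable Python functions and sklearn-style
estimators rather than GUI workflows.

## The methods in brief

**Outline sampling (extended eigenshape).**  The wing periphery is divided
into five zones by six anchor landmarks.  Each zone receives the smallest
number *m* of equally spaced (arc length) semilandmarks such that the
perimeter ratio — length of the *m*+1-point polyline over the digitized
zone length — exceeds 0.95 for *every* specimen.  With 13 vein landmarks
the standard scheme has 38 points.

**Superimposition.**  Classical generalized Procrustes analysis: center,
scale to unit centroid size, rotate (no reflection) to the iterated
consensus.

**Phylogenetic signal.**  The multivariate K statistic on species mean
shapes Y with Brownian covariance C (C_ij = shared root-to-MRCA branch
length):

    K = (MSE0 / MSE) / [(tr C − N/(1ᵀC⁻¹1)) / (N − 1)]

with MSE0 = Σ‖Y_i − a‖², MSE = Σ‖Z_i‖², Z = C^(−1/2)(Y − 1a) and
a the GLS phylogenetic mean.  K = 1 under Brownian evolution on the given
tree; significance is judged two-tailed against 1000 tip permutations.
Phylomorphospaces project ML ancestral estimates into the tip PCA and count
branch crossings.

**Discrimination.**  Covariance PCA retaining 95% of pooled variance, then
two-group CVA in Fisher form (w ∝ S_w⁻¹(m_A − m_B)); permutation Hotelling
T² for group separation; back-projected shape models with ×4 displacement
vectors (landmarks) or pixel-difference heatmaps (images); post-hoc and
leave-one-out jackknife confusion matrices with the Matthews correlation
coefficient; standardized major axis regression between discriminant axes.

**Contrast CNN.**  All n(n−1) ordered image pairs become |difference|
thumbnails labelled same/different group and train a small LeNet-5 variant
(28×28 → 10×25×25 → 10×12×12 → 20×9×9 → 20×4×4 → 320 → 2, in numpy,
seeded SGD).  Single images are identified by aggregating same-group
probabilities against grouped references, and stability is assessed by a
jackknife over randomly chosen target images.

## Worked example

```python
import wingmorph as wm

cfg = wm.SimulationConfig(n_species=12, n_per_species=4,
                          habitat_effect_size=0.02, seed=1)
ds = wm.simulate_dataset(cfg, wings=("forewing",))

aligned = wm.gpa_align(ds.configurations["forewing"])
means, order = wm.species_means(aligned, tip_order=ds.phylogeny.tip_names)
k = wm.kmult_test(means.reshape(len(means), -1), ds.phylogeny, B=199, seed=2)
print(f"K_mult = {k.K_observed:.3f}, p = {k.p_value:.3f}")

y = ds.labels["forewing"]["landscape"].to_numpy()
clf = wm.PCACVADiscriminant(var_threshold=0.95).fit(aligned.flat(), y)
post = clf.confusion(aligned.flat(), y)
jack = wm.jackknife_loo(aligned.flat(), y)
print(f"post-hoc accuracy {post.accuracy:.2f}, "
      f"jackknife {jack.accuracy:.2f} (MCC {jack.mcc:.2f})")
```

prints (this exact world):

```
K_mult = 0.227, p = 0.345
post-hoc accuracy 1.00, jackknife 1.00 (MCC 1.00)
```

Read: species mean shapes show no significant phylogenetic covariation
(K well below 1, inside the permutation band), while the habitat-linked
shape effect built into this simulated world is recovered perfectly by the
landmark discriminant — the generator's effect size (0.02 of wing length,
4× the within-species noise) is deliberately strong.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main pipeline from scratch on a freshly simulated
world: Procrustes alignment, the K_mult permutation test with
phylomorphospace crossing counts, landmark- and image-based PCA-CVA with
permutation T², jackknife confusion summaries and SMA regression between
the two habitat-factor discriminant axes, and a reduced-schedule contrast-
CNN discrimination with its jackknife.  It prints the summary tables and
writes the results JSON to `--out`.
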