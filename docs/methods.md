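# Methods

## The classification model

The classifier operates on current density distribution maps (CDDMs): pairs
of same-shape grids of current density magnitude (dimensionless, normalized
by the per-map maximum so max = 1) and current direction angle (radians,
wrapped to (−π, π]). The computational object is the 10×10 vector grid whose
row-major flattening gives the length-100 stage-1 vectors; rendered
"pixel" images of CDDMs are treated as visualizations of this grid, not as
separate data. Grid dimensions are configurable but must be even and at
least 2×2 so the quadrant split is exact.

**Stage 1.** Pearson correlation is computed separately over the flattened
magnitude vectors and angle vectors of the query and each reference map, and
the two coefficients are multiplied into the *resulting correlation
coefficient*. Per group the m largest resulting correlations are averaged
(m = 3 by default, configurable 1–5; on the default synthetic cohort the
macro accuracy varies by well under 0.05 across this range, so the choice is
not critical). Groups are ranked descending; ties are broken by a frozen
canonical label order (NORM1, NORM2, MDAM, NONCOR, MVD_M, MVD_F, CAD1–5,
LVH1–3) so rankings are deterministic.

Two conventions make the pipeline total:

* a zero-variance (constant) vector has undefined Pearson correlation; it is
  scored r = 0, reading "no variation" as "no evidence of similarity";
* angles enter the correlation as plain reals. No circular statistic is
  used, so two geometrically similar direction fields that straddle the ±π
  branch cut can correlate lower than their similarity warrants. This
  mirrors the method as defined; the synthetic generator keeps template
  angle fields away from systematic branch-cut artifacts, but users applying
  the package to data with angles clustered near ±π should be aware of it.
  A related literal-formula consequence: when both channel correlations are
  negative, their product is positive and is treated as (weak) similarity.

**Escalation rules.** The packaged tables list, for each of five
low-precision groups (LVH1, LVH2, LVH3, CAD3, NORM1) the groups most often
misclassified *into* it, and for each of six low-sensitivity groups (NORM2,
MVD_F, MVD_M, NONCOR, LVH2, CAD2) the groups their members are most often
lost *to*, as observed on the original clinical cohort. A query escalates
when its top-ranked group keys a table and the 2nd- or 3rd-ranked group is
one of that key's partners. Frozen precedence choices, where the source
material is silent: the low-precision condition is checked before the
low-sensitivity condition (only LVH2 keys both tables, and false positives
are that listing's leading concern); within a condition the rank-2 match
beats the rank-3 match (the higher-correlated group is the stronger
confusion candidate); exactly one duel is run per query, with no
re-escalation of the duel winner.

**Stage 2.** The map is split into quadrants Q1 (top-left), Q2 (top-right),
Q3 (bottom-left), Q4 (bottom-right); the feature layout is, per quadrant,
magnitude then angle channel, each contributing mean, variance, kurtosis,
skewness — 32 features in a frozen order. Moment conventions: population
variance (divisor N); kurtosis non-excess (normal ≈ 3); skewness the
standardized third moment; a constant sample gets variance 0 and, because
the standardized moments are 0/0 there, skewness and kurtosis 0 by
convention. The k-NN duel uses brute-force distances (training sets are a
few dozen maps; no tree acceleration is warranted), with three metrics:
Cityblock (L1), Euclidean (L2, implemented as the root of the summed squared
differences — ordering-equivalent to the squared form and a true metric, so
the triangle inequality holds), and Chebyshev (L∞ maximum coordinate
difference). Neighbour-distance ties are broken by stable reference order;
an even vote split is resolved by the single nearest neighbour's label —
deterministic and standard, needed because the registry contains even k
(4, 10, 12). The per-pair registry transcribes the grid-search results of
the original clinical study ("Manhattan"/"Eucledian"/"Chebychev" spellings
normalized at load); unlisted pairs default to (cityblock, 1). The stage-2
training set is the current reference set restricted to the duel's two
labels.

## Evaluation protocol

One-vs-all binarization per class gives TPR = TP/P, SPC = TN/N,
PPV = TP/(TP+FP) with 0/0 → 0 (a never-predicted class scores 0 precision
rather than crashing), ACC = (TP+TN)/(P+N); P = 0 or N = 0 raises an
explicit undefined-metric error. The macro average accuracy is the
unweighted mean of per-class accuracies.

Cross-validation is balanced repeated holdout: per iteration, a reference
set of `per_group` maps per class (20 × 14 = 280 at defaults) and a
*disjoint* experimental set of the same shape are drawn; the experimental
set is classified against the reference with the full cascade.
Disjointness is enforced (and asserted at run time): overlapping draws
would leak k = 1 self-matches and r = 1 self-correlations, inflating every
figure. Rates are averaged over iterations at the rate level (mean of
per-iteration rates), not by pooling counts; confusion matrices and the
rank-of-true-group distribution are pooled over all iterations. The same
reference set serves both stages.

The per-pair grid search evaluates binary k-NN accuracy for each metric ×
k ∈ 1..15 over the same kind of balanced draws restricted to the two
groups; the argmax is reported with ties broken toward smaller k, then
metric order cityblock, euclidean, chebyshev (simpler settings win ties),
and the full 45-row mean-accuracy table is emitted so users can re-rank by
another criterion if they prefer.

## Synthetic cohort generator

No public CDDM cohort exists, so the generator produces a labeled stand-in
with the *statistical* structure the classifier assumes — it makes no claim
about MCG physics. Each class template is a magnitude field summing
isotropic Gaussian blobs on normalized [0,1]² coordinates (normalized to
max 1 after summation) plus an angle field that is a base angle plus a
linear gradient in the grid coordinates.

Class geometry is derived, not hand-drawn: the 14 classes are embedded in a
3-D latent space by classical (Torgerson) multidimensional scaling of
shortest-path distances on the class-confusability graph — an edge for
every pair in the packaged low-precision/low-sensitivity tables and for
each adjacent severity pair in CAD1–CAD5 and LVH1–LVH3. Blob centres, base
angle, angle gradient, blob width and secondary-blob amplitude are all
affine in the latent coordinates, so tabulated confusable pairs are close
in every cue and neighbouring severities differ by small shifts. Two
dimensions proved too few — they collapsed several confusable families onto
nearly identical templates — hence three. The `separation` parameter in
[0, 1] scales the latent coordinates (0 collapses all classes, 1 spreads
them fully).

Within-class variability is i.i.d. additive Gaussian noise per node:
magnitude noise is clipped at 0 and the map re-normalized (so per-node
dispersion at a node with clean value c is inflated by roughly √(1+c²) by
the peak-coupling of re-normalization — relevant when validating the noise
model empirically); angle noise is re-wrapped. Draws are reproducible per
(seed, class, draw index) via independent seeded streams, so cohorts are
byte-identical across runs and invariant to generation order.

**Default conditions (frozen).** separation 0.6, magnitude noise SD 0.05,
angle noise SD 0.15, 40 maps per group (supporting one 20-per-group
reference plus one disjoint 20-per-group experimental draw per iteration),
seed 2021. Within-class variability of real CDDM cohorts is not publicly
characterized, so these levels were calibrated once, by design, to place
the generator in the regime the method targets: high but imperfect stage-1
recovery with its confusion mass concentrated on the tabulated confusable
pairs (so the escalation rules have real work to do and the two-stage
improvement is observable). At these conditions the stage-1 ranking puts
the true group in the top three for ≈ 83% of queries (the clinical study
observed 86%), escalates ≈ 45% of queries, and shows nonzero stage-1
confusion on 14 of the 23 tabulated confusable pairs.

**What passing on synthetic data does and does not show.** The generator
validates the machinery — correlation ranking, rule firing, duel mechanics,
the evaluation bookkeeping — under a controlled confusion structure. It does
not validate clinical performance: real CDDMs have correlated, non-Gaussian
within-class variability, class-imbalanced cohorts, and physiological
structure no blob model captures. The published per-group characteristic
table is therefore shipped as a fixture for the macro-averaging worked
example, never regenerated from synthetic data.

## Numerical choices and degenerate inputs

* All-zero magnitude grids are rejected (no scale to normalize by);
  negative or non-finite magnitudes and non-finite angles are validation
  errors.
* Angle wrapping maps to the half-open interval (−π, π]; 2π and −π both
  wrap to values inside the interval (0 and π respectively).
* Pearson outputs are clipped to [−1, 1] to absorb last-bit float
  excursions; correlation of anything with a constant vector is 0.
* Map files round-trip through text at `%.17g`, reproducing doubles to
  ≤ 1e-12.
* Problem sizes in the test-suite and acceptance runs (cohorts of 40 maps
  per group, 10–20 holdout iterations) were chosen as the smallest sizes at
  which the stochastic figures are stable to well under a point; the
  protocol's defaults (20 iterations, 20 per group) are used unchanged.

## Known limitations

* Linear correlation on wrapped angles (see above) — a circular correlation
  variant is deliberately out of the default path.
* The escalation tables are frozen clinical-cohort artifacts; re-learning
  them from a new cohort's confusion matrix is out of scope. The pair
  registry, in contrast, *can* be regenerated from any labeled cohort with
  `cddmclass sweep --all-pairs`.
* No probabilistic confidence beyond the correlation scores; no multi-round
  duels; single fixed grid size per cohort.
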