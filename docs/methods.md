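# Methods

## The task and what the package computes

In a homecage novel-object-recognition (NOR) experiment, a mouse lives in a
monitored cage with two object windows (left and right). The protocol runs
four phases — habituation (baseline objects), sample (two new objects for
24 h), retention (baseline restored, 24 h or 7 d), and test (one familiar
duplicate, one never-seen object). An overhead camera records at 2 frames/s;
pose estimation yields per-frame keypoints (snout, ears, spine, tail base)
from which per-frame "exploration" of either object is classified.

The package computes, from per-frame exploration labels:

* per-phase exploration times T_nov and T_fam and the discrimination index
  DI = (T_nov − T_fam) / (T_nov + T_fam) ∈ [−1, 1];
* the relative (paired) DI, DI_test − DI_sample, the headline recognition
  measure — pairing within animal cancels stable side preferences;
* 1-min binned time courses, latency to first exploration, peak-bin
  comparisons, first-approach (novel vs familiar) proportions with an exact
  binomial test, and the sample-exploration vs relative-DI correlation;
* nest-position and corridor-exit bias analyses;
* an annotator-agreement surrogate model quantifying how annotation
  ambiguity propagates into the DI.

Analysis windows: the sample DI uses the whole sample phase; the test DI
uses only the first 20 min after the animal's first interaction with either
object, where exploration concentrates. "First interaction" is the first
classified exploratory frame on either side — the only machine-observable
definition. The latency reference point is the phase (object-change) start,
not the first post-change corridor exit. Gaussian smoothing of binned time
courses (σ = 4 bins, kernel truncated at ±4σ, renormalised at edges) is
display-only; every statistic uses unsmoothed values. The "4 standard
deviations" smoothing convention is ambiguous between kernel width and
truncation; we read it as σ = 4 bins and document that choice here.

## Exploration classification

Exploration is the posture in which the animal faces an object with its
snout near it. Features per frame and side: snout–object-window distance
(cm), heading alignment (angle between the ears-midpoint→snout axis and the
snout→window vector, degrees), body elongation (snout to tail base), and
body-centre speed. The feature set beyond distance and alignment is this
package's choice.

* Geometric rule: exploratory on a side iff distance ≤ 3 cm and alignment
  ≤ 45° (conventional NOR proximity annulus; both configurable and recorded
  in output metadata). If both sides qualify the nearer object wins — the
  cage geometry makes dual exploration physically impossible; exact ties
  break to the left, documented.
* Random forest (scikit-learn) on the same features, mirroring production
  pipelines in which exploration is identified by a trained ensemble. A
  temporal 80/20 split reports held-out balanced accuracy (a random split
  would leak across adjacent frames of one bout).

Frames whose snout confidence falls below 0.6 are unreliable: they inherit
the previous frame's label only inside a bout, otherwise they are
non-exploratory. Post-processing closes gaps ≤ 1 frame and drops bouts
shorter than 2 frames, smoothing single-frame flicker at 2 fps. Gap closing
can in principle make the two sides collide on a frame; the collision breaks
to the left, consistent with the tie rule.

## Synthetic session generator

The generator emulates what the cage records — keypoints plus ground-truth
labels — with a discrete-time (per-frame) Markov state machine over
nest / corridor-left / corridor-right / roam / explore-left / explore-right.
Frames are the recording's native unit at 2 fps, so a per-frame chain rather
than a continuous-time process is the natural discretisation.

Per-side exploration hazard while roaming:

    λ_side(t) = baseline_hazard × side_mult × boost(t) × novelty(side)

* `baseline_hazard` = 0.006 bouts s⁻¹ side⁻¹; with 2.5 s mean bouts this
  gives ≈ 0.9 s/min/side of baseline exploration.
* `boost(t)` = 1 + A·exp(−Δt/τ) after each object change, A = 6, τ = 480 s.
  3τ ≈ 24 min puts recovery to baseline within 20–30 min of the change, and
  the boosted rate peaks near 12 s/min summed over sides, the scale seen in
  homecage recordings. The retention-phase change (baseline objects return)
  reuses the same machinery scaled by `retention_boost_scale` = 0.25: the
  response to re-presented familiar objects is real but much weaker, and no
  quantitative amplitude is established, so a fixed fraction is the minimal
  choice.
* `novelty(side)` = f = 1.67 on the novel side during the test phase — the
  ~67% higher exploration rate of a novel object, which corresponds to
  DI = (f−1)/(f+1) = 0.2509. With f = 1 and side_bias = 1 the law is
  exchangeable between sides.

Bout, nest-stay and corridor-stay durations are geometric (discrete
exponential). Real bout durations are not well characterised; the
exponential family is a modelling convenience, and no result here depends on
the bout-length distribution beyond its mean. After a corridor exit, the
next bout's side is the corridor's side with probability
`corridor_side_coupling` (default 0.5 = unbiased, matching the observed
near-0.5 corridor scores).

Keypoints are rendered consistently with the state: during exploration the
snout sits on an annulus inside the object window with the head axis
pointing at the window centre; roaming follows a reflected random walk kept
clear of both access windows; in the nest the skeleton contracts around the
body centre (curled-up posture), which also places the dwell-heatmap argmax
at the nest. Isotropic Gaussian jitter (SD 1 px) and Beta(20, 1) confidences
peaked near 1, with ~1% low-confidence dropout frames, provide minimal
realistic degradation for classifier tests.

One seed expands into independent substreams (state process, keypoint
rendering, per-mouse sessions) via `numpy` seed sequences: cohorts are
reproducible while mice stay independent.

What the generator does **not** emulate: drinking/licking microstructure,
light-cycle and thermal rhythms, object-identity preferences, climbing or
chewing postures, pose-estimation failure modes beyond isotropic jitter, and
any within-session non-stationarity other than the novelty boost. Passing
tests therefore demonstrate the pipeline's correctness on data obeying the
stated generative law, not classifier performance on real video.

## Annotator simulation and the surrogate model

Assume N true exploratory instances. A simulated annotator selects
`round(ss·N)` frames of which `round(pef·ss·N)` are true frames drawn
uniformly without replacement (counts use round-half-to-even); the remainder
are false positives drawn from a non-exploratory pool defaulting to frames
within 3 frames of a true bout — real annotation errors are boundary
near-misses, not arbitrary frames. If `pef·ss > 1` the request is
contradictory and raises (the model-level grid caps the true count at N with
a warning instead, keeping the grid total).

Expected agreement between two independent annotators is the Monte-Carlo
mean of |T₁∩T₂|/(ss·N), which converges to the hypergeometric expectation
pef²·ss; false-positive frames are assumed idiosyncratic and never overlap.
The empirical overlap matrix is oriented M[A][B] = |A∩B|/|A| (row =
reference annotator); both orientations are recoverable from the identity
M[A][B]·|A| = M[B][A]·|B| = |A∩B|. The (SS, PEF) grid spans SS ∈ [0.5, 1.5]
and PEF ∈ [0.5, 1.0] for N from 500 to 13,600 (250 s to 113 min at 2 fps);
default 200 replicates per cell keep the Monte-Carlo SE below 0.5
percentage points even at N = 500. Varying N across this range moves the
grid by well under 3 percentage points. Observed pairwise overlaps invert
into the admissible (SS, PEF) cells whose expectation falls within the
observed [min, max].

The surrogate DI model draws SS₁, SS₂ independently and uniformly — the
minimal assumption for "randomly chosen sample sizes" — and evaluates
DI = (f·SS₁ − SS₂)/(f·SS₁ + SS₂); N and PEF cancel. With SS ~ U(0.5, 1.5)
the analytic negative fraction is P(SS₂ > f·SS₁) = 0.1324 (≈13% of 1,000
surrogates); constrained to SS ∈ [0.8, 1.2] the worst case
(SS₁ = 0.8, SS₂ = 1.2) gives DI = 0.0536 > 0, so the entire distribution —
including its 1st percentile (α = 0.01) — stays positive.

## Bias analyses

Nest: dwell heatmap (1-cm grid, body centre = mean of spine keypoints,
sample + retention phases) → argmax cell = nest → distances to the two
object windows → k-means (k = 2, 10 restarts, fixed seed) over mice, cluster
identity resolved by comparing cluster-mean distances; degenerate cohorts
fall back to the per-mouse nearest-object rule, exact equidistance breaks to
left. Which body point defines dwell is unspecified in common practice; the
spine mean is the most stable choice against head movements.

Corridor: visits are detected in the generator as corridor-state occupancy
(hardware beam-break signals are not derivable from keypoints); each
interval between consecutive visits scores the first explored object 0
(same side) or 1 (opposite), skipping empty intervals; the mean is tested
against 0.5.

## Statistics

Paired/one-sample/two-sample t, Pearson r, Shapiro–Wilk and the exact
binomial test delegate to scipy; Benjamini–Hochberg to statsmodels; the
three-way ANOVA (facility × object × side, all interactions) is a
fixed-effects statsmodels OLS with Type II sums of squares (types coincide
in balanced designs). The binomial test is one-sided toward novel-first (the
directional hypothesis), two-sided by flag. Exact one-sided tails for
published-scale counts are 0.0096 (15/19) and 0.036 (25/38 at 0.5) —
reported p-values in the literature for these counts are sometimes smaller
(0.007, 0.03), consistent with a different sidedness or mid-p convention;
we implement the exact tail and do not tune. A 0/0 exploration window makes
the DI undefined (NaN): it is flagged and excluded from cohort tests rather
than coerced to 0. The BH family is the set of tests reported together in
one analysis table.

## Problem sizes

The generator's default phase durations are the full study schedule (9 d /
24 h / 24 h / 2 h). The analysis drivers and tests use minutes-scale phases
(e.g. 10 min habituation, 2 h sample, 30–60 min retention, 30–40 min test)
and cohorts of 6–20 mice — sizes chosen so every statistical property under
test (hazard integrals, DI recovery within 3 SE, corridor-score null) is
already well resolved; all rate and effect-size parameters are the
study-scale values. Acceptance-level surrogate computations use the model's
native sizes (1,000 surrogates, 11×11 grids, 200 replicates per cell).

## Known limitations

* The geometric rule and the forest share the same feature definitions, so
  the forest's advantage on real data (irregular postures) is not visible on
  synthetic sessions where the rule is near-Bayes-optimal.
* The surrogate model treats annotator samples as exchangeable uniform
  draws; systematic biases (consistently early/late bout boundaries) are out
  of scope.
* Cohort-level analyses assume independent animals; no mixed-effects
  modelling, survival analysis of bout durations, or cross-facility
  meta-analysis beyond the ANOVA contract.
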