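# Methods

## The classification

`dirfix` classifies free-viewing scene fixations by their temporal
relation to the annotated objects they land on:

* **Detection (D)** — the first fixation of the trial landing on a given
  object;
* **Inspection (I)** — a fixation landing on the same object as the
  immediately preceding fixation;
* **Return (R)** — a fixation landing on an object fixated earlier in
  the trial, after at least one intervening fixation elsewhere.

A fixation hitting no object is *unlabelled* (background). Formally, for
fixation *i* with hit set *H_i* (the objects within the tolerance margin
of its position), object *o ∈ H_i* is detected iff *o ∉ H_j* for all
*j < i*, inspected iff *o ∈ H_{i−1}*, and returned iff *o ∈ H_j* for some
*j < i−1* and *o ∉ H_{i−1}*. The classifier is a single left-to-right
pass keeping a per-object last-hit index, so labels of a prefix never
change when fixations are appended (the classification is online).

Two consequences of these definitions are worth spelling out:

* Per object and trial, the hit count decomposes exactly as
  #hits = #D + #I + #R with #D ∈ {0, 1}.
* With a positive margin one fixation can hit several objects and hence
  carry several class flags at once (e.g. inspect one object while
  detecting an adjacent one). Per *object*, each fixation assigns exactly
  one role: an object that is both "inspected from the previous fixation"
  and "hit earlier in the trial" counts as Inspection only, which keeps
  per-class dwell sums well defined.

## Hit testing with a tolerance margin

Object annotations are boolean pixel masks with a depth order. Raw masks
may overlap (e.g. text printed on a book); overlaps are resolved in
favour of the object nearest the viewer, after which supports are
pairwise disjoint. Hit testing precomputes one exact Euclidean distance
transform per object (`scipy.ndimage.distance_transform_edt`), so a
query is a constant-time lookup per object. A fixation hits every object
whose distance at its pixel is ≤ the margin; the margin default is
0.5 degrees of visual angle (dva) converted through the screen geometry
(≈ 20 px on a 1200-px / 29.6-dva display). Margin 0 restores a strict
partition (every fixation carries at most one flag).

Numerical choices: continuous fixation coordinates are rounded to the
nearest pixel centre before the distance lookup — sub-pixel interpolation
of a distance field sampled at mask resolution would be spurious
precision. Out-of-image fixations are reported unlabellable (empty hit
set), not errors. dva→px conversion uses the horizontal scale; a warning
fires if the display's horizontal and vertical pixel pitches differ by
more than 2%.

## The content-agnostic heuristic

When no masks exist, a spatial heuristic approximates the scheme: two
fixations closer than θ = 10% of the image width are treated as landing
on the same pseudo-object. Fixation *i* is Inspection if
‖p_i − p_{i−1}‖ < θ, else Return if some earlier fixation *j < i − 1*
lies within θ (the most recent such *j* anchors the pseudo-object — a
deterministic tie-break), else Detection. The inequality is strict for
the heuristic and non-strict for the mask margin, matching the two
definitions' wording ("closer than" vs "on or within"). Exactly one
class per fixation; the first fixation is always a Detection.

Agreement between the schemes is counted per fixation on class flags
(the heuristic has no true object identities), conditioned by default on
the object scheme: of the fixations the object scheme calls class *c*,
which fraction does the heuristic also call *c*? The reverse
conditioning is available as an option. On scenes whose objects are
single points separated by more than 2θ, with fixations exactly on the
points, the two schemes coincide exactly — a degenerate-equivalence
check in the test suite.

## Fixation maps and split-half consistency

Per image and class, observers are split into two halves (odd/even
enumeration order). Each half's fixations of each class are binned onto
a ×4-downsampled grid and smoothed with an isotropic Gaussian
(default σ = 1 dva, truncated at 3σ). Each fixation deposits unit mass;
duration weighting is available but off by default. The kernel, width,
duration weighting and grid resolution are this package's declared
defaults — they are the conventional choices for fixation heatmaps, not
values inherited from any particular dataset.

For every ordered class pair (c_A, c_B) the group-A map of c_A is
Pearson-correlated with the group-B map of c_B. Correlations are
clipped to ±(1 − 10⁻⁷), Fisher z-transformed, averaged across images,
back-transformed and squared, giving a 3×3 shared-variance matrix whose
diagonal holds within-class consistency. Undefined correlations
(constant maps, e.g. an empty Return map) are excluded pairwise and
counted, never imputed. For a single image the pipeline reduces to the
plain squared correlation (a limit the tests check to 10⁻¹²).

**Diagonal bootstrap.** Whether within-class consistency exceeds
between-class consistency is tested by comparing the mean z over all
diagonal entries against a null distribution of means of coefficients
subsampled without replacement from the whole tensor (diagonal and
off-diagonal alike), 10,000 iterations, one-sided with an add-one
correction and ties counted as extreme. The subsample size defaults to
2,100 (the diagonal count of a 700-image corpus); analyses at other
corpus sizes should pass 3 × n_images. Known property: diagonal cells
share no fixation maps with one another, whereas randomly subsampled
cells often do and are therefore positively correlated; the null
consequently overstates the variance of the diagonal mean and the test
is mildly conservative. Calibration on label-shuffled corpora puts the
empirical rejection rate at α = 0.05 near 0.02.

## Dwell-time dynamics

Overall dwell proportion of class *c* is the summed duration of
fixations flagged *c* divided by the trial's total fixation duration;
classes are normalised independently, so a multi-flag fixation
contributes its full duration to each of its classes (with margin 0 the
four classes partition the total to 10⁻⁹).

Time courses use adjacent, non-overlapping 50 ms bins from 150 to
3000 ms of viewing time. A fixation contributes to every bin its
interval [onset, onset + duration) overlaps; bins and fixation intervals
are half-open. Per-bin class proportions weight by in-bin overlap length
by default (a fixation spanning three bins contributes its in-bin share
to each); attributing the full duration to every overlapped bin is an
explicit alternative. Fixation-duration and saccade-amplitude curves
average the full duration, respectively the Euclidean distance to the
previous fixation, over class-c fixations overlapping the bin. The
observer is the unit of analysis throughout: curves are computed per
observer, then averaged with a t-based 95% CI; empty bins are missing
values, not zeros.

**Trial-duration comparison.** Group differences in per-observer
statistics (e.g. dwell proportions over a common 150–2000 ms range) are
tested by pooled resampling: all observers of both conditions are
pooled, each of 10,000 iterations draws the smaller group's size (43 of
144 in the motivating design) without replacement and records the mean;
the two-sided p compares the small group's observed mean against this
null (ties extreme, add-one correction), Bonferroni-corrected across the
three classes. Two-sided is the default because directional surprises
are expected in this literature; a one-sided flag exists.

## Synthetic data

The generator emulates the structure of annotated free-viewing data at
configurable scale. Scenes: rectangles or ellipses placed with a minimum
pairwise separation, an optional fraction of deliberately occluding
objects (resolved by placement order), Bernoulli semantic attributes,
defaults of 1200 × 900 px / 29.6 × 22.2 dva and eight objects per scene
(the regime of the OSIE-style corpora this package targets). Scanpaths:
per-trial class tokens — new object / same object / return / background —
drawn i.i.d. from a configurable mix, then realised in feasibility
order: a token impossible in the current state (an inspection before any
object has been fixated, a return before any object is revisitable) is
deferred until it becomes possible rather than replaced. This keeps the
realised class frequencies unbiased estimates of the mix even in short
trials, where a naive per-fixation draw with remapping inflates
Detections by several percentage points; only when no remaining token is
feasible is one remapped (e.g. new → return once all objects are
visited). Positions scatter around the target object's centroid
(rejection-sampled into its support); background fixations respect the
hit-test margin, so they are guaranteed unlabelled. Durations are
log-normal (median 250 ms, σ = 0.4 — the usual scene-viewing regime);
the first onset is 150 ms and onsets accumulate from durations (saccade
durations are neglected). An optional linear ramp of the mix across the
trial emulates the drift from detections toward inspections and returns
over viewing time.

The generator records its intended class per fixation. When objects are
separated by more than twice the margin and the scatter keeps samples on
their objects, classifier labels equal the intent exactly (the
"exactness regime", asserted at agreement 1.0 across 20 seeded corpora);
under crowding or occlusion agreement is reported, not asserted. What
the generator does *not* emulate: saccade trajectories and durations,
centre bias, photometric content, pursuit, or any coupling between
object semantics and gaze beyond the attribute labels — so passing tests
validate the algorithms and their statistical calibration, not claims
about real human gaze.

## Semantic dwell profiles

Objects carry binary semantic attributes from a 12-name vocabulary;
near-redundant pairs are stripped before analysis (Face removed where
Emotion is present, Smell where Taste, Operability and Gazed where
Touched, Watchable where Text). The dwell table reports, per class and
attribute, the mean across observers of the dwell share spent on
attribute-carrying objects. The default denominator is the observer's
total labelled (D∪I∪R) dwell, shared across the whole table so cells are
comparable across classes; a per-class denominator is a flag. A
multi-object fixation carrying an attribute through any of its class-c
objects counts once. The module also emits the long-format per-observer
table that repeated-measures ANOVAs or mixed models consume; those fits
are deliberately out of scope.

## Problem sizes and determinism

All randomness flows from explicit seeds (configs carry a seed; the CLI
derives per-component seeds from one root). The validation suite runs on
desk-scale corpora chosen to make each check statistically meaningful:
1,000 mixed-regime trials for the classifier/oracle equivalence, 20
corpora of 50 trials × 20 fixations (12-object, 480 × 360 px scenes) for
class-mix recovery, 30 images × 8 observers for the consistency
construction, and 50 replicates for each null calibration. The filtering
defaults (onset ≥ 100 ms, duration ≥ 100 ms) keep boundary values; the
choice of ≥ over > at exactly 100 ms is a declared convention, as the
convention is not standardised.

## Known limitations

* Static scenes only; no pursuit or dynamic-object tracking.
* No fixation-event detection: inputs are already-parsed fixations.
* The heuristic's 10% threshold is calibrated for diverse complex
  scenes; sparser or denser stimuli may need adjustment.
* The diagonal bootstrap is mildly conservative (see above).
* Mask accuracy bounds everything downstream; the margin compensates for
  annotation and calibration slack but also creates multi-label
  fixations that make class proportions sum to more than 1.
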