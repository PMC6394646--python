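# Methods

This note documents the models implemented in `adlfuse`, the assumptions and
parameter choices behind them, what the synthetic data generator does and
does not emulate, and the package's known limitations.

## Frame and belief model

All evidence lives on a frame of discernment Θ of activity labels (default:
15 ADLs in a fixed order).  Focal elements follow the power-set (Shafer)
model: distinct activities are mutually exclusive, so two different
singletons intersect to ∅, and the full set Θ is admitted so a vacuous
(total-ignorance) BBA exists and acts as the neutral element of combination.
Free-model intersection elements (θᵢ ∩ θⱼ as a non-empty hypothesis) are not
enumerated: every belief assignment the pipeline produces is Bayesian
(singletons only), and restriction can only create sub-*unions*, so nothing
in the computation requires them.

The frame order is load-bearing: it defines canonical subset representation
and breaks every tie deterministically (arg-max decisions, candidate-set
boundaries).

Numerical conventions:

* masses must sum to 1 within 1e-9; constructor inputs off by up to 1e-6 are
  renormalized with a warning, and belief rows quoted at 4 decimal places
  (which can be off by ~2e-4) must be renormalized explicitly via
  `normalize=True` — deviations beyond the tolerance are otherwise errors;
* a PCR redistribution term with denominator mᵢ(A) + mⱼ(X) = 0 necessarily
  has a zero numerator and is defined as 0 (continuity convention);
* zero masses are dropped from storage, which also keeps the combination
  loops over focal-element tuples small.

## Combination rules

`combine_pcr5` implements the two-source closed form term by term:
conjunctive consensus over all focal-element pairs with non-empty
intersection, plus proportional redistribution of each conflicting product
back to its two generating elements.  `combine_pcr6` enumerates ordered
s-tuples of focal elements: consensus tuples contribute their product to the
common intersection; totally conflicting tuples have the product split among
the s participating elements in proportion to the mass each source assigned.
The two rules coincide exactly at s = 2 (tested to 1e-12 over random pairs).

`pcr_bruteforce` is an intentionally independent second route: it is written
from the per-source form of the rule (for each source i and element A, sum
mᵢ(A)²·Π mⱼ(Yⱼ)/(mᵢ(A)+Σ mⱼ(Yⱼ)) over conflicting tuples of the *other*
sources) and computed in exact `Fraction` arithmetic.  The test suite checks
the fast float implementations against it exhaustively over all 231 Bayesian
BBAs with masses on a 0.05 grid of a 3-label frame (all 53 361 ordered pairs),
and over ~13 000 grid triples (an evenly spaced 20-BBA subgrid exhaustively,
plus 5 000 seeded random triples); full triple enumeration (231³ ≈ 1.2×10⁷
combinations through both routes) is out of proportion to the information it
adds, since the per-tuple arithmetic has no data-dependent branches beyond
what pairs and sampled triples already cover.  Observed agreement is at
machine precision.

`FusionTrace` records every conflicting product and its redistribution
shares; the shares of each product sum to that product (1e-9), and the total
redistributed conflict equals 1 minus the conjunctive consensus mass.

## Knowledge source

A time–activity table scores each (time period, activity) cell on an integer
0–10 scale.  Converting a timestamp to a BBA is row-wise normalization of
the period containing the clock time.  Conventions chosen where the table
format is ambiguous:

* a printed period "a–b" is half-open [a, b + 1 min), so contact-adjacent
  printed rows ("6:51–7:20", "7:21–7:30") partition the day and a boundary
  instant belongs to the period that starts there; an end time of 00:00
  means midnight at the end of the day;
* timestamps in an uncovered gap follow a policy: `error` or the default
  `nearest-period` (a routine table should degrade gracefully, not crash on
  a one-minute sliver);
* an all-zero row means the source abstains: uniform BBA plus a warning,
  never a veto of every activity;
* optional location–activity and activity-transition tables are supported;
  when present and their context keys are supplied, each yields its own BBA
  and all are chained pairwise with PCR5 in the fixed order time → location
  → transition.  The chaining order and rule are this package's design
  choice; nothing in the source formulation prescribes how multiple tables
  combine, and PCR5 chaining keeps the result order-independent in practice
  only up to the rule's (mild) non-associativity, hence the fixed order.

Weekday and weekend/holiday variants are selected by the calendar date
(scoped tables take precedence over `any`).

## Image source (bag-of-tags classifier)

The annotator contract is a list of L ≈ 20 textual tags per image; the
package defines the interface and never runs a CNN itself.  Training pools,
for every activity class k and tag i:

* tf(i,k): tag frequency in the class's pooled tags — tf is a per-(tag,
  class) quantity, so the pooled-class reading is the one under which every
  factor of the final weight is well defined;
* idf(i) = ln(|D| / (d(i)+1)) with one BoT = one document, counted over
  *all* classes (the per-class alternative would make idf depend on k twice);
* e1(i,k): base-2 entropy of the tag's occurrence counts across the class's
  individual BoTs — high when the tag recurs stably through the class;
* e2(i): base-2 entropy of the tag's document counts across classes — high
  when the tag is generic; remapped by R(e2) = 1 − e2/(log₂K + λ), λ = 0.01,
  which stays strictly positive even for perfectly uniform tags.

The final weight tf·idf·e1·R(e2) is clipped at 0: with "+1" smoothing, idf
is negative for near-ubiquitous tags, and negative values are meaningless in
a top-M ranking and in cosine space.  Each class center keeps the M = 20
highest-weight tags (ties lexicographic); classification embeds the input
BoT's raw tag counts and all centers in the union center vocabulary, takes
per-class cosine similarity, and sum-normalizes to a Bayesian BBA (the raw
similarity vector does not sum to 1).  A BoT sharing no tag with any center
abstains (uniform BBA, low-confidence flag).  Tag normalization is casefold
+ trim only — annotator tags are already canonical words, so stemming would
destroy information ("meeting" vs "meet").

Note on naming: e1 is called the *inter-class* factor and e2 the
*intra-class* factor, although e1 is computed within one class and e2 across
classes; the names follow the terminology of the originating formulation,
the formulas are authoritative.

## Sensor source

3-s non-overlapping windows at 90 Hz (270 samples), each centered on an
image timestamp so all three sources describe the same instant.  Windows
with at least one sample in ±1.5 s are kept (edge-replicated and flagged if
short); empty ones are skipped.  The 127-dimensional descriptor is, in fixed
order: per-channel mean/std/range/RMS (4×6), order-6 Burg autoregressive
coefficients (6×6), 10-bin equal-width binned distribution over the
channel's min–max (6×10), accelerometer pairwise correlations (3),
accelerometer signal magnitude area (1), and GPS speed/latitude/longitude
(3) with carry-forward of the most recent fix.  This is the unique natural
assignment of the standard HAR feature list that totals exactly 127; the
layout in `sensors.FEATURE_NAMES` is authoritative for this package.
Degenerate inputs have fixed conventions: constant channel → AR coefficients
0, correlation 0, all binned mass in bin 1.  Burg was chosen for AR
estimation because it is stable on 270-sample windows; the gain term is
excluded (the 6 coefficients, not 7).

Classification: features standardized with training statistics (RBF kernels
need comparable scales), one-against-one RBF SVM, (C, γ) selected by
stratified 5-fold cross-validated accuracy over a logarithmic grid spanning
the optima reported for comparable activity datasets — (16, 0.33) and
(5.29, 0.57) — then refit with per-pair sigmoid (Platt) posterior
calibration.  The solver is scikit-learn's; the quadratic program itself is
deliberately not re-implemented.  Posteriors become the sensor BBA; frame
labels missing from training receive zero mass.

## Fusion network

Level 1: PCR5 of knowledge and image.  Conflict predicate (configurable):

* `argmax` (default): the two top decisions disagree, ties resolved by frame
  order before comparison — the plain reading of "the two sources give
  conflicting results";
* `mass`: the conjunctive conflict mass of the pair exceeds a threshold —
  the measure-theoretic alternative, exposed because the choice is genuinely
  open.

No conflict → the level-1 arg-max is final and the sensors are never
touched.  Conflict → candidates are the Nc = 3 top-belief singletons *of the
level-1 fused BBA* (ranking by the fused pair rather than either raw source
follows from treating level 1 as the best available two-source summary);
boundary ties keep the smaller frame index.  All three raw source BBAs are
restricted to the candidates and renormalized (a source losing all its mass
falls back to uniform over the candidates — abstention, not veto), then
combined with three-source PCR6; the final label is the arg-max over the
candidates.  Sensors never enter level 1: that asymmetry *is* the
architecture's priority model.

The simplified variant (no knowledge tables) descends candidates directly
from the image BBA and fuses image + sensors with PCR5.

With Nc = |Θ| and conflict forced, the full network reduces exactly to plain
three-source PCR6 — used both as a consistency test and to replay the
bundled worked example.

## Synthetic data generator

The generator *defines the package's study conditions*; defaults:
15 classes, 100 images/class (training) and 60 (test), L = 20 tags/image,
one image per 4 s, IMU at 90 Hz, 10-image bouts, GPS dropped at rate 0.1.

What it emulates, and why those choices:

* **Tags**: 6 signature tags per class (draw probabilities 0.30…0.10),
  mixture weight 0.55 signature vs Zipf-distributed background vocabulary of
  24 generic tags; 13 % of images draw their signature tags from a
  designated confusion partner (entertainment↔TV, computer use↔writing,
  shopping↔walking, …).  The partner mechanism is what gives the image
  source a realistic ~12 % error rate with *structured* (not uniform)
  confusions, the regime decision-level fusion is meant to correct.
* **IMU**: sedentary classes share one identical low-variance-around-gravity
  model — so motion data genuinely cannot separate them; walking and
  shopping are gait oscillations at 2.0 and 1.5 Hz with different
  amplitudes; lying down reorients gravity onto the body's x-axis; cleaning
  and washing up are bursty (exponential on/off envelopes); transportation
  is smoothed vibration noise.  Frequencies are far below the 45 Hz Nyquist
  limit.
* **GPS**: log-normal speeds with medians 0.02–0.04 m/s (sedentary), 0.7
  (shopping), 1.4 (walking), 11 (transport).
* **Schedule**: per-activity hour-range affinities (e.g. lying down at
  night, meetings on weekday mornings, entertainment on weekend afternoons)
  are used twice — to sample bout start times *and* to emit the knowledge
  tables — so the knowledge source is informative by construction but
  coarse, since many activities share hours.  Confusion partners are given
  dissimilar schedules on purpose: that is the channel through which
  knowledge disambiguates what the camera confuses.

Every bout is placed in its own calendar week (preserving weekday and clock
time), so exported CSV streams are strictly time-ordered.

What it does **not** emulate: real annotator vocabularies and their
correlated errors, sensor drift and calibration error, activity transitions
inside a bout, label noise, inter-wearer variability.  Passing the benchmark
therefore demonstrates the *structural* claims (fusion ≥ each source;
locomotion separable by sensors while sedentary activities are not), not
field accuracy on real recordings.

## Benchmark problem sizes and expected behaviour

The default benchmark trains on 1 500 windows/images and tests on 900
(100/60 per class), with a reduced 3×3 (C, γ) grid; one replicate runs in
well under a minute on a single core.  Typical fixed-seed results: image
macro-F1 ≈ 0.87, sensors ≈ 0.39 (locomotion classes ≥ 0.98, sedentary ≈
0.1), knowledge ≈ 0.2, fusion ≈ 0.89–0.90.  The fusion gain is modest by
design — the image source is strong, and the hierarchical network's job is
to add sensor evidence only where it helps.

## Known limitations

* The package never runs an image annotator; tag quality is an input
  assumption, not a measured quantity.
* PCR rules are non-associative; chaining order for optional knowledge
  tables is fixed rather than learned.
* Only two fusion levels; no temporal smoothing across consecutive images,
  although activity durations clearly carry information.
* The 127-feature layout is one defensible reading of the standard HAR
  feature list; retrained accuracy on other datasets will differ from any
  particular reference implementation of the same list.
* Free-DSm focal elements beyond singletons + Θ are not supported.
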