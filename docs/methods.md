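# Methods

## The curation model

A micrograph is picked twice by independent picker runs, giving pick sets A
and B in which each physical particle ideally has one pick per set. Each set
is recentered by an independent classification run; the recentered positions
of the same particle from the two sets are compared. The per-particle distance
D (Å) between the recentered A-point and B-point measures recentering
reproducibility. The curation rule keeps one-to-one cross-set pairs with
D strictly below a threshold D_TH and rejects everything else; survivors are
split back into their two sets and the cycle repeats.

The discriminating assumption: a particle with enough signal is recentered to
its true center by any reasonable classification (error σ_hi of a few Å),
whereas a pick on noise is recentered essentially at random over the
classifier's translational search range (effective σ_lo of tens of Å).
Under isotropic Gaussian recentering error σ per axis and per point, the A−B
difference vector is Gaussian with variance 2σ² per axis, D² is exponential,
and the single-round keep probability is

    P(D < D_TH) = 1 − exp(−D_TH² / (4 σ²))        (`duster.core.keep_probability`)

At the working point D_TH = 20 Å this gives ≈ 0.99998 for σ = 3 Å and
≈ 0.0274 for σ = 60 Å. This closed form assumes *isolated* particles: if the
recentering clouds of neighboring particles overlap (inter-particle spacing
not ≫ σ_lo), cross-particle pairs inflate junk retention above the formula.
The simulators and tests therefore use spacings large relative to σ_lo when a
closed-form comparison is intended.

## Distance matching

Candidate pairs are all cross-set pairs on the same micrograph with D < D_TH
(strict inequality — the rule is "shorter than"; a pair at exactly D_TH is
rejected, which is tested). `match_pairs` returns the exact optimal one-to-one
matching: maximum number of pairs, and among maximum matchings the minimum
total distance. It is computed per connected component of the candidate graph
with the Hungarian algorithm (`scipy.optimize.linear_sum_assignment`), using a
penalty larger than any feasible total distance for non-candidate cells so
cardinality strictly dominates. Components are found by union-find over
KD-tree range queries, so the cost scales with the number of *local* conflicts,
not with table size.

This optimal matching was chosen over ascending-distance greedy acceptance
deliberately: greedy is maximal but not maximum (a short edge can block an
augmenting path and lose a pair), whereas the optimal matching is
deterministic, A/B-symmetric (up to exact distance ties, which have measure
zero for continuous coordinates), monotone in D_TH, and equal by construction
to the exhaustive oracle the test suite checks against.

A second mode, `pooled_cluster`, reproduces the semantics of duplicate-removal
tools that pool both sets and single-linkage-cluster at the separation
distance: every pick in a cluster containing members of both sets is kept.
It is provided for fidelity comparisons with that workflow; the one-to-one
mode is the default because the pooled rule is order-dependent in the tools
that implement it and can keep same-set chains.

Same-set near-duplicates (two A-picks within D_TH) can optionally be
pre-merged (`same_set_dedup_A`, keep-first-by-id); off by default and logged.

## The built-in recentering engine

`recenter2d` is a translational (rotation-free) reference-free K-class
classifier: boxes are extracted at picks (mean-subtracted, variance-
normalized; a constant box becomes zeros, not NaN), classes are initialized
from a seeded random partition, and each iteration scores every box against
every class average over all integer shifts |dx|,|dy| ≤ max_shift via FFT
cross-correlation, assigns the argmax class and shift, and re-averages the
shifted members. Empty classes are reseeded from the worst-fitting particle.
Iteration stops after `n_iter` rounds or when fewer than 0.5% of assignments
change. Class probabilities are a softmax over per-class best correlations
with temperature 0.05 of the correlation scale — only the [0, 1] range and
the ordering of this score are meaningful, which is all the probability
filter uses.

Two details matter for correctness:

* **Gauge fixing.** Translation-only alignment is invariant under a constant
  offset applied to (class average, all member shifts), so an average can
  converge off-center and bias every recentered point by a constant — fatal
  for a method that compares recentered positions across runs. Each
  iteration, every class average is rolled so its positive-intensity centroid
  sits at index `box // 2`, the in-box position of the pick under the
  extraction convention. This makes shifts absolute: a particle sitting
  exactly on its pick has shift (0, 0).

* **Stochastic shift reporting (`shift_mode="sample"`, the default for the
  curation engine).** Both pick sets see the *same* micrograph noise, so a
  deterministic argmax over the correlation field recenters even pure-noise
  picks to the same noise feature in both replicate runs — reproducibly, and
  therefore uncurably. Maximum-likelihood classifiers do not behave this way:
  their translation posterior for a low-S/N particle is nearly flat and the
  reported center moves with every re-randomization. The engine emulates this
  by drawing the reported shift from the Boltzmann distribution exp(corr/T)
  over the search window after the iteration has converged. For
  variance-normalized boxes against unit-norm averages, pure-noise
  correlations have unit standard deviation, so T = 1 is the Gaussian-noise
  posterior; the default T = 1.5 tempers it mildly because the field is an
  overconfident posterior (the box's own noise is part of the class average).
  A decisive peak (high-S/N particles sit ≳ 10 standard deviations above the
  field) is still reported at the peak; a noise-flat field yields an
  essentially uniform draw, irreproducible across replicate seeds. Sampling
  is deterministic given the seed. `shift_mode="argmax"` (with exact-recovery
  guarantees on clean data) remains available and is what the planted-offset
  unit tests exercise.

Defaults: box 48 px (63.8 Å at 1.33 Å/px), K = 6, max_shift = box//2 − 4 =
20 px. The search window spans most of the box — as translation search does
in SPA classification — and must exceed D_TH (15 px at 1.33 Å/px), otherwise
even uniformly-scattered junk lands inside the threshold too often for the
distance rule to discriminate. Edge policy: picks whose box crosses the image
edge are dropped ("skip", default) or kept via reflective padding
("pad-reflect"); dropped picks count as rejected in the round statistics.

## Curation loop and filters

`run_duster` applies recenter→match→split for `rounds` cycles (presets: 20 Å /
7 rounds for 2D-style recentering, 15 Å / 6 rounds for 3D-style), with
per-set, per-round seeds derived from the master seed via
`numpy.random.SeedSequence`. Each set advances with its *own* recentered
coordinates — the pair midpoint is never used — mirroring the split of
curated particles into two sets for independent re-extraction. Early stop on
100% retention is recorded as "converged"; total elimination is a warning
state, not an exception.

The duplicated filters all follow one principle — *an accident in one
replicate must not kill a particle*:

* `probability_filter`: remove iff class probability < floor (default 0.3) in
  **all** replicates;
* `decoy_filter`: remove iff assigned to a decoy class in **all** replicates
  (equivalent to the probability filter with 0/1 indicator scores — tested);
* `duplicated_class_selection`: keep iff the assigned class is in the keep-set
  in **both** replicates (selection, unlike removal, must agree).

`comprehensive_duster` runs R recenterings per set (distinct seeds) and
matches all R × R cross-set combinations per round. How the per-combination
kept sets combine is genuinely open; both rules are implemented and
`intersection` is the default (a pick survives only if kept in *every*
combination) as the stricter reading of curating "for all nine combinations"
(R = 3). The combinations share recenterings, so intersection retention is
*not* keep_probability^(R²); the test suite checks it against a Monte-Carlo
oracle that simulates the full dependency.

## Synthetic data

Two fidelity levels share one truth schema (particle id, micrograph,
center, S/N class, template id):

* **Coordinate-level (abstract).** Picks are truth + Gaussian jitter with
  per-set miss and false-positive rates; recentering is modelled directly as
  truth + N(0, σ²) with σ = 3 Å (high) / 60 Å (junk), false positives
  recentering around the pick. Class probabilities are Beta(8,2) / Beta(2,8).
  This path makes the closed forms exactly testable, and scales to 10⁵
  particles via a jittered-lattice placement (`placement="grid"`).
* **Rendered.** Micrographs are sums of planted templates plus white
  unit-variance Gaussian noise. High-S/N particles are five-lobed
  ring-of-Gaussians templates (randomly rotated; a small pentameric complex
  is the motivating shape) or soft discs at S/N 2.0 — S/N defined as signal
  variance over the template support divided by noise variance, and the
  painted amplitude is calibrated to that definition (verified by an
  estimator test). Junk is low-amplitude random Gaussian blobs at S/N 0.002,
  chosen so the whole-template matched-filter significance √(support · S/N)
  is below one noise standard deviation: the junk class models objects that
  classification *cannot* recognize, which is the regime the method addresses.
  (At S/N ≈ 0.05 the blobs become detectable and the classifier legitimately
  — and reproducibly — centers them; that is a different, curable-by-selection
  regime.) Default planting: 80 + 80 particles per 1280² px micrograph at
  1.33 Å/px, minimum center separation 56 px so an extraction box contains at
  most one planted object, picker jitter σ = 5 Å, miss rate 2%, false-positive
  rate 5%.

What the rendered path does *not* model: CTF, beam-induced motion, ice
thickness gradients, structured contaminants, particle overlap, rotationally
inconsistent views. Passing tests therefore demonstrate the curation logic
and the reproducibility mechanism, not performance on real micrographs; on
real data the recentering engine is expected to be an external 2D/3D
classification consumed via `--recenterer external`.

## Evaluation conventions

Precision is over *picks* (fraction of kept picks originating from high-S/N
particles; false positives count against it), recall over *particles*
(fraction of high-S/N particles with ≥ 1 kept pick) — a particle has two
picks and either may survive. Provenance from the simulator is used when
present; otherwise picks are attributed to the nearest planted particle
within a radius. Empty kept sets report precision null, recall 0.
`retention_curve` reuses one fixed recentering across the whole D_TH grid, so
the curve is exactly monotone. Reports (JSON/CSV) contain no timestamps and
are byte-reproducible for a given config and seed; timestamps live in the log.

## Numerical and interface choices

* Coordinates: 0-based pixel centers, x = column, y = row, origin top-left;
  pixels in files, Å for all distances (px × pixel size), conversion at the
  I/O boundary only. Pick units in files are pixels; thresholds are Å.
* Pick ids are assigned at read time from (source-path hash, file order) and
  never reused, giving stable identity across rounds.
* STAR subset: one data block, one loop, whitespace-separated fields,
  RELION-compatible tags where they exist; unknown columns round-trip as
  opaque strings. MRC: mode 2, single image or stack, pixel size from the
  cell/grid header fields.
* Matching ties (exact equal distances) resolve deterministically through the
  assignment solver; with continuous coordinates they do not occur.
* The noise-shift "≈ uniform" contract is tested via what the argmax of a
  smooth stationary field provably satisfies — exact quadrant equiprobability
  (isotropy) plus a spread floor — rather than exact uniformity, which does
  not hold on a bounded window (edge cells are favored).
* Problem sizes in the test and acceptance runs (10⁵ particles for the
  retention law, 2 × 10³ per class × 10 seeds for the separation point,
  4 × (60 + 60) planted particles for the rendered end-to-end run) were
  chosen to put Monte-Carlo error well inside the asserted tolerances while
  keeping the default suite fast.

## Known limitations

* Rotation is not searched; the rendered high-S/N templates are either
  rotationally forgiving (ring-like average) or planted aligned. Real 2D
  classification confers rotational alignment that this engine does not.
* The sampled-shift mechanism is a *model* of classifier irreproducibility,
  calibrated by contract (decisive peaks stay put, flat fields scatter), not
  against any specific ML implementation.
* The pooled-cluster mode reports pair distances from an optimal matching
  within kept clusters; tools implementing pooled duplicate removal may
  differ on chain-shaped clusters.
* `--recenterer external` performs a single curation round per invocation;
  iterating requires re-running the external classification between rounds.
* Class-probability semantics beyond "a per-particle score in [0, 1]" are not
  modelled; the 0.3 floor is a convention of the workflow, exposed as
  configuration.
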