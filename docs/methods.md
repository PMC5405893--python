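# Methods

`naplines` re-creates, end to end, a two-line visual-search study of
sensitivity to nonaccidental properties (NAPs): parametric stimulus
triplets, a V1-like GaborJet similarity audit of the stimuli, the
factorial odd-one-out trial design, a synthetic observer that stands in
for human participants, and the reaction-time statistics. This note
documents the model choices, parameters, and limitations.

## Stimulus geometry

Each stimulus is one or two line elements (`Segment`: center,
orientation, chord length, signed sagitta) in degrees of visual angle,
origin at the stimulus center, y up. Curvature is parametrized by the
sagitta rather than 1/radius so that the straight line (sagitta 0) is an
interior point of the parameter space.

Thirteen conditions cover NAP contrasts between two objects (alignment,
collinearity, five junction types), within one object (cotermination,
expansion vs. constant separation, collinearity, curvature of edges and
of the configural axis), and a single-line curvature control. Every
condition is reduced to **one scalar parameter** whose boundary value
(0 by construction) is the nonaccidental configuration. A triplet holds

- base: `boundary + delta`
- nonaccidental (NAP) variant: `boundary`
- metric (MP) variant: `boundary + 2*delta`

so that |param(MP) − param(base)| = |param(NAP) − param(base)| exactly —
the equidistance rule that makes "same change, opposite directions"
precise.

Per-condition default deltas (config values, not measurements): 10° for
angular parameters, 0.35° for positional offsets and slides, 0.3°
sagitta for curvature. `generic_to_X` uses a 0.95° slide because its
generic variants must clear the crossing segment's half-length (0.6°) to
remain contact-free.

Two hard constraints shape every construction:

1. **Center gap.** The distance between the two segment centers of every
   *base* stimulus equals the configured gap (default 1.5°) exactly; one
   closed-form calibration constant per condition (a stem length, arm
   length, or anchor point solved from a circle–line intersection)
   enforces this. Variants deviate slightly because the manipulation
   moves geometry. A replication configuration sets the gap to 2.25°;
   for the crossing junctions (`generic_to_X`, `X_to_T`) the default
   shapes cannot reach that gap inside a 3° box, so the builders fall
   back to adapted stem angles/lengths that preserve the exact gap at
   the cost of a somewhat larger extent (extent validation is therefore
   asserted only for the default configuration).
2. **Extent.** The bounding-box long side of every default-configuration
   stimulus is 3° within a 0.1° tolerance (several conditions hit 3°
   exactly by anchoring one element of that length).

Some constraints interact: two collinear segments whose centers are
1.5° apart and whose union spans 3° necessarily nearly touch end to end;
`collinearity_between` therefore keeps a 0.06° ink margin between the
near endpoints so the two objects never fuse into one stroke. For the
same reason `alignment` uses two *vertical, side-by-side* edges (offset
manipulated vertically), which are disjoint at every parameter value.

**Shared frame.** All three variants of a triplet are positioned
relative to the *base* stimulus's bounding-box center. Recentering each
variant to its own bounding box would inject a translation between
variants that has nothing to do with the manipulated parameter and would
contaminate the translation-sensitive GaborJet audit.

**Exemplars.** Six exemplars per condition are generated from an ordered
list of (pose rotation, mirror) candidates — upright and 90°-rotated
poses crossed with {identity, left–right, up–down} — deduplicated by
canonical triplet geometry; mirror-symmetric combinations are skipped
and replaced by small-rotation (±10°) poses. Only the thin single-line
control ever needs those (a single segment is point-symmetric, so its
left–right and up–down mirrors coincide); ±10° rotations keep a 3°-long
line's bounding extent within tolerance (3cos10° ≈ 2.95°). Several
canonical constructions are deliberately asymmetric (unequal segment
lengths, unequal cotermination arm angles 20°/29°, one tilted and one
horizontal expansion edge, a 0.3° lateral offset between curvature
edges) precisely so that the six mirrored exemplars are geometrically
distinct.

**Jitter.** Display jitter translates a whole stimulus by ±0.25° per
coordinate and rotates it by ±5° about its center, drawn from a seeded
generator; it is applied per placement at layout time, never during
stimulus generation or the audit.

## Rendering

White strokes (level 1.0) on mid-gray (0.5), 32 px/° on a 4° canvas
(128×128), 2 px stroke width, anti-aliased. Strokes are rasterized from
an exact distance field: pixel coverage is a linear ramp of the pixel
center's distance to the stroke outline (butt caps for straight chords,
round caps along dense arc polylines; the polyline chord error is far
below a quarter pixel). Distance-field rendering makes rasterization
commute with geometric mirroring to floating-point precision, a property
the jet-mirror-equivariance test relies on. Without anti-aliasing the
output is exactly two-valued, and a straight stroke's foreground area is
width × length pixels.

## GaborJet model

A jet is the set of complex Gabor filter magnitudes at one image
location; the feature vector concatenates jets on a 12×12 grid with 5
scales × 8 orientations (2,880 magnitudes), ordered row-major over
(grid row, grid column, scale, orientation). Spatial frequencies are
log-spaced from 16 down to 2 cycles/image; the envelope width is
sigma = 2π in carrier units (about one octave). Kernels are quadrature
pairs truncated at 2.5 envelope SDs (capped at the image side — the
2 c/img kernel's nominal support exceeds a 128 px image) and
DC-corrected after truncation so uniform fields elicit exactly zero
response. Phase is discarded. Jets are computed by FFT convolution and
sampled at the grid points; the image mean is subtracted first to
suppress boundary-padding artifacts.

Similarity between feature vectors is the cosine
dot(a,b)/(‖a‖‖b‖) ∈ [0,1] (magnitudes are nonnegative);
dissimilarity is 1 − similarity.

**Matchedness audit.** For each triplet (canonical pose, no jitter) the
audit computes sim(NAP, base) and sim(MP, base). A triplet counts as
*properly matched* when sim_nap ≥ sim_mp − 0.01, i.e. the two variants
are equally similar to the base within tolerance or the NAP variant is
closer. With the default geometry 62/78 triplets (0.795) are matched:
ten conditions are matched on every triplet, while the three curvature
conditions are systematically NAP-mismatched by 0.06–0.08. The
mechanism is diagnosable per scale: at the two finest scales a straight
line concentrates its energy into a single orientation and jet row,
while base and MP arcs both spread it — so the *boundary* stimulus is
genuinely special to fine V1-like channels. This is an honest property
of the audit under this geometry, reported as-is; it parallels the
original study's own caveat that curvature-edge effects might partly
reflect low-level stimulus differences.

## Experiment design

78 triplets × 2 changed variants (MP/NAP) × 2 target roles (the variant
is the odd one out, or the base is, among three variant distractors) ×
4 target quadrants = 1,248 trials, each combination once. Quadrant
centers lie at 5° eccentricity, polar angles 45°/135°/225°/315°.
Interleaved mode shuffles all trials; blocked mode (the replication's
regime) shuffles condition order and trial order within condition. A
session is the full table for one participant, no breaks modeled.

## Synthetic observer

Reaction time for participant p on a trial of condition c:

    RT = shift + exp( N( log(baseline_c − advantage_c·[NAP trial]) + u_p,
                         sigma_trial ) ),   u_p ~ N(0, sigma_participant)

a shifted lognormal with a participant effect on the log scale. Under
this form the population median of (RT|MP) − (RT|NAP) equals the
generating advantage, which is exactly the quantity the median-based
analysis estimates. Defaults: 10 participants, shift 250 ms,
sigma_trial 0.35, sigma_participant 0.1, baselines 600–950 ms per
condition, advantage 60 ms for most conditions, 15 ms for
expansion-vs-constant (the near-null condition), 80 ms for curvature
edges and the single-line control, and 140 ms for curvature of the axis
— so the 2×2 interaction contrasts have a qualitative pattern (edges ≈
control, axis > control) to detect. Accuracy is Bernoulli at 0.90
(metric) / 0.97 (nonaccidental); errors pick a uniformly random wrong
quadrant. Everything is reproducible from one integer seed.

The generator emulates right-skew, participant-level speed differences,
a condition-specific NAP advantage, and near-ceiling accuracy. It does
*not* model sequential effects, learning or fatigue, speed–accuracy
trade-offs, RT–accuracy coupling within trials, eye movements, or any
mechanistic decision process — so passing tests demonstrate that the
analysis pipeline recovers what this generative family encodes, not
that it would be robust to every property of human RT data.

## Statistical analysis

- **Medians:** per participant × condition × changed-variant cell,
  correct trials only by default (a flag includes errors), midpoint
  convention for even counts; empty cells are an error naming the cell.
- **Paired t, one-tailed:** on d_p = median_MP − median_NAP, alternative
  mean(d) > 0, df = n−1. Zero-variance degenerate inputs return the
  limiting p (0/1), all-zero differences return t = 0, p = 0.5.
- **Bonferroni:** strict p < alpha/13; 13 is the number of conditions
  tested, consistent with a p = .005 result failing at alpha = .05.
- **2×2 within-subject interaction:** F(1, n−1) computed as the squared
  paired t of each participant's difference of differences, with a
  two-tailed p; verified against statsmodels' repeated-measures ANOVA.
- **Accuracy:** descriptive proportions with binomial SEs only.
- **Model–behavior correlation:** Pearson r between per-triplet mean
  RT difference (NAP − MP) and GaborJet similarity difference
  (sim_nap − sim_mp) with a two-tailed p at df = 76. The similarity
  sign convention is configurable (`mp_minus_nap` negates x).

**Calibration.** `calibration.calibrate_condition` replicates the
one-condition experiment (96 trials × 10 participants) through the real
simulate→medians→t path. Under the null observer the uncorrected
one-tailed test rejects at 0.0475 over 2,000 replicates (nominal 0.05);
at a 60 ms advantage power is ≈0.93 and the mean recovered advantage
matches the estimator's expectation 60·exp(sigma_participant²/2).

## Problem sizes and numerics

The default test suite audits all 78 triplets once (about half a minute
of FFT convolutions), runs 2,000 null and 500+300 non-null calibration
replicates, and executes the full pipeline twice to check bitwise
determinism. Geometric deduplication of exemplars rounds coordinates to
1e-6 before hashing; segment representations are canonicalized
(orientation in [0, 180), sagitta sign flipped accordingly) so that
equivalent chords compare equal. All randomness flows through
numpy Generators seeded explicitly; nothing reads global RNG state.

## Known limitations

- All parameter magnitudes (deltas, baselines, advantages) are package
  defaults, not measured values; the original study's effect sizes are
  shown only graphically and its stimulus magnitudes only pictorially.
- The GaborJet configuration (grid, scales, frequency span, image
  resolution) is a standard choice, not the original study's unreported
  one, so audit similarities are comparable qualitatively, not
  numerically.
- The replication configuration preserves the 2.25° gap exactly but
  relaxes the 3° extent for the two crossing-junction conditions.
- Display timing, fixation, key capture, and photometric calibration are
  out of scope; rendering exists only to feed the model audit.
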