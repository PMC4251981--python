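# Methods

## Motion measurement

Each recording is an ordered grayscale frame sequence (nominally 15 Hz, ~30 s,
one embryo per frame).  Shi-Tomasi corners are detected with a relative
quality threshold (default 0.01 of the strongest response), a minimum
separation of 5 px, and a cap of 400 features.  No segmentation is attempted:
chorion and debris features are tracked alongside the embryo, because the
measurement is deliberately integrative.

Features are followed between consecutive frames by pyramidal Lucas-Kanade
tracking (default 15-px window, 3 pyramid levels, up to 30 iterations,
convergence at 0.01 px).  The gradient structure tensor comes from the
earlier frame; a track is discarded when the tensor is near-singular
(minimum eigenvalue below 1e-5 per window pixel on intensities in [0, 1]),
the point leaves the frame, or the final mean window residual exceeds 0.08.
Corners are re-detected whenever surviving tracks drop below half of the last
detection count.

Each frame pair reduces to four measures.  With C_old, C_new the centroids of
the matched positions and φᵢ the wrapped (−π, π] change of each feature's
angle about the centroid:

- pos = Σ max(φᵢ, 0), neg = Σ max(−φᵢ, 0) — summed clockwise / anticlockwise
  rotation.  "Clockwise" is a positive wrapped angle in image coordinates
  (x right, y down), i.e. the on-screen sense.  Sums, not means: a
  large-bodied movement recruiting many features should produce a larger
  peak.
- rho = ‖C_new − C_old‖, theta = direction of that displacement (defined as 0
  when rho < 1e-9 px, where the polar angle is meaningless).

Unreliable displacements are removed before the reduction: pairs whose
displacement magnitude exceeds max(median + 5·MAD, 12 px) are dropped.  The
absolute floor matters: during a tail flick the displacement distribution is
bimodal (static body: median and MAD near zero; tail features: several px),
and a purely relative cut would discard exactly the motion being measured.
12 px per frame ≈ 180 px/s at 15 Hz, faster than any plausible embryo feature
at this magnification, so only tracking failures lie above it.  Fewer than 3
surviving pairs yields an all-zero "gap" frame, logged but kept in place so
the series stays aligned with the video.

## Spectral fingerprint

The canonical series length is 448 frame pairs (449 frames): its DFT has
exactly 224 non-DC bins and bin k has period 448/(15k) s, which reproduces
every printed edge of the 18 analysed period bands after 2-decimal rounding
(band 1 starts at 29.87 s with k = 1; the Nyquist bin gives 0.13 s).  Longer
records are truncated to their first 448 samples; shorter ones are an error.

A bin joins the band whose printed [lower, upper] range contains its rounded
period; bins matching two bands (shared printed edges at 0.27, 0.21 and
0.19 s) go to the lower-index band, and bins falling in the printed gaps
(e.g. 0.51–0.45 s) stay unassigned rather than being interpolated into a
neighbour.  Band values are sums (not means) of bin magnitudes, preserving
additivity of spectral mass across bands of unequal width.  The 4 measures ×
18 bands give 72 features, transformed as ln(x + 1).  The log base is
immaterial downstream: Bray-Curtis is invariant under uniform positive
rescaling (tested explicitly).  Series are not detrended; excluding the DC
bin already removes the mean, and linear trends over 30 s are negligible for
these measures.

## Multivariate comparison

Bray-Curtis dissimilarity (Σ|aᵢ−bᵢ|/Σ(aᵢ+bᵢ)) is computed between
log-fingerprints; two all-zero vectors get dissimilarity 0 with a warning.
ANOSIM ranks all n(n−1)/2 dissimilarities with mid-ranks for ties and
computes R = (r̄_between − r̄_within)/(n(n−1)/4), in [−1, 1].  Working with
dissimilarities rather than percent similarities only reverses the rank
order consistently, which leaves R and the nMDS configuration unchanged.
The permutation p-value is (#{R_perm ≥ R_obs} + 1)/(n_perm + 1) over random
label permutations from a seeded generator (default 9999, bit-reproducible);
an exact mode enumerates every distinct label arrangement for small samples.
Pairwise period tests are reported unadjusted, mirroring the usual pairwise
ANOSIM presentation; a Bonferroni factor can be applied by the caller.

Non-metric MDS of the five period-mean fingerprints minimises Kruskal
stress-1 via SMACOF with isotonic regression (scikit-learn), best of 20
random restarts, up to 300 iterations, convergence tolerance 1e-12 (tight
enough that exactly embeddable configurations reach stress below 1e-6).
Degenerate all-equal dissimilarities produce an arbitrary configuration with
a warning.

## Tail-flick counting and the count route

The activity trace a_t = pos_t + neg_t (option: max of the two) is scanned
for local maxima whose robust z-score (a − median)/(1.4826·MAD) reaches 4,
accepted greedily in descending height with a 0.5-s refractory separation;
with MAD = 0 (flat baseline) any positive maximum counts.  The robust score
makes counts invariant to uniform rescaling of the trace.  z = 4 is a
conservative default for "large peaks"; overlays of detected events on the
activity trace allow manual recalibration.

Counts are averaged over the four cycles of each period to one value per
embryo × period, then tested with a one-way within-subject ANOVA
(F = MS_period / MS_period×subject) and paired t contrasts with a Bonferroni
factor equal to the number of pairs (10).  Counts are analysed untransformed.
The concordance report categorises each period pair (***, **, *, ns) for the
spectral and count routes and counts pairs agreeing on significance at 0.05.

## The synthetic experiment

The generator produces the study conditions at two levels.  Parametric
records skip the vision stack: pos/neg are half-normal baseline jitter
(sd 0.01 rad) plus a raised-cosine heart-beat component (2.3 Hz, amplitude
0.05 rad — non-negative by construction) plus half-sine flick bursts (0.3 s,
typical peak 1 rad); rho gets a correlated 2-px burst and jitter; theta is
random where the centroid moves.  Rendered sequences draw a speckle-textured
ellipse inside a chorion ring (256² px by default), a tapered textured tail
that sweeps 30° out-and-back over each flick, a pulsing heart spot, and
additive pixel noise of 0.005 (≈1 grey level at 8 bit, typical camera read
noise; larger values seed spurious corners in the dark background).

Flick onsets follow a renewal process: gaps are a 2×duration refractory dead
time plus an exponential, with the exponential mean chosen so the long-run
onset rate equals the nominal per-30-s rate, and an equilibrium start so the
expected count is unbiased.  (A Poisson process thinned by the refractory
period would undershoot the nominal rate by ~15% at the highest rate used.)

A full experiment is 15 embryos × 20 cycles over five periods with default
rates (2.68, 3.5, 8.25, 3.87, 0.97) flicks per 30 s — a pulse-and-recovery
time course with a gradual onset, so the first exposure half sits near
baseline, and a late-recovery undershoot.  Three layers of heterogeneity
emulate real between-animal variability: a per-embryo lognormal rate
multiplier (σ = 0.5, set so the spread of per-embryo means matches standard
errors of about 18–25% of the mean over 15 embryos), a per-embryo lognormal
flick-vigor multiplier (σ = 0.5; animals differ in movement magnitude, not
just rate), per-event amplitude jitter (σ = 0.4), and a ×1.5 vigor factor at
the exposure peak.  Without vigor heterogeneity the fingerprints are
unrealistically clean and rank-based tests on 60-vs-60 recordings resolve
even ~1.3× rate shifts that the count route (and real data of this kind)
cannot.

What the generator does **not** emulate: within-embryo temporal
autocorrelation across cycles (cycles are independent given the embryo),
response-latency differences, developmental drift over the 2.5-h experiment,
optical artefacts (focus drift, illumination flicker), and embryo rotation
inside the chorion.  Passing tests therefore demonstrate correctness of the
measurement and inference machinery under known signal structure, not
performance on any particular real dataset.

## Problem sizes and numerical choices

The test suite runs the full five-period experiment at 15 embryos × 20
cycles with 9999 ANOSIM permutations over 20 seeds for the qualitative
pattern check, and 60 seeds at 299 permutations for the null calibration;
rendered-video checks use 150-frame sequences at 256² px — sizes chosen to
exercise every code path at full statistical fidelity while keeping a laptop
run in minutes.  Angle wrapping maps to (−π, π] with the boundary assigned
to +π.  Ties in dissimilarities take mid-ranks.  The permutation p includes
the observed labelling in numerator and denominator.  All randomness flows
from explicit integer seeds through numpy Generators; spawned seed sequences
keep per-recording streams independent and reproducible.

## Known limitations

- The four measures weight every tracked feature equally; a feature-dense
  chorion can dilute embryo signal in rho/theta.
- Band gaps mean some spectral mass (notably periods 0.51–0.45 s) never
  reaches the fingerprint; this is intentional fidelity to the fixed band
  list, not an optimised design.
- The RM-ANOVA assumes sphericity and is applied to raw counts; with very
  low rates (recovery undershoot) counts are skewed and a GLMM would be more
  efficient — out of scope here.
- ANOSIM treats recordings as exchangeable under permutation although
  repeated measures of the same embryos are correlated; this matches the
  classic workflow the package reproduces, and the synthetic null
  calibration shows the realised size of the test is controlled under a
  fully exchangeable configuration.
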