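# Methods

This note documents the models and procedures `chronospread` implements,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical choices made where the design was
genuinely open. Every empirical claim here is one the test suite or
`scripts/acceptance.py` computes.

## Time grid, binning and local time

The day is partitioned into 96 half-open 15-minute intervals
`[t, t + 1/4)` with circular adjacency (bin 95 precedes bin 0).
Timestamps must be timezone-aware and are converted to local civil time
— by default `Europe/Rome` (CET with daylight-saving transitions), the
convention of the Italian data stream this design mirrors — before the
bin index `⌊4·h⌋` is taken. Each post lands in exactly one bin, so
binning is a partition; naive timestamps are rejected rather than
guessed.

## Activity curves and circular smoothing

A user's activity curve is the share of their posts per bin; it is
undefined for users without posts (they are excluded upstream rather
than contributing zeros). Cluster curves are unweighted means of member
curves, so every user carries the same weight regardless of volume.

Smoothing is a circular Gaussian rolling average. The nominal window is
90 minutes (6 bins) with σ = 3 bins; because an even tap count cannot
be centred on a bin, the kernel uses symmetric offsets −3…+3 (seven
taps spanning ±45 min) with normalised weights. The kernel is linear,
mass-preserving, and has constants as fixed points. The
disinformative-activity variant defaults to σ = 6 bins, the printed
value for that signal; whether that σ is a typo for 3 is unknowable
from the source, so both are plain arguments.

## Archetype clustering

Users below the infrequent threshold (default 240 posts, strict `<`)
are set aside as the *infrequent* archetype. Remaining users'
Gaussian-smoothed 96-bin curves are clustered with k-means (Euclidean
metric, k-means++ initialisation, 10 restarts, seeded; k = 3 in the
reference configuration). Validity indices per candidate k:
Calinski–Harabasz, Davies–Bouldin, Silhouette (scikit-learn),
generalized Dunn (single-linkage separation over maximal diameter) and
COP (mean intra-centroid distance over a max-min outside separation,
size-weighted); orientation flags mark the lower-is-better indices, and
degenerate cases (singleton clusters) yield flagged NaNs.

Clusters are named from the clock time of their activity peak: before
12:00 → *morning*, after 20:00 → *evening*, otherwise *intermediate*.
These thresholds are heuristics and configurable. In small samples an
intermediate cluster peaking just before noon can collide with the
morning cluster under the fixed thresholds; the pipeline then falls
back to rank-based naming (clusters ordered by peak time on the circle
cut at 4:00, the activity minimum: earliest = morning, latest =
evening). Naming and waking-window inference read the Gaussian-smoothed
cluster means rather than the harmonic truncation, because a one- or
two-harmonic reconstruction of a bimodal curve can displace its peak
across a naming border.

## Harmonic truncation and the choice of m

Cluster curves are transformed with the real DFT; harmonic `n` has
amplitude `2|X_n|/96` (DC and Nyquist: `|X_n|/96`) and the DC term's
sign is carried by its phase. The reconstruction keeps the DC level
plus the `m` non-DC harmonics of largest amplitude; amplitude ties are
broken toward the lower frequency (the smoother curve). `m` may range
up to 48: the 96-point real DFT carries 48 non-DC components including
the Nyquist term, and the full set reproduces the input to machine
precision (verified to < 1e-9 in acceptance).

`m ∈ [1, 4]` is selected per curve by an elbow rule voted over seven
curve-distance metrics: for each metric the improvement
`Δ(m) = D(m−1) − D(m)` is computed and the metric votes for the
smallest in-range `m` whose following improvement is smaller, falling
back to the range maximum; the final `m` is the smallest member of the
modal vote set. Because harmonics are kept in descending amplitude
order, MSE improvements are non-increasing by construction, so MSE (and
usually MAE) vote `m = 1`; on synthetic curves the rule therefore
selects small `m` (1–2). The raw vote table is always available for
audit (`select_m(..., return_votes=True)`).

Curve-distance conventions (curves as planar polylines over hours):
discrete Fréchet and DTW are the standard dynamic programmes, verified
against exhaustive coupling enumeration for short curves; *area*
integrates `|y_a − y_b|` over the shared abscissa; *curve length* is
the absolute arc-length difference; *PCM* compares curves after
translating to the origin and normalising each to unit arc length —
a deliberately simple stand-in for partial curve mapping that keeps its
offset insensitivity, adequate here because compared curves always
share their domain.

## Waking windows

The heightened-activity onset maximises the circular sum of the
smoothed curve over `[onset, onset + n)` with `n = 16 h` (64 bins);
ties break to the earliest onset after midnight, and a direct per-onset
summation avoids the floating-point cancellation that a running
difference would introduce into exact ties. The complement is
*prolonged wakefulness*. The printed case-split for "within n hours
past t" is strict at both ends; applied literally to the window sum it
would exclude the onset bin itself and make a 16-hour block ambiguous
by one bin, so the window op includes its start bin (covering exactly
4n bins) while the standalone predicate keeps the strict semantics.
The fast implementation is property-tested against a 96-candidate
exhaustive scan.

## Content ratios

The nine source categories carry ordinal Harm Scores 1–9; *Shadow*
(score 6) merges into *Other* for analysis, both excluded from the
classified set. Scores ≥ 7 define the potentially disinformative set.
Per-user per-bin ratios divide disinformative posts by classified
posts; empty-denominator bins are NaN, and cluster means mask NaNs
rather than zero-filling (zero-filling would bias the mean toward 0).
Before harmonic truncation, per-user curves receive one Gaussian pass
(window 6, σ 3) and residual undefined cluster bins are filled by
circular linear interpolation, with the interpolated-bin count
reported. Susceptibility times are bins strictly above the third
quartile (linear-interpolation quantile) of the 96 smoothed values,
computed per cluster.

## Day/night definitions and statistics

Geometric sunrise/sunset uses the NOAA solar-position equations at
solar altitude −0.833° (refraction plus solar disc), validated against
an independent almanac-algorithm implementation to within 2 minutes.
The fixed clock borders take the monthly first-day sun times over a
year at the Italian centroid (42.5° N, 12.5° E) and summarise each by
the midpoint of its annual extremes, rounded to the nearest quarter
hour — yielding 6:30 and 18:45; the arithmetic-mean convention (6:45
for sunrise) is available via `method="mean"`. With margin `s` (default
1 h), day is `[start+s, end−s)` and night `[end+s, start−s)` on the
circular grid; the daylight definition repeats this per month, the
waking definition uses the inferred window.

The Mann–Whitney U statistic counts pairs with `x > y` plus half-ties
(the convention consistent with its small-sample examples). For pooled
sizes ≤ 12 the p-value is exact by enumerating all group assignments
(valid under ties); above that, a normal approximation with tie and
continuity corrections, which agrees with the exact path to < 0.01 in
p at the boundary. Spearman, χ² (Pearson, no continuity correction)
and Shapiro–Wilk are delegated to scipy.

### The dip test

Hartigan's dip — the sup-distance from the empirical cdf to the nearest
unimodal cdf (convex then concave, a jump permitted at the mode) — is
computed exactly by a junction decomposition: for each candidate mode
knot, band feasibility splits into a greatest-convex-minorant check on
the left, a least-concave-majorant check on the right, and a coupling
threshold from linear certificate lines; the dip is the minimum over
junctions of the largest of the three, found with an early-exit scan
ordered by the cheap hull bounds. The construction is verified exactly
(≤ 1e-9) against an independent linear-programming envelope oracle.
Cost grows roughly quadratically in the number of distinct values, so
binned curves (≤ 96 knots) are fast while large continuous samples are
slower; `dip_test_curve` therefore expands a curve into a pseudo-sample
of bin values weighted by mass (default 10,000 draws, seeded) and
calibrates against uniform draws snapped to the same grid, keeping
observed and null dips on a common discrete support. The statistic is
location-scale invariant (property-tested); it is not invariant under
general non-affine monotone maps, which change the spacings the hulls
see.

## The synthetic generator

The generator emulates the statistical shape of the restricted data
stream: four archetypes in configurable proportions (defaults 0.18 /
0.22 / 0.15 / 0.45 with infrequent posters the largest group); per-user
time-of-day from a mixture of one or two wrapped-normal components
(sampled as `N(μ, σ) mod 24`) with bimodal defaults — morning peaking
9:30 with an evening echo, intermediate near noon and 21:00, evening
at 23:15, infrequent nearly flat; truncated-lognormal post counts with
the infrequent archetype capped at 239 and the others floored at 240;
an 8-category simplex per archetype in which mainstream media dominate,
evening types carry the largest and infrequent posters the smallest
disinformative share (implied overall ratios roughly 0.16–0.31);
calendar days uniform over the span (default the 2020-01-22 to
2022-08-01 study window) with lockdown days (2020-03-09 to 2020-05-18)
upweighted ×1.8; and a ×1.5 multiplicative night elevation
(22:30–06:30) of the disinformative categories, renormalised. Output
timestamps are localised to CET/CEST with nonexistent times shifted
forward across the spring transition.

What it deliberately does not emulate: retweet cascades and network
structure, text content, per-post geography beyond optional
coordinates, weekday/weekend structure, bot-like duplication, or
nonstationary archetype membership. Passing tests therefore demonstrate
that the pipeline recovers the planted diurnal and content structure
under clean sampling assumptions — not that real streams satisfy those
assumptions.

## Acceptance experiment design and problem sizes

The recovery experiments fix their conditions in code: archetype
recovery plants three single-peak archetypes ≥ 6 h apart (σ = 1.5 h,
300 users, ≈ 550 posts each); waking-onset recovery plants a bimodal
intensity concentrated in a 16-hour block (peaks 10:30/18:30,
σ = 2.4 h, 20 users × 100 runs) and compares the inferred onset with
the theoretical onset of the planted intensity; night-elevation power
and null calibration use a flat-activity archetype (wrapped-normal
σ = 50 h ≈ uniform) so the day/night comparison isolates the category
mechanism from activity gradients — with the generator's default ×1.5
boost for power (40 users × 100 runs) and boost 1.0 for the null
(20 users × 200 runs, Kolmogorov–Smirnov uniformity of one-tailed
p-values). Determinism re-runs a 40-user pipeline twice and compares
artifacts byte-for-byte. These sizes keep the whole acceptance run
under a minute on one CPU while leaving the tested effects far from
threshold.

## Known limitations

* The elbow rule's literal reading biases `m` small; the reference
  analysis reported `m = 3–4`, but that value is data-dependent and not
  reproducible without the restricted stream.
* Table-level U statistics depend on the unit of observation (per-bin
  values here); per-bin-per-date and per-user units would give larger
  samples and different magnitudes.
* The dip implementation's exactness is proven against the LP oracle
  only on sampled cases; its worst-case cost on large continuous
  samples (thousands of distinct values) is quadratic-to-cubic and it
  is not intended for them.
* PCM and curve-length follow simplified conventions documented above,
  not the original reference implementations.
* Solar times are geometric; atmospheric variation (±1–2 min) is
  ignored, which the quarter-hour rounding absorbs.
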