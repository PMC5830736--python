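# Methods

This note records the models implemented in `songdyad`, the parameter
choices that matter, and what the synthetic-data generators do and do not
emulate.

## Study geometry

All analyses are organised around a *dyad scenario*: a focal singer who has
been singing alone, and a second singer whose song onset at `onset_s` splits
the timeline into a BEFORE period (focal alone, up to 45 min) and a DURING
period (both singing, up to 45 min). Each period is tiled into 15-min
windows (`window_len_s = 900`). DURING windows tile forward from the onset;
BEFORE windows tile backward from it, clipped to the actual start of the
solo recording. A leading partial BEFORE window is kept only if it spans at
least 2/3 of a full window (600 s): solo spans shorter than the nominal
45 min are common, and shorter fragments would make per-window metrics
incomparable. Phrases are assigned to windows by their midpoints, which is
unambiguous and symmetric at boundaries; transitions are counted within
windows only, never across a window boundary, so per-window switching rates
are self-contained before averaging.

## Song-pattern metrics

**Switching rate.** `SR = Tn / (Pn − 1)` with `Tn` the number of adjacent
phrase pairs with different types and `Pn` the phrase count in the window.
Undefined for fewer than two phrases; undefined windows are recorded but
excluded from period means.

**Relative song evenness.** `J′ = −Σ pᵢ log pᵢ / log k` over the `k` phrase
types in the singer's repertoire, with `0·log 0 := 0`, so repertoire types
that go unsung in a window still enlarge `k` but contribute no entropy.
Natural logs are used internally; the base cancels. The repertoire is the
union of types the singer used across his analysed span (BEFORE + DURING for
the focal singer, DURING for the second): population song changes across
seasons, so only types demonstrably present at the time of recording count,
and the per-singer union is the closest observable to that. Fixing `k` per
singer rather than per window keeps `J′` comparable across windows.

## Phrase-type overlap and its time-shift null

Because song is continuous, cyclical, and drawn from a shared repertoire,
two simultaneous singers will overlap in phrase type by chance; the question
is whether they overlap *more* (matching) or *less* (avoidance) than chance.
Both singers' phrase types are sampled every 8 s (`grid_interval_s`) across
the DURING period, anchored at the onset. Grid points covered by no phrase
(surfacing, or the sequence not reaching there) are gaps. The statistic is
the proportion of co-sampled points (both non-gap) with equal labels — a
proportion rather than a raw count because time-shifted sequences cover the
grid unevenly, which would confound a count with coverage.

The null translates the second singer's entire sequence (phrase order,
durations, and internal gaps preserved exactly) to a start time drawn
uniformly in the BEFORE period, with no wrap-around, and recomputes the
proportion on the same grid; 1000 replicates per dyad by default. A
replicate whose shifted sequence co-covers less than 25% of the grid is
redrawn (up to 10 times, then recorded as missing and reported): a statistic
computed on a sliver of shared coverage is numerically unstable. Tail
p-values use the add-one correction `p = (1 + #{null ≥ obs}) / (1 + reps)`
with ties counted, so p is never exactly 0 at finite replicates; both tails
are always reported because avoidance is as interpretable as matching.
Results are bit-reproducible for a fixed scenario seed.

## Movement metrics

Tracks are planar (meters, local projection). Linear interpolation onto a
regular grid within the observed span substitutes for the field
localization toolchain's interpolation, which is out of scope here; no
extrapolation is ever performed. Separations are Euclidean distances between
interpolated positions; the dyad statistic is (start separation, end
separation, change = end − start) over the DURING window. If a track does
not quite cover a window endpoint, the nearest covered time within 300 s is
used — surfacing gaps near window edges are routine — and larger gaps are
errors, never silently patched.

The meander ratio accumulates path length over positions at 5-min bin
boundaries (oversampling noisy localizations inflates path length) and
divides by the chord between the first and last boundary positions. It is
reported as undefined when the chord is under 1 m: with localization errors
of tens of meters, a near-zero chord makes the ratio meaningless.

The spatial null superimposes solo singers — males recorded singing alone at
non-overlapping times, who therefore cannot have been interacting — pairwise
as if simultaneous: `n` singers give `C(n, 2)` pairs (18 → 153), each
contributing start/end separations and a delta computed from endpoint
positions only, matching the shape of deposited start/end position tables.

## Statistical tests

Thin wrappers over `scipy.stats` with explicit contracts. Proportions are
arcsine-square-root transformed (`arcsin √p`, the standard variance
stabiliser; the transform's square root is a deliberate reading of
"arcsine transformed") before paired t-tests of focal BEFORE vs DURING and
focal vs second. Movement comparisons are non-parametric: two-sample K-S
(asymptotic p) for observed-vs-null distributions, Mann-Whitney U (exact
when the combined tie-free sample is ≤ 20, else normal approximation with
tie and continuity corrections) for change-in-distance by outcome and for
focal-vs-second meander, and the Wilcoxon signed-rank test (exact up to 25
tie-free nonzero differences) for paired meander ratios. Exact small-sample
distributions matter because realistic study sizes are 9–11 dyads.
Degenerate inputs (zero-variance differences, all values tied) raise a
distinct signal rather than returning a fabricated p. No multiple-testing
correction is applied, matching the analysis design this package
implements.

## Synthetic-data generators

The generators exist so that every stage has an input with known structure.

**Song.** The repertoire defaults to 10 shared types. At each phrase start
the singer switches to the next theme in cyclic repertoire order with
probability `switch_prob`; repetition counts are therefore geometric, and
the expected switching rate equals `switch_prob` exactly, giving a clean
parameter-recovery target. The default `switch_prob = 0.12` sits in the
range typical of solo singers. Phrase durations are truncated normal
(mean 15 s, s.d. 4 s, floor 3 s, truncation by resampling) so sequences stay
continuous; surfacing gaps occur after a phrase with probability 0.05
(≈ every 5 min at the default phrase scale) and last 45 s.

**Dyad.** The second singer runs his own song process but, at each of his
phrase starts, adopts the focal's concurrent phrase type with probability
`coupling_m` (he finishes his current phrase first, respecting eventual
variety). `coupling_m = 0` gives independent songs — the calibration case in
which the overlap test's right-tail p should be uniform — and `coupling_m`
near 1 gives strong matching, the power case. An optional quit rule
truncates one singer's annotations at the first sampled instant the pair
closes within a threshold, emulating song cessation on close approach.

**Tracks.** A correlated random walk: constant speed (default 1 m/s),
heading perturbed each 60-s step by Gaussian noise of s.d. `turn_sd_rad`,
optionally steered toward an attraction point by correcting 0.3 of the
bearing error per step. `turn_sd_rad = 0` without a target yields exactly
straight travel. Solo populations scatter start positions uniformly over a
6 km × 3 km footprint, the scale of a coastal recording array.

What the generators do **not** emulate: localization error and its spatial
anisotropy (tracks are noise-free), singer arrival/departure from the array,
within-song phrase-duration autocorrelation, repertoire differences between
individuals, and any dependence of movement on song content. Tests passing
on synthetic data therefore certify the *computations* — metric
definitions, null construction, calibration of the resampling test — not
robustness to field measurement error.

## Numerical and design choices

- Undefined metrics (one-phrase windows, zero co-coverage, sub-ε chords,
  degenerate tests) are explicit signals, reported and excluded, never
  silently coerced to 0 or NaN arithmetic.
- The overlap grid is anchored at the onset, making observed and null
  statistics deterministic functions of inputs and seed; the Monte Carlo
  loop runs on integer-coded interval arrays and is pinned to the public
  per-sample path by a consistency test.
- Tie handling in the Monte Carlo tails counts `null == observed` in both
  tails (conservative in each direction), with a 1e-12 guard for float
  proportions.
- Outcome classification calls a singer quit if his last phrase ends more
  than 120 s before the DURING end — long enough to span surfacing gaps,
  short against the 45-min period. A singer who quit before half of DURING
  is excluded from the song-pattern and matching tables (his windowed
  metrics would mix singing with silence) but retained in the spatial
  tables, where cessation is itself the outcome of interest.
- Report problem sizes used by the test suite: dyads of ~90 min with
  ~350 phrases per singer, 200-replicate Monte Carlo nulls over 20-scenario
  calibration sweeps, and 50-seed parameter-recovery runs; the CLI and
  acceptance script default to the full 1000-replicate design.

## Known limitations

- Movement analyses take tracks as inputs; acoustic localization and its
  uncertainty are out of scope.
- The meander path uses 5-min bin-boundary positions; using every 2.5-min
  localization would increase path estimates on noisy tracks.
- The endpoint-snap tolerance (300 s) and the partial-window threshold
  (2/3) are pragmatic defaults where field practice is not standardised;
  both are explicit parameters.
- The Mann-Whitney exact path declines ties; tied data fall back to the
  corrected normal approximation even in small samples.
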