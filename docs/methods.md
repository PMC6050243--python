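# Methods

This note documents the models and procedures behind `spitrain`, the
parameter choices that matter, and what the synthetic generators do and do
not emulate.

## Pulse trains and intervals

A pulse train is a strictly increasing sequence of event times in seconds.
Validation treats events closer than 10 µs as duplicates, matching the
resolution of 100-kHz acquisition systems. Analyses operate on declared
windows — by default the first 120 s of a recording, with the window start
exposed as a parameter because there is no canonical choice of excerpt
within a longer recording. Windows are half-open, `[start, start+length)`,
so adjacent windows partition the events without double counting.

Intervals are `IPI_i = (t_i − t_{i−1}) × 1000` ms. Histograms use uniform
left-closed bins anchored at 0 ms, default width 2 ms, extended one bin
past the largest interval so a value on a bin edge always falls in the bin
to its right. Population averages over individuals are arithmetic per-bin
means with SD (ddof = 1) and SEM = SD/√n, zero-padding shorter histograms.

## SPI features

Each window is summarized by five variables: total EOD count, run count,
mode IPI, and the longest/shortest interval.

*Runs.* Adjacent interval pairs are classed positive / negative / equal; a
run is a maximal streak of one class. "Equal" means a difference of
magnitude ≤ `tie_tol_ms`, default 0: with continuous-valued synthetic
intervals exact ties never occur, while digitized recordings produce exact
ties at the acquisition resolution. The tolerance is exposed because
float-grid data (e.g. a metronomic train built from a rounded time grid)
otherwise fragments one constant run into many. For n iid continuous
intervals the expected run count is `(2(n−1) − 1)/3`; positively
correlated (sticky) processes produce fewer, longer runs. Both properties
are verified by simulation.

*Mode IPI.* Continuous intervals have no meaningful raw multiset mode, so
the mode is the center of the tallest histogram bin (lowest bin wins
ties). Consequence: a constant 50-ms train reports mode 51 ms (center of
bin [50, 52)), which can exceed the largest observed interval by up to half
a bin. This is accepted as the price of a well-defined estimator.

## Serial correlation

For lags `i = 0..max_lag`,

    SC_i = ( mean_{k=1..N−i}(IPI_k · IPI_{k+i}) − mean(IPI)² ) / VAR(IPI),

where the product mean is truncated to the pairs available at that lag
while the mean and *population* variance use the full sequence. Both
denominator moments are computed from the same raw-moment expression
(`⟨x²⟩ − ⟨x⟩²`), so `SC_0 = 1` holds exactly in floating point. Lagged
product sums use direct dot products up to N = 2048 and an FFT
autocorrelation above (the two paths agree to ~1e-12; the FFT makes the
250-permutation band on N = 3000 sequences cheap). A constant sequence has
zero variance and is rejected as degenerate; `max_lag` must leave at least
two pairs. The default `max_lag` is 150, capped at N/4.

*Chance level.* The sequence is permuted `n_permutations = 250` times and
SC recomputed at lags 1..max_lag. Per lag, a one-sided normal-theory bound
`mean ± z_{1−α}·SD` (α = 0.01) is formed, and the per-lag bounds are
averaged over all lags into a single scalar threshold on each side — one
horizontal line, which is how a chance level is usually drawn against a
correlogram. Because "a 99% confidence interval above the mean, averaged
over all intervals" admits other readings, an empirical-percentile bound
(`method="percentile"`) and a pool-lags-first construction
(`pooling="pooled"`) are available; on renewal data all three agree within
a few tens of percent and the normal/per-lag default is used throughout.
At the degenerate limit α = 0.5 the two bounds coincide at the permutation
mean. For iid data the upper bound approaches `z_{0.99}/√N`, and the
fraction of lags exceeding it stays at the nominal 1% rate — verified on
both iid-generated and scrambled sequences (measured ≈ 0.01–0.012,
asserted ≤ 0.03 over 100 sequences of N = 3000).

*SC duration.* The first lag `i ≥ 1` with `SC_i` below the *upper* bound,
multiplied by the recording's median IPI. Comparing against the upper
bound only follows the reading that memory is indicated by positive excess
correlation; a sequence that never drops below the bound within `max_lag`
is censored at `max_lag × median` and flagged rather than left undefined.
Scrambled surrogates decorrelate at lag 1 with probability ≈ 1 − α, so
their duration is essentially the median IPI.

*Scrambling.* A seeded uniformly random permutation of the interval
multiset: it preserves every order-free statistic (sum, extrema,
histogram, median, and four of the five SPI features) and destroys exactly
the temporal order, making it the renewal surrogate of choice.

Group comparisons of SC durations use the Kruskal–Wallis test; durations
are right-skewed and possibly censored, so a rank test is appropriate.

## PCA and group tests

The five features are log10-transformed (any base is equivalent after
standardization; base 10 is fixed for reproducibility), centered, scaled
to unit variance (ddof = 1), and decomposed by SVD. Loadings are unit-norm
per component, the component sign is fixed by making the largest-magnitude
loading positive, and explained fractions over all retained components sum
to 1. Constant columns after the log transform are rejected by name.

A note on attainable explained variance: after standardization each
feature contributes exactly one unit of variance, so if only two of five
features discriminate two clusters, PC1 cannot explain more than about
2/5 of the variance no matter how well separated the clusters are. On
feature tables from the two species presets all five features co-vary with
the species contrast and PC1 in practice explains > 95%.

Pairwise feature association uses the Pearson coefficient with its exact
p-value; the two-sample location test is Welch's t (the default of the
usual statistical toolchains); multi-group comparisons use Kruskal–Wallis.
The 68% normal-contour ellipses often drawn around groups in PCA score
plots are provided as a data annotation (center, semi-axes, angle), not as
rendered figures.

## Playback preference

Sessions consist of (by default) 8 playback intervals of 120 s. Zone times
are logged in the physical tank frame (B near end A, D near end E, C
neutral); because the side carrying each stimulus is interchanged between
intervals, times are mapped onto stimulus identity per interval before
summation. `SOP = (t_B − t_D)/(t_B + t_D)` over the summed, unswapped
times; undefined (both totals zero) sessions are flagged and excluded from
tests. Antisymmetry under stimulus swap and invariance under uniform time
rescaling are exact and property-tested.

The one-sample preference test is a t-test against SOP = 0, with an
explicit degenerate flag when all values coincide. The across-condition
comparison arcsine-transforms SOP — `arcsin(SOP)` on [−1, 1] by default,
with `arcsin √((SOP+1)/2)` as an alternative, since the conventional
arcsine-square-root transform is only defined for proportions — and runs a
repeated-measures ANOVA with fish as the repeated factor when the design
is complete, falling back to a mixed model (random fish intercept, Wald
test on condition terms) with a warning when cells are missing. Pairwise
differences use Tukey's HSD on the transformed values. Responsiveness
(total time outside the neutral zone) is compared the same way after a
square-root transform (a literal square is available as a config switch;
root is the conventional variance stabilizer for durations).

## Synthetic generators

The generators exist so that every analysis stage has inputs with known
ground truth.

*Processes.* `renewal` draws iid intervals from a gamma/lognormal mixture.
`sticky_state` is a semi-Markov chain: each state has an interval
distribution and a dwell parameter d; the chain stays for a
Geometric(1/d)-distributed number of intervals (mean d) and then jumps
uniformly to another state, so stationary occupancy is proportional to
dwell. State autocorrelation decays roughly like (1 − 2/d)^lag for two
states, making SC extent monotone in d — the basis of the
parameter-recovery checks (Spearman ρ = 1 across dwells 20/50/100 and
AR(1) φ = 0.5/0.8/0.95, 50 seeds per level, N = 3000, max_lag 300; the
larger lag range avoids censoring at dwell 100, where the mean first
sub-chance lag is near 150). `ar1_log` is a Gaussian AR(1) on log-interval
with stationary mean/SD fixed, giving smooth geometric decay.

*Species presets.* `bimodal_burster` is a three-state sticky chain: two
tight burst states whose gamma densities peak at 14 and 23 ms (dwells 9
and 7 intervals) plus a broad lognormal pause state (mean 120 ms, SD 80
ms, dwell 4). The pause state is what reconciles the two calibration
anchors — histogram peaks at 14/23 ms *and* a mean rate near 3157 pulses
per 120 s (mean IPI ≈ 38 ms): two narrow components alone would imply a
mean IPI near 18 ms. It also produces the long maximum intervals
(hundreds of ms) characteristic of bursty discharge. `broadband_slow` is
a two-state chain of broad gamma distributions (mean 55 SD 15; mean 125 SD
25; dwells 40/40) with ≥ 80% of interval mass in 25–150 ms, ≈ 1300 pulses
per 120 s, and long timing memory. Calibration tolerances (peaks within
one 2-ms bin, counts within 15%) are engineering choices on top of
population summaries. Measured preset behaviour: event-count means within
~2% of the anchors; mean SC durations ≈ 160 ms (burster) vs ≈ 4 s
(broadband).

*Playback cohorts.* Each fish's latent preference is the cohort preference
θ perturbed by Gaussian noise on the Fisher-z (atanh) scale, which keeps
preferences inside [−1, 1] and leaves the boundaries ±1 exact (a fish with
θ = 1 never visits the far zone). Median preference equals θ; the mean is
slightly shrunk toward 0 by the tanh nonlinearity, and equals θ exactly
when the noise is 0. Per interval, roughly half the time (uniform ±30%)
is spent responding, split between the zones by the latent preference;
sides are balanced (4 A / 4 E) in random order. At θ = 0.4, SD 0.3,
n = 12, the one-sample test rejects in ≈ 99% of cohorts at α = 0.05.

*What the generators do not emulate.* Stationarity is assumed within a
window — real fish drift between behavioural states over minutes.
Discharge patterns tied to movement or interaction (named burst types,
cessations), EOD waveforms, and measurement artefacts (missed or spurious
pulses) are out of scope; zone-time noise in playback sessions enters only
through the response-fraction jitter, not through a movement model. Tests
passing on these generators therefore validate the *statistical machinery*
(estimator correctness, type-I control, power, monotone recovery), not the
biological fidelity of any particular dataset.

## Numerical and design choices, briefly

- All randomness flows through `numpy.random.default_rng` from explicit
  integer seeds; permutations, scrambles and simulations are reproducible.
- Problem sizes in the validation suite (e.g. 100 sequences of N = 3000
  with 250 permutations; 50 seeds per memory level; 500 cohorts) keep each
  check's Monte-Carlo error a small fraction of the asserted margin.
- Histogram mode ties break to the lowest bin; greedy peak extraction for
  multimodal histograms enforces a minimum peak separation (default 6 ms)
  so adjacent bins of one broad mode are not double-counted.
- Zone-time validation allows 1 s of slack per interval for tracking
  round-off.
- Degenerate inputs fail loudly and specifically: constant sequences for
  SC, constant columns for PCA (by feature name), all-zero preference
  zones as a flagged undefined SOP, zero-variance preference tests as a
  degenerate flag.

## Known limitations

- The repeated-measures Tukey step tests transformed values without a
  repeated-measures correction (as is common when following an omnibus
  ANOVA with a multiple-comparison procedure from a different package).
- The chance band is a scalar averaged over lags; a strongly
  lag-dependent null (very short sequences, large `max_lag`) would merit
  the per-lag percentile variant.
- SC durations are censored at `max_lag × median IPI`; comparisons between
  groups whose true memory extent exceeds the lag range will be
  compressed. Choose `max_lag` generously relative to the expected
  correlation length.
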