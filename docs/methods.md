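# Methods

`alphaconn` implements an infant-EEG alpha-band functional-connectivity
analysis: overlapping 1-s epochs from annotated continuous recordings,
Hann-tapered FFT, debiased weighted phase lag index (dbWPLI) connectivity
averaged over 7–8 Hz, Network-Based-Statistics (NBS) group comparison with
edge-wise Mann–Whitney tests, and cohort-level univariate statistics and
Spearman brain–behaviour correlations. A synthetic EEG/cohort generator with
known ground truth makes every stage testable without access to clinical
recordings.

## Epoching and inclusion

Validity annotations (`inattention`, `interference`, `artefact`) are unioned
and their complement within `[0, duration)` forms the valid segments; all
intervals are half-open and sample indexing is 0-based. Each segment of
length `L` seconds yields `floor((L − T)/(T(1−o))) + 1` epochs of length
`T = 1 s` at overlap `o = 0.5`, never crossing a segment boundary. Epochs
whose peak absolute amplitude exceeds 200 µV on any channel are dropped
(threshold configurable; the criterion is peak-absolute, not peak-to-peak).
A subject enters group analyses only with **strictly more than 120** clean
epochs pooled across stimulus conditions. The per-epoch mean is removed
before tapering to stop DC leakage; no re-referencing, detrending, ICA or
channel interpolation is performed.

## Spectral estimation and dbWPLI

Each epoch is Hann-tapered (periodic window) and transformed with a real
FFT; 1-s epochs give a 1-Hz resolution, so the 7–8 Hz band comprises exactly
the bins at 7 and 8 Hz. With `X_j = F_a(j)·conj(F_b(j))` the epoch-`j`
cross-spectrum of channels `a, b` at one bin, the estimator is

    dbWPLI = Σ_{j≠k} Im(X_j)·Im(X_k) / Σ_{j≠k} |Im(X_j)|·|Im(X_k)|
           = [(Σ Im X_j)² − Σ (Im X_j)²] / [(Σ |Im X_j|)² − Σ (Im X_j)²],

computed per bin with the streaming identity (the O(n²) pairwise form is
kept as a cross-check oracle) and then averaged over the band's bins,
missing-aware. The pairwise-product construction removes the positive bias
of the squared WPLI: under independence its expectation is ≈ 0; values are
bounded above by 1 and may be negative. Because only the imaginary
cross-spectrum enters, zero-lag (volume-conducted) mixing contributes
nothing; a zero denominator marks the pair *undefined* (NaN) rather than
zero. Imaginary parts below `1e−12·|X|` are flushed to zero so that pairs
whose cross-spectrum is analytically real come out undefined instead of
being estimated from FFT rounding noise — real data are unaffected, since
genuine imaginary parts sit many orders of magnitude above this.

Global connectivity is the mean of the strictly-lower-triangle entries,
ignoring undefined ones; selected-connection connectivity is the analogous
mean over a fixed edge mask (the fronto-central set identified in a prior
cohort is not published as coordinates, so the mask is a required input; the
tests use a synthetic mask over the planted edges). Overlapping epochs are
treated as independent observations by the estimator — a known bias source
accepted for comparability with the original analysis. FFT normalisation
cancels in dbWPLI; power spectra use 1/N.

## Network-Based Statistics

Each edge receives a Mann–Whitney U (group A vs B) converted to Z by the
tie-corrected normal approximation, oriented so positive Z means A
stochastically larger; all-tied edges get Z = 0. Edges with Z above the
threshold (default 1.96, one-tailed, as in the replicated analysis — the
threshold is a tuning parameter of NBS, not a significance level) form a
graph whose connected components are scored by **extent** (edge count;
intensity = summed Z is available). Group labels are permuted (default
5000 times; if the requested count reaches the number of distinct
assignments, all are enumerated with a warning) and each observed component
gets `p = (1 + #{null max ≥ observed}) / (1 + n_perm)`, never exactly zero.
Since U is linear in the fixed pooled ranks, the whole permutation null is
one membership-matrix × rank-matrix product followed by a union-find over
supra-threshold edges, which keeps 200 calibration cohorts × 500
permutations under a few seconds. The discrete max-component statistic and
the +1/+1 estimator make the test mildly conservative: simulated family-wise
error at nominal 0.05 typically lands around 0.02–0.05. Undefined edge
values are rejected rather than imputed; in practice the estimator only
produces them on measure-zero (exactly real) cross-spectra.

## Cohort statistics

The dispatcher chooses Student's t only when Shapiro–Wilk in both groups
*and* Levene's test (centered on the mean, the classic form) all fail to
reject at 0.05; otherwise Mann–Whitney. Under ideal normal data this picks
the t-test in only ≈ 86% of samples — each assumption test still rejects 5%
of the time — which the tests assert as ≥ 75%.

Mann–Whitney reports U for the first group, the tie-corrected
normal-approximation z without continuity correction, and r = z/√N. Exact
two-tailed p doubles the smaller tail of the enumerated tie-free U null
(equivalent to summing both tails, since that null is symmetric); it is used
when there are no ties and n₁·n₂ ≤ 400, otherwise the asymptotic p is
reported — mirroring the exact/asymptotic split in the published tables.
With ties, exact mode falls back to asymptotic with a warning. The 2×2 sex
tables use Pearson chi-square without continuity correction (this reproduces
the published values exactly). Spearman correlations are pairwise-complete
with average ranks. Winsorising replaces every occurrence of the maximum by
the largest strictly smaller value (the single-extreme case the analysis
used, extended to ties); note this operation is *not* idempotent — repeated
application keeps walking down the order statistics — so it is applied
exactly once. Benjamini–Hochberg FDR (via `statsmodels`) is applied only to
correlation families without an a-priori hypothesis. RRB subtype scores sum
ADI-R item "ever" scores over configurable item sets; the bundled default
sets are literature-derived groupings (Repetitive Motor Behaviours,
Insistence on Sameness, Circumscribed Interests), shipped as an editable
YAML file because the exact item lists of the replicated analysis are not
public.

## Synthetic data

The generator emulates just enough of infant EEG for ground-truth testing:

* **Background**: per-channel 1/f^α noise (α = 1 by default, white noise for
  unit tests), generated by spectral shaping; an optional channels × sources
  zero-lag mixing matrix emulates volume conduction.
* **Coupling**: each configured pair shares a narrow-band analytic
  oscillator (Gaussian spectral profile, default 1 Hz bandwidth around the
  centre frequency) injected into both channels with a fixed phase lag.
  Strength `s ∈ [0, 1]` mixes shared and independent oscillators with
  amplitudes √s and √(1−s), so the analytic cross-correlation equals `s`:
  s = 0 is independence, s = 1 a perfectly consistent lag. The empirical
  strength → dbWPLI mapping is monotone but estimator- and SNR-dependent; it
  is verified by simulation (monotone over {0, .25, .5, .75, 1}; > 0.8 at
  s = 1, ≈ 0 at s = 0 at SNR 4), not assumed.
* **SNR** is the RMS ratio of each oscillatory component to the noise;
  infinite SNR drops the noise on coupled channels.
* **Cohorts**: per group, each subject's true strength is drawn from a
  normal distribution clipped to [0, 1] and applied to the template's
  coupling pairs; each trait scale is `a + b·strength + N(0, σ)`, optionally
  rounded and clipped at 0 to mimic interview totals. Same seed ⇒
  bit-identical recordings and tables (per-subject seeds derive from the
  cohort seed).

What the generator does **not** emulate: realistic head-model topographies,
blink/EMG artefact waveforms, non-stationarity, electrode bridging, or the
128-electrode montage (the default desk-scale montage is 16–32 channels;
channel count is configuration). Passing tests therefore demonstrate the
correctness of the estimators and inference machinery under known ground
truth, not the physiological validity of any particular finding on real
recordings.

## Problem sizes and numerical choices

Simulated checks use desk-scale conditions chosen once: estimator
calibration at 2–32 channels and 100–1000 epochs; NBS calibration with 16
channels, 10 + 10 subjects, 500 permutations, 200 null cohorts and a
power check with a 5-edge subnetwork shifted 3 noise-sd in a 13 vs 20
design; end-to-end recovery with 16 subjects, 6 channels, 64-s recordings
at 250 Hz (127 epochs each, comfortably above the >120 inclusion rule) and
SNR 4. Tolerances: streaming-vs-pairwise dbWPLI agreement at 1e−10;
independence grand mean within ±0.01 at 1000 epochs; exact-U enumeration
agreement at 1e−12. Degenerate inputs are errors, not silent repairs:
empty edge masks, zero-margin 2×2 tables, zero rank variance, <2 epochs,
bands outside the available bins.

## Known limitations

* Overlapping epochs violate the estimator's independence assumption; the
  debiasing is therefore approximate, matching the original analysis.
* The NBS extent statistic has little power for isolated single-edge
  effects (a component of extent 1 is rarely larger than the null maximum);
  effects confined to one connection are better probed by the selected-edge
  summaries.
* Whether the original network analysis scored components by extent or
  intensity is not documented; extent is the default here, intensity a flag.
* The exact two-tailed Mann–Whitney convention (doubling the smaller tail)
  can differ from tail-summation conventions in edge cases with asymmetric
  alternatives; the U null itself is symmetric, so tie-free results agree.
* EDF files are read (via MNE) but not written; the simulator emits
  delimited matrices with JSON sidecars.
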