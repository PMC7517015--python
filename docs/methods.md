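# Methods

## The problem and the refinement idea

A 24-hour RR-interval series mixes sleep, rest and activity, and the mix
differs between subjects and between cohorts: heart-failure (CHF)
patients are largely sedentary, healthy (NSR) subjects are not. Entropy
statistics computed over whole recordings therefore compare unlike
physiological states and overlap heavily between groups. The refinement
implemented here keeps only *fast-heart-rate sequences* — windows that
follow a short RR interval and stay fast and stable — on the reasoning
that fast HR in CHF arises from the disease (sympathetic compensation,
reduced vagal tone) while in healthy subjects it arises from exertion,
so these windows carry the most group-discriminative structure. Two
further screens improve within-subject homogeneity (a DTW similarity
filter) and flag which subjects yield enough usable signal at all
(typing by surviving-segment count).

## Pipeline stages and parameters

| Stage | Parameter | Default | Meaning |
|---|---|---|---|
| cleaning | `max_rr_ms` | 2000 ms | intervals above this are artifacts (missed beats) |
| cleaning | label rule | `!= 'N'` removed | ectopic beats corrupt entropy estimates |
| selection | `trigger_ms` | 600 ms | an interval at/below this opens a candidate window |
| selection | `seg_n` | 300 beats | window length; also the SampEn series length N |
| selection | `max_median_ms`, `max_mode_ms` | 600 ms (non-strict) | the window stays fast on average and in its most common value |
| selection | `max_sd_ms` | 50 ms (strict) | the window is stable, not a transient dip |
| trimming | band | mean ± 3·SD | per-segment 99% normal range, single pass, SD with n−1 |
| DTW filter | `dtw_threshold` | 10 | max column-median normalized DTW cost |
| typing | `type_boundary` | 90 segments | type I (≥ 90) vs type II; 0 ⇒ excluded |
| SampEn | `m` | 1 | embedding dimension |
| SampEn | `r_physical_ms` | 12 ms | 1.5 × the nominal 8 ms period of a 128 Hz ECG |
| SampEn | `r_fraction` | 0.10 | traditional mode: r = 0.10 × segment SD |
| evaluation | sweep | 1% of range, 101 points | thresholds from min to max entropy |

All defaults live in `PipelineConfig` and are overridable per stage (CLI
flags or a YAML config).

## Definitions and numerical choices

**Sample entropy.** Templates are the m-point windows X_i^m, 1 ≤ i ≤ n−m;
distance is Chebyshev; matches use d ≤ r; self-matches are excluded. Both
the m-match count B and the (m+1)-match count A run over the shared index
range 1..n−m, so the last m-window is not a B-template. Consequences:
A ≤ B (the value is never negative), and exact time-reversal invariance
does not hold — reversal swaps which boundary window is excluded — though
the discrepancy is O(1/n) (the tests assert agreement to 0.05 at n = 150).
If A or B is zero the result is an NaN sentinel, not an exception: a long
pipeline must not abort on one degenerate segment; undefined rows are kept
in the entropy table, flagged, logged, and excluded from aggregates. n is
the post-trim effective length, not the nominal 300. The implementation
counts matches on a full pairwise distance matrix (O(n²) memory, n ≤ 300);
an independent pure-loop oracle in the tests checks it to 1e-12.

**Tolerance.** The physical tolerance stays at exactly 12 ms (the
convention rounds the 128 Hz period to 8 ms; 1.5 × 7.8125 = 11.72 is not
used). Traditional mode computes 0.10 × SD on the post-trim values and
raises on a constant segment.

**Selection scan.** Left-to-right; the candidate window excludes the
trigger interval itself. After an accepted window the scan resumes just
past it (accepted segments cannot overlap); after a rejection it advances
one beat. The mode of a window is well defined because RR values are
quantized to the sampling grid; ties take the smallest modal value. The
SD gate is strict (< 50), median/mode gates non-strict (≤ 600).

**DTW.** Local distance is |x_i − y_j| in ms; the cumulative distance is
the standard corner-to-corner dynamic program over steps {diag, up,
left}; the reported cost divides the minimal cumulative distance by the
path length N recovered by backtracking (tie-break diagonal, then
vertical, then horizontal), with max(k,m) ≤ N ≤ k+m−1. Two constant
series at levels a, b therefore cost exactly |a−b|. Because tied optimal
paths can differ in length, the arguments are put in a canonical
(lexicographic) order before the DP so that cost(x,y) == cost(y,x)
exactly. The inner loop is numba-jitted; no banding or pruning is used,
so results are exact. Column medians in the per-subject filter exclude
the diagonal zero; a subject with a single segment keeps it trivially.

**Evaluation.** CHF is the positive class and low entropy predicts CHF
(SampEn ≤ c). Se is non-decreasing and Sp non-increasing in c under this
rule, so the swept ROC points plus the (0,0) and (1,1) anchors cover the
unit square and trapezoid integration is well posed; the tests check it
against the exact rank-statistic (Mann–Whitney) AUC. c* is the smallest
threshold attaining the maximal Youden J. The t-test is pooled-variance
Student (Welch behind a flag); p-values below the double-precision floor
are reported as 0. Classification is segment-level: each surviving
segment is one sample, so subjects with more segments weigh more.

**Stage interplay.** The selection gates operate on untrimmed values
(selection precedes trimming); the DTW filter also compares untrimmed
segments; ±3·SD trimming is applied immediately before entropy, to both
the exhaustively segmented dataset (Dataset0) and the refined ones
(Dataset1/2). Typing uses post-DTW counts; a subject with selected
segments that are all discarded by DTW ends at count 0 and is excluded.

## The synthetic cohort generator

`simulate_recording` emulates the features the pipeline's decisions rely
on, per subject: a circadian baseline (sinusoid with a 24-h period in
beats) plus AR(1) beat-to-beat noise; fast-HR episodes that overwrite the
baseline; ectopic beats labeled 'V' with shortened intervals; rare
artifact intervals (2.1–4 s, labeled 'N' as a missed-beat artifact
would be); and quantization of all physiological values to multiples of
7.8125 ms with a 250 ms floor. Episodes are AR(1) with the profile's own
autocorrelation and marginal SD `fast_episode_sd_ms` — real RR series are
strongly autocorrelated, and this choice is what makes within-subject DTW
costs land on a realistic scale (NSR-like segments near the threshold 10,
CHF-like well under it) instead of the far larger costs white-noise
windows would produce. Episode lengths are uniform on 400–1200 beats;
the 400 floor guarantees a 300-beat post-trigger window can fit inside
one episode.

Default profiles (NSR-like / CHF-like): base RR 800/640 ms, circadian
amplitude 120/40 ms, AR(1) φ 0.9 with innovation SD 25/6 ms, episodes at
mean 555/560 ms with SD 35/10 ms, episode rate 1.5/3.5 per 10⁴ beats,
ectopic rate 0.005/0.02, artifact rate 5×10⁻⁴, 100,000 beats (roughly a
day of beats; also the CLI default). The episode rates were set so the
per-subject Dataset1 segment yield mirrors the ratio seen in real
cohorts, where CHF subjects contribute roughly twice the fast-HR
segments per recording that NSR subjects do.

What the generator does **not** emulate: real transition dynamics into
and out of tachycardia, respiratory sinus arrhythmia, compensatory
pauses after ectopy, inter-subject heterogeneity of episode rate, or any
validated HRV model (IPFM, point processes). The archetypes are far more
separable than real NSR/CHF cohorts — pipeline runs on them produce AUC
≈ 1.0 and entropy gaps of ~0.7, versus ~0.26 gaps on real data — so
passing end-to-end tests demonstrates that the machinery is correct and
that the refinement preserves/widens a real separation, not that these
accuracy figures transfer to patients. Under the default rates and only
ten subjects per arm, no subject typically reaches the 90-segment type-I
boundary (post-DTW counts cluster in the 50–90 range for CHF-like
subjects); the type-I report is then marked not evaluable rather than
fabricated from an empty scope.

## Problem sizes used in tests and the acceptance script

Oracle-equivalence tests use series of length ≤ 250 (entropy, against a
pure-Python counter) and ≤ 10 (DTW, against exhaustive path
enumeration, ~1.5M paths at 10×10). The end-to-end check and
`scripts/acceptance.py` run the (10 + 10) × 100,000-beat cohort —
about 6,500 Dataset0 segments and ~50,000 DTW pairs — which completes
in well under a minute on one CPU.

## Known limitations

- The scan-advance policy after a rejected candidate (one beat) and the
  exclusion of self-matches in SampEn are conventional choices; counts
  on real data may shift slightly under alternatives.
- The DTW filter is O(n²) in a subject's segment count with a 300×300 DP
  per pair; thousands of segments per subject would call for an
  exact-preserving blocked implementation.
- Binary WFDB annotation files are not parsed; users convert to RR text
  first (e.g. `ann2rr`).
- Segment-level classification inflates the effective sample size of
  prolific subjects; no subject-level cross-validation is provided.
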