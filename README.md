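# hrvrefine

Data refinement for heart-failure detection from 24-hour RR-interval
recordings.

Long-term heart-rate-variability (HRV) analysis compares subjects across
wildly different mixtures of rest, sleep and activity, which blurs the
boundary between congestive heart failure (CHF) and normal sinus rhythm
(NSR). `hrvrefine` implements a refinement pipeline that, instead of using
the whole 24-h series, keeps only the windows most likely to expose a
subject's intrinsic cardiac state, then discriminates the groups with
sample entropy computed at a *physical* tolerance (fixed in milliseconds,
not scaled by each segment's SD). It is intended for HRV researchers
working with beat-annotated RR lists such as the PhysioNet NSR/CHF RR
Interval Databases, or with the bundled synthetic cohorts.

## Method

Starting from a beat-annotated RR series (ms):

1. **Cleaning** — drop intervals > 2 s (artifacts), then intervals whose
   beat label is not `N` (ectopic beats).
2. **Fast-HR sequence selection** — at every interval ≤ 600 ms, take the
   300 intervals that follow; keep the window iff median ≤ 600 ms,
   mode ≤ 600 ms and SD < 50 ms. Accepted windows never overlap.
3. **Outlier trimming** — inside each segment, remove values outside
   mean ± 3·SD (applied immediately before entropy computation).
4. **DTW similarity filter** — for each subject, compute the pairwise
   dynamic-time-warping cost matrix over segments, where
   `COST = (Σₙ wₙ)/N` is the cumulative |Δ| along the optimal warping
   path divided by its length N; discard segments whose column median
   cost exceeds 10.
5. **Subject typing** — subjects keeping ≥ 90 segments are *type I*
   (high-quality signal), fewer is *type II*, none is excluded.
6. **Classification** — per-segment sample entropy

   `SampEn(m, r, N) = −ln(Σᵢ Aᵢᵐ(r) / Σᵢ Bᵢᵐ(r))`

   with m = 1, N = 300 and the physical tolerance r = 12 ms (1.5× the
   nominal 8 ms sampling period of a 128 Hz ECG; the traditional
   r = 0.10·SD is available too). Segments are labelled CHF when
   SampEn ≤ c; the threshold sweep (1% steps of the observed range)
   yields Se/Sp/Acc, the ROC/AUC, the Youden-optimal cut-point c\*, and
   cut-points constrained to Se > 99% or Sp > 99%.

## Worked example

```bash
hrvrefine simulate --n-nsr 3 --n-chf 3 --beats 30000 --seed 7 --out cohort/
hrvrefine run --in cohort/manifest.csv --out run/
```

prints

```
Dataset2: NSR 0.916 vs CHF 0.206, AUC 1.0000
artifacts in run
```

meaning: after refinement (Dataset2 = fast-HR-selected, DTW-filtered
segments), the NSR-like subjects' mean segment entropy (0.916) sits far
above the CHF-like subjects' (0.206) — regular, low-variability fast
heart rate is the CHF signature — and the threshold classifier separates
the two groups' segments perfectly (AUC 1.0; the synthetic archetypes are
deliberately more distinct than real cohorts). `run/` contains the
per-stage interval/segment counts (`counts.csv`, `group_counts.csv`),
the per-segment entropy tables for Dataset0/1/2, the subject typing, and
JSON classification reports for the ALL / type-I / type-II scopes.

Every stage is also available as its own subcommand (`preprocess`,
`select`, `dtw-filter`, `type-subjects`, `entropy`, `evaluate`) reading
and writing plain CSV, and as library functions
(`hrvrefine.sample_entropy`, `hrvrefine.dtw_cost`, ...). To analyze real
data, convert each recording to RR text (`rr_ms label` per line, e.g.
via WFDB `ann2rr -i <rec> -a ecg -V -w`) and list the files in a
`subject_id,group,path` manifest CSV.

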