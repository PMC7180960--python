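# Methods

## The model

`habitspectrum` represents one observation window of a person's activities of
daily living (ADLs) — e.g. *slept 10 min, then watched TV 60 min* — as a
periodic real signal and works in its frequency domain.  Given an activity
registry mapping each activity name to a positive integer ID, a window with
activities (w₁…w_j) and durations (A₁…A_j) in minutes defines the harmonic
sum

    g(t) = Σₙ₌₁…ⱼ Aₙ · cos((n+1)·t + φ·wₙ),   t ∈ [0, 2π)

i.e. the n-th *observed* activity drives harmonic n+1 of a common
fundamental, carrying its duration as amplitude and its ID as phase offset
(φ = `phase_scale`, default 1 rad per ID unit).  Harmonic 1 — the series
mean — is pinned to zero amplitude, so the encoding starts at the second
harmonic.  The signal is sampled at `n_samples` = 400 points over one
fundamental period, rectified (|g|), and transformed with an FFT; the
magnitudes of the first `n_frames` = 200 bins, divided by `n_samples`, form
the **behavioral spectrum**: a fixed-length, non-negative vector whatever
the number of activities in the window.

Two exact properties follow from linearity of the DFT and of rectification
under positive scaling:

* scaling all durations by c > 0 scales every spectrum value by exactly c;
* reordering activities permutes phases across harmonic positions and
  changes the interference pattern of the rectified signal, hence the
  spectral shape — the representation is order-sensitive.

An alternative construction in which the activity ID is used directly as the
angular frequency is kept behind `SignalConfig(mode="id_frequency")` for
comparison.  It is order-blind (the sum over activities commutes), which is
precisely why the positional construction above is the package's canonical
encoding.

Rectification matters: without it the one-sided magnitude at bin n is
exactly Aₙ₋₁/2 regardless of the phases, so *all* downstream features would
be order-blind.  Rectification mixes phase information into every bin.  Its
side effect is that features that would be exactly order-invariant on the
unrectified spectrum (mean, SD, variance) become invariant only to ≈1–2%
under order reversal, while the lag-1 autocorrelation moves noticeably more;
the tests assert exactly this contrast.  Rectification can be disabled with
`SignalConfig(rectify=False)`.

## Variability features

Each spectrum f = [f₁…f_m] is summarised by five features
v = [f_mean, f_dev, f_var, r_k, s]:

* mean, standard deviation and variance with the population denominator 1/m;
* lag-k autocorrelation
  r_k = Σₙ₌₁^{m−k}(fₙ−f̄)(fₙ₊ₖ−f̄) / Σₙ(fₙ−f̄)², k = 1 by default
  (|r_k| ≤ 1 by Cauchy–Schwarz);
* Shannon entropy with natural logarithm of the spectrum normalised to a
  probability distribution, with 0·log 0 := 0 — so a uniform spectrum
  scores ln m (ln 200 ≈ 5.30) and a one-hot spectrum scores 0.  A raw mode
  (`entropy_mode="raw"`) applies −Σ fₙ ln fₙ to the unnormalised values;
  it is scale-dependent and can go negative, and is provided only for
  comparison.

Degenerate conventions: a numerically constant spectrum (f_dev ≤ 10⁻¹² ·
max(1, |f_mean|)) has r_k = 0, and an all-zero spectrum has entropy 0; both
emit a warning.  Mean and SD scale linearly, variance quadratically, and
r_k and s are invariant under positive scaling of the spectrum.

## Clustering and habit-count selection

Either representation (raw 200-frame spectra, or the five-feature vectors)
is clustered with Lloyd k-means, k-means++ initialisation, best of
`restarts` = 50 random restarts (scikit-learn backend; deterministic for a
given seed).  Restarts address the local-minimum problem inherent in
k-means.  Cluster quality is the **uncentered explained-variance ratio**

    EV(k) = 1 − Σᵢ‖uᵢ − c(uᵢ)‖² / Σᵢ‖uᵢ‖²,

which is positive already at k = 1 for data with a nonzero mean; the
conventional centred BSS/TSS ratio (identically 0 at k = 1) is available as
`ev_mode="bss_tss"`.  All-zero data (denominator 0) define EV = 1 with a
warning.

The habit count is suggested by the elbow rule on the EV-vs-k curve for
k = 1…k_max: the interior k maximising the downward bend
2·e[k] − e[k−1] − e[k+1], ties resolved to the smallest k.  The full curve
is always returned so a human can override the suggestion.  To make the
curve provably non-decreasing in k at finite restarts, each k also gets one
warm-started run seeded with the k−1 centroids plus the point farthest from
its assigned centroid; Lloyd iteration from that seed cannot increase the
within-cluster sum of squares, so best-of-all-runs WSS is monotone in k.

Variability vectors are z-scored before clustering (their features differ by
four orders of magnitude; without standardisation the entropy axis dominates
all distances).  The pipeline's EV table for the variability route is
computed on per-feature *scaled but uncentred* features (V/σ): the cluster
geometry — distances, assignments, WSS — is identical to the z-scored fit
(WSS is translation-invariant), but the ratio keeps the mean term, so the
column is positive at k = 1, monotone in k, and comparable with the raw
route, which is clustered and scored unstandardised.  Raw spectra share a
common physical unit (minutes) across frames, so per-frame standardisation
would be inappropriate there.

## Synthetic data

Real smart-home / care-home logs are not distributable, so the package
generates logs with planted structure in two regimes:

* **session** — short self-paced sessions over 6 activity types (cooking,
  eating, drinking, studying, sleeping, watching TV), each session at most
  20 minutes of mean duration, emulating a university smart-home study with
  28 recorded sessions;
* **full_day** — whole days over 25 activity types, split into
  morning (05:00–12:00) / afternoon (12:00–18:00) / night (18:00–05:00)
  phases (the boundaries are a package choice; only the three-phase split
  itself is inherent to the regime), emulating a care-home annotation study
  with 12 residents.

A *habit template* is an ordered activity list with mean durations; each
observation window draws a template by its mixing weight and perturbs it
with truncated-normal duration jitter (floor 1 minute — durations must stay
positive), adjacent-order swaps, and activity drops.  Session defaults:
three habits over disjoint activity pairs with 10% duration jitter, 0.1 swap
and 0.05 drop probability.  The template shapes (lengths 2/4/5, distinct
alternation patterns and total durations) were designed so the three habits
occupy distinct, roughly equidistant regions of the standardized variability
space: the second-difference elbow rule identifies the correct count only
when no cluster pair is much closer than the rest, which is what
"well-separated habits" should mean.  `well_separated_session_config` is the
noise-floor variant (jitter only, equal weights) used for recovery studies;
recovery is scored with the adjusted Rand index (ARI) against the planted
labels.

What the generator does *not* emulate: sensor noise and activity
mis-recognition (logs are assumed correctly labelled), within-template
duration correlations, day-of-week or seasonal structure, and multi-person
confounds.  Passing recovery tests therefore shows that the encoding and
clustering recover planted sequence/duration structure, not that real ADL
logs contain such structure.

## Problem sizes and verified behaviour

The test suite works at the scale of the emulated studies: 28–60 session
windows, 12 subjects × 7 days × 3 phases for full days, spectra of 200
frames.  Verified properties include: best-of-restarts k-means reaches the
exhaustive minimum-WSS partition on ≥95% of small random instances
(n ≤ 10, k ≤ 3, enumerated labellings as the oracle); with three
well-separated planted habits and 60 windows, variability clustering at
k = 3 reaches ARI ≥ 0.9 in ≥90% of seeds and the elbow suggests k = 3 in
≥90% of seeds; mean ARI degrades monotonically as duration jitter grows
through {0, 5, 15, 30} minutes; and the seed-averaged EV of the variability
route is at least that of the raw route at every k on session-regime data.

## Known limitations

* The FFT normalisation (per-sample division) and the phase scale are
  conventions; different choices rescale spectra and shift feature values,
  so absolute feature magnitudes are comparable only within one
  configuration.
* Activity IDs enter as phases in radians; IDs that differ by a multiple of
  2π would nearly collide.  With integer IDs ≤ 25 and `phase_scale` = 1 no
  two are congruent; for larger registries set `phase_scale` = 2π/(max_id+1).
* The elbow rule needs k_max at least suggested_k + 1 and is undefined below
  three curve points (falls back to the largest k available).
* k-means assumes roughly isotropic clusters in the (standardized) feature
  space; strongly elongated habit groups may be split or merged.
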