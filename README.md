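# habitspectrum

Habit discovery from activity-of-daily-living (ADL) logs.

Smart homes and care facilities can log *which* activities a person performs,
*in what order*, and *for how long* — but a flat log does not say what the
person's habits are.  `habitspectrum` turns each observation window (a short
session, or a morning/afternoon/night phase of a day) into a fixed-length
numerical signature and clusters those signatures across days and subjects:
each cluster is a recurring pattern of activity order and duration, i.e. a
habit.  The intended users are researchers in ambient assisted living and
digital health who have labelled activity logs (from any recognition system)
and want an unsupervised, interpretable habit summary.

## Method

For a window with activities w₁…w_j (integer activity IDs from a registry)
and durations A₁…A_j (minutes), the package builds the harmonic sum

    g(t) = Σₙ₌₁…ⱼ Aₙ · cos((n+1) t + wₙ),   t ∈ [0, 2π)

— the n-th observed activity drives harmonic n+1, with its duration as
amplitude and its ID as phase; harmonic 1 (the series mean) stays silent.
g is sampled (400 points), rectified, and Fourier-transformed; the first 200
FFT magnitude bins are the **behavioral spectrum** f = [f₁…f₂₀₀], a
fixed-length non-negative vector for any j.  Each spectrum is optionally
reduced to the five-feature **variability vector**

    v = [f_mean, f_dev, f_var, r₁, s]

(mean, SD, variance, lag-1 autocorrelation, normalised Shannon entropy).
Spectra or variability vectors are clustered with best-of-restarts k-means;
cluster count k is chosen from the uncentered explained-variance curve
EV(k) = 1 − Σᵢ‖uᵢ − c(uᵢ)‖² / Σᵢ‖uᵢ‖² by the elbow rule.  A synthetic-log
generator with planted habit templates makes the whole pipeline testable
end-to-end; recovery is scored with the adjusted Rand index (ARI).
See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

Encoding the observation *slept 10 min, then watched TV 60 min* with
registered IDs watching_tv = 1, sleeping = 2:

```python
import numpy as np
from habitspectrum import (HabitSequence, load_registry, harmonic_parameters,
                           behavioral_spectrum, variability_features)

registry = load_registry({"watching_tv": 1, "sleeping": 2})
seq = HabitSequence("resident_A", "session",
                    ids=(registry.id_of("sleeping"), registry.id_of("watching_tv")),
                    durations=(10.0, 60.0))
for h in harmonic_parameters(seq).harmonics:
    print(f"harmonic {h.index}: amplitude={h.amplitude:g} min, phase={h.phase:g}")
spectrum = behavioral_spectrum(seq)
print("spectrum length:", len(spectrum))
v = variability_features(spectrum)
print(f"mean={v.f_mean:.4f}  sd={v.f_dev:.4f}  var={v.f_var:.4f}  "
      f"r1={v.r_k:.4f}  entropy={v.s:.4f}")
```

prints

```
harmonic 1: amplitude=0 min, phase=0
harmonic 2: amplitude=10 min, phase=2
harmonic 3: amplitude=60 min, phase=1
spectrum length: 200
mean=0.3524  sd=2.8634  var=8.1992  r1=0.1033  entropy=1.9374
```

The first activity (sleeping, 10 min) sits on harmonic 2 with phase 2 and
amplitude 10; the second (TV, 60 min) on harmonic 3 with phase 1 and
amplitude 60.  Swapping the two activities, or changing a duration, changes
the spectrum — order and duration are both encoded.

End-to-end on a synthetic session log with three planted habits
(60 windows, duration jitter only):

```python
from habitspectrum import RunConfig, run_pipeline, write_activity_log
from habitspectrum.synthetic import well_separated_session_config, simulate_log

cfg = well_separated_session_config(n_sequences=60, seed=7)
events, truth = simulate_log(cfg)
write_activity_log(events, "log.csv", cfg.registry)
cfg.registry.to_csv("registry.csv")
result = run_pipeline(RunConfig(log_path="log.csv", registry_path="registry.csv",
                                out_dir="out", k_max=6, restarts=50, seed=7))
print(result.explained["session"].round(4))
print(result.manifest["suggested_k"])
```

```
      raw  variability
k
1  0.7997       0.9740
2  0.9803       0.9894
3  0.9961       0.9989
4  0.9968       0.9992
5  0.9974       0.9994
6  0.9979       0.9995
{'session/raw': 2, 'session/variability': 3}
```

Both explained-variance columns rise monotonically with k; the elbow on the
variability column lands on k = 3, the true number of planted habits, and
the resulting assignment matches the planted labels (ARI 1.0 on this seed).
The same stages are available from the shell:

```sh
habitspectrum simulate --regime session --out data/
habitspectrum run --log data/log.csv --registry data/registry.csv --out results/
```

`habitspectrum run` writes `spectra.csv`, `variability.csv`, per-window
`explained_variance_*.csv` and `clusters_*.csv` tables, and a `manifest.json`
that makes the run byte-reproducible.

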