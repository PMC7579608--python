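# microstate-lab

EEG microstate analysis for resting-state group studies — with a synthetic
cohort generator that makes every stage of the pipeline verifiable against
known ground truth.

Spontaneous EEG unfolds as a sequence of *microstates*: scalp potential
topographies that stay quasi-stable for ~80–120 ms before switching. Four
canonical classes (A–D) explain most of the topographic variance at rest,
and their temporal parameters — mean duration, frequency of occurrence,
time coverage, per-state field strength — index the dynamics of large-scale
brain networks. This package implements the full analysis used to compare
such parameters between two participant groups (e.g. autistic and typically
developing children) across eyes-closed/eyes-open resting conditions:

* **Preprocessing**: resample to 125 Hz, zero-phase 2–20 Hz band-pass +
  60 Hz notch, 2 s epochs, amplitude/flatness artifact flagging, Perrin
  spherical-spline interpolation of bad channels, average reference; the
  first 10 artifact-free epochs per condition enter the analysis.
* **Microstate extraction**: topographies at GFP peaks → polarity-invariant
  T-AAHC clustering (K=4) per participant, second-level clustering into
  group maps per group × condition, sorting against a normative A–D
  reference, and sample-wise backfitting by absolute spatial correlation.
* **Parameters**: GEV, duration, frequency, coverage, per-state GFP and
  transition probabilities per class.
* **Statistics**: per parameter × class 2×2 mixed ANOVA (group × eye
  condition) with partial η² and observed power, Bonferroni post hoc
  contrasts (α=0.0125), and log(x+1) Pearson correlations with covariates.
* **Synthetic cohorts**: a hidden semi-Markov generator (gamma run lengths,
  canonical templates, pink spatially-correlated noise at programmed SNR,
  per-participant jitter, programmable group × condition effects) emulating
  the 13+13 × EC/EO study design, with EDF export and ground-truth
  sidecars.

The scientific model and every numerical convention are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
import numpy as np
from microstate_lab import (
    MicrostateModel, StateDynamics, make_canonical_templates, make_montage,
    simulate_recording, average_reference,
)

montage = make_montage(32)
canon = make_canonical_templates(montage)
dyn = StateDynamics(mean_durations_ms=(74, 69, 67, 64), snr=2.0, gfp_uv=10.0)
epochs, truth = simulate_recording(canon, dyn, n_epochs=10, seed=42)

model = MicrostateModel(average_reference(epochs), n_states=4, normative=canon)
results = model.fit()
print(results.summary())
```

prints

```
Microstate analysis  (K=4, 20.0 s analyzed, 809 GFP peaks)
Total GEV: 85.08 %

class    GEV %  duration ms  frequency Hz  coverage %   GFP µV
    A    25.56         74.8          3.70       29.96    10.78
    B    20.99         66.0          3.60       24.44    10.81
    C    18.95         62.1          3.50       22.68    10.99
    D    19.57         58.6          3.65       22.92    10.93
```

Four microstate classes tile the 20 s of data: each class is dominant for
~23–30% of the time in stable runs of ~59–75 ms (close to the programmed
64–74 ms means), recurs 3–4 times per second, and the four maps together
explain 85% of the GFP-weighted topographic variance. Label accuracy
against the generator's ground truth here is 99.6%.

Cohort-level analysis is one call (or `microstate-lab run` from a shell):

```python
from microstate_lab import PipelineConfig, run_pipeline

cfg = PipelineConfig()           # protocol defaults: 125 Hz, 2–20 Hz, K=4 …
res = run_pipeline(cfg, seed=7)  # simulates the 13+13 × EC/EO default cohort
print(res.anova.query("parameter=='duration' and `class`=='C'"))
```

The command-line interface mirrors the library
(`microstate-lab simulate|preprocess|extract|backfit|params|stats|run`);
`simulate` writes EDF recordings plus a cohort manifest, `run` executes
the full pipeline on a manifest (or simulates one) and emits tidy CSVs of
parameters, ANOVA tables, post hocs and correlations.

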