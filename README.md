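# specdecode

Separation of epoched M/EEG activity into aperiodic (1/f-like) and
oscillatory components, and multivariate decoding of task state from each
component.

## What problem this addresses

Electrophysiological power spectra mix two kinds of signal: a broadband
aperiodic background, well described over a band by `P(f) ∝ 1/f^χ` (a
straight line in log-log coordinates, summarised by its slope, intercept
and broadband power), and band-limited oscillations (theta 3–7 Hz, alpha
8–12 Hz, beta 15–30 Hz) riding on top of it. Treating raw band power as
"oscillation" conflates the two. This package is for researchers who want
to ask, on epoched multichannel recordings with a factorial task design
(task × content × demand), *which* of these components carries information
about cognitive state, whether that information generalizes across tasks,
and where it sits across channels or ROIs.

The pipeline:

1. **Preprocess** — peak-to-peak epoch rejection (350 µV EEG / 5000 fT
   magnetometer / 4000 fT/cm gradiometer defaults), evoked-potential
   subtraction per condition cell (isolating induced activity), and
   cropping to the 0.3–1.5 s analysis window.
2. **IRASA** (irregular-resampling auto-spectral analysis) — per epoch and
   channel, resample the series by factors h = 1.10 … 1.90 and 1/h,
   geometric-mean the branch spectra and take the median across h: a power
   law is invariant under this operation while narrow-band peaks are
   displaced and removed. Yields per-trial aperiodic broadband power
   (3–30 Hz), log-log slope and intercept, and signed theta/alpha/beta
   oscillatory power.
3. **Decode** — per subject, signal and binary contrast: average random
   groups of 4 trials into pseudo-trials, z-score per feature, PCA to 99%
   variance, linear SVM, stratified 5-fold cross-validation repeated 25
   times; performance is the ROC AUC. Cross-task generalization trains on
   one subtask and tests on another.
4. **Patterns** — Haufe projection (covariance × weights) turns classifier
   weights into interpretable activation patterns; z-scored group averages
   with percentile thresholding for display.
5. **Inference** — one-tailed one-sample t tests of AUC against 0.5 with
   Benjamini–Hochberg FDR control, and permutation tests (K = 1000,
   add-one p) of mean within-subject spatial pattern correlations.
6. **Geometry** — condition-mean states embedded in 2-D by PCA and
   superimposed across tasks and subjects with scaling-free Procrustes
   alignment.

Because raw recordings with this design are rarely shareable, the package
includes a first-class synthetic-data generator (`specdecode.simulate`)
producing epochs with known power-law exponents, non-phase-locked
oscillations, optional evoked transients and condition effects routed
through per-channel maps — every applied factor is recorded as ground
truth, which is how the test suite validates the whole chain end to end.

## Worked example

```python
import numpy as np
from specdecode import (
    DecodeConfig, IrasaConfig, SimConfig, gen_epoch_set,
    decode_within, extract_features, group_auc_test,
)
from specdecode.simulate import ConditionEffect, half_map
from specdecode.preprocess import crop_window, subtract_evoked

# small cohort: hard trials get a 10% aperiodic amplitude reduction on the
# first half of the channels; the default 10 Hz oscillation gains 25%
cfg = SimConfig(
    n_subjects=5, n_trials_per_condition=24, n_channels=16,
    demand_effect=ConditionEffect(amplitude_factor=0.9, channel_map=half_map(16)),
    seed=42,
)
epochs, truth = gen_epoch_set(cfg)

epochs = crop_window(subtract_evoked(epochs), 0.3, 1.5)
features = extract_features(epochs, IrasaConfig())

for signal in ("bb_power", "theta"):
    aucs = []
    for subject in sorted(epochs.labels["subject"].unique()):
        mask = (
            (features.labels["subject"] == subject)
            & (features.labels["task"] == "WM")
            & (features.labels["content"] == "alphanumeric")
        ).to_numpy()
        sf = features.signal(signal, mask)
        res = decode_within(sf, sf.labels["demand"].to_numpy(),
                            DecodeConfig(n_reps=5, seed=0))
        aucs.append(res.auc)
    t, p = group_auc_test(aucs, chance=0.5, tail="one")
    print(f"{signal:9s} per-subject AUC: "
          + " ".join(f"{a:.2f}" for a in aucs)
          + f" | group mean {np.mean(aucs):.3f}, t = {t:.2f}, p = {p:.4f}")
```

Output:

```
bb_power  per-subject AUC: 0.62 0.62 0.66 0.74 0.98 | group mean 0.724, t = 3.31, p = 0.0148
theta     per-subject AUC: 0.70 0.88 0.60 0.46 0.74 | group mean 0.676, t = 2.51, p = 0.0332
```

Demand is decodable from aperiodic broadband power (the simulated 10%
amplitude reduction is a 19% power reduction on mapped channels), and the
one-tailed group test against chance (AUC = 0.5) is significant at the
group level. Theta also decodes above chance here because the simulated
10 Hz oscillation gains amplitude under demand and the 8–12 Hz energy
bleeds into neighbouring bands at 1.2 s spectral resolution.

## Command line

Every stage is also a subcommand exchanging TSV tables and a documented
epoch container (`data.npy` + JSON sidecar):

```bash
specdecode simulate --config sim.json --out epochs/
specdecode separate --epochs epochs/ --out features.tsv
specdecode decode --features features.tsv --contrast demand --out decoding.tsv
specdecode run-all --config run.json --seed 7 --out results/
```

`run-all` executes the whole pipeline (features, decoding, generalization
matrices, pattern tables, stats summary, embeddings, run manifest) and is
bit-reproducible for a fixed config and seed.

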