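# hhtmicrostate

Frequency-band EEG microstate analysis with a Hilbert–Huang front-end.

Multichannel EEG can be described as a sequence of *microstates*: scalp
potential topographies that stay quasi-stable for ~80–120 ms and then switch
abruptly. Classical microstate analysis works on the broadband signal and
loses frequency-domain information; band-pass filtering recovers bands but
destroys the instantaneous spectral structure of the data. This package
implements the alternative: the EEG is decomposed per channel with CEEMDAN
(complete ensemble empirical mode decomposition with adaptive noise), spurious
modes are screened by mutual information with the source signal, and each
intrinsic mode function's Hilbert instantaneous frequency `F(t) = (1/2π) dθ/dt`
assigns every sample of every mode to one of the five canonical EEG bands
(delta 0.5–4, theta 4–8, alpha 8–12, beta 12–30, gamma 30–40 Hz). Microstate
analysis then runs per band.

The microstate machinery is the standard polarity-invariant pipeline:

- **GFP** `GFP(t) = sqrt((1/C) Σ_i (V_i(t) − V̄(t))²)` — the spatial standard
  deviation across the C electrodes; its local maxima are the high-SNR
  topographies used for clustering.
- **Modified k-means** — assignment by maximal squared spatial correlation
  `l_n = argmax_k (x_nᵀ a_k)² / ‖x_n‖²` (polarity ignored), template update as
  the dominant eigenvector of the within-cluster map covariance.
- **GEV** `Σ_n (GFP_n · corr(x_n, a_{l_n}))² / Σ_n GFP_n²` and the
  **CV criterion** `σ̂² ((C−1)/(C−K−1))²` for choosing the microstate count K.
- **Backfitting** every sample to its best template and extraction of the
  temporal parameters per class: mean duration (MD, ms), occurrences per
  second (OPS), time-coverage ratio (TCR, with the identity
  TCR = OPS × MD/1000), and per-class GEV (%).

For method comparison the package provides a zero-phase FIR band-pass
front-end ("FIR-Microstate" baseline), the polarity-invariant topographic
similarity index, a permutation test for topographic differences between
groups, per-band GEV comparison tables, and a classifier-ready feature
export. A ground-truthed synthetic-EEG generator (planted templates,
gamma-distributed segment durations, band-limited sources, sensor noise)
makes the whole pipeline testable without any external dataset; EDF and
plain matrix formats are read for real data.

## Worked example

```python
import numpy as np
from dataclasses import replace
import hhtmicrostate as hm

# 45-channel, 60 s synthetic EEG with 4 planted microstate templates, SNR 5
spec = hm.SyntheticSpec(C=45, fs=250, duration=60, K=4, seed=7, noise_sigma=0)
spec = replace(spec, noise_sigma=hm.noise_sigma_for_snr(spec, 5.0))
rec, truth = hm.simulate_microstate_eeg(spec)

peaks = hm.find_gfp_peaks(hm.gfp(rec))
maps = hm.extract_peak_maps(rec, peaks)
best_k, table, models = hm.select_k(maps, range(2, 9), seed=11)
print(table)
#>    K  gev_total        cv
#> 0  2   0.575710  0.845603
#> 1  3   0.800739  0.416731
#> 2  4   0.979190  0.045726
#> 3  5   0.979317  0.047806
#> 4  6   0.979426  0.050091
#> 5  7   0.979543  0.052535
#> 6  8   0.979646  0.055215
print(best_k)
#> 4
```

The CV criterion is minimized at K = 4, the planted template count, and the
four templates explain ~98% of the GFP-weighted variance. Backfitting and
parameter extraction (with a 30 ms minimum segment duration) then recover
the planted temporal statistics:

```python
model = models[best_k]
seq = hm.backfit(model, rec, min_segment_samples=int(0.03 * rec.fs))
params = hm.microstate_parameters(seq, rec, model)
print(params.table.round(2))
#>    class   MD_ms  OPS_per_s   TCR  GEV_pct
#> 0      0  100.83       2.32  0.23    22.70
#> 1      1  108.36       2.43  0.26    24.97
#> 2      2   99.13       2.52  0.25    24.04
#> 3      3  100.64       2.52  0.25    24.35
```

MD sits near the generated gamma mean of 100 ms and each class covers about
a quarter of the recording, matching the ground truth within a few percent.

A command-line interface wraps the same stages
(`hhtmicrostate simulate | preprocess | decompose | bands | microstate … |
compare … | features export | run`); `hhtmicrostate run --config cfg.yaml`
executes the full pipeline and writes a manifest with checksums of every
artifact.

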