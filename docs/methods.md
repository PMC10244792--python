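# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Time–frequency front-end

### EMD sifting

Plain empirical mode decomposition extracts intrinsic mode functions (IMFs)
by repeatedly subtracting the mean of the upper and lower cubic-spline
envelopes through the local extrema. An IMF must (approximately) have
extrema and zero-crossing counts differing by at most one, and a locally
zero envelope mean. Choices:

- **Stopping rule** — Cauchy-style criterion on the envelope-mean energy,
  `Σ m² / Σ h² < 0.2` (the classic default), with a hard cap of 100 sifting
  iterations per mode. The decomposition ends when the residual has fewer
  than three extrema or the mode cap `⌊log₂ N⌋ − 1` is reached.
- **Boundaries** — extrema sequences are mirror-extended by two extrema
  about each end before spline fitting. Edge effects remain the dominant
  error source, which is why all downstream accuracy statistics exclude an
  edge margin (default 0.5 s, configurable).

### CEEMDAN

The ensemble variant adds, at stage *k*, the *k*-th EMD mode of each of *n*
white-noise realizations to the running residual, extracts one sifted mode
from each perturbed copy, and averages; the stage residual is defined by
subtraction, so `Σ IMFs + residual = x` holds to machine precision by
construction. All noise flows from a single seed; decompositions are
bit-reproducible.

- **Ensemble size** — default 50 realizations.
- **Noise amplitude β** (noise std as a fraction of the stage signal's std)
  — default **0.1**. At β = 0.2 the ensemble perturbation is strong enough
  to split a noise-free tone across two adjacent modes in this sifting
  configuration (measured max-mode energy fractions 0.49–0.88 across seeds
  and ensemble sizes, versus 0.93–0.99 at β = 0.1), which defeats the
  decomposition's purpose; β = 0.1 preserves single-tone integrity while
  still suppressing mode mixing.
- Ensemble-averaged modes are only *approximate* IMFs: averaging leaves
  low-energy noise residues with micro-ripples that inflate raw extrema
  counts. The extrema/zero-crossing balance is therefore a property of the
  sifting operation, and is validated there.

### IMF selection by mutual information

Spurious modes are screened by the mutual information between each IMF and
the source signal, estimated from an equal-width 2-D histogram
(`max(8, ⌈√N⌉)` bins capped at 64, natural log; empty cells contribute
zero). Modes below 5% of the maximum mutual information are folded into the
residual, so reconstruction is conserved. The histogram estimator is
symmetric and invariant under monotone affine rescaling of either argument.
Note that mutual information measures *any* statistical dependence: smooth
noise-residue modes retain non-trivial MI with the source, so this screen
removes independent-noise modes, not approximation artifacts.

### Hilbert banding

Each kept IMF is mapped to its analytic signal; the instantaneous frequency
is the time derivative of the unwrapped phase divided by 2π (Hz), computed
with central differences (one-sided at the edges). Two band-assignment
modes exist:

- **samplewise** (default) — a mode's sample contributes to the band its
  instantaneous frequency falls in at that instant; the per-sample sum of
  band signals equals the sum of kept IMFs wherever F(t) lies in
  [0.5, 40) Hz. This preserves the instantaneous spectral structure.
- **imf-mean** — a whole mode goes to the band containing its
  amplitude-weighted mean frequency.

Bands are half-open `[low, high)`: delta 0.5–4, theta 4–8, alpha 8–12,
beta 12–30, gamma 30–40 Hz; negative or non-finite instantaneous
frequencies (possible where the envelope is near zero) fall outside every
band. The FIR baseline front-end is a windowed-sinc (Hamming) band-pass
applied forward–backward, with the tap count targeting a transition width
of 25% of the band's low edge (1 Hz floor), capped for short inputs.

## Microstate analysis

Clustering runs on the average-referenced topographies at GFP peaks only
(`g[t−1] < g[t] ≥ g[t+1]`, plateau keeps its first sample); backfitting
labels all samples. The modified k-means is polarity-invariant: assignment
maximizes the squared spatial projection, the template update is the
dominant eigenvector (SVD) of the within-cluster map block, and empty
clusters are reseeded from the worst-explained map. Defaults: 20 restarts,
tolerance 1e-6 on the relative change of the residual variance σ̂², 500
iteration cap, ties toward the lowest class index, template signs fixed by
making the largest-magnitude component positive. σ̂² is non-increasing
across iterations within a restart; the best restart by total GEV wins.

K selection fits every K in a range (default 2–8) with seeds `seed + K` and
returns the argmin of the CV criterion together with the full GEV/CV table,
so other heuristics (e.g. largest between-group difference) can be applied
downstream.

**Backfitting and the minimum segment duration.** Every sample is labeled
by maximal squared spatial correlation with the templates; polarity and
positive rescaling of the recording change no label. Runs shorter than
`min_segment_samples` can be absorbed into the better-correlating neighbor
(shortest run first; each merge removes a boundary, so the procedure
terminates). The default is 0 (no smoothing). For *recovery analyses on
oscillatory synthetic data* a 30 ms minimum duration is used and
recommended: a sinusoidal source carries no spatial information at its zero
crossings, so unsmoothed labels flicker there and mean duration is biased
downward by construction (roughly threefold at 10 Hz); 30 ms is the
field's customary small-segment rejection threshold and restores unbiased
duration estimates (measured MD error < 5% at SNR 5).

Parameters per class: MD = mean run length (ms), OPS = runs per second,
TCR = labeled-sample fraction, GEV in percent. `TCR = OPS · MD / 1000`
holds exactly; boundary-truncated runs count like any other; an absent
class reports MD as missing and zero OPS/TCR.

## Comparison statistics

The similarity index between two topographies is the absolute spatial
Pearson correlation of the average-referenced maps — symmetric, polarity-
and scale-invariant, in [0, 1].

**Permutation test.** Group topographic difference is tested by comparing
the two groups' mean topographies: all pooled maps are first
polarity-aligned against the pooled dominant eigenvector (a reference that
does not depend on the group split, so the statistic is exchangeable under
membership shuffling), and each group's mean map is the arithmetic mean of
its aligned maps. The null distribution shuffles membership; small
similarity indicates difference, so `p = (#{null ≤ observed} + 1)/(n_perm + 1)`.
An earlier design that averaged each set via its own dominant eigenvector
was abandoned: a shuffled set's eigenvector snaps to its majority template,
so under a true difference the null concentrates at the same near-zero
similarity as the observed value, and measured power at per-channel SNR 10
was only 0.93. The pooled-alignment statistic is exact under the null
(measured rejection rate 0.047 at α = 0.05 over 1000 replications) with
power ~1.0 in the same setting. No multiple-testing correction is applied
across band × class grids by default; a Bonferroni option exists.

## Synthetic data generator

A recording is a sequence of segments; each segment activates one of K
planted templates (unit-norm, zero-mean, pairwise |r| ≤ 0.3 by default),
multiplied by a sinusoid at a frequency drawn uniformly from the class's
source band, with 10 ms Hann on/off ramps against step discontinuities,
plus white Gaussian sensor noise. Segment durations are gamma-distributed
(default mean 100 ms, shape 4 — inside the mean-duration range typically
reported for EEG microstates); consecutive segments never repeat a class;
durations round to whole samples (minimum 1). Defaults mirror a 45-channel,
250 Hz montage. The generator emits the exact per-sample labels, templates,
realized per-class MD/OPS/TCR and per-sample source frequency.

What it does **not** emulate: 1/f background spectra, dipolar source
geometry and volume conduction, artifacts (blinks, EMG), non-stationary
noise, overlapping simultaneous sources. Passing tests therefore establish
the pipeline's correctness and recovery behavior under the stated
generative model, not its performance on real EEG.

SNR is defined as RMS(signal)/RMS(noise) over all channels and samples;
`noise_sigma_for_snr` renders the noiseless recording once (same seed, same
segment sequence) to compute the noise level for a target SNR.

## Validation problem sizes

The acceptance computations use: an 8 s, 250 Hz two-tone (2 + 20 Hz)
mixture for reconstruction and IMF validity; 8 s pure tones at 2/10/25 Hz
for instantaneous frequency; a 2/10/25 Hz mixture for band-partition
fidelity; toy instances of ≤ 5 maps for brute-force GEV/CV agreement; a
45-channel, 60 s, K = 4 recording at SNR 5 for planted-model recovery and
K selection over 2–8; 200 null and 100 alternative replications of the
permutation test (45 channels, 20 maps per group — the montage and group
size of the motivating study — n_perm = 999, per-channel SNR 10); and the
HHT-vs-FIR comparison averaged over 5 replicate 12-channel, 16 s
alpha-band recordings at SNR 5 (single-recording gaps have a ~3 pp
standard deviation, so replication is part of the protocol). These sizes
are the package's validation conditions; all are generated at run time
from seeds.

## Known limitations

- EMD/CEEMDAN edge effects; all accuracy claims exclude the configurable
  edge margin.
- Ensemble-averaged modes are approximate IMFs (see above).
- CEEMDAN's mode alignment is sensitive to the noise amplitude β; the 0.1
  default was chosen for tone integrity, and heavily broadband signals may
  warrant different values.
- The CV criterion's penalty is weak for large channel counts; K selection
  on very noisy data may prefer larger K than the generative truth.
- Group-level fitting concatenates peak maps across recordings
  (single-level); a two-level per-recording mode is available but
  non-default.
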