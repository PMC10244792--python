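"""Ground-truthed synthetic EEG with planted microstate structure.

The generator emulates the structure of average-referenced multichannel
resting/task EEG used for microstate analysis: a sequence of quasi-stable
segments, each driven by one of K planted unit-norm topographies modulated
by a band-limited oscillation, plus white sensor noise.  Defaults mirror a
45-channel, 250 Hz montage with gamma-distributed segment durations of
mean 100 ms (shape 4), inside the mean-duration range typically reported
for EEG microstates (~80-130 ms).

The generator is the ground truth for the pipeline's tests: it emits the
exact per-sample labels, templates and realized per-class MD/OPS/TCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EEGRecording

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_templates",
    "simulate_microstate_eeg",
    "simulate_band_mixture",
    "noise_sigma_for_snr",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic microstate EEG generator.

    ``source_band`` may be a single (low, high) Hz interval shared by all
    classes or a list of one interval per class.  ``amplitude`` is the peak
    µV scale of the oscillation projected through a unit-norm template;
    ``noise_sigma`` the per-channel white-noise std in µV.
    """

    C: int = 45
    fs: float = 250.0
    duration: float = 60.0
    K: int = 4
    duration_mean_ms: float = 100.0
    duration_shape: float = 4.0
    source_band: tuple[float, float] | list[tuple[float, float]] = (8.0, 12.0)
    amplitude: float = 10.0
    noise_sigma: float = 1.0
    max_xcorr: float = 0.3
    seed: int = 0
    ramp_ms: float = 10.0
    templates: np.ndarray | None = field(default=None, repr=False)

    def band_for_class(self, k: int) -> tuple[float, float]:
        if isinstance(self.source_band, list):
            return self.source_band[k]
        return self.source_band


@dataclass
class GroundTruth:
    """Everything the generator knows: labels, templates, realized parameters."""

    labels: np.ndarray             # per-sample class index
    templates: np.ndarray          # K x C
    params: pd.DataFrame           # per class: MD_ms, OPS_per_s, TCR
    source_frequency: np.ndarray   # per-sample Hz of the active oscillation
    segments: list[tuple[int, int, int]]


def make_templates(C: int, K: int, max_xcorr: float = 0.3, seed: int = 0) -> np.ndarray:
    """K unit-norm, zero-mean template topographies with bounded pairwise |r|.

    Rows are drawn in the zero-sum subspace and redrawn (bounded retries)
    until every pairwise absolute Pearson correlation is at most
    ``max_xcorr``; an exactly orthogonal construction is the fallback, so
    the constraint is always met.  Deterministic given ``seed``.
    """
    if not 0 < max_xcorr < 1:
        raise ValueError("max_xcorr must be in (0, 1)")
    if K >= C:
        raise ValueError("need K < C")
    rng = np.random.default_rng(seed)

    def _draw() -> np.ndarray:
        t = rng.standard_normal((K, C))
        t -= t.mean(axis=1, keepdims=True)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        return t

    for _ in range(200):
        t = _draw()
        corr = t @ t.T
        np.fill_diagonal(corr, 0.0)
        if np.all(np.abs(corr) <= max_xcorr):
            return t
    # fallback: exact orthogonal set inside the zero-sum subspace
    g = rng.standard_normal((C, K))
    g -= g.mean(axis=0, keepdims=True)
    q, _ = np.linalg.qr(g)
    t = q.T[:K]
    t -= t.mean(axis=1, keepdims=True)
    t /= np.linalg.norm(t, axis=1, keepdims=True)
    corr = t @ t.T
    np.fill_diagonal(corr, 0.0)
    if not np.all(np.abs(corr) <= max_xcorr):
        raise RuntimeError(f"could not build {K} templates with |r| <= {max_xcorr}")
    return t


def _segment_envelope(length: int, ramp: int) -> np.ndarray:
    """Hann on/off ramps over the first/last ``ramp`` samples of a segment."""
    env = np.ones(length)
    r = min(ramp, length // 2)
    if r > 0:
        win = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = win
        env[length - r:] = win[::-1]
    return env


def simulate_microstate_eeg(spec: SyntheticSpec) -> tuple[EEGRecording, GroundTruth]:
    """Generate a recording as a label-switching sequence of template bursts.

    Segment durations are gamma(shape, mean/shape) in ms, rounded to whole
    samples (minimum 1); consecutive segments never repeat a class; each
    segment's source is a sinusoid at a frequency drawn uniformly from the
    class's band, with Hann on/off ramps; white Gaussian sensor noise is
    added per channel.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    templates = (
        spec.templates
        if spec.templates is not None
        else make_templates(spec.C, spec.K, spec.max_xcorr, seed=spec.seed)
    )
    if templates.shape != (spec.K, spec.C):
        raise ValueError("templates shape must be (K, C)")

    scale_ms = spec.duration_mean_ms / spec.duration_shape
    ramp = int(round(spec.ramp_ms * spec.fs / 1000.0))

    labels = np.empty(n, dtype=int)
    freqs = np.empty(n)
    data = np.zeros((spec.C, n))
    segments: list[tuple[int, int, int]] = []
    t0 = 0
    prev = -1
    while t0 < n:
        dur_ms = rng.gamma(spec.duration_shape, scale_ms)
        length = max(1, int(round(dur_ms * spec.fs / 1000.0)))
        length = min(length, n - t0)
        if length == 0:
            break
        choices = [k for k in range(spec.K) if k != prev] or list(range(spec.K))
        k = int(rng.choice(choices))
        lo, hi = spec.band_for_class(k)
        f = float(rng.uniform(lo, hi))
        phase = float(rng.uniform(0, 2 * np.pi))
        t = np.arange(t0, t0 + length) / spec.fs
        s = spec.amplitude * _segment_envelope(length, ramp) * np.sin(2 * np.pi * f * t + phase)
        data[:, t0 : t0 + length] += np.outer(templates[k], s)
        labels[t0 : t0 + length] = k
        freqs[t0 : t0 + length] = f
        segments.append((k, t0, length))
        prev = k
        t0 += length
    if segments and segments[0][2] == n:
        raise ValueError("duration too short: a single segment covers the recording")

    if spec.noise_sigma > 0:
        data += spec.noise_sigma * rng.standard_normal(data.shape)

    rows = []
    dur_total = n / spec.fs
    for k in range(spec.K):
        k_segs = [ln for c, _, ln in segments if c == k]
        covered = sum(k_segs)
        rows.append(
            {
                "class": k,
                "MD_ms": (covered / len(k_segs)) * 1000.0 / spec.fs if k_segs else np.nan,
                "OPS_per_s": len(k_segs) / dur_total,
                "TCR": covered / n,
            }
        )
    truth = GroundTruth(labels, templates, pd.DataFrame(rows), freqs, segments)
    labels_txt = [f"ch{i}" for i in range(spec.C)]
    return EEGRecording(data, spec.fs, labels_txt), truth


def noise_sigma_for_snr(spec: SyntheticSpec, snr: float) -> float:
    """Per-channel noise std giving RMS(signal)/RMS(noise) == snr.

    Computed from a noiseless render of the same spec (same seed, so the
    segment sequence is identical).
    """
    from dataclasses import replace

    clean, _ = simulate_microstate_eeg(replace(spec, noise_sigma=0.0))
    return float(np.sqrt(np.mean(clean.data**2)) / snr)


def simulate_band_mixture(
    tones: list[tuple[float, float]],
    fs: float,
    duration: float,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sum of sinusoids (frequency, amplitude) with seeded phases plus noise."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    out = np.zeros(n)
    for f, amp in tones:
        if f >= fs / 2:
            raise ValueError(f"tone at {f} Hz aliases at fs={fs}")
        phase = rng.uniform(0, 2 * np.pi)
        out += amp * np.sin(2 * np.pi * f * t + phase)
    if noise_sigma > 0:
        out += noise_sigma * rng.standard_normal(n)
    return out
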