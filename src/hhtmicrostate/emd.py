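"""Empirical mode decomposition, CEEMDAN, and mutual-information IMF selection.

The sifting implementation follows the classic scheme: intrinsic mode
functions (IMFs) are extracted by repeatedly subtracting the mean of the
upper and lower cubic-spline envelopes until a Cauchy-style SD criterion is
met.  CEEMDAN (complete ensemble EMD with adaptive noise) averages the
first sifted mode over an ensemble of noise-perturbed copies at every
stage, where the stage-k perturbation is the k-th EMD mode of each white
noise realization.  Because every stage residual is defined by subtraction,
the decomposition reconstructs the input exactly (up to floating point).

Spurious low-information modes are screened by the mutual information
between each IMF and the original signal, estimated from an equal-width
2-D histogram in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "IMFSet",
    "MIResult",
    "sift_emd",
    "ceemdan_decompose",
    "mutual_information",
    "select_imfs",
    "default_max_imfs",
    "default_mi_bins",
]

# Classic Huang sifting defaults; the SD threshold is the Cauchy-style
# stopping criterion on consecutive sifting iterates.
SD_STOP_DEFAULT = 0.2
MAX_SIFT_ITERS_DEFAULT = 100
N_REALIZATIONS_DEFAULT = 50
# Noise std as a fraction of the (stage) signal std.  0.1 keeps a noise-free
# tone in a single mode; larger values make the ensemble noise strong enough
# to split tones across adjacent modes under this sifting configuration.
BETA_DEFAULT = 0.1
RETAIN_FRACTION_DEFAULT = 0.05


def default_max_imfs(n: int) -> int:
    """Default mode-count cap, floor(log2 N) - 1 (at least 1)."""
    return max(1, int(np.floor(np.log2(n))) - 1)


def default_mi_bins(n: int) -> int:
    """Histogram bin count max(8, ceil(sqrt N)), capped at 64."""
    return min(64, max(8, int(np.ceil(np.sqrt(n)))))


@dataclass
class IMFSet:
    """Ordered IMFs plus residual for one signal.

    IMFs run from highest to lowest characteristic frequency; their sum plus
    the residual reconstructs the source signal.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray
    source_length: int
    meta: dict = field(default_factory=dict)

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out

    def as_matrix(self) -> np.ndarray:
        """IMFs stacked as rows, residual last."""
        return np.vstack(self.imfs + [self.residual]) if self.imfs else self.residual[None, :]


@dataclass
class MIResult:
    """Per-IMF mutual information with the source, and the retention mask."""

    imi_values: np.ndarray
    bin_count: int
    kept_mask: np.ndarray


# ---------------------------------------------------------------------------
# extrema / envelopes / sifting
# ---------------------------------------------------------------------------


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (plateaus collapse to one index)."""
    dx = np.diff(x)
    sign = np.sign(dx)
    # propagate the previous non-zero slope through flat runs
    nonzero = sign != 0
    if not nonzero.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nonzero, np.arange(len(sign)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, sign[np.maximum(idx, 0)], 0)
    turn = filled[1:] * filled[:-1]
    cand = np.where(turn < 0)[0] + 1
    maxima = cand[filled[cand] < 0]  # rising then falling
    minima = cand[filled[cand] > 0]
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def _mirror_extend(idx: np.ndarray, val: np.ndarray, n: int, n_mirror: int = 2):
    """Mirror up to ``n_mirror`` extrema about each end of the support [0, n-1]."""
    left_i = (-idx[:n_mirror][::-1])[..., :]
    left_v = val[:n_mirror][::-1]
    right_i = 2 * (n - 1) - idx[-n_mirror:][::-1]
    right_v = val[-n_mirror:][::-1]
    ext_i = np.concatenate([left_i, idx, right_i])
    ext_v = np.concatenate([left_v, val, right_v])
    # mirroring can produce duplicate abscissae when an extremum sits at the edge
    ext_i, unique = np.unique(ext_i, return_index=True)
    return ext_i, ext_v[unique]


def _envelope_mean(x: np.ndarray) -> np.ndarray | None:
    """Mean of the cubic-spline upper and lower envelopes, or None if unsiftable."""
    maxima, minima = _local_extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    n = len(x)
    t = np.arange(n)
    mi, mv = _mirror_extend(maxima, x[maxima], n)
    upper = CubicSpline(mi, mv)(t)
    mi, mv = _mirror_extend(minima, x[minima], n)
    lower = CubicSpline(mi, mv)(t)
    return 0.5 * (upper + lower)


def _sift_one(
    r: np.ndarray, sd_stop: float, max_sift_iters: int
) -> np.ndarray | None:
    """Extract one IMF from ``r`` by sifting; None if ``r`` has too few extrema."""
    h = r
    for _ in range(max_sift_iters):
        mean = _envelope_mean(h)
        if mean is None:
            return None if h is r else h
        h_next = h - mean
        denom = np.sum(h * h) + 1e-300
        sd = np.sum(mean * mean) / denom
        h = h_next
        if sd < sd_stop:
            break
    return h


def _is_residual(x: np.ndarray) -> bool:
    maxima, minima = _local_extrema(x)
    return maxima.size + minima.size < 3


def sift_emd(
    signal: np.ndarray,
    max_imfs: int | None = None,
    sd_stop: float = SD_STOP_DEFAULT,
    max_sift_iters: int = MAX_SIFT_ITERS_DEFAULT,
) -> IMFSet:
    """Plain EMD: successive sifting until the residual is (near-)monotone.

    Each IMF approximately satisfies the two defining restrictions: the
    numbers of extrema and zero crossings differ by at most one, and the
    local envelope mean is close to zero.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.size < 8:
        raise ValueError("signal too short to place spline envelopes")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if max_imfs is None:
        max_imfs = default_max_imfs(x.size)
    if max_imfs < 1:
        raise ValueError("max_imfs must be >= 1")

    imfs: list[np.ndarray] = []
    r = x.copy()
    while len(imfs) < max_imfs and not _is_residual(r):
        imf = _sift_one(r, sd_stop, max_sift_iters)
        if imf is None:
            break
        imfs.append(imf)
        r = r - imf
    return IMFSet(imfs, r, x.size, meta={"method": "emd"})


# ---------------------------------------------------------------------------
# CEEMDAN
# ---------------------------------------------------------------------------


def ceemdan_decompose(
    signal: np.ndarray,
    n_realizations: int = N_REALIZATIONS_DEFAULT,
    beta: float = BETA_DEFAULT,
    seed: int = 0,
    max_imfs: int | None = None,
    sd_stop: float = SD_STOP_DEFAULT,
    max_sift_iters: int = MAX_SIFT_ITERS_DEFAULT,
) -> IMFSet:
    """Complete ensemble EMD with adaptive noise.

    Stage 1 averages the first EMD mode of ``x + beta*std(x)*w_j`` over the
    ensemble; stage k >= 2 perturbs the running residual with the k-th EMD
    mode of each noise realization, scaled to ``beta`` times the residual's
    standard deviation.  The final residual is defined by subtraction, so
    ``sum(imfs) + residual == signal`` to floating-point accuracy.
    Fully deterministic given ``seed``.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.size < 8:
        raise ValueError("signal too short to decompose")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    if n_realizations < 2:
        raise ValueError("n_realizations must be >= 2")
    if not 0 < beta < 1:
        raise ValueError("beta must be in (0, 1)")
    if max_imfs is None:
        max_imfs = default_max_imfs(x.size)

    meta = {
        "method": "ceemdan",
        "n_realizations": n_realizations,
        "noise_std_fraction": beta,
        "seed": seed,
    }
    sigma_x = float(np.std(x))
    if sigma_x == 0.0:  # degenerate constant input
        return IMFSet([], x.copy(), x.size, meta=meta)

    rng = np.random.default_rng(seed)
    noises = rng.standard_normal((n_realizations, x.size))
    # modes of each unit-variance noise realization, reused at every stage
    noise_modes = [
        sift_emd(w, max_imfs=max_imfs, sd_stop=sd_stop, max_sift_iters=max_sift_iters).imfs
        for w in noises
    ]

    imfs: list[np.ndarray] = []
    r = x.copy()
    for k in range(max_imfs):
        if _is_residual(r):
            break
        scale = beta * float(np.std(r)) if k > 0 else beta * sigma_x
        acc = np.zeros_like(x)
        count = 0
        for j in range(n_realizations):
            modes_j = noise_modes[j]
            perturb = scale * modes_j[k] if k < len(modes_j) else 0.0
            imf_j = _sift_one(r + perturb, sd_stop, max_sift_iters)
            if imf_j is None:
                imf_j = r + perturb  # unsiftable: treat the stage input as the mode
            acc += imf_j
            count += 1
        imf_k = acc / count
        imfs.append(imf_k)
        r = r - imf_k

    residual = x - np.sum(imfs, axis=0) if imfs else x.copy()
    return IMFSet(imfs, residual, x.size, meta=meta)


# ---------------------------------------------------------------------------
# mutual information and IMF selection
# ---------------------------------------------------------------------------


def mutual_information(imf: np.ndarray, signal: np.ndarray, n_bins: int | None = None) -> float:
    """Histogram mutual information (nats) between an IMF and the source signal.

    Uses equal-width binning per variable over its own range; empty cells
    contribute zero.  A pair of constant series has zero MI by convention.
    """
    a = np.asarray(imf, dtype=np.float64)
    b = np.asarray(signal, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("imf and signal must have equal length")
    if n_bins is None:
        n_bins = default_mi_bins(a.size)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(a, b, bins=n_bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / (px @ py)[mask])))


def select_imfs(
    imfset: IMFSet,
    signal: np.ndarray,
    n_bins: int | None = None,
    retain_fraction: float = RETAIN_FRACTION_DEFAULT,
) -> tuple[IMFSet, MIResult]:
    """Screen out low-information IMFs by mutual information with the source.

    IMFs with MI below ``retain_fraction`` times the maximum MI are folded
    into the residual, so the reconstruction identity is preserved.
    ``retain_fraction = 0`` keeps everything.
    """
    if imfset.n_imfs == 0:
        raise ValueError("empty IMF set")
    if not 0 <= retain_fraction <= 1:
        raise ValueError("retain_fraction must be in [0, 1]")
    x = np.asarray(signal, dtype=np.float64)
    if n_bins is None:
        n_bins = default_mi_bins(x.size)
    imi = np.array([mutual_information(imf, x, n_bins) for imf in imfset.imfs])
    threshold = retain_fraction * imi.max()
    kept = imi >= threshold
    if retain_fraction == 0:
        kept[:] = True

    new_residual = imfset.residual.copy()
    kept_imfs = []
    for keep, imf in zip(kept, imfset.imfs):
        if keep:
            kept_imfs.append(imf)
        else:
            new_residual += imf
    meta = dict(imfset.meta)
    meta["kept_mask"] = kept.tolist()
    meta["imi_values"] = imi.tolist()
    selected = IMFSet(kept_imfs, new_residual, imfset.source_length, meta=meta)
    return selected, MIResult(imi, n_bins, kept)
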