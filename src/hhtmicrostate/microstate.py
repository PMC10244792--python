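"""Polarity-invariant EEG microstate analysis.

Multichannel EEG is modeled as a sequence of quasi-stable scalp
topographies.  The analysis pipeline is the standard one:

1. global field power (GFP) — the per-sample standard deviation across
   electrodes — and its local maxima, the high-SNR moments;
2. modified k-means clustering of the average-referenced GFP-peak maps,
   where assignment uses squared spatial correlation (polarity ignored)
   and each template is the dominant eigenvector of its cluster's map
   covariance;
3. model selection over the cluster count K by global explained variance
   (GEV) and the cross-validation (CV) criterion;
4. backfitting every sample to its best template and extraction of the
   temporal parameters: mean duration (MD, ms), occurrences per second
   (OPS, /s), time-coverage ratio (TCR, fraction) and per-class GEV (%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EEGRecording

__all__ = [
    "GFPSeries",
    "PeakMaps",
    "MicrostateModel",
    "LabelSequence",
    "MicrostateParams",
    "gfp",
    "find_gfp_peaks",
    "extract_peak_maps",
    "modified_kmeans",
    "gev",
    "cv_criterion",
    "select_k",
    "backfit",
    "microstate_parameters",
    "segment_runs",
]

UNASSIGNED = -1


@dataclass
class GFPSeries:
    """Global field power over time with detected peak indices."""

    values: np.ndarray
    fs: float
    peak_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


@dataclass
class PeakMaps:
    """Average-referenced topographies at GFP peaks (N_p x C)."""

    maps: np.ndarray
    source_indices: np.ndarray
    normalized: bool = False

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class MicrostateModel:
    """K unit-norm average-referenced template topographies with fit statistics."""

    templates: np.ndarray  # K x C
    labels: np.ndarray     # over the fitted samples
    gev_total: float
    gev_per_class: np.ndarray
    cv: float
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.templates.shape[0]

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate labels (0-based; UNASSIGNED = -1) and derived runs."""

    labels: np.ndarray
    fs: float

    @property
    def segments(self) -> list[tuple[int, int, int]]:
        """Runs as (class, start sample, length), tiling the labeled samples."""
        return segment_runs(self.labels)


@dataclass
class MicrostateParams:
    """Per-class temporal parameters; table rows ordered by class index."""

    table: pd.DataFrame  # columns: class, MD_ms, OPS_per_s, TCR, GEV_pct

    def per_class(self, k: int) -> dict:
        row = self.table[self.table["class"] == k]
        return row.iloc[0].to_dict()


# ---------------------------------------------------------------------------
# GFP and peak maps
# ---------------------------------------------------------------------------


def gfp(rec: EEGRecording) -> GFPSeries:
    """GFP(t): standard deviation of potentials across electrodes at each sample."""
    values = rec.data.std(axis=0, ddof=0)
    return GFPSeries(values, rec.fs)


def find_gfp_peaks(g: GFPSeries, min_distance_samples: int = 0) -> np.ndarray:
    """Local maxima of the GFP curve: g[t-1] < g[t] >= g[t+1] (plateaus keep
    their first sample).  With a minimum distance, peaks are kept greedily
    from highest to lowest."""
    v = g.values
    if v.size < 3:
        raise ValueError("need at least 3 samples to find peaks")
    idx = np.where((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:]))[0] + 1
    if min_distance_samples > 0 and idx.size > 1:
        order = idx[np.argsort(v[idx])[::-1]]
        kept: list[int] = []
        for i in order:
            if all(abs(i - j) >= min_distance_samples for j in kept):
                kept.append(i)
        idx = np.array(sorted(kept), dtype=int)
    g.peak_indices = idx
    return idx


def extract_peak_maps(rec: EEGRecording, peaks: np.ndarray) -> PeakMaps:
    """Average-referenced topographies at the given peak samples."""
    peaks = np.asarray(peaks, dtype=int)
    if peaks.size == 0:
        raise ValueError("empty peak list")
    maps = rec.data[:, peaks].T.copy()
    maps -= maps.mean(axis=1, keepdims=True)
    return PeakMaps(maps, peaks)


# ---------------------------------------------------------------------------
# modified k-means
# ---------------------------------------------------------------------------


def _fix_sign(template: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| component positive."""
    i = int(np.argmax(np.abs(template)))
    return template if template[i] >= 0 else -template


def _dominant_eigvec(X: np.ndarray) -> np.ndarray:
    """Unit dominant right singular vector of the map block X (rows = maps)."""
    # SVD of the thin block is cheaper and more stable than forming X^T X
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return _fix_sign(vt[0])


def _sigma2(X: np.ndarray, templates: np.ndarray, labels: np.ndarray) -> float:
    """Residual noise variance: sum(x'x - (a'x)^2) / (N (C-1))."""
    n, c = X.shape
    proj = np.einsum("nc,nc->n", X, templates[labels])
    total = np.einsum("nc,nc->n", X, X)
    return float(np.sum(total - proj**2) / (n * (c - 1)))


def _assign(X: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Polarity-invariant assignment: argmax (x' a_k)^2; ties -> lowest index."""
    proj = X @ templates.T
    return np.argmax(proj**2, axis=1)


def modified_kmeans(
    maps: PeakMaps | np.ndarray,
    K: int,
    n_restarts: int = 20,
    max_iters: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> MicrostateModel:
    """Polarity-invariant modified k-means on topographic maps.

    Assignment maximizes the squared spatial projection; template update is
    the dominant eigenvector of the within-cluster map covariance.  Each
    restart iterates until the relative change of the residual variance
    falls below ``tol``; the best restart by total GEV is returned.
    Deterministic given ``seed``.
    """
    X = maps.maps if isinstance(maps, PeakMaps) else np.asarray(maps, dtype=np.float64)
    X = X - X.mean(axis=1, keepdims=True)
    n, c = X.shape
    if not 1 <= K <= min(n, c - 2):
        raise ValueError(f"K={K} out of range for {n} maps, {c} channels")
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0):
        raise ValueError("degenerate all-zero map in input")

    rng = np.random.default_rng(seed)
    best: MicrostateModel | None = None
    for restart in range(n_restarts):
        init = rng.choice(n, size=K, replace=False)
        templates = np.array([_fix_sign(X[i] / norms[i]) for i in init])
        labels = _assign(X, templates)
        prev_s2 = np.inf
        converged = False
        n_iter = 0
        trajectory: list[float] = []
        for n_iter in range(1, max_iters + 1):
            for k in range(K):
                members = labels == k
                if not members.any():
                    # reseed an empty cluster from the worst-explained map
                    proj = np.einsum("nc,nc->n", X, templates[labels])
                    resid = np.einsum("nc,nc->n", X, X) - proj**2
                    worst = int(np.argmax(resid))
                    templates[k] = _fix_sign(X[worst] / norms[worst])
                else:
                    templates[k] = _dominant_eigvec(X[members])
            labels = _assign(X, templates)
            s2 = _sigma2(X, templates, labels)
            trajectory.append(s2)
            if prev_s2 < np.inf and abs(prev_s2 - s2) <= tol * max(prev_s2, 1e-300):
                converged = True
                break
            prev_s2 = s2

        total, per_class = gev(X, templates, labels)
        if best is None or total > best.gev_total:
            cv = cv_criterion(X, templates, labels) if K < c - 1 else np.nan
            best = MicrostateModel(
                templates.copy(),
                labels.copy(),
                total,
                per_class,
                cv,
                meta={
                    "restarts": n_restarts,
                    "restart": restart,
                    "iterations": n_iter,
                    "seed": seed,
                    "converged": converged,
                    "sigma2_trajectory": trajectory,
                },
            )
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# fit statistics
# ---------------------------------------------------------------------------


def _spatial_corr(X: np.ndarray, templates: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Spatial Pearson correlation of each map with its assigned template."""
    Xc = X - X.mean(axis=1, keepdims=True)
    T = templates - templates.mean(axis=1, keepdims=True)
    a = T[labels]
    num = np.einsum("nc,nc->n", Xc, a)
    den = np.linalg.norm(Xc, axis=1) * np.linalg.norm(a, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(den > 0, num / den, 0.0)
    return corr


def gev(
    maps_or_rec: np.ndarray | EEGRecording,
    model_or_templates: MicrostateModel | np.ndarray,
    labels: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Global explained variance: GFP²-weighted squared spatial correlation.

    ``GEV = sum_n (GFP_n * corr(x_n, a_{l_n}))^2 / sum_n GFP_n^2``; per-class
    terms restrict the numerator to the samples assigned to that class.
    Unassigned samples (label < 0) contribute to the denominator only.
    """
    if isinstance(maps_or_rec, EEGRecording):
        X = maps_or_rec.data.T
    else:
        X = np.asarray(maps_or_rec, dtype=np.float64)
    templates = (
        model_or_templates.templates
        if isinstance(model_or_templates, MicrostateModel)
        else np.asarray(model_or_templates)
    )
    labels = np.asarray(labels, dtype=int)
    Xc = X - X.mean(axis=1, keepdims=True)
    c = X.shape[1]
    gfp_n = np.linalg.norm(Xc, axis=1) / np.sqrt(c)  # std across channels
    denom = float(np.sum(gfp_n**2))
    if denom == 0:
        raise ValueError("zero total GFP")
    K = templates.shape[0]
    assigned = labels >= 0
    corr = np.zeros(X.shape[0])
    corr[assigned] = _spatial_corr(Xc[assigned], templates, labels[assigned])
    contrib = (gfp_n * corr) ** 2
    per_class = np.array(
        [float(np.sum(contrib[(labels == k)])) for k in range(K)]
    ) / denom
    return float(np.sum(contrib[assigned]) / denom), per_class


def cv_criterion(
    maps: np.ndarray | EEGRecording,
    model_or_templates: MicrostateModel | np.ndarray,
    labels: np.ndarray,
) -> float:
    """Cross-validation criterion: sigma^2 * ((C-1)/(C-K-1))^2.

    ``sigma^2 = sum_n (x_n'x_n - (a_{l_n}'x_n)^2) / (N (C-1))`` — the
    residual variance after projecting each map on its template.  Smaller
    is better; the factor penalizes larger template counts.
    """
    X = maps.data.T if isinstance(maps, EEGRecording) else np.asarray(maps, dtype=np.float64)
    templates = (
        model_or_templates.templates
        if isinstance(model_or_templates, MicrostateModel)
        else np.asarray(model_or_templates)
    )
    labels = np.asarray(labels, dtype=int)
    n, c = X.shape
    K = templates.shape[0]
    if c - K - 1 <= 0:
        raise ValueError(f"CV undefined for K={K} with {c} channels (need K < C-1)")
    Xc = X - X.mean(axis=1, keepdims=True)
    s2 = _sigma2(Xc, templates, labels)
    return float(s2 * ((c - 1) / (c - K - 1)) ** 2)


def select_k(
    maps: PeakMaps | np.ndarray,
    k_range: Sequence[int] = range(2, 9),
    n_restarts: int = 20,
    max_iters: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[int, pd.DataFrame, dict[int, MicrostateModel]]:
    """Fit every K in ``k_range``; return the K minimizing CV plus the GEV/CV table.

    All fits share the seed policy ``seed + K`` so runs are reproducible and
    independent of the range ordering.  The full table is returned so other
    selection heuristics can be applied downstream.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    rows = []
    models: dict[int, MicrostateModel] = {}
    for K in k_range:
        model = modified_kmeans(
            maps, K, n_restarts=n_restarts, max_iters=max_iters, tol=tol, seed=seed + K
        )
        models[K] = model
        rows.append({"K": K, "gev_total": model.gev_total, "cv": model.cv})
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["cv"].idxmin(), "K"])
    return best_k, table, models


# ---------------------------------------------------------------------------
# backfitting and temporal parameters
# ---------------------------------------------------------------------------


def segment_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Decompose a label series into runs (class, start, length)."""
    runs = []
    n = len(labels)
    i = 0
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        runs.append((int(labels[i]), i, j - i))
        i = j
    return runs


def backfit(
    model: MicrostateModel,
    rec: EEGRecording,
    min_segment_samples: int = 0,
) -> LabelSequence:
    """Label every sample with its best template by squared spatial correlation.

    Polarity and overall scale of the recording are ignored.  When
    ``min_segment_samples > 0``, runs shorter than that are absorbed into
    the neighboring run whose template correlates better, repeated until
    stable.
    """
    if model.n_channels != rec.n_channels:
        raise ValueError(
            f"model has {model.n_channels} channels, recording has {rec.n_channels}"
        )
    X = rec.data.T - rec.data.T.mean(axis=1, keepdims=True)
    T = model.templates - model.templates.mean(axis=1, keepdims=True)
    Tn = T / np.linalg.norm(T, axis=1, keepdims=True)
    proj = X @ Tn.T
    labels = np.argmax(proj**2, axis=1)

    if min_segment_samples > 0:
        corr2 = proj**2  # ||x|| factor is label-independent
        # absorb the shortest sub-threshold run into its better-correlating
        # neighbor, one at a time; every merge removes a run boundary, so
        # the loop terminates
        while True:
            change = np.flatnonzero(np.diff(labels)) + 1
            starts = np.concatenate([[0], change])
            lengths = np.diff(np.concatenate([starts, [len(labels)]]))
            if len(starts) == 1:
                break
            short = np.flatnonzero(lengths < min_segment_samples)
            if short.size == 0:
                break
            i = int(short[np.argmin(lengths[short])])
            sl = slice(int(starts[i]), int(starts[i] + lengths[i]))
            left = int(labels[starts[i] - 1]) if i > 0 else None
            right = int(labels[starts[i] + lengths[i]]) if i < len(starts) - 1 else None
            if left is None:
                target = right
            elif right is None:
                target = left
            else:
                target = left if corr2[sl, left].mean() >= corr2[sl, right].mean() else right
            labels[sl] = target
    return LabelSequence(labels, rec.fs)


def microstate_parameters(
    seq: LabelSequence,
    rec: EEGRecording,
    model: MicrostateModel,
) -> MicrostateParams:
    """Per-class MD (ms), OPS (/s), TCR (fraction) and GEV (%) from a backfit.

    MD is the mean run length in ms; OPS the run count per second of
    recording; TCR the fraction of samples covered; GEV the class's share
    of explained variance over all samples, in percent.  The identity
    ``TCR = OPS * MD / 1000`` holds exactly for every present class.
    Boundary-truncated runs count like any other run.
    """
    labels = seq.labels
    n = len(labels)
    if n != rec.n_samples:
        raise ValueError("label sequence and recording length differ")
    duration_s = n / seq.fs
    runs = segment_runs(labels)
    _, gev_per_class = gev(rec, model, labels)

    rows = []
    for k in range(model.n_states):
        k_runs = [(c, s, ln) for c, s, ln in runs if c == k]
        count = len(k_runs)
        covered = sum(ln for _, _, ln in k_runs)
        if count == 0:
            md = np.nan
            ops = 0.0
            tcr = 0.0
        else:
            md = (covered / count) * 1000.0 / seq.fs
            ops = count / duration_s
            tcr = covered / n
        rows.append(
            {
                "class": k,
                "MD_ms": md,
                "OPS_per_s": ops,
                "TCR": tcr,
                "GEV_pct": 100.0 * gev_per_class[k],
            }
        )
    return MicrostateParams(pd.DataFrame(rows))
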