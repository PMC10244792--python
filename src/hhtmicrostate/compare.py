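"""Topographic similarity, permutation testing, and method-comparison tables.

The similarity index between two scalp topographies is the absolute spatial
Pearson correlation of the average-referenced maps — polarity-invariant,
scale-invariant, bounded in [0, 1].  Group differences in topography are
tested by a permutation test on the similarity of the two groups'
mean-templates, where a mean-template is the dominant eigenvector of the
set's map covariance (polarity-safe averaging) and the null distribution
shuffles set membership.  Small observed similarity signals a difference,
so the p-value is the fraction of shuffles at least as dissimilar.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .microstate import MicrostateModel, MicrostateParams

__all__ = [
    "SimilarityResult",
    "similarity_index",
    "similarity_matrix",
    "permutation_test_similarity",
    "band_gev_table",
    "export_features",
]


@dataclass
class SimilarityResult:
    index: float
    p_value: float | None
    n_permutations: int
    seed: int


def _centre(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def similarity_index(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Absolute spatial Pearson correlation of two average-referenced maps."""
    a = _centre(np.asarray(map_a, dtype=np.float64))
    b = _centre(np.asarray(map_b, dtype=np.float64))
    if a.shape != b.shape:
        raise ValueError("maps must share the channel count")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance map")
    return float(abs(a @ b) / (na * nb))


def similarity_matrix(
    templates_a: MicrostateModel | np.ndarray,
    templates_b: MicrostateModel | np.ndarray,
) -> np.ndarray:
    """K_a x K_b matrix of pairwise similarity indices."""
    A = templates_a.templates if isinstance(templates_a, MicrostateModel) else np.asarray(templates_a)
    B = templates_b.templates if isinstance(templates_b, MicrostateModel) else np.asarray(templates_b)
    if A.shape[1] != B.shape[1]:
        raise ValueError("template sets must share the channel count")
    out = np.empty((A.shape[0], B.shape[0]))
    for i in range(A.shape[0]):
        for j in range(B.shape[0]):
            out[i, j] = similarity_index(A[i], B[j])
    return out


def _mean_template(maps: np.ndarray) -> np.ndarray:
    """Polarity-safe average of a map set: dominant eigenvector of sum x x'."""
    X = maps - maps.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    return vt[0]


def permutation_test_similarity(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> SimilarityResult:
    """Permutation test for topographic difference between two map sets.

    The statistic is the similarity index between the two groups' mean
    topographies, where every map's polarity is first aligned against the
    pooled dominant eigenvector (a permutation-invariant reference, so the
    statistic is exchangeable under membership shuffling).  The null is
    built by shuffling set membership ``n_perm`` times; since small
    similarity indicates a difference, the p-value is
    ``(#{null <= observed} + 1) / (n_perm + 1)``.  Deterministic given
    ``seed``.
    """
    A = np.asarray(maps_a, dtype=np.float64)
    B = np.asarray(maps_b, dtype=np.float64)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("map sets must be 2-D with a common channel count")
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each set needs at least 2 maps")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")

    pool = np.vstack([A, B])
    pool = pool - pool.mean(axis=1, keepdims=True)
    n_a, n_tot = len(A), len(pool)
    # polarity alignment against the pooled dominant eigenvector; the
    # reference does not depend on the A/B split
    ref = _mean_template(pool)
    signs = np.where(pool @ ref >= 0, 1.0, -1.0)
    aligned = pool * signs[:, None]

    def _stat(ma: np.ndarray, mb: np.ndarray) -> np.ndarray:
        ma = ma - ma.mean(axis=-1, keepdims=True)
        mb = mb - mb.mean(axis=-1, keepdims=True)
        num = np.abs(np.einsum("...c,...c->...", ma, mb))
        den = (np.linalg.norm(ma, axis=-1) * np.linalg.norm(mb, axis=-1))
        return num / (den + 1e-300)

    observed = float(_stat(aligned[:n_a].mean(axis=0), aligned[n_a:].mean(axis=0)))

    rng = np.random.default_rng(seed)
    # permutation index matrix: each row one shuffle of the pooled membership
    perm = np.argsort(rng.random((n_perm, n_tot)), axis=1)
    null = _stat(aligned[perm[:, :n_a]].mean(axis=1),
                 aligned[perm[:, n_a:]].mean(axis=1))

    p = (np.sum(null <= observed) + 1) / (n_perm + 1)
    return SimilarityResult(observed, float(p), n_perm, seed)


def band_gev_table(models_by_frontend: Mapping[str, Mapping[str, MicrostateModel]]) -> pd.DataFrame:
    """Total GEV (percent) per band and front-end, for HHT-vs-FIR comparison.

    ``models_by_frontend`` maps front-end name ("hht", "fir", ...) to a
    mapping band name -> fitted model.  One row per band, one GEV column
    per front-end.
    """
    frontends = list(models_by_frontend)
    bands: list[str] = []
    for fe in frontends:
        for band in models_by_frontend[fe]:
            if band not in bands:
                bands.append(band)
    rows = []
    for band in bands:
        row: dict = {"band": band}
        for fe in frontends:
            model = models_by_frontend[fe].get(band)
            row[f"gev_pct_{fe}"] = 100.0 * model.gev_total if model is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def export_features(
    params_by_recording: Sequence[Mapping[str, MicrostateParams]],
    groups: Sequence[str],
    select: Sequence[tuple[str, int, str]] | None = None,
) -> pd.DataFrame:
    """Flatten per-recording, per-band microstate parameters into a feature table.

    One row per recording; columns named ``{band}_c{class}_{param}`` for the
    parameters MD_ms / OPS_per_s / TCR / GEV_pct, plus a ``group`` label
    column.  ``select`` optionally restricts to (band, class, parameter)
    triples; column order is deterministic.
    """
    if len(params_by_recording) != len(groups):
        raise ValueError("one group label per recording required")
    param_names = ["MD_ms", "OPS_per_s", "TCR", "GEV_pct"]
    rows = []
    schema: list[str] | None = None
    for rec_params, group in zip(params_by_recording, groups):
        row: dict = {}
        for band in rec_params:
            table = rec_params[band].table
            for _, r in table.iterrows():
                k = int(r["class"])
                for p in param_names:
                    if select is not None and (band, k, p) not in select:
                        continue
                    row[f"{band}_c{k}_{p}"] = r[p]
        cols = list(row)
        if schema is None:
            schema = cols
        elif cols != schema:
            raise ValueError("inconsistent feature schema across recordings")
        row["group"] = group
        rows.append(row)
    return pd.DataFrame(rows)
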