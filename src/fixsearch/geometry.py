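"""Representational similarity analysis and population geometry.

Representations live in "unit space": the population response to stimulus s
is the vector of mean firing rates of all units, and a stimulus set is a
point cloud in that space.  RSA compares dissimilarity matrices
(1 - Pearson r between population patterns) across populations with a
Spearman correspondence and a label-shuffling permutation test.  Geometry
summarizes attentional reshaping of the cloud through pairwise Euclidean
distances and the angles between population vectors, contrasted between
target and distractor fixations in the early (50-150 ms) and late
(150-225 ms) windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "DissimilarityMatrix",
    "GeometrySummary",
    "dissimilarity_matrix",
    "rsa_correspondence",
    "population_geometry",
    "geometry_contrast",
    "pca_embedding",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric stimulus-pair matrix of 1 - Pearson r, zero diagonal."""

    labels: np.ndarray
    values: np.ndarray

    @property
    def n(self) -> int:
        return len(self.labels)

    def lower_triangle(self) -> np.ndarray:
        i, j = np.tril_indices(self.n, k=-1)
        return self.values[i, j]


@dataclass
class GeometrySummary:
    """Pairwise distances and angles for one condition and window."""

    window: str  # early | late
    condition: str  # target | distractor
    pair_index: np.ndarray  # (n_pairs, 2) stimulus indices
    pair_distances: np.ndarray
    pair_angles_deg: np.ndarray
    undefined_pairs: np.ndarray  # pairs involving a zero vector


def dissimilarity_matrix(response: np.ndarray, labels=None) -> DissimilarityMatrix:
    """1 - Pearson correlation between per-stimulus population patterns.

    ``response`` is [n_units x n_stimuli]; entry (i, j) of the output is
    1 - r between columns i and j.
    """
    r = np.asarray(response, float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("response must be [n_units x n_stimuli] with >= 2 units")
    sd = r.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateInputError(
            f"stimulus column(s) {bad.tolist()} have zero variance across units"
        )
    labels = np.arange(r.shape[1]) if labels is None else np.asarray(labels)
    corr = np.corrcoef(r, rowvar=False)
    values = 1.0 - corr
    np.fill_diagonal(values, 0.0)
    values = 0.5 * (values + values.T)  # enforce exact symmetry
    return DissimilarityMatrix(labels=labels, values=values)


def rsa_correspondence(
    dm_a: DissimilarityMatrix,
    dm_b: DissimilarityMatrix,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple:
    """Spearman correspondence between two DMs with a permutation p-value.

    The observed rho is computed over the lower triangles.  The null
    shuffles the stimulus labels of one DM (rows and columns jointly) each
    run; ``p = fraction of null rho >= observed``.  Bonferroni correction
    across multiple comparisons is the caller's responsibility.
    """
    if dm_a.n != dm_b.n or not np.array_equal(
        np.sort(dm_a.labels), np.sort(dm_b.labels)
    ):
        raise ValueError("dissimilarity matrices must share their label set")
    # align dm_b to dm_a's label order: labels_b[order] == labels_a
    order = np.argsort(dm_b.labels)[np.argsort(np.argsort(dm_a.labels))]
    vals_b = dm_b.values[np.ix_(order, order)]
    i, j = np.tril_indices(dm_a.n, k=-1)
    rho = stats.spearmanr(dm_a.values[i, j], vals_b[i, j]).statistic
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = rng.permutation(dm_a.n)
        shuffled = vals_b[np.ix_(perm, perm)]
        null[k] = stats.spearmanr(dm_a.values[i, j], shuffled[i, j]).statistic
    p = float(np.mean(null >= rho))
    return float(rho), p


def population_geometry(
    response_target: np.ndarray,
    response_distractor: np.ndarray,
    window: str = "late",
) -> tuple:
    """Pairwise distances and angles of the population point clouds.

    Both inputs are [n_units x n_stimuli] over the same stimulus set.  For
    every stimulus pair (i, j) and each condition, the distance is
    ``||v_i - v_j||`` and the angle is ``arccos(v_i . v_j / |v_i||v_j|)``,
    where ``v_s`` is the population mean-rate vector of stimulus s.  Pairs
    involving a zero vector get NaN angles and are reported in
    ``undefined_pairs`` rather than dropped.
    """
    rt = np.asarray(response_target, float)
    rd = np.asarray(response_distractor, float)
    if rt.shape != rd.shape:
        raise ValueError("condition response matrices must have equal shape")

    def summarize(resp: np.ndarray, condition: str) -> GeometrySummary:
        n_stim = resp.shape[1]
        i, j = np.tril_indices(n_stim, k=-1)
        vi = resp[:, i]
        vj = resp[:, j]
        dist = np.linalg.norm(vi - vj, axis=0)
        ni = np.linalg.norm(vi, axis=0)
        nj = np.linalg.norm(vj, axis=0)
        undefined = (ni == 0) | (nj == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cosang = (vi * vj).sum(axis=0) / (ni * nj)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ang[undefined] = np.nan
        return GeometrySummary(
            window=window,
            condition=condition,
            pair_index=np.column_stack([i, j]),
            pair_distances=dist,
            pair_angles_deg=ang,
            undefined_pairs=np.column_stack([i, j])[undefined],
        )

    return summarize(rt, "target"), summarize(rd, "distractor")


def geometry_contrast(
    summary_target: GeometrySummary, summary_distractor: GeometrySummary
) -> dict:
    """Per-pair normalized contrasts and paired t tests, target vs distractor.

    Returns distance and angle contrasts
    ``(target - distractor) / (target + distractor)`` per stimulus pair plus
    two-tailed paired t statistics across pairs (df = n_pairs - 1).
    """
    if not np.array_equal(summary_target.pair_index, summary_distractor.pair_index):
        raise ValueError("summaries must cover the same stimulus pairs")

    def contrasts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        out = np.full(len(a), np.nan)
        ok = np.isfinite(a) & np.isfinite(b) & ((a + b) > 0)
        out[ok] = (a[ok] - b[ok]) / (a[ok] + b[ok])
        return out

    dist_c = contrasts(
        summary_target.pair_distances, summary_distractor.pair_distances
    )
    ang_c = contrasts(
        summary_target.pair_angles_deg, summary_distractor.pair_angles_deg
    )

    def paired_t(a: np.ndarray, b: np.ndarray) -> tuple:
        ok = np.isfinite(a) & np.isfinite(b)
        if np.allclose(a[ok], b[ok]):  # identical conditions: no effect
            return 0.0, 1.0, int(ok.sum()) - 1
        res = stats.ttest_rel(a[ok], b[ok])
        return float(res.statistic), float(res.pvalue), int(ok.sum()) - 1

    t_dist, p_dist, df_dist = paired_t(
        summary_target.pair_distances, summary_distractor.pair_distances
    )
    t_ang, p_ang, df_ang = paired_t(
        summary_target.pair_angles_deg, summary_distractor.pair_angles_deg
    )
    return {
        "window": summary_target.window,
        "distance_contrast": dist_c,
        "angle_contrast": ang_c,
        "t_distance": t_dist,
        "p_distance": p_dist,
        "df_distance": df_dist,
        "t_angle": t_ang,
        "p_angle": p_ang,
        "df_angle": df_ang,
    }


def pca_embedding(mean_responses: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Project stimuli onto the top principal components of the unit-space cloud.

    ``mean_responses`` is [n_units x n_stimuli]; the output is
    [n_stimuli x n_dims] coordinates for report plots.  If the cloud has
    fewer informative dimensions than requested, the embedding is truncated
    with a warning.
    """
    from sklearn.decomposition import PCA

    resp = np.asarray(mean_responses, float)
    if resp.shape[0] < n_dims:
        raise ValueError("need at least n_dims units")
    cloud = resp.T  # stimuli as points
    pca = PCA(n_components=min(n_dims, *cloud.shape))
    coords = pca.fit_transform(cloud)
    rank = int(np.sum(pca.explained_variance_ > 1e-12))
    if rank < n_dims:
        warnings.warn(
            f"point cloud supports only {rank} informative dimension(s); "
            f"embedding truncated",
            RuntimeWarning,
            stacklevel=2,
        )
        coords = coords[:, :max(rank, 1)]
    return coords
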