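"""Axis-coding detection: PLS encoding models with a split-and-permute test.

A unit "axis-codes" when its firing rate is a linear function of the
stimulus position along some axis of a high-dimensional visual feature
space.  Because the feature dimension (512 by default) far exceeds the
number of stimuli, the encoding model is fit by partial least squares
(SIMPLS, 4 components) from feature vectors to per-stimulus firing rates,
and significance is assessed with a permutation test: in each run the
stimulus labels are shuffled, the stimuli are split 50/50 into train/test,
and the Pearson correlation between predicted and actual held-out rates
forms the null distribution.  A unit is flagged when its observed held-out
correlation exceeds the 95th percentile of the null; the observed
correlation doubles as the strength of axis coding.

SIMPLS is implemented directly in numpy: the permutation procedure needs
on the order of 10^5 small fits, where per-call overhead dominates.  For a
univariate response SIMPLS coincides with NIPALS PLS1, which the test suite
exploits to cross-check coefficients against scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError

__all__ = ["PlsModel", "AxisFit", "fit_pls_encoding", "axis_permutation_test"]

ALPHA = 0.05


@dataclass
class PlsModel:
    """Fitted PLS regression from feature vectors to rates."""

    coefficients: np.ndarray  # (D,)
    intercept: float
    n_components: int

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, float) @ self.coefficients + self.intercept


@dataclass
class AxisFit:
    """Outcome of the axis-coding permutation test for one unit."""

    n_components: int
    coefficients: np.ndarray
    r_observed: float
    p_perm: float
    is_axis: bool
    strength: float  # == r_observed
    null_r: np.ndarray  # the permutation null distribution


def _simpls(x: np.ndarray, y: np.ndarray, n_components: int) -> tuple:
    """SIMPLS regression vector for a univariate response.

    Returns ``(beta, intercept)``.  Components whose scores vanish (rank
    exhausted) are dropped silently.
    """
    x_mean = x.mean(axis=0)
    y_mean = y.mean()
    x0 = x - x_mean
    y0 = y - y_mean
    d = x.shape[1]
    s = x0.T @ y0
    v_basis = np.empty((d, n_components))
    r_weights = np.empty((d, n_components))
    q_loadings = np.empty(n_components)
    used = 0
    for a in range(n_components):
        r = s.copy()
        t = x0 @ r
        norm_t = np.linalg.norm(t)
        if norm_t <= 1e-12 * max(1.0, np.linalg.norm(y0)):
            break
        t /= norm_t
        r /= norm_t
        p = x0.T @ t
        v = p.copy()
        if a > 0:
            vb = v_basis[:, :a]
            v -= vb @ (vb.T @ p)
        norm_v = np.linalg.norm(v)
        if norm_v <= 1e-12:
            break
        v /= norm_v
        s = s - v * (v @ s)
        r_weights[:, a] = r
        v_basis[:, a] = v
        q_loadings[a] = y0 @ t
        used += 1
    if used == 0:
        beta = np.zeros(d)
    else:
        beta = r_weights[:, :used] @ q_loadings[:used]
    return beta, float(y_mean - x_mean @ beta)


def fit_pls_encoding(
    features: np.ndarray, rates: np.ndarray, n_components: int = 4
) -> PlsModel:
    """Fit the PLS encoding model (centered SIMPLS) for one unit."""
    x = np.asarray(features, float)
    y = np.asarray(rates, float)
    if x.ndim != 2 or len(y) != x.shape[0]:
        raise ValueError("features must be [n_stimuli x D] matching rates")
    if x.shape[0] <= n_components:
        raise InsufficientDataError(
            f"need more than {n_components} stimuli, got {x.shape[0]}"
        )
    if np.ptp(y) == 0:
        raise DegenerateInputError("rates have zero variance")
    beta, intercept = _simpls(x, y, n_components)
    return PlsModel(coefficients=beta, intercept=intercept,
                    n_components=n_components)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0  # constant predictions carry no signal
    return float(a @ b / denom)


def _split_r(
    x: np.ndarray, y: np.ndarray, order: np.ndarray, n_components: int
) -> float:
    """Held-out prediction r for one 50/50 split (train = first half)."""
    half = len(y) // 2
    train, test = order[:half], order[half:]
    beta, intercept = _simpls(x[train], y[train], n_components)
    pred = x[test] @ beta + intercept
    return _pearson(pred, y[test])


def axis_permutation_test(
    features: np.ndarray,
    rates: np.ndarray,
    n_components: int = 4,
    n_perm: int = 1000,
    seed: int = 0,
    observed: str = "single",
) -> AxisFit:
    """Axis-coding significance by split-and-permute.

    For each of ``n_perm`` runs the rates are shuffled relative to the
    feature rows, a random 50/50 train/test split is drawn, and the held-out
    prediction correlation enters the null distribution.  The observed
    statistic uses unshuffled rates: with ``observed="single"`` (default) it
    comes from one seed-fixed split, which keeps it exchangeable with
    single-run null draws and makes the null flag rate 5%; with
    ``observed="ensemble"`` it is the mean over the same splits as the null
    runs (lower variance, but conservative under the null because a mean of
    null draws almost never exceeds their 95th percentile).

    ``p_perm`` is the fraction of null correlations at or above the observed
    one; the unit is flagged when ``p_perm < 0.05``, i.e. when the observed
    correlation exceeds the 95th percentile of the null.
    """
    if observed not in ("single", "ensemble"):
        raise ValueError("observed must be 'single' or 'ensemble'")
    x = np.ascontiguousarray(np.asarray(features, float))
    y = np.asarray(rates, float)
    n = len(y)
    if x.shape[0] != n:
        raise ValueError("features and rates length mismatch")
    if n < 20:
        raise InsufficientDataError(f"need at least 20 stimuli, got {n}")
    if np.ptp(y) == 0:
        raise DegenerateInputError("rates have zero variance")

    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    obs_runs = np.empty(n_perm) if observed == "ensemble" else None
    r_single = _split_r(x, y, rng.permutation(n), n_components)
    for k in range(n_perm):
        order = rng.permutation(n)
        shuffle = rng.permutation(n)
        null_r[k] = _split_r(x, y[shuffle], order, n_components)
        if obs_runs is not None:
            obs_runs[k] = _split_r(x, y, order, n_components)
    r_observed = r_single if obs_runs is None else float(obs_runs.mean())

    p_perm = float(np.mean(null_r >= r_observed))
    model = fit_pls_encoding(x, y, n_components)
    return AxisFit(
        n_components=n_components,
        coefficients=model.coefficients,
        r_observed=float(r_observed),
        p_perm=p_perm,
        is_axis=bool(p_perm < ALPHA),
        strength=float(r_observed),
        null_r=null_r,
    )
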