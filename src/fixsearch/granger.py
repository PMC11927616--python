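"""Frequency-domain Granger causality between spike trains and LFPs.

Pipeline per spike-LFP pair and condition: fixation-aligned 200 ms segments
are detrended (per-segment least-squares line), ensemble-demeaned (the
across-segment mean waveform is subtracted sample-wise) and KPSS-screened
for level stationarity; spikes are binned at the LFP rate and demeaned per
segment.  A bivariate VAR is then fit by least squares pooled across the
surviving segments (no regression across segment boundaries), its order
chosen by AIC.  Spectral Granger causality follows the transfer-matrix
formula

    G_{j->i}(f) = -ln( 1 - (Sigma_jj - Sigma_ij^2 / Sigma_ii) |H_ij(f)|^2
                       / S_ii(f) )

with H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1} and S = H Sigma H*.
A time-domain Geweke measure (log ratio of restricted to full residual
variance) serves as an independent consistency oracle: the frequency
integral of G over [-fs/2, fs/2] / fs should match it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .errors import (
    DegenerateInputError,
    InsufficientDataError,
    UnstableModelError,
)
from .rates import normalized_contrast

__all__ = [
    "VarModel",
    "GcEstimate",
    "preprocess_segments",
    "kpss_screen",
    "fit_var",
    "spectral_granger",
    "time_domain_granger_oracle",
    "gc_contrast",
]

KPSS_CRIT_5PCT = 0.463  # level-stationarity 5% critical value
THETA_BAND = (4.0, 12.0)


@dataclass
class VarModel:
    """Stable bivariate VAR: x_t = sum_k A_k x_{t-k} + e_t, cov(e) = Sigma."""

    order: int
    coefficients: np.ndarray  # (p, 2, 2)
    sigma: np.ndarray  # (2, 2)
    fs: float

    def companion_radius(self) -> float:
        p = self.order
        comp = np.zeros((2 * p, 2 * p))
        comp[:2, :] = np.concatenate(self.coefficients, axis=1)
        if p > 1:
            comp[2:, :-2] = np.eye(2 * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class GcEstimate:
    freqs: np.ndarray
    gc_x_to_y: np.ndarray
    gc_y_to_x: np.ndarray

    def band_mean(self, band=THETA_BAND) -> tuple:
        lo, hi = band
        mask = (self.freqs >= lo) & (self.freqs <= hi)
        if not mask.any():
            raise ValueError(f"band [{lo}, {hi}] Hz contains no frequency bins")
        return (
            float(self.gc_x_to_y[mask].mean()),
            float(self.gc_y_to_x[mask].mean()),
        )


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_segments(lfp_segments, spike_segments, fs: float = 1000.0):
    """Detrend, ensemble-demean and bin, returning per-segment (spike, lfp) pairs.

    ``lfp_segments`` is a list of equal-length sample arrays;
    ``spike_segments`` is a list of spike-time arrays (ms relative to segment
    onset).  Each LFP segment loses its least-squares line, then the
    across-segment ensemble mean; binned spike counts are demeaned per
    segment.  Returns a list of [T x 2] arrays with column 0 = spikes,
    column 1 = LFP.
    """
    if len(lfp_segments) < 2:
        raise InsufficientDataError(
            "ensemble demeaning needs at least two segments"
        )
    if len(lfp_segments) != len(spike_segments):
        raise ValueError("need one spike segment per LFP segment")
    n_win = len(lfp_segments[0])
    t = np.arange(n_win, dtype=float)
    t_c = t - t.mean()
    dt_ms = 1000.0 / fs
    detrended = []
    for seg in lfp_segments:
        seg = np.asarray(seg, float)
        if len(seg) != n_win:
            raise ValueError("all LFP segments must have equal length")
        slope = (t_c @ seg) / (t_c @ t_c)
        detrended.append(seg - (seg.mean() + slope * t_c))
    detrended = np.asarray(detrended)
    detrended -= detrended.mean(axis=0)  # ensemble mean, sample-wise

    out = []
    for lfp, spikes in zip(detrended, spike_segments):
        binned = np.bincount(
            np.clip((np.asarray(spikes, float) / dt_ms).astype(int), 0, n_win - 1),
            minlength=n_win,
        ).astype(float)
        binned -= binned.mean()
        out.append(np.column_stack([binned, lfp]))
    return out


def kpss_screen(segment: np.ndarray, min_len: int = 50) -> tuple:
    """KPSS level-stationarity statistic and flag for one segment.

    Uses the Bartlett-kernel long-run variance with lag
    ``floor(4 * (T/100)^(1/4))``; the segment is flagged non-stationary when
    the statistic exceeds the 5% critical value 0.463.
    Returns ``(statistic, stationary_flag)``.
    """
    from statsmodels.tsa.stattools import kpss

    segment = np.asarray(segment, float)
    t_len = len(segment)
    if t_len < min_len:
        raise InsufficientDataError(f"KPSS needs >= {min_len} samples, got {t_len}")
    if np.ptp(segment) == 0:
        return 0.0, True  # constant series is trivially level-stationary
    nlags = int(np.floor(4.0 * (t_len / 100.0) ** 0.25))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # p-value interpolation warnings
        stat, _, _, _ = kpss(segment, regression="c", nlags=nlags)
    return float(stat), bool(stat <= KPSS_CRIT_5PCT)


# ---------------------------------------------------------------------------
# VAR fitting


def _pooled_lagged(pairs, order: int) -> tuple:
    ys, xs = [], []
    for seg in pairs:
        t_len = seg.shape[0]
        if t_len <= order:
            continue
        y = seg[order:]
        x = np.concatenate(
            [seg[order - k:t_len - k] for k in range(1, order + 1)], axis=1
        )
        ys.append(y)
        xs.append(x)
    if not ys:
        raise InsufficientDataError("segments shorter than the VAR order")
    return np.concatenate(ys), np.concatenate(xs)


def fit_var(pairs, max_order: int = 15, fs: float = 1000.0) -> VarModel:
    """Bivariate VAR by pooled least squares with AIC order selection.

    ``pairs`` is a list of [T x 2] preprocessed arrays; lagged design rows
    never cross segment boundaries.  The selected model must be stable
    (companion spectral radius < 1).
    """
    pairs = [np.asarray(p, float) for p in pairs]
    pooled = np.concatenate(pairs, axis=0)
    if np.ptp(pooled, axis=0).min() == 0:  # empty single segments are fine
        raise DegenerateInputError("a channel is constant across all segments")
    best = None
    for p in range(1, max_order + 1):
        try:
            y, x = _pooled_lagged(pairs, p)
        except InsufficientDataError:
            break
        n_obs = y.shape[0]
        if n_obs <= 10 * (4 * p + 2):  # pre-condition on usable samples
            break
        coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
        if rank < x.shape[1]:
            raise DegenerateInputError("rank-deficient lagged design")
        resid = y - x @ coef
        sigma = resid.T @ resid / (n_obs - x.shape[1])
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise DegenerateInputError("singular residual covariance")
        aic = logdet + 2.0 * (4 * p) / n_obs
        if best is None or aic < best[0]:
            best = (aic, p, coef, sigma)
    if best is None:
        raise InsufficientDataError("not enough pooled samples for any order")
    _, p, coef, sigma = best
    a_mats = np.stack([coef[2 * k:2 * (k + 1)].T for k in range(p)])
    model = VarModel(order=p, coefficients=a_mats, sigma=sigma, fs=fs)
    if model.companion_radius() >= 1.0:
        raise UnstableModelError(
            f"VAR({p}) fit is unstable (spectral radius "
            f"{model.companion_radius():.3f})"
        )
    return model


# ---------------------------------------------------------------------------
# spectral Granger causality


def spectral_granger(model: VarModel, freqs: np.ndarray | None = None) -> GcEstimate:
    """Spectral GC in both directions on a frequency grid.

    Defaults to the coherence grid of a 200 ms window at the model's
    sampling rate (fs/200 Hz spacing up to Nyquist).  Raises a conditioning
    error naming the frequency if the transfer-matrix inversion is
    near-singular.
    """
    if freqs is None:
        n_win = int(round(0.2 * model.fs))
        freqs = np.fft.rfftfreq(n_win, d=1.0 / model.fs)
    freqs = np.asarray(freqs, float)
    sigma = model.sigma
    p = model.order
    gc = np.zeros((2, len(freqs)))
    eye = np.eye(2)
    for fi, f in enumerate(freqs):
        a_f = eye.astype(complex).copy()
        for k in range(1, p + 1):
            a_f -= model.coefficients[k - 1] * np.exp(
                -2j * np.pi * f * k / model.fs
            )
        if np.abs(np.linalg.det(a_f)) < 1e-12:
            raise DegenerateInputError(
                f"transfer-matrix inversion ill-conditioned at {f:g} Hz"
            )
        h = np.linalg.inv(a_f)
        s = h @ sigma @ h.conj().T
        for i in range(2):
            j = 1 - i
            corrected = sigma[j, j] - sigma[i, j] ** 2 / sigma[i, i]
            ratio = corrected * np.abs(h[i, j]) ** 2 / np.real(s[i, i])
            gc[j, fi] = -np.log(max(1.0 - ratio, 1e-300))
    # direction index: gc[src, :]; variable 0 = x, 1 = y
    return GcEstimate(freqs=freqs, gc_x_to_y=gc[0], gc_y_to_x=gc[1])


def time_domain_granger_oracle(pairs, max_order: int = 15) -> tuple:
    """Time-domain Geweke measures ln(var_restricted / var_full) per direction.

    The full model is the pooled bivariate VAR; the restricted model for
    each target variable is a univariate autoregression on its own past.
    Excluding the other variable turns the target's own process into an
    ARMA, so the restricted AR gets its own (longer) AIC-selected order —
    truncating it at the VAR's order would overstate the restricted
    residual variance.  Returns ``(gc_x_to_y, gc_y_to_x)``.
    """
    pairs = [np.asarray(p, float) for p in pairs]
    full = fit_var(pairs, max_order=max_order)
    p = full.order
    y_full, x_full = _pooled_lagged(pairs, p)
    max_r = max(4 * p, 20)
    out = []
    for i in (1, 0):  # target variable: first y (x->y), then x (y->x)
        coef_f, _, _, _ = np.linalg.lstsq(x_full, y_full[:, i], rcond=None)
        var_f = np.var(y_full[:, i] - x_full @ coef_f,
                       ddof=x_full.shape[1])
        best = None
        for q in range(1, max_r + 1):
            try:
                y_r, x_r = _pooled_lagged(pairs, q)
            except InsufficientDataError:
                break
            target = y_r[:, i]
            own = x_r[:, np.arange(q) * 2 + i]
            if target.size <= 10 * q:
                break
            coef_r, _, _, _ = np.linalg.lstsq(own, target, rcond=None)
            resid = target - own @ coef_r
            var_r = np.var(resid, ddof=own.shape[1])
            aic = np.log(var_r) + 2.0 * q / target.size
            if best is None or aic < best[0]:
                best = (aic, var_r)
        out.append(float(np.log(best[1] / var_f)))
    return out[0], out[1]


def geweke_integral(est: GcEstimate, fs: float) -> tuple:
    """Frequency integral of spectral GC over [-fs/2, fs/2] divided by fs.

    By Geweke's identity this matches the time-domain measure; the spectrum
    is symmetric, so the integral is 2/fs times the one over [0, fs/2].
    """
    scale = 2.0 / fs
    return (
        float(np.trapezoid(est.gc_x_to_y, est.freqs) * scale),
        float(np.trapezoid(est.gc_y_to_x, est.freqs) * scale),
    )


def gc_contrast(
    gc_distractor: GcEstimate, gc_target: GcEstimate, band=THETA_BAND
) -> dict:
    """Normalized band contrast (distractor - target)/(distractor + target).

    Band-means each estimate then forms the contrast per direction; positive
    values mean target fixations reduced the Granger influence.
    """
    if not np.array_equal(gc_distractor.freqs, gc_target.freqs):
        raise ValueError("estimates must share their frequency grid")
    d_xy, d_yx = gc_distractor.band_mean(band)
    t_xy, t_yx = gc_target.band_mean(band)
    return {
        "x_to_y": normalized_contrast(d_xy, t_xy),
        "y_to_x": normalized_contrast(d_yx, t_yx),
    }
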