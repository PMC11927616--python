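"""Fixation-windowed spike-LFP coherence.

Each fixation contributes one 200 ms window starting at fixation onset.  The
spike train is binned into delta counts at the LFP sampling rate, both
signals are mean-subtracted per window and Hanning-tapered, and auto- and
cross-spectra are averaged across fixations before forming

    C_xy(f) = |S_xy(f)| / sqrt(S_x(f) * S_y(f))

which is bounded in [0, 1].  To remove sample-size bias between conditions,
the two conditions are equalized to the same number of fixations and the
same number of spikes (random subsampling, repeated and averaged).  Spikes
and LFP must come from different electrodes so spike waveform bleed-through
cannot masquerade as coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, SameElectrodeError

__all__ = [
    "FixationSegment",
    "SpectralEstimate",
    "extract_fixation_segments",
    "equalize_condition_samples",
    "spike_field_coherence",
    "equalized_coherence",
    "band_average",
]

WINDOW_MS = 200.0
THETA_BAND = (4.0, 12.0)


@dataclass
class FixationSegment:
    """One fixation-aligned analysis window."""

    lfp: np.ndarray  # samples in [onset, onset + window)
    spikes: np.ndarray  # spike times in ms relative to onset, in [0, window)
    onset_ms: float = 0.0


@dataclass
class SpectralEstimate:
    freqs: np.ndarray
    values: np.ndarray
    n_fixations_used: int
    n_spikes_used: int
    taper: str = "hanning"


def extract_fixation_segments(
    session,
    fixation_events,
    channel,
    unit,
    window_ms: float = WINDOW_MS,
) -> tuple:
    """Paired (LFP, spike) segments for a unit/channel and a set of fixations.

    The window is fixed at ``window_ms`` from fixation onset regardless of
    fixation duration (short fixations simply extend into the following
    saccade/fixation).  Fixations whose window runs past the end of the LFP
    trace are dropped; the count of dropped fixations is returned alongside
    the segments as ``(segments, n_dropped)``.
    """
    if unit.electrode_id == channel.electrode_id:
        raise SameElectrodeError(
            f"unit {unit.unit_id} and channel {channel.channel_id} share "
            f"electrode {unit.electrode_id}"
        )
    fs = channel.fs
    n_win = int(round(window_ms * fs / 1000.0))
    spikes = np.asarray(unit.spike_times_ms, float)
    segments = []
    dropped = 0
    for onset in np.asarray(fixation_events["t_on_ms"], float):
        start = int(round(onset * fs / 1000.0))
        if start < 0 or start + n_win > len(channel.samples):
            dropped += 1
            continue
        lfp = np.asarray(channel.samples[start:start + n_win], float)
        lo, hi = np.searchsorted(spikes, [onset, onset + window_ms])
        segments.append(
            FixationSegment(
                lfp=lfp, spikes=spikes[lo:hi] - onset, onset_ms=float(onset)
            )
        )
    return segments, dropped


def _total_spikes(segments) -> int:
    return int(sum(len(s.spikes) for s in segments))


def _delete_spikes(segments, n_delete: int, rng) -> list:
    """Randomly remove ``n_delete`` spikes across all segments of a condition."""
    counts = np.array([len(s.spikes) for s in segments])
    flat = np.concatenate(
        [np.full(c, i) for i, c in enumerate(counts)] or [np.empty(0, int)]
    ).astype(int)
    kill = rng.choice(len(flat), size=n_delete, replace=False)
    per_seg_kill = {}
    offsets = np.concatenate([[0], np.cumsum(counts)])
    for k in kill:
        seg = flat[k]
        per_seg_kill.setdefault(seg, []).append(k - offsets[seg])
    out = []
    for i, s in enumerate(segments):
        if i in per_seg_kill:
            keep = np.ones(len(s.spikes), bool)
            keep[np.array(per_seg_kill[i], int)] = False
            out.append(
                FixationSegment(s.lfp, s.spikes[keep], s.onset_ms)
            )
        else:
            out.append(s)
    return out


def equalize_condition_samples(
    segs_a, segs_b, n_repeats: int = 20, seed: int = 0
) -> list:
    """Matched segment-set pairs with equal fixation and spike counts.

    Per repeat, the condition with more fixations is subsampled (without
    replacement) to the smaller count, then spikes are deleted at random
    from the condition with more total spikes until spike counts match.
    Returns a list of ``(segs_a, segs_b)`` pairs, one per repeat; downstream
    estimates are averaged over repeats.
    """
    if not segs_a or not segs_b:
        raise InsufficientDataError("both conditions need at least one fixation")
    if _total_spikes(segs_a) == 0 or _total_spikes(segs_b) == 0:
        raise InsufficientDataError("a condition has zero spikes")
    rng = np.random.default_rng(seed)
    n_fix = min(len(segs_a), len(segs_b))
    pairs = []
    for _ in range(n_repeats):
        sub = []
        for segs in (segs_a, segs_b):
            if len(segs) > n_fix:
                idx = rng.choice(len(segs), size=n_fix, replace=False)
                sub.append([segs[i] for i in idx])
            else:
                sub.append(list(segs))
        n_spk = [_total_spikes(s) for s in sub]
        target = min(n_spk)
        for c in (0, 1):
            if n_spk[c] > target:
                sub[c] = _delete_spikes(sub[c], n_spk[c] - target, rng)
        pairs.append((sub[0], sub[1]))
    return pairs


def spike_field_coherence(
    segments,
    fs: float = 1000.0,
    min_segments: int = 10,
    min_spikes: int = 50,
) -> SpectralEstimate:
    """Magnitude coherence between binned spikes and LFP across segments."""
    if len(segments) < min_segments or _total_spikes(segments) < min_spikes:
        raise InsufficientDataError(
            f"need >= {min_segments} segments and >= {min_spikes} spikes, got "
            f"{len(segments)} segments / {_total_spikes(segments)} spikes"
        )
    n_win = len(segments[0].lfp)
    taper = np.hanning(n_win)
    dt_ms = 1000.0 / fs
    sx = np.zeros(n_win // 2 + 1)
    sy = np.zeros(n_win // 2 + 1)
    sxy = np.zeros(n_win // 2 + 1, dtype=complex)
    for seg in segments:
        if len(seg.lfp) != n_win:
            raise ValueError("all segments must have equal length")
        binned = np.bincount(
            np.clip((seg.spikes / dt_ms).astype(int), 0, n_win - 1),
            minlength=n_win,
        ).astype(float)
        x = (binned - binned.mean()) * taper
        y = (seg.lfp - seg.lfp.mean()) * taper
        fx = np.fft.rfft(x)
        fy = np.fft.rfft(y)
        sx += np.abs(fx) ** 2
        sy += np.abs(fy) ** 2
        sxy += fx * np.conj(fy)
    n = len(segments)
    sx /= n
    sy /= n
    sxy /= n
    denom = np.sqrt(sx * sy)
    values = np.zeros_like(sx)
    powered = denom > 0
    values[powered] = np.abs(sxy[powered]) / denom[powered]
    return SpectralEstimate(
        freqs=np.fft.rfftfreq(n_win, d=1.0 / fs),
        values=values,
        n_fixations_used=n,
        n_spikes_used=_total_spikes(segments),
    )


def equalized_coherence(
    segs_a,
    segs_b,
    fs: float = 1000.0,
    n_repeats: int = 20,
    seed: int = 0,
    min_segments: int = 10,
    min_spikes: int = 50,
) -> tuple:
    """Repeat-averaged coherence for two equalized conditions.

    Convenience wrapper: equalize, estimate per repeat, average the
    coherence spectra.  Returns a ``(SpectralEstimate, SpectralEstimate)``
    pair in the input order.
    """
    pairs = equalize_condition_samples(segs_a, segs_b, n_repeats, seed)
    acc = [None, None]
    ests = [None, None]
    for sub_a, sub_b in pairs:
        for c, sub in enumerate((sub_a, sub_b)):
            est = spike_field_coherence(sub, fs, min_segments, min_spikes)
            acc[c] = est.values if acc[c] is None else acc[c] + est.values
            ests[c] = est
    out = []
    for c in range(2):
        out.append(
            SpectralEstimate(
                freqs=ests[c].freqs,
                values=acc[c] / len(pairs),
                n_fixations_used=ests[c].n_fixations_used,
                n_spikes_used=ests[c].n_spikes_used,
            )
        )
    return out[0], out[1]


def band_average(est: SpectralEstimate, band=THETA_BAND) -> float:
    """Mean of the spectral values at frequency bins inside the closed band."""
    lo, hi = band
    mask = (est.freqs >= lo) & (est.freqs <= hi)
    if not mask.any():
        raise ValueError(
            f"band [{lo}, {hi}] Hz contains no frequency bins "
            f"(resolution {est.freqs[1] - est.freqs[0]:g} Hz)"
        )
    return float(est.values[mask].mean())
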