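"""Synthetic fixation-search sessions with planted ground truth.

Emulates a free-gaze visual search experiment in primate visual cortex: a
central fixation (400 ms) is followed by a foveal cue (500-1300 ms) and a
500 ms delay, then a search array of 11 items (2 targets sharing the cue's
category, drawn from 20 possible locations) that the subject scans with a
sequence of fixations until a target is held for 800 ms.

The generator plants four effects with known ground truth so every
downstream stage of the pipeline can be validated:

* category-clustered stimulus features (stand-ins for deep-network
  embeddings, 512-D by default);
* "axis-coding" units whose firing rate is a monotone (softplus) function of
  a linear projection of the feature vector, next to null units whose
  per-stimulus rates are drawn independently of the features;
* a multiplicative attentional gain on target fixations, confined to the
  late window 150-225 ms after fixation onset;
* theta-band (4-12 Hz) spike-field coupling whose depth is lower on target
  than on distractor fixations (target-induced desynchronization), with the
  same theta phase driving the spike-rate modulation and the LFP oscillation
  of an area.

Spikes are drawn from an inhomogeneous Poisson process at 1 ms resolution;
LFPs are a drifting-frequency theta sinusoid plus 1/f noise.  Times are in
ms throughout; intervals are half-open ``[t_on, t_off)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SessionIOError

__all__ = [
    "CATEGORIES",
    "StimulusSet",
    "SyntheticConfig",
    "Unit",
    "LfpChannel",
    "Session",
    "GroundTruth",
    "generate_stimulus_features",
    "generate_unit_population",
    "generate_session",
    "write_session",
    "read_session",
]

CATEGORIES = ("face", "house", "flower", "hand")

EVENT_COLUMNS = [
    "trial_id",
    "event_type",
    "t_on_ms",
    "t_off_ms",
    "stimulus_id",
    "is_target",
    "location_id",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class StimulusSet:
    """Stimulus identities, categories and feature vectors.

    ``features[i]`` is the feature embedding of ``stimulus_id[i]``; rows are
    finite and each category contains at least two stimuli.
    """

    stimulus_id: np.ndarray  # (n,) int
    category: np.ndarray  # (n,) str
    features: np.ndarray  # (n, D) float

    def __post_init__(self) -> None:
        self.stimulus_id = np.asarray(self.stimulus_id, dtype=int)
        self.category = np.asarray(self.category, dtype=object)
        self.features = np.asarray(self.features, dtype=float)
        if len(np.unique(self.stimulus_id)) != len(self.stimulus_id):
            raise ValueError("stimulus_id values must be unique")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature rows must be finite")
        for cat, cnt in zip(*np.unique(self.category, return_counts=True)):
            if cnt < 2:
                raise ValueError(f"category {cat!r} has fewer than 2 stimuli")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_id)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def index_of(self, stimulus_ids: np.ndarray) -> np.ndarray:
        """Row indices of the given stimulus ids."""
        lookup = {s: i for i, s in enumerate(self.stimulus_id)}
        return np.array([lookup[s] for s in np.asarray(stimulus_ids)], dtype=int)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the session generator; defaults are the emulated study design."""

    n_stimuli_per_category: int = 40
    n_features: int = 512
    separation: float = 8.0  # pairwise distance between category feature means
    n_units_per_area: dict = field(
        default_factory=lambda: {"V4": 8, "TEO": 6, "TE": 8, "OFC": 4}
    )
    n_channels_per_area: int = 2
    fraction_axis: float = 0.5
    baseline_rate_range: tuple = (8.0, 25.0)  # spikes/s, uniform per unit
    axis_modulation: float = 1.5  # slope of the softplus drive, in SD of w.x
    axis_category_alignment: float = 0.7  # axis weight on category-contrast axes
    nonaxis_rate_sigma: float = 0.5  # log-sd of feature-independent rates
    attention_gain: float = 1.5  # late-window gain on target fixations (axis units)
    nonaxis_effect_scale: float = 0.3  # shrink of planted effects for null units
    locking_distractor: float = 0.6
    locking_target: float = 0.2
    theta_band: tuple = (4.0, 12.0)
    theta_amplitude: float = 1.0
    noise_amplitude: float = 1.0  # std of the 1/f LFP noise
    fs: float = 1000.0  # LFP sampling rate, Hz
    n_trials: int = 300
    fixation_mean_ms: float = 208.0
    fixation_sd_ms: float = 154.0
    fixation_min_ms: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stimuli_per_category < 2 or self.n_features < 2:
            raise ValueError("counts must be >= 2")
        if self.n_trials <= 0 or self.n_channels_per_area <= 0:
            raise ValueError("counts must be positive")
        if any(n <= 0 for n in self.n_units_per_area.values()):
            raise ValueError("unit counts must be positive")
        if not 0.0 <= self.fraction_axis <= 1.0:
            raise ValueError("fraction_axis must lie in [0, 1]")
        for lock in (self.locking_distractor, self.locking_target):
            if not 0.0 <= lock < 1.0:
                raise ValueError("locking depths must lie in [0, 1)")
        if self.attention_gain <= 0:
            raise ValueError("attention_gain must be positive")
        if self.fs < 2.0 * self.theta_band[1]:
            raise ValueError("fs must be at least twice the upper theta edge")


@dataclass
class Unit:
    unit_id: int
    area: str
    electrode_id: str
    spike_times_ms: np.ndarray  # sorted ascending


@dataclass
class LfpChannel:
    channel_id: int
    area: str
    electrode_id: str
    samples: np.ndarray
    fs: float


@dataclass
class Session:
    """One recording session: event table, spike trains and LFP traces."""

    events: pd.DataFrame
    units: list
    lfp: list
    duration_ms: float
    #: per-trial search-array composition (trial_id, stimulus_id, is_target,
    #: location_id); 11 rows per trial of which exactly 2 are targets
    arrays: pd.DataFrame | None = None

    def unit_by_id(self, unit_id: int) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(f"no unit with id {unit_id}")

    def channel_by_id(self, channel_id: int) -> LfpChannel:
        for c in self.lfp:
            if c.channel_id == channel_id:
                return c
        raise KeyError(f"no LFP channel with id {channel_id}")

    def fixations(self) -> pd.DataFrame:
        """Search-epoch fixation events (each carries stimulus_id, is_target)."""
        fix = self.events[self.events.event_type == "fixation"]
        return fix.reset_index(drop=True)


@dataclass
class GroundTruth:
    """Planted per-unit and per-channel parameters for recovery tests."""

    unit_id: np.ndarray
    area: np.ndarray
    is_axis: np.ndarray  # bool
    axis_weights: np.ndarray  # (n_units, D); zero rows for non-axis units
    baseline_rate: np.ndarray  # spikes/s
    attention_gain: np.ndarray
    locking_distractor: np.ndarray
    locking_target: np.ndarray
    stim_rates: np.ndarray  # (n_units, n_stimuli) mean rate per stimulus
    channel_theta_amplitude: dict = field(default_factory=dict)
    channel_theta_band: tuple = (4.0, 12.0)

    def __post_init__(self) -> None:
        nz = np.abs(self.axis_weights).sum(axis=1) > 0
        if not np.array_equal(nz, self.is_axis.astype(bool)):
            raise ValueError("is_axis must match non-zero axis_weights rows")
        if np.any(self.baseline_rate <= 0):
            raise ValueError("baseline rates must be positive")

    @property
    def n_units(self) -> int:
        return len(self.unit_id)


# ---------------------------------------------------------------------------
# stimulus features


def generate_stimulus_features(
    n_per_category: int,
    n_features: int = 512,
    separation: float = 8.0,
    seed: int = 0,
) -> StimulusSet:
    """Category-clustered feature vectors emulating deep-network embeddings.

    Category means are placed at pairwise Euclidean distance ``separation``
    (on a random orthonormal frame) and stimuli scatter isotropically around
    their mean with unit variance per dimension.  ``separation = 0`` gives
    featureless (single-cluster) stimuli; the 8.0 default makes category
    identity linearly decodable from the features at >95% held-out accuracy,
    mirroring embeddings whose leading principal component separates
    animate from inanimate categories.
    """
    if n_per_category <= 0 or n_features < 2:
        raise ValueError("n_per_category must be positive and n_features >= 2")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    # random orthonormal directions -> category means at exact pairwise distance
    basis, _ = np.linalg.qr(rng.standard_normal((n_features, len(CATEGORIES))))
    means = (separation / math.sqrt(2.0)) * basis.T  # (4, D)
    n_total = n_per_category * len(CATEGORIES)
    category = np.repeat(np.array(CATEGORIES, dtype=object), n_per_category)
    features = rng.standard_normal((n_total, n_features))
    for c, cat in enumerate(CATEGORIES):
        features[category == cat] += means[c]
    return StimulusSet(
        stimulus_id=np.arange(n_total), category=category, features=features
    )


# ---------------------------------------------------------------------------
# unit population


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def generate_unit_population(
    config: SyntheticConfig, stimuli: StimulusSet, seed: int = 0
) -> GroundTruth:
    """Plant axis-coding and feature-independent units.

    Axis units fire at ``softplus(m * z + 1)`` scaled to their baseline rate,
    where ``z`` is the standardized projection of the stimulus features onto
    a random unit axis and ``m`` is ``axis_modulation``; the softplus link
    keeps rates positive while staying near-linear over the operating range,
    so a linear encoding model remains well-specified.  Non-axis units get
    log-normal per-stimulus rates drawn independently of the features — an
    exact null for permutation-test calibration.

    Attentional gain and theta phase-locking are planted at full strength in
    axis units and shrunk toward null by ``nonaxis_effect_scale`` in
    non-axis units, so group contrasts (axis > non-axis) have a known sign.
    """
    rng = np.random.default_rng(seed)
    n_stim = stimuli.n_stimuli
    d = stimuli.n_features
    if d != config.n_features:
        raise ValueError(
            f"stimuli have {d} features but config specifies {config.n_features}"
        )

    areas, unit_ids = [], []
    for area, n in config.n_units_per_area.items():
        areas.extend([area] * n)
        unit_ids.extend(range(len(unit_ids), len(unit_ids) + n))
    areas = np.array(areas, dtype=object)
    unit_ids = np.array(unit_ids, dtype=int)
    n_units = len(unit_ids)

    # per-area random assignment of the axis flag at the requested fraction
    is_axis = np.zeros(n_units, dtype=bool)
    for area in config.n_units_per_area:
        idx = np.flatnonzero(areas == area)
        n_axis = int(round(config.fraction_axis * len(idx)))
        is_axis[rng.choice(idx, size=n_axis, replace=False)] = True

    baseline = rng.uniform(*config.baseline_rate_range, size=n_units)
    weights = np.zeros((n_units, d))
    stim_rates = np.empty((n_units, n_stim))
    x_centered = stimuli.features - stimuli.features.mean(axis=0)
    # orthonormal basis of the category-mean subspace: axis units partially
    # align with it, like cortical units tracking the leading feature PCs
    cat_means = np.stack(
        [x_centered[stimuli.category == c].mean(axis=0) for c in CATEGORIES]
    )
    cat_basis = np.linalg.qr(cat_means.T)[0] if np.linalg.norm(cat_means) > 0 else None
    align = config.axis_category_alignment
    for i in range(n_units):
        if is_axis[i]:
            w = rng.standard_normal(d)
            w /= np.linalg.norm(w)
            if cat_basis is not None and align > 0:
                w_cat = cat_basis @ rng.standard_normal(cat_basis.shape[1])
                norm = np.linalg.norm(w_cat)
                if norm > 0:
                    w = align * w_cat / norm + (1.0 - align) * w
                    w /= np.linalg.norm(w)
            drive = x_centered @ w
            z = drive / drive.std()
            raw = _softplus(config.axis_modulation * z + 1.0)
            stim_rates[i] = baseline[i] * raw / raw.mean()
            weights[i] = w
        else:
            sig = config.nonaxis_rate_sigma
            stim_rates[i] = baseline[i] * np.exp(
                sig * rng.standard_normal(n_stim) - 0.5 * sig**2
            )

    shrink = config.nonaxis_effect_scale
    gain = np.where(
        is_axis,
        config.attention_gain,
        1.0 + (config.attention_gain - 1.0) * shrink,
    )
    lock_mid = 0.5 * (config.locking_distractor + config.locking_target)
    half_gap = 0.5 * (config.locking_distractor - config.locking_target)
    lock_d = np.where(
        is_axis, config.locking_distractor, lock_mid + half_gap * shrink
    )
    lock_t = np.where(is_axis, config.locking_target, lock_mid - half_gap * shrink)

    theta_amp = {}
    for area in config.n_units_per_area:
        for k in range(config.n_channels_per_area):
            theta_amp[f"{area}_ch{k}"] = config.theta_amplitude

    return GroundTruth(
        unit_id=unit_ids,
        area=areas,
        is_axis=is_axis,
        axis_weights=weights,
        baseline_rate=baseline,
        attention_gain=gain,
        locking_distractor=lock_d,
        locking_target=lock_t,
        stim_rates=stim_rates,
        channel_theta_amplitude=theta_amp,
        channel_theta_band=tuple(config.theta_band),
    )


# ---------------------------------------------------------------------------
# session timeline and signal synthesis

_SACCADE_MS = 30.0  # inter-fixation gap
_FIRST_FIX_LATENCY_MS = 150.0  # array onset -> first search fixation
_HOLD_MS = 800.0  # target hold completing a trial
_MAX_SEARCH_MS = 3000.0  # force trial completion beyond this
_ITI_MS = 300.0


def _lognormal_params(mean: float, sd: float) -> tuple:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - 0.5 * sigma2
    return mu, math.sqrt(sigma2)


def _build_timeline(
    config: SyntheticConfig, stimuli: StimulusSet, rng: np.random.Generator
) -> tuple:
    """Event table and array-composition table for all trials."""
    mu, sigma = _lognormal_params(config.fixation_mean_ms, config.fixation_sd_ms)
    by_cat = {c: stimuli.stimulus_id[stimuli.category == c] for c in CATEGORIES}
    rows = []
    array_rows = []
    t = 0.0
    for trial in range(config.n_trials):
        rows.append((trial, "initial_fixation", t, t + 400.0, -1, False, -1))
        t += 400.0
        cue_dur = rng.uniform(500.0, 1300.0)
        cue_cat = "face" if rng.random() < 0.5 else "house"
        cue_stim = int(rng.choice(by_cat[cue_cat]))
        rows.append((trial, "cue_on", t, t + cue_dur, cue_stim, False, -1))
        t += cue_dur
        rows.append((trial, "delay", t, t + 500.0, -1, False, -1))
        t += 500.0

        # search array: 2 targets from the cue category, 9 distractors from
        # the other three categories, placed on 11 of 20 locations
        targets = rng.choice(by_cat[cue_cat], size=2, replace=False)
        other = np.concatenate(
            [by_cat[c] for c in CATEGORIES if c != cue_cat]
        )
        distractors = rng.choice(other, size=9, replace=False)
        items = np.concatenate([targets, distractors])
        item_is_target = np.array([True, True] + [False] * 9)
        locations = rng.choice(20, size=11, replace=False)
        for k in range(11):
            array_rows.append(
                (trial, int(items[k]), bool(item_is_target[k]),
                 int(locations[k]))
            )

        t_array = t
        fix_t = t_array + _FIRST_FIX_LATENCY_MS
        fix_rows = []
        for _ in range(40):  # hard cap on fixations per trial
            k = int(rng.integers(0, 11))
            tgt = bool(item_is_target[k])
            forced = (fix_t - t_array) > _MAX_SEARCH_MS
            if forced and not tgt:  # give up and jump to a target
                k = int(rng.integers(0, 2))
                tgt = True
            final = tgt and (forced or rng.random() < 0.5)
            if final:
                dur = _HOLD_MS
            else:
                dur = max(
                    config.fixation_min_ms, float(rng.lognormal(mu, sigma))
                )
            fix_rows.append(
                (trial, "fixation", fix_t, fix_t + dur, int(items[k]), tgt,
                 int(locations[k]))
            )
            fix_t += dur
            if final:
                break
            fix_t += _SACCADE_MS
        rows.append((trial, "array_on", t_array, fix_t, -1, False, -1))
        rows.extend(fix_rows)
        t = fix_t + _ITI_MS
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events = events.sort_values(["t_on_ms", "event_type"]).reset_index(drop=True)
    arrays = pd.DataFrame(
        array_rows,
        columns=["trial_id", "stimulus_id", "is_target", "location_id"],
    )
    return events, arrays


def _theta_phase(
    n_samples: int, band: tuple, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Phase of a theta oscillation whose frequency drifts inside the band."""
    lo, hi = band
    walk = rng.uniform(lo, hi) + np.concatenate(
        ([0.0], np.cumsum(rng.standard_normal(n_samples - 1) * 0.01))
    )
    # fold the unbounded walk back into [lo, hi] (triangle-wave reflection)
    width = hi - lo
    f = lo + np.abs(np.mod(walk - lo, 2.0 * width) - width)
    return 2.0 * np.pi * np.cumsum(f) / fs


def _pink_noise(n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nonzero = freqs > 0
    scale[nonzero] = 1.0 / np.sqrt(freqs[nonzero])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n=n_samples)
    return out / out.std()


def generate_session(
    config: SyntheticConfig,
    stimuli: StimulusSet,
    truth: GroundTruth,
    seed: int = 0,
) -> Session:
    """Simulate spike trains and LFPs for one session.

    The instantaneous rate of a unit is its planted per-stimulus rate during
    the cue and during search fixations, its baseline rate elsewhere,
    multiplied by ``1 + locking * cos(theta phase)`` within fixations (with
    condition-dependent locking depth) and by the attentional gain in the
    late window [150, 225) ms of target fixations.  Spike counts are Poisson
    per 1 ms bin with uniform jitter inside the bin.  Each LFP channel is
    ``theta_amplitude * cos(theta phase of its area) + 1/f noise``; the theta
    phase is shared between an area's LFP channels and its units' rate
    modulation, which is what makes spike-field coherence controllable.
    """
    if truth.stim_rates.shape[1] != stimuli.n_stimuli:
        raise ValueError("ground truth and stimulus set sizes do not match")
    rng = np.random.default_rng(seed)
    events, arrays = _build_timeline(config, stimuli, rng)
    duration_ms = float(events.t_off_ms.max()) + _ITI_MS
    n_samples = int(math.ceil(duration_ms * config.fs / 1000.0))
    dt_ms = 1000.0 / config.fs

    areas = list(config.n_units_per_area)
    phase = {
        a: _theta_phase(n_samples, config.theta_band, config.fs, rng)
        for a in areas
    }
    cosines = {a: np.cos(p) for a, p in phase.items()}
    stim_index = {s: i for i, s in enumerate(stimuli.stimulus_id)}

    cues = events[events.event_type == "cue_on"]
    fixes = events[events.event_type == "fixation"]

    units = []
    for i in range(truth.n_units):
        area = str(truth.area[i])
        rate = np.full(n_samples, truth.baseline_rate[i])
        cos_phase = cosines[area]
        for ev in cues.itertuples():
            a, b = _sample_span(ev.t_on_ms, ev.t_off_ms, dt_ms, n_samples)
            rate[a:b] = truth.stim_rates[i, stim_index[ev.stimulus_id]]
        for ev in fixes.itertuples():
            a, b = _sample_span(ev.t_on_ms, ev.t_off_ms, dt_ms, n_samples)
            r0 = truth.stim_rates[i, stim_index[ev.stimulus_id]]
            lock = (
                truth.locking_target[i]
                if ev.is_target
                else truth.locking_distractor[i]
            )
            seg = r0 * (1.0 + lock * cos_phase[a:b])
            if ev.is_target:
                la, lb = _sample_span(
                    ev.t_on_ms + 150.0, ev.t_on_ms + 225.0, dt_ms, n_samples
                )
                seg[max(la - a, 0): max(lb - a, 0)] *= truth.attention_gain[i]
            rate[a:b] = seg
        counts = rng.poisson(rate * dt_ms / 1000.0)
        idx = np.repeat(np.arange(n_samples), counts)
        spikes = np.sort((idx + rng.random(idx.size)) * dt_ms)
        units.append(
            Unit(
                unit_id=int(truth.unit_id[i]),
                area=area,
                electrode_id=f"{area}_e{int(np.sum(truth.area[:i] == area))}",
                spike_times_ms=spikes,
            )
        )

    channels = []
    cid = 0
    for area in areas:
        for k in range(config.n_channels_per_area):
            amp = truth.channel_theta_amplitude.get(
                f"{area}_ch{k}", config.theta_amplitude
            )
            samples = amp * np.cos(phase[area]) + config.noise_amplitude * (
                _pink_noise(n_samples, rng)
            )
            channels.append(
                LfpChannel(
                    channel_id=cid,
                    area=area,
                    electrode_id=f"{area}_e{k}",
                    samples=samples.astype(np.float32),
                    fs=config.fs,
                )
            )
            cid += 1

    return Session(
        events=events, units=units, lfp=channels, duration_ms=duration_ms,
        arrays=arrays,
    )


def _sample_span(
    t_on_ms: float, t_off_ms: float, dt_ms: float, n_samples: int
) -> tuple:
    a = int(math.floor(t_on_ms / dt_ms))
    b = int(math.ceil(t_off_ms / dt_ms))
    return max(a, 0), min(b, n_samples)


# ---------------------------------------------------------------------------
# session I/O (plain-text layout + raw float32 LFP)


def write_session(
    path,
    session: Session,
    stimuli: StimulusSet | None = None,
    truth: GroundTruth | None = None,
) -> None:
    """Write a session directory.

    Layout: ``events.csv``, ``units.csv``, ``spikes/unit_<id>.csv`` (one
    spike time per line), ``lfp/channel_<id>.f32`` (little-endian float32)
    with ``lfp_meta.csv``, plus optional ``features.csv`` and
    ``ground_truth.csv``.
    """
    from pathlib import Path

    path = Path(path)
    (path / "spikes").mkdir(parents=True, exist_ok=True)
    (path / "lfp").mkdir(parents=True, exist_ok=True)

    session.events.to_csv(path / "events.csv", index=False)
    if session.arrays is not None:
        session.arrays.to_csv(path / "arrays.csv", index=False)
    pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "area": [u.area for u in session.units],
            "electrode_id": [u.electrode_id for u in session.units],
        }
    ).to_csv(path / "units.csv", index=False)
    for u in session.units:
        pd.DataFrame({"spike_time_ms": u.spike_times_ms}).to_csv(
            path / "spikes" / f"unit_{u.unit_id}.csv", index=False
        )
    pd.DataFrame(
        {
            "channel_id": [c.channel_id for c in session.lfp],
            "area": [c.area for c in session.lfp],
            "electrode_id": [c.electrode_id for c in session.lfp],
            "fs_hz": [c.fs for c in session.lfp],
            "n_samples": [len(c.samples) for c in session.lfp],
        }
    ).to_csv(path / "lfp_meta.csv", index=False)
    for c in session.lfp:
        c.samples.astype("<f4").tofile(path / "lfp" / f"channel_{c.channel_id}.f32")
    if stimuli is not None:
        feat = pd.DataFrame(
            stimuli.features,
            columns=[f"f{j}" for j in range(stimuli.n_features)],
        )
        feat.insert(0, "category", stimuli.category)
        feat.insert(0, "stimulus_id", stimuli.stimulus_id)
        feat.to_csv(path / "features.csv", index=False)
    if truth is not None:
        pd.DataFrame(
            {
                "unit_id": truth.unit_id,
                "area": truth.area,
                "is_axis": truth.is_axis.astype(int),
                "baseline_rate": truth.baseline_rate,
                "attention_gain": truth.attention_gain,
                "locking_distractor": truth.locking_distractor,
                "locking_target": truth.locking_target,
            }
        ).to_csv(path / "ground_truth.csv", index=False)


def read_session(path):
    """Read a session directory written by :func:`write_session`.

    Returns ``(session, stimuli_or_None, ground_truth_table_or_None)``; the
    ground truth comes back as the scalar per-unit table (a DataFrame), not a
    full :class:`GroundTruth`.
    Raises :class:`SessionIOError` naming the first missing component file.
    """
    from pathlib import Path

    path = Path(path)
    for required in ("events.csv", "units.csv", "lfp_meta.csv"):
        if not (path / required).exists():
            raise SessionIOError(f"{required} not found in {path}")

    events = pd.read_csv(path / "events.csv")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise SessionIOError(f"events.csv missing columns {missing}")
    units_meta = pd.read_csv(path / "units.csv")
    units = []
    for row in units_meta.itertuples():
        spike_file = path / "spikes" / f"unit_{row.unit_id}.csv"
        if not spike_file.exists():
            raise SessionIOError(f"spikes/unit_{row.unit_id}.csv not found")
        spikes = pd.read_csv(spike_file)["spike_time_ms"].to_numpy(dtype=float)
        units.append(
            Unit(int(row.unit_id), str(row.area), str(row.electrode_id),
                 np.sort(spikes))
        )
    lfp_meta = pd.read_csv(path / "lfp_meta.csv")
    channels = []
    for row in lfp_meta.itertuples():
        lfp_file = path / "lfp" / f"channel_{row.channel_id}.f32"
        if not lfp_file.exists():
            raise SessionIOError(f"lfp/channel_{row.channel_id}.f32 not found")
        samples = np.fromfile(lfp_file, dtype="<f4")
        if len(samples) != int(row.n_samples):
            raise SessionIOError(
                f"lfp/channel_{row.channel_id}.f32 has {len(samples)} samples, "
                f"expected {int(row.n_samples)}"
            )
        channels.append(
            LfpChannel(int(row.channel_id), str(row.area), str(row.electrode_id),
                       samples, float(row.fs_hz))
        )
    duration = float(events.t_off_ms.max()) if len(events) else 0.0
    arrays = None
    if (path / "arrays.csv").exists():
        arrays = pd.read_csv(path / "arrays.csv")
    session = Session(events=events, units=units, lfp=channels,
                      duration_ms=duration, arrays=arrays)

    stimuli = None
    if (path / "features.csv").exists():
        feat = pd.read_csv(path / "features.csv")
        fcols = [c for c in feat.columns if c.startswith("f") and c[1:].isdigit()]
        fcols.sort(key=lambda c: int(c[1:]))
        stimuli = StimulusSet(
            stimulus_id=feat["stimulus_id"].to_numpy(int),
            category=feat["category"].to_numpy(object),
            features=feat[fcols].to_numpy(float),
        )
    truth_table = None
    if (path / "ground_truth.csv").exists():
        truth_table = pd.read_csv(path / "ground_truth.csv")
    return session, stimuli, truth_table
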