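"""Spike-density functions, windowed firing rates and normalized contrast indices.

All times are in milliseconds and all analysis windows are half-open
``[t_on, t_off)`` so adjacent windows never double-count a spike.  Rates are
reported in spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError

__all__ = [
    "RateWindow",
    "WINDOWS",
    "spike_density_function",
    "windowed_rate",
    "normalize_to_max",
    "normalized_contrast",
]


@dataclass(frozen=True)
class RateWindow:
    """A named analysis window, in ms relative to an anchor event.

    The canonical windows (see :data:`WINDOWS`) are the early
    feature-coding window [50, 150) and late attention window [150, 225)
    after fixation onset, the pre-cue baseline [-150, 0), and the cue
    response window [50, 200) after cue onset.
    """

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError(
                f"window {self.name!r}: start ({self.start_ms}) must precede "
                f"end ({self.end_ms})"
            )

    @property
    def length_ms(self) -> float:
        return self.end_ms - self.start_ms


#: Canonical analysis windows used throughout the pipeline.
WINDOWS: dict[str, RateWindow] = {
    "feature": RateWindow("feature", 50.0, 150.0),
    "attention": RateWindow("attention", 150.0, 225.0),
    "baseline": RateWindow("baseline", -150.0, 0.0),
    "cue_response": RateWindow("cue_response", 50.0, 200.0),
}


def spike_density_function(
    spike_times: np.ndarray,
    t_grid: np.ndarray,
    growth_ms: float = 1.0,
    decay_ms: float = 20.0,
) -> np.ndarray:
    """Continuous firing-rate estimate from spike times via a causal EPSP kernel.

    Each spike is convolved with the kernel
    ``K(t) = (1 - exp(-t/growth)) * exp(-t/decay)`` for ``t >= 0`` (zero for
    ``t < 0``), which projects activity forward in time like an excitatory
    postsynaptic potential.  The kernel is normalized to unit area so that an
    isolated spike contributes area 1 and the trace estimates rate in
    spikes/s (times in ms; the area normalization uses the analytic integral
    ``decay^2 / (growth + decay)`` in ms, converted so the output is per
    second).

    Parameters
    ----------
    spike_times
        Spike times in ms, any order.
    t_grid
        Strictly increasing evaluation grid in ms.
    growth_ms, decay_ms
        Kernel rise and fall time constants in ms; must be positive.
    """
    if growth_ms <= 0 or decay_ms <= 0:
        raise ValueError("kernel time constants must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or (t_grid.size > 1 and not np.all(np.diff(t_grid) > 0)):
        raise ValueError("t_grid must be strictly increasing")
    spike_times = np.asarray(spike_times, dtype=float)

    # analytic area of K in ms: int_0^inf (1-e^{-t/g}) e^{-t/d} dt = d - gd/(g+d)
    area_ms = decay_ms - growth_ms * decay_ms / (growth_ms + decay_ms)
    out = np.zeros_like(t_grid)
    if spike_times.size == 0:
        return out
    # dt[i, j] = t_grid[i] - spike[j]; kernel applied where dt >= 0
    dt = t_grid[:, None] - spike_times[None, :]
    mask = dt >= 0
    dt = np.where(mask, dt, 0.0)
    k = (1.0 - np.exp(-dt / growth_ms)) * np.exp(-dt / decay_ms)
    out = np.where(mask, k, 0.0).sum(axis=1)
    return out / area_ms * 1000.0  # ms^-1 -> spikes/s


def windowed_rate(
    spike_times: np.ndarray, anchor_ms: float, window: RateWindow
) -> float:
    """Mean firing rate (spikes/s) in a half-open window anchored at an event.

    Counts spikes with ``t in [anchor+start, anchor+end)`` and divides by the
    window length in seconds.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    lo = anchor_ms + window.start_ms
    hi = anchor_ms + window.end_ms
    n = int(np.count_nonzero((spike_times >= lo) & (spike_times < hi)))
    return n / (window.length_ms / 1000.0)


def windowed_rates(
    spike_times: np.ndarray, anchors_ms: np.ndarray, window: RateWindow
) -> np.ndarray:
    """Vectorized :func:`windowed_rate` over many anchor events."""
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    anchors_ms = np.asarray(anchors_ms, dtype=float)
    lo = np.searchsorted(spike_times, anchors_ms + window.start_ms, side="left")
    hi = np.searchsorted(spike_times, anchors_ms + window.end_ms, side="left")
    return (hi - lo) / (window.length_ms / 1000.0)


def normalize_to_max(condition_rates: np.ndarray) -> np.ndarray:
    """Divide a vector of condition rates by its maximum (max entry becomes 1)."""
    rates = np.asarray(condition_rates, dtype=float)
    m = rates.max(initial=-np.inf)
    if not m > 0:
        raise DegenerateInputError(
            "cannot normalize: maximum rate across conditions is not positive"
        )
    return rates / m


def normalized_contrast(a: float, b: float) -> float:
    """Normalized contrast ``(a - b) / (a + b)``, bounded in [-1, 1].

    The sign convention belongs to the caller: the attention index passes
    (target, distractor); desynchronization and Granger-causality contrasts
    pass (distractor, target).
    """
    if a < 0 or b < 0:
        raise ValueError("normalized_contrast expects non-negative inputs")
    s = a + b
    if s == 0:
        raise DegenerateInputError("normalized contrast undefined: a + b = 0")
    return (a - b) / s
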