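"""Unit screening: visual responsiveness, receptive-field class, category
selectivity (SI) and attention selectivity.

All hypothesis tests follow the conventions of the fixation-aligned search
analysis: Wilcoxon rank-sum for independent response samples, Wilcoxon
signed-rank for the paired per-stimulus target/distractor comparison, alpha
0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, InsufficientDataError
from .rates import normalized_contrast

__all__ = [
    "UnitScreenRecord",
    "assess_visual_responsiveness",
    "classify_rf",
    "category_selectivity_index",
    "classify_category",
    "detect_attention_selectivity",
]

ALPHA = 0.05
SI_THRESHOLD = 0.13  # face response at least 130% of house response


@dataclass
class UnitScreenRecord:
    """Per-unit screening outcome (one row of ``unit_screen.csv``)."""

    unit_id: int
    area: str
    visually_responsive: bool
    responsive_p: float
    rf_class: str
    R_face: float
    R_house: float
    SI: float
    category_class: str
    attention_selective: bool
    attention_p: float
    attention_index: float


def _ranksum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided Wilcoxon rank-sum p-value for x stochastically greater than y."""
    return stats.mannwhitneyu(x, y, alternative="greater").pvalue


def assess_visual_responsiveness(
    cue_rates: np.ndarray,
    array_rates: np.ndarray,
    baseline_rates: np.ndarray,
    min_n: int = 5,
) -> tuple:
    """Flag a unit as visually responsive.

    A unit is responsive when its firing rate to either the cue or the
    search array is significantly greater than baseline (rank-sum, p < 0.05).
    Returns ``(flag, p_cue, p_array)`` with the per-epoch p-values kept for
    the RF classification that follows.
    """
    cue_rates = np.asarray(cue_rates, float)
    array_rates = np.asarray(array_rates, float)
    baseline_rates = np.asarray(baseline_rates, float)
    if min(len(cue_rates), len(array_rates), len(baseline_rates)) < min_n:
        raise InsufficientDataError(
            f"need at least {min_n} observations per sample"
        )
    p_cue = _ranksum_greater(cue_rates, baseline_rates)
    p_array = _ranksum_greater(array_rates, baseline_rates)
    return (p_cue < ALPHA) or (p_array < ALPHA), p_cue, p_array


def classify_rf(cue_response_p: float, array_response_p: float) -> str:
    """Receptive-field class from the cue/array responsiveness p-values.

    focal_foveal: responds only to the (foveal) cue; broad_foveal: to both
    cue and array; peripheral: only to the array; unclassified otherwise.
    """
    cue_sig = cue_response_p < ALPHA
    array_sig = array_response_p < ALPHA
    if cue_sig and not array_sig:
        return "focal_foveal"
    if cue_sig and array_sig:
        return "broad_foveal"
    if array_sig:
        return "peripheral"
    return "unclassified"


def category_selectivity_index(R_face: float, R_house: float) -> float:
    """Selectivity index (R_face - R_house) / (R_face + R_house).

    The responses are baseline-subtracted and may be negative; the index is
    clamped to +1 when R_face > 0 > R_house, to -1 when R_face < 0 < R_house,
    and clipped to [-1, 1] otherwise (the raw ratio can leave that range when
    the denominator is small and negative).
    """
    if R_face == 0 and R_house == 0:
        raise DegenerateInputError("SI undefined: both responses are zero")
    if R_face > 0 and R_house < 0:
        return 1.0
    if R_face < 0 and R_house > 0:
        return -1.0
    denom = R_face + R_house
    if denom == 0:
        raise DegenerateInputError("SI undefined: responses cancel exactly")
    return float(np.clip((R_face - R_house) / denom, -1.0, 1.0))


def classify_category(
    face_rates: np.ndarray,
    house_rates: np.ndarray,
    baseline_rates: np.ndarray | None = None,
    min_n: int = 5,
) -> tuple:
    """Category class from face-cue vs house-cue responses.

    Two criteria: a rank-sum test on the response samples (p < 0.05) and the
    SI on baseline-subtracted mean responses (|SI| > 0.13).  Returns
    ``(category_class, SI, p)`` where the class is ``face``, ``house``,
    ``nonselective`` (test not significant) or ``undefined`` (significant
    but the SI criterion not met).
    """
    face_rates = np.asarray(face_rates, float)
    house_rates = np.asarray(house_rates, float)
    if min(len(face_rates), len(house_rates)) < min_n:
        raise InsufficientDataError(f"need at least {min_n} rates per category")
    base = 0.0 if baseline_rates is None else float(np.mean(baseline_rates))
    r_face = float(face_rates.mean()) - base
    r_house = float(house_rates.mean()) - base
    p = stats.mannwhitneyu(face_rates, house_rates, alternative="two-sided").pvalue
    try:
        si = category_selectivity_index(r_face, r_house)
    except DegenerateInputError:
        si = 0.0
    if p >= ALPHA:
        return "nonselective", si, p
    if si > SI_THRESHOLD:
        return "face", si, p
    if si < -SI_THRESHOLD:
        return "house", si, p
    return "undefined", si, p


def detect_attention_selectivity(
    target_rates: np.ndarray,
    distractor_rates: np.ndarray,
    min_pairs: int = 6,
) -> tuple:
    """Paired target-vs-distractor comparison in the late window.

    ``target_rates[k]`` and ``distractor_rates[k]`` are the mean late-window
    (150-225 ms) firing rates for stimulus k when it was fixated as a target
    and as a distractor; the pairing unit is the stimulus.  Returns
    ``(flag, p, attention_index)`` with the attention index
    ``(FR_target - FR_distractor) / (FR_target + FR_distractor)`` computed on
    the across-stimulus mean rates.
    """
    target_rates = np.asarray(target_rates, float)
    distractor_rates = np.asarray(distractor_rates, float)
    if len(target_rates) != len(distractor_rates):
        raise ValueError("paired samples must have equal length")
    if len(target_rates) < min_pairs:
        raise InsufficientDataError(
            f"need at least {min_pairs} stimuli fixated in both roles"
        )
    diffs = target_rates - distractor_rates
    if np.allclose(diffs, 0.0):
        p = 1.0
    else:
        p = stats.wilcoxon(
            target_rates, distractor_rates, alternative="two-sided"
        ).pvalue
    index = normalized_contrast(
        float(target_rates.mean()), float(distractor_rates.mean())
    )
    return p < ALPHA, float(p), index
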