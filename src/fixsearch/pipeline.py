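"""Pipeline orchestration: simulate -> screen -> axis -> geometry ->
coherence -> granger -> report.

Each stage reads what it needs from an output directory, writes one or more
CSV tables there, and appends to a plain-text run log; ``manifest.json``
records the seed, a config hash and the stage outputs so a rerun with the
same config is reproducible (byte-identical for deterministic stages).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import axis as axis_mod
from . import coherence as coh_mod
from . import geometry as geo_mod
from . import granger as gc_mod
from . import screening
from . import synthetic
from .errors import FixsearchError, InsufficientDataError, SessionIOError
from .rates import WINDOWS, normalized_contrast, windowed_rates

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "group_comparison_stats",
    "build_report",
    "STAGES",
]

STAGES = ("simulate", "screen", "axis", "geometry", "coherence", "granger",
          "report")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``session_path`` points at an existing session directory; when None, a
    synthetic session is generated from ``synthetic_config``.
    """

    synthetic_config: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    session_path: str | None = None
    n_perm: int = 1000
    theta_band: tuple = (4.0, 12.0)
    equalization_repeats: int = 20
    coherence_min_fixations: int = 10
    coherence_min_spikes: int = 50
    granger_max_order: int = 8
    max_pairs: int | None = None  # cap on spike-LFP pairs (None = all)
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    def config_hash(self) -> str:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            return obj

        blob = json.dumps(clean(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# response extraction helpers


def _stimulus_mean_rates(unit, fixations: pd.DataFrame, window) -> pd.Series:
    """Mean windowed rate per stimulus over the given fixation events."""
    if not len(fixations):
        return pd.Series(dtype=float)
    rates = windowed_rates(
        unit.spike_times_ms, fixations["t_on_ms"].to_numpy(float), window
    )
    return pd.Series(rates).groupby(fixations["stimulus_id"].to_numpy()).mean()


def _response_matrix(units, fixations: pd.DataFrame, window, stimulus_ids):
    """[n_units x n_stimuli] mean-rate matrix over a fixed stimulus order."""
    mat = np.zeros((len(units), len(stimulus_ids)))
    for ui, unit in enumerate(units):
        means = _stimulus_mean_rates(unit, fixations, window)
        mat[ui] = means.reindex(stimulus_ids).to_numpy(float)
    return mat


def _both_role_stimuli(fix: pd.DataFrame) -> np.ndarray:
    """Stimuli fixated at least once as target and once as distractor."""
    tgt = set(fix.loc[fix.is_target.astype(bool), "stimulus_id"])
    dis = set(fix.loc[~fix.is_target.astype(bool), "stimulus_id"])
    return np.array(sorted(tgt & dis))


# ---------------------------------------------------------------------------
# stages


class _Run:
    """Shared state of one pipeline invocation."""

    def __init__(self, config: PipelineConfig, out_dir):
        self.config = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.session = None
        self.stimuli = None
        self.truth_table = None
        self.log_path = self.out / "run.log"

    def log(self, msg: str) -> None:
        with open(self.log_path, "a") as fh:
            fh.write(f"{time.strftime('%H:%M:%S')} {msg}\n")

    def load_session(self) -> None:
        if self.session is not None:
            return
        sess_dir = self.out / "session"
        if self.config.session_path is not None:
            sess_dir = Path(self.config.session_path)
        self.session, self.stimuli, self.truth_table = synthetic.read_session(
            sess_dir
        )
        if self.stimuli is None:
            raise SessionIOError(f"features.csv not found in {sess_dir}")

    def table(self, name: str) -> pd.DataFrame:
        path = self.out / name
        if not path.exists():
            raise SessionIOError(f"{name} not found; run the earlier stage first")
        return pd.read_csv(path)


def stage_simulate(run: _Run) -> None:
    cfg = run.config.synthetic_config
    seed = run.config.seed
    stimuli = synthetic.generate_stimulus_features(
        cfg.n_stimuli_per_category, cfg.n_features, cfg.separation, seed
    )
    truth = synthetic.generate_unit_population(cfg, stimuli, seed + 1)
    session = synthetic.generate_session(cfg, stimuli, truth, seed + 2)
    synthetic.write_session(run.out / "session", session, stimuli, truth)
    run.session, run.stimuli = session, stimuli
    run.truth_table = pd.read_csv(run.out / "session" / "ground_truth.csv")
    run.log(
        f"simulate: {len(session.units)} units, {len(session.lfp)} channels, "
        f"{len(session.fixations())} fixations"
    )


def stage_screen(run: _Run) -> None:
    run.load_session()
    sess = run.session
    ev = sess.events
    cues = ev[ev.event_type == "cue_on"]
    arrays = ev[ev.event_type == "array_on"]
    fix = sess.fixations()
    both = _both_role_stimuli(fix)
    records = []
    for unit in sess.units:
        cue_on = cues["t_on_ms"].to_numpy(float)
        cue_rates = windowed_rates(unit.spike_times_ms, cue_on,
                                   WINDOWS["cue_response"])
        base_rates = windowed_rates(unit.spike_times_ms, cue_on,
                                    WINDOWS["baseline"])
        arr_rates = windowed_rates(
            unit.spike_times_ms, arrays["t_on_ms"].to_numpy(float),
            WINDOWS["cue_response"],
        )
        responsive, p_cue, p_array = screening.assess_visual_responsiveness(
            cue_rates, arr_rates, base_rates
        )
        rf = screening.classify_rf(p_cue, p_array)

        cue_cat = run.stimuli.category[
            run.stimuli.index_of(cues["stimulus_id"].to_numpy())
        ]
        face_rates = cue_rates[cue_cat == "face"]
        house_rates = cue_rates[cue_cat == "house"]
        base = float(base_rates.mean())
        r_face = float(face_rates.mean()) - base
        r_house = float(house_rates.mean()) - base
        try:
            cat_class, si, _ = screening.classify_category(
                face_rates, house_rates, base_rates
            )
        except InsufficientDataError:
            cat_class, si = "undefined", np.nan

        att_flag, att_p, att_idx = False, np.nan, np.nan
        if len(both) >= 6:
            tgt = _stimulus_mean_rates(
                unit, fix[fix.is_target.astype(bool)], WINDOWS["attention"]
            ).reindex(both)
            dis = _stimulus_mean_rates(
                unit, fix[~fix.is_target.astype(bool)], WINDOWS["attention"]
            ).reindex(both)
            try:
                att_flag, att_p, att_idx = screening.detect_attention_selectivity(
                    tgt.to_numpy(float), dis.to_numpy(float)
                )
            except (InsufficientDataError, FixsearchError):
                pass
        records.append(
            screening.UnitScreenRecord(
                unit_id=unit.unit_id, area=unit.area,
                visually_responsive=responsive, responsive_p=min(p_cue, p_array),
                rf_class=rf, R_face=r_face, R_house=r_house, SI=si,
                category_class=cat_class, attention_selective=att_flag,
                attention_p=att_p, attention_index=att_idx,
            )
        )
    table = pd.DataFrame([dataclasses.asdict(r) for r in records])
    table.to_csv(run.out / "unit_screen.csv", index=False)
    run.log(f"screen: {len(table)} units, "
            f"{int(table.attention_selective.sum())} attention-selective")


def stage_axis(run: _Run) -> None:
    run.load_session()
    fix = run.session.fixations()
    distractor_fix = fix[~fix.is_target.astype(bool)]
    rows = []
    for k, unit in enumerate(run.session.units):
        means = _stimulus_mean_rates(unit, distractor_fix, WINDOWS["feature"])
        stim_ids = means.index.to_numpy()
        feats = run.stimuli.features[run.stimuli.index_of(stim_ids)]
        try:
            fit = axis_mod.axis_permutation_test(
                feats, means.to_numpy(float), n_perm=run.config.n_perm,
                seed=run.config.seed * 100003 + k,
            )
            rows.append((unit.unit_id, fit.n_components, fit.r_observed,
                         fit.p_perm, fit.is_axis, fit.strength))
        except FixsearchError as exc:
            run.log(f"axis: unit {unit.unit_id} skipped ({exc})")
    pd.DataFrame(
        rows,
        columns=["unit_id", "n_components", "r_observed", "p_perm", "is_axis",
                 "strength"],
    ).to_csv(run.out / "axis_fits.csv", index=False)
    run.log(f"axis: {len(rows)} units fit")


def stage_geometry(run: _Run) -> None:
    run.load_session()
    sess = run.session
    fix = sess.fixations()
    both = _both_role_stimuli(fix)
    if len(both) < 3:
        raise InsufficientDataError(
            "geometry needs >= 3 stimuli fixated in both roles"
        )
    tgt_fix = fix[fix.is_target.astype(bool)]
    dis_fix = fix[~fix.is_target.astype(bool)]
    geo_rows, contrast_rows = [], []
    for window in ("feature", "attention"):
        wname = "early" if window == "feature" else "late"
        rt = _response_matrix(sess.units, tgt_fix, WINDOWS[window], both)
        rd = _response_matrix(sess.units, dis_fix, WINDOWS[window], both)
        st, sd = geo_mod.population_geometry(rt, rd, window=wname)
        for summ in (st, sd):
            for (i, j), dist, ang in zip(
                summ.pair_index, summ.pair_distances, summ.pair_angles_deg
            ):
                geo_rows.append((wname, summ.condition, int(both[i]),
                                 int(both[j]), dist, ang))
        c = geo_mod.geometry_contrast(st, sd)
        contrast_rows.append(
            (wname, float(np.nanmean(c["distance_contrast"])),
             c["t_distance"], c["p_distance"], c["df_distance"],
             float(np.nanmean(c["angle_contrast"])),
             c["t_angle"], c["p_angle"], c["df_angle"])
        )
    pd.DataFrame(
        geo_rows,
        columns=["window", "condition", "stimulus_i", "stimulus_j", "distance",
                 "angle_deg"],
    ).to_csv(run.out / "geometry.csv", index=False)
    pd.DataFrame(
        contrast_rows,
        columns=["window", "mean_distance_contrast", "t_distance", "p_distance",
                 "df_distance", "mean_angle_contrast", "t_angle", "p_angle",
                 "df_angle"],
    ).to_csv(run.out / "geometry_contrasts.csv", index=False)

    # RSA: neural DMs (per area, early-window distractor responses) against
    # the stimulus-feature DM, Bonferroni across areas
    stim_order = (
        _stimulus_mean_rates(sess.units[0], dis_fix, WINDOWS["feature"])
        .index.to_numpy()
    )
    feat_dm = geo_mod.dissimilarity_matrix(
        run.stimuli.features[run.stimuli.index_of(stim_order)].T,
        labels=stim_order,
    )
    areas = sorted({u.area for u in sess.units})
    rsa_rows = []
    comparisons = []
    for area in areas:
        units = [u for u in sess.units if u.area == area]
        if len(units) < 2:
            continue
        resp = _response_matrix(units, dis_fix, WINDOWS["feature"], stim_order)
        try:
            dm = geo_mod.dissimilarity_matrix(resp, labels=stim_order)
        except FixsearchError:
            continue
        rho, p = geo_mod.rsa_correspondence(
            dm, feat_dm, n_perm=run.config.n_perm, seed=run.config.seed + 17
        )
        comparisons.append((f"{area}_vs_features", rho, p))
    n_comp = max(len(comparisons), 1)
    for name, rho, p in comparisons:
        rsa_rows.append((name, rho, p, min(1.0, p * n_comp)))
    pd.DataFrame(
        rsa_rows, columns=["comparison", "spearman_rho", "p_perm", "p_bonferroni"]
    ).to_csv(run.out / "rsa.csv", index=False)
    run.log(f"geometry: {len(both)} stimuli in both roles, "
            f"{len(rsa_rows)} RSA comparisons")


def _spike_lfp_pairs(run: _Run):
    pairs = [
        (u, c)
        for u in run.session.units
        for c in run.session.lfp
        if u.electrode_id != c.electrode_id
    ]
    if run.config.max_pairs is not None:
        pairs = pairs[: run.config.max_pairs]
    return pairs


def stage_coherence(run: _Run) -> None:
    run.load_session()
    cfg = run.config
    fix = run.session.fixations()
    tgt_fix = fix[fix.is_target.astype(bool)]
    dis_fix = fix[~fix.is_target.astype(bool)]
    freq_rows, band_rows = [], []
    skipped = 0
    for u, c in _spike_lfp_pairs(run):
        try:
            segs_t, _ = coh_mod.extract_fixation_segments(run.session, tgt_fix,
                                                          c, u)
            segs_d, _ = coh_mod.extract_fixation_segments(run.session, dis_fix,
                                                          c, u)
            est_d, est_t = coh_mod.equalized_coherence(
                segs_d, segs_t, fs=c.fs, n_repeats=cfg.equalization_repeats,
                seed=cfg.seed + u.unit_id * 1009 + c.channel_id,
                min_segments=cfg.coherence_min_fixations,
                min_spikes=cfg.coherence_min_spikes,
            )
        except FixsearchError:
            skipped += 1
            continue
        for cond, est in (("distractor", est_d), ("target", est_t)):
            for f, v in zip(est.freqs, est.values):
                freq_rows.append((u.unit_id, c.channel_id, cond, f, v,
                                  est.n_fixations_used, est.n_spikes_used))
        theta_d = coh_mod.band_average(est_d, cfg.theta_band)
        theta_t = coh_mod.band_average(est_t, cfg.theta_band)
        desync = normalized_contrast(theta_d, theta_t)
        band_rows.append((u.unit_id, u.area, c.channel_id, c.area, theta_d,
                          theta_t, desync))
    pd.DataFrame(
        freq_rows,
        columns=["spike_unit", "lfp_channel", "condition", "freq_hz",
                 "coherence", "n_fix", "n_spikes"],
    ).to_csv(run.out / "coherence.csv", index=False)
    pd.DataFrame(
        band_rows,
        columns=["spike_unit", "spike_area", "lfp_channel", "lfp_area",
                 "theta_coherence_distractor", "theta_coherence_target",
                 "desynchronization_index"],
    ).to_csv(run.out / "coherence_band.csv", index=False)
    run.log(f"coherence: {len(band_rows)} pairs, {skipped} skipped")


def stage_granger(run: _Run) -> None:
    run.load_session()
    cfg = run.config
    fix = run.session.fixations()
    conditions = {
        "target": fix[fix.is_target.astype(bool)],
        "distractor": fix[~fix.is_target.astype(bool)],
    }
    band_rows = []
    skipped = 0
    for u, c in _spike_lfp_pairs(run):
        per_cond = {}
        try:
            for cond, f_ev in conditions.items():
                segs, _ = coh_mod.extract_fixation_segments(run.session, f_ev,
                                                            c, u)
                lfps = [s.lfp for s in segs]
                spikes = [s.spikes for s in segs]
                processed = gc_mod.preprocess_segments(lfps, spikes, fs=c.fs)
                kept = []
                for seg in processed:
                    _, stationary = gc_mod.kpss_screen(seg[:, 1])
                    if stationary:
                        kept.append(seg)
                if len(kept) < cfg.coherence_min_fixations:
                    raise InsufficientDataError(
                        f"{len(kept)} stationary segments"
                    )
                model = gc_mod.fit_var(kept, max_order=cfg.granger_max_order,
                                       fs=c.fs)
                est = gc_mod.spectral_granger(model)
                per_cond[cond] = (est, len(kept), model.order)
        except FixsearchError:
            skipped += 1
            continue
        est_d, n_d, p_d = per_cond["distractor"]
        est_t, n_t, p_t = per_cond["target"]
        contrast = gc_mod.gc_contrast(est_d, est_t, cfg.theta_band)
        d_xy, d_yx = est_d.band_mean(cfg.theta_band)
        t_xy, t_yx = est_t.band_mean(cfg.theta_band)
        band_rows.append(
            (u.unit_id, u.area, c.channel_id, c.area, "spike_to_lfp",
             d_xy, t_xy, contrast["x_to_y"], n_d, n_t, p_d, p_t)
        )
        band_rows.append(
            (u.unit_id, u.area, c.channel_id, c.area, "lfp_to_spike",
             d_yx, t_yx, contrast["y_to_x"], n_d, n_t, p_d, p_t)
        )
    pd.DataFrame(
        band_rows,
        columns=["spike_unit", "spike_area", "lfp_channel", "lfp_area",
                 "direction", "gc_theta_distractor", "gc_theta_target",
                 "gc_contrast", "n_seg_distractor", "n_seg_target",
                 "var_order_distractor", "var_order_target"],
    ).to_csv(run.out / "granger_band.csv", index=False)
    run.log(f"granger: {len(band_rows) // 2} pairs, {skipped} skipped")


# ---------------------------------------------------------------------------
# group statistics and report


def group_comparison_stats(
    unit_table: pd.DataFrame,
    axis_fits: pd.DataFrame,
    alpha: float = 0.05,
) -> dict:
    """Population-level tests mirroring the group summaries of the analysis.

    * binomial test per area: is the number of flagged units above the
      chance rate (= the selection alpha)?
    * chi-squared test for proportion differences between areas;
    * two-sample t for attention index, axis vs non-axis units;
    * per-area 2x2 contingency of attention selectivity within axis units
      (Bonferroni across areas).
    """
    merged = unit_table.merge(axis_fits[["unit_id", "is_axis"]], on="unit_id")
    areas = sorted(merged.area.unique())
    binomial_rows = []
    for flag_col in ("is_axis", "attention_selective"):
        for area in areas:
            sub = merged[merged.area == area]
            k = int(sub[flag_col].sum())
            n = len(sub)
            if n == 0:
                continue
            p = stats.binomtest(k, n, alpha, alternative="greater").pvalue
            binomial_rows.append((flag_col, area, k, n, k / n, float(p)))
    binomial = pd.DataFrame(
        binomial_rows,
        columns=["flag", "area", "n_flagged", "n_units", "proportion", "p"],
    )

    chi2_rows = []
    for flag_col in ("is_axis", "attention_selective"):
        table = np.array(
            [
                [
                    int(merged[(merged.area == a)][flag_col].sum()),
                    int((~merged[merged.area == a][flag_col].astype(bool)).sum()),
                ]
                for a in areas
            ]
        )
        if np.all(table.sum(axis=1) > 0) and len(areas) > 1:
            res = stats.chi2_contingency(table, correction=False)
            chi2_rows.append((flag_col, float(res.statistic), float(res.pvalue)))
    chi2 = pd.DataFrame(chi2_rows, columns=["flag", "chi2", "p"])

    ax = merged[merged.is_axis.astype(bool)]["attention_index"].dropna()
    nx = merged[~merged.is_axis.astype(bool)]["attention_index"].dropna()
    if len(ax) >= 2 and len(nx) >= 2:
        t_res = stats.ttest_ind(ax, nx)
        attention_t = {
            "t": float(t_res.statistic), "p": float(t_res.pvalue),
            "mean_axis": float(ax.mean()), "mean_nonaxis": float(nx.mean()),
            "n_axis": len(ax), "n_nonaxis": len(nx),
        }
    else:
        attention_t = {"t": np.nan, "p": np.nan, "mean_axis": np.nan,
                       "mean_nonaxis": np.nan, "n_axis": len(ax),
                       "n_nonaxis": len(nx)}

    enrich_rows = []
    for area in areas:
        sub = merged[merged.area == area]
        tbl = np.array(
            [
                [
                    int((sub.is_axis.astype(bool)
                         & sub.attention_selective.astype(bool)).sum()),
                    int((sub.is_axis.astype(bool)
                         & ~sub.attention_selective.astype(bool)).sum()),
                ],
                [
                    int((~sub.is_axis.astype(bool)
                         & sub.attention_selective.astype(bool)).sum()),
                    int((~sub.is_axis.astype(bool)
                         & ~sub.attention_selective.astype(bool)).sum()),
                ],
            ]
        )
        if np.all(tbl.sum(axis=1) > 0) and np.all(tbl.sum(axis=0) > 0):
            res = stats.chi2_contingency(tbl, correction=False)
            p_bonf = min(1.0, float(res.pvalue) * len(areas))
            enrich_rows.append((area, float(res.statistic), float(res.pvalue),
                                p_bonf))
    enrichment = pd.DataFrame(
        enrich_rows, columns=["area", "chi2", "p", "p_bonferroni"]
    )
    return {"binomial": binomial, "chi2": chi2, "attention_t": attention_t,
            "enrichment": enrichment}


def build_report(run: _Run) -> None:
    """Summary tables (one per figure analog) plus a ground-truth scorecard."""
    sections = {}
    skipped = []
    try:
        unit_table = run.table("unit_screen.csv")
        axis_fits = run.table("axis_fits.csv")
        group = group_comparison_stats(unit_table, axis_fits, run.config.alpha)
        group["binomial"].to_csv(run.out / "report_proportions.csv", index=False)
        group["chi2"].to_csv(run.out / "report_area_chi2.csv", index=False)
        group["enrichment"].to_csv(run.out / "report_enrichment.csv", index=False)
        pd.DataFrame([group["attention_t"]]).to_csv(
            run.out / "report_attention_by_class.csv", index=False
        )
        sections["group"] = group
    except SessionIOError as exc:
        skipped.append(f"group stats: {exc}")

    merged = None
    try:
        merged = run.table("unit_screen.csv").merge(
            run.table("axis_fits.csv")[["unit_id", "is_axis"]], on="unit_id"
        )
    except SessionIOError:
        pass

    for name, out_name, value_col, key_col in (
        ("coherence_band.csv", "report_desync_by_class.csv",
         "desynchronization_index", "spike_unit"),
        ("granger_band.csv", "report_gc_by_class.csv", "gc_contrast",
         "spike_unit"),
    ):
        try:
            band = run.table(name)
        except SessionIOError as exc:
            skipped.append(f"{name}: {exc}")
            continue
        if merged is None or not len(band):
            skipped.append(f"{name}: no unit classes available")
            continue
        band = band.merge(
            merged[["unit_id", "is_axis"]], left_on=key_col, right_on="unit_id"
        )
        rows = []
        group_cols = ["direction"] if "direction" in band.columns else [None]
        for direction in (band.direction.unique() if group_cols[0] else [None]):
            sub = band if direction is None else band[band.direction == direction]
            a = sub[sub.is_axis.astype(bool)][value_col].dropna()
            n = sub[~sub.is_axis.astype(bool)][value_col].dropna()
            if len(a) >= 2 and len(n) >= 2:
                t_res = stats.ttest_ind(a, n)
                rows.append((direction or "all", float(a.mean()),
                             float(n.mean()), float(t_res.statistic),
                             float(t_res.pvalue), len(a), len(n)))
        pd.DataFrame(
            rows,
            columns=["direction", "mean_axis", "mean_nonaxis", "t", "p",
                     "n_axis", "n_nonaxis"],
        ).to_csv(run.out / out_name, index=False)

    # ground-truth recovery scorecard for synthetic runs
    if run.truth_table is None:
        truth_path = run.out / "session" / "ground_truth.csv"
        if truth_path.exists():
            run.truth_table = pd.read_csv(truth_path)
    if run.truth_table is not None:
        try:
            axis_fits = run.table("axis_fits.csv")
            unit_table = run.table("unit_screen.csv")
            sc = scorecard(run.truth_table, axis_fits, unit_table,
                           run.out / "coherence_band.csv")
            pd.DataFrame([sc]).to_csv(run.out / "report_scorecard.csv",
                                      index=False)
        except SessionIOError as exc:
            skipped.append(f"scorecard: {exc}")
    else:
        skipped.append("scorecard: no ground truth (real session)")

    with open(run.out / "report_skipped.txt", "w") as fh:
        fh.write("\n".join(skipped) + ("\n" if skipped else ""))
    run.log(f"report: {len(skipped)} sections skipped")


def scorecard(
    truth_table: pd.DataFrame,
    axis_fits: pd.DataFrame,
    unit_table: pd.DataFrame,
    coherence_band_path=None,
) -> dict:
    """Planted-effect recovery summary for a synthetic run."""
    merged = truth_table.merge(axis_fits, on="unit_id",
                               suffixes=("_true", "_det"))
    planted = merged.is_axis_true.astype(bool)
    detected = merged.is_axis_det.astype(bool)
    sensitivity = (
        float((planted & detected).sum() / planted.sum()) if planted.any()
        else np.nan
    )
    specificity = (
        float((~planted & ~detected).sum() / (~planted).sum())
        if (~planted).any() else np.nan
    )
    att = truth_table.merge(unit_table, on="unit_id")
    gain_up = att[att.attention_gain > 1.0]["attention_index"].dropna()
    mean_att = float(gain_up.mean()) if len(gain_up) else np.nan
    out = {
        "axis_sensitivity": sensitivity,
        "axis_specificity": specificity,
        "mean_attention_index_gain_units": mean_att,
    }
    if coherence_band_path is not None and Path(coherence_band_path).exists():
        band = pd.read_csv(coherence_band_path)
        if len(band):
            out["mean_desynchronization_index"] = float(
                band.desynchronization_index.mean()
            )
    return out


# ---------------------------------------------------------------------------
# entry point


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "screen": stage_screen,
    "axis": stage_axis,
    "geometry": stage_geometry,
    "coherence": stage_coherence,
    "granger": stage_granger,
    "report": build_report,
}


def run_pipeline(config: PipelineConfig, out_dir, stages=STAGES) -> Path:
    """Execute the requested stages in order; halt on the first failure.

    Writes ``manifest.json`` (seed, config hash, completed stages) to the
    output directory and returns its path.  Partial outputs of completed
    stages are retained if a later stage fails.
    """
    run = _Run(config, out_dir)
    if config.session_path is None and "simulate" not in stages:
        run.load_session()  # must already exist in out_dir
    completed = []
    manifest_path = run.out / "manifest.json"
    try:
        for stage in stages:
            if stage not in _STAGE_FUNCS:
                raise ValueError(f"unknown stage {stage!r}")
            try:
                _STAGE_FUNCS[stage](run)
            except Exception as exc:
                run.log(f"{stage}: FAILED ({exc})")
                raise FixsearchError(f"stage {stage!r} failed: {exc}") from exc
            completed.append(stage)
    finally:
        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "stages_completed": completed,
            "alpha": config.alpha,
            "n_perm": config.n_perm,
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return run.out
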