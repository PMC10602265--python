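"""Scanpath statistics: filters, object assignment, fitness, diagnostics.

All functions operate on event tables -- pandas DataFrames in the common
schema produced by the simulator and by the synthetic-reference generator
(`scene_id, run_id, event_type {fov, sac}, t_start_ms, t_end_ms, x/y start
and end in px, object_id, amplitude_dva, duration_ms`) -- so human reference
data and simulated data are evaluated by exactly the same code path.

The headline objective is the fitness ``-(d_SA + d_FD) / 2`` where ``d_SA``
and ``d_FD`` are two-sample Kolmogorov-Smirnov distances of the pooled
saccade-amplitude and foveation-duration samples against the reference.
Beyond that, the module provides the functional foveation categories
(Background / Detection / Inspection / Return), their time course, per-object
dwell-time regression, inter-saccade turning angles, return-saccade and
object-return statistics, and first-detection agreement.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from gazesim.scene_data import SceneBundle

__all__ = [
    "MIN_FOVEATION_MS",
    "MIN_SACCADE_DVA",
    "filter_events",
    "ObjectAssigner",
    "assign_objects",
    "assign_event_objects",
    "categorize_foveations",
    "add_categories",
    "ks_statistic",
    "fitness",
    "sequential_stats",
    "object_dwell_times",
    "dwell_regression",
    "object_return_stats",
    "first_detections",
    "first_detection_agreement",
    "category_timecourse",
    "evaluation_report",
]

MIN_FOVEATION_MS = 100.0 / 3.0  # one frame at 30 fps
MIN_SACCADE_DVA = 0.5  # smaller saccades count as fixational microsaccades

CATEGORIES = ("Background", "Detection", "Inspection", "Return")


def filter_events(events: pd.DataFrame) -> pd.DataFrame:
    """Drop sub-frame foveations and microsaccades.

    Foveations shorter than one frame (33.3 ms) and saccades with amplitude
    below 0.5 dva are removed.  Applied identically to simulated and
    reference tables before any statistic is computed.
    """
    if events.empty:
        return events.copy()
    fov = events.event_type == "fov"
    keep = np.where(
        fov,
        events.duration_ms >= MIN_FOVEATION_MS,
        events.amplitude_dva >= MIN_SACCADE_DVA,
    )
    return events[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Object assignment for position-only gaze traces
# ---------------------------------------------------------------------------


class ObjectAssigner:
    """Maps gaze positions to object ids with a 1-dva tolerance ring.

    A gaze sample counts as on object ``i`` when it lies inside the mask
    ``O_i`` dilated by ``radius_dva`` (tolerance for tracking inaccuracy);
    otherwise it is on the background.  Ambiguities inside the dilation ring
    resolve to the object with the nearest mask pixel.  Per-frame distance
    transforms are cached, so assigning many runs on one scene is cheap.
    """

    def __init__(self, bundle: SceneBundle, radius_dva: float = 1.0):
        self.bundle = bundle
        self.radius_px = radius_dva * bundle.px_per_dva
        self._cache: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}

    def _frame_maps(self, frame: int) -> Tuple[np.ndarray, np.ndarray]:
        if frame not in self._cache:
            labels = self.bundle.objects[frame]
            dist, (iy, ix) = ndimage.distance_transform_edt(
                labels == 0, return_indices=True
            )
            nearest = labels[iy, ix]
            self._cache[frame] = (dist, nearest)
        return self._cache[frame]

    def at(self, frame: int, x: float, y: float) -> int:
        """Object id at a continuous gaze position, 0 for background."""
        xi = int(np.clip(round(x), 0, self.bundle.width_px - 1))
        yi = int(np.clip(round(y), 0, self.bundle.height_px - 1))
        labels = self.bundle.objects[frame]
        if labels[yi, xi] > 0:
            return int(labels[yi, xi])
        dist, nearest = self._frame_maps(frame)
        if dist[yi, xi] <= self.radius_px:
            return int(nearest[yi, xi])
        return 0


def assign_objects(trace: pd.DataFrame, bundle: SceneBundle,
                   radius_dva: float = 1.0,
                   assigner: Optional[ObjectAssigner] = None) -> pd.Series:
    """Per-frame on-object ids for the foveation frames of a gaze trace."""
    if assigner is None:
        assigner = ObjectAssigner(bundle, radius_dva)
    ids = np.full(len(trace), -1)
    fov = (trace.state == "fov").to_numpy()
    frames = trace.frame.to_numpy()
    xs = trace.x_px.to_numpy()
    ys = trace.y_px.to_numpy()
    for k in np.nonzero(fov)[0]:
        ids[k] = assigner.at(int(frames[k]), xs[k], ys[k])
    return pd.Series(ids, index=trace.index, name="object_id")


def assign_event_objects(events: pd.DataFrame, trace: pd.DataFrame,
                         bundle: SceneBundle, radius_dva: float = 1.0,
                         assigner: Optional[ObjectAssigner] = None) -> pd.DataFrame:
    """Fill each foveation's ``object_id`` by the majority rule.

    A foveation event gets the id of the mask its frames spent the most
    time on.  Needed for position-only traces (human reference data and
    the space-based models); object-mode events keep their known target id.
    """
    ids = assign_objects(trace, bundle, radius_dva, assigner).to_numpy()
    frame_ms = bundle.frame_ms
    out = events.copy()
    frames = trace.frame.to_numpy()
    for k, row in out.iterrows():
        if row.event_type != "fov":
            continue
        lo = int(math.floor(row.t_start_ms / frame_ms))
        hi = int(math.ceil(row.t_end_ms / frame_ms))
        sel = ids[(frames >= lo) & (frames < max(hi, lo + 1)) & (ids >= 0)]
        if len(sel) == 0:
            continue
        vals, counts = np.unique(sel, return_counts=True)
        out.at[k, "object_id"] = int(vals[np.argmax(counts)])
    return out


# ---------------------------------------------------------------------------
# Functional foveation categories
# ---------------------------------------------------------------------------


def categorize_foveations(object_ids: Sequence[int]) -> List[str]:
    """Classify a chronological id sequence into functional categories.

    Background: id 0.  Detection: the scanpath's first foveation of this
    object.  Inspection: same object as the immediately preceding foveation
    (a within-object saccade).  Return: a previously foveated object that is
    not the immediately preceding one (background breaks inspection chains).
    """
    seen: set = set()
    prev: Optional[int] = None
    cats: List[str] = []
    for oid in object_ids:
        oid = int(oid)
        if oid == 0:
            cats.append("Background")
        elif oid not in seen:
            cats.append("Detection")
        elif oid == prev:
            cats.append("Inspection")
        else:
            cats.append("Return")
        if oid != 0:
            seen.add(oid)
        prev = oid
    return cats


def add_categories(events: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``category`` column per (scene, run) foveation sequence."""
    out = events.copy()
    out["category"] = None
    for _, idx in out.groupby(["scene_id", "run_id"]).groups.items():
        sub = out.loc[idx]
        sub = sub.sort_values("t_start_ms")
        fmask = sub.event_type == "fov"
        cats = categorize_foveations(sub.loc[fmask, "object_id"].astype(int))
        out.loc[sub.index[fmask], "category"] = cats
    return out


# ---------------------------------------------------------------------------
# Distribution distances and fitness
# ---------------------------------------------------------------------------


def ks_statistic(sample_a: Iterable[float], sample_b: Iterable[float]) -> float:
    """Two-sample Kolmogorov-Smirnov distance sup |F(x) - G(x)| in [0, 1]."""
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("KS statistic requires non-empty samples")
    return float(stats.ks_2samp(a, b, method="asymp").statistic)


def fitness(sim: pd.DataFrame, ref: pd.DataFrame) -> float:
    """Objective ``-(d_SA + d_FD) / 2`` on pooled filtered event tables.

    ``d_SA`` compares saccade amplitudes, ``d_FD`` foveation durations,
    pooled across all scenes and runs.  0 is the maximum (identical
    distributions); the value is never below -1.
    """
    d_fd = ks_statistic(sim[sim.event_type == "fov"].duration_ms,
                        ref[ref.event_type == "fov"].duration_ms)
    d_sa = ks_statistic(sim[sim.event_type == "sac"].amplitude_dva,
                        ref[ref.event_type == "sac"].amplitude_dva)
    return -(d_sa + d_fd) / 2.0


# ---------------------------------------------------------------------------
# Sequential diagnostics
# ---------------------------------------------------------------------------


def _wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def sequential_stats(events: pd.DataFrame, n_bins: int = 30,
                     smooth_bins: int = 5) -> Dict[str, object]:
    """Turning-angle and return-saccade diagnostics.

    The relative angle ``phi`` between consecutive saccade direction vectors
    is in (-180, 180]; with screen y pointing down, positive angles are
    clockwise turns on screen (only ``|phi|`` enters the published
    statistics).  Return saccades are consecutive pairs with
    ``|phi| > 178`` degrees and amplitude difference below 1.5 dva.  The
    angle-binned median preceding foveation duration uses 12-degree bins
    smoothed by a centered circular moving average across 5 bins.
    """
    angles: List[float] = []
    amp_diffs: List[float] = []
    prev_durations: List[float] = []
    n_pairs = 0
    n_saccades = 0

    for _, sub in events.groupby(["scene_id", "run_id"]):
        sub = sub.sort_values("t_start_ms")
        sacs = sub[sub.event_type == "sac"]
        n_saccades += len(sacs)
        if len(sacs) < 2:
            continue
        dirs = np.degrees(np.arctan2(sacs.y_end_px - sacs.y_start_px,
                                     sacs.x_end_px - sacs.x_start_px)).to_numpy()
        amps = sacs.amplitude_dva.to_numpy()
        onsets = sacs.t_start_ms.to_numpy()
        fovs = sub[sub.event_type == "fov"]
        for k in range(1, len(sacs)):
            phi = _wrap_angle(dirs[k] - dirs[k - 1])
            angles.append(phi)
            amp_diffs.append(abs(amps[k] - amps[k - 1]))
            # foveation immediately preceding the second saccade of the pair
            between = fovs[(fovs.t_end_ms <= onsets[k] + 1e-9)
                           & (fovs.t_start_ms >= onsets[k - 1] - 1e-9)]
            prev_durations.append(
                float(between.duration_ms.iloc[-1]) if len(between) else np.nan
            )
            n_pairs += 1

    angles_arr = np.asarray(angles)
    amp_arr = np.asarray(amp_diffs)
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    hist, _ = np.histogram(angles_arr, bins=edges) if n_pairs else (np.zeros(n_bins, int), edges)

    med = np.full(n_bins, np.nan)
    if n_pairs:
        which = np.clip(np.digitize(angles_arr, edges) - 1, 0, n_bins - 1)
        pd_arr = np.asarray(prev_durations)
        for b in range(n_bins):
            vals = pd_arr[(which == b) & ~np.isnan(pd_arr)]
            if vals.size:
                med[b] = np.median(vals)
    # centered circular moving average, NaN-aware
    half = smooth_bins // 2
    smoothed = np.full(n_bins, np.nan)
    for b in range(n_bins):
        window = med[(np.arange(b - half, b + half + 1)) % n_bins]
        window = window[~np.isnan(window)]
        if window.size:
            smoothed[b] = window.mean()

    frac_gt135 = float(np.mean(np.abs(angles_arr) > 135.0)) if n_pairs else np.nan
    returns = ((np.abs(angles_arr) > 178.0) & (amp_arr < 1.5)) if n_pairs else np.zeros(0, bool)
    return {
        "angles_deg": angles_arr,
        "angle_hist": hist,
        "bin_edges_deg": edges,
        "frac_gt135": frac_gt135,
        "return_saccade_ratio": float(returns.mean()) if n_pairs else np.nan,
        "n_pairs": n_pairs,
        "n_saccades": n_saccades,
        "median_prev_duration_by_angle": smoothed,
    }


# ---------------------------------------------------------------------------
# Object-level statistics
# ---------------------------------------------------------------------------


def object_dwell_times(events: pd.DataFrame,
                       include_background: bool = False) -> pd.Series:
    """Total foveation time per (scene, object), averaged over runs."""
    fov = events[(events.event_type == "fov") & (events.object_id >= 0)]
    if not include_background:
        fov = fov[fov.object_id > 0]
    if fov.empty:
        return pd.Series(dtype=float)
    per_run = fov.groupby(["scene_id", "run_id", "object_id"]).duration_ms.sum()
    n_runs = events.groupby("scene_id").run_id.nunique()
    total = per_run.groupby(["scene_id", "object_id"]).sum()
    return total / n_runs.reindex(total.index.get_level_values(0)).to_numpy()


def dwell_regression(sim: pd.DataFrame, ref: pd.DataFrame,
                     include_background: bool = False) -> Dict[str, float]:
    """Least-squares line of simulated vs reference per-object dwell times.

    A perfect correspondence gives slope 1, intercept 0, r^2 = 1.  Objects
    missing from one side enter with zero dwell.
    """
    ds = object_dwell_times(sim, include_background)
    dr = object_dwell_times(ref, include_background)
    idx = ds.index.union(dr.index)
    x = dr.reindex(idx, fill_value=0.0).to_numpy()
    y = ds.reindex(idx, fill_value=0.0).to_numpy()
    if len(idx) < 2 or np.allclose(x, x[0]):
        return {"slope": np.nan, "intercept": np.nan, "r2": np.nan, "n_objects": len(idx)}
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "n_objects": len(idx)}


def object_return_stats(events: pd.DataFrame) -> Dict[str, float]:
    """Saccades returning to a previously foveated (not current) object.

    The return time is measured from the end of that object's last
    foveation to the landing of the returning saccade (the onset of the new
    foveation on it).  Reported as a ratio over all saccades plus the
    median return time.
    """
    return_times: List[float] = []
    n_saccades = 0
    for _, sub in events.groupby(["scene_id", "run_id"]):
        sub = sub.sort_values("t_start_ms").reset_index(drop=True)
        last_off: Dict[int, float] = {}
        prev_fov_id: Optional[int] = None
        for _, row in sub.iterrows():
            if row.event_type == "sac":
                n_saccades += 1
                continue
            oid = int(row.object_id)
            if oid > 0 and oid in last_off and prev_fov_id != oid:
                return_times.append(row.t_start_ms - last_off[oid])
            if oid > 0:
                last_off[oid] = row.t_end_ms
            prev_fov_id = oid
    ratio = len(return_times) / n_saccades if n_saccades else np.nan
    med = float(np.median(return_times)) if return_times else np.nan
    return {"object_return_ratio": ratio, "median_return_ms": med,
            "n_returns": len(return_times), "n_saccades": n_saccades}


def first_detections(events: pd.DataFrame) -> pd.Series:
    """Modal first-detected (non-background) object id per scene."""
    firsts: Dict[str, List[int]] = {}
    for (scene, _run), sub in events.groupby(["scene_id", "run_id"]):
        fov = sub[(sub.event_type == "fov") & (sub.object_id > 0)]
        if fov.empty:
            continue
        first = fov.sort_values("t_start_ms").object_id.iloc[0]
        firsts.setdefault(scene, []).append(int(first))
    modal = {}
    for scene, ids in firsts.items():
        vals, counts = np.unique(ids, return_counts=True)
        modal[scene] = int(vals[np.argmax(counts)])
    return pd.Series(modal, dtype=int)


def first_detection_agreement(sim: pd.DataFrame, ref: pd.DataFrame) -> float:
    """Fraction of scenes where sim and reference agree on the modal
    first-detected object."""
    fs, fr = first_detections(sim), first_detections(ref)
    scenes = fs.index.intersection(fr.index)
    if len(scenes) == 0:
        return np.nan
    return float((fs[scenes] == fr[scenes]).mean())


def category_timecourse(events: pd.DataFrame, bin_ms: float = 100.0,
                        duration_ms: Optional[float] = None) -> pd.DataFrame:
    """Share of concurrently ongoing foveation time per category per bin.

    Saccade time is excluded; within each bin the proportions are
    normalised over foveation time only, so they sum to 1 wherever any
    foveation overlaps the bin.
    """
    if "category" not in events.columns:
        events = add_categories(events)
    fov = events[events.event_type == "fov"]
    if duration_ms is None:
        duration_ms = float(events.t_end_ms.max()) if len(events) else 0.0
    n_bins = int(math.ceil(duration_ms / bin_ms))
    table = np.zeros((n_bins, len(CATEGORIES)))
    for _, row in fov.iterrows():
        c = CATEGORIES.index(row.category)
        lo, hi = row.t_start_ms, row.t_end_ms
        b0, b1 = int(lo // bin_ms), min(int(math.ceil(hi / bin_ms)), n_bins)
        for b in range(b0, b1):
            overlap = min(hi, (b + 1) * bin_ms) - max(lo, b * bin_ms)
            if overlap > 0:
                table[b, c] += overlap
    totals = table.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        props = np.where(totals > 0, table / totals, np.nan)
    return pd.DataFrame(
        props, columns=list(CATEGORIES),
        index=pd.Index((np.arange(n_bins) + 0.5) * bin_ms, name="t_ms"),
    )


def evaluation_report(sim: pd.DataFrame, ref: pd.DataFrame) -> Dict[str, float]:
    """Flat summary combining the main statistics of both tables."""
    sim_f, ref_f = filter_events(sim), filter_events(ref)
    d_fd = ks_statistic(sim_f[sim_f.event_type == "fov"].duration_ms,
                        ref_f[ref_f.event_type == "fov"].duration_ms)
    d_sa = ks_statistic(sim_f[sim_f.event_type == "sac"].amplitude_dva,
                        ref_f[ref_f.event_type == "sac"].amplitude_dva)
    seq_sim = sequential_stats(sim_f)
    seq_ref = sequential_stats(ref_f)
    ret_sim = object_return_stats(sim_f)
    reg = dwell_regression(sim_f, ref_f)
    report = {
        "d_FD": d_fd,
        "d_SA": d_sa,
        "fitness": -(d_sa + d_fd) / 2.0,
        "frac_gt135_sim": seq_sim["frac_gt135"],
        "frac_gt135_ref": seq_ref["frac_gt135"],
        "return_saccade_ratio_sim": seq_sim["return_saccade_ratio"],
        "object_return_ratio_sim": ret_sim["object_return_ratio"],
        "median_object_return_ms_sim": ret_sim["median_return_ms"],
        "dwell_slope": reg["slope"],
        "dwell_intercept": reg["intercept"],
        "dwell_r2": reg["r2"],
        "first_detection_agreement": first_detection_agreement(sim_f, ref_f),
    }
    return report
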