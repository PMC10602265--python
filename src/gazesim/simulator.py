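"""Scanpath simulation: the frame loop tying all mechanisms together.

One call to :func:`simulate_scanpath` produces one scanpath for one scene,
one model variant and one seed.  Per frame it combines the feature map, the
gaze-centred sensitivity and the inhibition of return into drift rates,
advances the accumulator race by one step (scaled by the fraction of the
frame spent foveating), and either updates the gaze (pursuit + jitter) or
-- on a threshold crossing -- closes the foveation event at the linearly
interpolated decision time, executes a saccade with an amplitude-dependent
duration, and resets the race.

The five published variants are configurations of three switches:

========  ==============  ==============  ========
variant   selection mode  feature source  IOR mode
========  ==============  ==============  ========
S.ll      space           lowlevel        space
S.hl      space           highlevel       space
O.ll      object          lowlevel        object
O.cb      object          none            object
M.ll      object          lowlevel        space
========  ==============  ==============  ========

``lowlevel`` vs ``highlevel`` name which precomputed saliency map the scene
bundle was built from; the arithmetic is identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from gazesim.attention_fields import (
    CenterBiasParams,
    FoveationHistory,
    IorParams,
    SensitivityParams,
    center_bias_map,
    combined_feature_map,
    inhibition_object,
)
from gazesim.gaze_update import (
    clip_to_frame,
    fixational_jitter,
    foveation_drift,
    saccade_landing,
)
from gazesim.saccadic_decision import (
    DdmParams,
    DecisionState,
    ddm_step,
    detect_crossing,
    drift_rates_object,
    drift_rates_space,
    saccade_duration,
)
from gazesim.scene_data import SceneBundle

__all__ = [
    "ModelSpec",
    "FoveationEvent",
    "SaccadeEvent",
    "Scanpath",
    "simulate_scanpath",
    "run_batch",
    "scanpaths_to_events",
    "EVENT_COLUMNS",
    "VARIANTS",
]

EVENT_COLUMNS = [
    "scene_id",
    "run_id",
    "event_type",
    "t_start_ms",
    "t_end_ms",
    "x_start_px",
    "y_start_px",
    "x_end_px",
    "y_end_px",
    "object_id",
    "amplitude_dva",
    "duration_ms",
]

# Fitted best-individual parameter values per variant (sigma in dva, r per
# frame); used as defaults so a variant can be simulated out of the box.
VARIANTS: Dict[str, Dict[str, float]] = {
    "S.ll": dict(selection="space", source="lowlevel", ior="space",
                 sigma_s=12.51, theta=0.384, s=0.011, r=1 / 253.3, sigma_i=7.79),
    "S.hl": dict(selection="space", source="highlevel", ior="space",
                 sigma_s=10.71, theta=1.715, s=0.092, r=1 / 296.0, sigma_i=4.51),
    "M.ll": dict(selection="object", source="lowlevel", ior="space",
                 sigma_s=9.09, theta=1.068, s=0.247, r=1 / 170.6, sigma_i=6.06),
    "O.ll": dict(selection="object", source="lowlevel", ior="object",
                 sigma_s=13.75, theta=2.128, s=0.230, r=1 / 272.0, xi=0.72),
    "O.cb": dict(selection="object", source="none", ior="object",
                 sigma_s=5.81, theta=2.973, s=0.236, r=1 / 159.4, xi=0.95),
}


@dataclass
class ModelSpec:
    """A model variant plus all free parameters.

    Lengths (``sigma_s``, ``sigma_i``, ``sigma_d``) are in dva and converted
    to pixels at use; ``r`` is the IOR recovery slope per frame; ``theta``
    and ``s`` are the threshold and noise level of the accumulator race.
    """

    variant: str
    selection_mode: str  # "space" | "object"
    feature_source: str  # "lowlevel" | "highlevel" | "none"
    ior_mode: str  # "space" | "object"
    sigma_s: float
    theta: float
    s: float
    r: float
    sigma_i: Optional[float] = None
    xi: Optional[float] = None
    sigma_d: float = 0.125
    center_bias: CenterBiasParams = field(default_factory=CenterBiasParams)

    @classmethod
    def from_variant(cls, variant: str, **overrides) -> "ModelSpec":
        """Build a spec for one of the published variants, with overrides."""
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; options: {sorted(VARIANTS)}")
        cfg = VARIANTS[variant]
        spec = cls(
            variant=variant,
            selection_mode=cfg["selection"],
            feature_source=cfg["source"],
            ior_mode=cfg["ior"],
            sigma_s=cfg["sigma_s"],
            theta=cfg["theta"],
            s=cfg["s"],
            r=cfg["r"],
            sigma_i=cfg.get("sigma_i"),
            xi=cfg.get("xi"),
        )
        spec = replace(spec, **overrides)
        spec.validate()
        return spec

    def validate(self) -> None:
        if self.selection_mode not in ("space", "object"):
            raise ValueError("selection_mode must be 'space' or 'object'")
        if self.ior_mode not in ("space", "object"):
            raise ValueError("ior_mode must be 'space' or 'object'")
        if self.selection_mode == "space" and self.ior_mode != "space":
            raise ValueError("space-based selection requires space-based IOR")
        if self.ior_mode == "space" and (self.sigma_i is None or self.sigma_i <= 0):
            raise ValueError("space IOR requires sigma_i > 0")
        if self.ior_mode == "object" and (self.xi is None or not 0 <= self.xi <= 1):
            raise ValueError("object IOR requires xi in [0, 1]")
        if self.sigma_s <= 0 or self.theta <= 0 or self.s < 0 or self.r <= 0:
            raise ValueError("sigma_s, theta > 0; s >= 0; r > 0")

    def ior_params(self) -> IorParams:
        return IorParams(mode=self.ior_mode, r=self.r, sigma_i=self.sigma_i, xi=self.xi)

    def ddm_params(self) -> DdmParams:
        return DdmParams(theta=self.theta, s=self.s)


@dataclass
class FoveationEvent:
    onset_ms: float
    offset_ms: float
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    object_id: int  # -1 = not assigned (space-based models)
    category: Optional[str] = None

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


@dataclass
class SaccadeEvent:
    onset_ms: float
    duration_ms: float
    x_start: float
    y_start: float
    x_end: float
    y_end: float
    amplitude_dva: float
    angle_deg: float
    truncated: bool = False

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms


@dataclass
class Scanpath:
    scene_id: str
    run_id: int
    events: List[Union[FoveationEvent, SaccadeEvent]]
    trace: pd.DataFrame

    def foveations(self) -> List[FoveationEvent]:
        return [e for e in self.events if isinstance(e, FoveationEvent)]

    def saccades(self) -> List[SaccadeEvent]:
        return [e for e in self.events if isinstance(e, SaccadeEvent)]

    def to_events(self) -> pd.DataFrame:
        """Event table in the common CSV schema (times ms, amplitudes dva)."""
        rows = []
        for e in self.events:
            if isinstance(e, FoveationEvent):
                rows.append((self.scene_id, self.run_id, "fov", e.onset_ms,
                             e.offset_ms, e.x_start, e.y_start, e.x_end, e.y_end,
                             e.object_id, np.nan, e.duration_ms))
            else:
                rows.append((self.scene_id, self.run_id, "sac", e.onset_ms,
                             e.offset_ms, e.x_start, e.y_start, e.x_end, e.y_end,
                             -1, e.amplitude_dva, e.duration_ms))
        return pd.DataFrame(rows, columns=EVENT_COLUMNS)


class _SpaceIorField:
    """Cached spatial IOR map: one static unit-peak Gaussian per target.

    Target locations are allocentric and never move, so each Gaussian is
    rendered once; only the linear decay weights change over time.
    """

    def __init__(self, xx: np.ndarray, yy: np.ndarray, sigma_px: float, r: float):
        self.xx, self.yy = xx, yy
        self.two_s2 = 2.0 * sigma_px ** 2
        self.r = r
        self.gaussians: List[np.ndarray] = []
        self.times: List[float] = []

    def add(self, x: float, y: float, t: float) -> None:
        g = np.exp(-((self.xx - x) ** 2 + (self.yy - y) ** 2) / self.two_s2)
        self.gaussians.append(g)
        self.times.append(t)

    def field(self, t: float) -> np.ndarray:
        out = np.zeros_like(self.xx, dtype=float)
        for g, th in zip(self.gaussians, self.times):
            w = 1.0 - (t - th) * self.r
            if w > 0:
                out += w * g
        np.minimum(out, 1.0, out=out)
        return out


def simulate_scanpath(bundle: SceneBundle, spec: ModelSpec,
                      seed: Union[int, np.random.SeedSequence, np.random.Generator],
                      run_id: int = 0) -> Scanpath:
    """Simulate one scanpath; fully deterministic given (bundle, spec, seed).

    The simulation starts with a foveation at the frame centre (observers
    are cued to the display centre at video onset).  Foveation and saccade
    events tile the full video duration with no gaps; a saccade that would
    extend past the last frame is truncated there and flagged.
    """
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T, H, W = bundle.n_frames, bundle.height_px, bundle.width_px
    ppd = bundle.px_per_dva
    frame_ms = bundle.frame_ms
    ddm = spec.ddm_params()
    ior = spec.ior_params()
    object_mode = spec.selection_mode == "object"

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    cb = center_bias_map(W, H, spec.center_bias)
    sigma_s_px = spec.sigma_s * ppd
    history = FoveationHistory()
    space_ior = (
        _SpaceIorField(xx, yy, spec.sigma_i * ppd, spec.r)
        if spec.ior_mode == "space" else None
    )

    n_targets = (int(bundle.objects.max()) + 1) if object_mode else H * W
    state = DecisionState(targets=np.arange(n_targets))

    gaze = bundle.center
    fov_id = int(bundle.objects[0][int(round(gaze[1])), int(round(gaze[0]))]) if object_mode else -1
    history.foveated = fov_id if object_mode else None
    fov_start = 0.0  # frames
    fov_start_pos = gaze
    sac_end = 0.0  # frames; end time of the ongoing saccade
    sac_from: Tuple[float, float] = gaze  # interpolation anchors for the trace
    sac_to: Tuple[float, float] = gaze
    sac_onset = 0.0

    events: List[Union[FoveationEvent, SaccadeEvent]] = []
    trace_rows = []

    for t in range(T):
        if sac_end >= t + 1:  # frame fully inside a saccade: no evidence
            f = (t - sac_onset) / max(sac_end - sac_onset, 1e-12)
            px = sac_from[0] + (sac_to[0] - sac_from[0]) * min(max(f, 0.0), 1.0)
            py = sac_from[1] + (sac_to[1] - sac_from[1]) * min(max(f, 0.0), 1.0)
            trace_rows.append((t, t * frame_ms, px, py, "sac", -1))
            continue

        start = max(float(t), sac_end)
        nu = (t + 1) - start

        F = combined_feature_map(bundle, t, spec.feature_source,
                                 spec.center_bias, cb_map=cb)
        S = np.exp(-((xx - gaze[0]) ** 2 + (yy - gaze[1]) ** 2)
                   / (2.0 * sigma_s_px ** 2))
        labels = bundle.objects[t]
        if object_mode and fov_id > 0:
            S[labels == fov_id] = 1.0

        if object_mode:
            counts = np.bincount(labels.ravel(), minlength=n_targets)[:n_targets]
            state.alive = counts > 0
            if spec.ior_mode == "object":
                inh: Union[Dict[int, float], np.ndarray] = {
                    i: inhibition_object(history, float(t), i, ior)
                    for i in range(n_targets)
                }
            else:
                inh = space_ior.field(float(t))
            rates = drift_rates_object(F, S, labels, inh, n_targets=n_targets)
        else:
            I = space_ior.field(float(t))
            rates = drift_rates_space(F, S, I).ravel()

        V_prev = ddm_step(state, rates, nu, ddm, rng)
        crossing = detect_crossing(V_prev, state.V, spec.theta, state.alive)

        if crossing is None:
            trace_rows.append((t, t * frame_ms, gaze[0], gaze[1], "fov", fov_id))
            drift_mode = "object" if object_mode else "flow"
            gaze = foveation_drift(gaze, bundle, t, drift_mode,
                                   foveated_object=fov_id if object_mode else None,
                                   scale=nu)
            gaze = fixational_jitter(gaze, spec.sigma_d, ppd, rng, W, H)
            continue

        winner, frac = crossing
        t_dec = start + frac * nu
        trace_rows.append((t, t * frame_ms, gaze[0], gaze[1], "fov", fov_id))

        events.append(FoveationEvent(
            onset_ms=fov_start * frame_ms,
            offset_ms=t_dec * frame_ms,
            x_start=fov_start_pos[0], y_start=fov_start_pos[1],
            x_end=gaze[0], y_end=gaze[1],
            object_id=fov_id,
        ))

        if object_mode:
            landing = saccade_landing(winner, "object", rng,
                                      labels=labels, F=F, S=S)
        else:
            landing = saccade_landing(winner, "space", rng, width=W)
        amp = math.hypot(landing[0] - gaze[0], landing[1] - gaze[1]) / ppd
        tau_ms = saccade_duration(amp)
        tau_frames = tau_ms / frame_ms
        truncated = t_dec + tau_frames > T
        events.append(SaccadeEvent(
            onset_ms=t_dec * frame_ms,
            duration_ms=min(tau_ms, (T - t_dec) * frame_ms),
            x_start=gaze[0], y_start=gaze[1],
            x_end=landing[0], y_end=landing[1],
            amplitude_dva=amp,
            angle_deg=math.degrees(math.atan2(landing[1] - gaze[1],
                                              landing[0] - gaze[0])),
            truncated=truncated,
        ))

        if spec.ior_mode == "space":
            space_ior.add(landing[0], landing[1], t_dec)
        elif fov_id > 0:
            history.touch(fov_id, t_dec)

        sac_onset, sac_end = t_dec, t_dec + tau_frames
        sac_from, sac_to = gaze, landing
        gaze = clip_to_frame(landing[0], landing[1], W, H)
        fov_id = int(winner) if object_mode else -1
        history.foveated = fov_id if object_mode else None
        fov_start = sac_end
        fov_start_pos = gaze
        state.reset()

    if fov_start < T:  # final foveation absorbs the remaining time
        events.append(FoveationEvent(
            onset_ms=fov_start * frame_ms,
            offset_ms=T * frame_ms,
            x_start=fov_start_pos[0], y_start=fov_start_pos[1],
            x_end=gaze[0], y_end=gaze[1],
            object_id=fov_id,
        ))

    trace = pd.DataFrame(
        trace_rows, columns=["frame", "t_ms", "x_px", "y_px", "state", "object_id"]
    )
    return Scanpath(scene_id=bundle.scene_id, run_id=run_id, events=events, trace=trace)


def run_batch(bundles: Union[SceneBundle, Sequence[SceneBundle]], spec: ModelSpec,
              n_runs: int = 12, base_seed: int = 0) -> List[Scanpath]:
    """Simulate ``n_runs`` scanpaths per scene with reproducible seed streams.

    Run ``r`` of scene ``k`` uses an rng derived from ``(base_seed, k, r)``,
    so re-execution with the same ``base_seed`` reproduces every scanpath
    and distinct runs use distinct streams.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if isinstance(bundles, SceneBundle):
        bundles = [bundles]
    out = []
    for k, bundle in enumerate(bundles):
        for r in range(n_runs):
            rng = np.random.default_rng(np.random.SeedSequence((base_seed, k, r)))
            out.append(simulate_scanpath(bundle, spec, rng, run_id=r))
    return out


def scanpaths_to_events(scanpaths: Sequence[Scanpath]) -> pd.DataFrame:
    """Concatenate the event tables of a batch of scanpaths."""
    if not scanpaths:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat([sp.to_events() for sp in scanpaths], ignore_index=True)
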