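"""Attention fields: center bias, gaze-dependent sensitivity, inhibition of return.

Three maps are recomputed every frame and multiplied into the drift rates of
the saccadic race:

* the scene features ``F`` -- a per-frame saliency field, normalised to unit
  maximum and weighted by an anisotropic Gaussian center bias;
* the visual sensitivity ``S`` -- a unit-peak isotropic Gaussian of width
  ``sigma_s`` (dva) centred at the current gaze, optionally raised to 1 over
  the currently foveated object mask (object-based spread of attention);
* the inhibition ``I`` -- either a spatial map of decaying Gaussians around
  previous saccade targets (space mode) or a per-object scalar (object mode).

All Gaussians here are unit-peak rather than density-normalised: the rule
that sensitivity is *set to one* over the foveated mask, and the clipping of
the inhibition map at 1, both fix the natural scale of these fields to
[0, 1]; any constant rescaling would be absorbed by the fitted decision
threshold and noise level anyway.

Times are measured in frames throughout this module; the inhibition-decay
slope ``r`` is per frame (an inhibited target recovers fully after ``1/r``
frames).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

__all__ = [
    "CenterBiasParams",
    "SensitivityParams",
    "IorParams",
    "FoveationHistory",
    "center_bias_map",
    "combined_feature_map",
    "sensitivity_map",
    "inhibition_map_space",
    "inhibition_object",
]


@dataclass
class CenterBiasParams:
    """Anisotropic Gaussian prior for the tendency to look at screen centre.

    ``variance_x`` is the variance of the horizontal term for coordinates
    normalised to [-1, 1]; ``anisotropy`` multiplies the vertical exponent,
    making the prior wider along y for values < 1.
    """

    variance_x: float = 0.22
    anisotropy: float = 0.45

    def __post_init__(self) -> None:
        if self.variance_x <= 0:
            raise ValueError("variance_x must be > 0")
        if not 0 < self.anisotropy <= 1:
            raise ValueError("anisotropy must be in (0, 1]")


@dataclass
class SensitivityParams:
    sigma_s: float  # dva
    mode: str = "space"  # "space" | "object"

    def __post_init__(self) -> None:
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be > 0")


@dataclass
class IorParams:
    """Inhibition-of-return parameters.

    ``mode="space"`` inhibits previous saccade-target *locations* with
    Gaussians of width ``sigma_i`` (dva) in fixed screen coordinates;
    ``mode="object"`` inhibits previously foveated *objects*, with the
    currently foveated object suppressed by the within-object factor ``xi``.
    Both decay linearly to zero with slope ``r`` per frame.
    """

    mode: str = "space"
    r: float = 1.0 / 250.0
    sigma_i: Optional[float] = None  # dva, space mode
    xi: Optional[float] = None  # [0, 1], object mode

    def __post_init__(self) -> None:
        if self.mode not in ("space", "object"):
            raise ValueError("mode must be 'space' or 'object'")
        if self.r <= 0:
            raise ValueError("r must be > 0")
        if self.mode == "space":
            if self.sigma_i is None or self.sigma_i <= 0:
                raise ValueError("space mode requires sigma_i > 0")
        else:
            if self.xi is None or not 0.0 <= self.xi <= 1.0:
                raise ValueError("object mode requires xi in [0, 1]")


@dataclass
class FoveationHistory:
    """Scanpath history feeding the inhibition-of-return mechanism.

    Space mode stores previous saccade targets ``(x, y, t)`` in fixed screen
    coordinates at decision time (they are never updated with scene motion).
    Object mode stores, per object id, the last time (frames) the gaze was
    on its mask, plus the currently foveated id.
    """

    targets: List[Tuple[float, float, float]] = field(default_factory=list)
    last_on: Dict[int, float] = field(default_factory=dict)
    foveated: Optional[int] = None

    def add_target(self, x: float, y: float, t: float) -> None:
        if self.targets and t < self.targets[-1][2]:
            raise ValueError("history times must be non-decreasing")
        self.targets.append((float(x), float(y), float(t)))

    def touch(self, object_id: int, t: float) -> None:
        """Record that the gaze is on ``object_id``'s mask at time ``t``."""
        self.last_on[int(object_id)] = float(t)


# ---------------------------------------------------------------------------
# Field constructors
# ---------------------------------------------------------------------------


def center_bias_map(width: int, height: int,
                    params: CenterBiasParams = CenterBiasParams()) -> np.ndarray:
    """Center-bias field, value 1 at the image centre, shape (height, width).

    Each axis is normalised independently to [-1, 1];
    ``G(x, y) = exp(-x^2 / (2 v) - y^2 * a / (2 v))`` with ``v`` the
    horizontal variance and ``a`` the anisotropy ratio.
    """
    if width <= 0 or height <= 0:
        raise ValueError("geometry must be positive")
    x = np.linspace(-1.0, 1.0, width) if width > 1 else np.zeros(1)
    y = np.linspace(-1.0, 1.0, height) if height > 1 else np.zeros(1)
    ex = x ** 2 / (2.0 * params.variance_x)
    ey = y ** 2 * params.anisotropy / (2.0 * params.variance_x)
    return np.exp(-(ex[None, :] + ey[:, None]))


def combined_feature_map(bundle, frame: int, source: str = "lowlevel",
                         params: CenterBiasParams = CenterBiasParams(),
                         cb_map: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame feature field, max-normalised and center-bias weighted.

    ``source`` selects what plays the role of the feature map: ``lowlevel``
    or ``highlevel`` use the bundle's feature field (the distinction is which
    precomputed map was loaded into the bundle; the arithmetic is identical),
    ``none`` uses an all-ones field so the output is the center bias alone.
    An all-zero frame stays all-zero instead of dividing by zero.
    """
    if not 0 <= frame < bundle.n_frames:
        raise IndexError(f"frame {frame} out of range")
    if source not in ("lowlevel", "highlevel", "none"):
        raise ValueError(f"unknown feature source {source!r}")
    if cb_map is None:
        cb_map = center_bias_map(bundle.width_px, bundle.height_px, params)
    if source == "none":
        return cb_map.copy()
    feat = np.asarray(bundle.features[frame], dtype=np.float64)
    peak = feat.max()
    if peak > 0:
        feat = feat / peak
    return feat * cb_map


def sensitivity_map(gaze: Tuple[float, float], width: int, height: int,
                    params: SensitivityParams, px_per_dva: float,
                    foveated_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Unit-peak Gaussian sensitivity around the gaze position.

    In object mode, every pixel of the currently foveated object mask is set
    to exactly 1 (uniform spread of attention across the attended object);
    foveating the background sets no region to 1.
    """
    gx, gy = gaze
    sigma_px = params.sigma_s * px_per_dva
    yy, xx = np.mgrid[0:height, 0:width]
    s = np.exp(-((xx - gx) ** 2 + (yy - gy) ** 2) / (2.0 * sigma_px ** 2))
    if params.mode == "object":
        if foveated_mask is None:
            raise ValueError("object mode requires a foveated mask (possibly empty)")
        s[foveated_mask] = 1.0
    return s


def inhibition_map_space(history: FoveationHistory, t: float, params: IorParams,
                         width: int, height: int, px_per_dva: float) -> np.ndarray:
    """Spatial inhibition map: decaying Gaussians at previous targets.

    ``I(x, y, t) = min(1, sum_h G_h(x, y) * max(0, 1 - (t - t_h) * r))`` with
    ``G_h`` a unit-peak Gaussian of width ``sigma_i`` at target ``h``.
    Targets older than ``1/r`` frames contribute nothing.
    """
    if params.mode != "space":
        raise ValueError("inhibition_map_space requires space-mode parameters")
    out = np.zeros((height, width))
    if not history.targets:
        return out
    latest = max(th for _, _, th in history.targets)
    if t < latest:
        raise ValueError("query time earlier than the latest history entry")
    sigma_px = params.sigma_i * px_per_dva
    yy, xx = np.mgrid[0:height, 0:width]
    for (xh, yh, th) in history.targets:
        decay = max(0.0, 1.0 - (t - th) * params.r)
        if decay == 0.0:
            continue
        out += decay * np.exp(
            -((xx - xh) ** 2 + (yy - yh) ** 2) / (2.0 * sigma_px ** 2)
        )
    np.minimum(out, 1.0, out=out)
    return out


def inhibition_object(history: FoveationHistory, t: float, object_id: int,
                      params: IorParams) -> float:
    """Scalar inhibition of one object at time ``t`` (frames).

    The currently foveated object is inhibited by the within-object factor
    ``xi``; an object left at ``t_h`` recovers linearly,
    ``max(0, 1 - r (t - t_h))``.  The background (id 0) is never inhibited
    -- it is too large and heterogeneous to suppress as a unit -- and an
    object never foveated returns 0.
    """
    if params.mode != "object":
        raise ValueError("inhibition_object requires object-mode parameters")
    object_id = int(object_id)
    if object_id == 0:
        return 0.0
    if history.foveated == object_id:
        return float(params.xi)
    if object_id not in history.last_on:
        return 0.0
    return max(0.0, 1.0 - params.r * (t - history.last_on[object_id]))
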