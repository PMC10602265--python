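"""Gaze evolution between and at saccades: pursuit, jitter, landing.

During a foveation frame the gaze first drifts with the scene (smooth
pursuit: the foveated object's centroid shift in the object-based models,
the bilinearly interpolated optical flow in the space-based ones) and then
receives Brownian fixational jitter.  A winning saccade lands exactly on the
selected pixel (space mode) or on a pixel sampled inside the winning
object's mask with probability proportional to features x sensitivity
(object mode); there is no landing-error model.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

__all__ = [
    "clip_to_frame",
    "bilinear_flow",
    "foveation_drift",
    "fixational_jitter",
    "saccade_landing",
]

Vec = Tuple[float, float]


def clip_to_frame(x: float, y: float, width: int, height: int) -> Vec:
    return (float(np.clip(x, 0.0, width - 1)), float(np.clip(y, 0.0, height - 1)))


def bilinear_flow(flow_frame: np.ndarray, x: float, y: float) -> Vec:
    """Bilinear interpolation of a (H, W, 2) flow field at a sub-pixel point.

    Out-of-range lookups use the nearest edge.
    """
    H, W = flow_frame.shape[:2]
    x = float(np.clip(x, 0.0, W - 1))
    y = float(np.clip(y, 0.0, H - 1))
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    x1, y1 = min(x0 + 1, W - 1), min(y0 + 1, H - 1)
    fx, fy = x - x0, y - y0
    top = flow_frame[y0, x0] * (1 - fx) + flow_frame[y0, x1] * fx
    bot = flow_frame[y1, x0] * (1 - fx) + flow_frame[y1, x1] * fx
    v = top * (1 - fy) + bot * fy
    return float(v[0]), float(v[1])


def foveation_drift(gaze: Vec, bundle, frame: int, mode: str,
                    foveated_object: Optional[int] = None,
                    scale: float = 1.0) -> Vec:
    """Pursuit shift for one foveation frame; result clipped to the frame.

    ``mode="object"``: shift by the foveated object's centroid displacement
    from ``frame`` to ``frame + 1`` (background or no object: no shift).
    ``mode="flow"``: shift by the optical flow at the gaze position.
    ``scale`` weights the shift for partially foveated frames.
    """
    if frame + 1 >= bundle.n_frames:
        return gaze
    x, y = gaze
    if mode == "object":
        if foveated_object is None or foveated_object == 0:
            return gaze
        c0 = bundle.centroid(foveated_object, frame)
        c1 = bundle.centroid(foveated_object, frame + 1)
        if c0 is None or c1 is None:
            return gaze  # object absent; nothing to pursue
        dx, dy = c1[0] - c0[0], c1[1] - c0[1]
    elif mode == "flow":
        dx, dy = bilinear_flow(bundle.flow[frame], x, y)
    else:
        raise ValueError(f"unknown drift mode {mode!r}")
    return clip_to_frame(x + dx * scale, y + dy * scale,
                         bundle.width_px, bundle.height_px)


def fixational_jitter(gaze: Vec, sigma_d_dva: float, px_per_dva: float,
                      rng: np.random.Generator, width: int, height: int) -> Vec:
    """One step of the 2D random walk modelling fixational eye movements.

    Adds independent N(0, sigma_d * px_per_dva) to each coordinate, once per
    foveation frame -- during fixation and pursuit alike.
    """
    if sigma_d_dva < 0:
        raise ValueError("sigma_d must be >= 0")
    if sigma_d_dva == 0:
        return gaze
    sd = sigma_d_dva * px_per_dva
    dx, dy = rng.normal(0.0, sd, size=2)
    return clip_to_frame(gaze[0] + dx, gaze[1] + dy, width, height)


def saccade_landing(winner, mode: str, rng: np.random.Generator,
                    labels: Optional[np.ndarray] = None,
                    F: Optional[np.ndarray] = None,
                    S: Optional[np.ndarray] = None,
                    width: Optional[int] = None) -> Vec:
    """Landing position of a saccade to ``winner``.

    Space mode: ``winner`` is a flat pixel index; the landing is exactly
    that pixel.  Object mode: ``winner`` is an object id and the landing is
    sampled over its mask with probability proportional to ``F * S`` at
    decision time (inhibition is uniform within an object and drops out of
    the normalisation); an all-zero weight mask falls back to uniform.
    """
    if mode == "space":
        if width is None:
            raise ValueError("space mode requires the frame width")
        idx = int(winner)
        return float(idx % width), float(idx // width)
    if labels is None or F is None or S is None:
        raise ValueError("object mode requires labels, F and S")
    ys, xs = np.nonzero(labels == int(winner))
    if xs.size == 0:
        raise ValueError(f"object {winner} has an empty mask")
    w = (F[ys, xs] * S[ys, xs]).astype(float)
    total = w.sum()
    if total <= 0:
        p = np.full(xs.size, 1.0 / xs.size)
    else:
        p = w / total
    k = rng.choice(xs.size, p=p)
    return float(xs[k]), float(ys[k])
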