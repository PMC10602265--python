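"""Saccadic decision-making: a race of drift-diffusion accumulators.

Every potential saccade target -- each pixel in the space-based models, each
object (including the background) in the object-based ones -- accumulates
evidence for moving the gaze there.  The drift rate combines features,
sensitivity and inhibition; diffusion noise of level ``s`` perturbs every
accumulator independently.  The first accumulator to reach the threshold
``theta`` wins, and the crossing time is interpolated linearly inside the
frame so foveation durations have sub-frame resolution.  The decision
process is updated once per frame (``dt`` = 1 frame); the fraction
``nu_fov`` of a frame actually spent foveating scales the update, and
mid-saccade frames (``nu_fov`` = 0) accumulate nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np

__all__ = [
    "DdmParams",
    "DecisionState",
    "drift_rates_space",
    "drift_rates_object",
    "ddm_step",
    "detect_crossing",
    "saccade_duration",
]

# masks at or below this pixel count get zero drift (below plausible object
# scale, and keeps the log-size normalisation away from log(1) = 0)
MIN_MASK_SIZE = 2

SACCADE_MS_PER_DVA = 2.7
SACCADE_INTERCEPT_MS = 23.0


@dataclass
class DdmParams:
    theta: float  # decision threshold
    s: float  # diffusion noise level
    dt: float = 1.0  # time step, frames

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if self.s < 0:
            raise ValueError("s must be >= 0")


@dataclass
class DecisionState:
    """Per-target accumulators of the race.

    ``targets`` are flat pixel indices (space mode) or object ids including
    the background (object mode).  ``alive`` marks targets allowed to
    accumulate and win; accumulators of absent objects stay frozen at 0.
    """

    targets: np.ndarray
    V: np.ndarray = field(default=None)  # type: ignore[assignment]
    alive: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets)
        if self.V is None:
            self.V = np.zeros(len(self.targets))
        if self.alive is None:
            self.alive = np.ones(len(self.targets), dtype=bool)

    def reset(self) -> None:
        self.V[:] = 0.0


def drift_rates_space(F: np.ndarray, S: np.ndarray, I: np.ndarray) -> np.ndarray:
    """Per-pixel drift rates ``mu = F * S * (1 - I)``."""
    if not (F.shape == S.shape == I.shape):
        raise ValueError("field shapes must match")
    return F * S * (1.0 - I)


def drift_rates_object(F: np.ndarray, S: np.ndarray, labels: np.ndarray,
                       inhibition: Union[Dict[int, float], np.ndarray],
                       n_targets: Optional[int] = None) -> np.ndarray:
    """Per-object drift rates with logarithmic size normalisation.

    ``mu_i = sum_mask F * S * (1 - I) / (|mask| * ln |mask|)``.

    ``inhibition`` is either a ``{object_id: scalar}`` mapping (purely
    object-based inhibition) or a spatial field of the same shape as the
    frame (mixed model: the space-based inhibition map enters the per-pixel
    sum).  Index 0 of the result is the background.  Empty or tiny masks
    (``<= 2`` px) get rate 0.
    """
    if F.shape != S.shape or F.shape != labels.shape:
        raise ValueError("field shapes must match")
    if n_targets is None:
        n_targets = int(labels.max()) + 1
    flat_labels = labels.ravel()
    counts = np.bincount(flat_labels, minlength=n_targets)[:n_targets]

    if isinstance(inhibition, np.ndarray):
        if inhibition.shape != F.shape:
            raise ValueError("spatial inhibition shape mismatch")
        weights = (F * S * (1.0 - inhibition)).ravel()
        sums = np.bincount(flat_labels, weights=weights, minlength=n_targets)[:n_targets]
    else:
        weights = (F * S).ravel()
        sums = np.bincount(flat_labels, weights=weights, minlength=n_targets)[:n_targets]
        inh = np.array([inhibition.get(i, 0.0) for i in range(n_targets)])
        sums = sums * (1.0 - inh)

    with np.errstate(divide="ignore", invalid="ignore"):
        denom = counts * np.log(np.maximum(counts, 1))
    denom = np.maximum(denom, 1.0)
    mu = sums / denom
    mu[counts <= MIN_MASK_SIZE] = 0.0
    return mu


def ddm_step(state: DecisionState, rates: np.ndarray, nu_fov: float,
             params: DdmParams, rng: np.random.Generator) -> np.ndarray:
    """One accumulation step; returns the previous decision variables.

    ``V_i <- V_i + nu_fov * (mu_i dt + s eps_i sqrt(dt))`` with independent
    standard-normal ``eps_i`` per live target.  ``nu_fov = 0`` leaves the
    state untouched (no evidence is gathered mid-saccade).
    """
    if not 0.0 <= nu_fov <= 1.0:
        raise ValueError("nu_fov must be in [0, 1]")
    V_prev = state.V.copy()
    if nu_fov == 0.0:
        return V_prev
    rates = np.asarray(rates, dtype=float)
    if rates.shape != state.V.shape:
        raise ValueError("one rate per target required")
    drift = rates * params.dt
    if params.s > 0:
        noise = params.s * rng.standard_normal(len(state.V)) * np.sqrt(params.dt)
    else:
        noise = 0.0
    delta = nu_fov * (drift + noise)
    state.V = np.where(state.alive, state.V + delta, state.V)
    return V_prev


def detect_crossing(V_prev: np.ndarray, V_new: np.ndarray, theta: float,
                    alive: Optional[np.ndarray] = None
                    ) -> Optional[Tuple[int, float]]:
    """First threshold crossing within one step, or None.

    Among targets with ``V_new >= theta``, the winner has the earliest
    linearly interpolated crossing fraction ``(theta - V_prev) / (V_new -
    V_prev)``; ties break toward larger ``V_new``, then smaller index.
    Returns ``(winner_index, fraction in [0, 1])``.
    """
    crossed = V_new >= theta
    if alive is not None:
        crossed &= alive
    idx = np.nonzero(crossed)[0]
    if idx.size == 0:
        return None
    dv = V_new[idx] - V_prev[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (theta - V_prev[idx]) / dv
    # degenerate: started at/above threshold, or no movement -> crossed at 0
    frac = np.where((dv <= 0) | (V_prev[idx] >= theta), 0.0, frac)
    frac = np.clip(frac, 0.0, 1.0)
    order = np.lexsort((idx, -V_new[idx], frac))
    best = order[0]
    return int(idx[best]), float(frac[best])


def saccade_duration(amplitude_dva: float) -> float:
    """Saccade duration in ms: linear main-sequence law 2.7 ms/dva + 23 ms."""
    if amplitude_dva < 0:
        raise ValueError("amplitude must be >= 0")
    return SACCADE_MS_PER_DVA * amplitude_dva + SACCADE_INTERCEPT_MS
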