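"""Synthetic "human-like" reference scanpaths for testing and fitting.

Real free-viewing data shows log-normally distributed foveation durations
and Gamma-distributed saccade amplitudes; this module draws event tables
directly from those fitted forms (defaults: log-normal mu = 5.735,
sigma = 0.838 for durations in ms, expectation ~439.6 ms; Gamma shape 1.43,
scale 6.50 for amplitudes in dva) and places them on a scene so that object
assignment, category analysis and fitness evaluation all have a reference
to run against without any eye-tracking download.  It also wraps the
simulator itself as a reference generator with known parameters, which is
what the parameter-recovery harness fits against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from gazesim.evaluation import ObjectAssigner
from gazesim.saccadic_decision import saccade_duration
from gazesim.scene_data import SceneBundle
from gazesim.simulator import EVENT_COLUMNS, ModelSpec, run_batch, scanpaths_to_events

__all__ = ["ReferenceSpec", "synth_reference", "model_as_reference"]


@dataclass
class ReferenceSpec:
    """Parameters of the synthetic reference generator.

    ``p_object`` is the probability that a saccade is aimed at a pixel of a
    currently present object rather than in a uniformly random direction;
    it puts realistic mass of foveation time on objects without distorting
    the amplitude distribution much.
    """

    n_subjects: int = 12
    fd_mu: float = 5.735  # log-normal location of durations (log-ms)
    fd_sigma: float = 0.838
    sa_shape: float = 1.43  # Gamma shape of amplitudes (dva)
    sa_scale: float = 6.50  # Gamma scale (dva)
    p_object: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if min(self.fd_sigma, self.sa_shape, self.sa_scale) <= 0 or self.n_subjects < 1:
            raise ValueError("distribution parameters must be positive")
        if not 0.0 <= self.p_object <= 1.0:
            raise ValueError("p_object must be in [0, 1]")


def _aim(rng: np.random.Generator, pos: Tuple[float, float], amp_px: float,
         W: int, H: int) -> Tuple[float, float]:
    """Landing at distance ``amp_px`` in a uniform direction, kept in frame.

    Directions are re-drawn while the landing falls outside the display
    (clipping as a last resort would distort the amplitude distribution).
    """
    for _ in range(50):
        a = rng.uniform(0, 2 * math.pi)
        x = pos[0] + amp_px * math.cos(a)
        y = pos[1] + amp_px * math.sin(a)
        if 0 <= x <= W - 1 and 0 <= y <= H - 1:
            return x, y
    return (float(np.clip(x, 0, W - 1)), float(np.clip(y, 0, H - 1)))


def synth_reference(spec: ReferenceSpec, bundle: SceneBundle) -> pd.DataFrame:
    """Draw an event table of alternating foveations and saccades.

    Per subject the events tile [0, video duration]: foveation durations
    are log-normal, saccade amplitudes Gamma, the last foveation absorbs
    whatever time remains.  Gaze starts at the display centre.  Foveation
    object ids are assigned from the label field with the same 1-dva
    tolerance used for real gaze traces.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    assigner = ObjectAssigner(bundle)
    W, H = bundle.width_px, bundle.height_px
    ppd = bundle.px_per_dva
    D = bundle.duration_ms
    if math.exp(spec.fd_mu) > D * 100:
        raise ValueError("duration distribution cannot fit a single event")

    rows = []
    for subj in range(spec.n_subjects):
        t = 0.0
        pos = bundle.center
        while t < D:
            dur = float(rng.lognormal(spec.fd_mu, spec.fd_sigma))
            end = min(t + dur, D)
            frame = min(int(((t + end) / 2) // bundle.frame_ms), bundle.n_frames - 1)
            oid = assigner.at(frame, pos[0], pos[1])
            rows.append((bundle.scene_id, subj, "fov", t, end, pos[0], pos[1],
                         pos[0], pos[1], oid, np.nan, end - t))
            t = end
            if t >= D:
                break
            # choose the next target
            frame = min(int(t // bundle.frame_ms), bundle.n_frames - 1)
            present = [i for i in bundle.object_ids()
                       if frame in bundle.object_registry[i]]
            if present and rng.uniform() < spec.p_object:
                oid = int(rng.choice(present))
                ys, xs = np.nonzero(bundle.objects[frame] == oid)
                k = rng.integers(len(xs))
                landing = (float(xs[k]), float(ys[k]))
            else:
                amp_px = float(rng.gamma(spec.sa_shape, spec.sa_scale)) * ppd
                landing = _aim(rng, pos, amp_px, W, H)
            amp = math.hypot(landing[0] - pos[0], landing[1] - pos[1]) / ppd
            tau = saccade_duration(amp)
            end = min(t + tau, D)
            rows.append((bundle.scene_id, subj, "sac", t, end, pos[0], pos[1],
                         landing[0], landing[1], -1, amp, end - t))
            t = end
            pos = landing
    table = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    table.attrs["provenance"] = "reference"
    return table


def model_as_reference(bundles: Union[SceneBundle, Sequence[SceneBundle]],
                       spec: ModelSpec, n_runs: int = 12, seed: int = 0
                       ) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Use the simulator itself as reference with known ground truth.

    Returns the pooled event table (tagged as reference) together with the
    generating parameter values, enabling parameter-recovery experiments.
    """
    paths = run_batch(bundles, spec, n_runs=n_runs, base_seed=seed)
    table = scanpaths_to_events(paths)
    table.attrs["provenance"] = "reference"
    truth = {
        "sigma_s": spec.sigma_s,
        "theta": spec.theta,
        "s": spec.s,
        "r": spec.r,
    }
    if spec.sigma_i is not None:
        truth["sigma_i"] = spec.sigma_i
    if spec.xi is not None:
        truth["xi"] = spec.xi
    return table, truth
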