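"""Full scanpath simulation: event bookkeeping, variants, determinism."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_symmetric_scene
from gazesim.attention_fields import SensitivityParams, sensitivity_map
from gazesim.saccadic_decision import drift_rates_object
from gazesim.scene_data import SceneBundle, SynthObject, SynthSpec, synth_scene
from gazesim.simulator import (
    ModelSpec,
    VARIANTS,
    run_batch,
    scanpaths_to_events,
    simulate_scanpath,
)


def total_event_time(scanpath):
    return sum(e.duration_ms for e in scanpath.events)


class TestEventBookkeeping:
    @pytest.mark.parametrize("variant", sorted(VARIANTS))
    def test_events_tile_video_duration(self, small_scene, variant):
        sp = simulate_scanpath(small_scene, ModelSpec.from_variant(variant), seed=5)
        assert total_event_time(sp) == pytest.approx(small_scene.duration_ms, abs=1e-6)
        # contiguous, alternating, starting with a foveation at t = 0
        assert sp.events[0].onset_ms == 0.0
        for prev, nxt in zip(sp.events, sp.events[1:]):
            assert nxt.onset_ms == pytest.approx(prev.offset_ms, abs=1e-9)
            assert type(prev) is not type(nxt)

    def test_first_foveation_starts_at_frame_center(self, small_scene):
        sp = simulate_scanpath(small_scene, ModelSpec.from_variant("O.ll"), seed=1)
        fov0 = sp.foveations()[0]
        cx, cy = small_scene.center
        assert (fov0.x_start, fov0.y_start) == (cx, cy)
        assert sp.trace.frame.tolist() == list(range(small_scene.n_frames))

    def test_same_seed_reproduces_trace(self, small_scene):
        spec = ModelSpec.from_variant("O.ll")
        a = simulate_scanpath(small_scene, spec, seed=9)
        b = simulate_scanpath(small_scene, spec, seed=9)
        pd.testing.assert_frame_equal(a.to_events(), b.to_events())
        pd.testing.assert_frame_equal(a.trace, b.trace)

    def test_saccade_amplitude_consistent_with_endpoints(self, small_scene):
        sp = simulate_scanpath(small_scene, ModelSpec.from_variant("S.ll"), seed=2)
        for sac in sp.saccades():
            d = np.hypot(sac.x_end - sac.x_start, sac.y_end - sac.y_start)
            assert sac.amplitude_dva == pytest.approx(d / small_scene.px_per_dva)
            if not sac.truncated:
                assert sac.duration_ms == pytest.approx(2.7 * sac.amplitude_dva + 23)


class TestNoiselessRace:
    def test_first_saccade_matches_closed_form(self, static_scene):
        """With s = 0 and no jitter the race is deterministic: the winner is
        the argmax-rate target and the decision time is theta / mu."""
        spec = ModelSpec.from_variant("O.ll", s=0.0, sigma_d=0.0, theta=1.0)
        sp = simulate_scanpath(static_scene, spec, seed=0)

        from gazesim.attention_fields import combined_feature_map
        F = combined_feature_map(static_scene, 0, "lowlevel", spec.center_bias)
        S = sensitivity_map(static_scene.center, static_scene.width_px,
                            static_scene.height_px,
                            SensitivityParams(spec.sigma_s, "space"),
                            static_scene.px_per_dva)
        mu = drift_rates_object(F, S, static_scene.objects[0], {0: 0.0, 1: 0.0})
        winner = int(np.argmax(mu))
        expected_ms = spec.theta / mu[winner] * static_scene.frame_ms

        first_sac = sp.saccades()[0]
        assert sp.foveations()[1].object_id == winner
        assert first_sac.onset_ms == pytest.approx(expected_ms, rel=1e-9)

    def test_pursuit_tracks_object_trajectory(self):
        """With no jitter and an unreachable threshold, foveating a moving
        object reproduces its trajectory exactly."""
        spec_scene = SynthSpec(
            width_px=80, height_px=60, n_frames=100, px_per_dva=2.0,
            objects=[SynthObject(position=(39.5, 29.5), velocity=(0.35, -0.15),
                                 size_px=(16, 12))],
            background_level=0.1, noise_sd=0.0, seed=0, scene_id="pursuit")
        bundle = synth_scene(spec_scene)
        # place the object under the initial gaze
        assert bundle.objects[0][30, 40] == 1
        spec = ModelSpec.from_variant("O.ll", theta=1e9, s=0.0, sigma_d=0.0)
        sp = simulate_scanpath(bundle, spec, seed=0)
        assert len(sp.saccades()) == 0
        c0 = np.array(bundle.centroid(1, 0))
        g0 = np.array([sp.trace.x_px.iloc[0], sp.trace.y_px.iloc[0]])
        for t in range(bundle.n_frames):
            ct = np.array(bundle.centroid(1, t))
            gt = np.array([sp.trace.x_px.iloc[t], sp.trace.y_px.iloc[t]])
            assert np.abs((gt - g0) - (ct - c0)).max() < 1e-6


class TestVariantWiring:
    def test_center_bias_only_model_ignores_features(self, small_scene):
        spec = ModelSpec.from_variant("O.cb")
        a = simulate_scanpath(small_scene, spec, seed=4)
        rng = np.random.default_rng(0)
        perturbed = SceneBundle(
            scene_id=small_scene.scene_id,
            width_px=small_scene.width_px, height_px=small_scene.height_px,
            n_frames=small_scene.n_frames, fps=small_scene.fps,
            px_per_dva=small_scene.px_per_dva,
            features=rng.uniform(0, 1, small_scene.features.shape).astype(np.float32),
            objects=small_scene.objects, flow=small_scene.flow)
        b = simulate_scanpath(perturbed, spec, seed=4)
        pd.testing.assert_frame_equal(a.to_events(), b.to_events())

    def test_object_mode_lands_inside_target_mask(self, small_scene):
        sp = simulate_scanpath(small_scene, ModelSpec.from_variant("O.ll"), seed=6)
        events = sp.events
        for k, e in enumerate(events):
            if not hasattr(e, "amplitude_dva"):
                continue
            if k + 1 >= len(events):
                continue
            target = events[k + 1].object_id
            frame = int(e.onset_ms / small_scene.frame_ms)
            labels = small_scene.objects[frame]
            assert labels[int(round(e.y_end)), int(round(e.x_end))] == target

    def test_space_selection_requires_space_ior(self):
        with pytest.raises(ValueError):
            ModelSpec.from_variant("S.ll", ior_mode="object", xi=0.5)


class TestBatches:
    def test_batch_reproducible_and_streams_distinct(self, small_scene):
        spec = ModelSpec.from_variant("O.ll")
        a = scanpaths_to_events(run_batch(small_scene, spec, n_runs=3, base_seed=1))
        b = scanpaths_to_events(run_batch(small_scene, spec, n_runs=3, base_seed=1))
        pd.testing.assert_frame_equal(a, b)
        runs = [g for _, g in a.groupby("run_id")]
        assert not runs[0].reset_index(drop=True).equals(runs[1].reset_index(drop=True))

    def test_single_run(self, small_scene):
        out = run_batch(small_scene, ModelSpec.from_variant("O.cb"), n_runs=1)
        assert len(out) == 1

    def test_symmetric_scene_splits_first_targets(self):
        """On a mirror-symmetric two-object scene the noisy race should not
        pick the same first target in all 12 runs."""
        bundle = make_symmetric_scene()
        spec = ModelSpec.from_variant("O.ll")
        paths = run_batch(bundle, spec, n_runs=12, base_seed=3)
        firsts = set()
        for sp in paths:
            fovs = sp.foveations()
            if len(fovs) > 1:
                firsts.add(fovs[1].object_id)
        assert len(firsts) >= 2
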