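"""Event filters, object assignment, categories, KS fitness, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from gazesim.evaluation import (
    ObjectAssigner,
    add_categories,
    assign_event_objects,
    categorize_foveations,
    category_timecourse,
    dwell_regression,
    filter_events,
    first_detections,
    first_detection_agreement,
    fitness,
    ks_statistic,
    object_return_stats,
    sequential_stats,
)
from gazesim.scene_data import SynthObject, SynthSpec, synth_scene, transform_scene
from gazesim.simulator import EVENT_COLUMNS, ModelSpec, simulate_scanpath


def ev(scene="s", run=0, etype="fov", t0=0.0, t1=100.0, x0=0.0, y0=0.0,
       x1=0.0, y1=0.0, oid=0, amp=np.nan):
    return (scene, run, etype, t0, t1, x0, y0, x1, y1, oid, amp, t1 - t0)


def table(rows):
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def brute_force_ks(a, b):
    """Independent oracle: enumerate the ECDF difference at every point."""
    pts = sorted(set(a) | set(b))
    a, b = np.asarray(a), np.asarray(b)
    return max(abs((a <= x).mean() - (b <= x).mean()) for x in pts)


class TestFilter:
    def test_short_foveations_removed(self):
        t = table([ev(t0=0, t1=30), ev(t0=0, t1=34)])
        out = filter_events(t)
        assert len(out) == 1 and out.duration_ms.iloc[0] == 34

    def test_microsaccades_removed(self):
        t = table([ev(etype="sac", amp=0.4), ev(etype="sac", amp=0.6)])
        out = filter_events(t)
        assert len(out) == 1 and out.amplitude_dva.iloc[0] == 0.6

    def test_empty_table(self):
        assert filter_events(table([])).empty


@pytest.fixture(scope="module")
def bundle():
    spec = SynthSpec(
        width_px=60, height_px=40, n_frames=12, px_per_dva=4.0,
        objects=[SynthObject(shape="rectangle", size_px=(12, 12),
                             position=(20, 20), velocity=(0, 0))],
        background_level=0.1, noise_sd=0.0, seed=0, scene_id="assign")
    return synth_scene(spec)


class TestObjectAssignment:

    def test_within_one_dva_of_mask_counts_as_object(self, bundle):
        a = ObjectAssigner(bundle)
        # mask spans x in [14, 26]; 0.8 dva = 3.2 px outside still assigns
        assert a.at(0, 26 + 3.2, 20) == 1
        assert a.at(0, 20, 20) == 1

    def test_far_from_mask_is_background(self, bundle):
        a = ObjectAssigner(bundle)
        assert a.at(0, 26 + 6.0, 20) == 0  # 1.5 dva outside

    def test_majority_rule_per_event(self, bundle):
        frame_ms = bundle.frame_ms
        # 6 frames on the object, 4 frames far away on background
        trace = pd.DataFrame({
            "frame": range(10),
            "t_ms": [i * frame_ms for i in range(10)],
            "x_px": [20] * 6 + [55] * 4,
            "y_px": [20] * 6 + [5] * 4,
            "state": ["fov"] * 10,
            "object_id": [-1] * 10,
        })
        events = table([ev(t0=0, t1=10 * frame_ms, oid=-1)])
        out = assign_event_objects(events, trace, bundle)
        assert out.object_id.iloc[0] == 1


class TestCategories:
    @pytest.mark.parametrize("ids,expected", [
        ([0, 3, 3, 5, 3],
         ["Background", "Detection", "Inspection", "Detection", "Return"]),
        ([0, 0, 0], ["Background"] * 3),
        ([2, 0, 2], ["Detection", "Background", "Return"]),
    ])
    def test_worked_examples(self, ids, expected):
        assert categorize_foveations(ids) == expected

    def test_at_most_one_detection_per_object(self, small_scene):
        sp = simulate_scanpath(small_scene, ModelSpec.from_variant("O.ll"), seed=8)
        cats = add_categories(sp.to_events())
        fov = cats[cats.event_type == "fov"]
        det = fov[fov.category == "Detection"]
        assert det.object_id.is_unique
        assert set(fov.category) <= {"Background", "Detection", "Inspection", "Return"}


class TestKsAndFitness:
    def test_identical_samples_zero(self):
        assert ks_statistic([1, 2, 3], [1, 2, 3]) == 0.0

    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [4, 5, 6], 1.0),
        ([1, 2], [1, 3], 0.5),
    ])
    def test_worked_examples(self, a, b, expected):
        assert ks_statistic(a, b) == pytest.approx(expected)
        assert brute_force_ks(a, b) == pytest.approx(expected)

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 40))
            b = rng.normal(0.3, 1.4, rng.integers(3, 40))
            assert ks_statistic(a, b) == pytest.approx(brute_force_ks(a, b))

    def test_fitness_arithmetic(self):
        # d_FD: durations {100,200} vs {100,300} -> 0.5
        # d_SA: amplitudes {1,2,3} vs {4,5,6} -> 1.0
        sim = table([ev(t0=0, t1=100), ev(t0=0, t1=200)]
                    + [ev(etype="sac", amp=a) for a in (1, 2, 3)])
        ref = table([ev(t0=0, t1=100), ev(t0=0, t1=300)]
                    + [ev(etype="sac", amp=a) for a in (4, 5, 6)])
        assert fitness(sim, ref) == pytest.approx(-(1.0 + 0.5) / 2)
        assert fitness(sim, sim) == 0.0
        assert -1.0 <= fitness(sim, ref) <= 0.0


class TestSequentialStats:
    def saccade(self, t0, p0, p1, run=0):
        amp = float(np.hypot(p1[0] - p0[0], p1[1] - p0[1]))
        return ev(etype="sac", run=run, t0=t0, t1=t0 + 30, x0=p0[0], y0=p0[1],
                  x1=p1[0], y1=p1[1], amp=amp)

    def test_opposite_vectors_give_180(self):
        t = table([
            self.saccade(0, (0, 0), (10, 0)),
            ev(t0=30, t1=330),
            self.saccade(330, (10, 0), (0, 0)),
        ])
        out = sequential_stats(t)
        assert out["angles_deg"][0] == pytest.approx(180.0)
        assert out["frac_gt135"] == 1.0

    def test_orthogonal_vectors_give_90(self):
        t = table([
            self.saccade(0, (0, 0), (10, 0)),
            self.saccade(330, (10, 0), (10, 10)),
        ])
        assert abs(sequential_stats(t)["angles_deg"][0]) == pytest.approx(90.0)

    def test_return_saccade_criterion(self):
        # |phi| = 179 with amplitude difference 0.5 -> return; with 2.0 -> not
        def pair(run, amp2):
            a1 = 5.0
            ang = np.radians(179.0)
            p1 = (amp2 * np.cos(ang), amp2 * np.sin(ang))
            return [
                self.saccade(0, (0, 0), (a1, 0), run=run),
                self.saccade(330, (a1, 0), (a1 + p1[0], p1[1]), run=run),
            ]
        t = table(pair(0, 4.5) + pair(1, 7.0))
        out = sequential_stats(t)
        assert out["return_saccade_ratio"] == pytest.approx(0.5)

    def test_median_preceding_duration_binned(self):
        t = table([
            self.saccade(0, (0, 0), (10, 0)),
            ev(t0=30, t1=430),  # 400 ms foveation before the return
            self.saccade(430, (10, 0), (0, 0)),
        ])
        out = sequential_stats(t)
        med = out["median_prev_duration_by_angle"]
        assert np.nanmax(med) == pytest.approx(400.0)


class TestObjectStats:
    def test_identical_dwell_gives_identity_line(self):
        rows = [ev(run=0, t0=i * 1000, t1=i * 1000 + d, oid=i + 1)
                for i, d in enumerate((500, 800, 300))]
        sim = table(rows)
        ref = table(rows)
        reg = dwell_regression(sim, ref)
        assert reg["slope"] == pytest.approx(1.0)
        assert reg["intercept"] == pytest.approx(0.0, abs=1e-9)
        assert reg["r2"] == pytest.approx(1.0)

    def test_single_return_with_600ms_gap(self):
        t = table([
            ev(t0=0, t1=500, oid=1),
            ev(etype="sac", t0=500, t1=600, amp=5),
            ev(t0=600, t1=1000, oid=2),
            ev(etype="sac", t0=1000, t1=1100, amp=5),
            ev(t0=1100, t1=1500, oid=1),
        ])
        out = object_return_stats(t)
        assert out["n_returns"] == 1
        assert out["median_return_ms"] == pytest.approx(600.0)
        assert out["object_return_ratio"] == pytest.approx(0.5)

    def test_first_detection_modal_and_agreement(self):
        sim = table([ev(run=0, t0=0, t1=100, oid=0),
                     ev(run=0, t0=100, t1=200, oid=4),
                     ev(run=1, t0=0, t1=100, oid=4),
                     ev(run=2, t0=0, t1=100, oid=2)])
        assert first_detections(sim)["s"] == 4
        ref = table([ev(run=0, t0=0, t1=100, oid=4)])
        assert first_detection_agreement(sim, ref) == 1.0


class TestTimecourse:
    def test_proportions_sum_to_one(self):
        t = add_categories(table([
            ev(t0=0, t1=250, oid=0),
            ev(etype="sac", t0=250, t1=300, amp=5),
            ev(t0=300, t1=1000, oid=1),
        ]))
        tc = category_timecourse(t, bin_ms=100.0, duration_ms=1000.0)
        sums = tc.sum(axis=1, skipna=True)
        assert np.allclose(sums, 1.0)

    def test_all_background(self):
        t = add_categories(table([ev(t0=0, t1=1000, oid=0)]))
        tc = category_timecourse(t, bin_ms=200.0, duration_ms=1000.0)
        assert np.allclose(tc.Background, 1.0)

    def test_control_transform_increases_background_share(self):
        """Keeping a scanpath fixed while the scene is time-reversed and
        mirrored moves foveation time from the (off-center) object to the
        background."""
        spec = SynthSpec(
            width_px=60, height_px=40, n_frames=12, px_per_dva=4.0,
            objects=[SynthObject(shape="rectangle", size_px=(10, 10),
                                 position=(15, 10), velocity=(0, 0))],
            background_level=0.1, noise_sd=0.0, seed=0, scene_id="ctrl")
        bundle = synth_scene(spec)
        frame_ms = bundle.frame_ms
        trace = pd.DataFrame({
            "frame": range(12),
            "t_ms": [i * frame_ms for i in range(12)],
            "x_px": [15.0] * 12,
            "y_px": [10.0] * 12,
            "state": ["fov"] * 12,
            "object_id": [-1] * 12,
        })
        events = table([ev(t0=0, t1=12 * frame_ms, oid=-1)])
        on_orig = assign_event_objects(events, trace, bundle)
        on_ctrl = assign_event_objects(events, trace, transform_scene(bundle))
        orig_bg = (on_orig.object_id == 0).mean()
        ctrl_bg = (on_ctrl.object_id == 0).mean()
        assert ctrl_bg > orig_bg
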