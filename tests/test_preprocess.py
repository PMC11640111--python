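"""Interpolation, normalization, windowing, variant assembly and splits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from collarml import preprocess as pp
from collarml import synthetic as syn
from collarml.evaluation import ConfusionMatrix

from conftest import make_session


class TestInterpolateEvent:
    def test_affine_channel_is_exact(self):
        funcs = {"imu": lambda t: np.stack([2.0 * t + 1.0, -t, 0 * t], axis=1)}
        s = make_session(funcs, duration_s=10.0,
                         events=[syn.StateEvent("Idle", 2.0, 7.0)])
        al = pp.interpolate_event(s, s.events[0], "imu")
        grid = np.linspace(2.0, 7.0, 500)
        np.testing.assert_allclose(al.values[:, 0], 2.0 * grid + 1.0, atol=1e-9)
        np.testing.assert_allclose(al.values[:, 1], -grid, atol=1e-9)
        assert al.values.shape == (500, 3)

    def test_single_low_rate_sample_gives_constant(self):
        funcs = {"temperature": lambda t: 20.0 + t}
        s = make_session(funcs, duration_s=10.0,
                         events=[syn.StateEvent("Idle", 2.9, 3.8)])
        al = pp.interpolate_event(s, s.events[0], "imu-audio-env")
        temp = al.values[:, al.channel_names.index("temperature_ch1")]
        np.testing.assert_allclose(temp, 23.0)  # single sample at t=3

    @pytest.mark.parametrize("fusion,C", [("imu", 3), ("imu-audio", 4),
                                          ("imu-audio-env", 8)])
    def test_fusion_channel_counts(self, fusion, C):
        s = make_session(duration_s=5.0)
        al = pp.interpolate_event(s, s.events[0], fusion)
        assert al.values.shape == (500, C)

    def test_empty_event_window_errors(self):
        s = make_session(duration_s=10.0)
        ev = syn.StateEvent("Idle", 3.2, 3.9)  # no integer second inside
        with pytest.raises(pp.DataError, match="temperature"):
            pp.interpolate_event(s, ev, "imu-audio-env")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_bruteforce_two_point_interpolation(self, seed):
        """Independent oracle: for each grid time, locate the bracketing
        knots and interpolate by hand."""
        rng = np.random.default_rng(seed)
        knots_v = rng.normal(size=1001)
        funcs = {"imu": lambda t: np.stack([knots_v[:len(t)]] * 3, axis=1)}
        s = make_session(funcs, duration_s=10.0,
                         events=[syn.StateEvent("Idle", 1.0, 9.0)])
        al = pp.interpolate_event(s, s.events[0], "imu")
        t_knots = s.streams["imu"].timestamps
        mask = (t_knots >= 1.0) & (t_knots <= 9.0)
        tk, vk = t_knots[mask], knots_v[:len(t_knots)][mask]
        grid = np.linspace(1.0, 9.0, 500)
        expect = np.empty(500)
        for i, g in enumerate(grid):
            j = np.searchsorted(tk, g, side="right") - 1
            j = min(max(j, 0), len(tk) - 2)
            w = (g - tk[j]) / (tk[j + 1] - tk[j])
            expect[i] = (1 - w) * vk[j] + w * vk[j + 1]
        np.testing.assert_allclose(al.values[:, 0], expect, atol=1e-9)


class TestZNormalize:
    def test_hand_computed_values(self):
        # modality with values [1, 2, 3]: z = (x - 2) / sqrt(2/3)
        streams_session = make_session(duration_s=2.0)
        t = streams_session.streams["temperature"].timestamps
        streams_session.streams["temperature"].values = np.array([[1.0], [2.0], [3.0]])[:len(t)]
        zn, stats = pp.znormalize_session(streams_session)
        np.testing.assert_allclose(zn.streams["temperature"].values.ravel(),
                                   [-1.224744871, 0.0, 1.224744871], atol=1e-6)
        assert stats.mean["temperature"] == pytest.approx(2.0)

    def test_output_mean_zero_sd_one(self):
        funcs = {"imu": lambda t: np.stack([np.sin(t), np.cos(2 * t), t], axis=1)}
        s = make_session(funcs, duration_s=5.0)
        zn, _ = pp.znormalize_session(s)
        v = zn.streams["imu"].values
        assert abs(v.mean()) < 1e-9
        assert abs(v.std() - 1.0) < 1e-9

    def test_constant_channel_becomes_zero_with_warning(self, caplog):
        s = make_session({"pressure": lambda t: np.full_like(t, 1013.0)},
                         duration_s=3.0)
        with caplog.at_level("WARNING"):
            zn, _ = pp.znormalize_session(s)
        assert np.all(zn.streams["pressure"].values == 0.0)
        assert any("pressure" in r.message for r in caplog.records)

    def test_affine_invariance(self):
        funcs = {"audio": lambda t: np.sin(3 * t)}
        a = make_session(funcs, duration_s=4.0)
        b = make_session({"audio": lambda t: 5.0 * np.sin(3 * t) + 7.0}, duration_s=4.0)
        za, _ = pp.znormalize_session(a)
        zb, _ = pp.znormalize_session(b)
        np.testing.assert_allclose(za.streams["audio"].values,
                                   zb.streams["audio"].values, atol=1e-9)

    def test_idempotence(self):
        funcs = {"imu": lambda t: np.stack([np.sin(t), t, t ** 2], axis=1)}
        s = make_session(funcs, duration_s=5.0)
        once, _ = pp.znormalize_session(s)
        twice, _ = pp.znormalize_session(once)
        np.testing.assert_allclose(once.streams["imu"].values,
                                   twice.streams["imu"].values, atol=1e-9)


class TestWindowing:
    def _aligned(self, seed=0):
        rng = np.random.default_rng(seed)
        return pp.AlignedSequence("Idle", rng.normal(size=(500, 4)),
                                  ["a", "b", "c", "d"], ("d0", 0))

    def test_twenty_windows_partition_input(self):
        al = self._aligned()
        windows = pp.window_sequence(al)
        assert len(windows) == 20
        np.testing.assert_array_equal(
            np.concatenate([w.values for w in windows]), al.values)
        for k, w in enumerate(windows):
            assert w.window_index == k
            np.testing.assert_array_equal(w.values, al.values[25 * k:25 * k + 25])

    def test_non_divisible_rows_rejected(self):
        al = self._aligned()
        al.values = al.values[:499]
        with pytest.raises(ValueError):
            pp.window_sequence(al)


class TestSelectTopStates:
    def test_identity_confusion_breaks_ties_lexicographically(self):
        labels = [f"s{i:02d}" for i in range(20)][::-1]  # unsorted on purpose
        cm = ConfusionMatrix(np.eye(20, dtype=int) * 3, labels)
        top = pp.select_top_states(cm, 10)
        assert top == sorted(labels)[:10]

    def test_distinct_recalls_selects_top_k(self):
        cm = ConfusionMatrix(np.array([[9, 1, 1], [1, 5, 1], [1, 1, 1]]),
                             ["a", "b", "c"])
        assert pp.select_top_states(cm, 2) == ["a", "b"]

    def test_k_equals_K_returns_all(self):
        cm = ConfusionMatrix(np.eye(4, dtype=int), list("abcd"))
        assert pp.select_top_states(cm, 4) == list("abcd")

    def test_k_too_large_errors(self):
        cm = ConfusionMatrix(np.eye(3, dtype=int), list("abc"))
        with pytest.raises(ValueError):
            pp.select_top_states(cm, 5)

    def test_empty_row_has_zero_recall(self):
        counts = np.array([[0, 0], [0, 5]])
        cm = ConfusionMatrix(counts, ["a", "b"])
        assert pp.select_top_states(cm, 1) == ["b"]


class TestVariantsAndSplits:
    def test_sample_counts_interpolate_vs_subsample(self, normalized_sessions):
        sessions = normalized_sessions[:2]
        interp = pp.build_dataset_variant(sessions, "interpolate", 50, "imu")
        sub = pp.build_dataset_variant(sessions, "subsample", 50, "imu")
        assert len(interp.samples) == 100
        assert len(sub.samples) == 2000
        assert sub.n_channels == 3

    def test_ten_state_requires_subset(self, normalized_sessions):
        with pytest.raises(ValueError):
            pp.build_dataset_variant(normalized_sessions, "interpolate", 10, "imu")

    def test_subset_defines_vocabulary(self, normalized_sessions):
        subset = sorted(m.state_name for m in syn.default_catalogue()[:10])
        var = pp.build_dataset_variant(normalized_sessions, "interpolate", 10,
                                       "imu-audio", subset)
        assert var.vocabulary == subset
        assert var.n_channels == 4
        assert all(s.label in subset for s in var.samples)

    def test_insufficient_data_raises_explicitly(self, normalized_sessions):
        with pytest.raises(pp.DataError, match="insufficient data"):
            pp.build_dataset_variant(normalized_sessions, "interpolate", 50,
                                     "imu", min_per_state=10)

    def test_window_level_split_sizes(self, normalized_sessions):
        var = pp.build_dataset_variant(normalized_sessions[:1], "subsample", 50, "imu")
        split = pp.split_train_test(var, 0.7, seed=1, level="window")
        n = len(var.samples)
        assert len(split.train) + len(split.test) == n
        assert abs(len(split.train) - 0.7 * n) <= 50  # one window-group per label

    def test_event_level_split_has_no_leakage(self, normalized_sessions):
        var = pp.build_dataset_variant(normalized_sessions, "subsample", 50, "imu")
        split = pp.split_train_test(var, 0.7, seed=0, level="event")
        train_prov = {s.provenance for s in split.train}
        test_prov = {s.provenance for s in split.test}
        assert train_prov.isdisjoint(test_prov)

    def test_split_reproducible(self, normalized_sessions):
        var = pp.build_dataset_variant(normalized_sessions, "interpolate", 50, "imu")
        a = pp.split_train_test(var, 0.7, seed=9, level="event")
        b = pp.split_train_test(var, 0.7, seed=9, level="event")
        assert [id(s) for s in a.train] == [id(s) for s in b.train]

    def test_single_group_label_goes_to_train_with_warning(self, normalized_sessions):
        var = pp.build_dataset_variant(normalized_sessions[:1], "interpolate", 50, "imu")
        with pytest.warns(UserWarning):
            split = pp.split_train_test(var, 0.7, seed=0, level="event")
        assert len(split.test) == 0  # every label has exactly one event

    def test_nothing_dropped_silently(self, normalized_sessions):
        subset = sorted(m.state_name for m in syn.default_catalogue()[:10])
        var = pp.build_dataset_variant(normalized_sessions, "subsample", 10,
                                       "imu", subset)
        # 3 dogs x 10 events x 20 windows
        assert len(var.samples) == 3 * 10 * 20
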