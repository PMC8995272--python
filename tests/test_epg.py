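import numpy as np
import pytest

from mrfviz import (
    FlipAngleSequence,
    build_dictionary,
    jiang_like_pattern,
    load_dictionary,
    make_grid,
    save_dictionary,
    simulate_signal,
    without_inversion,
)


class TestMakeGrid:
    def test_printed_grid_counts(self, full_scale_grid):
        assert full_scale_grid.t1_values.size == 67
        assert full_scale_grid.t2_values.size == 30
        # Independent enumeration of the T1 > T2 filter
        expected = sum(
            1 for t2 in full_scale_grid.t2_values for t1 in full_scale_grid.t1_values if t1 > t2
        )
        assert full_scale_grid.n_entries == expected == 1855

    def test_single_entry(self):
        g = make_grid(100, 100, 30, 10, 10, 10)
        assert g.n_entries == 1 and tuple(g.entries[0]) == (100.0, 10.0)

    def test_empty_after_filter(self):
        with pytest.raises(ValueError):
            make_grid(10, 10, 10, 20, 20, 10)

    def test_entries_ordered_t2_major_and_unique(self, small_grid):
        e = small_grid.entries
        keys = list(zip(e[:, 1], e[:, 0]))  # (T2, T1) lexicographic
        assert keys == sorted(keys)
        assert len(set(map(tuple, e))) == len(e)


class TestSimulateSignal:
    def test_zero_flip_train_gives_zero_signal(self):
        seq = FlipAngleSequence(angles=np.zeros(20), inversion=False)
        assert np.all(simulate_signal(800, 100, seq) == 0)

    def test_inversion_recovery_null_point(self):
        t1 = 700.0
        seq = FlipAngleSequence(angles=np.array([90.0]), inversion=True)
        null = simulate_signal(t1, 100.0, seq, ti_ms=t1 * np.log(2))
        assert abs(null[0]) < 1e-6
        # closed form: signal after delay t equals 1 - 2 exp(-t/T1)
        for t in (50.0, 300.0, 1500.0):
            s = simulate_signal(t1, 100.0, seq, ti_ms=t)
            assert s[0] == pytest.approx(1 - 2 * np.exp(-t / t1), abs=1e-12)

    def test_sign_convention(self):
        seq = FlipAngleSequence(angles=np.array([30.0, 30.0]), inversion=True)
        assert simulate_signal(800, 100, seq, ti_ms=1.0)[0] < 0
        assert simulate_signal(800, 100, without_inversion(seq))[0] >= 0

    def test_matches_isochromat_oracle(self, isochromat_oracle):
        rng = np.random.default_rng(42)
        for trial in range(3):
            t1 = rng.uniform(100, 2000)
            t2 = rng.uniform(10, min(300.0, t1))
            seq = FlipAngleSequence(
                angles=rng.uniform(0, 70, 40), inversion=bool(trial % 2)
            )
            epg = simulate_signal(t1, t2, seq, max_orders=200)
            iso = isochromat_oracle(t1, t2, seq)
            assert np.max(np.abs(epg - iso.real)) < 1e-3
            assert np.max(np.abs(iso.imag)) < 1e-6

    def test_constant_train_against_oracle(self, isochromat_oracle):
        seq = FlipAngleSequence(angles=np.full(50, 30.0), inversion=False)
        epg = simulate_signal(800, 100, seq, max_orders=200)
        iso = isochromat_oracle(800, 100, seq)
        assert np.max(np.abs(epg - iso.real)) < 1e-3

    def test_t2_longer_than_t1_permitted_in_kernel(self):
        seq = FlipAngleSequence(angles=np.full(5, 30.0), inversion=False)
        s = simulate_signal(100, 300, seq)
        assert np.all(np.isfinite(s))

    def test_nonpositive_relaxation_rejected(self):
        seq = FlipAngleSequence(angles=np.array([30.0]))
        with pytest.raises(ValueError):
            simulate_signal(0, 100, seq)
        with pytest.raises(ValueError):
            simulate_signal(800, -5, seq)


class TestBuildDictionary:
    def test_shape_and_magnitude_bound(self, small_dict, small_grid, short_seq):
        assert small_dict.signals.shape == (small_grid.n_entries, len(short_seq))
        assert np.abs(small_dict.signals).max() <= 1.0 + 1e-12

    def test_normalized_rows(self, small_grid, short_seq):
        d = build_dictionary(small_grid, short_seq, normalize=True)
        assert np.allclose(np.linalg.norm(d.signals, axis=1), 1.0, atol=1e-9)
        assert d.normalized

    def test_inversion_improves_t1_separation(self):
        """Entries differing only in T1 are further apart with the inversion
        pulse than without: the inversion boosts T1 encoding."""
        seq = jiang_like_pattern(1000, 0)
        with_inv = [simulate_signal(t1, 100.0, seq) for t1 in (500.0, 1500.0)]
        bare = without_inversion(seq)
        without = [simulate_signal(t1, 100.0, bare) for t1 in (500.0, 1500.0)]
        assert np.linalg.norm(with_inv[0] - with_inv[1]) > np.linalg.norm(
            without[0] - without[1]
        )


class TestDictionaryIO:
    def test_lossless_round_trip(self, small_dict, tmp_path):
        path = tmp_path / "dict.h5"
        save_dictionary(small_dict, path)
        loaded = load_dictionary(path)
        assert np.array_equal(loaded.signals, small_dict.signals)
        assert np.array_equal(loaded.grid.entries, small_dict.grid.entries)
        assert loaded.sequence == small_dict.sequence
        assert loaded.normalized == small_dict.normalized

    def test_truncated_file_rejected(self, small_dict, tmp_path):
        path = tmp_path / "dict.h5"
        save_dictionary(small_dict, path)
        data = path.read_bytes()
        path.write_bytes(data[: len(data) // 3])
        with pytest.raises(Exception):
            load_dictionary(path)

    def test_grid_recoverable_from_file_alone(self, small_dict, small_grid, tmp_path):
        path = tmp_path / "dict.h5"
        save_dictionary(small_dict, path)
        loaded = load_dictionary(path)
        assert np.array_equal(loaded.grid.t1_values, small_grid.t1_values)
        assert np.array_equal(loaded.grid.t2_values, small_grid.t2_values)
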