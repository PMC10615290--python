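import numpy as np
import pytest

from sparus.acquisition import (
    Phantom,
    PlaneWaveSequence,
    ValidationError,
    decimate_aperture,
    excitation_pulse,
    make_linear_array,
    mask_rf,
    pulse_sigma,
    simulate_rf,
)


class TestMakeLinearArray:
    def test_default_aperture_width(self, dense_array):
        assert dense_array.aperture_width == pytest.approx(127 * 70e-6)
        assert dense_array.aperture_width == pytest.approx(8.89e-3)

    def test_two_element_symmetry(self):
        arr = make_linear_array(2, 1e-3, 1e6, 0.6)
        assert arr.element_positions == pytest.approx([-0.5e-3, 0.5e-3])

    def test_positions_symmetric_and_uniform(self, dense_array):
        pos = dense_array.element_positions
        assert np.allclose(pos + pos[::-1], 0.0, atol=1e-18)
        assert np.allclose(np.diff(pos), 70e-6)

    def test_wavelength(self, dense_array):
        # oracle: c / f
        assert dense_array.wavelength(1480.0) == pytest.approx(1480.0 / 28e6)
        assert dense_array.wavelength(1480.0) == pytest.approx(52.9e-6, rel=1e-2)

    def test_all_active_by_default(self, dense_array):
        assert dense_array.active_mask.all()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_elements": 1},
            {"pitch": 0.0},
            {"pitch": -70e-6},
            {"center_freq": -1.0},
            {"frac_bandwidth": 0.0},
            {"frac_bandwidth": 2.5},
        ],
    )
    def test_invalid_geometry_rejected(self, kwargs):
        base = dict(n_elements=128, pitch=70e-6, center_freq=28e6, frac_bandwidth=0.6)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            make_linear_array(**base)


class TestDecimateAperture:
    def test_factor2_gives_140um(self, dense_array):
        sparse = decimate_aperture(dense_array, 2)
        assert sparse.n_active == 64
        assert sparse.effective_pitch == pytest.approx(140e-6)

    def test_factor8_gives_560um(self, dense_array):
        sparse = decimate_aperture(dense_array, 8)
        assert sparse.n_active == 16
        assert sparse.effective_pitch == pytest.approx(560e-6)

    def test_factor1_is_identity(self, dense_array):
        same = decimate_aperture(dense_array, 1)
        assert np.array_equal(same.active_mask, dense_array.active_mask)

    def test_geometry_unchanged(self, dense_array):
        sparse = decimate_aperture(dense_array, 8)
        assert sparse.pitch == dense_array.pitch
        assert np.array_equal(sparse.element_positions, dense_array.element_positions)

    def test_twice_by_two_equals_by_four(self, dense_array):
        twice = decimate_aperture(decimate_aperture(dense_array, 2), 2)
        once = decimate_aperture(dense_array, 4)
        assert np.array_equal(twice.active_mask, once.active_mask)

    def test_phase_offsets_pattern(self, dense_array):
        sparse = decimate_aperture(dense_array, 2, phase=1)
        assert np.flatnonzero(sparse.active_mask)[0] == 1

    @pytest.mark.parametrize("factor,phase", [(0, 0), (129, 0), (2, 2), (2, -1)])
    def test_invalid_args(self, dense_array, factor, phase):
        with pytest.raises(ValidationError):
            decimate_aperture(dense_array, factor, phase)


class TestExcitationPulse:
    def test_unit_peak_at_zero(self):
        assert excitation_pulse(0.0, 28e6, 0.6) == 1.0

    def test_decays_to_zero(self):
        sigma = pulse_sigma(28e6, 0.6)
        assert abs(excitation_pulse(50 * sigma, 28e6, 0.6)) < 1e-12
        assert abs(excitation_pulse(-50 * sigma, 28e6, 0.6)) < 1e-12

    def test_minus6db_spectral_width(self):
        # oracle: DFT of the sampled pulse.  Measured at 250 MHz: the
        # -6 dB band edge (36.4 MHz) exceeds Nyquist at the 62.5 MHz DAQ
        # rate, so the width is only measurable at an alias-free rate.
        fs = 250e6
        sigma = pulse_sigma(28e6, 0.6)
        t = np.arange(-8 * sigma, 8 * sigma, 1 / fs)
        spec = np.abs(np.fft.rfft(excitation_pulse(t, 28e6, 0.6), 1 << 16))
        f = np.fft.rfftfreq(1 << 16, 1 / fs)
        pk = int(spec.argmax())
        half = spec[pk] * 10 ** (-6 / 20)
        above = spec >= half
        lo, hi = pk, pk
        while above[lo - 1]:
            lo -= 1
        while above[hi + 1]:
            hi += 1
        width = f[hi] - f[lo]
        assert width == pytest.approx(0.6 * 28e6, rel=0.05)


def _single_scatterer_rf(x, z, array, seq, **kwargs):
    phantom = Phantom(np.array([[x, z]]), np.array([1.0]))
    return simulate_rf(phantom, array, seq, **kwargs)


class TestSimulateRF:
    def test_on_axis_round_trip_time(self, dense_array, clean_sequence):
        rf = _single_scatterer_rf(0.0, 10e-3, dense_array, clean_sequence)
        center = dense_array.n_elements // 2  # element at x = +35 um
        trace = rf.traces[3, center]  # angle 0
        t_peak = rf.t0 + trace.argmax() / rf.sampling_rate
        expected = 2 * 0.01 / 1480.0  # 13.51 us
        assert t_peak == pytest.approx(expected, abs=2 / rf.sampling_rate + 1e-9)

    def test_off_axis_arrival_oracle(self, clean_sequence):
        # oracle: direct geometric path-length computation
        arr = make_linear_array(2, 8e-3, 28e6, 0.6)  # elements at +-4 mm
        rf = _single_scatterer_rf(0.0, 10e-3, arr, clean_sequence)
        trace = rf.traces[3, 1]  # element at +4 mm
        t_peak = rf.t0 + trace.argmax() / rf.sampling_rate
        expected = 0.01 / 1480.0 + np.sqrt(0.004**2 + 0.01**2) / 1480.0
        assert t_peak == pytest.approx(expected, abs=2 / rf.sampling_rate)

    def test_masked_channels_are_zero(self, dense_array, clean_sequence):
        sparse = decimate_aperture(dense_array, 8)
        phantom = Phantom(np.array([[0.0, 5e-3]]), np.array([1.0]))
        rf = simulate_rf(phantom, sparse, clean_sequence)
        assert np.all(rf.traces[:, ~sparse.active_mask, :] == 0.0)
        assert np.any(rf.traces[:, sparse.active_mask, :] != 0.0)

    def test_mask_rf_equals_sparse_simulation(self, dense_array, clean_sequence):
        sparse = decimate_aperture(dense_array, 4)
        phantom = Phantom(
            np.array([[1e-3, 6e-3], [-0.5e-3, 8e-3]]), np.array([1.0, 0.7])
        )
        n = 4000
        rf_dense = simulate_rf(phantom, dense_array, clean_sequence, n_samples=n)
        rf_sparse = simulate_rf(phantom, sparse, clean_sequence, n_samples=n)
        assert np.array_equal(mask_rf(rf_dense, sparse).traces, rf_sparse.traces)

    def test_linearity(self, clean_sequence):
        arr = make_linear_array(16, 140e-6, 28e6, 0.6)
        rng = np.random.default_rng(3)
        pos_a = np.column_stack([rng.uniform(-2e-3, 2e-3, 5), rng.uniform(3e-3, 9e-3, 5)])
        pos_b = np.column_stack([rng.uniform(-2e-3, 2e-3, 4), rng.uniform(3e-3, 9e-3, 4)])
        pa = Phantom(pos_a, rng.standard_normal(5))
        pb = Phantom(pos_b, rng.standard_normal(4))
        n = 4000
        rf_a = simulate_rf(pa, arr, clean_sequence, n_samples=n)
        rf_b = simulate_rf(pb, arr, clean_sequence, n_samples=n)
        rf_ab = simulate_rf(pa.merged_with(pb), arr, clean_sequence, n_samples=n)
        ref = rf_a.traces + rf_b.traces
        assert np.allclose(rf_ab.traces, ref, rtol=1e-9, atol=1e-12 * np.abs(ref).max())

    def test_echo_timing_brute_force_oracle(self, clean_sequence):
        # 100 random scatterer/element/angle triples vs direct path lengths
        arr = make_linear_array(8, 500e-6, 28e6, 0.6)
        rng = np.random.default_rng(17)
        c = clean_sequence.sound_speed
        for _ in range(100):
            x, z = rng.uniform(-2e-3, 2e-3), rng.uniform(2e-3, 9e-3)
            e = int(rng.integers(0, 8))
            a = int(rng.integers(0, clean_sequence.n_angles))
            rf = _single_scatterer_rf(x, z, arr, clean_sequence)
            theta = clean_sequence.angles_rad[a]
            ex = arr.element_positions[e]
            tau = (z * np.cos(theta) + x * np.sin(theta)) / c + np.hypot(x - ex, z) / c
            t_peak = rf.t0 + rf.traces[a, e].argmax() / rf.sampling_rate
            assert abs(t_peak - tau) <= 1.0 / rf.sampling_rate + 1e-12

    def test_seeded_phantom_reproducible(self, dense_array, clean_sequence):
        from sparus.phantoms import tooth_phantom

        p1 = tooth_phantom(1.4, seed=5)
        p2 = tooth_phantom(1.4, seed=5)
        rf1 = simulate_rf(p1, dense_array, clean_sequence)
        rf2 = simulate_rf(p2, dense_array, clean_sequence)
        assert np.array_equal(rf1.traces, rf2.traces)

    def test_window_too_short_names_requirement(self, dense_array, clean_sequence):
        with pytest.raises(ValidationError, match=r"need at least \d+"):
            _single_scatterer_rf(0.0, 10e-3, dense_array, clean_sequence, n_samples=100)

    def test_empty_phantom_rejected(self, dense_array, clean_sequence):
        with pytest.raises(ValidationError):
            simulate_rf(
                Phantom(np.empty((0, 2)), np.empty(0)), dense_array, clean_sequence
            )


class TestPlaneWaveSequence:
    def test_default_seven_angles_five_degree_spacing(self):
        seq = PlaneWaveSequence()
        assert seq.n_angles == 7
        assert seq.angles == pytest.approx(tuple(np.arange(-15.0, 16.0, 5.0)))

    def test_angles_strictly_increasing_enforced(self):
        with pytest.raises(ValidationError):
            PlaneWaveSequence(angles=(0.0, 0.0, 5.0))

    def test_carrier_nyquist_enforced(self, dense_array):
        seq = PlaneWaveSequence(sampling_rate=50e6)
        with pytest.raises(ValidationError, match="Nyquist"):
            seq.validate_for(dense_array)

    def test_phantom_depth_positive(self):
        with pytest.raises(ValidationError):
            Phantom(np.array([[0.0, -1e-3]]), np.array([1.0]))
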