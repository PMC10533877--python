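"""Simulator contracts: closed-form traces, phantoms, sweeps, datasets."""

import numpy as np
import pytest

from phonocell import (
    AcquisitionParams,
    CellPhantom,
    ClassLabel,
    MaterialPoint,
    generate_dataset,
    random_cell_mask,
    simulate_parameter_sweep,
    simulate_scan,
    simulate_trace,
)
from phonocell.simulate import ClassParamModel


@pytest.fixture
def material():
    return MaterialPoint(1600.0, 1.0)


class TestSimulateTrace:
    def test_matches_closed_form_pointwise(self, acq, material):
        # independent oracle: direct evaluation of the decaying sinusoid
        tr = simulate_trace(material, acq, amplitude=0.8, phase=0.3)
        t = np.arange(256) * 10e-12
        f_b = 2 * 1.37 * 1600.0 / 780e-9
        expected = 0.8 * np.sin(2 * np.pi * f_b * t + 0.3) * np.exp(
            -1.0 * 1e6 * 1600.0 * t)
        np.testing.assert_allclose(tr.samples, expected, atol=1e-12)

    def test_zero_amplitude_no_noise_is_null_signal(self, acq, material):
        tr = simulate_trace(material, acq, amplitude=0.0, noise_sigma=0.0)
        assert not np.any(tr.samples)

    def test_dominant_fft_frequency(self, acq, material):
        # independent FFT-peak oracle (plain numpy, no package helpers)
        tr = simulate_trace(material, acq, noise_sigma=0.0)
        spec = np.abs(np.fft.rfft(tr.samples, n=16 * 256))
        freqs = np.fft.rfftfreq(16 * 256, d=10e-12)
        peak = freqs[np.argmax(spec)]
        assert peak == pytest.approx(2 * 1.37 * 1600.0 / 780e-9, rel=0.01)

    def test_sweep_lower_bounds_are_valid(self, acq):
        tr = simulate_trace(MaterialPoint(1550.0, 0.25), acq)
        assert len(tr) == 256

    def test_envelope_nonincreasing(self, acq):
        tr = simulate_trace(MaterialPoint(1700.0, 1.5), acq, noise_sigma=0.0)
        x = np.abs(tr.samples)
        # local maxima of |s| must decrease monotonically in time
        peaks = [x[i] for i in range(1, 255) if x[i] >= x[i-1] and x[i] >= x[i+1]
                 and x[i] > 1e-9]
        assert all(a >= b for a, b in zip(peaks, peaks[1:]))

    def test_seed_determinism(self, acq, material):
        a = simulate_trace(material, acq, noise_sigma=0.2, rng_seed=42)
        b = simulate_trace(material, acq, noise_sigma=0.2, rng_seed=42)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_negative_noise_rejected(self, acq, material):
        with pytest.raises(ValueError):
            simulate_trace(material, acq, noise_sigma=-0.1)

    def test_interface_event_flips_phase(self, acq, material):
        plain = simulate_trace(material, acq)
        jumped = simulate_trace(material, acq, interface_time_s=1e-9,
                                interface_phase_jump=np.pi)
        t = np.arange(256) * 10e-12
        np.testing.assert_allclose(jumped.samples[t < 1e-9],
                                   plain.samples[t < 1e-9])
        np.testing.assert_allclose(jumped.samples[t >= 1e-9],
                                   -plain.samples[t >= 1e-9], atol=1e-12)


class TestSimulateScan:
    def test_all_background_phantom(self, acq):
        ph = CellPhantom(grid_shape=(9, 9),
                        cell_mask=np.zeros((9, 9), dtype=bool))
        scan = simulate_scan(ph, acq, rng_seed=0)
        assert (scan.labels == int(ClassLabel.BACKGROUND)).all()

    def test_default_grid_has_3721_traces(self, acq):
        ph = CellPhantom()  # default 61 x 61
        scan = simulate_scan(ph, acq, rng_seed=1)
        assert scan.n_traces == 61 * 61

    def test_seed_determinism(self, acq):
        scans = [simulate_scan(CellPhantom(grid_shape=(11, 11)), acq,
                               rng_seed=5) for _ in range(2)]
        np.testing.assert_array_equal(scans[0].traces, scans[1].traces)
        np.testing.assert_array_equal(scans[0].labels, scans[1].labels)

    def test_labels_follow_mask(self, acq):
        rng = np.random.default_rng(3)
        mask = random_cell_mask((15, 15), rng)
        ph = CellPhantom(grid_shape=(15, 15), cell_mask=mask,
                        class_of_cell=ClassLabel.ABNORMAL)
        scan = simulate_scan(ph, acq, rng_seed=3)
        assert (scan.labels[mask] == int(ClassLabel.ABNORMAL)).all()
        assert (scan.labels[~mask] == int(ClassLabel.BACKGROUND)).all()

    def test_mask_coverage_in_range(self):
        for seed in range(5):
            mask = random_cell_mask((31, 31), np.random.default_rng(seed))
            frac = mask.mean()
            assert 0.15 < frac < 0.65  # blob trimming may shave the low end


class TestParameterSweep:
    def test_counting_and_provenance(self, acq):
        out = simulate_parameter_sweep([1600.0, 1700.0], [0.5, 1.0], acq,
                                       noise_sigma=0.1, rng_seed=0,
                                       replicates=3)
        assert len(out) == 12
        mats = {(m.sound_velocity, m.attenuation_coeff) for m, _ in out}
        assert mats == {(1600.0, 0.5), (1600.0, 1.0),
                        (1700.0, 0.5), (1700.0, 1.0)}

    def test_default_ranges(self, acq):
        out = simulate_parameter_sweep(acq=acq, noise_sigma=0.0, rng_seed=0)
        nus = [m.sound_velocity for m, _ in out]
        alphas = [m.attenuation_coeff for m, _ in out]
        assert min(nus) == 1550.0 and max(nus) == 1850.0
        assert min(alphas) == 0.25 and max(alphas) == 3.0

    def test_noise_off_replicates_identical(self, acq):
        out = simulate_parameter_sweep([1600.0], [1.0], acq, noise_sigma=0.0,
                                       rng_seed=0, replicates=2)
        np.testing.assert_array_equal(out[0][1].samples, out[1][1].samples)

    def test_empty_grid_rejected(self, acq):
        with pytest.raises(ValueError):
            simulate_parameter_sweep([], [1.0], acq)


class TestGenerateDataset:
    def test_balance_80_cells(self, acq):
        scans = generate_dataset(n_cells_per_class=8, n_batches=4,
                                 grid_shape=(7, 7), acq=acq, rng_seed=0)
        assert len(scans) == 16
        for label in (ClassLabel.NORMAL, ClassLabel.ABNORMAL):
            for batch in range(1, 5):
                n = sum(1 for s in scans
                        if s.cell_class == label and s.batch_id == batch)
                assert n == 2

    def test_minimal_dataset(self, acq):
        scans = generate_dataset(n_cells_per_class=1, n_batches=1,
                                 grid_shape=(7, 7), acq=acq, rng_seed=0)
        assert len(scans) == 2

    def test_indivisible_batches_rejected(self, acq):
        with pytest.raises(ValueError):
            generate_dataset(n_cells_per_class=10, n_batches=4,
                             grid_shape=(7, 7), acq=acq)

    def test_class_ordering_of_centroids(self, acq):
        # abnormal (cancer) cells must land below normal cells in mean nu
        # and mean alpha0 across a seeded 20-cell draw
        scans = generate_dataset(n_cells_per_class=10, n_batches=1,
                                 grid_shape=(7, 7), acq=acq, rng_seed=12)
        by_class = {c: [] for c in (ClassLabel.NORMAL, ClassLabel.ABNORMAL)}
        for s in scans:
            by_class[s.cell_class].append(
                (s.phantom.centroid_nu, s.phantom.centroid_alpha0))
        mean = {c: np.mean(v, axis=0) for c, v in by_class.items()}
        assert mean[ClassLabel.ABNORMAL][0] < mean[ClassLabel.NORMAL][0]
        assert mean[ClassLabel.ABNORMAL][1] < mean[ClassLabel.NORMAL][1]

    def test_batch_drift_applied_to_cells_only(self, acq):
        model = ClassParamModel(batch_nu_drift=30.0)
        scans = generate_dataset(n_cells_per_class=2, n_batches=2,
                                 grid_shape=(9, 9), acq=acq,
                                 class_param_model=model, rng_seed=1,
                                 noise_sigma=0.0)
        # background pixels keep the shared mean across batches
        bg_means = [s.nu_map[~s.phantom.cell_mask].mean() for s in scans]
        assert np.ptp(bg_means) < 15.0
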