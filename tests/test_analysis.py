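"""Spectrum I/O, peak tracking, calibration fits and the synthetic generator."""

import numpy as np
import pytest

from omcsim.analysis import (
    SpectrumSeries,
    SyntheticSeriesSpec,
    fit_calibration,
    fit_sensitivity,
    generate_synthetic_series,
    read_spectrum,
    track_peaks,
    write_spectrum,
)
from omcsim.dispersion import DispersionSet
from omcsim.spectrum import TransmissionSpectrum



def single_pol_set(lam, dn):
    """Single-polarization phase model: clean carrier fringes."""
    n_odd = 1.42 * np.ones_like(lam)
    return DispersionSet(
        lam_um=lam, n_even_x=n_odd + dn, n_odd_x=n_odd,
        n_even_y=n_odd + dn, n_odd_y=n_odd,
    )


def make_series(ddn=2e-3, conditions=(1.3333, 1.3334, 1.3335, 1.3336, 1.3337),
                noise=0.0, jitter=0.0, seed=7, n_points=8001):
    lam = np.linspace(0.58, 1.02, 45)
    base = single_pol_set(lam, dn=1.5e-3 * np.ones_like(lam))
    spec = SyntheticSeriesSpec(
        dispersion=base,
        conditions=list(conditions),
        ddn_dcondition_x=ddn,
        ddn_dcondition_y=ddn,
        window_nm=(600.0, 1000.0),
        intensity_noise_sd=noise,
        wavelength_jitter_sd_nm=jitter,
        seed=seed,
        n_points=n_points,
    )
    return generate_synthetic_series(spec)


class TestReadWriteSpectrum:
    def test_round_trip(self, tmp_path):
        spec = TransmissionSpectrum(
            lam_nm=np.linspace(600, 700, 50), power=np.random.default_rng(0).random(50)
        )
        path = tmp_path / "s.tsv"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        assert back.provenance == "measured"
        assert back.lam_nm.size == 50
        assert np.allclose(back.power, spec.power, atol=1e-7)

    def test_db_dialect_round_trip(self, tmp_path):
        spec = TransmissionSpectrum(
            lam_nm=np.linspace(600, 700, 40),
            power=0.5 + 0.4 * np.sin(np.linspace(0, 8, 40)),
        )
        path = tmp_path / "s_db.tsv"
        write_spectrum(spec, path, dialect="db")
        back = read_spectrum(path, dialect="db")
        assert np.allclose(back.power, spec.power, rtol=1e-6)

    def test_shuffled_wavelengths_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("600 0.5\n650 0.4\n620 0.6\n")
        with pytest.raises(ValueError, match="increasing"):
            read_spectrum(path)

    def test_non_numeric_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("600 0.5\nabc 0.4\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_spectrum(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\n")
        with pytest.raises(ValueError, match="empty"):
            read_spectrum(path)

    def test_comma_delimited_accepted(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("600.0,0.5\n601.0,0.6\n602.0,0.4\n")
        assert read_spectrum(path).lam_nm.size == 3


class TestTrackPeaks:
    def test_identical_spectra_zero_shift(self):
        series = make_series(ddn=0.0, noise=0.0)
        tracks = track_peaks(series)
        assert len(tracks) > 5
        for t in tracks:
            assert not t.lost
            assert np.allclose(t.shifts_nm, 0.0, atol=1e-9)

    def test_programmed_shift_recovered(self):
        """Phase-model shifts are recovered at the wavelength-grid resolution.

        A fringe at phase L dn / lam = const moves by
        dlam/dc = lam (d dn/dc) / G with G = dn here (dn flat in lambda).
        """
        series = make_series(ddn=2e-3)
        tracks = track_peaks(series)
        kept = [t for t in tracks if not t.lost]
        assert kept
        for t in kept:
            lam0 = t.wavelengths_nm[0]
            expected_step = 1e-4 * 2e-3 * lam0 / 1.5e-3  # ~0.1 nm per step
            steps = np.diff(t.wavelengths_nm)
            assert np.allclose(steps, expected_step, atol=0.03)

    def test_tracking_exact_for_small_steps(self):
        """No mis-association while per-step shift < 25% of fringe spacing."""
        series = make_series(ddn=2e-3)
        tracks = track_peaks(series)
        assert all(not t.lost for t in tracks)
        # shifts must be smooth: no fringe-hop jumps
        for t in tracks:
            assert np.all(np.abs(np.diff(t.wavelengths_nm)) < 5.0)

    def test_all_tracks_lost_raises(self):
        lam = np.linspace(600, 1000, 4001)
        a = TransmissionSpectrum(lam_nm=lam, power=np.cos(lam / 3.0) ** 2)
        b = TransmissionSpectrum(lam_nm=lam, power=np.full(lam.size, 0.5))
        series = SpectrumSeries(spectra=[a, b], conditions=np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="lost"):
            track_peaks(series)

    def test_single_spectrum_rejected(self):
        series = make_series(conditions=(1.3333,))
        with pytest.raises(ValueError, match="two spectra"):
            track_peaks(series)


class TestFits:
    def test_perfect_linear_track_fits_exactly(self):
        series = make_series(ddn=2e-6)
        tracks = track_peaks(series)
        fits = fit_sensitivity(tracks, series.conditions)
        assert fits
        for f in fits:
            assert f.r_squared > 0.9999
            assert f.residual_sd_nm < 0.02

    def test_known_slope_recovered_within_two_sd(self):
        """A -4600 nm/RIU track with 0.05 nm position noise is recovered."""
        from omcsim.analysis import PeakTrack

        rng = np.random.default_rng(5)
        sri = np.array([1.3333, 1.3334, 1.3335, 1.3336, 1.3337])
        slope = -4600.0
        lam = 820.0 + slope * (sri - sri[0]) + rng.normal(0, 0.05, sri.size)
        fits = fit_sensitivity([PeakTrack(label="P1", wavelengths_nm=lam)], sri)
        f = fits[0]
        # standard error of an OLS slope over these 5 conditions
        se = 0.05 / (np.std(sri) * np.sqrt(sri.size))
        assert f.slope == pytest.approx(slope, abs=2 * se)

    def test_slope_recovered_from_noisy_spectra(self):
        """End-to-end: spectra with intensity noise still yield the slope."""
        ddn = -8.6e-3  # gives lam * ddn / dn ~ -4600 nm/RIU at 800 nm
        series = make_series(ddn=ddn, noise=0.003, jitter=0.01, seed=3)
        # prominence well above the noise floor: count real fringes only
        tracks = track_peaks(series, prominence=0.2)
        fits = fit_sensitivity([t for t in tracks if not t.lost], series.conditions)
        assert fits
        for f in fits:
            assert f.slope < 0
            track = next(t for t in tracks if t.label == f.track_label)
            expected = ddn * track.wavelengths_nm[0] / 1.5e-3
            assert f.slope == pytest.approx(expected, rel=0.10)

    def test_two_conditions_insufficient(self):
        series = make_series(conditions=(1.3333, 1.3334))
        tracks = track_peaks(series)
        with pytest.raises(ValueError, match=">= 3"):
            fit_sensitivity(tracks, series.conditions)

    def test_calibration_with_replicates(self):
        rng = np.random.default_rng(11)
        conc = np.repeat([12.0, 24.0, 36.0, 48.0], 3)
        lam = -0.05 * conc + 820.0 + rng.normal(0, 0.1, conc.size)
        from omcsim.analysis import PeakTrack

        track = PeakTrack(label="P1", wavelengths_nm=lam)
        fits = fit_calibration(
            [track], conc, predictor="concentration",
            replicate_ids=list(np.tile([0, 1, 2], 4)),
        )
        f = fits[0]
        assert f.r_squared >= 0.98
        assert f.slope == pytest.approx(-0.05, rel=0.15)
        assert f.replicate_sd_nm is not None and f.replicate_sd_nm < 0.3
        assert f.linear_range == (12.0, 48.0)

    def test_log_concentration_predictor_validation(self):
        from omcsim.analysis import PeakTrack

        track = PeakTrack(label="P1", wavelengths_nm=np.array([820.0, 819.0, 818.0]))
        with pytest.raises(ValueError, match="positive"):
            fit_calibration([track], [0.0, 1.0, 2.0], predictor="log-concentration")

    def test_degenerate_predictor_rejected(self):
        from omcsim.analysis import PeakTrack

        track = PeakTrack(label="P1", wavelengths_nm=np.array([820.0, 819.0, 818.0]))
        with pytest.raises(ValueError, match="degenerate"):
            fit_sensitivity([track], [1.333, 1.333, 1.333])


class TestSyntheticGenerator:
    def test_same_seed_identical(self):
        a = make_series(noise=0.02, jitter=0.05, seed=42)
        b = make_series(noise=0.02, jitter=0.05, seed=42)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.power, sb.power)
            assert np.array_equal(sa.lam_nm, sb.lam_nm)

    def test_zero_noise_equals_clean_forward_model(self):
        noisy = make_series(noise=0.0, jitter=0.0)
        again = make_series(noise=0.0, jitter=0.0, seed=99)
        for sa, sb in zip(noisy.spectra, again.spectra):
            assert np.array_equal(sa.power, sb.power)

    def test_noise_averages_to_clean_value(self):
        """Mean of 100 noisy realizations within 3 standard errors of clean."""
        clean = make_series(noise=0.0, conditions=(1.3333,), n_points=101)
        sd = 0.05
        vals = []
        for seed in range(100):
            s = make_series(noise=sd, conditions=(1.3333,), seed=seed, n_points=101)
            vals.append(s.spectra[0].power[50])
        se = sd / np.sqrt(100)
        assert abs(np.mean(vals) - clean.spectra[0].power[50]) < 3 * se

    def test_empty_conditions_rejected(self):
        lam = np.linspace(0.6, 1.0, 11)
        with pytest.raises(ValueError, match="empty"):
            SyntheticSeriesSpec(dispersion=single_pol_set(lam, 1e-3 * np.ones_like(lam)),
                                conditions=[])

    def test_series_straddling_dtp_shifts_both_ways(self):
        """Peaks left of the DTP red-shift while right-side peaks blue-shift.

        Phase model: dn(lambda; c) = k (lambda - lt(c))^2 / lambda + m(c) lambda
        with the turning point lt blue-shifting as the condition rises.  The
        group difference changes sign at lt, so tracked fringes on the two
        sides move in opposite directions.
        """
        from omcsim.spectrum import InterferometerConfig, simulate_transmission

        k, lt0, c0 = 0.008, 1.00, 1.393
        lam = np.linspace(0.62, 1.32, 71)
        conditions = [c0, c0 + 1e-4, c0 + 2e-4]
        spectra = []
        for c in conditions:
            lt = lt0 - 2.0 * (c - c0)
            dn = k * (lam - lt) ** 2 / lam + 0.1 * (c - c0) * lam
            spectra.append(simulate_transmission(
                single_pol_set(lam, dn),
                InterferometerConfig(window_nm=(650, 1290), p1x=1.0, p1y=0.0),
            ))
        series = SpectrumSeries(spectra=spectra, conditions=np.array(conditions))
        tracks = [t for t in track_peaks(series) if not t.lost]
        left = [t for t in tracks if t.wavelengths_nm[0] < lt0 * 1e3 - 60]
        right = [t for t in tracks if t.wavelengths_nm[0] > lt0 * 1e3 + 60]
        assert left and right
        # red shift left of the turning point, blue shift right of it
        assert all(t.shifts_nm[-1] > 0 for t in left)
        assert all(t.shifts_nm[-1] < 0 for t in right)
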