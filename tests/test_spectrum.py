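"""Forward transmission model, fringe counting and the DTP predictor chain.

Predictor-chain tests run on the analytic stand-in dispersion model (see
conftest) through the ``dispersion_provider`` hook, so they exercise the
peak-map fitting, inversion and DTP search logic without finite-difference
solves.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omcsim.dispersion import DispersionSet
from omcsim.spectrum import (
    CouplerModel,
    InterferometerConfig,
    TransmissionSpectrum,
    count_peaks,
    simulate_beat_spectrum,
    simulate_transmission,
)

from conftest import toy_provider, toy_turning_point_um


def flat_set(lam, dn=2e-3, db=0.0):
    n_odd = 1.42 * np.ones_like(lam)
    return DispersionSet(
        lam_um=lam,
        n_even_x=n_odd + dn + db,
        n_odd_x=n_odd,
        n_even_y=n_odd + dn,
        n_odd_y=n_odd,
    )


@pytest.fixture
def toy_model():
    return CouplerModel(dispersion_provider=toy_provider)


class TestSimulateTransmission:
    lam = np.linspace(0.55, 1.05, 41)

    def test_energy_conservation_machine_precision(self):
        dset = flat_set(self.lam, dn=3e-3, db=2e-4)
        cfg = InterferometerConfig(window_nm=(600, 1000))
        p3 = simulate_transmission(dset, cfg)
        p4 = simulate_transmission(
            dset, InterferometerConfig(window_nm=(600, 1000), port=4)
        )
        assert np.max(np.abs(p3.power + p4.power - 1.0)) < 1e-14

    def test_zero_phase_sends_all_power_to_port3(self):
        dset = flat_set(self.lam, dn=0.0)
        cfg = InterferometerConfig(window_nm=(600, 1000))
        spec = simulate_transmission(dset, cfg)
        assert np.allclose(spec.power, 1.0)
        assert np.allclose(
            simulate_transmission(dset, InterferometerConfig(window_nm=(600, 1000), port=4)).power,
            0.0,
        )

    def test_window_beyond_data_rejected(self):
        dset = flat_set(self.lam)
        with pytest.raises(ValueError, match="beyond"):
            simulate_transmission(dset, InterferometerConfig(window_nm=(500, 1000)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            InterferometerConfig(coupling_length_mm=0)
        with pytest.raises(ValueError):
            InterferometerConfig(p1x=0.7, p1y=0.5)
        with pytest.raises(ValueError):
            InterferometerConfig(port=5)


class TestCountPeaks:
    lam = np.linspace(0.55, 1.05, 41)

    def test_flat_spectrum_has_no_peaks(self):
        spec = TransmissionSpectrum(
            lam_nm=np.linspace(600, 1000, 500), power=np.full(500, 0.7)
        )
        assert count_peaks(spec) == 0

    @given(dn=st.floats(5e-4, 5e-3))
    @settings(deadline=None, max_examples=20)
    def test_count_matches_analytic_phase_span(self, dn):
        """Noiseless two-mode fringe count within +/-1 of the phase span."""
        dset = flat_set(self.lam, dn=dn)
        cfg = InterferometerConfig(window_nm=(600, 1000), p1x=1.0, p1y=0.0)
        spec = simulate_transmission(dset, cfg)
        length_nm = 12e6
        expected = length_nm * dn * (1 / 600 - 1 / 1000)  # phase span / 2 pi
        # a maximum can sit just outside either window edge, so the count
        # may fall short of the phase span by up to one fringe per edge
        assert abs(count_peaks(spec, window_nm=(600, 1000)) - expected) < 2


    def test_empty_window_rejected(self):
        spec = TransmissionSpectrum(
            lam_nm=np.linspace(600, 1000, 100), power=np.random.rand(100)
        )
        with pytest.raises(ValueError, match="window"):
            spec.detect_peaks(window_nm=(1100, 1200))

    def test_subgrid_peak_refinement(self):
        """Parabolic refinement recovers a peak centre off the sample grid."""
        lam = np.linspace(600, 700, 201)  # 0.5 nm grid
        true = 650.17
        spec = TransmissionSpectrum(lam_nm=lam, power=np.cos(0.1 * (lam - true)) ** 2)
        peaks = spec.detect_peaks()
        nearest = min(peaks, key=lambda p: abs(p.wavelength_nm - true))
        assert nearest.wavelength_nm == pytest.approx(true, abs=0.02)


class TestBeatSpectrum:
    def test_beat_ignores_common_mode_splitting(self):
        lam = np.linspace(0.55, 1.05, 41)
        cfg = InterferometerConfig(window_nm=(600, 1000))
        small = simulate_beat_spectrum(flat_set(lam, dn=1e-3, db=1e-4), cfg)
        large = simulate_beat_spectrum(flat_set(lam, dn=9e-3, db=1e-4), cfg)
        assert np.allclose(small.power, large.power)

    def test_fringe_spacing_grows_toward_turning_point(self, toy_model):
        """Adjacent beat peaks broaden approaching the DTP (max at the DTP)."""
        d, sri = 2.6, 1.393
        lt_um = toy_turning_point_um(d, sri)
        lam = np.linspace(lt_um - 0.50, lt_um + 0.05, 56)
        dset = toy_provider(toy_model.cross_section(d, sri), lam)
        spec = simulate_beat_spectrum(
            dset,
            InterferometerConfig(window_nm=((lt_um - 0.48) * 1e3, lt_um * 1e3)),
        )
        pk = [p.wavelength_nm for p in spec.detect_peaks()]
        gaps = np.diff(pk)
        assert len(gaps) >= 3
        assert np.all(np.diff(gaps) > 0)  # spacing increases toward the DTP


class TestPeakDiameterMap:
    def test_counts_decrease_and_inverse_round_trips(self, toy_model):
        pdm = toy_model.build_peak_diameter_map(np.linspace(2.0, 3.2, 9))
        assert np.all(np.diff(pdm.counts) < 0)
        for d in (2.1, 2.6, 3.0):
            n = float(pdm.predicted_counts(d))
            assert pdm.diameter_from_peak_count(n) == pytest.approx(d, abs=0.12)

    def test_out_of_range_count_rejected(self, toy_model):
        pdm = toy_model.build_peak_diameter_map(np.linspace(2.0, 3.2, 9))
        with pytest.raises(ValueError):
            pdm.diameter_from_peak_count(3 * pdm.counts[0])

    def test_grid_validation(self, toy_model):
        with pytest.raises(ValueError, match="8 diameter"):
            toy_model.build_peak_diameter_map([2.0, 2.5, 3.0])
        with pytest.raises(ValueError, match="2.0-3.2"):
            toy_model.build_peak_diameter_map(np.linspace(1.0, 3.0, 9))


class TestDtpPredictionChain:
    def test_dtp_matches_programmed_turning_point(self, toy_model):
        for d, sri in [(2.4, 1.333), (2.8, 1.335)]:
            lt_nm = toy_turning_point_um(d, sri) * 1e3
            assert toy_model.dtp(d, sri) == pytest.approx(lt_nm, abs=1.0)

    def test_dtp_monotonic_in_diameter_and_sri(self, toy_model):
        assert toy_model.dtp(2.4, 1.333) < toy_model.dtp(2.6, 1.333)
        assert toy_model.dtp(2.6, 1.343) < toy_model.dtp(2.6, 1.333)

    def test_predict_dtp_round_trip(self, toy_model):
        pdm = toy_model.build_peak_diameter_map(np.linspace(2.0, 3.2, 9))
        n_air = float(pdm.predicted_counts(2.5))
        pred = toy_model.predict_dtp(n_air, 1.333)
        assert pred.diameter_um == pytest.approx(2.5, abs=0.05)
        expected = toy_turning_point_um(pred.diameter_um, 1.333) * 1e3
        assert pred.dtp_nm == pytest.approx(expected, abs=2.0)

    def test_predict_dtp_input_validation(self, toy_model):
        with pytest.raises(ValueError, match="6-65"):
            toy_model.predict_dtp(100, 1.333)
        with pytest.raises(ValueError, match="SRI"):
            toy_model.predict_dtp(20, 1.50)

    def test_dtp_surface_monotone_with_missing_cells_explicit(self, toy_model):
        toy_model.build_peak_diameter_map(np.linspace(2.0, 3.2, 9))
        surf = toy_model.build_dtp_surface(
            n_range=[10, 20, 30], sri_range=[1.333, 1.338, 1.343]
        )
        finite = surf.dtp_nm[np.isfinite(surf.dtp_nm)]
        assert finite.size == surf.dtp_nm.size
        # decreasing along both axes: more peaks = thinner waist = bluer DTP
        assert np.all(np.diff(surf.dtp_nm, axis=0) < 0)
        assert np.all(np.diff(surf.dtp_nm, axis=1) < 0)
        assert surf.query(5, 1.333) is None  # outside the grid: no extrapolation

    def test_sensitivity_prediction_diverges_at_dtp(self, toy_model):
        toy_model.build_peak_diameter_map(np.linspace(2.0, 3.2, 9))
        pred = toy_model.predict_dtp(20, 1.333)
        at_dtp = toy_model.sensitivity_from_peak_count(20, pred.dtp_nm, 1.333)
        assert at_dtp.diverging
        away = toy_model.sensitivity_from_peak_count(20, pred.dtp_nm - 80, 1.333)
        assert not away.diverging
        assert np.isfinite(away.s_nm_per_riu)

    def test_recommend_peak_count(self, toy_model):
        toy_model.build_peak_diameter_map(np.linspace(2.0, 3.2, 9))
        lam_op, sri = 900.0, 1.333
        # requirement 0 -> smallest count in range
        assert toy_model.recommend_peak_count(0.0, lam_op, sri) == 6
        s20 = abs(toy_model.sensitivity_from_peak_count(20, lam_op, sri).s_nm_per_riu)
        s30 = abs(toy_model.sensitivity_from_peak_count(30, lam_op, sri).s_nm_per_riu)
        assert s30 > s20  # |S| grows with the fringe count at fixed wavelength
        need = 0.5 * (s20 + s30)
        rec = toy_model.recommend_peak_count(need, lam_op, sri, n_range=(6, 40))
        assert 20 < rec <= 30
        assert toy_model.recommend_peak_count(1e12, lam_op, sri, n_range=(6, 30)) is None
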