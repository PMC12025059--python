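"""Two-mode interference transmission model and the air-spectrum DTP predictor.

The coupler output ports carry

    P3 = P1x cos^2(phi_x/2) + P1y cos^2(phi_y/2)
    P4 = P1x sin^2(phi_x/2) + P1y sin^2(phi_y/2)
    phi_p = 2 pi L (n_even^p - n_odd^p) / lambda

so P3 + P4 = P1 identically.  With an unpolarized source this is

    P3 = 1/2 + 1/2 cos(phi_mean) cos(dphi/2),

a fast carrier set by the mean even/odd splitting modulated by the slow
*beat* of the differential birefringence dphi = 2 pi L (dn_x - dn_y) /
lambda.  The fringe family a spectrometer resolves -- and the one whose
count fingerprints the waist diameter -- is the beat
(``simulate_beat_spectrum``); its stationary point is the DTP.  Counting
the beat fringes of the air spectrum therefore infers the diameter
(fringe count grows roughly exponentially as the waist narrows), and with
the diameter known the DTP at any surrounding index follows from the
dispersion engine.  That chain -- air peak count -> diameter -> DTP(SRI)
-> sensitivity -- lets a fabricated sensor's liquid-phase behaviour be
predicted from a dry measurement.

``CouplerModel`` bundles the chain with a dispersion cache so repeated
predictions (peak-diameter map, DTP surface) reuse solved sweeps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import curve_fit
from scipy.signal import find_peaks, peak_prominences, peak_widths

from omcsim.dispersion import (
    DEFAULT_FORMULATION,
    DEFAULT_SPACING_UM,
    DispersionSet,
    build_dispersion_set,
    group_difference,
    locate_dtp,
    normalize_formulation,
    sensitivity,
)
from omcsim.geometry import CrossSection, build_cross_section

#: Default peak-counting window (nm) for air spectra; covers the working
#: range of the 600-980 nm spectrometer with a small margin.
DEFAULT_AIR_WINDOW_NM = (600.0, 1000.0)
#: Default prominence threshold for fringe counting (normalized power).
DEFAULT_PROMINENCE = 0.01


@dataclass(frozen=True)
class InterferometerConfig:
    """Forward-model settings for the two-mode interferometer."""

    coupling_length_mm: float = 12.0
    p1x: float = 0.5
    p1y: float = 0.5
    window_nm: tuple[float, float] = DEFAULT_AIR_WINDOW_NM
    port: int = 3

    def __post_init__(self) -> None:
        if self.coupling_length_mm <= 0:
            raise ValueError("coupling length must be positive")
        if abs(self.p1x + self.p1y - 1.0) > 1e-12:
            raise ValueError("input powers must satisfy P1x + P1y = 1")
        if self.port not in (3, 4):
            raise ValueError("output port must be 3 or 4")


@dataclass
class DetectedPeak:
    wavelength_nm: float
    prominence: float
    width_nm: float


@dataclass
class TransmissionSpectrum:
    """Wavelength grid with normalized power at one output port."""

    lam_nm: np.ndarray
    power: np.ndarray
    port: int = 3
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.lam_nm = np.asarray(self.lam_nm, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.lam_nm.size != self.power.size:
            raise ValueError("wavelength and power arrays differ in length")
        if self.lam_nm.size and np.any(np.diff(self.lam_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def detect_peaks(
        self,
        window_nm: tuple[float, float] | None = None,
        prominence: float = DEFAULT_PROMINENCE,
    ) -> list[DetectedPeak]:
        """Local maxima above a prominence threshold, sorted by wavelength.

        Peak positions are refined to sub-grid precision by a least-squares
        parabola through the samples around each maximum.  The fitting
        window scales with the fringe width (about a quarter of the FWHM),
        which averages intensity noise down instead of amplifying it the
        way a bare three-point vertex formula would on a fine grid.
        """
        lam, p = self.lam_nm, self.power
        if window_nm is not None:
            sel = (lam >= window_nm[0]) & (lam <= window_nm[1])
            if not np.any(sel):
                raise ValueError("peak-counting window is empty")
            lam, p = lam[sel], p[sel]
        idx, _ = find_peaks(p, prominence=prominence)
        if idx.size == 0:
            return []
        prom = peak_prominences(p, idx)[0]
        width = peak_widths(p, idx, rel_height=0.5)[0]
        step = np.median(np.diff(lam)) if lam.size > 1 else 0.0
        out = []
        for i, pr, w in zip(idx, prom, width):
            lam_pk = lam[i]
            k = int(np.clip(round(w / 4), 1, 30))
            sl = slice(max(i - k, 0), min(i + k + 1, lam.size))
            t = lam[sl] - lam[i]
            if t.size >= 3:
                c2, c1, _ = np.polyfit(t, p[sl], 2)
                if c2 < 0:
                    vertex = -c1 / (2 * c2)
                    if abs(vertex) <= (k + 0.5) * step:
                        lam_pk = lam[i] + vertex
            out.append(DetectedPeak(float(lam_pk), float(pr), float(w * step)))
        return out


def simulate_transmission(
    dset: DispersionSet,
    config: InterferometerConfig = InterferometerConfig(),
    n_points: int | None = None,
) -> TransmissionSpectrum:
    """Forward-model the port spectrum from even/odd dispersion curves.

    The window must lie inside the dispersion data.  The wavelength grid is
    auto-refined to at least 16 samples per interference fringe (estimated
    from the total phase excursion across the window).
    """
    lam_lo, lam_hi = config.window_nm
    data_lo, data_hi = dset.lam_um[0] * 1e3, dset.lam_um[-1] * 1e3
    if lam_lo < data_lo - 1e-9 or lam_hi > data_hi + 1e-9:
        raise ValueError(
            f"window {config.window_nm} nm extends beyond dispersion data "
            f"({data_lo:.0f}-{data_hi:.0f} nm)"
        )
    dn_x = CubicSpline(dset.lam_um, dset.delta_n("x"))
    dn_y = CubicSpline(dset.lam_um, dset.delta_n("y"))
    length_nm = config.coupling_length_mm * 1e6

    def phases(lam_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lam_um = lam_nm * 1e-3
        return (
            2 * np.pi * length_nm * dn_x(lam_um) / lam_nm,
            2 * np.pi * length_nm * dn_y(lam_um) / lam_nm,
        )

    if n_points is None:
        probe = np.linspace(lam_lo, lam_hi, 64)
        px, py = phases(probe)
        span = max(
            float(np.sum(np.abs(np.diff(px)))), float(np.sum(np.abs(np.diff(py))))
        )
        n_points = int(max(1001, 16 * span / (2 * np.pi)))
    lam_nm = np.linspace(lam_lo, lam_hi, n_points)
    phi_x, phi_y = phases(lam_nm)
    p3 = config.p1x * np.cos(phi_x / 2) ** 2 + config.p1y * np.cos(phi_y / 2) ** 2
    power = p3 if config.port == 3 else 1.0 - p3
    return TransmissionSpectrum(lam_nm=lam_nm, power=power, port=config.port)


def simulate_beat_spectrum(
    dset: DispersionSet,
    config: InterferometerConfig = InterferometerConfig(),
    n_points: int | None = None,
) -> TransmissionSpectrum:
    """Fringe-contrast interferogram of the differential-birefringence beat.

    Returns cos^2(dphi/2) with dphi = 2 pi L (dn_x - dn_y) / lambda -- the
    slowly varying factor of the port-3 spectrum that survives spectrometer
    resolution, whose maxima are the characteristic interference peaks used
    for diameter fingerprinting.  The grid is auto-refined to >= 16 samples
    per beat fringe.
    """
    lam_lo, lam_hi = config.window_nm
    data_lo, data_hi = dset.lam_um[0] * 1e3, dset.lam_um[-1] * 1e3
    if lam_lo < data_lo - 1e-9 or lam_hi > data_hi + 1e-9:
        raise ValueError(
            f"window {config.window_nm} nm extends beyond dispersion data "
            f"({data_lo:.0f}-{data_hi:.0f} nm)"
        )
    db = CubicSpline(dset.lam_um, dset.delta_n("x") - dset.delta_n("y"))
    length_nm = config.coupling_length_mm * 1e6

    def beat_phase(lam_nm: np.ndarray) -> np.ndarray:
        return 2 * np.pi * length_nm * db(lam_nm * 1e-3) / lam_nm

    if n_points is None:
        probe = np.linspace(lam_lo, lam_hi, 128)
        span = float(np.sum(np.abs(np.diff(beat_phase(probe)))))
        n_points = int(max(1001, 16 * span / (2 * np.pi)))
    lam_nm = np.linspace(lam_lo, lam_hi, n_points)
    phi = beat_phase(lam_nm)
    p3 = np.cos(phi / 2) ** 2
    power = p3 if config.port == 3 else 1.0 - p3
    return TransmissionSpectrum(lam_nm=lam_nm, power=power, port=config.port)


def count_peaks(
    spectrum: TransmissionSpectrum,
    window_nm: tuple[float, float] | None = None,
    prominence: float = DEFAULT_PROMINENCE,
) -> int:
    """Number of interference peaks inside the window."""
    return len(spectrum.detect_peaks(window_nm=window_nm, prominence=prominence))


def _exp_model(d: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-b * d) + c


@dataclass
class PeakDiameterMap:
    """Fitted relationship between air fringe count and waist diameter.

    The sampled counts follow N(d) = a exp(-b d) + c; the inverse lookup
    interpolates the fitted curve monotonically, not the raw points.
    """

    d_grid_um: np.ndarray
    counts: np.ndarray
    coefficients: tuple[float, float, float]
    window_nm: tuple[float, float]
    rms_residual: float

    def predicted_counts(self, d_um: np.ndarray | float) -> np.ndarray | float:
        return _exp_model(np.asarray(d_um, dtype=float), *self.coefficients)

    def diameter_from_peak_count(
        self, n_air: float, extrapolation_um: float = 0.15
    ) -> float:
        """Invert the fitted exponential to a waist diameter (um).

        The fitted model is inverted analytically, so peak counts slightly
        beyond the sampled range remain usable (the device-selection range
        extends a little past the mapped diameters); extrapolation further
        than ``extrapolation_um`` beyond the grid raises.
        """
        a, b, c = self.coefficients
        if n_air <= c:
            raise ValueError(f"peak count {n_air} at or below the fitted floor {c:.2f}")
        d = float(-np.log((n_air - c) / a) / b)
        lo, hi = self.d_grid_um[0], self.d_grid_um[-1]
        if not (lo - extrapolation_um <= d <= hi + extrapolation_um):
            raise ValueError(
                f"peak count {n_air} maps to d={d:.3f} um, beyond the calibrated "
                f"{lo}-{hi} um range"
            )
        if not (lo <= d <= hi):
            warnings.warn(
                f"peak count {n_air} maps to d={d:.3f} um, extrapolating the "
                "fitted curve slightly beyond the sampled diameters",
                stacklevel=2,
            )
        return d


@dataclass
class DtpSurface:
    """DTP wavelength over (air peak count, SRI), with missing cells explicit."""

    n_peaks: np.ndarray
    sri: np.ndarray
    dtp_nm: np.ndarray  # shape (len(n_peaks), len(sri)); NaN = missing
    diameters_um: np.ndarray

    def query(self, n_air: float, sri: float) -> float | None:
        """Bilinear interpolation inside the grid; None at/through missing cells."""
        if not (self.n_peaks[0] <= n_air <= self.n_peaks[-1]):
            return None
        if not (self.sri[0] <= sri <= self.sri[-1]):
            return None
        i = int(np.clip(np.searchsorted(self.n_peaks, n_air) - 1, 0, len(self.n_peaks) - 2))
        j = int(np.clip(np.searchsorted(self.sri, sri) - 1, 0, len(self.sri) - 2))
        cell = self.dtp_nm[i : i + 2, j : j + 2]
        if not np.all(np.isfinite(cell)):
            return None
        tx = (n_air - self.n_peaks[i]) / (self.n_peaks[i + 1] - self.n_peaks[i])
        ty = (sri - self.sri[j]) / (self.sri[j + 1] - self.sri[j])
        top = cell[0, 0] * (1 - ty) + cell[0, 1] * ty
        bot = cell[1, 0] * (1 - ty) + cell[1, 1] * ty
        return float(top * (1 - tx) + bot * tx)


@dataclass
class DtpPrediction:
    dtp_nm: float
    diameter_um: float
    sri: float
    n_air: float | None = None


@dataclass
class SensitivityPrediction:
    s_nm_per_riu: float
    dtp_nm: float
    lam_op_nm: float
    distance_to_dtp_nm: float
    diameter_um: float
    diverging: bool


DispersionProvider = Callable[[CrossSection, np.ndarray], DispersionSet]


class CouplerModel:
    """End-to-end predictor tying geometry, dispersion and spectra together.

    Parameters mirror the fabricated device: waist/coupling length ``L``
    (12 mm), the geometry convention for the quoted waist diameter, and the
    air peak-counting window.  A ``dispersion_provider`` hook may replace
    the finite-difference engine (used for fast analytic tests and
    oracles); by default sweeps are solved with ``build_dispersion_set``
    and cached per (diameter, SRI, grid) so composite predictions reuse
    them.
    """

    def __init__(
        self,
        convention: str = "two-touching-circles",
        spacing_um: float = DEFAULT_SPACING_UM,
        coupling_length_mm: float = 12.0,
        air_window_nm: tuple[float, float] = DEFAULT_AIR_WINDOW_NM,
        prominence: float = DEFAULT_PROMINENCE,
        formulation: str = DEFAULT_FORMULATION,
        layer_thickness_nm: float = 0.0,
        layer_index: float = 1.45,
        dispersion_provider: DispersionProvider | None = None,
        n_air_samples: int = 9,
        dtp_fine_step_nm: float = 10.0,
        dtp_coarse_step_nm: float = 50.0,
    ) -> None:
        self.convention = convention
        self.spacing_um = spacing_um
        self.coupling_length_mm = coupling_length_mm
        self.air_window_nm = air_window_nm
        self.prominence = prominence
        self.formulation = normalize_formulation(formulation)
        self.layer_thickness_nm = layer_thickness_nm
        self.layer_index = layer_index
        self.n_air_samples = n_air_samples
        self.dtp_fine_step_nm = dtp_fine_step_nm
        self.dtp_coarse_step_nm = dtp_coarse_step_nm
        self._provider = dispersion_provider
        self._cache: dict[tuple, DispersionSet] = {}
        self._map: PeakDiameterMap | None = None

    # -- plumbing ---------------------------------------------------------

    def cross_section(self, d_um: float, sri: float) -> CrossSection:
        return build_cross_section(
            d=d_um,
            n_ext=sri,
            layer_thickness_nm=self.layer_thickness_nm,
            layer_index=self.layer_index,
            convention=self.convention,  # type: ignore[arg-type]
        )

    def dispersion(self, d_um: float, sri: float, lam_grid_um: np.ndarray) -> DispersionSet:
        key = (
            round(d_um, 6),
            round(sri, 8),
            round(float(lam_grid_um[0]), 6),
            round(float(lam_grid_um[-1]), 6),
            len(lam_grid_um),
        )
        if key not in self._cache:
            cs = self.cross_section(d_um, sri)
            if self._provider is not None:
                self._cache[key] = self._provider(cs, lam_grid_um)
            else:
                self._cache[key] = build_dispersion_set(
                    cs, lam_grid_um, spacing_um=self.spacing_um, allow_coarse_grid=True
                )
        return self._cache[key]

    def interferometer(self, window_nm: tuple[float, float] | None = None) -> InterferometerConfig:
        return InterferometerConfig(
            coupling_length_mm=self.coupling_length_mm,
            window_nm=window_nm or self.air_window_nm,
        )

    # -- air spectra ------------------------------------------------------

    def air_dispersion(self, d_um: float) -> DispersionSet:
        lo, hi = self.air_window_nm
        lam = np.linspace((lo - 25.0) * 1e-3, (hi + 25.0) * 1e-3, self.n_air_samples)
        return self.dispersion(d_um, 1.0, lam)

    def air_spectrum(self, d_um: float, n_points: int | None = None) -> TransmissionSpectrum:
        """Air beat interferogram -- the spectrometer-visible fringe family."""
        return simulate_beat_spectrum(
            self.air_dispersion(d_um), self.interferometer(), n_points=n_points
        )

    def air_peak_count(self, d_um: float) -> int:
        """Number of characteristic interference peaks in the air window."""
        return count_peaks(self.air_spectrum(d_um), prominence=self.prominence)

    # -- peak-count <-> diameter map --------------------------------------

    def build_peak_diameter_map(
        self, d_grid_um: Sequence[float] | None = None
    ) -> PeakDiameterMap:
        """Simulate air spectra over a diameter grid and fit N(d) = a e^{-bd} + c.

        A non-monotone count sequence triggers one retry with doubled
        spectral sampling before failing.
        """
        if d_grid_um is None:
            d_grid_um = np.linspace(2.0, 3.2, 13)
        d_grid = np.asarray(list(d_grid_um), dtype=float)
        if len(d_grid) < 8:
            raise ValueError("need at least 8 diameter samples")
        if np.any(d_grid < 2.0 - 1e-9) or np.any(d_grid > 3.2 + 1e-9):
            raise ValueError("diameter grid must stay within 2.0-3.2 um")

        def counts_for(n_points: int | None) -> np.ndarray:
            out = []
            for d in d_grid:
                spec = self.air_spectrum(d, n_points=n_points)
                out.append(count_peaks(spec, prominence=self.prominence))
            return np.asarray(out, dtype=float)

        counts = counts_for(None)
        if np.any(np.diff(counts) >= 0):
            counts = counts_for(30001)
            if np.any(np.diff(counts) >= 0):
                raise RuntimeError("peak counts not strictly decreasing with diameter")

        b0 = np.log(counts[0] / counts[-1]) / (d_grid[-1] - d_grid[0])
        p0 = (counts[0] * np.exp(b0 * d_grid[0]), b0, 0.0)
        popt, _ = curve_fit(_exp_model, d_grid, counts, p0=p0, maxfev=20000)
        resid = counts - _exp_model(d_grid, *popt)
        self._map = PeakDiameterMap(
            d_grid_um=d_grid,
            counts=counts,
            coefficients=tuple(popt),
            window_nm=self.air_window_nm,
            rms_residual=float(np.sqrt(np.mean(resid**2))),
        )
        return self._map

    @property
    def peak_diameter_map(self) -> PeakDiameterMap:
        if self._map is None:
            self.build_peak_diameter_map()
        return self._map

    # -- DTP --------------------------------------------------------------

    def dtp(
        self,
        d_um: float,
        sri: float,
        coarse_window_nm: tuple[float, float] | None = None,
    ) -> float:
        """DTP wavelength (nm) for a given diameter and surrounding index.

        Two-stage search: a coarse sweep brackets the sign change of the
        governing group difference, then a fine sweep at <= 10 nm step
        refines the crossing by monotone inverse interpolation.  The coarse
        window is centred on a rough scaling of the solved model (DTP
        red-shifts ~0.44 nm per nm of diameter, blue-shifts ~6 nm per 0.001
        SRI); if no crossing is bracketed there the full solvable window is
        scanned before giving up.
        """

        def coarse_locate(window: tuple[float, float]):
            lo, hi = window
            n_coarse = max(7, int(np.ceil((hi - lo) / self.dtp_coarse_step_nm)) + 1)
            lam_coarse = np.linspace(lo * 1e-3, hi * 1e-3, n_coarse)
            dset = self.dispersion(d_um, sri, lam_coarse)
            group = group_difference(dset, formulation=self.formulation)  # type: ignore[arg-type]
            return locate_dtp(group)

        wide = (700.0, 1580.0) if sri < 1.36 else (580.0, 1250.0)
        if coarse_window_nm is None:
            guess = 980.0 + 440.0 * (d_um - 2.0) - 6100.0 * (sri - 1.333)
            lo = float(np.clip(guess - 170.0, wide[0], wide[1] - 300.0))
            hi = float(np.clip(guess + 170.0, lo + 300.0, wide[1]))
            loc = coarse_locate((lo, hi))
            if loc is None:
                coarse_window_nm = wide
                loc = coarse_locate(wide)
        else:
            wide = coarse_window_nm
            loc = coarse_locate(coarse_window_nm)
        if loc is None:
            raise ValueError(
                f"no DTP inside {coarse_window_nm or wide} nm for d={d_um} um, SRI={sri}"
            )
        guess_nm = loc.primary_nm
        lo, hi = wide

        half = 60.0
        fine_lo = max(lo, guess_nm - half)
        fine_hi = min(hi, guess_nm + half)
        n_fine = int(np.ceil((fine_hi - fine_lo) / self.dtp_fine_step_nm)) + 1
        n_fine = max(n_fine, 7)
        lam_fine = np.linspace(fine_lo * 1e-3, fine_hi * 1e-3, n_fine)
        dset_f = self.dispersion(d_um, sri, lam_fine)
        group_f = group_difference(dset_f, formulation=self.formulation)  # type: ignore[arg-type]
        loc_f = locate_dtp(group_f)
        if loc_f is None:
            return guess_nm
        return loc_f.primary_nm

    def predict_dtp(self, n_air: float, sri: float) -> DtpPrediction:
        """Air peak count -> inferred diameter -> DTP at the given SRI."""
        if not (6 <= n_air <= 65):
            raise ValueError("air peak count must lie in the calibrated range 6-65")
        if not (1.30 <= sri <= 1.42):
            raise ValueError("SRI must lie within 1.30-1.42")
        d = self.peak_diameter_map.diameter_from_peak_count(n_air)
        return DtpPrediction(
            dtp_nm=self.dtp(d, sri), diameter_um=d, sri=sri, n_air=n_air
        )

    def build_dtp_surface(
        self,
        n_range: Sequence[float] | None = None,
        sri_range: Sequence[float] | None = None,
    ) -> DtpSurface:
        """Tabulate DTP over (air peak count, SRI); unsolvable cells are NaN."""
        n_peaks = np.asarray(n_range if n_range is not None else np.arange(6, 61, 6), float)
        sris = np.asarray(
            sri_range if sri_range is not None else np.linspace(1.333, 1.343, 6), float
        )
        pdm = self.peak_diameter_map
        diams = np.array([pdm.diameter_from_peak_count(n) for n in n_peaks])
        dtp = np.full((len(n_peaks), len(sris)), np.nan)
        for i, d in enumerate(diams):
            for j, s in enumerate(sris):
                try:
                    dtp[i, j] = self.dtp(d, s)
                except ValueError:
                    pass  # cell marked missing
        return DtpSurface(n_peaks=n_peaks, sri=sris, dtp_nm=dtp, diameters_um=diams)

    # -- sensitivity ------------------------------------------------------

    def sensitivity_from_peak_count(
        self, n_air: float, lam_op_nm: float, sri: float
    ) -> SensitivityPrediction:
        """Predicted dip sensitivity at an operating wavelength.

        Evaluates the evanescent sensitivity formula at ``lam_op_nm`` for
        the diameter inferred from the air fringe count, and reports the
        distance to the DTP.
        """
        d = self.peak_diameter_map.diameter_from_peak_count(n_air)
        dtp_nm = self.dtp(d, sri)
        lo = min(lam_op_nm, dtp_nm) - 60.0
        hi = max(lam_op_nm, dtp_nm) + 60.0
        n_pts = int(np.ceil((hi - lo) / self.dtp_fine_step_nm)) + 1
        lam = np.linspace(lo * 1e-3, hi * 1e-3, max(n_pts, 9))
        dset = self.dispersion(d, sri, lam)
        group = group_difference(dset, formulation=self.formulation)  # type: ignore[arg-type]
        if self._provider is None:
            curve = sensitivity(
                dset,
                group,
                lam_n_um=lam_op_nm * 1e-3,
                cross_section=self.cross_section(d, sri),
            )
        else:
            # custom providers compute their own SRI response by perturbation
            dn_hi = self._provider(self.cross_section(d, sri + 5e-4), lam)
            dn_lo = self._provider(self.cross_section(d, sri - 5e-4), lam)
            if self.formulation == "per-polarization":
                ddn = (dn_hi.delta_n("x") - dn_lo.delta_n("x")) / 1e-3
            else:
                ddn = (
                    (dn_hi.delta_n("x") - dn_hi.delta_n("y"))
                    - (dn_lo.delta_n("x") - dn_lo.delta_n("y"))
                ) / 1e-3
            curve = sensitivity(dset, group, lam_n_um=lam_op_nm * 1e-3, ddn_dn=ddn)
        assert curve.s_at_lam_n is not None
        return SensitivityPrediction(
            s_nm_per_riu=curve.s_at_lam_n,
            dtp_nm=dtp_nm,
            lam_op_nm=lam_op_nm,
            distance_to_dtp_nm=dtp_nm - lam_op_nm,
            diameter_um=d,
            diverging=curve.diverging_at_lam_n,
        )

    def recommend_peak_count(
        self,
        required_abs_sensitivity: float,
        lam_op_nm: float,
        sri: float,
        n_range: tuple[int, int] = (6, 65),
    ) -> int | None:
        """Smallest air peak count whose predicted |S| meets the requirement.

        |S| at a fixed operating wavelength grows with the fringe count
        (the DTP moves toward the window), so a bisection over the integer
        range suffices.  Returns None when even the largest count falls
        short.
        """
        if required_abs_sensitivity < 0:
            raise ValueError("sensitivity requirement must be >= 0")
        lo, hi = n_range
        if required_abs_sensitivity == 0:
            return lo
        # clamp to the invertible span of the fitted peak/diameter map
        pdm = self.peak_diameter_map
        lo = max(lo, int(np.ceil(pdm.predicted_counts(pdm.d_grid_um[-1] + 0.14))))
        hi = min(hi, int(np.floor(pdm.predicted_counts(pdm.d_grid_um[0] - 0.14))))
        if lo > hi:
            return None

        def ok(n: int) -> bool:
            pred = self.sensitivity_from_peak_count(n, lam_op_nm, sri)
            return pred.diverging or abs(pred.s_nm_per_riu) >= required_abs_sensitivity

        if not ok(hi):
            return None
        if ok(lo):
            return lo
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if ok(mid):
                hi = mid
            else:
                lo = mid
        return hi
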