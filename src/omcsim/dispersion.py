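"""Supermode dispersion curves, group birefringence and the DTP.

The interferometer phase in polarization p is set by the even/odd
effective-index difference  dn_p(lambda) = n_even^p - n_odd^p.  Fringe
motion under a change of the surrounding index n is governed by

    S_p(lambda) = lambda * (d dn_p / d n) / G_p(lambda),
    G_p = dn_p - lambda * d dn_p / d lambda,

where G_p is the even/odd *group*-index difference.  The dispersion turning
point (DTP) is the wavelength where G_p crosses zero: there the denominator
vanishes, the sensitivity diverges and flips sign.

Two formulations of the governing group quantity are provided:

* ``differential-birefringence`` (default): the group difference of
  dB(lambda) = B_even - B_odd = dn_x - dn_y, i.e. GB_even - GB_odd with
  B_i = n_i^x - n_i^y.  This is the slow beat phase of the birefringent
  coupler -- the fringe family a spectrometer resolves -- and it is the
  formulation that reproduces the device's observed fringe counts and
  turning points (see the methods note).
* ``per-polarization``: G_p built from the even/odd carrier difference of a
  single polarization, dn_p = n_even^p - n_odd^p.

Wavelength derivatives use a cubic spline through the sampled curves
(central differences are available as a cross-check); the SRI derivative is
a centred finite difference with configurable step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator
from scipy.optimize import brentq

from omcsim.geometry import CrossSection, rasterize
from omcsim.modesolver import MODE_CLASSES, solve_supermode

Formulation = Literal["differential-birefringence", "per-polarization"]

DEFAULT_FORMULATION: Formulation = "differential-birefringence"


def normalize_formulation(value: str) -> Formulation:
    """Accept common aliases for the two group-difference formulations."""
    aliases = {
        "differential-birefringence": "differential-birefringence",
        "beat": "differential-birefringence",
        "literal": "differential-birefringence",
        "per-polarization": "per-polarization",
        "per-pol": "per-polarization",
    }
    try:
        return aliases[value]  # type: ignore[return-value]
    except KeyError:
        raise ValueError(f"unknown formulation {value!r}") from None

#: Default grid spacing (um) for production dispersion solves.
DEFAULT_SPACING_UM = 0.02
#: Default SRI finite-difference step.
DEFAULT_SRI_STEP = 5e-4


def default_padding_um(n_ext: float) -> float:
    """Domain padding heuristic: strongly confined in air, loosely in liquid."""
    return 1.3 if n_ext < 1.1 else 2.6


@dataclass
class DispersionSet:
    """Sampled effective-index curves of the four supermodes.

    All curves share the strictly increasing ``lam_um`` grid.  Entries where
    a mode was lost (cutoff) are NaN and flagged in ``truncated``.
    """

    lam_um: np.ndarray
    n_even_x: np.ndarray
    n_odd_x: np.ndarray
    n_even_y: np.ndarray
    n_odd_y: np.ndarray
    provenance: dict = field(default_factory=dict)
    truncated: bool = False

    def delta_n(self, polarization: str = "x") -> np.ndarray:
        """Even/odd index difference dn_p of one polarization."""
        if polarization == "x":
            return self.n_even_x - self.n_odd_x
        return self.n_even_y - self.n_odd_y

    @property
    def b_even(self) -> np.ndarray:
        """Cross-polarization birefringence of the even supermode."""
        return self.n_even_x - self.n_even_y

    @property
    def b_odd(self) -> np.ndarray:
        return self.n_odd_x - self.n_odd_y


@dataclass
class GroupQuantities:
    """Group-index differences derived from one dispersion set."""

    lam_um: np.ndarray
    g_x: np.ndarray  # per-polarization even/odd group difference, x
    g_y: np.ndarray
    gb_even: np.ndarray  # group birefringence of B_even = n_even^x - n_even^y
    gb_odd: np.ndarray
    formulation: Formulation = DEFAULT_FORMULATION

    @property
    def delta_g(self) -> np.ndarray:
        """Governing group difference whose zero is the DTP."""
        if self.formulation == "per-polarization":
            return self.g_x
        return self.gb_even - self.gb_odd


@dataclass
class DtpLocation:
    """Zero crossings of the governing group difference."""

    primary_um: float
    all_um: tuple[float, ...]

    @property
    def primary_nm(self) -> float:
        return self.primary_um * 1e3


@dataclass
class SensitivityCurve:
    """Evanescent refractive-index sensitivity along the wavelength grid."""

    lam_um: np.ndarray
    s_nm_per_riu: np.ndarray
    ddn_dn: np.ndarray  # d(dn_p)/d n_ext along the grid
    dtp_um: float | None
    polarization: str = "x"
    lam_n_um: float | None = None  # tracked dip wavelength, if requested
    s_at_lam_n: float | None = None
    diverging_at_lam_n: bool = False


def build_dispersion_set(
    cross_section: CrossSection,
    lam_grid_um: np.ndarray,
    spacing_um: float = DEFAULT_SPACING_UM,
    padding_um: float | None = None,
    allow_coarse_grid: bool = False,
) -> DispersionSet:
    """Solve the four supermodes across a wavelength grid.

    The raster is built once and re-evaluated per wavelength (silica follows
    its Sellmeier curve, the surrounding medium is constant).  Solving each
    symmetry class separately makes the even/odd x x/y labelling exact at
    every wavelength, so no overlap tracking is required within a sweep.
    A wavelength where a supermode is no longer guided leaves NaN in that
    curve and sets ``truncated``.
    """
    lam = np.asarray(lam_grid_um, dtype=float)
    if lam.size == 0:
        raise ValueError("wavelength grid is empty")
    if lam.size > 1:
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not allow_coarse_grid and np.max(np.diff(lam)) > 0.0105:
            raise ValueError(
                "wavelength step exceeds 10 nm; pass allow_coarse_grid=True "
                "for exploratory scans"
            )
    if padding_um is None:
        padding_um = default_padding_um(cross_section.n_ext)

    pmap0 = rasterize(cross_section, spacing_um, padding_um, float(lam[0]))
    curves = {key: np.full(lam.size, np.nan) for key in MODE_CLASSES}
    truncated = False
    for i, lam_i in enumerate(lam):
        pmap = pmap0.at_wavelength(float(lam_i))
        for key in MODE_CLASSES:
            sols = solve_supermode(pmap, *key)
            if sols and sols[0].guided:
                curves[key][i] = sols[0].n_eff
            else:
                truncated = True
    if truncated:
        warnings.warn("mode cutoff inside the sweep window; curves truncated", stacklevel=2)

    return DispersionSet(
        lam_um=lam,
        n_even_x=curves[("even", "x")],
        n_odd_x=curves[("odd", "x")],
        n_even_y=curves[("even", "y")],
        n_odd_y=curves[("odd", "y")],
        provenance={
            "d_um": cross_section.d,
            "n_ext": cross_section.n_ext,
            "layer_thickness_nm": cross_section.layer_thickness_nm,
            "convention": cross_section.convention,
            "spacing_um": spacing_um,
            "padding_um": padding_um,
        },
        truncated=truncated,
    )


def _group_of(lam: np.ndarray, b: np.ndarray, method: str) -> np.ndarray:
    """G(lambda) = B - lambda dB/dlambda on the sample grid."""
    if method == "spline":
        spl = CubicSpline(lam, b)
        db = spl(lam, 1)
    elif method == "central":
        db = np.gradient(b, lam)
    else:
        raise ValueError(f"unknown derivative method {method!r}")
    return b - lam * db


def group_difference(
    dset: DispersionSet,
    formulation: Formulation = DEFAULT_FORMULATION,
    method: str = "spline",
) -> GroupQuantities:
    """Group-index differences of a dispersion set.

    Requires at least 5 wavelength samples for a stable spline derivative.
    """
    formulation = normalize_formulation(formulation)
    lam = dset.lam_um
    if lam.size < 5:
        raise ValueError("need at least 5 wavelength samples for derivatives")
    if np.any(~np.isfinite(dset.n_even_x + dset.n_odd_x + dset.n_even_y + dset.n_odd_y)):
        raise ValueError("dispersion set contains truncated (NaN) samples")
    return GroupQuantities(
        lam_um=lam,
        g_x=_group_of(lam, dset.delta_n("x"), method),
        g_y=_group_of(lam, dset.delta_n("y"), method),
        gb_even=_group_of(lam, dset.b_even, method),
        gb_odd=_group_of(lam, dset.b_odd, method),
        formulation=formulation,
    )


def locate_dtp(group: GroupQuantities) -> DtpLocation | None:
    """Zero crossings of the governing group difference.

    Each bracketing interval is refined with monotone (PCHIP) inverse
    interpolation; the first crossing is primary.  Returns None when the
    group difference does not change sign inside the window.
    """
    lam = group.lam_um
    dg = group.delta_g
    if lam.size < 5:
        raise ValueError("need at least 5 samples to locate the DTP")
    interp = PchipInterpolator(lam, dg)
    roots: list[float] = []
    sign = np.sign(dg)
    for i in range(lam.size - 1):
        if sign[i] == 0:
            roots.append(float(lam[i]))
        elif sign[i] * sign[i + 1] < 0:
            roots.append(float(brentq(interp, lam[i], lam[i + 1], xtol=1e-6)))
    if sign[-1] == 0:
        roots.append(float(lam[-1]))
    if not roots:
        return None
    return DtpLocation(primary_um=roots[0], all_um=tuple(roots))


def d_delta_n_d_sri(
    cross_section: CrossSection,
    lam_um: float | np.ndarray,
    delta_n: float = DEFAULT_SRI_STEP,
    spacing_um: float = DEFAULT_SPACING_UM,
    padding_um: float | None = None,
) -> dict[str, np.ndarray]:
    """Centred derivative of dn_p with respect to the surrounding index.

    Solves the four supermodes at SRI +/- ``delta_n`` with fixed geometry and
    raster.  Returns ``{"x": ..., "y": ...}`` arrays over ``lam_um``.
    """
    if delta_n <= 0:
        raise ValueError("SRI perturbation step must be positive")
    lam = np.atleast_1d(np.asarray(lam_um, dtype=float))
    if padding_um is None:
        padding_um = default_padding_um(cross_section.n_ext)
    out = {}
    for sign_label, sri in (
        ("hi", cross_section.n_ext + delta_n),
        ("lo", cross_section.n_ext - delta_n),
    ):
        cs = cross_section.with_sri(sri)
        pmap0 = rasterize(cs, spacing_um, padding_um, float(lam[0]))
        dn_x = np.empty(lam.size)
        dn_y = np.empty(lam.size)
        for i, lam_i in enumerate(lam):
            pmap = pmap0.at_wavelength(float(lam_i))
            sols = {key: solve_supermode(pmap, *key) for key in MODE_CLASSES}
            if any(not s or not s[0].guided for s in sols.values()):
                raise RuntimeError(f"mode lost at perturbed SRI {sri}")
            dn_x[i] = sols[("even", "x")][0].n_eff - sols[("odd", "x")][0].n_eff
            dn_y[i] = sols[("even", "y")][0].n_eff - sols[("odd", "y")][0].n_eff
        out[sign_label] = (dn_x, dn_y)
    ddx = (out["hi"][0] - out["lo"][0]) / (2 * delta_n)
    ddy = (out["hi"][1] - out["lo"][1]) / (2 * delta_n)
    return {"x": ddx, "y": ddy}


def sensitivity(
    dset: DispersionSet,
    group: GroupQuantities,
    lam_n_um: float | None = None,
    cross_section: CrossSection | None = None,
    polarization: str = "x",
    n_sri_samples: int = 3,
    sri_step: float = DEFAULT_SRI_STEP,
    ddn_dn: np.ndarray | None = None,
) -> SensitivityCurve:
    """Evaluate the dip sensitivity S = lambda * (d dn/dn) / G along the sweep.

    The SRI derivative is computed at ``n_sri_samples`` wavelengths spanning
    the window and interpolated (it varies slowly compared with G); pass a
    precomputed ``ddn_dn`` array over the full grid to skip those solves.
    Near the DTP the denominator vanishes: such points carry the sign of the
    divergence and ``diverging_at_lam_n`` is set when the requested dip sits
    within one grid step of the pole.
    """
    lam = group.lam_um
    if lam_n_um is not None and not (lam[0] <= lam_n_um <= lam[-1]):
        raise ValueError(f"lam_N={lam_n_um} um outside the sampled window")
    if group.formulation == "per-polarization":
        g = group.g_x if polarization == "x" else group.g_y
    else:
        g = group.delta_g
    if ddn_dn is None:
        if cross_section is None:
            raise ValueError("cross_section required to compute the SRI derivative")
        sample_lams = np.linspace(lam[0], lam[-1], max(2, n_sri_samples))
        dd_all = d_delta_n_d_sri(
            cross_section,
            sample_lams,
            delta_n=sri_step,
            spacing_um=dset.provenance.get("spacing_um", DEFAULT_SPACING_UM),
            padding_um=dset.provenance.get("padding_um"),
        )
        if group.formulation == "per-polarization":
            dd = dd_all[polarization]
        else:
            # governing index difference is dB = dn_x - dn_y
            dd = dd_all["x"] - dd_all["y"]
        ddn_dn = np.interp(lam, sample_lams, dd)

    lam_nm = lam * 1e3
    with np.errstate(divide="ignore"):
        s = lam_nm * ddn_dn / g
    dtp = locate_dtp(group)

    lam_n = lam_n_um
    s_at = None
    diverging = False
    if lam_n is not None:
        g_at = float(PchipInterpolator(lam, g)(lam_n))
        dd_at = float(np.interp(lam_n, lam, ddn_dn))
        step = float(np.median(np.diff(lam)))
        if dtp is not None and abs(lam_n - dtp.primary_um) < step:
            diverging = True
        if g_at == 0.0:
            s_at = np.inf
            diverging = True
        else:
            s_at = float(lam_n * 1e3 * dd_at / g_at)
    return SensitivityCurve(
        lam_um=lam,
        s_nm_per_riu=s,
        ddn_dn=np.asarray(ddn_dn),
        dtp_um=None if dtp is None else dtp.primary_um,
        polarization=polarization,
        lam_n_um=lam_n,
        s_at_lam_n=s_at,
        diverging_at_lam_n=diverging,
    )
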