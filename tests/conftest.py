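"""Shared fixtures.

Real finite-difference sweeps are expensive, so they are solved once per
session at a mildly reduced resolution (25 nm grid; the production default
is 20 nm) and shared.  For predictor- and analysis-layer tests a fast
analytic stand-in dispersion model with the same qualitative physics
(exponentially diameter-dependent beat strength, a group-difference zero
that red-shifts with diameter and blue-shifts with SRI, diverging
sensitivity at the turning point) is provided through the
``dispersion_provider`` hook.
"""

from __future__ import annotations

import numpy as np
import pytest

from omcsim.dispersion import DispersionSet, build_dispersion_set
from omcsim.geometry import CrossSection

TEST_SPACING_UM = 0.025

# --- analytic stand-in dispersion model (synthetic, not solved) -----------
#
# Beat birefringence  dB(lambda) = k (lambda - lt)^2 / lambda + m0 (n - n0) lambda
# with turning point lt(d, n) and strength k(d).  The linear-in-lambda term
# contributes nothing to the group difference (G(c*lambda) = 0), so the DTP
# sits exactly at lt while the SRI response stays finite there -- giving the
# textbook diverging, sign-flipping sensitivity.

TOY = {
    "lt0_um": 1.00,
    "dlt_dd": 0.44,  # um of DTP shift per um of diameter
    "dlt_dn": -2.0,  # um of DTP shift per RIU
    "k_liquid": 0.010,
    "k_air0": 0.0020,
    "gamma_air": 1.83,
    "lt_air0": 1.49,
    "dlt_air_dd": 0.30,
    "m0": 0.10,  # d(dB)/dn scale per RIU, times lambda (dominant term)
    "carrier": 0.020,  # even/odd splitting common to both polarizations
    "n_base": 1.40,
}


def toy_turning_point_um(d_um: float, n_ext: float) -> float:
    if n_ext < 1.1:
        return TOY["lt_air0"] + TOY["dlt_air_dd"] * (d_um - 2.0)
    return (
        TOY["lt0_um"]
        + TOY["dlt_dd"] * (d_um - 2.0)
        + TOY["dlt_dn"] * (n_ext - 1.333)
    )


def toy_beat(lam_um: np.ndarray, d_um: float, n_ext: float) -> np.ndarray:
    lt = toy_turning_point_um(d_um, n_ext)
    if n_ext < 1.1:
        k = TOY["k_air0"] * np.exp(-TOY["gamma_air"] * (d_um - 2.0))
        m = 0.0
    else:
        k = TOY["k_liquid"] * np.exp(-0.5 * (d_um - 2.0))
        m = TOY["m0"] * (n_ext - 1.333)
    return k * (lam_um - lt) ** 2 / lam_um + m * lam_um


def toy_provider(cs: CrossSection, lam_um: np.ndarray) -> DispersionSet:
    """Analytic dispersion sets for CouplerModel's provider hook."""
    lam = np.asarray(lam_um, dtype=float)
    db = toy_beat(lam, cs.d, cs.n_ext)
    n_odd = TOY["n_base"] - 0.01 * lam
    carrier = TOY["carrier"] + 0.002 * lam
    return DispersionSet(
        lam_um=lam,
        n_even_x=n_odd + carrier + db,
        n_odd_x=n_odd,
        n_even_y=n_odd + carrier,
        n_odd_y=n_odd,
        provenance={"model": "analytic-toy", "d_um": cs.d, "n_ext": cs.n_ext},
    )


def toy_sensitivity_nm_per_riu(lam_um: float, d_um: float, n_ext: float) -> float:
    """Closed-form dip sensitivity of the toy model (independent route)."""
    lt = toy_turning_point_um(d_um, n_ext)
    k = TOY["k_liquid"] * np.exp(-0.5 * (d_um - 2.0))
    ddn = -2 * k * (lam_um - lt) * TOY["dlt_dn"] / lam_um + TOY["m0"] * lam_um
    g = -2 * k * lt * (lam_um - lt) / lam_um
    return float(lam_um * 1e3 * ddn / g)


# --- session-scoped solved sweeps -----------------------------------------


@pytest.fixture(scope="session")
def solved_sweeps() -> dict[tuple[float, float], DispersionSet]:
    """Supermode dispersion around the turning points for three conditions."""
    lam = np.linspace(1.10, 1.30, 9)
    out = {}
    for d, sri in [(2.6, 1.333), (2.4, 1.333), (2.6, 1.335)]:
        cs = CrossSection(d=d, n_ext=sri)
        out[(d, sri)] = build_dispersion_set(
            cs, lam, spacing_um=TEST_SPACING_UM, allow_coarse_grid=True
        )
    return out


@pytest.fixture(scope="session")
def pair_modes_1um():
    """The four supermodes of the d=2.6 um coupler in water at 1 um."""
    from omcsim.geometry import rasterize
    from omcsim.modesolver import solve_modes

    cs = CrossSection(d=2.6, n_ext=1.333)
    pmap = rasterize(cs, TEST_SPACING_UM, 2.6, 1.0)
    return solve_modes(pmap)
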