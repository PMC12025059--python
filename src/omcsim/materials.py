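"""Material dispersion models.

Silica is described by the three-term Sellmeier equation

    n^2(lambda) = 1 + sum_i B_i lambda^2 / (lambda^2 - C_i),

with ``lambda`` in micrometres.  Surrounding media (air, water, glycerol
solutions) are treated as dispersionless constant-index materials: the
sensing experiments quote a single refractive-index value per solution, and
over the sub-micron working window the solvent dispersion is far below the
index steps being sensed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Supported evaluation window (um).  The Sellmeier fit and the mode solver
#: are only exercised inside this range.
WAVELENGTH_WINDOW_UM = (0.4, 1.6)


@dataclass(frozen=True)
class Material:
    """Dispersion model for one material.

    Exactly one of (``sellmeier_b``/``sellmeier_c``, ``constant_n``) is
    active.  Sellmeier coefficients follow the usual convention:
    ``sellmeier_b`` are the dimensionless oscillator strengths and
    ``sellmeier_c`` the squared resonance wavelengths in um^2.
    """

    name: str
    sellmeier_b: tuple[float, ...] | None = None
    sellmeier_c: tuple[float, ...] | None = None
    constant_n: float | None = None

    def __post_init__(self) -> None:
        has_sellmeier = self.sellmeier_b is not None or self.sellmeier_c is not None
        if has_sellmeier and self.constant_n is not None:
            raise ValueError("specify either Sellmeier coefficients or constant_n, not both")
        if has_sellmeier:
            if self.sellmeier_b is None or self.sellmeier_c is None:
                raise ValueError("both sellmeier_b and sellmeier_c are required")
            if len(self.sellmeier_b) != len(self.sellmeier_c):
                raise ValueError("sellmeier_b and sellmeier_c must have equal length")
        elif self.constant_n is None:
            raise ValueError("material needs Sellmeier coefficients or a constant index")
        elif self.constant_n < 1.0:
            raise ValueError(f"constant index must be >= 1, got {self.constant_n}")

    def index(self, wavelength_um: float | np.ndarray) -> float | np.ndarray:
        """Refractive index at ``wavelength_um`` (um)."""
        return material_index(self, wavelength_um)


def material_index(material: Material, wavelength_um: float | np.ndarray):
    """Evaluate the refractive index of ``material`` at ``wavelength_um``.

    Raises ``ValueError`` outside the supported 0.4-1.6 um window or at a
    Sellmeier resonance pole.
    """
    lam = np.asarray(wavelength_um, dtype=float)
    lo, hi = WAVELENGTH_WINDOW_UM
    if np.any(lam < lo) or np.any(lam > hi):
        raise ValueError(
            f"wavelength {wavelength_um} um outside supported window {lo}-{hi} um"
        )
    if material.constant_n is not None:
        out = np.full_like(lam, material.constant_n, dtype=float)
        return float(out) if np.isscalar(wavelength_um) else out

    lam2 = lam**2
    n2 = np.ones_like(lam2)
    for b, c in zip(material.sellmeier_b, material.sellmeier_c):
        denom = lam2 - c
        if np.any(np.abs(denom) < 1e-12):
            raise ValueError(f"wavelength {wavelength_um} um sits on a Sellmeier pole")
        n2 = n2 + b * lam2 / denom
    if np.any(n2 <= 1.0):
        raise ValueError("Sellmeier evaluation gave non-physical index <= 1")
    n = np.sqrt(n2)
    return float(n) if np.isscalar(wavelength_um) else n


#: Fused silica, three-term Sellmeier fit (Malitson's room-temperature
#: coefficients, the standard choice for SiO2 fiber modelling).
FUSED_SILICA = Material(
    name="fused-silica",
    sellmeier_b=(0.6961663, 0.4079426, 0.8974794),
    sellmeier_c=(0.0684043**2, 0.1162414**2, 9.896161**2),
)


def constant_medium(n: float, name: str | None = None) -> Material:
    """Dispersionless medium of index ``n`` (air, water, glycerol ...)."""
    return Material(name=name or f"medium-n{n:g}", constant_n=float(n))


AIR = constant_medium(1.0, "air")
WATER = constant_medium(1.333, "water")
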