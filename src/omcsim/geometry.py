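"""Cross-section geometry of the fused coupler waist and its rasterization.

The waist of a fused optical microfiber coupler is modelled as two identical
silica circles tangent at the origin, their centres on the x axis.  Under the
default ``two-touching-circles`` convention the quoted waist diameter ``d``
is the *composite* width of the fused pair, i.e. each circle has radius
``d/4``.  A ``single-circle`` convention (one circle of diameter ``d``) is
retained as an option.  Each core may be wrapped by a conformal annulus
representing the silane/antibody biofunctional layer, and the exterior is a
uniform surrounding medium of index ``n_ext`` (the SRI).

Rasterization assigns every grid cell the area-weighted average of the
material permittivities overlapping it, which keeps the total silica area
second-order accurate in the grid spacing.  The cross-section has mirror
symmetry about both axes; grid nodes are placed at half-integer offsets so
that both mirror planes fall exactly between columns/rows of nodes, which
the mode solver exploits for its quarter-domain symmetry reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from omcsim.materials import FUSED_SILICA, Material, material_index

GeometryConvention = Literal["two-touching-circles", "single-circle"]


@dataclass(frozen=True)
class CrossSection:
    """Waist cross-section: geometry plus the materials filling it.

    Parameters
    ----------
    d:
        Waist diameter in um.  Composite width of the fused pair under the
        default convention.
    core_material:
        Core glass (fused silica unless testing).
    n_ext:
        Surrounding refractive index (SRI), dimensionless.
    layer_thickness_nm:
        Conformal biofunctional-layer thickness in nm (0 disables the layer).
    layer_index:
        Refractive index of the functional layer.
    convention:
        ``two-touching-circles`` (default) or ``single-circle``.
    """

    d: float
    core_material: Material = FUSED_SILICA
    n_ext: float = 1.333
    layer_thickness_nm: float = 0.0
    layer_index: float = 1.45
    convention: GeometryConvention = "two-touching-circles"

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError(f"waist diameter must be positive, got {self.d}")
        if self.layer_thickness_nm < 0:
            raise ValueError("layer thickness must be >= 0")
        if self.n_ext < 1.0:
            raise ValueError("surrounding index must be >= 1")

    @property
    def circle_radius(self) -> float:
        """Radius of each silica circle (um)."""
        if self.convention == "two-touching-circles":
            return self.d / 4.0
        return self.d / 2.0

    @property
    def circle_centers(self) -> tuple[tuple[float, float], ...]:
        """Centres of the silica circles (um), on the x axis."""
        if self.convention == "two-touching-circles":
            r = self.circle_radius
            return ((-r, 0.0), (r, 0.0))
        return ((0.0, 0.0),)

    @property
    def layer_outer_radius(self) -> float:
        return self.circle_radius + self.layer_thickness_nm * 1e-3

    def n_core(self, wavelength_um: float) -> float:
        return float(material_index(self.core_material, wavelength_um))

    def with_sri(self, n_ext: float) -> "CrossSection":
        return replace(self, n_ext=n_ext)


def build_cross_section(
    d: float,
    n_ext: float = 1.333,
    layer_thickness_nm: float = 0.0,
    layer_index: float = 1.45,
    convention: GeometryConvention = "two-touching-circles",
    core_material: Material = FUSED_SILICA,
) -> CrossSection:
    """Validated constructor for the fused-waist cross-section.

    ``d`` is accepted in the fabrication-validated 1.5-4 um range (values
    outside raise); a functional layer with ``layer_index < n_ext`` cannot
    guide and is flagged with a warning, not an error.
    """
    if d <= 0:
        raise ValueError(f"waist diameter must be positive, got {d}")
    if not (1.5 <= d <= 4.0):
        raise ValueError(f"waist diameter {d} um outside the validated 1.5-4 um range")
    if not (0.0 <= layer_thickness_nm <= 50.0):
        raise ValueError("layer thickness must be within 0-50 nm")
    if layer_thickness_nm > 0 and layer_index < n_ext:
        warnings.warn(
            f"functional layer index {layer_index} below surrounding index {n_ext}: "
            "layer does not guide",
            stacklevel=2,
        )
    return CrossSection(
        d=d,
        core_material=core_material,
        n_ext=n_ext,
        layer_thickness_nm=layer_thickness_nm,
        layer_index=layer_index,
        convention=convention,
    )


def _circle_coverage(
    xg: np.ndarray, yg: np.ndarray, hx: float, hy: float, cx: float, cy: float, r: float
) -> np.ndarray:
    """Fraction of each grid cell covered by the disk of radius ``r`` at (cx, cy).

    Uses a signed-distance linear-coverage model: for a cell whose centre
    lies a signed distance ``s`` outside the circle edge, the covered
    fraction ramps linearly over the cell extent projected onto the local
    edge normal.  Because the model is antisymmetric about the edge the
    along-edge errors cancel; total area converges at second order in the
    spacing (exactly like sub-cell area averaging for straight edges).
    """
    dx = xg - cx
    dy = yg - cy
    rho = np.hypot(dx, dy)
    s = rho - r  # signed distance outside the edge
    with np.errstate(invalid="ignore", divide="ignore"):
        nx = np.where(rho > 0, np.abs(dx) / np.where(rho > 0, rho, 1.0), 1.0)
        ny = np.where(rho > 0, np.abs(dy) / np.where(rho > 0, rho, 1.0), 0.0)
    w = hx * nx + hy * ny  # cell width projected onto the edge normal
    frac = np.clip(0.5 - s / w, 0.0, 1.0)
    return frac


@dataclass
class PermittivityMap:
    """Relative-permittivity raster of one cross-section.

    ``x``/``y`` hold the node coordinates (um), ``eps`` the per-cell relative
    permittivity at the evaluation wavelength.  ``frac_core``/``frac_layer``
    are the wavelength-independent material fill fractions, kept so that a
    wavelength sweep re-evaluates the map without re-rasterizing.
    Mirror symmetry about both axes is recorded in ``symmetric_x`` /
    ``symmetric_y``; node placement guarantees the mirror planes x=0 and y=0
    bisect the grid.
    """

    x: np.ndarray
    y: np.ndarray
    eps: np.ndarray  # shape (len(y), len(x))
    frac_core: np.ndarray
    frac_layer: np.ndarray
    cross_section: CrossSection
    wavelength_um: float
    symmetric_x: bool = True
    symmetric_y: bool = True

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])

    @property
    def n_core(self) -> float:
        return self.cross_section.n_core(self.wavelength_um)

    @property
    def n_ext(self) -> float:
        return self.cross_section.n_ext

    def core_area(self) -> float:
        """Pixel-summed silica area (um^2)."""
        return float(self.frac_core.sum() * self.dx * self.dy)

    def analytic_core_area(self) -> float:
        cs = self.cross_section
        return len(cs.circle_centers) * np.pi * cs.circle_radius**2

    def at_wavelength(self, wavelength_um: float) -> "PermittivityMap":
        """Same raster re-evaluated at another wavelength (cheap)."""
        eps = _fractions_to_eps(
            self.frac_core, self.frac_layer, self.cross_section, wavelength_um
        )
        return PermittivityMap(
            x=self.x,
            y=self.y,
            eps=eps,
            frac_core=self.frac_core,
            frac_layer=self.frac_layer,
            cross_section=self.cross_section,
            wavelength_um=wavelength_um,
            symmetric_x=self.symmetric_x,
            symmetric_y=self.symmetric_y,
        )

    def quarter(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(x>0, y>0) quadrant of the raster: (x, y, eps) views."""
        nx2 = len(self.x) // 2
        ny2 = len(self.y) // 2
        return self.x[nx2:], self.y[ny2:], self.eps[ny2:, nx2:]


def _fractions_to_eps(
    frac_core: np.ndarray,
    frac_layer: np.ndarray,
    cs: CrossSection,
    wavelength_um: float,
) -> np.ndarray:
    n_core = cs.n_core(wavelength_um)
    frac_ext = 1.0 - frac_core - frac_layer
    return (
        frac_core * n_core**2
        + frac_layer * cs.layer_index**2
        + frac_ext * cs.n_ext**2
    )


def rasterize(
    cross_section: CrossSection,
    spacing_um: float,
    padding_um: float,
    wavelength_um: float = 1.0,
) -> PermittivityMap:
    """Rasterize a cross-section to a permittivity map.

    ``spacing_um`` is the uniform grid step; the map extends ``padding_um``
    of exterior medium beyond the outermost layer surface on every side.
    Nodes sit at half-integer multiples of the spacing so both mirror planes
    of the geometry bisect the grid.
    """
    cs = cross_section
    if spacing_um <= 0:
        raise ValueError("spacing must be positive")
    if cs.d / spacing_um < 40:
        raise ValueError(
            f"resolution too coarse: d/spacing = {cs.d / spacing_um:.1f} < 40"
        )
    if padding_um < 1.0:
        raise ValueError("padding must be >= 1 um of exterior medium")

    r_out = cs.layer_outer_radius
    if cs.convention == "two-touching-circles":
        half_x = cs.d / 2.0 + (r_out - cs.circle_radius) + padding_um
    else:
        half_x = r_out + padding_um
    half_y = r_out + padding_um

    h = spacing_um
    nx = 2 * int(np.ceil(half_x / h))
    ny = 2 * int(np.ceil(half_y / h))
    x = (np.arange(nx) - nx / 2 + 0.5) * h
    y = (np.arange(ny) - ny / 2 + 0.5) * h
    xg, yg = np.meshgrid(x, y)

    frac_core = np.zeros((ny, nx))
    frac_outer = np.zeros((ny, nx))
    for cx, cy in cs.circle_centers:
        frac_core += _circle_coverage(xg, yg, h, h, cx, cy, cs.circle_radius)
        if cs.layer_thickness_nm > 0:
            frac_outer += _circle_coverage(xg, yg, h, h, cx, cy, r_out)
    np.clip(frac_core, 0.0, 1.0, out=frac_core)
    if cs.layer_thickness_nm > 0:
        np.clip(frac_outer, 0.0, 1.0, out=frac_outer)
        frac_layer = np.clip(frac_outer - frac_core, 0.0, None)
        np.clip(frac_layer, 0.0, 1.0 - frac_core, out=frac_layer)
    else:
        frac_layer = np.zeros_like(frac_core)

    eps = _fractions_to_eps(frac_core, frac_layer, cs, wavelength_um)
    return PermittivityMap(
        x=x,
        y=y,
        eps=eps,
        frac_core=frac_core,
        frac_layer=frac_layer,
        cross_section=cs,
        wavelength_um=wavelength_um,
    )
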