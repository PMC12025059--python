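"""Full-vector finite-difference eigenmode solver for the coupler waist.

The transverse electric field (Ex, Ey) of a translation-invariant waveguide
satisfies the coupled vector Helmholtz eigenproblem

    [ Pxx  Pxy ] [Ex]          [Ex]
    [ Pyx  Pyy ] [Ey] = beta^2 [Ey]

with, writing eps for the relative permittivity and k0 = 2 pi / lambda,

    Pxx Ex = d/dx[ (1/eps) d(eps Ex)/dx ] + d2Ex/dy2 + k0^2 eps Ex
    Pyy Ey = d/dy[ (1/eps) d(eps Ey)/dy ] + d2Ey/dx2 + k0^2 eps Ey
    Pxy Ey = d/dx[ (1/eps) d(eps Ey)/dy ] - d2Ey/dxdy      (and Pyx likewise).

The operators are discretized on a uniform grid with area-averaged
permittivity; the polarization-dependent interface terms in Pxx/Pyy and the
cross blocks give the full-vector birefringence.

Symmetry reduction.  The fused-coupler cross-section has mirror planes x=0
(between the two cores) and y=0 (through both core centres).  Every guided
supermode is a symmetry eigenstate, and the four tracked supermodes occupy
the four distinct symmetry classes:

    parity  polarization   Ex parity (x, y)   Ey parity (x, y)
    even    x              (+, +)             (-, -)
    odd     x              (-, +)             (+, -)
    even    y              (-, -)             (+, +)
    odd     y              (+, -)             (-, +)

("even/odd" = dominant component symmetric/antisymmetric about the
inter-core plane x=0.)  Solving one quadrant with the matching
symmetric/antisymmetric boundary conditions both quarters the problem size
and *forces* the parity/polarization of the computed mode, making the
labels deterministic.  The outer boundary is a perfect electric wall
(E = 0); adequate padding is checked through the boundary-leak metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from omcsim.geometry import CrossSection, PermittivityMap, rasterize

Parity = Literal["even", "odd"]
Polarization = Literal["x", "y"]

#: (parity, polarization) -> parity signs (sx, sy) of the Ex component under
#: the x=0 and y=0 mirrors.  Ey carries the opposite signs on both axes.
MODE_CLASSES: dict[tuple[Parity, Polarization], tuple[int, int]] = {
    ("even", "x"): (+1, +1),
    ("odd", "x"): (-1, +1),
    ("even", "y"): (-1, -1),
    ("odd", "y"): (+1, -1),
}

#: Relative edge amplitude above which a solution is rejected as leaking
#: into the zero-field boundary.
BOUNDARY_LEAK_LIMIT = 1e-3


@dataclass
class ModeSolution:
    """One guided supermode at one wavelength.

    Field arrays live on the (x>0, y>0) quarter grid; ``full_fields``
    reconstructs the whole cross-section from the recorded parities.
    """

    wavelength_um: float
    n_eff: float
    ex: np.ndarray
    ey: np.ndarray
    parity: Parity
    polarization: Polarization
    residual: float
    x: np.ndarray
    y: np.ndarray
    n_core: float
    n_ext: float

    @property
    def guided(self) -> bool:
        return self.n_ext < self.n_eff < self.n_core

    @property
    def boundary_leak(self) -> float:
        """Max field amplitude on the outer (Dirichlet) edges, relative to peak."""
        peak = max(np.abs(self.ex).max(), np.abs(self.ey).max())
        edge = max(
            np.abs(self.ex[-1, :]).max(),
            np.abs(self.ex[:, -1]).max(),
            np.abs(self.ey[-1, :]).max(),
            np.abs(self.ey[:, -1]).max(),
        )
        return float(edge / peak)

    @property
    def energy_fraction_x(self) -> float:
        """Share of transverse field energy carried by the Ex component."""
        px = float(np.sum(self.ex**2))
        py = float(np.sum(self.ey**2))
        return px / (px + py)

    def full_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(x, y, Ex, Ey) over the full cross-section, mirrored from the quadrant."""
        sx, sy = MODE_CLASSES[(self.parity, self.polarization)]
        x_full = np.concatenate([-self.x[::-1], self.x])
        y_full = np.concatenate([-self.y[::-1], self.y])

        def mirror(f: np.ndarray, px: int, py: int) -> np.ndarray:
            top = np.concatenate([px * f[:, ::-1], f], axis=1)
            return np.concatenate([py * top[::-1, :], top], axis=0)

        return (
            x_full,
            y_full,
            mirror(self.ex, sx, sy),
            mirror(self.ey, -sx, -sy),
        )


def _stencil_matrix(
    coeffs: dict[tuple[int, int], np.ndarray], px: int, py: int
) -> sp.csr_matrix:
    """Assemble a <=9-point stencil into a sparse matrix on the quarter grid.

    ``coeffs[(di, dj)]`` multiplies the field at (ix+di, iy+dj) in the
    equation at (ix, iy).  Neighbours beyond the mirror planes (index -1)
    fold back onto index 0 weighted by the field parity ``px``/``py``;
    neighbours beyond the outer boundary are dropped (E = 0 wall).
    """
    sample = next(iter(coeffs.values()))
    ny, nx = sample.shape
    ix, iy = np.meshgrid(np.arange(nx), np.arange(ny))
    row = (iy * nx + ix).ravel()
    rows, cols, vals = [], [], []
    for (di, dj), c in coeffs.items():
        ti = ix + di
        tj = iy + dj
        fac = np.ones_like(c)
        if di < 0:
            ghost = ti < 0
            fac = np.where(ghost, px * fac, fac)
            ti = np.where(ghost, 0, ti)
        if dj < 0:
            ghost = tj < 0
            fac = np.where(ghost, py * fac, fac)
            tj = np.where(ghost, 0, tj)
        keep = ((ti < nx) & (tj < ny)).ravel()
        rows.append(row[keep])
        cols.append((tj * nx + ti).ravel()[keep])
        vals.append((c * fac).ravel()[keep])
    n = nx * ny
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


def _vector_operator(
    eps: np.ndarray, hx: float, hy: float, k0: float, sx: int, sy: int
) -> sp.csc_matrix:
    """Full-vector operator for one symmetry class on the quarter grid.

    ``sx, sy`` are the mirror parities of Ex; Ey carries the opposite ones.
    """
    epad = np.pad(eps, 1, mode="edge")
    ny, nx = eps.shape

    def sh(di: int, dj: int) -> np.ndarray:
        return epad[1 + dj : 1 + dj + ny, 1 + di : 1 + di + nx]

    e = eps
    e_e, e_w = sh(1, 0), sh(-1, 0)
    e_n, e_s = sh(0, 1), sh(0, -1)
    ehe, ehw = 0.5 * (e + e_e), 0.5 * (e + e_w)
    ehn, ehs = 0.5 * (e + e_n), 0.5 * (e + e_s)
    ones = np.ones_like(e)

    pxx = {
        (1, 0): e_e / (hx**2 * ehe),
        (-1, 0): e_w / (hx**2 * ehw),
        (0, 1): ones / hy**2,
        (0, -1): ones / hy**2,
        (0, 0): -e * (1.0 / ehe + 1.0 / ehw) / hx**2 - 2.0 / hy**2 + k0**2 * e,
    }
    pyy = {
        (0, 1): e_n / (hy**2 * ehn),
        (0, -1): e_s / (hy**2 * ehs),
        (1, 0): ones / hx**2,
        (-1, 0): ones / hx**2,
        (0, 0): -e * (1.0 / ehn + 1.0 / ehs) / hy**2 - 2.0 / hx**2 + k0**2 * e,
    }
    # Cross blocks vanish in homogeneous regions (eps ratios -> 1).
    cc = 1.0 / (4.0 * hx * hy)
    pxy = {
        (di, dj): di * dj * cc * (sh(di, dj) / sh(di, 0) - 1.0)
        for di in (-1, 1)
        for dj in (-1, 1)
    }
    pyx = {
        (di, dj): di * dj * cc * (sh(di, dj) / sh(0, dj) - 1.0)
        for di in (-1, 1)
        for dj in (-1, 1)
    }

    a_xx = _stencil_matrix(pxx, sx, sy)
    a_yy = _stencil_matrix(pyy, -sx, -sy)
    a_xy = _stencil_matrix(pxy, -sx, -sy)  # acts on Ey
    a_yx = _stencil_matrix(pyx, sx, sy)  # acts on Ex
    return sp.bmat([[a_xx, a_xy], [a_yx, a_yy]], format="csc")


def solve_supermode(
    pmap: PermittivityMap,
    parity: Parity,
    polarization: Polarization,
    n_candidates: int = 1,
    shift_guess: float | None = None,
) -> list[ModeSolution]:
    """Solve one symmetry class; returns candidates sorted by descending n_eff."""
    if not (pmap.symmetric_x and pmap.symmetric_y):
        raise ValueError("quarter-domain solver requires a mirror-symmetric map")
    sx, sy = MODE_CLASSES[(parity, polarization)]
    xq, yq, epsq = pmap.quarter()
    hx, hy = pmap.dx, pmap.dy
    lam = pmap.wavelength_um
    k0 = 2.0 * np.pi / lam
    n_shift = shift_guess if shift_guess is not None else pmap.n_core
    sigma = (k0 * n_shift) ** 2

    a = _vector_operator(epsq, hx, hy, k0, sx, sy)
    k = n_candidates
    vals, vecs = spla.eigs(a, k=k, sigma=sigma, which="LM")
    order = np.argsort(-vals.real)
    out: list[ModeSolution] = []
    n = epsq.size
    for idx in order:
        beta2 = float(vals[idx].real)
        if beta2 <= 0:
            continue
        v = vecs[:, idx].real
        # Fix the overall sign so the dominant component peaks positive.
        dom = v[:n] if polarization == "x" else v[n:]
        if dom[np.argmax(np.abs(dom))] < 0:
            v = -v
        resid = float(
            np.linalg.norm(a @ v - beta2 * v) / (abs(beta2) * np.linalg.norm(v))
        )
        out.append(
            ModeSolution(
                wavelength_um=lam,
                n_eff=float(np.sqrt(beta2) / k0),
                ex=v[:n].reshape(epsq.shape),
                ey=v[n:].reshape(epsq.shape),
                parity=parity,
                polarization=polarization,
                residual=resid,
                x=xq,
                y=yq,
                n_core=pmap.n_core,
                n_ext=pmap.n_ext,
            )
        )
    return out


def solve_modes(
    pmap: PermittivityMap,
    wavelength_um: float | None = None,
    n_modes: int = 4,
    shift_guess: float | None = None,
) -> list[ModeSolution]:
    """Return the ``n_modes`` largest-n_eff guided supermodes of the map.

    One symmetry class is solved per (parity, polarization) combination; the
    class structure guarantees the four tracked supermodes are each the top
    of their own class.  Non-guided solutions (n_eff <= n_ext) are filtered
    out; finding none at all is reported with a warning (mode cutoff), not
    an exception.
    """
    if n_modes < 4:
        raise ValueError("n_modes must be >= 4 (the four tracked supermodes)")
    if wavelength_um is not None and wavelength_um != pmap.wavelength_um:
        pmap = pmap.at_wavelength(wavelength_um)
    if shift_guess is not None and not (pmap.n_ext < shift_guess <= pmap.n_core * 1.01):
        raise ValueError("shift_guess must lie between n_ext and n_core")

    per_class = int(np.ceil(n_modes / 4))
    modes: list[ModeSolution] = []
    for parity, pol in MODE_CLASSES:
        modes.extend(
            solve_supermode(
                pmap, parity, pol, n_candidates=per_class, shift_guess=shift_guess
            )
        )
    guided = [m for m in modes if m.guided]
    for m in guided:
        if m.boundary_leak > BOUNDARY_LEAK_LIMIT:
            warnings.warn(
                f"mode ({m.parity},{m.polarization}) at {m.wavelength_um:.4f} um "
                f"leaks to the boundary (edge/peak {m.boundary_leak:.1e}); "
                "increase padding",
                stacklevel=2,
            )
    if not guided:
        warnings.warn("no guided supermode found (cutoff)", stacklevel=2)
    guided.sort(key=lambda m: -m.n_eff)
    return guided[:n_modes]


def classify_fields(
    ex_full: np.ndarray, ey_full: np.ndarray
) -> tuple[Parity, Polarization]:
    """Classify a supermode from its full-cross-section transverse fields.

    The inter-core mirror plane is taken at the vertical midline of the
    arrays (where the rasterizer places it).  Parity is even when the
    dominant transverse component correlates positively with its mirror
    image through that plane; polarization is the axis holding the majority
    of the transverse energy.  An energy split within 50 +/- 2 % or a
    symmetry correlation below 0.5 in magnitude is ambiguous and raises.
    """
    px = float(np.sum(ex_full**2))
    py = float(np.sum(ey_full**2))
    frac_x = px / (px + py)
    if abs(frac_x - 0.5) < 0.02:
        raise ValueError(f"ambiguous polarization: Ex energy fraction {frac_x:.3f}")
    pol: Polarization = "x" if frac_x > 0.5 else "y"
    dom = ex_full if pol == "x" else ey_full
    mirrored = dom[:, ::-1]
    corr = float(np.sum(dom * mirrored) / np.sum(dom * dom))
    if abs(corr) < 0.5:
        raise ValueError(f"ambiguous parity: symmetry correlation {corr:.3f}")
    parity: Parity = "even" if corr > 0 else "odd"
    return parity, pol


def classify_mode(mode: ModeSolution) -> tuple[Parity, Polarization]:
    """Field-symmetry classification of a solved mode.

    For quarter-domain solutions the parity of the dominant component is
    fixed by the boundary conditions, so this serves as a consistency check
    (the polarization part is a genuine measurement of the energy split);
    raises if the fields contradict the recorded labels.
    """
    _, _, ex_full, ey_full = mode.full_fields()
    parity, pol = classify_fields(ex_full, ey_full)
    if (parity, pol) != (mode.parity, mode.polarization):
        raise ValueError(
            f"field symmetry ({parity},{pol}) contradicts labels "
            f"({mode.parity},{mode.polarization})"
        )
    return parity, pol


def mode_overlap(a: ModeSolution, b: ModeSolution) -> float:
    """Normalized field overlap used for tracking modes across a sweep."""
    num = float(np.sum(a.ex * b.ex) + np.sum(a.ey * b.ey))
    na = np.sqrt(np.sum(a.ex**2) + np.sum(a.ey**2))
    nb = np.sqrt(np.sum(b.ex**2) + np.sum(b.ey**2))
    return abs(num) / (na * nb)


@dataclass
class ConvergenceStudy:
    """n_eff versus grid spacing for one supermode, with extrapolation."""

    spacings_um: np.ndarray
    n_eff: np.ndarray
    under_resolved: np.ndarray
    extrapolated: float
    observed_order: float | None
    monotone: bool


def convergence_study(
    cross_section: CrossSection,
    wavelength_um: float,
    spacings_um: Sequence[float],
    parity: Parity = "even",
    polarization: Polarization = "x",
    padding_um: float = 1.5,
) -> ConvergenceStudy:
    """Solve one supermode at a sequence of refining spacings.

    Spacings coarser than d/40 are flagged under-resolved and not solved.
    The limit is Richardson-extrapolated from the two finest resolved
    levels, using the observed convergence order when three levels allow
    estimating it.
    """
    spacings = np.asarray(list(spacings_um), dtype=float)
    if len(spacings) < 3:
        raise ValueError("need at least 3 spacings")
    if np.any(np.diff(spacings) >= 0):
        raise ValueError("spacings must be strictly refining (decreasing)")
    under = spacings > cross_section.d / 40.0
    neffs = np.full(len(spacings), np.nan)
    for i, h in enumerate(spacings):
        if under[i]:
            continue
        pmap = rasterize(cross_section, h, padding_um, wavelength_um)
        sols = solve_supermode(pmap, parity, polarization)
        if not sols:
            raise RuntimeError(f"no solution at spacing {h} um")
        neffs[i] = sols[0].n_eff

    resolved = neffs[~under]
    hs = spacings[~under]
    if len(resolved) < 2:
        raise RuntimeError("fewer than two resolved spacings")
    order: float | None = None
    monotone = bool(
        np.all(np.diff(resolved) > 0) or np.all(np.diff(resolved) < 0)
    )
    if len(resolved) >= 3:
        d1 = resolved[-2] - resolved[-3]
        d2 = resolved[-1] - resolved[-2]
        r1 = hs[-2] / hs[-3]
        if d2 != 0 and d1 / d2 > 0 and abs(r1 - hs[-1] / hs[-2]) < 1e-9:
            order = float(np.log(abs(d1 / d2)) / np.log(1.0 / r1))
    p = order if order is not None and 0.5 < order < 4 else 2.0
    r = hs[-2] / hs[-1]
    extrap = resolved[-1] + (resolved[-1] - resolved[-2]) / (r**p - 1.0)
    return ConvergenceStudy(
        spacings_um=spacings,
        n_eff=neffs,
        under_resolved=under,
        extrapolated=float(extrap),
        observed_order=order,
        monotone=monotone,
    )
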