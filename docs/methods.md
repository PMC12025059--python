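# Methods

## Physical model

The device is an optical microfiber coupler (OMC): two single-mode fibers
flame-tapered and fused side by side so that the joint waist, a few
micrometres wide and L = 12 mm long, guides light as supermodes of the
composite cross-section.  The waist supports four tracked supermodes -- the
symmetric ("even") and antisymmetric ("odd") combinations of the
individual-strand fundamentals, each in x and y polarization, with
effective indices n_even^x, n_even^y, n_odd^x, n_odd^y.  Output power at
port 3/4 follows the standard two-mode interference law

    P3 = P1x cos^2(phi_x/2) + P1y cos^2(phi_y/2),      P4 = P1 - P3,
    phi_p = 2 pi L (n_even^p - n_odd^p) / lambda,

with the input split P1x = P1y = 1/2 for the unpolarized halogen source.

### Which fringes the spectrometer sees

Writing dn_p = n_even^p - n_odd^p, the unpolarized port-3 spectrum
factorizes as

    P3 = 1/2 + 1/2 cos(phi_mean) cos(dphi/2),
    dphi = 2 pi L (dn_x - dn_y) / lambda = 2 pi L (B_even - B_odd) / lambda,

where B_even = n_even^x - n_even^y and B_odd = n_odd^x - n_odd^y are the
cross-polarization birefringences of the two supermode families.  The
carrier phase phi_mean oscillates on a few-nanometre scale for micron
waists (the solved even/odd splitting in air is ~2e-2, i.e. ~150 fringes
per 400 nm for L = 12 mm); the *beat* phase dphi, driven by the
differential birefringence dB = B_even - B_odd ~ 1e-4..1e-3, produces the
6-60 broad fringes per window actually resolved and counted.  All
observable regularities of the device -- the exponential growth of the air
fringe count as the waist narrows, the single broad fringe with maximal
broadening at the turning point in high-index liquid, and the printed
turning-point wavelengths themselves -- are reproduced by the beat phase
and not by the carrier.  The package therefore exposes both:
`simulate_transmission` evaluates the full two-mode intensity (carrier
times envelope; P3 + P4 = P1 exactly), while `simulate_beat_spectrum`
returns the beat interferogram cos^2(dphi/2) used for fringe counting and
peak tracking.

### Dispersion turning point and sensitivity

A fringe sits where dphi is constant; differentiating with respect to the
surrounding refractive index (SRI) n gives the dip sensitivity

    S(lambda_N) = lambda_N * d(B_even - B_odd)/dn / (GB_even - GB_odd),
    GB_i = B_i - lambda dB_i/dlambda,

the group-birefringence counterpart of dB.  The dispersion turning point
(DTP) is the zero of Delta G = GB_even - GB_odd: there the local fringe
spacing (proportional to lambda^2 / (L |Delta G|)) diverges, S diverges
with a sign flip, and the device reaches its extreme sensitivity.  This
"differential-birefringence" formulation is the package default.  The
per-polarization alternative -- G_p = dn_p - lambda d dn_p/dlambda built
from a single polarization's even/odd carrier -- is implemented behind the
`formulation` switch; applied to this geometry it puts the turning point
~9% red of the reference values, while the differential-birefringence form
lands within ~2%, which is why the latter was frozen (the choice was
calibrated once against the reference 2.6-um/SRI-1.333 turning point and
not revisited).

## Geometry and materials

* Cross-section: two identical silica circles tangent at the origin.  The
  quoted waist diameter d is the *composite* width, so each circle has
  radius d/4 ("two-touching-circles" convention; a "single-circle" option
  retains one circle of diameter d).  The degree-of-fusion continuum
  between tangent and merged circles is out of scope.
* Silica follows the three-term Malitson Sellmeier fit; surrounding media
  (air, water, glycerol) are dispersionless constants, as the sensing
  conditions are quoted as single SRI values.  Supported window 0.4-1.6 um.
* An optional conformal annulus of thickness t (0-50 nm) and index 1.45
  (typical silane/antibody layer; configurable -- the layer index is not
  known experimentally) wraps each circle.  A thicker coating raises every
  supermode index, as expected.  Its effect on the sensitivity at a fixed
  wavelength is configuration-dependent: the coating also moves the
  turning point, so |S| at a given wavelength can rise (DTP pulled closer)
  or fall (DTP pushed away, evanescent response screened) depending on
  geometry and observation window -- report the distance-to-DTP together
  with any layered-sensitivity comparison.
* Rasterization assigns each cell the area-weighted permittivity average.
  Cell coverage uses a signed-distance linear ramp projected on the local
  edge normal, which is antisymmetric about the interface and hence
  area-exact to second order in the spacing (verified: observed order >=
  1.5 against the analytic circle area, ~1e-3 relative area error at
  d/spacing = 40).

## Mode solver

Full-vector finite differences on the transverse electric field (Ex, Ey):
the coupled operator includes the polarization-dependent interface terms
d/dx[(1/eps) d(eps Ex)/dx] and the cross blocks d/dx[(1/eps) d(eps Ey)/dy]
- d2Ey/dxdy, discretized with second-order stencils and half-cell
permittivity averages; the cross blocks vanish identically in homogeneous
cells.  The eigenproblem A e = beta^2 e is solved by ARPACK shift-invert
with the shift at k0^2 n_core^2, so the largest guided modes come first.

The two mirror planes of the cross-section (x = 0 between the cores, y = 0
through them) quarter the domain.  Each of the four tracked supermodes is
the *largest* eigenvalue in its own symmetry class, selected by the
parity boundary conditions

    (parity, pol):  Ex parity (x, y)    Ey parity (x, y)
    even, x         (+, +)              (-, -)
    odd,  x         (-, +)              (+, -)
    even, y         (-, -)              (+, +)
    odd,  y         (+, -)              (-, +)

which makes the even/odd and x/y labelling exact by construction (no
overlap tracking needed inside a sweep) and cuts the work by ~8x.  The
outer boundary is a perfect electric wall; a boundary-leak metric (edge
amplitude / peak amplitude, limit 1e-3) guards against insufficient
padding.

Defaults and their rationale:

| parameter | default | why |
|---|---|---|
| grid spacing | 0.020 um | single-fiber oracle error 5e-6 in n_eff (two orders below the dn signals); 0.015 um moves the reference DTP by only +3 nm (+0.24%) at 2.5x cost |
| padding | 1.3 um (air), 2.6 um (liquid) | worst-case evanescent decay lengths; leak metric < 1e-3 across the sweeps used |
| eigensolver | ARPACK shift-invert, k=1 per class | largest guided mode per symmetry class; residuals ~1e-14 |

Accuracy cross-check: the same discretization solves a single circle
(d = 2.6 um, SRI 1.333) to within 5e-6 of the exact hybrid-mode
characteristic equation, and x/y fundamentals of the circular geometry are
degenerate to < 5e-5.

## Dispersion analysis

* Wavelength sweeps re-use one raster (material fractions are
  wavelength-independent) and re-evaluate silica permittivity per point.
* lambda-derivatives: cubic spline through the sampled curves (eigen-noise
  is ~1e-10, far below the 1e-4..1e-3 signals, so no smoothing is
  applied); central differences are available as a cross-check.  Spline
  end intervals are less accurate, so windows are chosen with margin
  around the quantity of interest.
* SRI derivative d(dB)/dn: centred difference with step 5e-4 RIU
  (Richardson-checked: halving the step changes it < 5%).
* DTP localization: sign change of Delta G refined by monotone (PCHIP)
  inverse interpolation; reported to 1 nm.  `CouplerModel.dtp` brackets
  the crossing with a coarse scan centred on a linear scaling of the
  solved model (about +0.44 nm DTP shift per nm of diameter, -6 nm per
  0.001 SRI) and refines with a <= 10 nm step sweep; if the heuristic
  window misses, the full solvable window is scanned.

## Air-fingerprint prediction chain

1. `air_peak_count(d)`: beat fringes counted as local maxima (prominence
   0.01) of the simulated air interferogram over 600-1000 nm -- the
   spectrometer window (600-980 nm) rounded up, fixed as the default
   counting window.
2. `build_peak_diameter_map`: counts over d = 2.0-3.2 um (13 points) are
   fitted with N(d) = a exp(-b d) + c by least squares; the inverse is the
   analytic inversion of the fitted curve, allowed to extrapolate at most
   0.15 um beyond the sampled diameters (with a warning) so the full
   device-selection range N = 6-65 stays invertible.
3. `predict_dtp(N_air, SRI)`: inverse map, then DTP at the inferred
   diameter.  `build_dtp_surface` tabulates DTP over (N, SRI) with
   unsolvable cells explicitly missing (queried as None, never
   extrapolated).
4. `sensitivity_from_peak_count` evaluates S at an operating wavelength
   together with its distance to the DTP; `recommend_peak_count` bisects
   the (monotone) |S|-vs-N relation for the smallest adequate fringe
   count.

## Spectrum analysis layer

Peak positions are refined by parabolic interpolation through the three
samples around each maximum (sub-grid precision, needed to emulate 0.01-nm
shift reporting on coarse spectrometer grids).  Tracks associate peaks
between consecutive conditions by nearest neighbour with a half-fringe
guard; a larger jump is indistinguishable from fringe hopping and marks
the track lost.  Shifts are signed (blue negative) and no sign convention
is enforced -- fringes on opposite sides of a DTP legitimately move in
opposite directions.  Sensitivity and calibration fits are ordinary least
squares of shift against SRI, concentration or log-concentration, with
R^2, residual SD, replicate SD (SD of per-replicate shifts at each
condition) and the linear-range endpoints (the supplied condition
extremes).

## Synthetic data generator

`generate_synthetic_series` forward-models a condition series from a
dispersion set (solved or analytic) whose even-mode indices respond
linearly to the condition, with two noise terms: per-sample Gaussian
intensity noise and a per-spectrum Gaussian wavelength offset
(spectrometer jitter).  A fixed seed fixes the output exactly.  It
emulates the fringe physics and first-order response of a real series; it
does *not* emulate source-spectrum shaping, wavelength-dependent coupling
visibility, detector nonlinearity, temperature drift, or binding
kinetics, so passing recovery tests demonstrate correctness of the
tracking/fitting chain, not robustness to those effects.

## Numerical edge cases

* Mode cutoff inside a sweep leaves NaN samples and flags the set
  truncated; group analysis refuses truncated sets.
* Degenerate SRI step (delta = 0), empty wavelength grids, non-monotone
  grids, and windows beyond the dispersion data raise immediately.
* Near the DTP pole the sensitivity is reported as diverging (sign
  preserved) rather than evaluated; the `diverging` flag accompanies any
  dip within one grid step of the crossing.
* Ambiguous mode classification (energy split within 50 +/- 2%, symmetry
  correlation < 0.5) raises rather than guessing.

## Problem sizes used in the shipped analyses

Dispersion sweeps use 9-42 wavelength points per geometry at the
production grid (roughly 150-400 grid cells per axis depending on padding
and diameter); the peak-diameter map samples 13 diameters with 9-point
air sweeps.  These sizes keep a full reproduction of the headline numbers
to tens of minutes on one core while leaving every reported digit
converged at the tolerances stated above.

## Known limitations

* The tangent-circle idealization ignores the fusion neck of a real
  coupler; absolute even/odd carrier splittings are therefore upper
  bounds, and agreement of the *beat* quantities with the reference
  device is at the few-percent level, not exact.
* The per-fiber-versus-composite diameter reading is fixed by calibration
  (composite); a fabricated device whose SEM diameter follows the other
  convention would need the `single-circle` option or a rescaled map.
* Zero-field outer boundaries bias n_eff slightly for weakly guided modes
  near cutoff; padding defaults keep this below ~1e-6 but very long
  wavelengths at small diameters approach the guard.
* Experimental absolute sensitivities (e.g. 1e5 nm/RIU near a DTP) depend
  on exactly how close the operating fringe sits to the pole; the package
  reports the distance-to-DTP alongside any predicted S for that reason.
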