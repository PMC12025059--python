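"""Independent oracle: exact two-layer step-index fiber dispersion relation.

The hybrid-mode characteristic equation of a circular step-index fiber
(core index n1, radius a, cladding n2) for azimuthal order l:

    (Jl'/(u Jl) + Kl'/(w Kl)) (Jl'/(u Jl) + (n2/n1)^2 Kl'/(w Kl))
        = (l * neff / n1)^2 (1/u^2 + 1/w^2)^2

with u = k0 a sqrt(n1^2 - neff^2), w = k0 a sqrt(neff^2 - n2^2).  The
largest root for l=1 is the HE11 fundamental.  Root-finding is done by a
dense sign-change scan plus Brent refinement, entirely independent of the
finite-difference solver it is used to check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import jv, kv


def he11_effective_index(
    n_core: float, n_clad: float, radius_um: float, wavelength_um: float
) -> float:
    k0 = 2.0 * np.pi / wavelength_um
    l = 1

    def chareq(neff: float) -> float:
        u = k0 * radius_um * np.sqrt(n_core**2 - neff**2)
        w = k0 * radius_um * np.sqrt(neff**2 - n_clad**2)
        jl = jv(l, u)
        kl = kv(l, w)
        jp = 0.5 * (jv(l - 1, u) - jv(l + 1, u))
        kp = -0.5 * (kv(l - 1, w) + kv(l + 1, w))
        lhs = (jp / (u * jl) + kp / (w * kl)) * (
            jp / (u * jl) + (n_clad**2 / n_core**2) * kp / (w * kl)
        )
        rhs = (l * neff / n_core) ** 2 * (1.0 / u**2 + 1.0 / w**2) ** 2
        return lhs - rhs

    xs = np.linspace(n_clad + 1e-7, n_core - 1e-7, 6000)
    vals = np.array([chareq(x) for x in xs])
    for i in range(len(xs) - 1, 0, -1):
        a, b = vals[i - 1], vals[i]
        if np.isfinite(a) and np.isfinite(b) and a * b < 0:
            return float(brentq(chareq, xs[i - 1], xs[i], xtol=1e-13))
    raise RuntimeError("no HE11 root found")
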