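"""Murnaghan equation-of-state fitting for energy-volume curves."""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def murnaghan_energy(v, e0: float, v0: float, b0: float, b0p: float):
    """Murnaghan E(V).

    ``E(V) = E0 + B0 V / B0' [ (V0/V)^B0' / (B0'-1) + 1 ] - B0 V0/(B0'-1)``
    with E in eV, V in A^3 and B0 in eV/A^3."""
    v = np.asarray(v, dtype=float)
    return (e0 + b0 * v / b0p * ((v0 / v) ** b0p / (b0p - 1.0) + 1.0)
            - b0 * v0 / (b0p - 1.0))


def fit_murnaghan(volumes, energies) -> dict:
    """Least-squares Murnaghan fit of an E(V) curve.

    Requires at least 5 points bracketing an interior minimum. Returns
    ``{"E0", "V0", "B0", "B0p", "residual"}`` (eV, A^3, eV/A^3)."""
    v = np.asarray(volumes, dtype=float)
    e = np.asarray(energies, dtype=float)
    if v.shape != e.shape or v.ndim != 1:
        raise ValueError("volumes and energies must be equal-length 1-d arrays")
    if len(v) < 5:
        raise ValueError("need at least 5 energy-volume points")
    order = np.argsort(v)
    v, e = v[order], e[order]
    imin = int(np.argmin(e))
    if imin in (0, len(v) - 1):
        raise ValueError("energy-volume data do not bracket an interior minimum")

    # initial guesses from a local parabola around the minimum
    sl = slice(max(0, imin - 2), min(len(v), imin + 3))
    coef = np.polyfit(v[sl], e[sl], 2)
    v0_init = float(-coef[1] / (2.0 * coef[0]))
    if not (v[0] < v0_init < v[-1]):
        v0_init = float(v[imin])
    e0_init = float(np.polyval(coef, v0_init))
    b0_init = float(max(2.0 * coef[0] * v0_init, 1e-4))  # B0 = V d2E/dV2
    x0 = np.array([e0_init, v0_init, b0_init, 4.0])

    def resid(p):
        return murnaghan_energy(v, *p) - e

    fit = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15)
    e0, v0, b0, b0p = (float(x) for x in fit.x)
    return {"E0": e0, "V0": v0, "B0": b0, "B0p": b0p,
            "residual": float(np.sqrt(np.mean(fit.fun ** 2)))}
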