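"""Benchmark error statistics: ME / MAE / MAX and their relative variants."""

from __future__ import annotations

import numpy as np


def error_stats(values, refs) -> dict:
    """Signed, absolute and maximal errors of ``values`` against ``refs``.

    ``error = value - ref``; ``relative error = 100 (value - ref) / |ref|``
    in percent. Returns ME, MAE, MAX (same units as the inputs) and MRE,
    MARE, RMAX (%), where the MAX entries are the largest errors in
    magnitude. Raises on a zero reference (relative errors undefined).
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(refs, dtype=float)
    if v.shape != r.shape or v.ndim != 1 or len(v) == 0:
        raise ValueError("values and refs must be equal-length non-empty 1-d arrays")
    if np.any(r == 0.0):
        raise ValueError("zero reference value; relative errors undefined")
    err = v - r
    rel = 100.0 * err / np.abs(r)
    return {
        "ME": float(err.mean()),
        "MAE": float(np.abs(err).mean()),
        "MAX": float(np.abs(err).max()),
        "MRE": float(rel.mean()),
        "MARE": float(np.abs(rel).mean()),
        "RMAX": float(np.abs(rel).max()),
    }
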