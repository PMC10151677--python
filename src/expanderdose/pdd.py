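"""Exponential fit to the distal part of a depth-dose curve.

The machine-calibration procedure fits A exp(-b d) to the computed PDD
between 5 and 15 cm and reads the fitted dose at 10 cm, smoothing the
statistical noise of a single-voxel lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class PDDFit:
    amplitude: float
    decay_per_cm: float
    value_at_depth: float
    depth_cm: float
    r_squared: float
    warnings: list[str] = field(default_factory=list)


def fit_pdd_exponential(
    depths_cm,
    dose,
    fit_range_cm: tuple[float, float] = (5.0, 15.0),
    report_depth_cm: float = 10.0,
) -> PDDFit:
    """Least-squares fit of A exp(-b d) on the fit range.

    Requires >= 5 points and positive doses in range; flags (but does not
    reject) non-monotone input, which usually indicates noise or geometry
    errors in the distal falloff.
    """
    d = np.asarray(depths_cm, float)
    y = np.asarray(dose, float)
    sel = (d >= fit_range_cm[0]) & (d <= fit_range_cm[1])
    if sel.sum() < 5:
        raise ValueError("need at least 5 points inside the fit range")
    d, y = d[sel], y[sel]
    if np.any(y <= 0):
        raise ValueError("non-positive dose inside the fit range")
    warnings = []
    order = np.argsort(d)
    if np.any(np.diff(y[order]) > 0):
        warnings.append("dose not monotonically decreasing inside the fit range")
    # initialize from the log-linear fit, refine with curve_fit
    b0, loga0 = np.polyfit(d, np.log(y), 1)
    popt, _ = curve_fit(lambda x, a, b: a * np.exp(-b * x), d, y, p0=(np.exp(loga0), -b0))
    a, b = float(popt[0]), float(popt[1])
    resid = y - a * np.exp(-b * d)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return PDDFit(a, b, a * np.exp(-b * report_depth_cm), report_depth_cm, r2, warnings)
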