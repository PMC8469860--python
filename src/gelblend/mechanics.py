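"""Compression-test processing for hydrogel cylinders.

Raw load–displacement pairs become engineering stress (load/area, MPa
with the N/mm² convention) and strain (displacement/initial height).
Hydrogel compression curves are nonlinear over their whole range, so a
single Young's modulus is not defined; instead the tangent modulus is
evaluated at chosen strains and the failure point is located as the
first large post-peak stress drop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .errors import DataError


@dataclass
class StressStrainCurve:
    stress: np.ndarray          # MPa
    strain: np.ndarray          # dimensionless
    area_mm2: float | None = None
    height_mm: float | None = None

    def __post_init__(self):
        self.stress = np.asarray(self.stress, float)
        self.strain = np.asarray(self.strain, float)
        if self.stress.shape != self.strain.shape:
            raise DataError("stress and strain series differ in length")


@dataclass
class MechanicalSummary:
    tangent_moduli: dict                    # strain -> MPa (nan past failure)
    failure_strength: float                 # MPa
    failure_strain: float
    hydrogel_type: str | None = None


def stress_strain(load_n, displacement_mm, area_mm2: float,
                  height_mm: float) -> StressStrainCurve:
    """Stress = load/area, strain = displacement/initial height."""
    if area_mm2 <= 0 or height_mm <= 0:
        raise DataError("sample area and height must be positive")
    load = np.asarray(load_n, float)
    disp = np.asarray(displacement_mm, float)
    if load.shape != disp.shape:
        raise DataError("load and displacement series differ in length")
    if np.any(np.diff(disp) < 0):
        warnings.warn("displacement not monotone; reordering by displacement",
                      stacklevel=2)
        order = np.argsort(disp, kind="stable")
        load, disp = load[order], disp[order]
    return StressStrainCurve(stress=load / area_mm2, strain=disp / height_mm,
                             area_mm2=area_mm2, height_mm=height_mm)


def failure_strength(curve: StressStrainCurve,
                     drop_fraction: float = 0.2) -> tuple[float, float]:
    """Failure stress and strain.

    The failure point is the running-maximum sample preceding the first
    post-peak drop larger than ``drop_fraction`` of the running maximum.
    """
    s = curve.stress
    if len(s) < 2:
        raise DataError("curve too short to locate failure")
    run_max = np.maximum.accumulate(s)
    peak_idx = np.argmax(s[:1])
    for i in range(1, len(s)):
        if s[i] < (1.0 - drop_fraction) * run_max[i - 1]:
            peak_idx = int(np.argmax(s[:i]))
            return float(s[peak_idx]), float(curve.strain[peak_idx])
    raise DataError(
        "no failure signature (post-peak drop) found; inspect the raw curve")


def tangent_modulus(curve: StressStrainCurve, strain_points,
                    smoothing_lam: float | None = None) -> dict:
    """Local slope dσ/dε at the requested strains (MPa).

    The pre-failure portion of the curve is smoothed with a cubic
    smoothing spline (generalized cross-validation picks the penalty
    unless ``smoothing_lam`` is given) and differentiated.  Strains at
    or beyond the failure strain are flagged as undefined (NaN).
    """
    try:
        _, eps_fail = failure_strength(curve)
    except DataError:
        eps_fail = float(curve.strain[-1]) + np.inf
    mask = curve.strain <= min(eps_fail, np.max(curve.strain))
    eps = curve.strain[mask]
    sig = curve.stress[mask]
    eps_u, idx = np.unique(eps, return_index=True)
    sig_u = sig[idx]
    if len(eps_u) < 4:
        raise DataError("too few pre-failure samples for a spline fit")
    spline = make_smoothing_spline(eps_u, sig_u, lam=smoothing_lam)
    deriv = spline.derivative()
    out = {}
    for e in strain_points:
        if e >= eps_fail or e > eps_u[-1] or e < eps_u[0]:
            out[float(e)] = float("nan")
        else:
            out[float(e)] = float(deriv(e))
    return out


def mechanical_summary(curve: StressStrainCurve, strain_points=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
                       hydrogel_type: str | None = None) -> MechanicalSummary:
    strength, eps_f = failure_strength(curve)
    moduli = tangent_modulus(curve, strain_points)
    return MechanicalSummary(tangent_moduli=moduli, failure_strength=strength,
                             failure_strain=eps_f, hydrogel_type=hydrogel_type)
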