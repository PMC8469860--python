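"""Elastic constants from minimized periodic cells (static method).

Six Voigt strain modes are applied as small affine deformations of the
cell (±strain, default 0.003), the cell is re-minimized under each, and
the virial stress response fills the 6×6 stiffness matrix by central
differences.  Isotropic moduli follow from averaged stiffness entries:
λ from the six off-diagonal normal couplings, μ from the shear diagonal,
E = μ(3λ+2μ)/(λ+μ) and K = λ + 2μ/3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .constants import KCAL_A3_TO_GPA
from .engine import NeighborList, MinimizationError, minimize, stress_tensor
from .errors import DivergenceError
from .forcefield import ForceField
from .system import ParticleSystem

log = logging.getLogger(__name__)


@dataclass
class StiffnessMatrix:
    """6×6 stiffness in Voigt convention, GPa."""

    C: np.ndarray

    def __post_init__(self):
        self.C = np.asarray(self.C, float)
        if self.C.shape != (6, 6):
            raise ValueError("stiffness matrix must be 6x6")
        if not np.all(np.isfinite(self.C)):
            raise ValueError("stiffness matrix entries must be finite")

    @property
    def symmetrized(self) -> np.ndarray:
        return 0.5 * (self.C + self.C.T)


@dataclass
class LameCoefficients:
    lam: float      # λ, GPa
    mu: float       # μ (shear modulus), GPa


@dataclass
class ElasticModuli:
    young: float    # E, GPa
    bulk: float     # K, GPa


def _voigt_deformation(mode: int, eps: float) -> np.ndarray:
    """Deformation gradient for Voigt mode 0..5 (xx, yy, zz, yz, xz, xy)."""
    F = np.eye(3)
    if mode < 3:
        F[mode, mode] += eps
    elif mode == 3:
        F[1, 2] += eps
    elif mode == 4:
        F[0, 2] += eps
    else:
        F[0, 1] += eps
    return F


def _voigt_stress(sigma: np.ndarray) -> np.ndarray:
    s = 0.5 * (sigma + sigma.T)
    return np.array([s[0, 0], s[1, 1], s[2, 2], s[1, 2], s[0, 2], s[0, 1]])


def stiffness_static(system: ParticleSystem, ff: ForceField,
                     strain_amplitude: float = 0.003,
                     force_tol: float = 0.05,
                     max_minimize_iter: int = 300) -> StiffnessMatrix:
    """Static-method stiffness matrix of a minimized periodic cell.

    For each Voigt mode the box and coordinates are mapped affinely by
    ±strain, re-minimized, and column j of C is the central difference
    of the Voigt stress over 2·strain.  Raises naming the failing mode
    if a strained minimization diverges.
    """
    base = minimize(system, ff, force_tol=force_tol,
                    max_iter=max_minimize_iter, strict=False).system
    # one pair list with a generous skin serves every strained copy:
    # at |strain| <= 0.003 atoms move far less than half the skin
    C = np.zeros((6, 6))
    for mode in range(6):
        sig = {}
        for sgn in (+1.0, -1.0):
            F = _voigt_deformation(mode, sgn * strain_amplitude)
            strained = base.copy()
            strained.cell = base.cell @ F.T
            strained.positions = base.positions @ F.T
            try:
                res = minimize(strained, ff, force_tol=force_tol,
                               max_iter=max_minimize_iter, strict=False)
            except (DivergenceError, MinimizationError) as err:
                raise type(err)(
                    f"strained minimization failed for Voigt mode "
                    f"{mode + 1} ({sgn:+.0f}): {err}") from err
            nl = NeighborList(res.system, ff)
            sig[sgn] = _voigt_stress(stress_tensor(res.system, ff, nlist=nl))
        C[:, mode] = (sig[+1.0] - sig[-1.0]) / (2.0 * strain_amplitude)
    return StiffnessMatrix(C=C * KCAL_A3_TO_GPA)


def lame_from_stiffness(stiff: StiffnessMatrix) -> LameCoefficients:
    """λ = mean of C12, C13, C21, C23, C31, C32; μ = mean of C44, C55, C66."""
    C = stiff.symmetrized
    lam = (C[0, 1] + C[0, 2] + C[1, 0] + C[1, 2] + C[2, 0] + C[2, 1]) / 6.0
    mu = (C[3, 3] + C[4, 4] + C[5, 5]) / 3.0
    return LameCoefficients(lam=float(lam), mu=float(mu))


def young_modulus(lame: LameCoefficients) -> float:
    """E = μ(3λ + 2μ)/(λ + μ)."""
    if abs(lame.lam + lame.mu) < 1e-300:
        raise ZeroDivisionError("degenerate material: λ + μ = 0")
    return lame.mu * (3.0 * lame.lam + 2.0 * lame.mu) / (lame.lam + lame.mu)


def bulk_modulus(lame: LameCoefficients) -> float:
    """K = λ + 2μ/3 (standard isotropic relation)."""
    return lame.lam + 2.0 * lame.mu / 3.0


def elastic_moduli(stiff: StiffnessMatrix) -> ElasticModuli:
    lame = lame_from_stiffness(stiff)
    return ElasticModuli(young=young_modulus(lame), bulk=bulk_modulus(lame))
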