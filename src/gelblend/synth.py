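"""Synthetic fixtures with known ground truth.

Four generators feed the analysis pipeline: SEM-like pore images
(dark disks, optionally nested, on a bright background), nonlinear
compression curves with a planted failure point, gravimetric weight
records inverted from target sorption percentages, and a periodic
harmonic simple-cubic lattice whose stiffness matrix is known in closed
form.  Every generator is deterministic under a fixed seed and
round-trips exactly through the corresponding analysis at zero noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage import draw

from .constants import KCAL_A3_TO_GPA
from .forcefield import ForceField
from .mechanics import StressStrainCurve
from .sorption import WeightRecord
from .system import ParticleSystem

BACKGROUND_LEVEL = 220.0
PORE_LEVEL = 70.0
NESTED_LEVEL = 20.0


@dataclass
class SyntheticTruth:
    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path):
        def _default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))
        with open(path, "w") as fh:
            json.dump({"generator": self.generator, "seed": self.seed,
                       "params": self.params}, fh, indent=2, default=_default)


# ---------------------------------------------------------------------------
# SEM-like micrographs

def gen_sem_image(n_pores: int = 60, median_diameter_um: float = 0.3,
                  sigma_log: float = 0.6, image_size: int = 512,
                  pixel_size_um: float | None = None,
                  nesting_fraction: float = 0.0, noise_level: float = 0.0,
                  seed: int = 0, max_attempts: int = 2000):
    """Draw non-overlapping dark disks on a bright background.

    Diameters are lognormal (median ``median_diameter_um``); a
    ``nesting_fraction`` of sufficiently large disks receives one darker
    disk nested inside (pore-within-pore).  The truth records the
    *realized* equivalent circular diameter of every drawn disk (pixel
    area), which is what a perfect analysis recovers.
    """
    if n_pores < 0 or median_diameter_um <= 0 or sigma_log < 0:
        raise ValueError("generator parameters must be positive")
    if pixel_size_um is None:
        pixel_size_um = 20.0 / image_size
    rng = np.random.default_rng(seed)
    img = np.full((image_size, image_size), BACKGROUND_LEVEL)

    wanted = median_diameter_um * np.exp(
        sigma_log * rng.standard_normal(n_pores))
    radii_px = np.clip(wanted / 2.0 / pixel_size_um, 2.0, image_size / 8.0)
    if np.pi * np.sum(radii_px ** 2) > 0.55 * image_size ** 2:
        raise ValueError("requested pore area exceeds the image area")

    placed = []   # (cy, cx, r_px)
    order = np.argsort(radii_px)[::-1]       # large disks first
    for k in order:
        r = radii_px[k]
        for _ in range(max_attempts):
            cy = rng.uniform(r + 3, image_size - r - 3)
            cx = rng.uniform(r + 3, image_size - r - 3)
            if all(np.hypot(cy - y, cx - x) > r + rr + 3.0
                   for y, x, rr in placed):
                placed.append((cy, cx, r))
                break
        else:
            raise ValueError("could not place all pores without overlap")

    realized = []
    nested_realized = []
    for i, (cy, cx, r) in enumerate(placed):
        rr, cc = draw.disk((cy, cx), r, shape=img.shape)
        img[rr, cc] = PORE_LEVEL
        realized.append(2.0 * np.sqrt(len(rr) / np.pi) * pixel_size_um)
        if (rng.uniform() < nesting_fraction and r >= 8.0):
            rn = max(2.0, 0.35 * r)
            nrr, ncc = draw.disk((cy, cx), rn, shape=img.shape)
            img[nrr, ncc] = NESTED_LEVEL
            nested_realized.append(
                2.0 * np.sqrt(len(nrr) / np.pi) * pixel_size_um)

    if noise_level > 0:
        img = img + rng.normal(0.0, noise_level, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    truth = SyntheticTruth(
        generator="sem_image", seed=seed,
        params={
            "pixel_size_um": pixel_size_um,
            "diameters_um": sorted(realized + nested_realized),
            "outer_diameters_um": sorted(realized),
            "nested_diameters_um": sorted(nested_realized),
            "noise_level": noise_level,
        })
    return img, truth


# ---------------------------------------------------------------------------
# compression curves

def gen_stress_strain(a: float = 0.024, b: float = 5.0,
                      failure_strain: float | None = None,
                      noise: float = 0.0, n_points: int = 200,
                      seed: int = 0):
    """σ(ε) = a·(e^{bε} − 1) truncated by a sharp drop at failure.

    ``failure_strain`` defaults to a uniform draw in [0.55, 0.70], the
    strain window in which hydrogel cylinders of this family fail.
    """
    rng = np.random.default_rng(seed)
    if failure_strain is None:
        failure_strain = float(rng.uniform(0.55, 0.70))
    if not 0.0 < failure_strain < 1.0:
        raise ValueError("failure_strain must be in (0, 1)")
    eps = np.linspace(0.0, failure_strain, n_points)
    sig = a * (np.exp(b * eps) - 1.0)
    sigma_f = float(sig[-1])
    if noise > 0:
        sig = sig + rng.normal(0.0, noise, sig.shape)
        sig[0] = 0.0
    # post-failure collapse: well past the 20% drop criterion
    post_eps = failure_strain + np.array([0.005, 0.010, 0.015])
    post_sig = sigma_f * np.array([0.3, 0.15, 0.05])
    curve = StressStrainCurve(
        stress=np.concatenate([sig, post_sig]),
        strain=np.concatenate([eps, post_eps]))
    truth = SyntheticTruth(
        generator="stress_strain", seed=seed,
        params={"a": a, "b": b, "failure_strain": failure_strain,
                "failure_stress": sigma_f, "noise": noise})
    return curve, truth


# ---------------------------------------------------------------------------
# gravimetric weight records

def _complete_sorption_targets(sd, wa, hd):
    given = [x is not None for x in (sd, wa, hd)]
    if sum(given) < 2:
        raise ValueError(
            "need at least two of swelling_degree, water_absorption, "
            "hydrolytic_degradation")
    if sum(given) == 3:
        implied = 100.0 * ((1 + wa / 100.0) * (1 - hd / 100.0) - 1.0)
        if abs(implied - sd) > 1e-6 * max(1.0, abs(sd)):
            raise ValueError(
                f"inconsistent targets: SD={sd} but WA/HD imply {implied:.4f}"
                " (the three are linked by one mass-balance identity)")
    elif sd is None:
        sd = 100.0 * ((1 + wa / 100.0) * (1 - hd / 100.0) - 1.0)
    elif wa is None:
        wa = 100.0 * ((1 + sd / 100.0) / (1 - hd / 100.0) - 1.0)
    else:
        hd = 100.0 * (1.0 - (1 + sd / 100.0) / (1 + wa / 100.0))
    return float(sd), float(wa), float(hd)


def gen_weight_records(water_content_pct: float,
                       swelling_degree_pct: float | None = None,
                       water_absorption_pct: float | None = None,
                       hydrolytic_degradation_pct: float | None = None,
                       base_dry_mass_g: float = 1.6,
                       relative_noise: float = 0.025,
                       n_replicates: int = 3, seed: int = 0,
                       hydrogel_type: str | None = None,
                       temperature_c: float | None = None):
    """Invert the sorption formulas into consistent weight quadruples.

    The three sorption percentages are linked by one identity
    (1 + SD/100) = (1 + WA/100)(1 − HD/100), so exactly two of them are
    free; the third is derived (or checked, if supplied).  Multiplicative
    Gaussian noise with relative standard deviation ``relative_noise``
    is applied independently to each weight of each replicate.
    """
    if not 0.0 <= water_content_pct < 100.0:
        raise ValueError("water content must be in [0, 100)")
    sd, wa, hd = _complete_sorption_targets(
        swelling_degree_pct, water_absorption_pct,
        hydrolytic_degradation_pct)
    if hd >= 100.0:
        raise ValueError("hydrolytic degradation must be < 100%")
    if base_dry_mass_g <= 0:
        raise ValueError("base dry mass must be positive")
    w_id = base_dry_mass_g
    w_iw = w_id / (1.0 - water_content_pct / 100.0)
    w_sd = w_id * (1.0 - hd / 100.0)
    w_sw = w_id * (1.0 + sd / 100.0)
    for name, w in [("initial_wet", w_iw), ("swollen_dry", w_sd),
                    ("swollen_wet", w_sw)]:
        if w <= 0:
            raise ValueError(f"targets imply non-positive {name} weight")

    rng = np.random.default_rng(seed)
    records = []
    for _ in range(n_replicates):
        f = 1.0 + relative_noise * rng.standard_normal(4) \
            if relative_noise > 0 else np.ones(4)
        f = np.maximum(f, 1e-3)
        records.append(WeightRecord(
            initial_wet=w_iw * f[0], initial_dry=w_id * f[1],
            swollen_wet=w_sw * f[2], swollen_dry=w_sd * f[3],
            hydrogel_type=hydrogel_type, temperature_c=temperature_c))
    truth = SyntheticTruth(
        generator="weight_records", seed=seed,
        params={"water_content_pct": water_content_pct,
                "swelling_degree_pct": sd, "water_absorption_pct": wa,
                "hydrolytic_degradation_pct": hd,
                "base_dry_mass_g": base_dry_mass_g,
                "relative_noise": relative_noise,
                "weights_g": {"initial_wet": w_iw, "initial_dry": w_id,
                              "swollen_wet": w_sw, "swollen_dry": w_sd}})
    return records, truth


# ---------------------------------------------------------------------------
# harmonic simple-cubic lattice (elasticity oracle)

def gen_toy_lattice(lattice_constant: float = 2.0,
                    spring_constant: float = 10.0,
                    n_cells: int = 3, mass: float = 12.011):
    """Periodic simple-cubic crystal with nearest-neighbor springs.

    With springs at their natural length a, the analytic stiffness is
    C11 = C22 = C33 = k/a and every other entry zero (nearest-neighbor
    springs carry no transverse or shear stiffness to first order).
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells per axis")
    a, k, n = lattice_constant, spring_constant, n_cells
    idx = np.arange(n)
    gx, gy, gz = np.meshgrid(idx, idx, idx, indexing="ij")
    lattice = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    pos = lattice * a
    natoms = len(pos)

    def site(i, j, l):
        return ((i % n) * n + (j % n)) * n + (l % n)

    bonds = []
    for i, j, l in lattice:
        bonds.append((site(i, j, l), site(i + 1, j, l)))
        bonds.append((site(i, j, l), site(i, j + 1, l)))
        bonds.append((site(i, j, l), site(i, j, l + 1)))
    # each site contributes its +x/+y/+z spring once; for n == 2 the two
    # rows joining the same pair are two physically distinct springs
    bonds = np.array(bonds, int)
    system = ParticleSystem(
        positions=pos.astype(float),
        masses=np.full(natoms, mass),
        charges=np.zeros(natoms),
        elements=np.full(natoms, "C"),
        names=np.full(natoms, "LAT"),
        species=np.full(natoms, "gelatin"),
        molecule_id=np.zeros(natoms, int),
        bonds=bonds,
        bond_k=np.full(len(bonds), k),
        bond_r0=np.full(len(bonds), a),
        cell=np.diag(np.full(3, n * a)),
    )
    C = np.zeros((6, 6))
    C[0, 0] = C[1, 1] = C[2, 2] = k / a * KCAL_A3_TO_GPA
    truth = SyntheticTruth(
        generator="toy_lattice", seed=0,
        params={"lattice_constant": a, "spring_constant": k,
                "n_cells": n, "stiffness_gpa": C})
    return system, truth


def lattice_forcefield(lattice_constant: float = 2.0) -> ForceField:
    """Bonds-only force field for the toy lattice (nonbonded disabled)."""
    return ForceField(lj={"C": (0.0, 0.5)}, cutoff=0.45 * lattice_constant,
                      coulomb=False)
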