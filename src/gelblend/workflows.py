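"""End-to-end desk-scale studies tying builder, engine and observables.

The central workflow builds amorphous gelatin/PVA cells over a range of
PVA mass percentages and several seeds, runs the scaled anneal-and-
equilibrate protocol, and measures density, fractional free volume,
hydrogen-bond donor/acceptor density, energy densities, interaction
decomposition and static-method elastic moduli.  Problem sizes are
desk-scale: one gelatin molecule (three 15-residue fibers) per cell and
20-unit PVA chains, with the protocol durations scaled down by ~10³.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .builder import BlendComposition, SimulationCell, pack_amorphous_cell
from .elasticity import (elastic_moduli, lame_from_stiffness,
                         stiffness_static)
from .engine import density, equilibrate_protocol, minimize
from .forcefield import ForceField, default_forcefield
from .observables import (donor_acceptor_density, energy_density,
                          fractional_free_volume, interaction_energy)

log = logging.getLogger(__name__)

DEFAULT_PVA_PERCENTS = (0.0, 40.0, 62.0, 70.0)   # modelled compositions
DEFAULT_PROTOCOL_SCALE = 1.0e-3
DEFAULT_INITIAL_DENSITY = 0.8     # g/cm³ at growth, before NPT relaxation


@dataclass
class BlendObservables:
    pva_target_percent: float
    pva_achieved_percent: float
    seed: int
    density_g_cm3: float
    ffv: float
    donor_acceptor_per_nm3: float
    young_gpa: float | None
    bulk_gpa: float | None
    lam_gpa: float | None
    mu_gpa: float | None
    e_density_bonded: float
    e_density_vdw: float
    e_density_electrostatic: float
    gelatin_gelatin_energy: float
    gelatin_pva_energy: float


def composition_for(pva_percent: float,
                    units_per_chain: int = 20) -> BlendComposition:
    if pva_percent == 0:
        return BlendComposition(n_gelatin_molecules=1, n_pva_chains=0,
                                pva_units_per_chain=units_per_chain,
                                target_pva_mass_percent=0.0)
    return BlendComposition.from_target(pva_percent,
                                        pva_units_per_chain=units_per_chain)


def prepare_blend_cell(pva_percent: float, seed: int,
                       scale: float = DEFAULT_PROTOCOL_SCALE,
                       initial_density: float = DEFAULT_INITIAL_DENSITY,
                       forcefield: ForceField | None = None,
                       units_per_chain: int = 20):
    """Pack, anneal and final-minimize one blend cell.

    Returns ``(cell, frames, stage_log)`` with the cell's system already
    relaxed at 298 K.
    """
    ff = forcefield if forcefield is not None else default_forcefield()
    comp = composition_for(pva_percent, units_per_chain)
    cell = pack_amorphous_cell(comp, seed=seed,
                               initial_density=initial_density,
                               forcefield=ff)
    system, frames, stage_log = equilibrate_protocol(
        cell.system, ff, scale=scale, seed=seed)
    res = minimize(system, ff, force_tol=0.2, max_iter=400, strict=False)
    cell = SimulationCell(system=res.system, composition=comp, seed=seed,
                          initial_density=initial_density,
                          max_force_after_min=res.max_force,
                          stage_log=stage_log)
    return cell, frames, stage_log


def measure_blend(cell: SimulationCell, frames,
                  forcefield: ForceField | None = None,
                  compute_stiffness: bool = True,
                  grid_spacing: float = 0.6) -> BlendObservables:
    ff = forcefield if forcefield is not None else default_forcefield()
    system = cell.system
    ffv = fractional_free_volume(system, probe_radius=0.0,
                                 grid_spacing=grid_spacing)
    da = donor_acceptor_density(system)
    inter = interaction_energy(system, ff)
    tail = frames[max(0, int(0.75 * len(frames))):]
    ed = {t: energy_density(tail, t).value
          for t in ("bonded", "vdw", "electrostatic")}
    young = bulk = lam = mu = None
    if compute_stiffness:
        C = stiffness_static(system, ff, force_tol=0.2,
                             max_minimize_iter=200)
        lame = lame_from_stiffness(C)
        moduli = elastic_moduli(C)
        young, bulk, lam, mu = (moduli.young, moduli.bulk,
                                lame.lam, lame.mu)
    return BlendObservables(
        pva_target_percent=cell.composition.target_pva_mass_percent,
        pva_achieved_percent=cell.composition.achieved_pva_mass_percent,
        seed=cell.seed,
        density_g_cm3=density(system),
        ffv=ffv.ffv,
        donor_acceptor_per_nm3=da.per_nm3,
        young_gpa=young, bulk_gpa=bulk, lam_gpa=lam, mu_gpa=mu,
        e_density_bonded=ed["bonded"],
        e_density_vdw=ed["vdw"],
        e_density_electrostatic=ed["electrostatic"],
        gelatin_gelatin_energy=inter.gelatin_gelatin,
        gelatin_pva_energy=inter.gelatin_pva,
    )


def pva_trend_study(pva_percents=DEFAULT_PVA_PERCENTS, seeds=(0, 1, 2),
                    scale: float = DEFAULT_PROTOCOL_SCALE,
                    compute_stiffness: bool = True,
                    forcefield: ForceField | None = None) -> pd.DataFrame:
    """Observables for every (composition, seed) pair as a DataFrame."""
    ff = forcefield if forcefield is not None else default_forcefield()
    rows = []
    for p in pva_percents:
        for seed in seeds:
            log.info("trend study: %.0f%% PVA, seed %d", p, seed)
            cell, frames, _ = prepare_blend_cell(p, seed, scale=scale,
                                                 forcefield=ff)
            obs = measure_blend(cell, frames, forcefield=ff,
                                compute_stiffness=compute_stiffness)
            rows.append(vars(obs))
    return pd.DataFrame(rows)


def trend_means(df: pd.DataFrame) -> pd.DataFrame:
    """Seed-averaged observables indexed by target PVA percent."""
    return df.groupby("pva_target_percent").mean(numeric_only=True)
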