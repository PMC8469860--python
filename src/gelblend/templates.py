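"""Monomer templates for gelatin residues and the vinyl-alcohol unit.

Representation: united-atom heavy sites (aliphatic hydrogens folded into
their carbon's mass) with *explicit* polar hydrogens on O and N — the
polar H are needed to classify hydrogen-bond donors.  Each template
carries rough local coordinates (relaxed later by minimization), partial
charges that sum to zero, and the internal bond list with per-bond
equilibrium lengths.

The gelatin model is a 15-residue fiber built from Pro, Gly, Hyp
(4-hydroxyproline), Glu, Gln, Ala and Lys; PVA is a chain of
–CH₂–CH(OH)– units, one hydroxyl per unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MASS
from .errors import ConfigurationError

_KIND_ELEMENT = {"N": "N", "O": "O", "H": "H", "C": "C",
                 "CH": "C", "CH2": "C", "CH3": "C"}

# bond force constants, kcal/(mol·Å²); gentler X-H springs keep 1 fs
# velocity-Verlet integration stable without constraints
K_BOND_HEAVY = 300.0
K_BOND_H = 250.0


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


@dataclass
class TemplateAtom:
    name: str
    kind: str           # united-atom kind, keys of constants.MASS
    charge: float
    xyz: np.ndarray

    @property
    def element(self) -> str:
        return _KIND_ELEMENT[self.kind]

    @property
    def mass(self) -> float:
        return MASS[self.kind]


@dataclass
class MonomerTemplate:
    """Building block: atoms, internal bonds and head/tail link sites."""

    name: str
    atoms: list[TemplateAtom]
    internal_bonds: list[tuple[int, int, float]]   # (i, j, r0)
    head: int
    tail: int
    out_dir: np.ndarray = field(default_factory=lambda: np.array([0.94, -0.34, 0.0]))
    link_r0: float = 1.33   # equilibrium length of the inter-unit bond

    def __post_init__(self):
        n = len(self.atoms)
        if not (0 <= self.head < n and 0 <= self.tail < n):
            raise ConfigurationError(f"{self.name}: link sites out of range")
        if self.head == self.tail and n > 1:
            raise ConfigurationError(f"{self.name}: link sites must be distinct")
        for i, j, _ in self.internal_bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ConfigurationError(f"{self.name}: bond ({i},{j}) invalid")
        if not np.isfinite(self.total_charge):
            raise ConfigurationError(f"{self.name}: non-finite total charge")
        self.out_dir = _unit(self.out_dir)

    @property
    def total_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    @property
    def mass(self) -> float:
        return float(sum(a.mass for a in self.atoms))

    def index(self, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.name == name:
                return i
        raise KeyError(name)


def _walk(parent_xyz, length, direction):
    return np.asarray(parent_xyz) + length * _unit(direction)


# ---------------------------------------------------------------------------
# shared backbone geometry (N at origin, chain advancing roughly along +x)
_N = np.zeros(3)
_CA = _walk(_N, 1.45, (0.94, 0.34, 0.0))
_C = _walk(_CA, 1.53, (0.94, -0.34, 0.0))
_O = _walk(_C, 1.23, (0.0, 0.55, 0.835))
_HN = _walk(_N, 1.01, (-0.51, 0.76, -0.43))

# side-chain walk directions (into ±z, marching -y)
_DA = _unit((0.0, -0.40, 0.92))
_DB = _unit((0.0, -0.92, -0.40))


def _backbone(ca_kind="CH", with_h=True):
    """Return (atoms, bonds) for the peptide backbone."""
    atoms = [TemplateAtom("N", "N", -0.40 if with_h else -0.30, _N.copy())]
    bonds = []
    if with_h:
        atoms.append(TemplateAtom("HN", "H", 0.25, _HN.copy()))
        bonds.append(("N", "HN", 1.01))
    atoms.append(TemplateAtom("CA", ca_kind, 0.10, _CA.copy()))
    bonds.append(("N", "CA", 1.45))
    atoms.append(TemplateAtom("C", "C", 0.45, _C.copy()))
    bonds.append(("CA", "C", 1.53))
    atoms.append(TemplateAtom("O", "O", -0.40, _O.copy()))
    bonds.append(("C", "O", 1.23))
    return atoms, bonds


def _finish(name, atoms, named_bonds):
    idx = {a.name: i for i, a in enumerate(atoms)}
    bonds = [(idx[a], idx[b], r0) for a, b, r0 in named_bonds]
    return MonomerTemplate(name=name, atoms=atoms, internal_bonds=bonds,
                           head=idx["N"], tail=idx["C"])


def _make_gly():
    atoms, bonds = _backbone(ca_kind="CH2")
    return _finish("Gly", atoms, bonds)


def _make_ala():
    atoms, bonds = _backbone()
    cb = _walk(_CA, 1.53, _DA)
    atoms.append(TemplateAtom("CB", "CH3", 0.0, cb))
    bonds.append(("CA", "CB", 1.53))
    return _finish("Ala", atoms, bonds)


def _make_pro(name="Pro"):
    atoms = [TemplateAtom("N", "N", -0.30, _N.copy()),
             TemplateAtom("CA", "CH", 0.10, _CA.copy())]
    cb = _walk(_CA, 1.53, _DA)
    cg = _walk(cb, 1.53, _DB)
    cd = np.array([0.655, -1.221, -0.509])   # closes the pyrrolidine ring
    atoms += [TemplateAtom("CB", "CH2", 0.0, cb),
              TemplateAtom("CG", "CH2", 0.0, cg),
              TemplateAtom("CD", "CH2", 0.15, cd),
              TemplateAtom("C", "C", 0.45, _C.copy()),
              TemplateAtom("O", "O", -0.40, _O.copy())]
    bonds = [("N", "CA", 1.45), ("CA", "CB", 1.53), ("CB", "CG", 1.53),
             ("CG", "CD", 1.53), ("CD", "N", 1.47),
             ("CA", "C", 1.53), ("C", "O", 1.23)]
    return _finish(name, atoms, bonds)


def _make_hyp():
    tpl = _make_pro(name="Hyp")
    atoms = list(tpl.atoms)
    cg_i = tpl.index("CG")
    atoms[cg_i] = TemplateAtom("CG", "CH", 0.20, atoms[cg_i].xyz)
    od = _walk(atoms[cg_i].xyz, 1.41, (0.7, -0.5, 0.5))
    hd = _walk(od, 0.96, (0.5, -0.5, 0.7))
    atoms += [TemplateAtom("OD1", "O", -0.60, od),
              TemplateAtom("HD1", "H", 0.40, hd)]
    named = [("N", "CA", 1.45), ("CA", "CB", 1.53), ("CB", "CG", 1.53),
             ("CG", "CD", 1.53), ("CD", "N", 1.47), ("CA", "C", 1.53),
             ("C", "O", 1.23), ("CG", "OD1", 1.41), ("OD1", "HD1", 0.96)]
    return _finish("Hyp", atoms, named)


def _make_glu():
    atoms, bonds = _backbone()
    cb = _walk(_CA, 1.53, _DA)
    cg = _walk(cb, 1.53, _DB)
    cd = _walk(cg, 1.52, _DA)
    oe1 = _walk(cd, 1.23, (0.85, -0.35, 0.4))
    oe2 = _walk(cd, 1.34, (-0.85, -0.45, 0.28))
    he2 = _walk(oe2, 0.96, (0.0, -0.9, 0.44))
    atoms += [TemplateAtom("CB", "CH2", 0.0, cb),
              TemplateAtom("CG", "CH2", 0.0, cg),
              TemplateAtom("CD", "C", 0.55, cd),
              TemplateAtom("OE1", "O", -0.45, oe1),
              TemplateAtom("OE2", "O", -0.55, oe2),
              TemplateAtom("HE2", "H", 0.45, he2)]
    bonds += [("CA", "CB", 1.53), ("CB", "CG", 1.53), ("CG", "CD", 1.52),
              ("CD", "OE1", 1.23), ("CD", "OE2", 1.34), ("OE2", "HE2", 0.96)]
    return _finish("Glu", atoms, bonds)


def _make_gln():
    atoms, bonds = _backbone()
    cb = _walk(_CA, 1.53, _DA)
    cg = _walk(cb, 1.53, _DB)
    cd = _walk(cg, 1.52, _DA)
    oe1 = _walk(cd, 1.23, (0.85, -0.35, 0.4))
    ne2 = _walk(cd, 1.33, (-0.85, -0.45, 0.28))
    he21 = _walk(ne2, 1.01, (0.0, -0.85, 0.53))
    he22 = _walk(ne2, 1.01, (-0.8, 0.2, 0.57))
    atoms += [TemplateAtom("CB", "CH2", 0.0, cb),
              TemplateAtom("CG", "CH2", 0.0, cg),
              TemplateAtom("CD", "C", 0.50, cd),
              TemplateAtom("OE1", "O", -0.50, oe1),
              TemplateAtom("NE2", "N", -0.70, ne2),
              TemplateAtom("HE21", "H", 0.35, he21),
              TemplateAtom("HE22", "H", 0.35, he22)]
    bonds += [("CA", "CB", 1.53), ("CB", "CG", 1.53), ("CG", "CD", 1.52),
              ("CD", "OE1", 1.23), ("CD", "NE2", 1.33),
              ("NE2", "HE21", 1.01), ("NE2", "HE22", 1.01)]
    return _finish("Gln", atoms, bonds)


def _make_lys():
    atoms, bonds = _backbone()
    cb = _walk(_CA, 1.53, _DA)
    cg = _walk(cb, 1.53, _DB)
    cd = _walk(cg, 1.53, _DA)
    ce = _walk(cd, 1.53, _DB)
    nz = _walk(ce, 1.47, _DA)
    hz1 = _walk(nz, 1.01, (0.6, -0.6, 0.53))
    hz2 = _walk(nz, 1.01, (-0.6, -0.6, 0.53))
    atoms += [TemplateAtom("CB", "CH2", 0.0, cb),
              TemplateAtom("CG", "CH2", 0.0, cg),
              TemplateAtom("CD", "CH2", 0.0, cd),
              TemplateAtom("CE", "CH2", 0.10, ce),
              TemplateAtom("NZ", "N", -0.80, nz),
              TemplateAtom("HZ1", "H", 0.35, hz1),
              TemplateAtom("HZ2", "H", 0.35, hz2)]
    bonds += [("CA", "CB", 1.53), ("CB", "CG", 1.53), ("CG", "CD", 1.53),
              ("CD", "CE", 1.53), ("CE", "NZ", 1.47),
              ("NZ", "HZ1", 1.01), ("NZ", "HZ2", 1.01)]
    return _finish("Lys", atoms, bonds)


def _make_vinyl_alcohol():
    c2 = np.zeros(3)
    c1 = _walk(c2, 1.53, (0.94, 0.34, 0.0))
    o = _walk(c1, 1.41, (0.0, -0.45, 0.89))
    h = _walk(o, 0.96, (0.6, -0.6, 0.53))
    atoms = [TemplateAtom("C2", "CH2", 0.0, c2),
             TemplateAtom("C1", "CH", 0.20, c1),
             TemplateAtom("OH", "O", -0.60, o),
             TemplateAtom("HO", "H", 0.40, h)]
    bonds = [(0, 1, 1.53), (1, 2, 1.41), (2, 3, 0.96)]
    return MonomerTemplate(name="VAL-unit", atoms=atoms, internal_bonds=bonds,
                           head=0, tail=1, link_r0=1.53)


AMINO_TEMPLATES: dict[str, MonomerTemplate] = {
    t.name: t for t in (_make_gly(), _make_ala(), _make_pro(), _make_hyp(),
                        _make_glu(), _make_gln(), _make_lys())
}

VINYL_ALCOHOL: MonomerTemplate = _make_vinyl_alcohol()


def get_residue_template(name: str) -> MonomerTemplate:
    try:
        return AMINO_TEMPLATES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown residue name {name!r}; available: "
            f"{sorted(AMINO_TEMPLATES)}") from None
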