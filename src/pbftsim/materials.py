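"""Elemental compositions, densities and nuclide inventories.

The simulator distinguishes four physical media: cell cytoplasm, cell
nucleus, the water-like buffer slab above the cell monolayer, and ambient
air.  Cytoplasm and nucleus share the same five-element soft-tissue recipe
at 1.27 g/cm^3; the buffer is water (H/O) at 1.00 g/cm^3.  A fifth,
hypothetical hydrogen-only medium serves as a null control: it contains no
boron, carbon, nitrogen or oxygen targets, so no alpha-producing nuclear
channel can fire in it.

Boron loading is expressed in mass parts-per-million (ppm) of natural boron
(19.9 atom-% B-10, 80.1 atom-% B-11).  Mixing follows the fixed-density
rule: the boron weight fraction is ppm*1e-6, all base fractions are rescaled
by (1 - ppm*1e-6), and the density is left unchanged.  A consequence worth
noting is that mass thickness and geometric thickness of a boron-loaded
buffer coincide with the unloaded one, so no thickness correction is needed
when comparing loaded and unloaded arms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Mapping

AVOGADRO = 6.02214076e23  # atoms/mol

# Standard atomic weights (g/mol).  Isotopically pure entries use the
# isotope mass; "B" is natural boron.
ATOMIC_MASS: Dict[str, float] = {
    "H": 1.00794,
    "B": 10.811,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "Ar": 39.948,
}

ATOMIC_NUMBER: Dict[str, int] = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "P": 15, "Ar": 18,
}

# Mean excitation energies, eV (ICRU-style elemental values).
MEAN_EXCITATION_EV: Dict[str, float] = {
    "H": 19.2, "B": 76.0, "C": 78.0, "N": 82.0, "O": 95.0,
    "P": 173.0, "Ar": 188.0,
}

#: natural boron isotopic atom fractions
B10_ATOM_FRACTION = 0.199
B11_ATOM_FRACTION = 0.801

_FRACTION_TOL = 1e-9


class MaterialError(ValueError):
    """Invalid material composition or unknown material name."""


@dataclass(frozen=True)
class MaterialComposition:
    """Elemental weight fractions plus bulk density.

    Fractions must be non-negative and sum to 1 within 1e-9; density is in
    g/cm^3 and must be positive.
    """

    name: str
    fractions: Mapping[str, float]
    density: float

    def __post_init__(self):
        fr = dict(self.fractions)
        for el, w in fr.items():
            if el not in ATOMIC_MASS:
                raise MaterialError(f"unknown element {el!r} in {self.name!r}")
            if w < 0:
                raise MaterialError(f"negative fraction for {el!r} in {self.name!r}")
        total = sum(fr.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise MaterialError(
                f"fractions of {self.name!r} sum to {total!r}, expected 1"
            )
        if self.density <= 0:
            raise MaterialError(f"density of {self.name!r} must be > 0")
        object.__setattr__(self, "fractions", fr)

    def fraction(self, element: str) -> float:
        return self.fractions.get(element, 0.0)

    def to_json(self) -> str:
        return json.dumps(
            {"name": self.name, "density": self.density,
             "fractions": dict(self.fractions)},
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "MaterialComposition":
        d = json.loads(text)
        return cls(name=d["name"], fractions=d["fractions"], density=d["density"])

    @classmethod
    def load(cls, path: str | Path) -> "MaterialComposition":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


@dataclass(frozen=True)
class NuclideInventory:
    """Atom number densities (atoms/cm^3) keyed by nuclide label.

    Natural boron is split into B10/B11 by atom fraction; every other
    element of the composition maps to its single dominant isotope
    (H1, C12, N14, O16, P31, Ar40).
    """

    densities: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        d = dict(self.densities)
        for k, v in d.items():
            if v < 0:
                raise MaterialError(f"negative number density for {k!r}")
        object.__setattr__(self, "densities", d)

    def get(self, nuclide: str) -> float:
        return self.densities.get(nuclide, 0.0)


_ELEMENT_TO_NUCLIDE = {
    "H": "H1", "C": "C12", "N": "N14", "O": "O16", "P": "P31", "Ar": "Ar40",
}

_BUILTINS: Dict[str, MaterialComposition] = {
    "cytoplasm": MaterialComposition(
        "cytoplasm",
        {"H": 0.1064, "O": 0.745, "C": 0.0904, "N": 0.0321, "P": 0.0261},
        1.27,
    ),
    "nucleus": MaterialComposition(
        "nucleus",
        {"H": 0.1064, "O": 0.745, "C": 0.0904, "N": 0.0321, "P": 0.0261},
        1.27,
    ),
    "buffer": MaterialComposition("buffer", {"H": 0.111, "O": 0.889}, 1.00),
    # standard dry air near sea level
    "air": MaterialComposition(
        "air", {"N": 0.755, "O": 0.232, "Ar": 0.013}, 1.205e-3
    ),
    # hypothetical null-control medium: hydrogen only, no alpha-producing targets
    "hydrogen_only": MaterialComposition("hydrogen_only", {"H": 1.0}, 1.00),
}


def builtin_material(name: str) -> MaterialComposition:
    """Return one of the built-in media by name.

    Valid names: ``cytoplasm``, ``nucleus``, ``buffer``, ``air``,
    ``hydrogen_only``.  Cytoplasm and nucleus are identical recipes.
    """
    try:
        return _BUILTINS[name]
    except KeyError:
        raise MaterialError(
            f"unknown material {name!r}; choose from {sorted(_BUILTINS)}"
        ) from None


def mix_boron(base: MaterialComposition, ppm: float) -> MaterialComposition:
    """Homogeneously mix natural boron into *base* at *ppm* by mass.

    The boron weight fraction becomes ppm*1e-6, existing fractions are
    rescaled by (1 - ppm*1e-6) and the density is held fixed.
    """
    if ppm < 0:
        raise MaterialError(f"ppm must be >= 0, got {ppm}")
    if ppm == 0:
        return base
    wb = ppm * 1e-6
    if wb > 1.0:
        raise MaterialError(f"ppm={ppm} exceeds 1e6 (pure boron)")
    scale = 1.0 - wb
    fr = {el: w * scale for el, w in base.fractions.items()}
    fr["B"] = fr.get("B", 0.0) + wb
    if wb == 1.0:
        fr = {"B": 1.0}
    return MaterialComposition(
        name=f"{base.name}+{ppm:g}ppmB", fractions=fr, density=base.density
    )


def number_densities(comp: MaterialComposition) -> NuclideInventory:
    """Convert weight fractions to nuclide number densities.

    N_i = rho * w_i * N_A / A_i; natural boron is split 19.9/80.1 atom-%
    into B10/B11.
    """
    dens: Dict[str, float] = {}
    for el, w in comp.fractions.items():
        n = comp.density * w * AVOGADRO / ATOMIC_MASS[el]
        if el == "B":
            dens["B10"] = dens.get("B10", 0.0) + n * B10_ATOM_FRACTION
            dens["B11"] = dens.get("B11", 0.0) + n * B11_ATOM_FRACTION
        else:
            key = _ELEMENT_TO_NUCLIDE[el]
            dens[key] = dens.get(key, 0.0) + n
    return NuclideInventory(dens)


def with_density(comp: MaterialComposition, density: float) -> MaterialComposition:
    return replace(comp, density=density)
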