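"""PHITS-style input-deck export.

Writes a structurally valid PHITS input deck for the configured cell
array: one RPP surface per cell and per nucleus plus the buffer slab and
ambient sphere, cell cards with per-cell material assignment reflecting
the boron flags, a disk source (monoenergetic or SOBP energy table), and
T-Track / T-Deposit / T-Gshow tally sections covering the array.  The
deck is a pure function of (config, geometry): fixed seed, fixed text.
Formatting parity with any particular external generator is not promised;
decks are meant to be structurally correct and human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List

from .config import SimulationConfig
from .geometry import Geometry
from .materials import MaterialComposition
from .transport import M_AIR, M_BUFFER, M_CYTO, M_CYTO_B, M_NUC, M_NUC_B, \
    TransportMedia, make_source

SECTION_ORDER = ("Title", "Parameters", "Source", "Material", "Surface",
                 "Cell", "T-Track", "T-Deposit", "T-Gshow")

_ELEMENT_Z = {"H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "P": 15, "Ar": 18}


@dataclass
class PhitsDeck:
    """Ordered named text sections of a PHITS input deck."""

    sections: Dict[str, str] = field(default_factory=dict)

    @property
    def text(self) -> str:
        parts = []
        for name in SECTION_ORDER:
            if name in self.sections:
                parts.append(f"[ {name} ]")
                parts.append(self.sections[name].rstrip("\n"))
        return "\n".join(parts) + "\n"

    @property
    def line_count(self) -> int:
        return self.text.count("\n")

    def save(self, path) -> None:
        Path(path).write_text(self.text)


def _material_card(idx: int, comp: MaterialComposition) -> List[str]:
    lines = [f"mat[{idx}]  $ {comp.name}  rho={comp.density:g} g/cm3"]
    for el, w in sorted(comp.fractions.items()):
        z = _ELEMENT_Z[el]
        # negative entries denote mass fractions in PHITS convention
        lines.append(f"    {z:>3d}000  -{w:.6g}")
    return lines


def export_phits_deck(config: SimulationConfig, geometry: Geometry,
                      media: TransportMedia | None = None) -> PhitsDeck:
    """Build the PHITS-style deck for *config*/*geometry*."""
    if media is None:
        media = TransportMedia(config)
    n = geometry.n
    deck = PhitsDeck()

    deck.sections["Title"] = (
        f"monolayer cell array {n}x{n} for proton boron fusion therapy study"
    )
    deck.sections["Parameters"] = "\n".join([
        " icntl   = 0",
        f" maxcas  = {config.maxcas}",
        f" maxbch  = {config.maxbch}",
        " negs    = 0",
        f" $ omp parallelization flag (metadata): {config.omp}",
        f" $ rng seed: {config.seed}",
    ])

    src = make_source(config, media)
    src_lines = [
        " s-type = 1        $ disk (pencil-axis cylinder) source",
        " proj   = proton",
        f" r0     = {config.r0 / 10.0:.6g}   $ cm",
        f" z0     = {config.tbuffer / 1e4:.6g}",
        f" z1     = {config.tbuffer / 1e4:.6g}",
        " dir    = -1.0",
    ]
    if config.sobp == 1:
        src_lines.append(" e-type = 1")
        src_lines.append(f" ne     = {len(src.energies)}")
        for e_k, w_k in zip(src.energies, src.weights):
            src_lines.append(f"   {e_k:.4f}  {w_k:.6e}")
    else:
        src_lines.append(f" e0     = {config.e0:.4f}")
    deck.sections["Source"] = "\n".join(src_lines)

    mat_ids = {M_CYTO: 1, M_CYTO_B: 2, M_NUC: 3, M_NUC_B: 4,
               M_BUFFER: 5, M_AIR: 6}
    mat_lines: List[str] = []
    used = {M_BUFFER, M_AIR}
    for i in range(n):
        for j in range(n):
            used.add(M_CYTO_B if geometry.borcheck[i, j] else M_CYTO)
            used.add(M_NUC_B if geometry.nucleus_boron(i, j) else M_NUC)
    for mid in sorted(used, key=lambda m: mat_ids[m]):
        mat_lines.extend(_material_card(mat_ids[mid], media.compositions[mid]))
    deck.sections["Material"] = "\n".join(mat_lines)

    # surfaces: µm -> cm
    def rpp(sid, b):
        x0, x1, y0, y1, z0, z1 = (v / 1e4 for v in b)
        return (f"{sid:<6d} rpp  {x0:.6g} {x1:.6g}  {y0:.6g} {y1:.6g}  "
                f"{z0:.6g} {z1:.6g}")

    surf_lines = [f"10     so   {config.airad:.6g}"]
    half = geometry.half
    surf_lines.append(rpp(11, (-half, half, -half, half, 0.0, config.tbuffer)))
    cell_sid = {}
    nuc_sid = {}
    sid = 1000
    for i in range(n):
        for j in range(n):
            cell_sid[i, j] = sid
            surf_lines.append(rpp(sid, geometry.cell_bounds(i, j, "cytoplasm")))
            sid += 1
            nuc_sid[i, j] = sid
            surf_lines.append(rpp(sid, geometry.cell_bounds(i, j, "nucleus")))
            sid += 1
    deck.sections["Surface"] = "\n".join(surf_lines)

    cell_lines = []
    cid = 100
    buf = media.compositions[M_BUFFER]
    air = media.compositions[M_AIR]
    cell_lines.append(f"{cid:<5d} {mat_ids[M_BUFFER]} -{buf.density:g}  -11")
    cid += 1
    box_refs = ["+11"]
    for i in range(n):
        for j in range(n):
            cmat = M_CYTO_B if geometry.borcheck[i, j] else M_CYTO
            nmat = M_NUC_B if geometry.nucleus_boron(i, j) else M_NUC
            cdens = media.compositions[cmat].density
            ndens = media.compositions[nmat].density
            cell_lines.append(
                f"{cid:<5d} {mat_ids[cmat]} -{cdens:g}  "
                f"-{cell_sid[i, j]} +{nuc_sid[i, j]}")
            cid += 1
            cell_lines.append(
                f"{cid:<5d} {mat_ids[nmat]} -{ndens:g}  -{nuc_sid[i, j]}")
            cid += 1
            box_refs.append(f"+{cell_sid[i, j]}")
    # ambient air: inside sphere, outside buffer and all cell boxes
    cell_lines.append(f"{cid:<5d} {mat_ids[M_AIR]} -{air.density:g}  -10 "
                      + " ".join(box_refs))
    cid += 1
    cell_lines.append(f"{cid:<5d} -1  +10   $ outer void")
    deck.sections["Cell"] = "\n".join(cell_lines)

    hx = half / 1e4
    tz = config.tcell / 1e4
    mesh = "\n".join([
        " mesh = xyz",
        f" xmin = {-hx:.6g}  xmax = {hx:.6g}  nx = {n}",
        f" ymin = {-hx:.6g}  ymax = {hx:.6g}  ny = {n}",
        f" zmin = {-tz:.6g}  zmax = 0.0  nz = 30",
    ])
    deck.sections["T-Track"] = "\n".join([
        mesh, " part = proton neutron alpha",
        " e-type = 1", " unit = 1", " axis = xy",
        " file = track.out",
    ])
    deck.sections["T-Deposit"] = "\n".join([
        mesh, " part = proton neutron alpha",
        " output = dose", " unit = 1", " axis = xy",
        " file = deposit.out",
    ])
    deck.sections["T-Gshow"] = "\n".join([
        " mesh = xyz",
        f" xmin = {-hx:.6g}  xmax = {hx:.6g}  nx = 400",
        " ymin = 0 ymax = 0 ny = 1",
        f" zmin = {-tz:.6g}  zmax = {config.tbuffer / 1e4:.6g}  nz = 400",
        " axis = xz", " output = 3", " file = gshow.out",
    ])
    return deck
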