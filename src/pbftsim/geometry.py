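"""Cell-array geometry: a monolayer of box cells under a buffer slab,
inside an ambient air sphere.

Coordinate convention (micrometres): the beam travels along -z.  z = 0 is
the buffer/cell interface; the cell layer occupies z in [-tcell, 0) and the
buffer slab z in [0, tbuffer).  The n x n array is centred on the beam axis
(x = y = 0), cells packed at 100% confluence (shared faces, no gaps).  Each
cell is an axis-aligned box with a centred cubic nucleus of side lnuc; the
cytoplasm is the cell box minus the nucleus box.  All boxes are half-open
[min, max) per axis so every point belongs to exactly one region.

Region identifiers are tuples::

    ("ambient",)                      air inside the sphere
    ("buffer",)                       buffer slab
    ("cell", i, j, "cytoplasm")       0 <= i, j < n
    ("cell", i, j, "nucleus")
    ("escaped",)                      outside the ambient sphere
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .config import ConfigError, SimulationConfig

RegionId = Tuple
AMBIENT: RegionId = ("ambient",)
BUFFER: RegionId = ("buffer",)
ESCAPED: RegionId = ("escaped",)

_EPS = 1e-9


@dataclass(frozen=True)
class CellRegion:
    """One subdomain (cytoplasm or nucleus) of one cell.

    ``bounds`` is the enclosing box; for the cytoplasm the nucleus box is
    carved out, so ``hollow_volume`` holds the nucleus volume to subtract.
    """

    i: int
    j: int
    subdomain: str  # "cytoplasm" | "nucleus"
    bounds: Tuple[float, float, float, float, float, float]  # xmin..zmax, µm
    borcheck: int
    material: str
    hollow_volume: float = 0.0

    @property
    def region_id(self) -> RegionId:
        return ("cell", self.i, self.j, self.subdomain)

    @property
    def volume(self) -> float:
        x0, x1, y0, y1, z0, z1 = self.bounds
        return (x1 - x0) * (y1 - y0) * (z1 - z0) - self.hollow_volume


@dataclass
class Geometry:
    """Built cell-array geometry with point-to-region lookup."""

    config: SimulationConfig
    borcheck: np.ndarray  # (n, n) uint8, cytoplasm boron flags

    n: int = field(init=False)
    lcell: float = field(init=False)
    half: float = field(init=False)          # array half-width, µm
    nuc_half: float = field(init=False)
    nuc_zlo: float = field(init=False)
    nuc_zhi: float = field(init=False)
    airad_um: float = field(init=False)

    def __post_init__(self):
        c = self.config
        self.n = int(c.n)
        self.lcell = c.lcell
        self.half = self.n * c.lcell / 2.0
        self.nuc_half = c.lnuc / 2.0
        # nucleus centred in z within [-tcell, 0)
        self.nuc_zlo = -(c.tcell + c.lnuc) / 2.0
        self.nuc_zhi = -(c.tcell - c.lnuc) / 2.0
        self.airad_um = c.airad * 1e4
        if self.borcheck.shape != (self.n, self.n):
            raise ConfigError(f"invalid 'cytob' flags: borcheck shape "
                              f"{self.borcheck.shape} != ({self.n}, {self.n})")

    # -- index helpers ----------------------------------------------------
    def cell_origin(self, i: int, j: int) -> Tuple[float, float]:
        return (-self.half + i * self.lcell, -self.half + j * self.lcell)

    def cell_center(self, i: int, j: int) -> Tuple[float, float]:
        x0, y0 = self.cell_origin(i, j)
        return (x0 + self.lcell / 2.0, y0 + self.lcell / 2.0)

    def nucleus_boron(self, i: int, j: int) -> int:
        """Nucleus inherits the cytoplasm flag only when nuclb is on."""
        return int(self.borcheck[i, j]) if self.config.nuclb == 1 else 0

    # -- lookup -----------------------------------------------------------
    def locate(self, point) -> RegionId:
        x, y, z = (float(v) for v in point)
        if x * x + y * y + z * z >= self.airad_um ** 2:
            return ESCAPED
        c = self.config
        if 0.0 <= z < c.tbuffer and -self.half <= x < self.half \
                and -self.half <= y < self.half:
            return BUFFER
        if -c.tcell <= z < 0.0 and -self.half <= x < self.half \
                and -self.half <= y < self.half:
            i = int((x + self.half) // self.lcell)
            j = int((y + self.half) // self.lcell)
            i = min(i, self.n - 1)
            j = min(j, self.n - 1)
            xc, yc = self.cell_center(i, j)
            if (xc - self.nuc_half <= x < xc + self.nuc_half and
                    yc - self.nuc_half <= y < yc + self.nuc_half and
                    self.nuc_zlo <= z < self.nuc_zhi):
                return ("cell", i, j, "nucleus")
            return ("cell", i, j, "cytoplasm")
        return AMBIENT

    # -- ray tracing ------------------------------------------------------
    def _box_exit(self, pos, dirn, lo, hi) -> float:
        """Distance to exit an axis-aligned box from inside (µm)."""
        t = np.inf
        for k in range(3):
            d = dirn[k]
            if d > _EPS:
                t = min(t, (hi[k] - pos[k]) / d)
            elif d < -_EPS:
                t = min(t, (lo[k] - pos[k]) / d)
        return max(t, 0.0)

    def _box_entry(self, pos, dirn, lo, hi) -> float:
        """Distance to enter an axis-aligned box from outside; inf if the
        ray misses."""
        tmin, tmax = 0.0, np.inf
        for k in range(3):
            d = dirn[k]
            if abs(d) < _EPS:
                if pos[k] < lo[k] or pos[k] >= hi[k]:
                    return np.inf
            else:
                t0 = (lo[k] - pos[k]) / d
                t1 = (hi[k] - pos[k]) / d
                if t0 > t1:
                    t0, t1 = t1, t0
                tmin = max(tmin, t0)
                tmax = min(tmax, t1)
        return tmin if tmin < tmax else np.inf

    def _sphere_exit(self, pos, dirn) -> float:
        b = float(np.dot(pos, dirn))
        c0 = float(np.dot(pos, pos)) - self.airad_um ** 2
        disc = b * b - c0
        if disc <= 0:
            return 0.0
        return -b + np.sqrt(disc)

    def cell_bounds(self, i, j, subdomain):
        c = self.config
        x0, y0 = self.cell_origin(i, j)
        if subdomain == "nucleus":
            xc, yc = self.cell_center(i, j)
            return (xc - self.nuc_half, xc + self.nuc_half,
                    yc - self.nuc_half, yc + self.nuc_half,
                    self.nuc_zlo, self.nuc_zhi)
        return (x0, x0 + self.lcell, y0, y0 + self.lcell, -c.tcell, 0.0)

    def distance_to_boundary(self, pos, dirn, region: RegionId) -> float:
        """Distance (µm) along *dirn* to the first surface at which the
        region changes."""
        pos = np.asarray(pos, dtype=float)
        dirn = np.asarray(dirn, dtype=float)
        c = self.config
        if region == ESCAPED:
            return np.inf
        if region == AMBIENT:
            cand = [self._sphere_exit(pos, dirn)]
            # bounding box of buffer + cell layer
            lo = (-self.half, -self.half, -c.tcell)
            hi = (self.half, self.half, c.tbuffer)
            cand.append(self._box_entry(pos, dirn, lo, hi))
            return min(cand)
        if region == BUFFER:
            lo = (-self.half, -self.half, 0.0)
            hi = (self.half, self.half, c.tbuffer)
            return self._box_exit(pos, dirn, lo, hi)
        _, i, j, sub = region
        b = self.cell_bounds(i, j, sub)
        lo, hi = (b[0], b[2], b[4]), (b[1], b[3], b[5])
        if sub == "nucleus":
            return self._box_exit(pos, dirn, lo, hi)
        # cytoplasm: leave the cell box or enter the nucleus box
        d_exit = self._box_exit(pos, dirn, lo, hi)
        nb = self.cell_bounds(i, j, "nucleus")
        d_nuc = self._box_entry(pos, dirn, (nb[0], nb[2], nb[4]),
                                (nb[1], nb[3], nb[5]))
        return min(d_exit, d_nuc)

    # -- region list / export --------------------------------------------
    def regions(self) -> List[CellRegion]:
        out = []
        nuc_vol = self.config.lnuc ** 3
        for i in range(self.n):
            for j in range(self.n):
                bor = int(self.borcheck[i, j])
                nbor = self.nucleus_boron(i, j)
                out.append(CellRegion(
                    i, j, "cytoplasm", self.cell_bounds(i, j, "cytoplasm"),
                    bor, "cytoplasm+B" if bor else "cytoplasm",
                    hollow_volume=nuc_vol))
                out.append(CellRegion(
                    i, j, "nucleus", self.cell_bounds(i, j, "nucleus"),
                    nbor, "nucleus+B" if nbor else "nucleus"))
        return out

    def to_json(self) -> str:
        return json.dumps(
            [{"id": list(r.region_id), "bounds": list(r.bounds),
              "subdomain": r.subdomain, "borcheck": r.borcheck,
              "material": r.material} for r in self.regions()],
            indent=1,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @property
    def boron_fraction(self) -> float:
        return float(np.mean(self.borcheck))


def assign_boron(config: SimulationConfig,
                 rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-cell cytoplasm boron flags (n, n) according to ``cytob``.

    Mode 0: no boron; mode 1: every cell; mode 2: a cell is boron-filled
    iff its uniform(0,1) draw falls below ``boron_threshold`` (0.5 by
    default).  Draws are consumed in row-major cell order so a fixed seed
    reproduces a layout exactly.
    """
    n = int(config.n)
    if config.cytob == 0:
        return np.zeros((n, n), dtype=np.uint8)
    if config.cytob == 1:
        return np.ones((n, n), dtype=np.uint8)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    draws = rng.random(n * n)
    return (draws < config.boron_threshold).astype(np.uint8).reshape(n, n)


def build_geometry(config: SimulationConfig,
                   rng: Optional[np.random.Generator] = None) -> Geometry:
    """Validate *config* and build the cell-array geometry with boron
    flags assigned per ``cytob``."""
    config.validate()
    flags = assign_boron(config, rng)
    return Geometry(config=config, borcheck=flags)


def locate_region(geometry: Geometry, point) -> RegionId:
    """Map a point (µm) to its unique region id (``("escaped",)`` outside
    the ambient sphere)."""
    return geometry.locate(point)


def render_boron_grid(geometry: Geometry) -> str:
    """Terminal rendering of the boron layout, one glyph per cell.

    ``.`` normal cell; ``b`` boron-filled cytoplasm with normal nucleus;
    ``B`` boron-filled cytoplasm and nucleus (nuclb on).  Rows are printed
    with j increasing upward so the text matches a beam's-eye plot.
    """
    n = geometry.n
    rows = []
    for j in range(n - 1, -1, -1):
        row = []
        for i in range(n):
            if geometry.borcheck[i, j]:
                row.append("B" if geometry.nucleus_boron(i, j) else "b")
            else:
                row.append(".")
        rows.append(" ".join(row))
    return "\n".join(rows)


def plot_boron_grid(geometry: Geometry, path=None):
    """Beam's-eye colour plot of the boron layout (matplotlib figure).

    Four-way colouring: cytoplasm normal/boron as the cell face, nucleus
    normal/boron as an inset square.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    n, L = geometry.n, geometry.lcell
    fig, ax = plt.subplots(figsize=(6, 6))
    for i in range(n):
        for j in range(n):
            x0, y0 = geometry.cell_origin(i, j)
            cyt = "#ffd54f" if geometry.borcheck[i, j] else "#64b5f6"
            nuc = "#66bb6a" if geometry.nucleus_boron(i, j) else "#ef9a9a"
            ax.add_patch(Rectangle((x0, y0), L, L, facecolor=cyt,
                                   edgecolor="k", linewidth=0.3))
            h = geometry.nuc_half
            xc, yc = geometry.cell_center(i, j)
            ax.add_patch(Rectangle((xc - h, yc - h), 2 * h, 2 * h,
                                   facecolor=nuc, edgecolor="none"))
    ax.set_xlim(-geometry.half, geometry.half)
    ax.set_ylim(-geometry.half, geometry.half)
    ax.set_aspect("equal")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_title("cytoplasm: blue=normal / yellow=boron; "
                 "nucleus: red=normal / green=boron", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
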