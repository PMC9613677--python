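"""Tally containers and derived statistics.

The simulator scores, per batch: energy deposition per cell subdomain
(cytoplasm/nucleus of every cell) and per bulk region (buffer, ambient
air) for protons, alphas and heavy recoils; escaped energy per species;
reaction and production counters (N13, C11, neutron births); and the full
alpha track-segment list.  Derived quantities follow the analysis a
cell-irradiation study needs: axial alpha depth-dose profiles with batch
standard errors, alpha hit counts per subdomain with (lower, average,
upper) bounds over repeated runs, the boron/normal enhancement factor,
and the alpha energy-deposition fraction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import SimulationConfig
from .geometry import Geometry
from .transport import AlphaTrack, TrackSegment

SPECIES = ("proton", "alpha", "recoil")


@dataclass
class TallyResults:
    """Batch-resolved simulation results.

    Deposition arrays are raw MeV per batch; divide by ``maxcas`` (or use
    :meth:`per_source`) for the per-source-particle normalization under
    which the analysis quantities are defined.
    """

    config: SimulationConfig
    hydrogen_only: bool
    nbatches: int
    maxcas: int
    #: (B, n, n, 2) MeV; last axis 0=cytoplasm, 1=nucleus
    cell_dep: Dict[str, np.ndarray]
    buffer_dep: Dict[str, np.ndarray]   # (B,)
    ambient_dep: Dict[str, np.ndarray]  # (B,)
    escaped: Dict[str, np.ndarray]      # (B,) incl. "neutron"
    counters: Dict[str, np.ndarray]     # (B,)
    source_energy: np.ndarray           # (B,)
    q_released: np.ndarray              # (B,)
    alpha_tracks: List[AlphaTrack]
    depth_dose: Optional[np.ndarray] = None       # (B, nbins) proton MeV
    depth_bin_edges: Optional[np.ndarray] = None  # z µm

    # -- construction -----------------------------------------------------
    @classmethod
    def from_batches(cls, config, geometry, media, source, batches, tracks,
                     hydrogen_only=False, depth_dose_bins=None):
        nb = len(batches)
        n = geometry.n
        cell = {sp: np.stack([b.cell[sp].reshape(n, n, 2) for b in batches])
                for sp in SPECIES}
        buf = {sp: np.array([b.buffer[sp] for b in batches]) for sp in SPECIES}
        amb = {sp: np.array([b.ambient[sp] for b in batches]) for sp in SPECIES}
        esc = {sp: np.array([b.escaped[sp] for b in batches])
               for sp in ("proton", "alpha", "neutron")}
        names = sorted({k for b in batches for k in b.counters})
        counters = {k: np.array([b.counters.get(k, 0.0) for b in batches])
                    for k in names}
        dd = None
        if depth_dose_bins is not None:
            dd = np.stack([b.depth_dose for b in batches])
        return cls(
            config=config, hydrogen_only=hydrogen_only, nbatches=nb,
            maxcas=config.maxcas, cell_dep=cell, buffer_dep=buf,
            ambient_dep=amb, escaped=esc, counters=counters,
            source_energy=np.array([b.source_energy for b in batches]),
            q_released=np.array([b.q_released for b in batches]),
            alpha_tracks=list(tracks), depth_dose=dd,
            depth_bin_edges=depth_dose_bins,
        )

    # -- convenience ------------------------------------------------------
    def cell_total(self, species: str) -> np.ndarray:
        """Total deposition in the whole cell array per batch, MeV."""
        return self.cell_dep[species].sum(axis=(1, 2, 3))

    def cell_total_per_source(self, species: str) -> np.ndarray:
        return self.cell_total(species) / self.maxcas

    def nucleus_total(self, species: str) -> np.ndarray:
        return self.cell_dep[species][..., 1].sum(axis=(1, 2))

    def cytoplasm_total(self, species: str) -> np.ndarray:
        return self.cell_dep[species][..., 0].sum(axis=(1, 2))

    def batch_mean_se(self, per_batch: np.ndarray) -> Tuple[float, float]:
        m = float(np.mean(per_batch))
        if len(per_batch) < 2:
            return m, float("nan")
        se = float(np.std(per_batch, ddof=1) / np.sqrt(len(per_batch)))
        return m, se

    def conservation_residual(self) -> np.ndarray:
        """Per-batch energy-ledger residual, MeV:
        source + q_released - deposits - escapes (should be ~0)."""
        dep = np.zeros(self.nbatches)
        for sp in SPECIES:
            dep = dep + self.cell_total(sp) + self.buffer_dep[sp] \
                + self.ambient_dep[sp]
        esc = sum(self.escaped[sp] for sp in self.escaped)
        return self.source_energy + self.q_released - dep - esc

    def counter_total(self, name: str) -> float:
        return float(self.counters.get(name, np.zeros(1)).sum())

    # -- persistence ------------------------------------------------------
    def to_dict(self, include_tracks: bool = True) -> dict:
        d = {
            "config": self.config.to_dict(),
            "hydrogen_only": self.hydrogen_only,
            "nbatches": self.nbatches,
            "maxcas": self.maxcas,
            "cell_dep": {k: v.tolist() for k, v in self.cell_dep.items()},
            "buffer_dep": {k: v.tolist() for k, v in self.buffer_dep.items()},
            "ambient_dep": {k: v.tolist() for k, v in self.ambient_dep.items()},
            "escaped": {k: v.tolist() for k, v in self.escaped.items()},
            "counters": {k: v.tolist() for k, v in self.counters.items()},
            "source_energy": self.source_energy.tolist(),
            "q_released": self.q_released.tolist(),
        }
        if include_tracks:
            d["alpha_tracks"] = [
                {"batch": t.batch, "history": t.history,
                 "birth_energy": t.birth_energy,
                 "birth_region": list(t.birth_region),
                 "segments": [
                     {"start": s.start.tolist(), "end": s.end.tolist(),
                      "region": list(s.region), "e_deposit": s.e_deposit,
                      "e_start": s.e_start} for s in t.segments]}
                for t in self.alpha_tracks
            ]
        if self.depth_dose is not None:
            d["depth_dose"] = self.depth_dose.tolist()
            d["depth_bin_edges"] = self.depth_bin_edges.tolist()
        return d

    def save(self, path, include_tracks: bool = True) -> None:
        Path(path).write_text(json.dumps(self.to_dict(include_tracks)))

    @classmethod
    def from_dict(cls, d: dict) -> "TallyResults":
        tracks = []
        for t in d.get("alpha_tracks", []):
            segs = [TrackSegment(np.array(s["start"]), np.array(s["end"]),
                                 tuple(s["region"]), "alpha",
                                 s["e_deposit"], s["e_start"])
                    for s in t["segments"]]
            tracks.append(AlphaTrack(t["batch"], t["history"],
                                     t["birth_energy"],
                                     tuple(t["birth_region"]), segs))
        return cls(
            config=SimulationConfig.from_dict(d["config"]),
            hydrogen_only=d["hydrogen_only"], nbatches=d["nbatches"],
            maxcas=d["maxcas"],
            cell_dep={k: np.array(v) for k, v in d["cell_dep"].items()},
            buffer_dep={k: np.array(v) for k, v in d["buffer_dep"].items()},
            ambient_dep={k: np.array(v) for k, v in d["ambient_dep"].items()},
            escaped={k: np.array(v) for k, v in d["escaped"].items()},
            counters={k: np.array(v) for k, v in d["counters"].items()},
            source_energy=np.array(d["source_energy"]),
            q_released=np.array(d["q_released"]),
            alpha_tracks=tracks,
            depth_dose=(np.array(d["depth_dose"])
                        if "depth_dose" in d else None),
            depth_bin_edges=(np.array(d["depth_bin_edges"])
                             if "depth_bin_edges" in d else None),
        )

    @classmethod
    def load(cls, path) -> "TallyResults":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# axial profile
# ---------------------------------------------------------------------------

@dataclass
class AxialProfile:
    """Binned alpha depth-dose over the cell layer, per source particle."""

    depth_um: np.ndarray       # bin centres, 0 .. -tcell
    mean: np.ndarray           # MeV per source particle per bin
    se: np.ndarray
    per_batch: np.ndarray      # (B, nbins)

    @property
    def total(self) -> float:
        return float(self.mean.sum())


def _segment_zbins(seg: TrackSegment, edges: np.ndarray) -> np.ndarray:
    """Fractional overlap of a segment's z-extent with each depth bin."""
    zlo = min(seg.start[2], seg.end[2])
    zhi = max(seg.start[2], seg.end[2])
    out = np.zeros(len(edges) - 1)
    if zhi - zlo < 1e-12:
        k = int(np.clip(np.searchsorted(edges, zlo) - 1, 0, len(out) - 1))
        out[k] = 1.0
        return out
    lo = np.maximum(edges[:-1], zlo)
    hi = np.minimum(edges[1:], zhi)
    ov = np.maximum(hi - lo, 0.0)
    return ov / (zhi - zlo)


def axial_profile(results: TallyResults, nbins: int = 30) -> AxialProfile:
    """Alpha energy deposition vs depth in the cell layer [0, -tcell].

    Per-bin uncertainty is the standard error over batches; with a single
    batch the SE is NaN and a warning is raised.
    """
    cfg = results.config
    edges = np.linspace(-cfg.tcell, 0.0, nbins + 1)
    per_batch = np.zeros((results.nbatches, nbins))
    for t in results.alpha_tracks:
        for s in t.segments:
            if s.region[0] != "cell":
                continue
            per_batch[t.batch] += s.e_deposit * _segment_zbins(s, edges)
    per_batch /= results.maxcas
    mean = per_batch.mean(axis=0)
    if results.nbatches < 2:
        warnings.warn("single batch: axial profile has no uncertainties",
                      stacklevel=2)
        se = np.full(nbins, np.nan)
    else:
        se = per_batch.std(axis=0, ddof=1) / np.sqrt(results.nbatches)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # present shallow-to-deep (0 -> -tcell)
    order = np.argsort(-centers)
    return AxialProfile(centers[order], mean[order], se[order],
                        per_batch[:, order])


# ---------------------------------------------------------------------------
# hit counts
# ---------------------------------------------------------------------------

@dataclass
class HitCounts:
    """Alpha hit totals of a single run (one hit per track per subdomain)."""

    nucleus: int
    cytoplasm: int
    n_source: int

    @property
    def nucleus_per_source(self) -> float:
        return self.nucleus / self.n_source

    @property
    def cytoplasm_per_source(self) -> float:
        return self.cytoplasm / self.n_source


@dataclass
class HitCountSummary:
    """(lower, average, upper) alpha hit counts over k independent runs."""

    nucleus: Tuple[float, float, float]
    cytoplasm: Tuple[float, float, float]
    runs: List[HitCounts] = field(default_factory=list)

    def __post_init__(self):
        for lo, avg, hi in (self.nucleus, self.cytoplasm):
            if not (lo <= avg <= hi):
                raise ValueError("hit summary must satisfy lower <= average <= upper")


def count_hits(tracks: Sequence[AlphaTrack], geometry: Geometry) -> HitCounts:
    """Count alpha hits: a track scores one hit in every distinct cell
    subdomain (cytoplasm or nucleus of a specific cell) any of its
    segments intersects — by crossing into it or being born inside."""
    nuc = 0
    cyt = 0
    for t in tracks:
        seen = set()
        for s in t.segments:
            if s.region[0] == "cell":
                seen.add(s.region)
        nuc += sum(1 for r in seen if r[3] == "nucleus")
        cyt += sum(1 for r in seen if r[3] == "cytoplasm")
    n_src = geometry.config.maxcas * geometry.config.maxbch
    return HitCounts(nuc, cyt, n_src)


def hit_count_study(config: SimulationConfig, k: int = 3,
                    base_seed: Optional[int] = None, **run_kwargs
                    ) -> HitCountSummary:
    """Repeat the simulation k times with independent seeds and summarize
    hit counts as (lower, average, upper)."""
    from .transport import run
    from .geometry import build_geometry

    if base_seed is None:
        base_seed = config.seed if config.seed is not None else 0
    runs = []
    for r in range(k):
        cfg = config.replace(seed=(base_seed + 1000003 * r) & 0x7FFFFFFF)
        res = run(cfg, **run_kwargs)
        geom = build_geometry(cfg)
        runs.append(count_hits(res.alpha_tracks, geom))
    nucs = [h.nucleus for h in runs]
    cyts = [h.cytoplasm for h in runs]
    return HitCountSummary(
        nucleus=(min(nucs), float(np.mean(nucs)), max(nucs)),
        cytoplasm=(min(cyts), float(np.mean(cyts)), max(cyts)),
        runs=runs,
    )


# ---------------------------------------------------------------------------
# enhancement factor & energy fraction
# ---------------------------------------------------------------------------

@dataclass
class EnhancementFactor:
    """Boron/normal ratio of total alpha energy deposition in the cells.

    ``value`` is the ratio of batch-mean totals (robust when single
    batches record no alpha energy); ``mean_of_ratios`` averages per-batch
    ratios over the batch pairs whose denominator is nonzero.  ``defined``
    is False when the normal arm deposited nothing at all.
    """

    value: float
    se: float
    ratio_of_means: float
    mean_of_ratios: float
    mean_of_ratios_se: float
    n_valid_batches: int
    defined: bool


def enhancement_factor(boron_results: TallyResults,
                       normal_results: TallyResults) -> EnhancementFactor:
    """Enhancement factor from paired runs (same seeds, same geometry)."""
    db = boron_results.cell_total_per_source("alpha")
    dn = normal_results.cell_total_per_source("alpha")
    if len(db) != len(dn):
        raise ValueError("paired runs must have the same number of batches")
    mb, seb = boron_results.batch_mean_se(db)
    mn, sen = normal_results.batch_mean_se(dn)
    if mn <= 0:
        return EnhancementFactor(float("nan"), float("nan"), float("nan"),
                                 float("nan"), float("nan"), 0, False)
    rom = mb / mn
    se = rom * float(np.sqrt((seb / mb) ** 2 + (sen / mn) ** 2)) \
        if mb > 0 and np.isfinite(seb) and np.isfinite(sen) else float("nan")
    valid = dn > 0
    if valid.any():
        ratios = db[valid] / dn[valid]
        mor = float(np.mean(ratios))
        mor_se = (float(np.std(ratios, ddof=1) / np.sqrt(valid.sum()))
                  if valid.sum() > 1 else float("nan"))
    else:
        mor, mor_se = float("nan"), float("nan")
    return EnhancementFactor(rom, se, rom, mor, mor_se,
                             int(valid.sum()), True)


@dataclass
class EnergyFraction:
    """Alpha share of (alpha + proton) energy deposition."""

    total: float
    cytoplasm: float
    nucleus: float
    defined: bool


def energy_fraction(results: TallyResults) -> EnergyFraction:
    """f = D_alpha / (D_alpha + D_proton) over the cell array and per
    subdomain class; NaN (defined=False) when nothing was deposited."""
    def frac(da, dp):
        tot = da + dp
        return da / tot if tot > 0 else float("nan")

    da_t = float(results.cell_total("alpha").sum())
    dp_t = float(results.cell_total("proton").sum())
    da_c = float(results.cytoplasm_total("alpha").sum())
    dp_c = float(results.cytoplasm_total("proton").sum())
    da_n = float(results.nucleus_total("alpha").sum())
    dp_n = float(results.nucleus_total("proton").sum())
    return EnergyFraction(frac(da_t, dp_t), frac(da_c, dp_c),
                          frac(da_n, dp_n), (da_t + dp_t) > 0)


# ---------------------------------------------------------------------------
# track maps
# ---------------------------------------------------------------------------

def track_map(segments: Sequence[TrackSegment], plane: str = "xy",
              resolution: int = 256,
              extent: Optional[Tuple[float, float]] = None
              ) -> Dict[str, np.ndarray]:
    """Rasterize track segments into per-species 2-D path-length maps.

    ``plane`` chooses the projection ("xy" beam's-eye or "xz"); ``extent``
    is the symmetric half-width in µm (defaults to the data extent).
    Returns {species: (resolution, resolution) array}.
    """
    ax = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    segs = list(segments)
    if extent is None:
        m = 1.0
        for s in segs:
            m = max(m, abs(s.start[ax[0]]), abs(s.start[ax[1]]),
                    abs(s.end[ax[0]]), abs(s.end[ax[1]]))
        extent = (-m, m)
    lo, hi = extent if isinstance(extent, tuple) else (-extent, extent)
    px = (hi - lo) / resolution
    out: Dict[str, np.ndarray] = {}
    for s in segs:
        grid = out.setdefault(s.species, np.zeros((resolution, resolution)))
        length = float(np.linalg.norm(s.end - s.start))
        nstep = max(int(length / (0.5 * px)) + 1, 1)
        ts = np.linspace(0.0, 1.0, nstep)
        pts = s.start[None, :] + ts[:, None] * (s.end - s.start)[None, :]
        u = ((pts[:, ax[0]] - lo) / px).astype(int)
        v = ((pts[:, ax[1]] - lo) / px).astype(int)
        ok = (u >= 0) & (u < resolution) & (v >= 0) & (v < resolution)
        np.add.at(grid, (u[ok], v[ok]), length / nstep)
    return out
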