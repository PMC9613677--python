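"""Condensed-history Monte Carlo transport of protons and alphas.

Protons start on a disk source at the top of the buffer slab travelling
along -z, lose energy continuously (CSDA, step-limited to a maximum
fractional energy loss and to region boundaries), and may undergo one
discrete alpha-producing reaction per history — all embedded channels are
absorbing, which terminates the proton.  Reaction probability over a step
of length ds is 1 - exp(-Sigma_tot * ds) with the macroscopic cross
section evaluated at the step's midpoint energy; the channel is selected
proportionally to N_i * sigma_i and the reaction point is drawn from the
truncated exponential along the step.  Alphas are transported on straight
lines with per-region CSDA energy deposition until they stop or leave the
ambient sphere.  Below the low-energy cutoffs (0.1 MeV protons, 0.05 MeV
alphas by default) the residual energy is deposited locally.

Multiple scattering is off by default so that depth-dose and reaction-rate
oracles stay analytic; an optional small-angle Gaussian (Highland) kick is
available behind the ``scattering`` config flag.

Randomness and pairing
----------------------
Each batch draws from an independent child stream of the run seed, and the
per-step uniforms are generated for *all* histories of a batch regardless
of their alive state.  Reaction products are sampled from a generator
keyed by (run seed, batch, history, event index).  Together these make two
runs that share a seed but differ only in boron loading follow common
random numbers: histories that react identically in both runs produce
bit-identical secondaries, which is what makes paired enhancement-factor
estimates sharp even when reactions are rare.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import nnls

from .config import SimulationConfig
from .geometry import AMBIENT, BUFFER, ESCAPED, Geometry, RegionId, build_geometry
from .materials import MaterialComposition, builtin_material, mix_boron, \
    number_densities, with_density
from .physics import (
    ParticleState,
    PhysicsError,
    ReactionChannel,
    ReactionOutcome,
    StoppingPowerModel,
    default_channels,
    macroscopic_cross_sections,
)

BARN_CM2 = 1e-24
UM_PER_CM = 1e4

# material ids used by the transport media
M_BUFFER, M_CYTO, M_CYTO_B, M_NUC, M_NUC_B, M_AIR = range(6)
# region class codes used by the vector engine
R_BUFFER, R_CYTO, R_NUC, R_AMBIENT = range(4)

_REGION_CLASS_NAMES = {R_BUFFER: "buffer", R_CYTO: "cytoplasm",
                       R_NUC: "nucleus", R_AMBIENT: "ambient"}


# ---------------------------------------------------------------------------
# media: materials + stopping/cross-section tables per region material
# ---------------------------------------------------------------------------

class TransportMedia:
    """All material-dependent data needed by transport, indexed by a small
    integer material id (buffer, cytoplasm +- boron, nucleus +- boron, air).

    ``hydrogen_only=True`` swaps every condensed medium for pure hydrogen
    at its original density — the null control in which no alpha-producing
    channel has a target.
    """

    ids = (M_BUFFER, M_CYTO, M_CYTO_B, M_NUC, M_NUC_B, M_AIR)

    def __init__(self, config: SimulationConfig, hydrogen_only: bool = False):
        self.config = config
        self.hydrogen_only = hydrogen_only
        h = builtin_material("hydrogen_only")
        if hydrogen_only:
            cyto = with_density(h, builtin_material("cytoplasm").density)
            nuc = cyto
            buf = with_density(h, builtin_material("buffer").density)
            air = with_density(h, builtin_material("air").density)
            cyto_b, nuc_b, buf_b = cyto, nuc, buf
        else:
            cyto = builtin_material("cytoplasm")
            nuc = builtin_material("nucleus")
            buf = builtin_material("buffer")
            air = builtin_material("air")
            cyto_b = mix_boron(cyto, config.ppm)
            nuc_b = mix_boron(nuc, config.ppm)
            buf_b = mix_boron(buf, config.ppmw)
        if config.watb == 1:
            buf = buf_b
        self.compositions: Dict[int, MaterialComposition] = {
            M_BUFFER: buf, M_CYTO: cyto, M_CYTO_B: cyto_b,
            M_NUC: nuc, M_NUC_B: nuc_b, M_AIR: air,
        }
        self.rho = {m: c.density for m, c in self.compositions.items()}
        self.channels = default_channels(config.o16_threshold)
        self.macro: Dict[int, List[Tuple[ReactionChannel, float]]] = {
            m: macroscopic_cross_sections(number_densities(c), self.channels)
            for m, c in self.compositions.items()
        }
        self._proton = {m: StoppingPowerModel(c, "proton")
                        for m, c in self.compositions.items()}
        self._alpha = {m: StoppingPowerModel(c, "alpha")
                       for m, c in self.compositions.items()}
        self.p_rcut = {m: float(self._proton[m].csda_range(config.proton_cutoff))
                       for m in self.ids}
        self.a_rcut = {m: float(self._alpha[m].csda_range(config.alpha_cutoff))
                       for m in self.ids}

    # -- stopping tables --------------------------------------------------
    def proton_model(self, mid: int) -> StoppingPowerModel:
        return self._proton[mid]

    def alpha_model(self, mid: int) -> StoppingPowerModel:
        return self._alpha[mid]

    def p_range(self, mid, energy):
        return self._proton[mid].csda_range(energy)

    def p_einv(self, mid, r):
        return self._proton[mid].energy_from_range(r)

    def sigma_total(self, mid, energy):
        """Macroscopic alpha-channel cross section, cm^-1 (vectorized)."""
        e = np.asarray(energy, dtype=float)
        sig = np.zeros_like(e)
        for chan, n_t in self.macro[mid]:
            sig += n_t * chan.cross_section(e) * BARN_CM2
        return sig

    def channel_weights(self, mid, energy: float):
        chans = self.macro[mid]
        w = np.array([n_t * chan.cross_section(energy) * BARN_CM2
                      for chan, n_t in chans])
        return chans, w

    def material_id(self, region: RegionId, geometry: Geometry) -> int:
        if region == BUFFER:
            return M_BUFFER
        if region == AMBIENT:
            return M_AIR
        if region == ESCAPED:
            raise PhysicsError("no material outside the ambient sphere")
        _, i, j, sub = region
        if sub == "nucleus":
            return M_NUC_B if geometry.nucleus_boron(i, j) else M_NUC
        return M_CYTO_B if geometry.borcheck[i, j] else M_CYTO

    def composition_for(self, region: RegionId, geometry: Geometry):
        return self.compositions[self.material_id(region, geometry)]


# ---------------------------------------------------------------------------
# source models
# ---------------------------------------------------------------------------

@dataclass
class SourceModel:
    """Disk source at the top of the buffer, beam along -z.

    The energy spectrum is a discrete set {(E_k, w_k)}; a monoenergetic
    beam is the single-point case.  Positions are uniform in area on the
    disk of radius ``r0_um`` centred on the array axis.
    """

    r0_um: float
    z0_um: float
    energies: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        e = np.atleast_1d(np.asarray(self.energies, dtype=float))
        w = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if e.size != w.size or e.size == 0:
            raise PhysicsError("energies/weights size mismatch")
        if np.any(w < 0):
            raise PhysicsError("SOBP weights must be >= 0")
        total = w.sum()
        if total <= 0:
            raise PhysicsError("SOBP weights must not all vanish")
        w = w / total
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)
        self._cumw = np.cumsum(w)

    @property
    def is_monoenergetic(self) -> bool:
        return self.energies.size == 1

    def sample_arrays(self, rng: np.random.Generator, n: int):
        """Vector draw of n source particles -> (x, y, energy) arrays.

        Draw order (u_r, u_theta[, u_e]) is fixed so paired runs consume
        streams identically.
        """
        u_r = rng.random(n)
        u_t = rng.random(n)
        r = self.r0_um * np.sqrt(u_r)
        theta = 2.0 * np.pi * u_t
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        if self.is_monoenergetic:
            e = np.full(n, float(self.energies[0]))
        else:
            u_e = rng.random(n)
            e = self.energies[np.searchsorted(self._cumw, u_e)]
        return x, y, e

    def sample(self, rng: np.random.Generator) -> ParticleState:
        x, y, e = self.sample_arrays(rng, 1)
        return ParticleState("proton", float(e[0]),
                             np.array([x[0], y[0], self.z0_um]),
                             np.array([0.0, 0.0, -1.0]))


def sample_source(source: SourceModel, rng: np.random.Generator) -> ParticleState:
    """Draw one source proton (disk position, -z direction, spectrum energy)."""
    return source.sample(rng)


def sobp_depth_dose(energies, weights, medium: MaterialComposition,
                    z_cm: np.ndarray, straggling_fraction: float = 0.018
                    ) -> np.ndarray:
    """Analytic summed depth-dose of a weighted pristine-peak set.

    Each pristine curve is S(E(z)) from CSDA range inversion, smoothed by
    a Gaussian of sigma = straggling_fraction * range; the default 1.8%
    lumps range straggling (~1.2% in water) with a typical accelerator
    energy spread.  Used both to fit SOBP weights and to verify flatness.
    """
    model = StoppingPowerModel(medium, "proton")
    rho = medium.density
    total = np.zeros_like(z_cm)
    dz = z_cm[1] - z_cm[0]
    for e_k, w_k in zip(np.atleast_1d(energies), np.atleast_1d(weights)):
        r_k = float(model.csda_range(e_k))  # g/cm^2
        res = r_k - z_cm * rho
        dose = np.zeros_like(z_cm)
        ok = res > model.csda_range(model.e_min)
        dose[ok] = model.stopping_power(model.energy_from_range(res[ok]))
        sigma_bins = straggling_fraction * (r_k / rho) / dz
        if sigma_bins > 0:
            dose = gaussian_filter1d(dose, sigma_bins, mode="nearest")
        total += w_k * dose
    return total


def build_sobp(e_max: float, nsobp: int, medium: MaterialComposition,
               mod_fraction: float = 0.25, flatness_tol: float = 0.05,
               r0_um: float = 300.0, z0_um: float = 0.0) -> SourceModel:
    """Construct a spread-out Bragg peak source.

    ``nsobp`` pristine energies are chosen so their CSDA ranges uniformly
    span the modulated interval [(1 - mod_fraction) * R_max, R_max]; the
    weights flattening the summed depth-dose over that interval are found
    by non-negative least squares.  If the requested flatness cannot be
    reached (nsobp too small) a warning is raised and the best fit
    returned.
    """
    if nsobp < 1:
        raise PhysicsError(f"nsobp must be >= 1, got {nsobp}")
    model = StoppingPowerModel(medium, "proton")
    rho = medium.density
    r_max = float(model.csda_range(e_max))
    if nsobp == 1:
        return SourceModel(r0_um, z0_um, np.array([e_max]), np.array([1.0]))
    r_ks = np.linspace((1.0 - mod_fraction) * r_max, r_max, nsobp)
    e_ks = np.asarray(model.energy_from_range(r_ks), dtype=float)
    z_cm = np.linspace(0.0, 1.03 * r_max / rho, 2000)
    curves = np.stack([
        sobp_depth_dose([e], [1.0], medium, z_cm) for e in e_ks
    ])
    # fit slightly wider than the nominal plateau so flatness holds up to
    # the plateau edges rather than sagging at the fit boundary
    fit = (z_cm >= r_ks[0] / rho + 0.012 * r_max / rho) \
        & (z_cm <= r_max / rho - 0.006 * r_max / rho)
    a = curves[:, fit].T
    target = np.ones(fit.sum()) * np.median(curves[-1, fit])
    w, _ = nnls(a, target)
    if w.sum() <= 0:
        raise PhysicsError("SOBP weight fit failed (all-zero weights)")
    w = w / w.sum()
    total = w @ curves
    nominal = (z_cm >= r_ks[0] / rho + 0.02 * r_max / rho) \
        & (z_cm <= r_max / rho - 0.015 * r_max / rho)
    plateau = total[nominal]
    ripple = (plateau.max() - plateau.min()) / plateau.mean()
    if ripple > flatness_tol:
        warnings.warn(
            f"SOBP plateau ripple {ripple:.1%} exceeds {flatness_tol:.0%} "
            f"with nsobp={nsobp}; returning best fit", stacklevel=2)
    return SourceModel(r0_um, z0_um, e_ks, w)


def make_source(config: SimulationConfig, media: TransportMedia) -> SourceModel:
    """Source implied by a configuration (monoenergetic or SOBP)."""
    r0_um = config.r0 * 1000.0
    if config.sobp == 1:
        src = build_sobp(config.e0, config.nsobp,
                         media.compositions[M_BUFFER],
                         mod_fraction=config.sobp_mod_fraction)
        return dataclasses.replace(src, r0_um=r0_um, z0_um=config.tbuffer)
    return SourceModel(r0_um, config.tbuffer,
                       np.array([config.e0]), np.array([1.0]))


# ---------------------------------------------------------------------------
# track records and events
# ---------------------------------------------------------------------------

@dataclass
class TrackSegment:
    start: np.ndarray   # µm
    end: np.ndarray     # µm
    region: RegionId
    species: str
    e_deposit: float    # MeV
    e_start: float      # MeV


@dataclass
class AlphaTrack:
    batch: int
    history: int
    birth_energy: float
    birth_region: RegionId
    segments: List[TrackSegment]

    @property
    def deposited(self) -> float:
        return sum(s.e_deposit for s in self.segments)

    @property
    def escaped_energy(self) -> float:
        return self.birth_energy - self.deposited


@dataclass
class DepositEvent:
    region: RegionId
    energy: float


@dataclass
class ReactionEvent:
    channel: str
    position: np.ndarray
    e_proton: float
    outcome: ReactionOutcome


@dataclass
class EscapeEvent:
    species: str
    energy: float


# ---------------------------------------------------------------------------
# scalar reference transport (single particles)
# ---------------------------------------------------------------------------

def _highland_kick(state_dir, e_mev, ds_gcm2, rng):
    """Small-angle Gaussian multiple-scattering deflection (Highland)."""
    # radiation length of water-like media ~36.08 g/cm^2
    x0 = 36.08
    p_beta = e_mev * (e_mev + 2 * 938.272) / (e_mev + 938.272)
    t = max(ds_gcm2 / x0, 1e-12)
    theta0 = 13.6 / p_beta * math.sqrt(t) * (1 + 0.038 * math.log(t))
    dx, dy = rng.normal(0.0, max(theta0, 0.0), 2)
    d = np.asarray(state_dir, dtype=float) + np.array([dx, dy, 0.0])
    return d / np.linalg.norm(d)


def step_proton(state: ParticleState, geometry: Geometry,
                media: TransportMedia, rng: np.random.Generator
                ) -> Tuple[list, ParticleState]:
    """Advance a proton by one condensed-history step.

    Returns (events, new_state); the proton is dead (alive=False) after a
    reaction, escape, or falling below the cutoff.  Reaction products are
    carried inside the ReactionEvent and are NOT transported here.
    """
    cfg = geometry.config
    if not state.alive or state.species != "proton":
        raise PhysicsError("step_proton needs a live proton")
    region = geometry.locate(state.position)
    events: list = []
    if region == ESCAPED:
        events.append(EscapeEvent("proton", state.energy))
        return events, dataclasses.replace(state, alive=False)
    mid = media.material_id(region, geometry)
    model = media.proton_model(mid)
    rho = media.rho[mid]
    e = state.energy
    r_e = float(model.csda_range(e))
    s_stop = max(r_e - media.p_rcut[mid], 0.0) / rho * UM_PER_CM
    r95 = float(model.csda_range((1.0 - cfg.max_frac_loss) * e))
    s_frac = max((r_e - r95) / rho * UM_PER_CM, 1e-3)
    d_bound = max(geometry.distance_to_boundary(state.position,
                                                state.direction, region), 0.0)
    ds = min(d_bound, s_frac)
    u1, u2, u3 = rng.random(3)
    if s_stop <= ds:
        # stops (reaches the cutoff) within this step: deposit everything
        events.append(DepositEvent(region, e))
        end = state.position + s_stop * state.direction
        return events, dataclasses.replace(state, energy=0.0, position=end,
                                           alive=False)
    e_new = float(model.energy_from_range(r_e - rho * ds / UM_PER_CM))
    e_mid = 0.5 * (e + e_new)
    sig = float(media.sigma_total(mid, e_mid))
    p_react = -math.expm1(-sig * ds / UM_PER_CM)
    if sig > 0 and u1 < p_react:
        t_cm = -math.log1p(-u3 * p_react) / sig
        t_um = min(t_cm * UM_PER_CM, ds)
        e_r = float(model.energy_from_range(r_e - rho * t_cm))
        pos = state.position + t_um * state.direction
        chans, w = media.channel_weights(mid, e_mid)
        cum = np.cumsum(w)
        k = int(np.searchsorted(cum, u2 * cum[-1]))
        chan = chans[min(k, len(chans) - 1)][0]
        outcome = chan.sample_products(e_r, rng, pos,
                                       history=state.history,
                                       batch=state.batch)
        events.append(DepositEvent(region, e - e_r))
        events.append(ReactionEvent(chan.label, pos, e_r, outcome))
        return events, dataclasses.replace(state, energy=0.0, position=pos,
                                           alive=False)
    events.append(DepositEvent(region, e - e_new))
    new_dir = state.direction
    if cfg.scattering:
        new_dir = _highland_kick(state.direction, e_mid,
                                 rho * ds / UM_PER_CM, rng)
    bounded = d_bound <= s_frac
    nudge = 1e-6 if bounded else 0.0
    new_pos = state.position + (ds + nudge) * state.direction
    new_state = dataclasses.replace(state, energy=e_new, position=new_pos,
                                    direction=new_dir)
    if e_new <= cfg.proton_cutoff + 1e-12:
        nxt = geometry.locate(new_pos)
        if nxt == ESCAPED:
            events.append(EscapeEvent("proton", e_new))
        else:
            events.append(DepositEvent(nxt, e_new))
        new_state = dataclasses.replace(new_state, energy=0.0, alive=False)
    return events, new_state


def transport_alpha(state: ParticleState, geometry: Geometry,
                    media: TransportMedia) -> List[TrackSegment]:
    """Straight-line CSDA transport of one alpha.

    Returns the per-region track segments; the alpha's escaped energy (if
    it left the ambient sphere) is ``state.energy - sum(e_deposit)``.
    """
    cfg = geometry.config
    pos = np.array(state.position, dtype=float)
    dirn = np.array(state.direction, dtype=float)
    e = float(state.energy)
    segments: List[TrackSegment] = []
    region = geometry.locate(pos)
    guard = 0
    while region != ESCAPED and e > 0.0:
        guard += 1
        if guard > 100000:
            raise RuntimeError("alpha transport failed to terminate")
        mid = media.material_id(region, geometry)
        model = media.alpha_model(mid)
        rho = media.rho[mid]
        r_e = float(model.csda_range(e))
        s_stop = max(r_e - media.a_rcut[mid], 0.0) / rho * UM_PER_CM
        d_bound = geometry.distance_to_boundary(pos, dirn, region)
        if d_bound < 1e-9:
            pos = pos + 1e-4 * dirn
            region = geometry.locate(pos)
            continue
        if s_stop <= d_bound:
            end = pos + s_stop * dirn
            segments.append(TrackSegment(pos.copy(), end, region, "alpha",
                                         e, e))
            e = 0.0
            break
        e_out = float(model.energy_from_range(r_e - rho * d_bound / UM_PER_CM))
        end = pos + d_bound * dirn
        segments.append(TrackSegment(pos.copy(), end, region, "alpha",
                                     e - e_out, e))
        e = e_out
        pos = end + 1e-6 * dirn
        region = geometry.locate(pos)
        if e <= cfg.alpha_cutoff + 1e-12 and region != ESCAPED:
            segments.append(TrackSegment(pos.copy(), pos.copy(), region,
                                         "alpha", e, e))
            e = 0.0
    return segments


def trace_history(state: ParticleState, geometry: Geometry,
                  media: TransportMedia, rng: np.random.Generator
                  ) -> Tuple[list, dict]:
    """Run one full history (proton + secondaries) through the scalar path.

    Returns (events, ledger) where the ledger carries the per-history
    energy balance: source + q_released = deposits + escaped (the
    conservation invariant, exact to the arithmetic of the bookkeeping).
    """
    ledger = {"source": state.energy, "deposited": 0.0, "escaped": 0.0,
              "q_released": 0.0}
    all_events: list = []
    proton_segments: List[TrackSegment] = []
    s = state
    while s.alive:
        p0 = s.position
        events, s = step_proton(s, geometry, media, rng)
        for ev in events:
            all_events.append(ev)
            if isinstance(ev, DepositEvent):
                ledger["deposited"] += ev.energy
            elif isinstance(ev, EscapeEvent):
                ledger["escaped"] += ev.energy
            elif isinstance(ev, ReactionEvent):
                out = ev.outcome
                ledger["q_released"] += out.q_effective
                ledger["deposited"] += out.local_deposit
                ledger["escaped"] += out.neutron_energy
                for prod in out.products:
                    segs = transport_alpha(prod, geometry, media)
                    dep = sum(sg.e_deposit for sg in segs)
                    ledger["deposited"] += dep
                    ledger["escaped"] += prod.energy - dep
                    all_events.extend(segs)
        proton_segments.append(TrackSegment(p0, s.position, ("proton",),
                                            "proton", 0.0, 0.0))
    return all_events, ledger


# ---------------------------------------------------------------------------
# vectorized batch engine and run()
# ---------------------------------------------------------------------------

class _BatchTally:
    """Per-batch accumulators filled by the vector engine."""

    def __init__(self, n: int, depth_bins: Optional[np.ndarray]):
        self.n = n
        self.cell = {sp: np.zeros(n * n * 2) for sp in
                     ("proton", "alpha", "recoil")}
        self.buffer = {sp: 0.0 for sp in ("proton", "alpha", "recoil")}
        self.ambient = {sp: 0.0 for sp in ("proton", "alpha", "recoil")}
        self.escaped = {sp: 0.0 for sp in ("proton", "alpha", "neutron")}
        self.counters: Dict[str, float] = {}
        self.source_energy = 0.0
        self.q_released = 0.0
        self.depth_bins = depth_bins
        self.depth_dose = (np.zeros(len(depth_bins) - 1)
                           if depth_bins is not None else None)

    def count(self, name, inc=1.0):
        self.counters[name] = self.counters.get(name, 0.0) + inc

    def add_cells(self, species, flat_idx, de):
        np.add.at(self.cell[species], flat_idx, de)

    def deposit_region_code(self, species, code, i, j, de):
        """Scalar deposit by region class code."""
        if de <= 0:
            return
        if code == R_BUFFER:
            self.buffer[species] += de
        elif code == R_AMBIENT:
            self.ambient[species] += de
        else:
            sub = 1 if code == R_NUC else 0
            self.cell[species][(i * self.n + j) * 2 + sub] += de

    def deposit_region_id(self, species, region: RegionId, de):
        if de <= 0:
            return
        if region == BUFFER:
            self.buffer[species] += de
        elif region == AMBIENT:
            self.ambient[species] += de
        elif region[0] == "cell":
            _, i, j, sub = region
            self.cell[species][(i * self.n + j) * 2 +
                               (1 if sub == "nucleus" else 0)] += de


def _region_code(region: RegionId) -> int:
    if region == BUFFER:
        return R_BUFFER
    if region == AMBIENT:
        return R_AMBIENT
    return R_NUC if region[3] == "nucleus" else R_CYTO


def _simulate_batch(geometry: Geometry, media: TransportMedia,
                    source: SourceModel, rng: np.random.Generator,
                    run_seed: int, batch_idx: int, tally: _BatchTally,
                    max_step_um: Optional[float] = None
                    ) -> List[AlphaTrack]:
    cfg = geometry.config
    n = geometry.n
    nh = int(cfg.maxcas)
    half, L = geometry.half, geometry.lcell
    ecut = cfg.proton_cutoff
    frac = cfg.max_frac_loss

    x, y, e = source.sample_arrays(rng, nh)
    tally.source_energy += float(e.sum())
    z = np.full(nh, float(source.z0_um))

    inside = (x >= -half) & (x < half) & (y >= -half) & (y < half)
    i_idx = np.clip(((x + half) // L).astype(np.int64), 0, n - 1)
    j_idx = np.clip(((y + half) // L).astype(np.int64), 0, n - 1)
    xc = -half + (i_idx + 0.5) * L
    yc = -half + (j_idx + 0.5) * L
    nhuc = geometry.nuc_half
    in_nuc = inside & (x >= xc - nhuc) & (x < xc + nhuc) \
        & (y >= yc - nhuc) & (y < yc + nhuc)
    bor = np.where(inside, geometry.borcheck[i_idx, j_idx], 0).astype(bool)
    nucbor = bor & (cfg.nuclb == 1)
    z_exit = -np.sqrt(np.maximum(geometry.airad_um ** 2 - x * x - y * y, 0.0))

    smax = 5
    seg_z = np.full((nh, smax), -np.inf)
    seg_mat = np.full((nh, smax), M_AIR, np.int8)
    seg_reg = np.full((nh, smax), R_AMBIENT, np.int8)
    n_seg = np.ones(nh, np.int64)

    out = ~inside
    seg_z[out, 0] = z_exit[out]

    cyto_mat = np.where(bor, M_CYTO_B, M_CYTO).astype(np.int8)
    nuc_mat = np.where(nucbor, M_NUC_B, M_NUC).astype(np.int8)

    c1 = inside & ~in_nuc
    seg_z[c1, 0] = 0.0
    seg_mat[c1, 0] = M_BUFFER
    seg_reg[c1, 0] = R_BUFFER
    seg_z[c1, 1] = -cfg.tcell
    seg_mat[c1, 1] = cyto_mat[c1]
    seg_reg[c1, 1] = R_CYTO
    seg_z[c1, 2] = z_exit[c1]
    n_seg[c1] = 3

    c2 = inside & in_nuc
    seg_z[c2, 0] = 0.0
    seg_mat[c2, 0] = M_BUFFER
    seg_reg[c2, 0] = R_BUFFER
    seg_z[c2, 1] = geometry.nuc_zhi
    seg_mat[c2, 1] = cyto_mat[c2]
    seg_reg[c2, 1] = R_CYTO
    seg_z[c2, 2] = geometry.nuc_zlo
    seg_mat[c2, 2] = nuc_mat[c2]
    seg_reg[c2, 2] = R_NUC
    seg_z[c2, 3] = -cfg.tcell
    seg_mat[c2, 3] = cyto_mat[c2]
    seg_reg[c2, 3] = R_CYTO
    seg_z[c2, 4] = z_exit[c2]
    n_seg[c2] = 5

    alive = np.ones(nh, bool)
    seg = np.zeros(nh, np.int64)
    ev_count = np.zeros(nh, np.int32)
    idx_all = np.arange(nh)
    alpha_queue: List[Tuple[float, float, float, float, int]] = []
    mids_present = list(media.ids)
    rho = media.rho
    guard = 0
    while alive.any():
        guard += 1
        if guard > 200000:
            raise RuntimeError("proton batch failed to terminate")
        u1 = rng.random(nh)
        u2 = rng.random(nh)
        u3 = rng.random(nh)
        segc = np.minimum(seg, n_seg - 1)
        m = seg_mat[idx_all, segc]
        zb = seg_z[idx_all, segc]
        reg = seg_reg[idx_all, segc]
        d_bound = np.maximum(z - zb, 0.0)

        r_e = np.zeros(nh)
        s_stop = np.zeros(nh)
        s_frac = np.zeros(nh)
        for mid in mids_present:
            msk = alive & (m == mid)
            if not msk.any():
                continue
            em = e[msk]
            rm = np.asarray(media.p_range(mid, em))
            r_e[msk] = rm
            s_stop[msk] = np.maximum(rm - media.p_rcut[mid], 0.0) \
                / rho[mid] * UM_PER_CM
            r95 = np.asarray(media.p_range(mid, (1.0 - frac) * em))
            s_frac[msk] = (rm - r95) / rho[mid] * UM_PER_CM
        s_frac = np.maximum(s_frac, 1e-3)
        if max_step_um is not None:
            s_frac = np.minimum(s_frac, max_step_um)
        ds = np.minimum(d_bound, s_frac)
        stopping = alive & (s_stop <= ds)
        ds = np.where(stopping, s_stop, ds)
        bounded = alive & ~stopping & (d_bound <= s_frac)

        e_new = np.zeros(nh)
        moving = alive & ~stopping
        for mid in mids_present:
            msk = moving & (m == mid)
            if not msk.any():
                continue
            e_new[msk] = np.asarray(media.p_einv(
                mid, r_e[msk] - rho[mid] * ds[msk] / UM_PER_CM))
        de = np.where(alive, e - np.where(stopping, 0.0, e_new), 0.0)
        e_mid = 0.5 * (e + np.where(stopping, 0.0, e_new))

        sig = np.zeros(nh)
        for mid in mids_present:
            msk = moving & (m == mid)
            if not msk.any():
                continue
            sig[msk] = media.sigma_total(mid, e_mid[msk])
        p_react = -np.expm1(-sig * ds / UM_PER_CM)
        react = moving & (u1 < p_react)

        # continuous deposits of everyone who does NOT react this step
        dep = np.where(react, 0.0, de)
        live = alive
        for code, store in ((R_BUFFER, "buffer"), (R_AMBIENT, "ambient")):
            msk = live & (reg == code) & (dep > 0)
            if msk.any():
                getattr(tally, store)["proton"] += float(dep[msk].sum())
        cellmask = live & ((reg == R_CYTO) | (reg == R_NUC)) & (dep > 0)
        if cellmask.any():
            flat = (i_idx[cellmask] * n + j_idx[cellmask]) * 2 \
                + (reg[cellmask] == R_NUC)
            tally.add_cells("proton", flat, dep[cellmask])
        if tally.depth_bins is not None:
            msk = live & (dep > 0)
            if msk.any():
                zmid = z[msk] - 0.5 * ds[msk]
                bi = np.searchsorted(tally.depth_bins, zmid) - 1
                ok = (bi >= 0) & (bi < len(tally.depth_dose))
                np.add.at(tally.depth_dose, bi[ok], dep[msk][ok])

        # discrete reactions (rare): scalar handling
        for k in np.flatnonzero(react):
            sig_k = sig[k]
            t_cm = -math.log1p(-u3[k] * p_react[k]) / sig_k
            t_um = min(t_cm * UM_PER_CM, ds[k])
            mid_k = int(m[k])
            e_r = float(media.p_einv(mid_k, r_e[k] - rho[mid_k] * t_cm))
            tally.deposit_region_code("proton", int(reg[k]),
                                      int(i_idx[k]), int(j_idx[k]),
                                      e[k] - e_r)
            chans, w = media.channel_weights(mid_k, float(e_mid[k]))
            cum = np.cumsum(w)
            ci = int(np.searchsorted(cum, u2[k] * cum[-1]))
            chan = chans[min(ci, len(chans) - 1)][0]
            pos = np.array([x[k], y[k], z[k] - t_um])
            ev_rng = np.random.default_rng(np.random.SeedSequence(
                [run_seed & 0x7FFFFFFF, batch_idx, int(k), int(ev_count[k])]))
            ev_count[k] += 1
            outcome = chan.sample_products(e_r, ev_rng, pos,
                                           history=int(k), batch=batch_idx)
            tally.count("rx_" + _REGION_CLASS_NAMES[int(reg[k])])
            tally.count("rx:" + chan.label)
            if outcome.residual:
                tally.count(outcome.residual)
            if outcome.neutron_energy > 0 or chan.produces_neutron:
                tally.count("neutron")
                tally.escaped["neutron"] += outcome.neutron_energy
            if outcome.local_deposit > 0:
                tally.deposit_region_code("recoil", int(reg[k]),
                                          int(i_idx[k]), int(j_idx[k]),
                                          outcome.local_deposit)
            tally.q_released += outcome.q_effective
            for prod in outcome.products:
                alpha_queue.append((prod, int(reg[k]), int(k)))
            alive[k] = False

        # advance the survivors
        adv = moving & ~react
        z = np.where(adv, z - ds, z)
        e = np.where(adv, e_new, e)
        # stopped protons were fully deposited above (dep included all of e)
        alive = alive & ~stopping
        cross = adv & bounded
        z[cross] = zb[cross]
        seg[cross] += 1
        esc = cross & (seg >= n_seg)
        if esc.any():
            tally.escaped["proton"] += float(e[esc].sum())
            alive[esc] = False

    # transport the queued alphas through the full 3-D geometry
    tracks: List[AlphaTrack] = []
    for prod, birth_code, hist in alpha_queue:
        tally.count("alpha_births")
        segs = transport_alpha(prod, geometry, media)
        dep_total = 0.0
        for sg in segs:
            tally.deposit_region_id("alpha", sg.region, sg.e_deposit)
            dep_total += sg.e_deposit
        tally.escaped["alpha"] += prod.energy - dep_total
        birth_region = geometry.locate(prod.position)
        tracks.append(AlphaTrack(batch_idx, hist, prod.energy,
                                 birth_region, segs))
    return tracks


def run(config: SimulationConfig, *, hydrogen_only: bool = False,
        depth_dose_bins: Optional[np.ndarray] = None,
        max_step_um: Optional[float] = None):
    """Run the full simulation: maxbch batches of maxcas histories.

    Results are deterministic for a fixed ``config.seed`` (a missing seed
    draws one from OS entropy and records it in the results).  Returns a
    :class:`pbftsim.tallies.TallyResults`.
    """
    from .tallies import TallyResults  # local import to avoid a cycle

    config.validate()
    if config.maxcas < 1:
        raise PhysicsError("maxcas must be >= 1")
    run_seed = config.seed
    if run_seed is None:
        run_seed = int(np.random.SeedSequence().generate_state(1)[0] & 0x7FFFFFFF)
        config = config.replace(seed=run_seed)
    geometry = build_geometry(config)
    media = TransportMedia(config, hydrogen_only=hydrogen_only)
    source = make_source(config, media)

    batches = []
    all_tracks: List[AlphaTrack] = []
    for b in range(config.maxbch):
        rng = np.random.default_rng(
            np.random.SeedSequence([run_seed & 0x7FFFFFFF, 1, b]))
        tally = _BatchTally(geometry.n, depth_dose_bins)
        tracks = _simulate_batch(geometry, media, source, rng,
                                 run_seed, b, tally, max_step_um)
        batches.append(tally)
        all_tracks.extend(tracks)
    return TallyResults.from_batches(config, geometry, media, source,
                                     batches, all_tracks,
                                     hydrogen_only=hydrogen_only,
                                     depth_dose_bins=depth_dose_bins)
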