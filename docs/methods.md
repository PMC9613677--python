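# Methods

## Model overview

`pbftsim` simulates proton irradiation of a monolayer cell array to
quantify alpha-particle dose enhancement from proton–boron fusion.  The
model has four parts: (1) a parametric geometry, (2) material media with
ppm-level boron loading, (3) embedded charged-particle physics, and (4) a
condensed-history transport engine feeding batch-resolved tallies.

### Geometry

Cells are axis-aligned boxes at 100% confluence (shared faces, no gaps),
each with a centred cubic nucleus; cytoplasm is the cell box minus the
nucleus box.  The beam travels along −z; z = 0 is the buffer/cell
interface, the cell layer occupies z ∈ [−tcell, 0) and the water buffer
z ∈ [0, tbuffer).  Everything sits inside an ambient sphere of dry air
(1.205 mg/cm³); outside it particles are scored as escaped.  All boxes
are half-open [min, max) per axis, so every point maps to exactly one
region and face ownership needs no tie-break rule.  The n×n array is
centred on the beam axis; with even n the axis runs along shared cell
faces, with odd n it pierces a central cell.

Boron loading modes (`cytob`): 0 none, 1 every cell, 2 random — a cell is
loaded iff a uniform(0,1) draw is below the acceptance threshold (0.5 by
default, exposed as `boron_threshold`).  Draws are consumed in row-major
cell order from a generator seeded by `seed`, so one integer reproduces a
layout exactly.  The nucleus inherits its cell's flag only when `nuclb`
is on; the buffer is loaded at `ppmw` when `watb` is on.

### Materials

Cytoplasm and nucleus share a five-element soft-tissue composition
(H 10.64, O 74.5, C 9.04, N 3.21, P 2.61 weight %) at 1.27 g/cm³; the
buffer is water (H 11.1 / O 88.9) at 1.00 g/cm³.  Boron is mixed in as
mass ppm of natural boron (19.9/80.1 atom % ¹⁰B/¹¹B; only ¹¹B feeds the
fusion channel) with the density held fixed — the convention under which
a loaded and an unloaded buffer of equal geometric thickness also have
equal mass thickness, so no thickness correction is needed for paired
comparisons.  A pure-hydrogen medium at each region's native density is
available as a null control with no alpha-producing targets.

### Stopping powers and ranges

Mass stopping powers use the shell-correction-free Bethe formula with
elemental mean excitation energies and Bragg additivity; below 1 MeV per
nucleon a matched power law S ∝ E^−0.5 continues the curve (the observed
slope of proton/alpha stopping between 0.1 and 1 MeV/u) and keeps the
CSDA integral finite.  CSDA ranges come from trapezoidal quadrature of
1/S on a 600-point logarithmic grid (1 keV–300 MeV) with log-log
interpolation and an exact inverse.  Against tabulated water values the
proton range is accurate to ≈0.5% at 25 MeV and ≈1% at 80 MeV; alpha
ranges at fusion energies (≈18 µm for 3.76 MeV in tissue) carry a larger
model uncertainty (tens of %), which affects absolute deposition patterns
but not the paired ratios the package reports.  Energies outside the
table are clamped with a warning; a user-supplied (E, S) table per
material overrides the analytic model.

### Reaction channels

Five absorbing channels are embedded as compact σ(E) tables (log-E linear
interpolation, exactly zero below each opening, nodes out to 250 MeV):

| channel | opening (MeV) | Q (MeV) | products |
|---|---|---|---|
| p + ¹¹B → 3α | exothermic (table from 0.1) | +8.682 | fixed energies 3.76 + 2×2.46 MeV, isotropic |
| ¹⁶O(p,α)¹³N | 5.66 (configurable) | −5.218 | two-body α, recoil deposited locally, ¹³N counted |
| ¹⁴N(p,α)¹¹C | 3.13 | −2.923 | two-body α, ¹¹C counted |
| ¹²C(p,p′3α) effective | 7.90 | −7.275 | three equal-share isotropic α |
| (p,n) effective on ¹⁶O | 10.0 | −9.4 | neutron counted; its energy booked as escaped |

The tables are shape-faithful digitizations of published evaluations:
the fusion channel carries the 675 keV resonance (peak ≈0.9 b) and a
slowly decaying high-energy tail; the boron-free channels sit at the
10–300 mb scale.  Absolute alpha yields are therefore
order-of-magnitude, not benchmark-grade; every derived statistic in the
package is either a ratio, an ordering, or a threshold effect, which are
robust to the absolute scale.

Two deliberate modelling choices: the ¹⁶O(p,α)¹³N opening uses the
conventionally quoted 5.66 MeV even though exact mass tables give
≈5.55 MeV — it is a configuration parameter, not silently corrected; and
fusion alphas use the fixed-energy model (entrance-channel energy not
added), with the per-event ledger booking the difference as an effective
Q so energy conservation stays exact.

### Transport

Protons: condensed-history steps limited by the region boundary and a 5%
maximum fractional energy loss (with an optional absolute cap when fine
depth-dose binning is requested).  Continuous loss follows the CSDA range
tables; the reaction probability over a step is 1 − exp(−Σ·Δs) with Σ
evaluated at the step midpoint energy (second-order accurate), the
channel drawn ∝ N_i σ_i and the reaction point from the truncated
exponential.  All channels absorb the proton.  Below the 0.1 MeV cutoff
the residual energy is deposited locally.  Protons travel in straight
lines by default so the depth-dose and thin-target oracles stay analytic;
a Highland small-angle Gaussian kick is available behind the
`scattering` flag.  Alphas are transported on straight lines with exact
per-region CSDA slowing (cutoff 0.05 MeV); heavy recoils deposit on the
spot and are tallied as a separate species so they inflate neither the
proton nor the alpha dose.

Per history the ledger source + ΣQ_effective = deposits + escapes closes
to arithmetic precision; the test suite enforces 10⁻⁴ MeV.

### Randomness and paired runs

A run seed (given, or drawn from OS entropy and recorded) spawns one
child stream per batch.  Inside a batch the per-step uniforms are drawn
for *all* histories regardless of alive state, and reaction products are
sampled from a generator keyed by (seed, batch, history, event index).
Consequently two runs sharing a seed but differing only in boron loading
follow common random numbers: histories that react identically in both
arms produce bit-identical secondaries.  This is what makes paired
enhancement-factor estimates sharp (variance ~ the handful of discordant
histories) and the boron ≥ normal dose orderings essentially
deterministic at matched seeds, even though alpha events are rare
(10⁻⁶–10⁻⁵ per proton at therapeutic energies and 100 ppm).

### Enhancement factor definition

"Average ratio of total alpha dose" admits two readings.  The package
computes both: the **ratio of batch-mean totals** (headline `value` —
well defined whenever the normal arm deposited anything at all) and the
**mean of per-batch ratios** over batch pairs with a nonzero
denominator.  With rare events many batches record zero alpha energy and
the per-batch ratio is 0/0; the ratio of means is the estimator that
survives this regime, which is why it is the headline.  A run whose
normal arm deposited nothing returns `defined=False` rather than a
number.

### SOBP construction

`nsobp` pristine energies are chosen so their CSDA ranges uniformly span
the modulated interval [(1 − mod_fraction)·R_max, R_max]
(mod_fraction = 0.25 by default, placing an 80 MeV plateau over roughly
3.8–5.1 cm of water).  Pristine depth-dose curves are S(E(z)) smoothed by
a Gaussian of 1.8% of range — range straggling (~1.2% in water) combined
with a typical accelerator energy spread — and weights flattening the sum
come from non-negative least squares on a 2000-point depth grid.  The
fit window extends slightly beyond the nominal plateau (1.2% proximal /
0.6% distal pads versus the 2% / 1.5% checked plateau) so flatness holds
to the plateau edges instead of sagging at the fit boundary; the nominal
plateau ripple is checked against 5% and a warning raised if `nsobp` is
too small to reach it.  `nsobp=1` degenerates to the pristine peak.

### Tallies and statistics

Energy deposition is scored per cell subdomain (cytoplasm/nucleus of
every cell), per bulk region, and per species, batch by batch;
uncertainties are standard errors over batches (bands at ±1 SE), and a
single-batch profile warns and reports NaN uncertainties.  The axial
alpha profile spans [0, −tcell] with 30 bins by default (1 µm bins for
30 µm cells); segment energy spreads over bins in proportion to z-overlap,
so the profile integral equals the cell-layer total exactly.  A **hit**
is one count per (alpha track, cell subdomain) pair — crossing into or
being born inside — the standard fluence-like single-count convention;
re-entries do not double count.  Hit studies over k independent seeds
report (lower, average, upper); both raw counts and per-source-particle
normalizations are available, since raw counts are only meaningful at a
stated history number.

## Study conditions and problem sizes

The default configuration is the reference scenario: a 20×20 array of
30 µm cells with 10 µm nuclei, buffer 1000 µm (5000 µm as the thick
variant), beam energies 25/35/70 MeV, disk source r0 = 0.30 mm (half the
array side), SOBP at 80 MeV with the cell layer at 10⁻⁴/4/4.5/4.8 cm,
100 ppm boron, 10 batches of 10⁴ histories.  The acceptance script runs
the entrance-position enhancement factor at 2×10⁶ protons per arm
(10 batches of 2×10⁵) — enough for a few dozen alpha events per arm,
which the paired design turns into a tight ratio — and measures the
random-boron fraction on a 100×100 array (10⁴ cells, 3σ binomial band
±0.015).  Tests that need guaranteed fusion events use a deliberately
boron-rich slow-down scenario (4 MeV beam degraded to ~1.2 MeV at the
cell layer, 2×10⁵ ppm) so that protons cross the 675 keV resonance
*inside* loaded cells; this is a physics stress test, not a clinical
condition.

## What the model does and does not capture

Passing tests demonstrate: correct geometry bookkeeping, exact energy
conservation, Bragg-peak placement at the CSDA range, threshold gating of
the boron-free channels, the null result of a hydrogen-only world, the
direction and pairing structure of boron enhancement, and the internal
consistency of all derived statistics.  They do **not** validate absolute
alpha yields or absolute dose against experiment: the cross-section
tables are shape-level, there is no intranuclear-cascade multiplicity, no
delta rays, no nuclear elastic scattering, no neutron or photon
transport (neutron births are counted, their energy booked as escaped),
no radioisotope decay (¹³N/¹¹C production is counted only), and energy-
loss straggling is not sampled (protons of equal energy stop at equal
depth; the SOBP model accounts for straggling only in its weight fit).
Multiple scattering is off by default.  Cells are rectangular boxes in a
single monolayer — no curved membranes, stacked layers, gaps or motion.
The `omp` input is carried as metadata only.

## Degenerate inputs and edge behaviour

Invalid configurations raise errors naming the offending field.  Points
exactly on shared faces belong to the lower-coordinate-owning box by the
half-open convention; z = 0 belongs to the buffer.  Source protons whose
disk position falls outside the array footprint (possible when
r0 > n·lcell/2) traverse ambient air only — the corner-cell shadowing the
reference disk radius produces is represented faithfully.  Cross sections
are zero above the last table node (tables extend to 250 MeV) and below
each opening.  `maxbch = 1` runs but yields NaN uncertainties with a
warning.
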