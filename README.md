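# pbftsim

A cellular-level Monte Carlo simulator for **proton boron fusion therapy
(PBFT)** dose enhancement.

PBFT proposes to boost proton radiotherapy by loading tumour cells with
boron: when a slowing proton meets a ¹¹B nucleus, the fusion reaction

```
p + ¹¹B → 3α     (one α at 3.76 MeV from ¹²C* → α + ⁸Be,
                  two α at 2.46 MeV from the ⁸Be breakup)
```

releases three short-range, densely ionizing alpha particles exactly where
cell killing is wanted.  Whether this mechanism actually adds meaningful
alpha dose at the cellular scale is contested, because protons also make
alphas without any boron — ¹⁶O(p,α)¹³N (opening at 5.66 MeV),
¹⁴N(p,α)¹¹C and ¹²C breakup all fire in ordinary tissue.  Settling the
question requires bookkeeping of alpha energy deposition in cytoplasm and
nucleus, cell by cell, for boron-loaded and boron-free arrays under
identical beams.

`pbftsim` provides that bookkeeping for radiobiology and medical-physics
users: an n×n monolayer of box cells (side `lcell`, thickness `tcell`,
centred cubic nucleus of side `lnuc`) under a water buffer slab of
thickness `tbuffer`, inside an ambient air sphere, irradiated by a disk
proton source — monoenergetic or a spread-out Bragg peak (SOBP) built by
non-negative least squares over pristine peaks.  Boron is mixed into
cytoplasm/nucleus/buffer in mass ppm at fixed density; the loading pattern
is uniform, absent, or random per cell (a cell is loaded iff a uniform
draw falls below 0.5).  A condensed-history transport engine (Bethe
stopping powers with CSDA ranges, embedded reaction-channel cross
sections, absorbing discrete reactions, straight-line alpha slowing)
produces per-region energy deposition with batch statistics, and the
analysis layer computes the quantities such a study reports:

* axial alpha depth-dose profiles over the cell layer, with batch
  standard errors;
* the **enhancement factor** `EF = D_α(boron) / D_α(normal)` from paired
  runs sharing random-number streams;
* the alpha **energy-deposition fraction** `f = D_α / (D_α + D_p)`;
* alpha **hit counts** per cytoplasm/nucleus with (lower, average, upper)
  bounds over repeated runs;
* 2-D track rasters, and a PHITS-style input deck of the same geometry
  for users who want to re-run the setup in a full transport code.

## Worked example

100 ppm of boron at the *entrance* of an 80 MeV SOBP should change the
alpha dose in the cell array by essentially nothing — at entrance energies
the fusion cross section is tiny and boron-free oxygen/carbon channels
dominate.  Paired runs (2×10⁶ protons per arm, shared seeds):

```python
from pbftsim import SimulationConfig, run, enhancement_factor

base = dict(n=20, e0=80.0, sobp=1, nsobp=25, tbuffer=1.0,
            maxcas=200_000, maxbch=10, seed=11)
normal = run(SimulationConfig(ppm=0,   cytob=0, nuclb=0, watb=0, **base))
boron  = run(SimulationConfig(ppm=100, cytob=1, nuclb=1, watb=1,
                              ppmw=100, **base))
ef = enhancement_factor(boron, normal)
print(f"enhancement factor at SOBP entrance: {ef.value:.4f}")
```

prints

```
enhancement factor at SOBP entrance: 1.0000
alpha dose in cell array (boron arm): 1.681e-05 +- 5.8e-06 MeV/proton
alpha births per 2e6 protons: 31
alpha hits: nucleus=5 cytoplasm=56
alpha energy fraction in cells: 4.92e-04
```

(the extra lines come from `batch_mean_se`, `count_hits` and
`energy_fraction` on the boron arm).  EF ≈ 1 here is the physics, not a
bug: the paired-stream design makes the ratio sharp even though alpha
events are rare, and the same machinery shows EF rising when the cell
layer sits near the distal end of the SOBP where protons are slow.

The same pipeline is scriptable from the shell:

```
pbftsim generate --n 20 --cytob 2 --seed 7          # boron layout, terminal grid
pbftsim run --e0 25 --tbuffer 1000 --cytob 1 --nuclb 1 --seed 7 --out r.json
pbftsim analyze --results r.json --profile-out profile.csv
pbftsim export-phits --n 20 --out cellarray.inp     # PHITS-style deck
pbftsim sobp --e0 80 --nsobp 25 --out sobp.csv      # SOBP weight table
```

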