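"""Simulation configuration: the 18 user inputs of the cell-array
generator plus run/physics options.

Field names follow the generator's conventional symbols: ``n`` (array edge
count, n^2 cells), ``lcell``/``tcell`` (cell side/thickness, µm), ``lnuc``
(nucleus side, µm), ``tbuffer`` (buffer slab thickness, µm), ``airad``
(ambient air radius, cm), ``maxcas``/``maxbch`` (histories per batch /
batches), ``e0`` (beam energy, MeV), ``sobp``/``nsobp`` (spread-out Bragg
peak flag / energy points), ``r0`` (disk source radius, mm), ``ppm``
(boron mass concentration in cells), ``cytob`` (cytoplasm boron mode:
0 normal, 1 all boron, 2 random), ``nuclb`` (nucleus boron flag), ``watb``
(buffer boron flag), ``ppmw`` (buffer boron ppm), ``omp`` (parallelization
flag, carried as metadata only).

Configs round-trip through flat YAML files keyed exactly by these names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Configuration rejected; the message names the offending field."""


@dataclass
class SimulationConfig:
    # --- cell array geometry ---
    n: int = 20
    lcell: float = 30.0      # µm
    tcell: float = 30.0      # µm
    lnuc: float = 10.0       # µm
    tbuffer: float = 1000.0  # µm
    airad: float = 10.0      # cm
    # --- run control ---
    maxcas: int = 10000
    maxbch: int = 10
    # --- source ---
    e0: float = 25.0         # MeV
    sobp: int = 0
    nsobp: int = 25
    r0: float = 0.30         # mm
    # --- boron loading ---
    ppm: float = 100.0
    cytob: int = 0
    nuclb: int = 0
    watb: int = 0
    ppmw: float = 100.0
    # --- misc ---
    omp: int = 0             # metadata only; no effect on results
    seed: Optional[int] = None
    # --- physics/run options (artifact additions) ---
    boron_threshold: float = 0.5    # random-boron acceptance threshold
    o16_threshold: float = 5.66     # O16(p,alpha)N13 channel opening, MeV
    proton_cutoff: float = 0.1      # MeV, residual deposited locally
    alpha_cutoff: float = 0.05      # MeV
    max_frac_loss: float = 0.05     # condensed-history step limiter
    scattering: bool = False        # small-angle multiple scattering (off: analytic oracle)
    sobp_mod_fraction: float = 0.25  # modulated fraction of the distal range

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        c = self
        def bad(field, msg):
            raise ConfigError(f"invalid {field!r}: {msg}")

        if int(c.n) != c.n or c.n < 1:
            bad("n", f"array edge count must be an integer >= 1, got {c.n}")
        for name in ("lcell", "tcell", "lnuc", "tbuffer", "airad", "r0"):
            if getattr(c, name) <= 0:
                bad(name, f"must be > 0, got {getattr(c, name)}")
        if c.lnuc >= c.lcell:
            bad("lnuc", f"nucleus side {c.lnuc} must be < cell side {c.lcell}")
        if c.lnuc > c.tcell:
            bad("lnuc", f"nucleus side {c.lnuc} must be <= cell thickness {c.tcell}")
        if c.e0 <= 0:
            bad("e0", f"beam energy must be > 0, got {c.e0}")
        if c.ppm < 0:
            bad("ppm", f"must be >= 0, got {c.ppm}")
        if c.ppmw < 0:
            bad("ppmw", f"must be >= 0, got {c.ppmw}")
        if c.cytob not in (0, 1, 2):
            bad("cytob", f"must be 0, 1 or 2, got {c.cytob}")
        for name in ("sobp", "nuclb", "watb", "omp"):
            if getattr(c, name) not in (0, 1):
                bad(name, f"must be 0 or 1, got {getattr(c, name)}")
        if c.maxcas < 1:
            bad("maxcas", f"must be >= 1, got {c.maxcas}")
        if c.maxbch < 1:
            bad("maxbch", f"must be >= 1, got {c.maxbch}")
        if c.sobp == 1 and c.nsobp < 2:
            bad("nsobp", f"SOBP needs >= 2 energy points, got {c.nsobp}")
        if not (0.0 <= c.boron_threshold <= 1.0):
            bad("boron_threshold", f"must be in [0, 1], got {c.boron_threshold}")
        if c.o16_threshold <= 0:
            bad("o16_threshold", f"must be > 0, got {c.o16_threshold}")
        if not (0.0 < c.max_frac_loss < 1.0):
            bad("max_frac_loss", f"must be in (0, 1), got {c.max_frac_loss}")
        # geometry must fit inside the ambient sphere
        half = c.n * c.lcell / 2.0
        extent = max(
            (2 * half * half + c.tcell ** 2) ** 0.5,
            (2 * half * half + c.tbuffer ** 2) ** 0.5,
        )
        if extent >= c.airad * 1e4:
            bad("airad", f"ambient radius {c.airad} cm does not enclose the "
                         f"array+buffer (extent {extent / 1e4:.3f} cm)")

    # -- file round trip --------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a key-value mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)
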