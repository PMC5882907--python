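"""Model parameters and reduced units.

The model works in reduced units: the unit of length is sigma = 2 nm (one
DNA monomer diameter), the unit of energy is epsilon = 1 kBT, and all bead
masses are 1.  Internally all coordinates are kept in nanometres and all
energies in kBT; the internal time unit is then 1 nm * sqrt(m/kBT), so one
MD time unit tau_MD = sigma*sqrt(m/epsilon) equals SIGMA_NM internal time
units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

# bead species codes (used in Topology.species arrays and kernels)
DNA = 0
CORE = 1
CROWDER = 2

SPECIES_NAMES = {DNA: "DNA", CORE: "CORE", CROWDER: "CROWDER"}

#: unit of length, nm (one DNA monomer diameter)
SIGMA_NM = 2.0
#: WCA cutoff in units of sigma (potential minimum, purely repulsive branch)
RC_SIGMA = 2.0 ** (1.0 / 6.0)
#: nucleosome core (and crowder) diameter, nm
CORE_DIAMETER_NM = 7.0
#: crowder diameter, nm (same as the core particles)
CROWDER_DIAMETER_NM = 7.0


def crowder_volume_nm3(diameter_nm: float = CROWDER_DIAMETER_NM) -> float:
    """Volume of one spherical crowder, (pi/6) d^3."""
    return np.pi / 6.0 * diameter_nm**3


@dataclass
class ForceFieldParams:
    """All force-field constants, in reduced units (sigma, kBT).

    ``r0`` shifts displace the repulsive LJ core outward so that beads of
    different diameters interact at the correct contact distance: 0 for
    DNA-DNA, 2.5 sigma for core-core (and anything involving a crowder,
    which has the same 7 nm diameter), 1.25 sigma for core-DNA.
    """

    sigma: float = SIGMA_NM            # nm
    epsilon: float = 1.0               # kBT
    rc: float = RC_SIGMA * SIGMA_NM    # nm, = 2^(1/6) sigma
    r0_dna_dna: float = 0.0            # nm
    r0_core_core: float = 2.5 * SIGMA_NM
    r0_core_dna: float = 1.25 * SIGMA_NM
    k_fene: float = 30.0               # kBT / sigma^2
    r_b: float = 1.5 * SIGMA_NM        # nm, FENE maximum extension
    k_angle: float = 25.0              # kBT / rad^2
    theta0: float = 0.0                # rad, straight chain
    k_wrap: float = 1000.0             # kBT / sigma^2, wrap + loop restraints
    k_collapse: float = 15.0           # kBT / sigma^2, clutch collapse pull
    mass: float = 1.0                  # reduced

    def __post_init__(self) -> None:
        if not np.isclose(self.rc, RC_SIGMA * self.sigma):
            raise ValueError("rc must equal 2^(1/6) sigma (purely repulsive LJ)")
        for name in ("k_fene", "k_angle", "k_wrap", "k_collapse"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    # --- unit helpers -------------------------------------------------
    @property
    def k_fene_nm(self) -> float:
        """FENE stiffness in kBT/nm^2."""
        return self.k_fene / self.sigma**2

    @property
    def k_wrap_nm(self) -> float:
        return self.k_wrap / self.sigma**2

    @property
    def k_collapse_nm(self) -> float:
        return self.k_collapse / self.sigma**2

    @property
    def tau_md(self) -> float:
        """MD time unit sigma*sqrt(m/epsilon), in internal time units."""
        return self.sigma * np.sqrt(self.mass / self.epsilon)

    def r0_matrix(self) -> np.ndarray:
        """Symmetric 3x3 table of r0 shifts (nm), indexed by species code."""
        r0 = np.zeros((3, 3))
        r0[DNA, DNA] = self.r0_dna_dna
        r0[CORE, CORE] = self.r0_core_core
        r0[DNA, CORE] = r0[CORE, DNA] = self.r0_core_dna
        # crowders mirror cores (same 7 nm diameter)
        r0[CROWDER, CROWDER] = self.r0_core_core
        r0[CORE, CROWDER] = r0[CROWDER, CORE] = self.r0_core_core
        r0[DNA, CROWDER] = r0[CROWDER, DNA] = self.r0_core_dna
        return r0

    # --- plain-text config I/O ---------------------------------------
    def to_file(self, path: str | Path) -> None:
        lines = ["# clutchpmf force-field constants, v1", ""]
        for key, val in asdict(self).items():
            lines.append(f"{key} = {val!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "ForceFieldParams":
        kwargs = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, val = line.partition("=")
            kwargs[key.strip()] = float(val)
        return cls(**kwargs)


@dataclass
class ClutchSpec:
    """Geometry of one nucleosome clutch.

    Euchromatin and heterochromatin clutches differ only in nucleosome
    count (11 vs 20) at a fixed 30 nm collapsed diameter; each nucleosome
    wraps 24 DNA monomers (144 bp) in 1.75 turns and consecutive
    nucleosomes are separated by 5 linker monomers (30 bp).
    """

    n_nucleosomes: int
    label: str
    wrap_monomers: int = 24
    wrap_turns: float = 1.75
    linker_monomers: int = 5
    target_diameter: float = 30.0  # nm

    def __post_init__(self) -> None:
        if self.n_nucleosomes < 1:
            raise ValueError("n_nucleosomes must be >= 1")
        if self.target_diameter <= CORE_DIAMETER_NM:
            raise ValueError("target_diameter must exceed the core diameter")

    @property
    def n_dna(self) -> int:
        """Total DNA bead count: wrapped plus linker monomers."""
        return (self.wrap_monomers * self.n_nucleosomes
                + self.linker_monomers * (self.n_nucleosomes - 1))

    @property
    def target_radius(self) -> float:
        return self.target_diameter / 2.0


def euchromatin_spec() -> ClutchSpec:
    """11 nucleosomes in a 30 nm clutch (euchromatin density)."""
    return ClutchSpec(n_nucleosomes=11, label="euchromatin")


def heterochromatin_spec() -> ClutchSpec:
    """20 nucleosomes in a 30 nm clutch (heterochromatin density)."""
    return ClutchSpec(n_nucleosomes=20, label="heterochromatin")


@dataclass
class CrowdingCondition:
    """Crowder bath condition: volume fraction and crowder size."""

    phi_c: float
    crowder_diameter: float = CROWDER_DIAMETER_NM  # nm

    def __post_init__(self) -> None:
        if not (0.0 <= self.phi_c < 0.74):
            raise ValueError("phi_c must lie in [0, 0.74)")
        if self.crowder_diameter <= 0:
            raise ValueError("crowder_diameter must be positive")

    def n_crowders(self, box_edge: float) -> int:
        if box_edge <= 0:
            raise ValueError("box_edge must be positive")
        v_box = box_edge**3
        return int(np.floor(self.phi_c * v_box / crowder_volume_nm3(self.crowder_diameter)))


@dataclass
class SimulationParams:
    """Langevin dynamics parameters.

    ``dt`` is in units of tau_MD; ``gamma`` is the friction per unit mass
    in 1/tau_MD.  Temperature is fixed at 1 kBT.
    """

    dt: float = 0.005            # tau_MD
    temperature: float = 1.0     # kBT
    gamma: float = 1.0           # 1 / tau_MD
    n_steps: int = 100_000
    equilibration: int = 10_000
    seed: int = 0
    neighbor_skin: float = 1.5   # nm
    sample_every: int = 5        # constraint-force sampling interval, steps

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def dt_internal(self, ff: ForceFieldParams) -> float:
        """Timestep in internal units (nm * sqrt(m/kBT))."""
        return self.dt * ff.tau_md

    def gamma_internal(self, ff: ForceFieldParams) -> float:
        return self.gamma / ff.tau_md
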