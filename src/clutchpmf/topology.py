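"""Topology container: beads, bonds, angles, restraints, box, coordinates.

A :class:`Topology` is a plain array-of-structs container shared by the
builders, the force field and the dynamics engine.  Restraints come in two
forms: harmonic pair restraints (wrap and loop-parallel tethers, each a
``(i, j, k, r0)`` record) and per-clutch collapse restraints (a flat-bottom
harmonic on each core's distance from the instantaneous centroid of its
clutch's cores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .params import CORE, CROWDER, DNA, SPECIES_NAMES


@dataclass
class CollapseRestraint:
    """Flat-bottom pull of every core toward its clutch core-centroid.

    Zero inside radius ``r_t`` (nm); harmonic with stiffness ``k``
    (kBT/nm^2) beyond.  The centre is the instantaneous centroid of
    ``core_indices``, so the restraint is translation invariant.
    """

    core_indices: np.ndarray  # int32
    r_t: float
    k: float


@dataclass
class Topology:
    species: np.ndarray                 # (N,) int8: DNA / CORE / CROWDER
    group: np.ndarray                   # (N,) int32: clutch id, -1 for crowders
    coords: np.ndarray                  # (N, 3) float64, nm
    bonds: np.ndarray                   # (nb, 2) int32, FENE pairs
    angles: np.ndarray                  # (na, 3) int32, consecutive bond triples
    hr_idx: np.ndarray                  # (m, 2) int32 harmonic restraint pairs
    hr_k: np.ndarray                    # (m,) kBT/nm^2
    hr_r0: np.ndarray                   # (m,) rest length, nm
    hr_kind: list = field(default_factory=list)   # per-restraint label
    collapse: list = field(default_factory=list)  # list[CollapseRestraint]
    box: float | None = None            # cubic edge, nm; None = open boundary
    ideal_crowders: bool = False        # crowder-crowder interactions off
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.species)

    def indices_of(self, species: int, group: int | None = None) -> np.ndarray:
        mask = self.species == species
        if group is not None:
            mask &= self.group == group
        return np.nonzero(mask)[0].astype(np.int32)

    def core_indices(self, group: int) -> np.ndarray:
        return self.indices_of(CORE, group)

    @property
    def groups(self) -> np.ndarray:
        g = np.unique(self.group)
        return g[g >= 0]

    def copy(self) -> "Topology":
        return Topology(
            species=self.species.copy(),
            group=self.group.copy(),
            coords=self.coords.copy(),
            bonds=self.bonds.copy(),
            angles=self.angles.copy(),
            hr_idx=self.hr_idx.copy(),
            hr_k=self.hr_k.copy(),
            hr_r0=self.hr_r0.copy(),
            hr_kind=list(self.hr_kind),
            collapse=[CollapseRestraint(c.core_indices.copy(), c.r_t, c.k)
                      for c in self.collapse],
            box=self.box,
            ideal_crowders=self.ideal_crowders,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------
    @staticmethod
    def empty() -> "Topology":
        return Topology(
            species=np.zeros(0, np.int8),
            group=np.zeros(0, np.int32),
            coords=np.zeros((0, 3)),
            bonds=np.zeros((0, 2), np.int32),
            angles=np.zeros((0, 3), np.int32),
            hr_idx=np.zeros((0, 2), np.int32),
            hr_k=np.zeros(0),
            hr_r0=np.zeros(0),
        )

    @staticmethod
    def merge(a: "Topology", b: "Topology", renumber_groups: bool = True) -> "Topology":
        """Concatenate two topologies (bead indices of ``b`` are offset)."""
        off = a.n_beads
        group_b = b.group.copy()
        if renumber_groups and len(group_b):
            shift = (a.group.max(initial=-1) + 1) if a.n_beads else 0
            group_b[group_b >= 0] += shift
        return Topology(
            species=np.concatenate([a.species, b.species]),
            group=np.concatenate([a.group, group_b]),
            coords=np.vstack([a.coords, b.coords]),
            bonds=np.vstack([a.bonds, b.bonds + off]).astype(np.int32),
            angles=np.vstack([a.angles, b.angles + off]).astype(np.int32),
            hr_idx=np.vstack([a.hr_idx, b.hr_idx + off]).astype(np.int32),
            hr_k=np.concatenate([a.hr_k, b.hr_k]),
            hr_r0=np.concatenate([a.hr_r0, b.hr_r0]),
            hr_kind=list(a.hr_kind) + list(b.hr_kind),
            collapse=[CollapseRestraint(c.core_indices.copy(), c.r_t, c.k)
                      for c in a.collapse]
                     + [CollapseRestraint(c.core_indices + off, c.r_t, c.k)
                        for c in b.collapse],
            box=a.box if a.box is not None else b.box,
            ideal_crowders=a.ideal_crowders or b.ideal_crowders,
            meta={**a.meta, **b.meta},
        )

    # --- serialization ------------------------------------------------
    def save(self, path) -> None:
        """Write the topology to an HDF5 container."""
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "clutchpmf-topology-v1"
            f.attrs["box"] = -1.0 if self.box is None else self.box
            f.attrs["ideal_crowders"] = self.ideal_crowders
            for name in ("species", "group", "coords", "bonds", "angles",
                         "hr_idx", "hr_k", "hr_r0"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("hr_kind",
                             data=np.array(self.hr_kind, dtype="S32"))
            grp = f.create_group("collapse")
            for i, c in enumerate(self.collapse):
                g = grp.create_group(str(i))
                g.create_dataset("core_indices", data=c.core_indices)
                g.attrs["r_t"] = c.r_t
                g.attrs["k"] = c.k

    @staticmethod
    def load(path) -> "Topology":
        with h5py.File(path, "r") as f:
            box = float(f.attrs["box"])
            collapse = []
            for key in sorted(f["collapse"], key=int):
                g = f["collapse"][key]
                collapse.append(CollapseRestraint(
                    core_indices=g["core_indices"][:].astype(np.int32),
                    r_t=float(g.attrs["r_t"]), k=float(g.attrs["k"])))
            return Topology(
                species=f["species"][:].astype(np.int8),
                group=f["group"][:].astype(np.int32),
                coords=f["coords"][:].astype(np.float64),
                bonds=f["bonds"][:].astype(np.int32),
                angles=f["angles"][:].astype(np.int32),
                hr_idx=f["hr_idx"][:].astype(np.int32),
                hr_k=f["hr_k"][:].astype(np.float64),
                hr_r0=f["hr_r0"][:].astype(np.float64),
                hr_kind=[s.decode() for s in f["hr_kind"][:]],
                collapse=collapse,
                box=None if box < 0 else box,
                ideal_crowders=bool(f.attrs["ideal_crowders"]),
            )

    def write_xyz(self, path, comment: str = "") -> None:
        """Export an XYZ snapshot (one pseudo-atom per bead)."""
        box = 0.0 if self.box is None else self.box
        with open(path, "w") as fh:
            fh.write(f"{self.n_beads}\n")
            fh.write(f"box={box:.3f} nm {comment}\n")
            for sp, (x, y, z) in zip(self.species, self.coords):
                fh.write(f"{SPECIES_NAMES[int(sp)][:3]} {x:.4f} {y:.4f} {z:.4f}\n")
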