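"""Energies and forces: purely repulsive shifted LJ (WCA) pairs, FENE
bonds, harmonic angles, and harmonic/flat-bottom restraints.

All pair interactions are excluded-volume only.  The pair potential is

    U(r) = 4 eps [ (sigma/(r-r0))^12 - (sigma/(r-r0))^6 ] + eps,
           for 0 < r - r0 < rc = 2^(1/6) sigma;  0 elsewhere,

where the shift r0 sets the effective particle size per species pair.
Approaches with r - r0 <= 0 are treated as divergent and flagged, never
clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import ForceFieldParams
from .topology import Topology


class DivergentPairError(ValueError):
    """A pair of beads is at or inside its divergence distance r0."""


class BondOverstretchError(ValueError):
    """A FENE bond is at or beyond its maximum extension R_b."""


@dataclass(frozen=True)
class PairInteraction:
    """One species pair's repulsive shifted-LJ parameters."""

    r0: float       # shift, nm
    sigma: float    # nm
    epsilon: float  # kBT
    rc: float       # nm, cutoff beyond r0

    def energy(self, r: float) -> float:
        return pair_energy(r, self)

    def force(self, r: float) -> float:
        return pair_force(r, self)


def pair_interaction(ff: ForceFieldParams, species_a: int, species_b: int) -> PairInteraction:
    return PairInteraction(r0=float(ff.r0_matrix()[species_a, species_b]),
                           sigma=ff.sigma, epsilon=ff.epsilon, rc=ff.rc)


def pair_energy(r, p: PairInteraction):
    """WCA energy at distance ``r`` (scalar or array), kBT."""
    r = np.asarray(r, dtype=float)
    rr = r - p.r0
    if np.any(rr <= 0):
        raise DivergentPairError(f"pair distance {r} is at or inside r0={p.r0}")
    s6 = (p.sigma / rr) ** 6
    u = np.where(rr < p.rc, 4.0 * p.epsilon * (s6 * s6 - s6) + p.epsilon, 0.0)
    return float(u) if u.ndim == 0 else u


def pair_force(r, p: PairInteraction):
    """-dU/dr of the WCA pair term (positive = repulsive)."""
    r = np.asarray(r, dtype=float)
    rr = r - p.r0
    if np.any(rr <= 0):
        raise DivergentPairError(f"pair distance {r} is at or inside r0={p.r0}")
    s6 = (p.sigma / rr) ** 6
    f = np.where(rr < p.rc, 4.0 * p.epsilon * (12.0 * s6 * s6 - 6.0 * s6) / rr, 0.0)
    return float(f) if f.ndim == 0 else f


def fene_energy(r, ff: ForceFieldParams):
    """FENE bond energy -1/2 k R_b^2 ln(1-(r/R_b)^2), kBT (r in nm)."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("bond length must be non-negative")
    if np.any(r >= ff.r_b):
        raise BondOverstretchError(f"bond length {r} >= R_b = {ff.r_b}")
    u = -0.5 * ff.k_fene_nm * ff.r_b**2 * np.log(1.0 - (r / ff.r_b) ** 2)
    return float(u) if u.ndim == 0 else u


def angle_energy(theta, ff: ForceFieldParams):
    """Harmonic bending energy 1/2 k (theta - theta0)^2, theta in rad.

    ``theta`` is the angle between consecutive *bond vectors*, so a
    straight chain has theta = 0.
    """
    theta = np.asarray(theta, dtype=float)
    u = 0.5 * ff.k_angle * (theta - ff.theta0) ** 2
    return float(u) if u.ndim == 0 else u


@dataclass
class EnergyReport:
    pair: float
    fene: float
    angle: float
    restraint: float

    @property
    def total(self) -> float:
        return self.pair + self.fene + self.angle + self.restraint


def _collapse_arrays(topology: Topology):
    off = np.zeros(len(topology.collapse) + 1, np.int32)
    cores = []
    rt = np.zeros(len(topology.collapse))
    kk = np.zeros(len(topology.collapse))
    for i, c in enumerate(topology.collapse):
        cores.append(np.asarray(c.core_indices, np.int32))
        off[i + 1] = off[i] + len(c.core_indices)
        rt[i] = c.r_t
        kk[i] = c.k
    cat = np.concatenate(cores).astype(np.int32) if cores else np.zeros(0, np.int32)
    return off, cat, rt, kk


def _kernel_args(topology: Topology, ff: ForceFieldParams):
    box = -1.0 if topology.box is None else float(topology.box)
    col_off, col_cores, col_rt, col_k = _collapse_arrays(topology)
    return dict(
        species=topology.species.astype(np.int8),
        box=box,
        r0_mat=ff.r0_matrix(),
        sigma=ff.sigma,
        eps=ff.epsilon,
        rc=ff.rc,
        bonds=topology.bonds,
        kfene=ff.k_fene_nm,
        rb=ff.r_b,
        angles=topology.angles,
        k_angle=ff.k_angle,
        hr_idx=topology.hr_idx,
        hr_k=topology.hr_k,
        hr_r0=topology.hr_r0,
        col_off=col_off,
        col_cores=col_cores,
        col_rt=col_rt,
        col_k=col_k,
    )


def _build_pairs(coords, species, box, ff: ForceFieldParams, ideal_crowders: bool,
                 skin: float = 0.0):
    range2 = (ff.r0_matrix() + ff.rc + skin) ** 2
    rmax = float(np.sqrt(range2.max()))
    cap = 80 * len(coords) + 1024
    while True:
        pair_i = np.empty(cap, np.int32)
        pair_j = np.empty(cap, np.int32)
        n = _kernels._neighbor_pairs(np.ascontiguousarray(coords), species,
                                     box, rmax, range2, ideal_crowders,
                                     pair_i, pair_j)
        if n >= 0:
            return pair_i, pair_j, n
        cap *= 4


def system_energy_forces(topology: Topology, coords: np.ndarray | None = None,
                         ff: ForceFieldParams | None = None):
    """Total energy breakdown and per-bead forces (exact gradients).

    Uses cell-list neighbor search with the minimum-image convention when
    the topology has a box.  Divergent configurations are reported with
    ``pair = +inf`` and forces of ``nan``.
    """
    ff = ff or ForceFieldParams()
    coords = np.ascontiguousarray(topology.coords if coords is None else coords,
                                  dtype=np.float64)
    args = _kernel_args(topology, ff)
    pair_i, pair_j, npairs = _build_pairs(coords, args["species"], args["box"],
                                          ff, topology.ideal_crowders)
    e_pair, e_fene, e_angle, e_rest, status = _kernels._energy_terms(
        coords, args["species"], args["box"], args["r0_mat"], args["sigma"],
        args["eps"], args["rc"], pair_i, pair_j, npairs,
        args["bonds"], args["kfene"], args["rb"],
        args["angles"], args["k_angle"],
        args["hr_idx"], args["hr_k"], args["hr_r0"],
        args["col_off"], args["col_cores"], args["col_rt"], args["col_k"])
    report = EnergyReport(pair=e_pair, fene=e_fene, angle=e_angle,
                          restraint=e_rest)
    forces = np.empty_like(coords)
    fstatus = _kernels._forces(
        coords, args["species"], args["box"], args["r0_mat"], args["sigma"],
        args["eps"], args["rc"], pair_i, pair_j, npairs,
        args["bonds"], args["kfene"], args["rb"],
        args["angles"], args["k_angle"],
        args["hr_idx"], args["hr_k"], args["hr_r0"],
        args["col_off"], args["col_cores"], args["col_rt"], args["col_k"],
        forces, 0.0)
    if status != _kernels.STATUS_OK or fstatus != _kernels.STATUS_OK:
        forces[:] = np.nan
    return report, forces


def system_energy_bruteforce(topology: Topology, coords: np.ndarray | None = None,
                             ff: ForceFieldParams | None = None) -> float:
    """O(N^2) reference for the total nonbonded pair energy (tests)."""
    ff = ff or ForceFieldParams()
    coords = topology.coords if coords is None else coords
    sp = topology.species
    r0m = ff.r0_matrix()
    d = coords[:, None, :] - coords[None, :, :]
    if topology.box is not None:
        d -= topology.box * np.rint(d / topology.box)
    r = np.sqrt((d ** 2).sum(-1))
    r0 = r0m[sp[:, None], sp[None, :]]
    iu = np.triu_indices(len(coords), k=1)
    rr = (r - r0)[iu]
    if topology.ideal_crowders:
        keep = ~((sp[iu[0]] == 2) & (sp[iu[1]] == 2))
        rr = rr[keep]
    if np.any(rr <= 0):
        return np.inf
    s6 = (ff.sigma / rr) ** 6
    u = np.where(rr < ff.rc, 4.0 * ff.epsilon * (s6 * s6 - s6) + ff.epsilon, 0.0)
    return float(u.sum())


def inter_group_energy(conf_a: np.ndarray, species_a: np.ndarray,
                       conf_b: np.ndarray, species_b: np.ndarray,
                       displacement: float,
                       ff: ForceFieldParams | None = None) -> float:
    """Cross-group WCA energy for two conformers at center displacement
    ``displacement`` along x (nm); +inf on any divergent cross pair.

    Intra-group terms are excluded by construction: this is the
    U_inter entering the exponential-insertion PMF estimator.
    """
    ff = ff or ForceFieldParams()
    return float(_kernels._cross_pair_energy(
        np.ascontiguousarray(conf_a, np.float64), species_a.astype(np.int8),
        np.ascontiguousarray(conf_b, np.float64), species_b.astype(np.int8),
        float(displacement), ff.r0_matrix(), ff.sigma, ff.epsilon, ff.rc))
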