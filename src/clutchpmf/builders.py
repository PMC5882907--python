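"""Topology builders: bare DNA chains, nucleosome chains, collapsed
clutches, crowder baths, and two-clutch systems.

Geometry conventions (nm): DNA monomers are 2 nm beads bonded at ~1 sigma;
each nucleosome core is wrapped by 24 DNA monomers on a 1.75-turn helix of
radius 4.5 nm (core-DNA contact distance r0 + sigma) and pitch 2 nm, so
adjacent gyres sit close and parallel; consecutive nucleosomes are joined
by 5 linker monomers.  Chains begin and end with wrapped segments.
"""

from __future__ import annotations

import numpy as np

from .params import (CORE, CROWDER, DNA, ClutchSpec, CrowdingCondition,
                     ForceFieldParams, SimulationParams)
from .topology import CollapseRestraint, Topology

WRAP_HELIX_RADIUS = 4.5   # nm = r0(core-DNA) + sigma
WRAP_HELIX_PITCH = 2.0    # nm, one DNA diameter per turn
LOOP_PARALLEL_OFFSET = 14  # beads ~ one helical turn (24/1.75 ~ 13.7)


class BuildError(ValueError):
    """Invalid builder specification or infeasible geometry."""


class PackingError(RuntimeError):
    """Could not place particles without excluded-volume violations."""


class CalibrationError(RuntimeError):
    """Collapse calibration failed to reach the target extent."""

    def __init__(self, msg: str, achieved_extent: float):
        super().__init__(msg)
        self.achieved_extent = achieved_extent


# ----------------------------------------------------------------------
def wlc_coords(n_monomers: int, k_angle: float, bond: float,
               rng: np.random.Generator) -> np.ndarray:
    """Chain coordinates with bending angles drawn from the Boltzmann
    distribution sin(theta) exp(-k theta^2/2) and uniform azimuths.

    This is the exact equilibrium of the phantom (non-interacting)
    discrete worm-like chain, used to start chain simulations near
    equilibrium so that slow global modes need no long burn-in.
    """
    # rejection sampling: Rayleigh envelope theta exp(-k theta^2/2),
    # acceptance sin(theta)/theta
    thetas = np.empty(n_monomers - 2)
    filled = 0
    while filled < len(thetas):
        m = 2 * (len(thetas) - filled) + 8
        cand = np.sqrt(-2.0 * np.log(rng.random(m))) / np.sqrt(k_angle)
        keep = cand[(rng.random(m) < np.sinc(cand / np.pi)) & (cand < np.pi)]
        take = min(len(keep), len(thetas) - filled)
        thetas[filled:filled + take] = keep[:take]
        filled += take
    coords = np.zeros((n_monomers, 3))
    u = np.array([1.0, 0.0, 0.0])
    coords[1] = coords[0] + bond * u
    for i in range(n_monomers - 2):
        # rotate u by theta about a random perpendicular axis
        phi = rng.random() * 2.0 * np.pi
        a = np.cross(u, [0.0, 0.0, 1.0])
        if np.linalg.norm(a) < 1e-9:
            a = np.cross(u, [0.0, 1.0, 0.0])
        a /= np.linalg.norm(a)
        b = np.cross(u, a)
        perp = np.cos(phi) * a + np.sin(phi) * b
        theta = thetas[i]
        u = np.cos(theta) * u + np.sin(theta) * perp
        coords[i + 2] = coords[i + 1] + bond * u
    return coords


def build_dna_chain(n_monomers: int, seed: int = 0,
                    ff: ForceFieldParams | None = None,
                    init: str = "straight") -> Topology:
    """A linear chain of DNA monomers at 1-sigma bond length.

    FENE bonds join consecutive beads; every interior bead carries a
    bending term on its two adjacent bond vectors.  ``init`` selects the
    starting geometry: a straight rod, or an equilibrium worm-like-chain
    draw (``"wlc"``, retried until free of excluded-volume overlaps).
    """
    ff = ff or ForceFieldParams()
    if n_monomers < 2:
        raise BuildError("a DNA chain needs at least 2 monomers")
    if init == "wlc":
        rng = np.random.default_rng(seed)
        for _ in range(100):
            coords = wlc_coords(n_monomers, ff.k_angle, 0.97 * ff.sigma, rng)
            d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
            iu = np.triu_indices(n_monomers, k=2)
            if d[iu].min() > 0.8 * ff.sigma:
                break
        else:
            raise BuildError("could not draw an overlap-free chain")
    elif init == "straight":
        coords = np.zeros((n_monomers, 3))
        coords[:, 0] = ff.sigma * np.arange(n_monomers)
    else:
        raise BuildError(f"unknown chain init {init!r}")
    bonds = np.column_stack([np.arange(n_monomers - 1),
                             np.arange(1, n_monomers)]).astype(np.int32)
    angles = np.column_stack([np.arange(n_monomers - 2),
                              np.arange(1, n_monomers - 1),
                              np.arange(2, n_monomers)]).astype(np.int32)
    return Topology(
        species=np.full(n_monomers, DNA, np.int8),
        group=np.zeros(n_monomers, np.int32),
        coords=coords,
        bonds=bonds,
        angles=angles,
        hr_idx=np.zeros((0, 2), np.int32),
        hr_k=np.zeros(0),
        hr_r0=np.zeros(0),
        meta={"builder": "dna_chain", "seed": seed},
    )


def build_nucleosome_chain(spec: ClutchSpec, ff: ForceFieldParams | None = None,
                           seed: int = 0) -> Topology:
    """An uncollapsed chain of nucleosomes.

    Each nucleosome contributes 24 wrapped DNA beads tethered to its core
    by stiff harmonic restraints at their helix rest distances, plus
    loop-parallel restraints between beads one helical turn apart;
    nucleosomes are joined by 5 straight linker beads.
    """
    ff = ff or ForceFieldParams()
    if WRAP_HELIX_RADIUS <= ff.r0_core_dna:
        raise BuildError("wrap helix radius inside the core-DNA contact distance")

    n_nuc = spec.n_nucleosomes
    n_wrap = spec.wrap_monomers
    n_link = spec.linker_monomers
    n_dna = spec.n_dna

    dphi = spec.wrap_turns * 2.0 * np.pi / (n_wrap - 1)
    height = WRAP_HELIX_PITCH * spec.wrap_turns
    z_per_phi = WRAP_HELIX_PITCH / (2.0 * np.pi)

    # nucleosome spacing chosen so the 6 linker bond segments are ~1 sigma
    phi_end = (n_wrap - 1) * dphi
    chord = 2.0 * WRAP_HELIX_RADIUS * np.sin(((phi_end % (2 * np.pi))) / 2.0)
    gap_target = (n_link + 1) * ff.sigma * 1.0
    axial_gap = np.sqrt(max(gap_target**2 - chord**2, (2.0 * ff.sigma) ** 2))
    spacing = axial_gap + height

    dna_xyz = np.zeros((n_dna, 3))
    core_xyz = np.zeros((n_nuc, 3))
    wrap_pairs = []   # (dna_idx, core_idx, rest)
    loop_pairs = []   # (dna_i, dna_j)

    idx = 0
    for k in range(n_nuc):
        x0 = k * spacing
        core_xyz[k] = (x0, 0.0, 0.0)
        start = idx
        for i in range(n_wrap):
            phi = i * dphi
            z_ax = -height / 2.0 + z_per_phi * phi
            dna_xyz[idx] = (x0 + z_ax,
                            WRAP_HELIX_RADIUS * np.cos(phi),
                            WRAP_HELIX_RADIUS * np.sin(phi))
            rest = float(np.sqrt(WRAP_HELIX_RADIUS**2 + z_ax**2))
            wrap_pairs.append((idx, n_dna + k, rest))
            idx += 1
        for i in range(start, start + n_wrap - LOOP_PARALLEL_OFFSET):
            loop_pairs.append((i, i + LOOP_PARALLEL_OFFSET))
        if k < n_nuc - 1:
            # straight linker from the last wrap bead to the next wrap start
            p_from = dna_xyz[idx - 1]
            phi0 = 0.0
            p_to = np.array([(k + 1) * spacing - height / 2.0,
                             WRAP_HELIX_RADIUS * np.cos(phi0),
                             WRAP_HELIX_RADIUS * np.sin(phi0)])
            for i in range(1, n_link + 1):
                t = i / (n_link + 1)
                dna_xyz[idx] = p_from + t * (p_to - p_from)
                idx += 1
    assert idx == n_dna

    coords = np.vstack([dna_xyz, core_xyz])
    species = np.concatenate([np.full(n_dna, DNA, np.int8),
                              np.full(n_nuc, CORE, np.int8)])
    bonds = np.column_stack([np.arange(n_dna - 1),
                             np.arange(1, n_dna)]).astype(np.int32)
    angles = np.column_stack([np.arange(n_dna - 2),
                              np.arange(1, n_dna - 1),
                              np.arange(2, n_dna)]).astype(np.int32)

    hr_idx = np.array([(i, j) for i, j, _ in wrap_pairs]
                      + [(i, j) for i, j in loop_pairs], np.int32)
    hr_r0 = np.array([r for _, _, r in wrap_pairs]
                     + [WRAP_HELIX_PITCH] * len(loop_pairs))
    hr_k = np.full(len(hr_idx), ff.k_wrap_nm)
    hr_kind = ["wrap"] * len(wrap_pairs) + ["loop-parallel"] * len(loop_pairs)

    topo = Topology(
        species=species,
        group=np.zeros(len(species), np.int32),
        coords=coords,
        bonds=bonds,
        angles=angles,
        hr_idx=hr_idx,
        hr_k=hr_k,
        hr_r0=hr_r0,
        hr_kind=hr_kind,
        meta={"builder": "nucleosome_chain", "label": spec.label,
              "n_nucleosomes": n_nuc, "seed": seed},
    )
    _check_no_divergence(topo, ff)
    return topo


def _check_no_divergence(topo: Topology, ff: ForceFieldParams) -> None:
    from .forcefield import system_energy_forces
    report, _ = system_energy_forces(topo, ff=ff)
    if not np.isfinite(report.total):
        raise BuildError("initial configuration has a divergent pair")


# ----------------------------------------------------------------------
def collapse_clutch(topology: Topology, spec: ClutchSpec,
                    sim: SimulationParams | None = None,
                    ff: ForceFieldParams | None = None,
                    calibrate: bool = True,
                    k_collapse: float | None = None,
                    extent_tol: float = 1.0,
                    mass_fraction: float = 0.99,
                    max_rounds: int = 10) -> Topology:
    """Collapse a nucleosome chain into a spherical clutch.

    Adds a harmonic restraint pulling every core toward the instantaneous
    core centroid and relaxes the chain.  When ``calibrate`` is set, the
    restraint stiffness is adjusted by a secant loop in (ln k, extent)
    until the 99%-mass radial extent of all beads reaches
    ``spec.target_radius`` within ``extent_tol``.  The calibrated
    stiffness is what differentiates the clutch densities: the densely
    packed 20-nucleosome clutch needs a strong pull (sharp boundary), the
    11-nucleosome clutch a weak one (soft, fluctuating fringe).
    """
    from . import dynamics, observables
    ff = ff or ForceFieldParams()
    sim = sim or SimulationParams(n_steps=30_000, seed=1)
    if topology.collapse:
        raise BuildError("topology already carries a collapse restraint")

    topo = topology.copy()
    cores = topo.core_indices(group=0)
    if len(cores) == 0:
        raise BuildError("collapse requires a nucleosome chain with cores")
    # initial stiffness guess grows with packing density (kBT/nm^2)
    k = 0.005 * spec.n_nucleosomes**2 if k_collapse is None else k_collapse
    topo.collapse.append(CollapseRestraint(core_indices=cores, r_t=0.0, k=k))

    # initial collapse: capped forces while the chain folds in and large
    # overlaps resolve
    dynamics.soft_relax(topo, ff=ff, n_steps=6000, seed=sim.seed)
    dynamics.relax(topo, ff=ff, n_steps=15_000, seed=sim.seed + 1)

    extent = np.nan
    target = spec.target_radius
    n_round = max(sim.n_steps, 10_000)
    lnk_prev = None
    ext_prev = None
    for it in range(max_rounds if calibrate else 1):
        lib = dynamics.sample_conformers(
            topo, params=SimulationParams(
                dt=sim.dt, gamma=sim.gamma, seed=sim.seed + 10 + it,
                n_steps=1, equilibration=n_round // 2),
            n_conformers=max(n_round // 400, 20),
            stride=400, ff=ff, check_decorrelation=False)
        profile = observables.radial_profile(lib, species=None)
        extent = observables.clutch_extent(profile, mass_fraction=mass_fraction)
        topo.coords = lib.frames[-1] + 0.0  # carry on from a relaxed frame
        if not calibrate or abs(extent - target) <= 0.35 * extent_tol:
            break
        lnk = np.log(k)
        slope = -4.0  # nm extent per ln k, conservative default
        if lnk_prev is not None and abs(lnk - lnk_prev) > 1e-3:
            s = (extent - ext_prev) / (lnk - lnk_prev)
            if s < -0.2:
                slope = s
        lnk_prev, ext_prev = lnk, extent
        step = np.clip((target - extent) / slope, -1.2, 1.2)
        k = float(np.exp(lnk + step))
        topo.collapse[0] = CollapseRestraint(cores, 0.0, k)
    else:
        if calibrate and abs(extent - target) > extent_tol:
            raise CalibrationError(
                f"collapse calibration reached extent {extent:.2f} nm "
                f"(target {target:.1f} nm)", achieved_extent=float(extent))
    topo.meta.update(collapsed=True, k_collapse=topo.collapse[0].k,
                     calibrated_extent=float(extent))
    return topo


# ----------------------------------------------------------------------
def crowder_count(box_edge: float, cond: CrowdingCondition) -> int:
    """Number of crowders giving volume fraction phi_c in a cubic box."""
    return cond.n_crowders(box_edge)


def place_crowders(topology: Topology, cond: CrowdingCondition, seed: int = 0,
                   ff: ForceFieldParams | None = None,
                   max_attempts_per_crowder: int = 400) -> Topology:
    """Insert crowder spheres at random non-overlapping positions.

    Overlap means any pair inside its divergence distance r0 (plus a
    small margin); the box is periodic.  The topology must have a box.
    """
    ff = ff or ForceFieldParams()
    if topology.box is None:
        raise BuildError("place_crowders requires a periodic box")
    n = cond.n_crowders(topology.box)
    box = topology.box
    # clear by nearly the full WCA contact so insertion energies stay mild
    margin = 0.95 * ff.sigma
    if cond.phi_c > 0 and box < 2.0 * (ff.r0_matrix()[CROWDER, CROWDER] + margin):
        raise PackingError("box smaller than one crowder clearance")
    if n == 0:
        return topology.copy()
    r0m = ff.r0_matrix()
    # required clearance of a crowder from each existing species
    clear = np.array([r0m[CROWDER, DNA], r0m[CROWDER, CORE],
                      r0m[CROWDER, CROWDER]]) + margin

    rng = np.random.default_rng(seed)
    existing = topology.coords
    ex_clear = clear[topology.species]
    placed = np.empty((n, 3))
    n_placed = 0
    attempts = 0
    max_attempts = max_attempts_per_crowder * n
    while n_placed < n:
        if attempts >= max_attempts:
            raise PackingError(
                f"placed {n_placed}/{n} crowders after {attempts} trials; "
                "phi_c too high for random insertion - grow the bath with a "
                "pre-equilibration protocol instead")
        attempts += 1
        p = rng.random(3) * box
        if len(existing):
            d = existing - p
            d -= box * np.rint(d / box)
            if np.any((d ** 2).sum(1) < ex_clear ** 2):
                continue
        if n_placed:
            d = placed[:n_placed] - p
            d -= box * np.rint(d / box)
            if np.any((d ** 2).sum(1) < clear[CROWDER] ** 2):
                continue
        placed[n_placed] = p
        n_placed += 1

    crowders = Topology(
        species=np.full(n, CROWDER, np.int8),
        group=np.full(n, -1, np.int32),
        coords=placed,
        bonds=np.zeros((0, 2), np.int32),
        angles=np.zeros((0, 3), np.int32),
        hr_idx=np.zeros((0, 2), np.int32),
        hr_k=np.zeros(0),
        hr_r0=np.zeros(0),
        box=box,
    )
    out = Topology.merge(topology, crowders, renumber_groups=False)
    out.meta.update(phi_c=cond.phi_c, n_crowders=n, crowder_seed=seed)
    return out


# ----------------------------------------------------------------------
def build_pair_topology(clutch_a: Topology, clutch_b: Topology, xi: float,
                        box: float | None = None, seed: int = 0,
                        ff: ForceFieldParams | None = None,
                        max_rotations: int = 80) -> Topology:
    """Two clutches with core centroids placed ``xi`` nm apart along x.

    Random rigid rotations are tried until the merged configuration is
    free of divergent pairs; if none is found the least-overlapping
    candidate is relaxed with capped forces under the distance constraint.
    """
    from . import dynamics
    from .forcefield import system_energy_forces
    ff = ff or ForceFieldParams()
    rng = np.random.default_rng(seed)
    center = np.full(3, box / 2.0) if box else np.zeros(3)
    off_a = center - np.array([xi / 2.0, 0, 0])
    off_b = center + np.array([xi / 2.0, 0, 0])

    def centered(t: Topology) -> np.ndarray:
        c = t.coords[t.core_indices(0)].mean(axis=0) if len(t.core_indices(0)) \
            else t.coords.mean(axis=0)
        return t.coords - c

    ca0, cb0 = centered(clutch_a), centered(clutch_b)

    def assemble(ca, cb) -> Topology:
        a = clutch_a.copy()
        a.coords = ca + off_a
        a.group[:] = 0
        b = clutch_b.copy()
        b.coords = cb + off_b
        b.group[:] = 1
        merged = Topology.merge(a, b, renumber_groups=False)
        merged.box = box
        return merged

    base = 0.0
    for t in (clutch_a, clutch_b):
        rep, _ = system_energy_forces(t, ff=ff)
        base += rep.total
    best = None
    best_score = np.inf
    for _ in range(max_rotations):
        qa = _rotmat(rng)
        qb = _rotmat(rng)
        cand = assemble(ca0 @ qa.T, cb0 @ qb.T)
        report, _ = system_energy_forces(cand, ff=ff)
        if np.isfinite(report.total) and report.total < base + 80.0:
            return cand
        score = _overlap_score(cand, ff)
        if score < best_score:
            best_score = score
            best = cand
    # fall back: capped-force relaxation while holding the constraint
    dynamics.soft_relax(best, ff=ff, n_steps=6000, seed=seed,
                        xi=xi, grp_a=best.core_indices(0),
                        grp_b=best.core_indices(1))
    report, _ = system_energy_forces(best, ff=ff)
    if not np.isfinite(report.total):
        raise PackingError(f"could not resolve clutch-clutch overlaps at xi={xi}")
    return best


def _overlap_score(topo: Topology, ff: ForceFieldParams) -> float:
    """Total penetration depth past the pair contact shells (nm)."""
    c = topo.coords
    sp = topo.species
    d = c[:, None, :] - c[None, :, :]
    if topo.box is not None:
        d -= topo.box * np.rint(d / topo.box)
    r = np.sqrt((d**2).sum(-1))
    rr = r - ff.r0_matrix()[sp[:, None], sp[None, :]] - 0.9 * ff.sigma
    iu = np.triu_indices(len(c), k=1)
    pen = rr[iu]
    return float(-pen[pen < 0].sum())


def _rotmat(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    q0, q1, q2, q3 = q
    return np.array([
        [1 - 2 * (q2 * q2 + q3 * q3), 2 * (q1 * q2 - q0 * q3), 2 * (q1 * q3 + q0 * q2)],
        [2 * (q1 * q2 + q0 * q3), 1 - 2 * (q1 * q1 + q3 * q3), 2 * (q2 * q3 - q0 * q1)],
        [2 * (q1 * q3 - q0 * q2), 2 * (q2 * q3 + q0 * q1), 1 - 2 * (q1 * q1 + q2 * q2)],
    ])
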