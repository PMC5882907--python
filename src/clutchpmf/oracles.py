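"""Analytic and brute-force oracles plus miniature test fixtures.

The Asakura-Oosawa (AO) depletion potential between two hard colloids of
radius R in an ideal bath of depletants of radius r_d at volume fraction
phi_c is

    W(xi) = -(phi_c / v_d) kBT V_ov(xi; a),   2R <= xi < 2a,
    V_ov  = (4 pi / 3) a^3 (1 - 3 xi/(4a) + xi^3/(16 a^3)),  a = R + r_d,

zero beyond 2a and infinite inside contact.  The attraction strength is
proportional to phi_c.  These closed forms, a Widom acceptance-ratio
Monte-Carlo estimate, and a set of deterministic miniature topologies form
the test backbone of the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .builders import build_dna_chain, build_nucleosome_chain
from .params import CORE, DNA, ClutchSpec, ForceFieldParams, crowder_volume_nm3
from .pmf import PMFCurve
from .topology import Topology


@dataclass
class AOSystem:
    """Two hard colloids in a depletant bath."""

    colloid_radius: float        # R, nm
    depletant_radius: float      # r_d, nm
    phi_c: float
    ideal: bool = True           # depletants mutually non-interacting

    def __post_init__(self) -> None:
        if self.colloid_radius <= 0 or self.depletant_radius <= 0:
            raise ValueError("radii must be positive")
        if self.phi_c < 0:
            raise ValueError("phi_c must be non-negative")

    @property
    def a(self) -> float:
        return self.colloid_radius + self.depletant_radius

    @property
    def v_d(self) -> float:
        return crowder_volume_nm3(2.0 * self.depletant_radius)


def lens_overlap_volume(xi, a):
    """Overlap volume of two spheres of radius ``a`` at centre distance xi."""
    xi = np.asarray(xi, float)
    v = (4.0 * np.pi / 3.0) * a**3 * (1.0 - 3.0 * xi / (4.0 * a)
                                      + xi**3 / (16.0 * a**3))
    return np.where(xi < 2.0 * a, v, 0.0)


def ao_pmf(sys: AOSystem, xi):
    """Closed-form AO depletion potential, kBT (+inf inside contact)."""
    if not sys.ideal:
        raise ValueError("closed-form AO requires ideal depletants; "
                         "use brute_force_pmf for interacting baths")
    xi = np.asarray(xi, float)
    w = np.where(xi < 2.0 * sys.colloid_radius, np.inf,
                 -(sys.phi_c / sys.v_d) * lens_overlap_volume(xi, sys.a))
    return float(w) if w.ndim == 0 else w


def ao_force_gradient(sys: AOSystem, xi):
    """dW/dxi of the AO potential (kBT/nm), valid for 2R <= xi."""
    xi = np.asarray(xi, float)
    dvov = np.where(xi < 2.0 * sys.a,
                    (4.0 * np.pi / 3.0) * sys.a**3
                    * (-3.0 / (4.0 * sys.a) + 3.0 * xi**2 / (16.0 * sys.a**3)),
                    0.0)
    g = -(sys.phi_c / sys.v_d) * dvov
    return float(g) if g.ndim == 0 else g


# ----------------------------------------------------------------------
def brute_force_pmf(sys: AOSystem, xi_grid, n_samples: int, seed: int,
                    box_edge: float = 40.0) -> PMFCurve:
    """Depletion PMF of two frozen colloids by Monte Carlo.

    Ideal depletants: exact Widom acceptance-ratio estimate
    F(xi) = -N kBT ln[p(xi)/p(ref)], where p is the probability that a
    random depletant insertion avoids both colloids and N is the bath
    population of the box.  Interacting (hard) depletants: Metropolis
    sampling of the bath with staged free-energy perturbation in xi.
    """
    xi_grid = np.sort(np.asarray(xi_grid, float))
    if xi_grid[0] < 2.0 * sys.colloid_radius:
        raise ValueError("grid extends inside colloid contact")
    if box_edge < 2.0 * (xi_grid[-1] / 2.0 + sys.a):
        raise ValueError("box too small for the outermost grid point")
    n_dep = sys.phi_c * box_edge**3 / sys.v_d
    if sys.ideal:
        rng = np.random.default_rng(seed)
        p = np.empty(len(xi_grid))
        for i, xi in enumerate(xi_grid):
            pts = rng.random((n_samples, 3)) * box_edge - box_edge / 2.0
            ok = np.ones(n_samples, bool)
            for cx in (-xi / 2.0, xi / 2.0):
                d = pts - np.array([cx, 0.0, 0.0])
                d -= box_edge * np.rint(d / box_edge)
                ok &= (d**2).sum(1) > sys.a**2
            p[i] = ok.mean()
        if np.any(p <= 0):
            raise ValueError("zero insertion acceptance; box too crowded")
        f = -n_dep * (np.log(p) - np.log(p[-1]))
        se_lnp = np.sqrt((1.0 - p) / (p * n_samples))
        se = n_dep * np.sqrt(se_lnp**2 + se_lnp[-1] ** 2)
        se[-1] = 0.0
        return PMFCurve(xi=xi_grid, f=f, se=se, xi_ref=float(xi_grid[-1]),
                        meta={"estimator": "widom-ideal", "phi_c": sys.phi_c,
                              "n_samples": n_samples, "seed": seed})
    # interacting hard depletants: staged acceptance-ratio perturbation
    fine = np.arange(xi_grid[-1], xi_grid[0] - 1e-9, -0.25)[::-1]
    ln_shrink, ln_expand, stage_var = _hard_depletion_stages(
        float(sys.colloid_radius), float(sys.depletant_radius),
        float(sys.phi_c), float(box_edge), fine, int(n_samples), int(seed))
    # dF(s -> s-1) = -ln P_shrink(at s) + ln P_expand(at s-1)
    dlnp = ln_shrink[1:] - ln_expand[:-1]
    f_fine = np.concatenate([-np.cumsum(dlnp[::-1])[::-1], [0.0]])
    var_fine = np.concatenate([np.cumsum(stage_var[::-1])[::-1], [0.0]])
    f = np.interp(xi_grid, fine, f_fine)
    se = np.sqrt(np.interp(xi_grid, fine, var_fine))
    return PMFCurve(xi=xi_grid, f=f, se=se, xi_ref=float(xi_grid[-1]),
                    meta={"estimator": "mc-hard", "phi_c": sys.phi_c,
                          "n_samples": n_samples, "seed": seed})


@njit(cache=True)
def _hard_depletion_stages(r_col, r_dep, phi, box, xi_stages, n_sweeps, seed):
    """Staged acceptance-ratio estimates between colloid separations.

    All-hard system: depletant-depletant contact 2 r_dep, colloid-
    depletant contact r_col + r_dep.  At each stage the bath is sampled
    by Metropolis moves around frozen colloids at xi; two indicator
    probabilities are recorded: that shrinking xi to the next-inner stage
    creates no overlap (P_shrink) and that expanding to the next-outer
    stage creates none (P_expand).  The acceptance-ratio free-energy
    difference for a segment is -ln P_shrink(outer) + ln P_expand(inner).
    Returns (ln_shrink, ln_expand, segment_var), the first two of length
    len(xi_stages) (edges unused), the variance per segment.
    """
    np.random.seed(seed)
    v_d = 4.0 / 3.0 * np.pi * r_dep**3
    n = int(phi * box**3 / v_d)
    a = r_col + r_dep
    dd = 2.0 * r_dep
    pos = np.empty((n, 3))
    n_stage = xi_stages.shape[0]
    ln_shrink = np.zeros(n_stage)
    ln_expand = np.zeros(n_stage)
    seg_var = np.zeros(n_stage - 1)

    # start at the largest separation, walk inward
    xi = xi_stages[n_stage - 1]
    # RSA initialisation
    placed = 0
    tries = 0
    while placed < n and tries < 200000:
        tries += 1
        x = (np.random.random() - 0.5) * box
        y = (np.random.random() - 0.5) * box
        z = (np.random.random() - 0.5) * box
        ok = True
        for cs in (-1.0, 1.0):
            dx = x - cs * xi / 2.0
            dx -= box * np.rint(dx / box)
            dy = y - box * np.rint(y / box)
            dz = z - box * np.rint(z / box)
            if dx * dx + dy * dy + dz * dz <= a * a:
                ok = False
                break
        if ok:
            for j in range(placed):
                dx = x - pos[j, 0]
                dy = y - pos[j, 1]
                dz = z - pos[j, 2]
                dx -= box * np.rint(dx / box)
                dy -= box * np.rint(dy / box)
                dz -= box * np.rint(dz / box)
                if dx * dx + dy * dy + dz * dz <= dd * dd:
                    ok = False
                    break
        if ok:
            pos[placed, 0] = x
            pos[placed, 1] = y
            pos[placed, 2] = z
            placed += 1
    if placed < n:
        n = placed

    step = 0.6 * r_dep
    for s in range(n_stage - 1, -1, -1):
        xi = xi_stages[s]
        burn = n_sweeps // 3 + 1
        hit_in = 0.0
        hit_out = 0.0
        tot = 0.0
        for sweep in range(burn + n_sweeps):
            for _ in range(n):
                k = np.random.randint(0, n)
                nx = pos[k, 0] + (np.random.random() - 0.5) * 2.0 * step
                ny = pos[k, 1] + (np.random.random() - 0.5) * 2.0 * step
                nz = pos[k, 2] + (np.random.random() - 0.5) * 2.0 * step
                ok = True
                for cs in (-1.0, 1.0):
                    dx = nx - cs * xi / 2.0
                    dx -= box * np.rint(dx / box)
                    dy = ny - box * np.rint(ny / box)
                    dz = nz - box * np.rint(nz / box)
                    if dx * dx + dy * dy + dz * dz <= a * a:
                        ok = False
                        break
                if ok:
                    for j in range(n):
                        if j == k:
                            continue
                        dx = nx - pos[j, 0]
                        dy = ny - pos[j, 1]
                        dz = nz - pos[j, 2]
                        dx -= box * np.rint(dx / box)
                        dy -= box * np.rint(dy / box)
                        dz -= box * np.rint(dz / box)
                        if dx * dx + dy * dy + dz * dz <= dd * dd:
                            ok = False
                            break
                if ok:
                    pos[k, 0] = nx
                    pos[k, 1] = ny
                    pos[k, 2] = nz
            if sweep >= burn:
                tot += 1.0
                # indicators: no overlap after moving the colloids to the
                # neighbouring inner / outer separations
                for direction in range(2):
                    if direction == 0 and s == 0:
                        continue
                    if direction == 1 and s == n_stage - 1:
                        continue
                    xi_trial = xi_stages[s - 1] if direction == 0 else xi_stages[s + 1]
                    clear = 1.0
                    for j in range(n):
                        for cs in (-1.0, 1.0):
                            dx = pos[j, 0] - cs * xi_trial / 2.0
                            dx -= box * np.rint(dx / box)
                            dy = pos[j, 1] - box * np.rint(pos[j, 1] / box)
                            dz = pos[j, 2] - box * np.rint(pos[j, 2] / box)
                            if dx * dx + dy * dy + dz * dz <= a * a:
                                clear = 0.0
                                break
                        if clear == 0.0:
                            break
                    if direction == 0:
                        hit_in += clear
                    else:
                        hit_out += clear
        p_in = max(hit_in / tot, 0.5 / tot)
        p_out = max(hit_out / tot, 0.5 / tot)
        if s > 0:
            ln_shrink[s] = np.log(p_in)
            seg_var[s - 1] += (1.0 - p_in) / (p_in * tot)
        if s < n_stage - 1:
            ln_expand[s] = np.log(p_out)
            seg_var[s] += (1.0 - p_out) / (p_out * tot)
        # move colloids inward for the next stage; push out any
        # now-overlapping depletant
        if s > 0:
            xi_next = xi_stages[s - 1]
            for j in range(n):
                for cs in (-1.0, 1.0):
                    dx = pos[j, 0] - cs * xi_next / 2.0
                    dx -= box * np.rint(dx / box)
                    dy = pos[j, 1] - box * np.rint(pos[j, 1] / box)
                    dz = pos[j, 2] - box * np.rint(pos[j, 2] / box)
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 <= a * a and d2 > 1e-12:
                        d = np.sqrt(d2)
                        push = (a - d) * 1.05
                        pos[j, 0] += push * dx / d
                        pos[j, 1] += push * dy / d
                        pos[j, 2] += push * dz / d
    return ln_shrink, ln_expand, seg_var


# ----------------------------------------------------------------------
FIXTURE_NAMES = ("single_core_pair", "soft_blob_pair", "bare_dna",
                 "mini_clutch_n2")


def make_fixture(name: str, seed: int = 0,
                 ff: ForceFieldParams | None = None) -> Topology:
    """Deterministic miniature systems used across the test suite.

    * ``single_core_pair``: two isolated nucleosome cores (groups 0, 1).
    * ``soft_blob_pair``: two loosely tethered 10-bead blobs (a core with
      a fuzzy 9-bead DNA corona) - a soft, euchromatin-like pair.
    * ``bare_dna``: a 100-bead DNA chain.
    * ``mini_clutch_n2``: a 2-nucleosome chain (53 DNA beads, 2 cores).
    """
    ff = ff or ForceFieldParams()
    if name == "single_core_pair":
        return Topology(
            species=np.array([CORE, CORE], np.int8),
            group=np.array([0, 1], np.int32),
            coords=np.array([[0.0, 0.0, 0.0], [8.0, 0.0, 0.0]]),
            bonds=np.zeros((0, 2), np.int32),
            angles=np.zeros((0, 3), np.int32),
            hr_idx=np.zeros((0, 2), np.int32),
            hr_k=np.zeros(0),
            hr_r0=np.zeros(0),
            meta={"fixture": name},
        )
    if name == "soft_blob_pair":
        rng = np.random.default_rng(seed)
        blobs = []
        for g, cx in enumerate((0.0, 20.0)):
            coords = [np.array([cx, 0.0, 0.0])]
            for _ in range(9):
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                coords.append(np.array([cx, 0.0, 0.0]) + u * (4.0 + rng.random()))
            nine = np.arange(1, 10, dtype=np.int32)
            blob = Topology(
                species=np.array([CORE] + [DNA] * 9, np.int8),
                group=np.full(10, g, np.int32),
                coords=np.array(coords),
                bonds=np.zeros((0, 2), np.int32),
                angles=np.zeros((0, 3), np.int32),
                hr_idx=np.column_stack([nine, np.zeros(9, np.int32)]),
                hr_k=np.full(9, 0.25),   # kBT/nm^2, loose tether
                hr_r0=np.full(9, 4.0),
                hr_kind=["tether"] * 9,
            )
            blobs.append(blob)
        out = Topology.merge(blobs[0], blobs[1], renumber_groups=False)
        out.meta["fixture"] = name
        return out
    if name == "bare_dna":
        topo = build_dna_chain(100, seed=seed, ff=ff)
        topo.meta["fixture"] = name
        return topo
    if name == "mini_clutch_n2":
        spec = ClutchSpec(n_nucleosomes=2, label="mini")
        topo = build_nucleosome_chain(spec, ff=ff, seed=seed)
        topo.meta["fixture"] = name
        return topo
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
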