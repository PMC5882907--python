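"""Canonical-ensemble sampling by Langevin dynamics (Gronbech-Jensen/Farago
scheme, whose configurational sampling carries no leading-order timestep
bias on stiff bonded terms).

The thermostat targets T = 1 kBT with friction gamma (default 1/tau_MD),
which samples the same configurational ensemble as the Nose-Hoover
thermostat it replaces while being unconditionally stable for this model.

A holonomic distance constraint between the core centroids of two clutch
groups supports constraint-biased PMF runs: the constraint is enforced by
exact SHAKE/RATTLE projections, and the constraint force f_c is sampled
with the blue-moon estimator

    f_c = -mu (F_B/M_B - F_A/M_A) . n  -  mu |v_perp|^2 / xi,

whose ensemble mean is dU/dxi - 2 kBT/xi for a rigid pair, so that the
integrand <f_c> + 2 kBT/s of the force-integration PMF reduces exactly to
the pair potential gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels
from .forcefield import _collapse_arrays
from .params import ForceFieldParams, SimulationParams
from .topology import Topology


class IntegrationError(RuntimeError):
    """Dynamics failed (divergent pair, overstretched bond, ...)."""

    def __init__(self, msg: str, step: int):
        super().__init__(f"{msg} at step {step}")
        self.step = step


@dataclass
class Trajectory:
    """Snapshots of a Langevin run, at a fixed stride."""

    frames: np.ndarray           # (n_frames, N, 3) nm
    species: np.ndarray
    box: float | None
    stride: int                  # steps between frames
    dt: float                    # tau_MD
    kinetic_temperature: np.ndarray = field(default_factory=lambda: np.zeros(0))
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "clutchpmf-trajectory-v1"
            f.attrs["box"] = -1.0 if self.box is None else self.box
            f.attrs["stride"] = self.stride
            f.attrs["dt"] = self.dt
            f.create_dataset("frames", data=self.frames,
                             chunks=(1,) + self.frames.shape[1:])
            f.create_dataset("species", data=self.species)
            f.create_dataset("kinetic_temperature", data=self.kinetic_temperature)

    def write_xyz(self, path) -> None:
        from .params import SPECIES_NAMES
        with open(path, "w") as fh:
            for frame in self.frames:
                fh.write(f"{frame.shape[0]}\n\n")
                for sp, (x, y, z) in zip(self.species, frame):
                    fh.write(f"{SPECIES_NAMES[int(sp)][:3]} {x:.4f} {y:.4f} {z:.4f}\n")


@dataclass
class ConformerLibrary:
    """Single-clutch snapshots, centred on the clutch core centroid."""

    frames: np.ndarray          # (n_conformers, N_clutch, 3) nm
    species: np.ndarray         # (N_clutch,)
    meta: dict = field(default_factory=dict)

    @property
    def n_conformers(self) -> int:
        return self.frames.shape[0]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "clutchpmf-conformers-v1"
            for key, val in self.meta.items():
                if isinstance(val, (int, float, str, bool, np.integer, np.floating)):
                    f.attrs[key] = val
            f.create_dataset("frames", data=self.frames)
            f.create_dataset("species", data=self.species)

    @staticmethod
    def load(path) -> "ConformerLibrary":
        with h5py.File(path, "r") as f:
            meta = {k: f.attrs[k] for k in f.attrs if k != "format"}
            return ConformerLibrary(frames=f["frames"][:],
                                    species=f["species"][:].astype(np.int8),
                                    meta=meta)


@dataclass
class ConstraintRecord:
    """Constraint-force statistics at one fixed pair distance."""

    xi: float
    samples: np.ndarray
    n_blocks: int = 10

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def mean(self) -> float:
        return float(self.samples.mean())

    @property
    def se(self) -> float:
        return block_se(self.samples, self.n_blocks)


def block_se(samples: np.ndarray, n_blocks: int = 10) -> float:
    """Standard error by block averaging (>= 10 blocks)."""
    n_blocks = max(n_blocks, 10)
    if len(samples) < n_blocks:
        raise ValueError("too few samples for block averaging")
    usable = (len(samples) // n_blocks) * n_blocks
    blocks = samples[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / np.sqrt(n_blocks))


# ----------------------------------------------------------------------
_STATUS_MSG = {
    _kernels.STATUS_DIVERGED: "divergent pair (r <= r0)",
    _kernels.STATUS_OVERSTRETCH: "FENE bond overstretched",
    _kernels.STATUS_NL_OVERFLOW: "neighbor-list overflow",
    _kernels.STATUS_CONSTRAINT: "constraint groups coincide",
}


def _md(topo: Topology, ff: ForceFieldParams, *, dt_tau: float, gamma_tau: float,
        kT: float, n_steps: int, seed: int, skin: float = 1.0,
        vel: np.ndarray | None = None, mobile: np.ndarray | None = None,
        xi: float = -1.0, grp_a=None, grp_b=None,
        snap_every: int = 0, n_snaps: int = 0,
        fc_every: int = 0, n_fc: int = 0,
        ke_every: int = 0, n_ke: int = 0,
        pair_cap: float = -1.0):
    """Low-level driver: integrates ``topo.coords`` in place."""
    n = topo.n_beads
    coords = np.ascontiguousarray(topo.coords, np.float64)
    if vel is None:
        rng = np.random.default_rng(np.uint32(seed) ^ np.uint32(0x9E3779B9))
        vel = rng.normal(scale=np.sqrt(kT / ff.mass), size=(n, 3))
    if mobile is None:
        mobile = np.ones(n, np.bool_)
    col_off, col_cores, col_rt, col_k = _collapse_arrays(topo)
    dt = dt_tau * ff.tau_md
    gamma = gamma_tau / ff.tau_md
    grp_a = np.zeros(0, np.int32) if grp_a is None else np.asarray(grp_a, np.int32)
    grp_b = np.zeros(0, np.int32) if grp_b is None else np.asarray(grp_b, np.int32)
    snaps = np.empty((n_snaps, n, 3)) if snap_every > 0 else np.empty((0, n, 3))
    fc_buf = np.empty(n_fc) if fc_every > 0 else np.empty(0)
    ke_buf = np.empty(n_ke) if ke_every > 0 else np.empty(0)
    box = -1.0 if topo.box is None else float(topo.box)

    # thermal impulses are drawn in chunks outside the kernel (vectorised
    # Gaussian generation dominates the per-step cost otherwise)
    rng = np.random.default_rng(np.int64(seed) % np.int64(2**31))
    beta_sd = np.sqrt(2.0 * gamma * kT * dt)
    chunk = int(min(n_steps, max(256, 6_000_000 // (3 * n))))
    species8 = topo.species.astype(np.int8)
    r0m = ff.r0_matrix()
    step0 = 0
    got_snaps = got_fc = got_ke = 0
    while step0 < n_steps:
        csteps = min(chunk, n_steps - step0)
        noise = rng.standard_normal((csteps, n, 3)) * beta_sd
        status, info, got_snaps, got_fc, got_ke = _kernels.run_md(
            coords, vel, species8, mobile, box,
            r0m, ff.sigma, ff.epsilon, ff.rc,
            topo.bonds, ff.k_fene_nm, ff.r_b,
            topo.angles, ff.k_angle,
            topo.hr_idx, topo.hr_k, topo.hr_r0,
            col_off, col_cores, col_rt, col_k,
            topo.ideal_crowders,
            dt, gamma, kT,
            noise, step0, skin,
            xi, grp_a, grp_b,
            snap_every, snaps, got_snaps,
            fc_every, fc_buf, got_fc,
            ke_every, ke_buf, got_ke,
            pair_cap)
        if status != _kernels.STATUS_OK:
            raise IntegrationError(_STATUS_MSG.get(status, f"status {status}"),
                                   info)
        step0 += csteps
    topo.coords = coords
    return snaps[:got_snaps], fc_buf[:got_fc], ke_buf[:got_ke], vel


def soft_relax(topo: Topology, ff: ForceFieldParams | None = None,
               n_steps: int = 3000, seed: int = 0, cap: float = 100.0,
               xi: float = -1.0, grp_a=None, grp_b=None) -> None:
    """Short capped-force relaxation (resolves build-time overlaps)."""
    ff = ff or ForceFieldParams()
    _md(topo, ff, dt_tau=0.002, gamma_tau=20.0, kT=1.0, n_steps=n_steps,
        seed=seed, pair_cap=cap, xi=xi, grp_a=grp_a, grp_b=grp_b)


def relax(topo: Topology, ff: ForceFieldParams | None = None,
          n_steps: int = 10_000, seed: int = 0) -> None:
    """Plain equilibration run; coordinates updated in place."""
    ff = ff or ForceFieldParams()
    _md(topo, ff, dt_tau=0.005, gamma_tau=1.0, kT=1.0, n_steps=n_steps,
        seed=seed)


# ----------------------------------------------------------------------
def run_langevin(topology: Topology, params: SimulationParams,
                 ff: ForceFieldParams | None = None,
                 snapshot_every: int = 1000,
                 mobile: np.ndarray | None = None) -> Trajectory:
    """Sample a topology; returns the production trajectory.

    Runs ``params.equilibration`` steps (discarded) followed by
    ``params.n_steps`` production steps with snapshots and kinetic-
    temperature samples every ``snapshot_every`` steps.  Identical
    (topology, params) with the same seed reproduce the trajectory
    bit-for-bit on one platform.
    """
    ff = ff or ForceFieldParams()
    topo = topology.copy()
    vel = None
    if params.equilibration > 0:
        _, _, _, vel = _md(topo, ff, dt_tau=params.dt, gamma_tau=params.gamma,
                           kT=params.temperature, n_steps=params.equilibration,
                           seed=params.seed, skin=params.neighbor_skin,
                           mobile=mobile)
    n_snaps = params.n_steps // snapshot_every
    snaps, _, ke, _ = _md(topo, ff, dt_tau=params.dt, gamma_tau=params.gamma,
                          kT=params.temperature, n_steps=params.n_steps,
                          seed=params.seed + 1, skin=params.neighbor_skin,
                          vel=vel, mobile=mobile,
                          snap_every=snapshot_every, n_snaps=n_snaps,
                          ke_every=snapshot_every, n_ke=n_snaps)
    return Trajectory(frames=snaps, species=topology.species.copy(),
                      box=topology.box, stride=snapshot_every, dt=params.dt,
                      kinetic_temperature=ke * 2.0 / 3.0,
                      meta={"seed": params.seed, "gamma": params.gamma})


def run_constrained_pair(pair_topology: Topology, xi: float,
                         params: SimulationParams,
                         ff: ForceFieldParams | None = None,
                         crowder_pre_equilibration: int = 10_000) -> ConstraintRecord:
    """Constraint-biased run: hold the two clutch core centroids at ``xi``.

    The constraint force is sampled every ``params.sample_every`` steps
    during production; its mean and block-averaged standard error enter
    the force-integration PMF.  Crowders (if present) are pre-equilibrated
    around the frozen clutches first.
    """
    ff = ff or ForceFieldParams()
    topo = pair_topology.copy()
    grp_a = topo.core_indices(0)
    grp_b = topo.core_indices(1)
    if len(grp_a) == 0 or len(grp_b) == 0:
        raise ValueError("pair topology must contain two clutch groups (0, 1)")

    has_crowders = np.any(topo.group < 0)
    vel = None
    if has_crowders and crowder_pre_equilibration > 0:
        mobile = (topo.group < 0)
        _md(topo, ff, dt_tau=params.dt, gamma_tau=params.gamma,
            kT=params.temperature, n_steps=crowder_pre_equilibration,
            seed=params.seed + 7, skin=params.neighbor_skin, mobile=mobile)
    if params.equilibration > 0:
        _, _, _, vel = _md(topo, ff, dt_tau=params.dt, gamma_tau=params.gamma,
                           kT=params.temperature, n_steps=params.equilibration,
                           seed=params.seed, skin=params.neighbor_skin,
                           xi=xi, grp_a=grp_a, grp_b=grp_b)
    n_fc = params.n_steps // params.sample_every
    _, fc, _, _ = _md(topo, ff, dt_tau=params.dt, gamma_tau=params.gamma,
                      kT=params.temperature, n_steps=params.n_steps,
                      seed=params.seed + 1, skin=params.neighbor_skin,
                      vel=vel, xi=xi, grp_a=grp_a, grp_b=grp_b,
                      fc_every=params.sample_every, n_fc=n_fc)
    # constraint preservation: the projection is exact along the centroid axis
    d = np.linalg.norm(topo.coords[grp_b].mean(0) - topo.coords[grp_a].mean(0))
    if abs(d - xi) > 1e-6 * ff.sigma:
        raise IntegrationError(f"constraint drifted to {d:.8f} (target {xi})", -1)
    return ConstraintRecord(xi=float(xi), samples=fc)


def sample_conformers(topology: Topology, params: SimulationParams,
                      n_conformers: int, stride: int,
                      ff: ForceFieldParams | None = None,
                      check_decorrelation: bool = True) -> ConformerLibrary:
    """Generate a library of clutch conformers (crowders stripped).

    Snapshots are taken every ``stride`` steps after equilibration and
    centred on the clutch core centroid.  The integrated autocorrelation
    time of the radius of gyration is estimated and compared with the
    stride; an insufficient stride is recorded as a metadata warning.
    """
    ff = ff or ForceFieldParams()
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    topo = topology.copy()
    vel = None
    if params.equilibration > 0:
        _, _, _, vel = _md(topo, ff, dt_tau=params.dt, gamma_tau=params.gamma,
                           kT=params.temperature, n_steps=params.equilibration,
                           seed=params.seed, skin=params.neighbor_skin)
    snaps, _, _, _ = _md(topo, ff, dt_tau=params.dt, gamma_tau=params.gamma,
                         kT=params.temperature, n_steps=n_conformers * stride,
                         seed=params.seed + 1, skin=params.neighbor_skin,
                         vel=vel, snap_every=stride, n_snaps=n_conformers)

    keep = np.nonzero(topo.group == 0)[0]
    frames = snaps[:, keep, :]
    species = topo.species[keep]
    cores = np.nonzero(species == 1)[0]
    center_idx = cores if len(cores) else np.arange(len(keep))
    frames = frames - frames[:, center_idx, :].mean(axis=1, keepdims=True)

    meta = {"phi_c": topology.meta.get("phi_c", 0.0), "stride": stride,
            "seed": params.seed, "n_conformers": n_conformers}
    if check_decorrelation and n_conformers >= 20:
        rg = np.sqrt(((frames - frames.mean(axis=1, keepdims=True)) ** 2)
                     .sum(axis=2).mean(axis=1))
        tau_frames = _integrated_autocorrelation(rg)
        meta["rg_autocorrelation_steps"] = float(tau_frames * stride)
        if tau_frames > 1.0:
            meta["decorrelation_warning"] = True
            warnings.warn(
                f"conformer stride {stride} steps is below the estimated "
                f"Rg autocorrelation time {tau_frames * stride:.0f} steps",
                stacklevel=2)
    return ConformerLibrary(frames=frames, species=species, meta=meta)


def _integrated_autocorrelation(x: np.ndarray) -> float:
    """Integrated autocorrelation time (in sample units) of a series."""
    x = x - x.mean()
    n = len(x)
    if n < 8 or np.allclose(x, 0):
        return 0.0
    f = np.fft.rfft(x, 2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n].real
    acf /= acf[0]
    tau = 1.0
    for k in range(1, min(n // 4, 2000)):
        if acf[k] < 0.05:
            break
        tau += 2.0 * acf[k]
    return float(tau)
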