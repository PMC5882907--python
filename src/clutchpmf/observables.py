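"""Structural observables over conformer libraries and trajectories:
radial density profiles, clutch extent, and DNA persistence length."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dynamics import ConformerLibrary, Trajectory
from .params import CORE, DNA, SPECIES_NAMES


@dataclass
class RadialProfile:
    """Mean per-conformer bead counts vs distance from the clutch centre.

    ``counts[i]`` is the average number of selected beads per conformer in
    ``[edges[i], edges[i+1])``; the counts integrate to the per-conformer
    bead count of the selected species.
    """

    edges: np.ndarray       # (nbins+1,) nm
    counts: np.ndarray      # (nbins,)
    species: int | None     # CORE, DNA or None for all
    meta: dict = field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_tsv(self, path) -> None:
        label = "ALL" if self.species is None else SPECIES_NAMES[self.species]
        header = (f"# clutchpmf radial profile, species={label}, "
                  f"bin_width={self.edges[1] - self.edges[0]:.3f} nm\n"
                  "r_nm\tcount_per_conformer\n")
        with open(path, "w") as fh:
            fh.write(header)
            for r, c in zip(self.centers, self.counts):
                fh.write(f"{r:.4f}\t{c:.6f}\n")


def radial_profile(lib: ConformerLibrary, species: int | None = CORE,
                   bin_width: float = 0.5) -> RadialProfile:
    """Histogram of bead distances from the per-conformer core centroid."""
    if lib.n_conformers == 0:
        raise ValueError("empty conformer library")
    cores = np.nonzero(lib.species == CORE)[0]
    center_idx = cores if len(cores) else np.arange(lib.frames.shape[1])
    centers = lib.frames[:, center_idx, :].mean(axis=1, keepdims=True)
    if species is None:
        sel = np.arange(lib.frames.shape[1])
    else:
        sel = np.nonzero(lib.species == species)[0]
    d = np.linalg.norm(lib.frames[:, sel, :] - centers, axis=2).ravel()
    rmax = max(d.max() + bin_width, bin_width)
    edges = np.arange(0.0, rmax + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    return RadialProfile(edges=edges,
                         counts=counts / lib.n_conformers,
                         species=species,
                         meta=dict(lib.meta))


def clutch_extent(profile: RadialProfile, mass_fraction: float = 0.99) -> float:
    """Radius (nm) enclosing ``mass_fraction`` of the profile's beads."""
    if not (0 < mass_fraction <= 1):
        raise ValueError("mass_fraction must be in (0, 1]")
    cum = np.cumsum(profile.counts)
    total = cum[-1]
    if total == 0:
        return 0.0
    target = mass_fraction * total
    k = int(np.searchsorted(cum, target))
    if k >= len(profile.counts):
        return float(profile.edges[-1])
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (target - prev) / max(cum[k] - prev, 1e-300)
    return float(profile.edges[k] + frac * (profile.edges[k + 1] - profile.edges[k]))


def persistence_length(traj: Trajectory | np.ndarray, s_max: int = 20,
                       r2_warn: float = 0.95):
    """DNA persistence length from bond-vector correlation decay.

    Fits ln<cos theta(s)> = -s b / lp over bond separations s = 1..s_max,
    where b is the mean bond length.  Accepts a bare-chain
    :class:`Trajectory` or a frames array (n_frames, n_beads, 3).
    Returns (lp_nm, lp_se_nm, r_squared); warns if the decay is not
    exponential (R^2 below ``r2_warn``).
    """
    frames = traj.frames if isinstance(traj, Trajectory) else np.asarray(traj)
    if frames.ndim != 3 or frames.shape[1] < s_max + 2:
        raise ValueError("need a trajectory of a chain with > s_max+1 beads")
    bonds = np.diff(frames, axis=1)                       # (nf, nb, 3)
    blen = np.linalg.norm(bonds, axis=2)
    u = bonds / blen[:, :, None]
    b_mean = float(blen.mean())
    s_vals = np.arange(1, s_max + 1)
    corr = np.empty(s_max)
    for i, s in enumerate(s_vals):
        corr[i] = float((u[:, :-s, :] * u[:, s:, :]).sum(axis=2).mean())
    if np.any(corr <= 0):
        raise ValueError("bond correlations non-positive inside the fit range")
    fit = stats.linregress(s_vals, np.log(corr))
    lp = -b_mean / fit.slope
    lp_se = b_mean * fit.stderr / fit.slope**2
    r2 = fit.rvalue**2
    if r2 < r2_warn:
        import warnings
        warnings.warn(f"bond-correlation decay is not exponential (R^2={r2:.3f})",
                      stacklevel=2)
    return float(lp), float(abs(lp_se)), float(r2)
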