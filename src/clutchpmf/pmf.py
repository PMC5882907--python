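"""Potential-of-mean-force estimators and the entropy decomposition.

Two independent estimators of the clutch-clutch PMF are provided:

* exponential insertion averaging over sampled conformer pairs,
      F(xi) = F(inf) - kBT ln < exp(-U_inter(xi)/kBT) >,
  with uniformly random mutual orientations and overlapping pairs
  contributing exactly zero to the average; and

* constraint-force integration,
      F_T(xi) = F_T(inf) + Int_inf^xi [ <f_c>_s + 2 kBT / s ] ds,
  where <f_c>_s is the mean constraint force from constraint-biased
  Langevin runs and 2 kBT/s removes the rotational-entropy Jacobian of
  the distance coordinate.

In a crowder bath, the total PMF F_T decomposes into the clutch
conformational-entropy part F_NUC (insertion estimator applied to
conformers sampled *in the presence* of crowders) and the crowder-entropy
part F_CRD = F_T - F_NUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .dynamics import ConformerLibrary, ConstraintRecord
from .params import ForceFieldParams


@dataclass
class PMFCurve:
    """Free energy vs pair distance, anchored to zero at ``xi_ref``."""

    xi: np.ndarray       # (n,) nm, strictly increasing
    f: np.ndarray        # (n,) kBT
    se: np.ndarray       # (n,) kBT
    xi_ref: float        # nm; F(xi_ref) = 0 by convention
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.xi = np.asarray(self.xi, float)
        self.f = np.asarray(self.f, float)
        self.se = np.asarray(self.se, float)
        if np.any(np.diff(self.xi) <= 0):
            raise ValueError("xi grid must be strictly increasing")
        if np.any(self.se < 0):
            raise ValueError("standard errors must be non-negative")

    def __len__(self) -> int:
        return len(self.xi)

    def to_tsv(self, path) -> None:
        prov = ", ".join(f"{k}={v}" for k, v in self.meta.items())
        with open(path, "w") as fh:
            fh.write(f"# clutchpmf PMF, xi_ref={self.xi_ref:.3f} nm; {prov}\n")
            fh.write("xi_nm\tF_kT\tSE_kT\n")
            for x, f_, s in zip(self.xi, self.f, self.se):
                fh.write(f"{x:.4f}\t{f_:.6f}\t{s:.6f}\n")

    @staticmethod
    def from_tsv(path) -> "PMFCurve":
        meta = {}
        xi_ref = np.nan
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    for tok in line[1:].split(";"):
                        for kv in tok.split(","):
                            if "=" in kv:
                                k, v = kv.split("=", 1)
                                k = k.strip()
                                v = v.strip()
                                if k == "xi_ref":
                                    xi_ref = float(v.split()[0])
                                else:
                                    meta[k] = v
                elif not line.startswith("xi_nm") and line.strip():
                    rows.append([float(t) for t in line.split()])
        arr = np.array(rows)
        return PMFCurve(xi=arr[:, 0], f=arr[:, 1], se=arr[:, 2],
                        xi_ref=xi_ref, meta=meta)


@dataclass
class ForceTable:
    """Mean constraint forces over a distance grid."""

    records: list  # list[ConstraintRecord], any order

    def __post_init__(self) -> None:
        xis = [r.xi for r in self.records]
        if len(set(xis)) != len(xis):
            raise ValueError("duplicate grid points in force table")

    def sorted(self) -> list:
        return sorted(self.records, key=lambda r: r.xi)


@dataclass
class PMFFeatures:
    """Scalar descriptors of a PMF curve (all distances in nm, F in kBT)."""

    vanish_distance: float | None   # outermost crossing of the threshold
    min_value: float | None         # well depth (None if curve is flat)
    min_location: float | None
    bump_height: float | None       # largest positive F beyond the well


# ----------------------------------------------------------------------
def pmf_insertion(lib_a: ConformerLibrary, lib_b: ConformerLibrary,
                  xi_grid: np.ndarray, n_pairs: int, seed: int,
                  ff: ForceFieldParams | None = None,
                  xi_ref: float | None = None,
                  rotate: bool = True) -> PMFCurve:
    """Exponential-insertion PMF over conformer pairs.

    At each grid distance, ``n_pairs`` (conformer, conformer, rotation,
    rotation) samples are drawn, conformer B is displaced along x, and
    exp(-U_inter/kBT) is averaged (overlaps contribute 0).  The curve is
    anchored to zero at ``xi_ref`` (default: the largest grid point).
    Standard errors propagate the SE of the exponential average through
    the logarithm (delta method).
    """
    ff = ff or ForceFieldParams()
    if lib_a.n_conformers == 0 or lib_b.n_conformers == 0:
        raise ValueError("conformer libraries must be non-empty")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    xi_grid = np.sort(np.asarray(xi_grid, float))
    xi_ref = float(xi_grid[-1]) if xi_ref is None else float(xi_ref)
    if xi_ref not in xi_grid:
        raise ValueError("xi_ref must be a grid point")

    ca = np.ascontiguousarray(lib_a.frames, np.float64)
    cb = np.ascontiguousarray(lib_b.frames, np.float64)
    spa = lib_a.species.astype(np.int8)
    spb = lib_b.species.astype(np.int8)
    r0m = ff.r0_matrix()

    f = np.empty(len(xi_grid))
    se = np.empty(len(xi_grid))
    ss = np.random.SeedSequence([seed, len(xi_grid), n_pairs])
    sub = ss.generate_state(len(xi_grid)) % (2**31)
    for i, xi in enumerate(xi_grid):
        sw, sw2 = _kernels.insertion_average(
            ca, cb, spa, spb, r0m, ff.sigma, ff.epsilon, ff.rc,
            float(xi), int(n_pairs), int(sub[i]), rotate)
        mean_w = sw / n_pairs
        if mean_w <= 0.0:
            f[i] = np.inf
            se[i] = np.inf
            continue
        var_w = max(sw2 / n_pairs - mean_w**2, 0.0)
        se_w = np.sqrt(var_w / n_pairs)
        f[i] = -np.log(mean_w)
        se[i] = se_w / mean_w
    iref = int(np.nonzero(xi_grid == xi_ref)[0][0])
    if not np.isfinite(f[iref]):
        raise ValueError("all pairs overlap at the reference distance")
    f = f - f[iref]
    f[iref] = 0.0
    meta = {"estimator": "insertion", "n_pairs": n_pairs, "seed": seed,
            "phi_c_a": lib_a.meta.get("phi_c", 0.0),
            "phi_c_b": lib_b.meta.get("phi_c", 0.0),
            "overlap_flag": bool(np.any(~np.isfinite(f)))}
    return PMFCurve(xi=xi_grid, f=f, se=se, xi_ref=xi_ref, meta=meta)


def pmf_constraint(force_table: ForceTable, xi_ref: float | None = None,
                   kT: float = 1.0) -> PMFCurve:
    """Integrate mean constraint forces into a PMF.

    Trapezoidal integration of <f_c>_s + 2 kBT/s from ``xi_ref`` (the
    stand-in for infinite separation, default the largest grid point)
    down to each grid distance; per-point standard errors are combined in
    quadrature with the composite trapezoid weights, assuming independent
    grid points.
    """
    recs = force_table.sorted()
    xi = np.array([r.xi for r in recs])
    if xi_ref is None:
        xi_ref = float(xi[-1])
    if xi_ref not in xi:
        raise ValueError("xi_ref must be a grid point")
    mean = np.array([r.mean for r in recs])
    se_pt = np.array([r.se for r in recs])
    if np.any(~np.isfinite(mean)) or np.any(~np.isfinite(se_pt)):
        raise ValueError("force table contains non-finite statistics")
    integrand = mean + 2.0 * kT / xi

    n = len(xi)
    iref = int(np.nonzero(xi == xi_ref)[0][0])
    f = np.zeros(n)
    var = np.zeros(n)
    # integrate downward from the reference point
    for k in range(iref - 1, -1, -1):
        h = xi[k + 1] - xi[k]
        f[k] = f[k + 1] - 0.5 * h * (integrand[k] + integrand[k + 1])
    # and upward for any grid points beyond it
    for k in range(iref + 1, n):
        h = xi[k] - xi[k - 1]
        f[k] = f[k - 1] + 0.5 * h * (integrand[k] + integrand[k - 1])
    # composite trapezoid weights for the error propagation
    for k in range(n):
        lo, hi = (k, iref) if k <= iref else (iref, k)
        w = np.zeros(n)
        for j in range(lo, hi):
            h = xi[j + 1] - xi[j]
            w[j] += 0.5 * h
            w[j + 1] += 0.5 * h
        var[k] = float(((w * se_pt) ** 2).sum())
    meta = {"estimator": "constraint",
            "n_samples": int(sum(r.n_samples for r in recs))}
    return PMFCurve(xi=xi, f=f, se=np.sqrt(var), xi_ref=xi_ref, meta=meta)


def decompose(f_t: PMFCurve, lib_a_crowded: ConformerLibrary,
              lib_b_crowded: ConformerLibrary, n_pairs: int, seed: int,
              ff: ForceFieldParams | None = None,
              xi_grid: np.ndarray | None = None):
    """Split the total PMF into clutch- and crowder-entropy parts.

    F_NUC is the insertion PMF over conformers sampled in the crowded
    bath, on the same grid and reference as ``f_t``; F_CRD = F_T - F_NUC
    pointwise, with standard errors combined in quadrature.
    Returns (f_nuc, f_crd).
    """
    if xi_grid is None:
        xi_grid = f_t.xi
    if not np.array_equal(np.sort(np.asarray(xi_grid, float)), f_t.xi):
        raise ValueError("grid mismatch between F_T and the decomposition grid")
    f_nuc = pmf_insertion(lib_a_crowded, lib_b_crowded, xi_grid, n_pairs, seed,
                          ff=ff, xi_ref=f_t.xi_ref)
    f_crd = PMFCurve(xi=f_t.xi.copy(),
                     f=f_t.f - f_nuc.f,
                     se=np.sqrt(f_t.se**2 + f_nuc.se**2),
                     xi_ref=f_t.xi_ref,
                     meta={"estimator": "decomposition",
                           "phi_c": lib_a_crowded.meta.get("phi_c", 0.0)})
    return f_nuc, f_crd


def pmf_features(curve: PMFCurve, vanish_threshold: float = 0.1) -> PMFFeatures:
    """Extract vanish distance, well depth/position and repulsive bump.

    The vanish distance is the outermost crossing of ``vanish_threshold``
    found by scanning inward from the reference point (linear
    interpolation between grid points); beyond it the interaction is
    considered decayed to zero.
    """
    xi, f = curve.xi, curve.f
    finite = np.isfinite(f)
    vanish = None
    for k in range(len(xi) - 1, -1, -1):
        if finite[k] and f[k] > vanish_threshold:
            if k + 1 < len(xi) and finite[k + 1]:
                # interpolate the crossing between k (above) and k+1 (below)
                f0, f1 = f[k], f[k + 1]
                t = (f0 - vanish_threshold) / max(f0 - f1, 1e-300)
                vanish = float(xi[k] + t * (xi[k + 1] - xi[k]))
            else:
                vanish = float(xi[k])
            break
    fin = f[finite]
    if len(fin) == 0 or np.allclose(fin, 0.0):
        return PMFFeatures(vanish, None, None, None)
    kmin = int(np.nanargmin(np.where(finite, f, np.nan)))
    min_value = float(f[kmin])
    min_location = float(xi[kmin])
    beyond = (xi > min_location) & finite & (f > 0)
    bump = float(f[beyond].max()) if np.any(beyond) else None
    return PMFFeatures(vanish, min_value, min_location, bump)
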