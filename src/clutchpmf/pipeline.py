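"""Study orchestration: build -> sample -> PMF sweep -> decomposition ->
features, from a single configuration.

A study runs one clutch pair (het-het, eu-eu or het-eu) over a list of
crowder volume fractions.  At phi_c = 0 the PMF comes from the insertion
estimator; at phi_c > 0 the total PMF F_T comes from constraint-force
integration and is decomposed into F_NUC (insertion over crowder-sampled
conformers) and F_CRD = F_T - F_NUC.  All stage outputs are TSV/JSON plus
XYZ snapshots; identical configs and seeds reproduce every file.
"""

from __future__ import annotations

import json
import hashlib
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import builders, dynamics, observables, pmf
from .params import (ClutchSpec, CrowdingCondition, ForceFieldParams,
                     SimulationParams, euchromatin_spec, heterochromatin_spec)

PAIR_CHOICES = ("het-het", "eu-eu", "het-eu")


@dataclass
class StudyConfig:
    """Configuration of one crowding study."""

    pair: str = "het-het"
    phi_c: tuple = (0.0, 0.1, 0.2, 0.3)
    xi_grid: tuple = ()              # empty -> preset default
    box: float = 60.0                # nm
    preset: str = "desk"             # desk | production
    n_conformers: int = 2000
    conformer_stride: int = 250
    n_insertion_pairs: int = 100_000
    steps_per_xi: int = 1_000_000
    equilibration: int = 20_000
    seed: int = 1
    out_dir: str = "study_out"
    vanish_threshold: float = 0.1    # kBT

    def __post_init__(self) -> None:
        if self.pair not in PAIR_CHOICES:
            raise ValueError(f"pair must be one of {PAIR_CHOICES}")
        if len(self.phi_c) == 0:
            raise ValueError("phi_c list must not be empty")
        if self.preset not in ("desk", "production"):
            raise ValueError("preset must be 'desk' or 'production'")
        if self.preset == "production":
            # protocol of record: 90 nm box, >= 1e8 steps per distance,
            # >= 1e6 insertion pairs
            self.box = 90.0
            self.steps_per_xi = max(self.steps_per_xi, 100_000_000)
            self.n_insertion_pairs = max(self.n_insertion_pairs, 1_000_000)
        if not self.xi_grid:
            hi = min(45.0, self.box / 2.0)
            self.xi_grid = tuple(np.arange(20.0, hi + 1e-9, 2.0))

    @staticmethod
    def from_yaml(path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = StudyConfig(**data)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["phi_c"] = list(self.phi_c)
        data["xi_grid"] = [float(x) for x in self.xi_grid]
        Path(path).write_text(yaml.safe_dump(data))

    def param_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=float).encode()
        ).hexdigest()[:12]


def _specs_for(pair: str):
    a = heterochromatin_spec() if pair.startswith("het") else euchromatin_spec()
    b = heterochromatin_spec() if pair.endswith("het") else euchromatin_spec()
    return a, b


def run_study(config: StudyConfig, ff: ForceFieldParams | None = None,
              specs: tuple | None = None) -> dict:
    """Execute the full study; returns the machine-readable summary.

    Writes, under ``config.out_dir``: PMF TSVs (F, F_T, F_NUC, F_CRD per
    condition), radial profiles, a features table, ``summary.json`` and a
    stage log with seeds and wall times.  Any stage failure is recorded
    in a partial-results manifest before the error propagates.
    """
    ff = ff or ForceFieldParams()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "study.log"
    summary: dict = {"config": asdict(config), "hash": config.param_hash(),
                     "conditions": {}, "failed": None}
    spec_a, spec_b = specs if specs is not None else _specs_for(config.pair)
    rng = np.random.SeedSequence(config.seed)
    seeds = iter(rng.generate_state(64) % (2**31))

    def log(msg: str) -> None:
        with open(log_path, "a") as fh:
            fh.write(f"[{time.strftime('%H:%M:%S')}] {msg}\n")

    log(f"study {config.pair} hash={config.param_hash()} seed={config.seed}")
    stage = "build"
    try:
        t0 = time.time()
        clutch_a = builders.collapse_clutch(
            builders.build_nucleosome_chain(spec_a, ff=ff, seed=int(next(seeds))),
            spec_a, sim=SimulationParams(n_steps=20_000, seed=int(next(seeds))), ff=ff)
        clutch_b = builders.collapse_clutch(
            builders.build_nucleosome_chain(spec_b, ff=ff, seed=int(next(seeds))),
            spec_b, sim=SimulationParams(n_steps=20_000, seed=int(next(seeds))), ff=ff)
        clutch_a.write_xyz(out / "clutch_a.xyz")
        clutch_b.write_xyz(out / "clutch_b.xyz")
        log(f"build done in {time.time() - t0:.0f} s "
            f"(k_a={clutch_a.meta['k_collapse']:.3g}, "
            f"k_b={clutch_b.meta['k_collapse']:.3g})")

        features_rows = []
        for phi in config.phi_c:
            stage = f"phi_c={phi}"
            t0 = time.time()
            cond = CrowdingCondition(phi_c=phi)
            tag = f"{config.pair}_phi{phi:g}"
            libs = []
            for label, clutch in (("a", clutch_a), ("b", clutch_b)):
                topo = clutch.copy()
                if phi > 0:
                    topo.box = config.box
                    topo.coords += config.box / 2.0 - topo.coords.mean(0)
                    topo = builders.place_crowders(topo, cond,
                                                   seed=int(next(seeds)), ff=ff)
                lib = dynamics.sample_conformers(
                    topo, SimulationParams(n_steps=1,
                                           equilibration=config.equilibration,
                                           seed=int(next(seeds))),
                    n_conformers=config.n_conformers,
                    stride=config.conformer_stride, ff=ff)
                libs.append(lib)
                if label == "a" or spec_a is not spec_b:
                    prof = observables.radial_profile(lib, species=None)
                    prof.to_tsv(out / f"profile_{tag}_{label}.tsv")
            lib_a, lib_b = libs
            xi_grid = np.asarray(config.xi_grid, float)

            if phi == 0:
                f_t = pmf.pmf_insertion(lib_a, lib_b, xi_grid,
                                        config.n_insertion_pairs,
                                        seed=int(next(seeds)), ff=ff)
                f_t.meta["phi_c"] = phi
                f_t.to_tsv(out / f"F_{tag}.tsv")
                f_nuc = f_crd = None
            else:
                records = []
                for xi in xi_grid:
                    pair_topo = builders.build_pair_topology(
                        clutch_a, clutch_b, float(xi), box=config.box,
                        seed=int(next(seeds)), ff=ff)
                    pair_topo = builders.place_crowders(pair_topo, cond,
                                                        seed=int(next(seeds)), ff=ff)
                    rec = dynamics.run_constrained_pair(
                        pair_topo, float(xi),
                        SimulationParams(n_steps=config.steps_per_xi,
                                         equilibration=config.equilibration,
                                         seed=int(next(seeds))), ff=ff)
                    records.append(rec)
                    log(f"  xi={xi:g}: <f_c>={rec.mean:.4f} +- {rec.se:.4f}")
                f_t = pmf.pmf_constraint(pmf.ForceTable(records))
                f_t.meta.update(phi_c=phi, pair=config.pair)
                f_t.to_tsv(out / f"FT_{tag}.tsv")
                f_nuc, f_crd = pmf.decompose(f_t, lib_a, lib_b,
                                             config.n_insertion_pairs,
                                             seed=int(next(seeds)), ff=ff)
                f_nuc.to_tsv(out / f"FNUC_{tag}.tsv")
                f_crd.to_tsv(out / f"FCRD_{tag}.tsv")

            feat = pmf.pmf_features(f_t, config.vanish_threshold)
            row = {"phi_c": phi, "pair": config.pair,
                   "vanish_nm": feat.vanish_distance,
                   "well_depth_kT": feat.min_value,
                   "well_position_nm": feat.min_location,
                   "bump_kT": feat.bump_height}
            features_rows.append(row)
            summary["conditions"][str(phi)] = {
                "features": row,
                "F_T": {"xi": f_t.xi.tolist(), "f": f_t.f.tolist(),
                        "se": f_t.se.tolist()},
            }
            if f_nuc is not None:
                summary["conditions"][str(phi)]["F_NUC"] = f_nuc.f.tolist()
                summary["conditions"][str(phi)]["F_CRD"] = f_crd.f.tolist()
                # decomposition identity holds by construction; recorded
                # here so downstream consumers can assert it
                summary["conditions"][str(phi)]["decomposition_max_residual"] = \
                    float(np.max(np.abs(f_t.f - f_nuc.f - f_crd.f)))
            log(f"{stage} done in {time.time() - t0:.0f} s")

        with open(out / "features.tsv", "w") as fh:
            cols = list(features_rows[0])
            fh.write("\t".join(cols) + "\n")
            for row in features_rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        summary["features"] = features_rows
    except Exception as exc:  # partial-results manifest, then re-raise
        summary["failed"] = {"stage": stage, "error": repr(exc)}
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        raise
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def plot_pmfs(tsv_paths, out_png) -> None:
    """Basic overlay plot of PMF curves (styling not a goal)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots()
    for path in tsv_paths:
        curve = pmf.PMFCurve.from_tsv(path)
        label = Path(path).stem
        ax.errorbar(curve.xi, curve.f, yerr=curve.se, label=label, capsize=2)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("pair distance (nm)")
    ax.set_ylabel("F (kBT)")
    ax.legend(fontsize=7)
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
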