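# clutchpmf

Coarse-grained simulation study of how macromolecular crowding modulates
the effective interaction between **nucleosome clutches** — the compact
groups of nucleosomes that form ~30 nm structural units of interphase
chromatin.  The package builds bead-spring models of clutches at
euchromatin density (11 nucleosomes per 30 nm sphere) and heterochromatin
density (20 nucleosomes), samples them by Langevin dynamics alone or in a
bath of 7 nm spherical crowders, estimates clutch–clutch potentials of
mean force (PMFs) with two independent estimators, and decomposes the
crowded PMF into a clutch-conformational-entropy part and a
crowder-entropy (depletion) part.

It is intended for people studying entropic (depletion) forces in
chromatin organisation, and more generally for anyone who wants a small,
fully testable reference implementation of constraint-biased PMF
estimation for soft, fluctuating objects in crowded baths.

## Model and estimators

All interactions are excluded volume: a purely repulsive shifted
Lennard-Jones (WCA) pair potential

    U(r) = 4ε[(σ/(r−r₀))¹² − (σ/(r−r₀))⁶] + ε,   0 < r−r₀ < 2^{1/6}σ,

with σ = 2 nm (one DNA monomer), ε = 1 k_BT, and shifts r₀ encoding bead
sizes (2 nm DNA, 7 nm cores and crowders).  DNA monomers are joined by
FENE bonds (k = 30 k_BT/σ², R_b = 1.5σ) with a harmonic bending term
(k_θ = 25 k_BT/rad², θ₀ = 0) tuned to a 50 nm persistence length.  Each
nucleosome wraps 24 DNA monomers in 1.75 turns, held by stiff harmonic
restraints; clutches are nucleosome chains collapsed by a harmonic pull
of every core toward the core centroid, with stiffness calibrated so the
radial bead distribution vanishes (99% mass) at 15 nm.

Two PMF estimators:

* **exponential insertion** (crowder-free, and F_NUC in the
  decomposition):  F(ξ) = −k_BT ln⟨exp(−U_inter(ξ)/k_BT)⟩ over pairs of
  independently sampled, randomly rotated clutch conformers at centre
  distance ξ;
* **constraint-force integration** (total F_T in a crowder bath):
  F_T(ξ) = F_T(ξ_ref) + ∫ [⟨f_c⟩_s + 2k_BT/s] ds, where ⟨f_c⟩_s is the
  mean constraint force of a holonomic centre-distance constraint and
  2k_BT/s removes the rotational-entropy Jacobian.

The crowder contribution is F_CRD = F_T − F_NUC.  Closed-form
Asakura–Oosawa depletion theory, a Widom acceptance-ratio Monte Carlo,
and exact Boltzmann draws of the worm-like chain serve as independent
oracles in the test suite.  See `docs/methods.md` for assumptions, parameters, and
numerical choices.

## Worked example

Build the heterochromatin clutch, sample conformers, and measure the
range of the crowder-free repulsion:

```python
import numpy as np
import clutchpmf as cp

spec = cp.heterochromatin_spec()                   # 20 nucleosomes / 30 nm
chain = cp.build_nucleosome_chain(spec, seed=1)
clutch = cp.collapse_clutch(chain, spec,
                            sim=cp.SimulationParams(n_steps=20_000, seed=2))
print(f"calibrated pull k = {clutch.meta['k_collapse']:.2f} kBT/nm^2, "
      f"99% extent = {clutch.meta['calibrated_extent']:.2f} nm")

lib = cp.sample_conformers(
    clutch, cp.SimulationParams(n_steps=1, equilibration=80_000, seed=3),
    n_conformers=2000, stride=700)
profile = cp.radial_profile(lib, species=None)
print(f"library extent = {cp.clutch_extent(profile):.2f} nm")

grid = np.arange(20.0, 46.0, 1.0)
pmf = cp.pmf_insertion(lib, lib, grid, n_pairs=100_000, seed=4)
feat = cp.pmf_features(pmf, vanish_threshold=0.1)
print(f"repulsion decays to 0.1 kBT at {feat.vanish_distance:.1f} nm")
```

Output from one run of the above (a few minutes on one CPU):

```
calibrated pull k = 4.97 kBT/nm^2, 99% extent = 15.34 nm
library extent = 15.34 nm
repulsion decays to 0.1 kBT at 30.0 nm
```

The calibrated pull stiffness is the quantity that distinguishes the two
chromatin states: the dense 20-nucleosome clutch needs a strong pull and
acquires a hard boundary and a sharp ~30 nm repulsion range, while the
11-nucleosome clutch needs a weak pull (k ≈ 0.5 kBT/nm²) and stays soft,
with a gently rising repulsive flank.  In a crowder bath, constraint
runs (`run_constrained_pair` + `pmf_constraint`) give the total F_T, and
`decompose` splits it into the repulsive clutch term and the attractive
depletion term, whose strength grows with crowder volume fraction.

A command-line interface mirrors the library
(`clutchpmf build | simulate | pmf-insertion | pmf-constraint |
decompose | features | run-study`); `run-study` drives the whole
campaign from a YAML config with `desk` and `production` presets.

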