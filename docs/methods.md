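# Methods

`clutchpmf` studies how macromolecular crowding modulates the effective
interaction between nucleosome clutches — compact groups of nucleosomes
that act as ~30 nm structural units of interphase chromatin.  Everything
in the model is excluded volume: the effective forces it produces are
purely entropic, arising from the conformational entropy of the clutches
and the translational entropy of the crowders.

## The model

**Beads and pair interactions.**  Three bead species: DNA monomers
(2 nm, six base pairs each), nucleosome core particles (7 nm), and inert
crowders (7 nm, representing an average nucleoplasmic protein of ~70 kDa).
All nonbonded pairs repel through a purely repulsive shifted
Lennard-Jones (WCA) potential

    U(r) = 4 eps [ (sigma/(r-r0))^12 - (sigma/(r-r0))^6 ] + eps,
           0 < r - r0 < rc = 2^(1/6) sigma,

with sigma = 2 nm and eps = 1 kBT the units of length and energy.  The
shift r0 sets effective sizes: 0 (DNA-DNA), 2.5 sigma (core-core and all
crowder pairs of the same 7 nm diameter), 1.25 sigma (core-DNA).
Approaches with r <= r0 are divergent and treated as fatal integration
errors, never clamped, so no silent energy injection can occur.
Electrostatics is deliberately absent; all charges are assumed screened
into the effective sizes.

**DNA connectivity.**  Consecutive DNA monomers are joined by FENE bonds
(k = 30 kBT/sigma^2, R_b = 1.5 sigma), which together with the WCA term
give a mean bond length of 0.97 sigma, and every pair of consecutive
bond vectors carries a harmonic bending term U = (k_angle/2) theta^2
with theta0 = 0 (straight chain) and k_angle = 25 kBT/rad^2.  The angle
is between bond *vectors*, so the stiff-limit persistence length is
l_p ~ b k_angle ~ 50 nm, the standard value for double-stranded DNA.

**Nucleosomes.**  Each nucleosome wraps 24 DNA monomers (144 bp) around
its core in 1.75 turns; wrapped beads are tethered to the core by stiff
harmonic restraints (1000 kBT/sigma^2) at their helix rest distances,
and beads one helical turn apart (offset 14 ~ 24/1.75) are restrained to
the helix pitch so the two gyres stay close and parallel.  The wrap
helix radius is 4.5 nm (core-DNA contact distance plus one DNA radius)
and the pitch is 2 nm (adjacent gyres touch); only the turn count and
bead number are fixed by the model definition, so radius and pitch are
choices recorded here.  Consecutive nucleosomes are joined by 5 linker
monomers (30 bp); chains begin and end with wrapped segments.

**Clutches.**  A clutch is a nucleosome chain collapsed into a sphere:
every core is pulled toward the instantaneous centroid of its clutch's
cores by a harmonic restraint.  The restraint is phenomenological — it
stands in for the histone-tail/linker-histone mediated aggregation that
the model does not resolve.  Two densities are studied at a fixed 30 nm
collapsed diameter: 11 nucleosomes (euchromatin density, ~6 per 11 nm of
fiber) and 20 nucleosomes (heterochromatin density, ~11 per 11 nm).  The
restraint stiffness is the one calibrated quantity in the model: a
secant loop in (ln k, extent) adjusts it until the 99%-mass radius of
the clutch's radial bead distribution reaches 15 nm (+- 0.35 nm stopping
tolerance).  The calibration itself differentiates the two chromatin
states: the densely packed 20-nucleosome clutch needs a strong pull
(k ~ 2-5 kBT/nm^2, hard sharp boundary), the 11-nucleosome clutch a weak
one (k ~ 0.3-0.6 kBT/nm^2, soft fluctuating fringe).  A flat-bottom
variant of the restraint (zero inside a radius, harmonic beyond) is
available through the same type but is not used by default: with the
stiffness needed to compact the dense clutch it gives both clutches a
hard edge and erases the soft/hard contrast between them.

**Crowders.**  phi_c in [0, 0.3] by volume; the count in a cubic box of
edge L is floor(phi_c L^3 / ((pi/6) d^3)).  Random sequential insertion
with a clearance of r0 + 0.95 sigma guarantees an overlap-free start at
mild insertion energies.  An "ideal crowder" mode (crowder-crowder
interactions off) exists for validation against closed-form depletion
theory only.

## Sampling

Langevin dynamics with the Gronbech-Jensen/Farago integrator at
dt = 0.005 tau_MD (tau_MD = sigma sqrt(m/eps), all masses 1) and
friction gamma = 1/tau_MD, targeting T = 1 kBT.  The thermostat choice
replaces a deterministic Nose-Hoover chain: both sample the canonical
configurational ensemble, and the stochastic thermostat is
unconditionally stable for this force field.  Neighbor lists are
Verlet lists with per-species-pair ranges and a 1.5 nm skin, rebuilt
from cell lists when any bead has moved half a skin; thermal impulses
are drawn in vectorized chunks outside the compiled kernel.  Identical
inputs and seeds reproduce trajectories bit-for-bit on one platform.

Two caveats on the integrator, measured against independent equilibrium
oracles on the bare 100-bead chain (pivot Monte Carlo, and exact phantom
worm-like-chain draws Boltzmann-reweighted by the excluded-volume
energy, which touches only ~0.1% of conformers for this stiff chain):

* configurational one-point statistics (bond lengths, single-angle
  distributions, harmonic-well variances) are reproduced to <1% at
  dt = 0.005 tau_MD;
* long-wavelength tangent correlations of semiflexible chains converge
  slowly in time: the slowest chain modes relax over thousands of
  tau_MD, so a single trajectory yields a persistence-length estimate
  with a several-nm spread however long it runs within desk scale.
  Stiffness measurements therefore pool many short replicas, each
  started from an exact Boltzmann draw of the phantom worm-like chain
  (`builders.wlc_coords`; excluded volume touches ~0.1% of draws): every
  frame is then an equilibrium sample, replicas are independent, and the
  pooled estimate reproduces the exact-ensemble value to ~1 nm.

**Constraint-biased runs.**  The distance between the core centroids of
two clutches is held fixed by exact SHAKE/RATTLE projections (a single
distance constraint is projected exactly, |xi_actual - xi| < 1e-6 sigma
every step).  The constraint force is sampled with the blue-moon
estimator f_c = -mu (F_B/M_B - F_A/M_A)·n - mu |v_perp|^2 / xi, whose
mean for a rigid pair is dU/dxi - 2 kBT/xi; the 2 kBT/s term added back
inside the force integral removes the rotational-entropy Jacobian of the
distance coordinate, so the integrated PMF of a rigid pair equals the
bare pair potential (validated analytically in the test suite).  The
sign convention is fixed by that validation: f_c is the force the
constraint exerts on clutch B along the A->B axis, negative when it
holds a repulsive pair together, and tending to -2 kBT/xi (not zero) for
a non-interacting pair.  Standard errors come from block averaging over
>= 10 blocks.

**Conformer libraries.**  Single-clutch runs (optionally in a crowder
bath) produce libraries of clutch-only snapshots centred on the core
centroid.  The integrated autocorrelation time of the radius of gyration
is estimated a posteriori; snapshot strides below it are recorded as a
metadata warning rather than hidden.  At the desk scale used by the
test suite (2000 conformers, stride 700-800 steps) successive snapshots
of the slowly breathing euchromatin clutch are partially correlated;
this inflates the (reported) statistical errors of ensemble averages but
does not bias them.

## PMF estimators

* **Exponential insertion** (crowder-free and F_NUC):
  F(xi) = -kBT ln < exp(-U_inter/kBT) > over pairs of independently
  sampled, uniformly randomly rotated conformers placed at centre
  distance xi.  Overlapping pairs (any cross pair at r <= r0) contribute
  exactly zero.  Errors by the delta method on the log of the mean.
* **Constraint-force integration** (F_T in crowded baths):
  F_T(xi) = integral from xi_ref down to xi of [<f_c>_s + 2 kBT/s] ds by
  composite trapezoid, anchored F(xi_ref) = 0 at the outermost grid
  point; per-point SEs propagate through the trapezoid weights assuming
  independent grid points.
* **Decomposition:** F_NUC re-applies the insertion estimator to
  conformers sampled in the crowded bath; F_CRD = F_T - F_NUC pointwise
  (identity exact by construction), SEs in quadrature.

Curve descriptors: the "vanish distance" is the outermost crossing of a
0.1 kBT threshold found scanning inward (linearly interpolated between
grid points); well depth/location and the outer repulsive bump are read
directly off the grid.

## Validation oracles

Closed-form Asakura-Oosawa depletion between hard colloids in an ideal
bath (W = -(phi_c/v_d) kBT V_ov, linear in phi_c); an exact Widom
acceptance-ratio Monte Carlo for the same system; a staged
acceptance-ratio Metropolis MC for interacting hard depletants
(qualitative: deeper-than-AO well); and exact reweighted worm-like-chain
draws (`builders.wlc_coords`) for chain statistics.  The equal-size case (R = r_d = 3.5 nm, phi_c = 0.2)
has a contact depth of -0.500 kBT — the same scale the clutch-pair
simulations produce, which is a consistency check between the bead-spring
machinery and depletion theory, not a fitted agreement.

## Problem sizes (desk scale)

The package's default protocol, used by the test suite and the
acceptance script, is a scaled-down version of the protocol of record
(which is available as the `production` pipeline preset: 90 nm box, 1e8 steps
per distance, 1e6 insertion pairs):

| stage | desk scale |
|---|---|
| collapse calibration | <= 10 rounds x 20k steps |
| conformer library | 2000 snapshots, stride 700-800, 80k equilibration |
| insertion PMF | 1e5 pairs per 1-nm grid point on [20, 45] nm |
| crowded F_T | 5 distances x 4e5 steps, 72 nm box |
| persistence length | 160-200 replicas x 5e4 steps from exact chain draws |

Two consequences of the scaling are documented rather than hidden.
First, the crowded-well depth at phi_c = 0.2 carries an integrated
statistical error of several tenths of kBT at these run lengths (the
per-distance mean-force SE is ~0.2-0.3 kBT/nm); assertions about the
well therefore include the propagated SE.  Resolving the ~0.5 kBT well
to +-0.1 kBT requires run lengths of order 1e7-1e8 steps per distance —
the production preset.  Second, the constrained-pair box must exceed
twice the largest measured distance (the depletion range of two 30 nm
clutches in a 7 nm crowder bath reaches ~36 nm); the crowded runs
therefore use a 72 nm box.

## Known limitations

* The collapse restraint is phenomenological; no inter-nucleosome
  attraction, histone tails, linker histones, or electrostatics.
* Clutch pairs are isolated: no linker DNA connects them to a longer
  chromatin fiber.
* With both clutch models calibrated to the same 15 nm 99%-mass radius,
  the euchromatin clutch's insertion PMF decays to 0.1 kBT near
  27-28 nm — inside the heterochromatin pair's ~30 nm rather than
  outside it.  A soft-fringed 11-nucleosome clutch whose mean profile
  truly vanishes at 15 nm cannot reach 9% pair-contact probability at
  34 nm (that requires routine excursions beyond ~17 nm); the model can
  produce a 34 nm range only if the euchromatin profile is allowed a
  low-amplitude tail beyond 15 nm (99% radius ~18 nm).  The package
  keeps the 15 nm calibration for both clutches and reports the shorter
  euchromatin range, together with the softness contrast (smaller
  |dF/dxi| on the repulsive flank) that survives the calibration.
* Synthetic crowders are monodisperse inert spheres; real nucleoplasm
  is polydisperse and weakly interacting, so quantitative depths are
  model statements, not cellular predictions.
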