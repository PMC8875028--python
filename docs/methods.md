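# Methods

## The model

Two coarse-grained chains live in an unbounded 2D plane (no periodic
box): a **vesicle**, modelled as a closed bead–spring ring, and a
**semiflexible polymer**, a linear bead–spring chain. Both carry
N+1 = 61 identical monomers by default. All quantities are in reduced
units: lengths in units of the maximum bond extension l_max, energies in
k_BT (kBT = 1).

Bonded neighbours interact through the FENE potential

    U_FENE(l) = -(k r0^2 / 2) ln[1 - ((l - l0)/r0)^2],

with k = 20, l0 = 0.7, l_min = 0.4, l_max = 1.0 and r0 = l_max - l0 =
0.3. The energy diverges as any bond approaches l_min or l_max; a trial
move that would take a bond outside the open interval has dU = +inf and
is rejected outright, so chain connectivity (and, combined with excluded
volume, non-crossing) is exact. The vesicle ring closes on itself: N+1
beads, N+1 bonds including the closure bond, so every monomer is
equivalent. The polymer has N bonds and two free ends.

Non-bonded monomers of the *same* chain repel/attract through a Morse
potential

    U_M(r) = eps [e^{-2 alpha (r - r_min)} - 2 e^{-alpha (r - r_min)}],

with alpha = 24, r_min = 0.8, eps = 1. With this large alpha the
potential is a steep excluded-volume core with a thin attractive skin;
it is truncated (unshifted) at r = 1.0, where its magnitude is below
2 x 10^-2 and decaying like e^{-24 r}. The ring-closure pair of the
vesicle counts as bonded and is excluded from the Morse sum.

The polymer alone carries a bending energy at each of its N-1 interior
vertices,

    U_b = kappa (1 + cos theta),

where theta is the interior vertex angle: a straight chain (theta = pi)
costs nothing, a fold (theta -> 0) costs 2 kappa. The vesicle is
**soft**: it has no bending term at all. kappa is the first control
parameter of the study.

The two chains interact only through a truncated Lennard-Jones well

    U_VP(r) = eps_vp [ (r_m/r)^12 - 2 (r_m/r)^6 ],    r <= 2.0,

whose minimum is exactly -eps_vp at r = r_m = 0.8, the same contact
distance as the Morse term, so the two non-bonded minima coincide and
eps_vp literally is the adsorption strength per contact — the second
control parameter. The r^-12 core doubles as inter-chain excluded
volume.

### The well-depth convention

The published form of the inter-chain potential mixes two LJ
conventions (a prefactor 4 together with an inner factor 2) and never
states sigma. We implement the depth-eps_vp form above; it is
algebraically identical to 4 eps_vp [(sigma/r)^12 - (sigma/r)^6] with
sigma = 0.8 * 2^{-1/6}. Because r_m is a configuration parameter, the
alternative reading (well depth 4 eps_vp) is obtained by scaling eps_vp
by 4, and the acceptance script reports that variant alongside the
default. Neither reading can be verified against the source, and the
absolute scale of the vesicle–polymer energy (and with it the adsorbed
morphology map) depends on it directly; this is the dominant systematic
uncertainty of the reimplementation. Simulated <U_VL> at (kappa=10,
eps_vp=2) is roughly four times deeper than the published value under
the default convention, which is consistent with the published model
having a substantially shallower effective contact well (for example a
small sigma ~ l_min, which would leave only the shallow LJ tail
accessible outside the Morse core); with no stated sigma this cannot be
settled, so the documented convention is kept and the discrepancy is
reported rather than fitted away.

## Metropolis dynamics

One Monte Carlo step (MCS) is 2(N+1) attempted moves. Each attempt
picks one bead uniformly from both chains, proposes a displacement
uniform on the open square (-0.25, 0.25)^2 (no radial reweighting: the
proposal is symmetric, so the plain Metropolis ratio is correct), and
accepts with probability min(e^{-dU/kBT}, 1). dU is computed
incrementally from only the terms touching the moved bead (its <= 2
bonds, <= 3 bending vertices, its Morse and LJ partners), which makes a
move O(N). The incremental path is verified against a full recompute to
1e-9 (with double-precision relative slack for the ~1e6 k_BT energies of
near-core overlap proposals).

A running total energy is updated by accepted dU and resynchronised
against a full O(N^2) recompute every 10^4 MCS; observed drift over 10^3
MCS is below 1e-6 k_BT. The production inner loop is numba-compiled
(~2-3 x 10^6 move attempts/s for N=60 on one core); a pure-Python
reference implementation of the identical dynamics backs the unit tests.

### Randomness and reproducibility

Replica seeds derive from a base seed through
`numpy.random.SeedSequence` spawning. Within a run, the compiled RNG is
reseeded at every block boundary (the equilibration span, then each
measurement interval) with a seed derived from (run seed, block index),
so a run is a pure function of its inputs and a checkpoint needs only
the bead coordinates plus the (seed, next-block) token to resume
bit-exactly. All derived seeds stay below 2^31.

### Sampling correctness checks

Two quadrature oracles pin the dynamics to closed-form Boltzmann
statistics: (i) a single FENE bond sampled in 2D must follow p(l)
proportional to l e^{-U(l)} (the radial measure), checked by a
Kolmogorov–Smirnov distance < 0.01 against the tabulated density at
10^6 samples; (ii) the mean vertex cosine of an isolated chain must
match the one-vertex quadrature average of cos(theta) under
e^{-kappa(1+cos theta)} at kappa = 0, 1, 10, 100 within 3 standard
errors (batch means). The Metropolis acceptance frequency at dU = 2 is
checked against e^-2.

## Schedules and problem sizes

The production protocol is 3 x 10^8 MCS per run with one measurement
every 10^6 MCS, 100 measurements per run and 100 independent replicas
(10^4 pooled samples); the final third of each run is the measurement
window, i.e. a 2:1 equilibration:measurement split, which is preserved
whenever the schedule is scaled. Scaled-down schedules are used
throughout the test suite and the acceptance script; the package's
desk-scale protocol is 10 replicas x 2.7 x 10^5 MCS per state point (100
measurements per run, 1000 pooled samples). Observed relaxation at
N=60: adsorption of the tangent-placed polymer completes within a few
10^4 MCS, collapse/wrapping within ~2-4 x 10^5 MCS (slowest for the
stiffer kappa=50 chain, whose state point therefore runs 5.4 x 10^5 MCS),
and the double-vesicle fold at (kappa=10, eps_vp=8) forms after
~2.5 x 10^5 MCS, which is why the fold-signature check also runs
6 x 10^5 MCS. Quantities measured at desk scale agree with themselves
across replicas but carry larger equilibration bias and statistical
error than the production protocol; pooled standard errors treat
samples as independent and therefore understate the error of strongly
autocorrelated observables.

Initial conformations: the vesicle starts as a regular (N+1)-gon with
edge l0; the polymer starts straight, tangent to the vesicle circle at
the contact distance r_m, with a per-replica random rotation about the
vesicle centre (a self-avoiding random-walk mode is also provided).
Replicas therefore differ in both seed and initial state.

## Observables

* **<U_VL>** — the instantaneous inter-chain LJ sum; pooled over all
  measurements of all replicas.
* **<R_ee>** — polymer end-to-end distance.
* **C(s) = <b_k . b_{k+s}>** — tangent–tangent correlation of the ring,
  averaged over all k with periodic indexing. Bond vectors are
  normalised by default (the curve is then cosine-like with C(0) = 1);
  the raw mode preserves the exact ring-closure identity
  sum_s C(s) = 0. For a regular polygon C(s) = cos(2 pi s / L) exactly.
  Per configuration the circular k-average makes C(s) = C(L-s) exact;
  ensemble curves are averaged without aligning fold orientations.
* **Asphericity** — (lam1 - lam2)^2/(lam1 + lam2)^2 of the 2D gyration
  tensor: 0 for a circle, 1 for a line.
* **Trough count** — number of negative local minima of C(s) after
  periodic moving-average smoothing (window 5), thinned to a minimum
  separation of L/10 (deeper trough wins; flat minima report their
  leftmost index). One trough: circular/oval; two: double vesicle;
  three: triple vesicle.

The shape classifier applies, in order: a rod-with-partial-adsorption
test (near-fully-extended polymer, R_ee > 0.8 N l0, with weak contact,
|U_VL| < 0.25 (N+1) eps_vp); the trough-count fold families; and within
the two-trough/elongated family a symmetry test on C(s) - C(L-s)
(bent shapes break it) with a trough-depth ratio >= 2 marking racquets.
All cut points are configuration values (`ShapeThresholds`) chosen so
the analytic signature curves classify correctly, and raw descriptors
are always reported alongside labels so data can be re-thresholded
without re-running.

## Known limitations

* Single-bead displacements relax large-scale modes slowly; there are
  no cluster, reptation or bias-potential moves, so free-energy barriers
  between morphologies are crossed only by waiting. Exact transition
  points are out of scope.
* The LJ sigma ambiguity above sets the absolute <U_VL> scale.
* The trough-count and classifier thresholds are heuristics standing in
  for by-eye fold counting; labels near threshold values are soft.
* Truncations are unshifted (Morse at 1.0, LJ at 2.5 r_m = 2.0), so
  pair energies jump by the (small) tail value at the cutoff; no tail
  corrections are applied.
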