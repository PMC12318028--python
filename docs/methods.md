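# Methods

`solvnet` is a desk-scale implementation of the analysis chain used in
neutron-diffraction solution-structure studies of hydrogen-bonded
mixtures: Metropolis Monte Carlo of rigid molecules, optional
empirical-potential (EP) refinement against a total structure factor,
and the structural analyses (radial distributions, structure factors,
coordination numbers, hydrogen-bond energetics and network topology,
spatial density maps).  This note records the models, the defaults and
the numerical choices, and what the synthetic-data tests do and do not
demonstrate about real data.

## Composition and ionisation

Composition arithmetic treats the liquid in light-isotope terms: molar
masses default to 17.031 (NH₃) and 18.015 (H₂O) g/mol and isotopic mass
differences are ignored, because isotopic substitution is assumed to
preserve structure and only changes scattering lengths.  The degree of
base dissociation follows Ostwald's dilution law
k_b = α²c₀/(1 − α), solved in closed form via the rationalised positive
root α = 2k_b / (k_b + √(k_b² + 4 k_b c₀)), which is numerically stable
in the physically relevant regime k_b ≪ c₀.  Ionisation is bookkeeping
only: the simulated boxes contain no NH₄⁺/OH⁻ species, consistent with
the per-mille ionisation of concentrated aqueous ammonia.

Scattering lengths default to b_H = −3.74 fm, b_D = +6.67 fm, and
Sears-table coherent lengths for O (5.803 fm) and N (9.36 fm); all are
configurable.  All hydrogens (H_W and H_A) are treated as exchangeable:
an isotope scheme's protium fraction x_H applies to both, and the
effective length x_H·b_H + (1 − x_H)·b_D replaces b_H in every
hydrogen-bearing weight.  The null composition (b_eff = 0) is
x_H = b_D/(b_D − b_H) ≈ 0.641.

## Reference potentials

Seed potentials are an SPC/E-like rigid water (q_O = −0.8476 e,
q_H = +0.4238 e, ε_O = 0.650 kJ/mol, σ_O = 3.166 Å, O–H 1.0 Å,
∠HOH 109.47°; hydrogens carry no LJ term) and an OPLS-like rigid
ammonia (q_N = −1.02 e, q_H = +0.34 e, ε_N = 0.711 kJ/mol,
σ_N = 3.42 Å, N–H 1.01 Å, ∠HNH 106.7°).  Mixing is Lorentz–Berthelot
(geometric ε, arithmetic σ); the Coulomb constant is
1389.35 kJ·Å/(mol·e²); units are Å, kJ/mol, e, K throughout.  Any
reported energetic quantity is meaningful only relative to this (fully
configurable) parameter set, and structure-refinement results are
expected to depend on it.

Molecules are rigid; "jiggle" moves (single-site displacements
restrained harmonically to the template's internal distances, spring
2000 kJ/mol/Ų) exist but are off by default because every observable
computed here is intermolecular.

Electrostatics use force-shifted truncation (V and dV/dr continuous and
zero at the cutoff) and LJ terms are truncated-and-shifted, with cutoff
min(12 Å, L/2).  No Ewald summation: at the box sizes used
(≈ 14–22 Å) force-shifted truncation is an accepted approximation for
structural Monte Carlo, and it keeps move energetics exactly consistent
with the total energy.  Explicit pair-energy evaluations (hydrogen-bond
energetics) default to the bare, uncut potentials.

## Monte Carlo sampler

Moves are whole-molecule translations (uniform, max 0.3 Å) and
rotations (random axis, max 15°), proposed 50:50 (45:45:10 when jiggles
are enabled); these sizes give ≈ 40–50% acceptance in the liquids
studied.  One sweep is one attempted move per molecule; equilibration
defaults to 2000 sweeps.  A move is accepted with probability
min(1, e^(−ΔU/kT)), k_B = 0.0083145 kJ/(mol·K).  Energies are tracked
incrementally (per-molecule differences) and agree with full
recomputation to < 10⁻⁵ kJ/mol over 10⁴ moves; molecules wrapped across
the periodic boundary are unwrapped about their first site before any
rigid-body move so rotations cannot distort them.  A single seeded
`numpy` generator drives box construction and sampling; identical seeds
give bit-identical trajectories.

## Empirical-potential refinement

The EP is a per-pair-type tabulated radial correction (grid step
0.05 Å, linear interpolation, zero beyond the grid) added to the pair
potentials — deliberately simpler than the Poisson-function expansion
of the published EPSR engine.  Each cycle: sample an ensemble, build
the simulated F(Q) = Σ_p w_p (S_p(Q) − 1) with the isotope weights
w_p, form ΔF = F_target − F_sim, distribute the misfit over pairs by
the least-norm rule ΔS_p = ΔF·w_p/Σ_q w_q², invert each ΔS_p through
the inverse Fourier transform to an r-space perturbation Δg_p, and add
ΔU_p(r) = −damping·kT·Δg_p(r), clipped to ±2 kJ/mol (damping 0.3).
Damping and the amplitude cap stabilise what is otherwise an ill-posed
inverse step.  The summed squared misfit is recorded per cycle;
refinement reports failure if it rises over three consecutive cycles.
The target Q grid must start at or above 2π/L, the smallest wavevector
a box of side L supports.

The pipeline's core validation is a parameter-recovery experiment: an
80-particle Lennard-Jones liquid with σ shifted by +0.1 Å provides the
target F(Q); refinement of the unshifted model moves the first g(r)
peak onto the target's within 0.05 Å (one to two histogram bins).  A
self-target run (target produced by the same model) leaves the EP at
the statistical noise floor.

## Scattering

Partial g_αβ(r) are minimum-image histograms (default bin 0.03 Å,
r_max = L/2) normalised by the ideal-shell count per central atom.
Only intermolecular pairs contribute by default — the covalent peaks of
rigid molecules are not solution structure — and the ideal count
excludes the partners that can never appear (self, same-molecule
sites), so g → 1 at large r without tail corrections; the finite-range
truncation is otherwise left as is.  Transforms use trapezoidal
quadrature on the tabulated grid, with an optional Lorch window
(off by default) to damp truncation ripple.  F(Q) is the bare weighted
sum over the i(i+1)/2 pairs with weights (2 − δ_αβ)c_αc_βb_αb_β, in
fm²; no self-scattering or normalisation convention is added.  Default
Q grid: 0.05–30 Å⁻¹ in 0.05 Å⁻¹ steps, resolving the ≈ 1.9/2.1 Å
hydrogen-bond features at desk-scale box sizes.

## Coordination numbers and peaks

The shell integral n_α^β = 4πρc_β ∫ r²g dr treats g as piecewise
constant over its histogram bins and integrates the exact sub-shell
volume of each (partial bins included).  This is the quadrature
consistent with the histogram estimator: a shell aligned with bin edges
reproduces the underlying pair counts identically, where trapezoidal
quadrature on bin centres carries a half-bin boundary bias of a few
tenths of a percent.  The like-pair normalisation records the effective
neighbour fraction (excluding self/same-molecule partners) so integral
and direct neighbour counting agree.  Peak finding smooths with a
centred 5-bin moving average (plateau ties break toward smaller r),
searches only r > 0.5 Å (excluded-volume guard), and reports the first
maximum with g > 1, the following minimum, and the FWHM of both the
smoothed and the raw curve (half level relative to zero).  The raw
curve is always used for integrals.

## Hydrogen-bond energetics

Identification is distance-only, per bond class: water→water requires
O_W–O_W ≤ 3.3 Å and H_W···O_W ≤ 2.4 Å; water→ammonia H_W···N_A
≤ 2.43 Å; ammonia→water H_A···O_W ≤ 2.49 Å; ammonia→ammonia
H_A···N_A ≤ 2.4 Å (this last contact shows only a weak shoulder near
2.2 Å, so its cutoff is a configurable choice rather than a measured
shell boundary).  The 30° angle criterion belongs to the
network-topology linkage, not to the energetics.  Each hydrogen donates
at most one bond, to its nearest eligible acceptor — deterministic and
free of double counting.  Waters partition into ammonia's first
solvation shell (FSS: O_W within 3.6 Å of any N_A) and bulk; the
donor's label subclassifies water→water bonds.  A bond's energy is the
full molecule–molecule LJ + Coulomb pair energy.  Per-class enthalpy
histograms (bin 0.5 kJ/mol, pooled over 11 frames saved 50 sweeps
apart) are summarised by nonlinear least-squares Gaussian fits
initialised at the sample moments; classes with < 50 bonds or
degenerate histograms are flagged and left unfitted.

On ensembles from the default (unrefined) potentials the donor
asymmetry is strong and robust — water-donated bonds ≈ −20 to
−22 kJ/mol, ammonia-donated ≈ −6 to −8 kJ/mol — but water→ammonia is
*not* the single strongest class: fixed-charge seed potentials lack the
polarisation/charge-transfer physics that makes nitrogen an unusually
strong acceptor, and the full experimental ordering emerges only from
ensembles refined against diffraction data.  The test suite asserts the
full ordering as specified and documents this limitation rather than
retuning the potentials.

## Network topology

A hydrogen-bonded water linkage requires O_W–O_W ≤ 3.3 Å and an
included angle ≤ 30°, where the angle is by default the donor
deviation — the angle at the donor oxygen between O→H and O→O,
minimised over the four candidate hydrogens of the pair; an alternative
convention (H–O–O measured at the acceptor) is switchable, since the
precise published definition lives in supplementary material not
reproduced here.  Rings are Franzblau shortest-path rings (no two
members joined by a strictly shorter outside path), enumerated by
bounded DFS anchored at each cycle's smallest node and filtered with
BFS distances, default maximum size 12.  Chains are maximal simple
paths whose internal nodes have degree 2 and which are themselves
shortest paths between their endpoints; traversal is lexicographic for
deterministic output, and pure cycles are not chains.  Clusters use the
looser distance-only criterion (connected components via union-find).
Ammonia is excluded from the water-network statistics; a mixed-species
mode exists to verify that ammonia molecules themselves form no
extended network.  All three censuses are validated against exhaustive
`networkx`-based enumeration on random graphs.

## Spatial density maps

Neighbour sites within a radius (3.5 Å around water, 4.0 Å around
ammonia, voxel 0.25 Å by default) are binned in the central molecule's
body frame: origin at the heavy atom, z along the symmetry axis (H–O–H
bisector / C₃ᵥ axis, toward the hydrogens), x toward one hydrogen's
projection.  Because the hydrogen choice is arbitrary, maps are by
default averaged over the point group (C₂ᵥ: 4 operations; C₃ᵥ: 6),
which also enforces the molecular symmetry.  The "top f" isosurface
threshold is defined on integrated density — the smallest set of
highest-density voxels holding a fraction f of the map's total — with
ranked selection so exact ties (e.g. a uniform map) still yield the
requested fraction of voxels; a ranked-voxel-count semantic would be
an alternative reading, and the integrated-density one is the default
because it matches the "most probable locations" phrasing.  Maps
export as Gaussian cube files plus TSV.

## Synthetic data: what it shows and what it does not

The generator produces (i) equilibrated mixture boxes at the study
conditions — 1 : 3.665 ammonia : water at 0.92 g/cm³ and 273/298 K,
scaled to 66 + 18 molecules, and pure-water boxes — and (ii) analytic
fixtures with known answers: an ideal gas (flat g(r), sine-law triplet
angles), an isolated proton-ordered diamond-cubic ice fragment with
O–O 2.76 Å (4-coordination, all-hexagon shortest-path rings,
tetrahedral angles), a tetrahedral 5-molecule cluster (109.47°), an
equilateral O–O–O triplet at 3.0 Å (the 60° interstitial signature)
and a linear water dimer.  Tests against these verify the *estimators
and algorithms* — histogram normalisation, transform round trips,
census correctness, oracle equivalence of the shell integral, EP
parameter recovery.  They do not certify agreement with experimental
ensembles: absolute coordination numbers, enthalpies and topology
distributions from seed potentials differ from data-refined EPSR
results, and the deposited experimental structure factors are not
bundled here.

Problem sizes in the tests (80–200 particle LJ boxes, 84-molecule
mixtures, 10–25 frames, hundreds to a thousand sweeps) were chosen as
the smallest ensembles on which the statistical assertions are stable;
all are configurable upward.

## Known limitations

- No Ewald electrostatics; truncation artefacts grow for much larger
  boxes or strongly charged species.
- Rigid molecules only; no intramolecular structure refinement.
- The EP representation (radial tables, least-norm pair distribution of
  the misfit) is a simplification of published EPSR; with several
  isotopic samples of conflicting information content the least-norm
  rule is not a substitute for a proper simultaneous fit.
- NH₄⁺/OH⁻ species, activity corrections and temperature dependence of
  k_b beyond the two tabulated values are out of scope.
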