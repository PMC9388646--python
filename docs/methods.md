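# Methods

This note documents the models, estimators and numerical choices behind
`unwindfes`, and states what the synthetic validation systems do and do not
establish about real membrane-protein simulations.

## Collective variables

**Switched secondary-structure scores.** The AlphaRMSD score of a residue
window sums, over every contiguous 6-residue block, a switching function of
the block's optimal-superposition RMSD (nm) against an ideal α-helix block:

    n(x) = (1 − (x/0.1)⁸) / (1 − (x/0.1)¹²)

The code evaluates the algebraically identical form
`(1 + u⁴)/(1 + u⁴ + u⁸)` with `u = x/0.1`, which removes the x = 0.1
singularity exactly (value 2/3) with no epsilon handling; continuity
matters because biased dynamics differentiates through the score. The
residual helicity is `f_H = S / S_Max` with `S_Max = window − 6 + 1`,
clamped to [0, 1]. AntiBetaRMSD applies the same switch to 3+3-residue
anti-parallel blocks, enumerating every ordered pair of 3-residue windows
from two distinct segments (same-chain windows need one intervening
residue). Block atoms are backbone N, Cα, C, O — a set that is complete
for every residue type including glycine; whether Cβ belongs in the block
is a genuinely open convention and this package fixes it this way.

The length scale of the switch is taken at its printed value, 0.1 nm, with
block RMSDs computed in nm. Common simulation engines default to 0.08 nm
for this CV; the choice shifts absolute S values slightly but not the
identities tested here (ideal helix → S exactly S_Max either way).

**Ideal backbones.** Reference blocks and synthetic chains are grown by
natural-extension placement from standard bond geometry (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å, trans peptide) with fixed
dihedrals: α-helix (φ, ψ) = (−57°, −47°), β-strand (−139°, 135°), extended
(180°, 180°). Because every residue of an ideal helix is related to the
next by the same screw transform, all equal-length windows are congruent;
this is what makes "S = S_Max exactly" a machine-precision identity rather
than an approximation. Consecutive Cα–Cα distances come out 3.804 Å.

**Superposition.** Minimum RMSD over rigid transforms uses centered
coordinates and the optimal proper rotation (quaternion/SVD). Two-atom and
collinear sets are accepted — the minimum is well defined even where the
rotation is not unique — and a brute-force quaternion-grid minimizer in the
test suite provides the independent check.

**Contacts.** Native-contact pairs are heavy-atom pairs strictly closer
than 4.5 Å in the reference; Q uses β = 50 nm⁻¹ and λ = 1.5. The
coordination number uses r₀ = 4.5 Å with exponents n = 6, m = 12 (the
conventional defaults, overridable); for m = 2n the switch reduces exactly
to `1/(1 + yⁿ)`, otherwise the removable point at r = r₀ is filled with
its limit n/m.

## Toy models

**Helix–coil chain.** Each of n = 12 sites is helical or coil with energy

    E(s) = Δe · #helical − J · #equal-neighbour-pairs

(Δe in kcal/mol, negative favouring helix; J ≥ 0 a cooperativity
coupling). This is the minimal Ising-type model whose equilibrium is
exactly enumerable (2¹² = 4096 states) while still exhibiting the
competition between per-residue stability and cooperativity that governs
helix unwinding. The partition function is cross-checked against an
independent 2×2 transfer matrix to 10⁻¹⁰ relative; chains longer than 20
sites refuse to enumerate and point to the transfer-matrix path. States
embed into 3D backbones (helical dihedrals on H sites; coil sites fixed at
(−120°, 120°) so fixtures are deterministic), with optional seeded Gaussian
coordinate noise. Across the 13 leading-run archetype states the geometric
residual helicity increases strictly with the helical-site count, so the
spin-chain CV and the geometric CV tell the same story.

**Analytic potentials.** A harmonic well (equipartition reference), a
tilted quartic double well `V(x) = h((x/a)² − 1)² + t·x/a` with defaults
h = 3 kcal/mol, a = 1 Å, t = 0.8 kcal/mol (basin split ≈ 1.52 kcal/mol by
quadrature at 310 K), a two-basin 2D surface, and a flat bounded interval.
Basin free energies are defined by Boltzmann quadrature over each side of
the barrier top.

**Two-chain fixture.** A 12-residue substrate (9 helical residues, a
3-residue C-terminal strand) faces a receptor strand and two
carboxylate-like acceptor groups standing in for a catalytic aspartate
dyad. The donor–acceptor distance and the D–H···A deviation from linearity
are solved for analytically and realized to better than 10⁻³; when
sheet-registered, the substrate strand and receptor strand are placed
verbatim from the ideal anti-parallel block, so AntiBetaRMSD ≥ 1 by
construction. Backbone C–N pairs of residues 10–11 and 11–12 are labelled
as the two candidate scissile bonds. Distances below 1.5 Å are rejected as
sterically impossible.

## Sampling

Continuous models move by first-order (overdamped) Euler–Maruyama
dynamics, `dx = −μ∇(U+V) dt + √(2 k_B T μ dt) ξ`, with unit effective mass
and mobility μ = 1/friction; defaults T = 310 K, friction 1 ps⁻¹,
dt = 0.002 ps (stable for the stiffest default potential, μ k dt ≈ 0.05),
reflecting walls at the stated domain. The discrete helix–coil chain moves
by single-site Metropolis flips against model-plus-bias energy, which
satisfies detailed balance exactly; this replaces the Langevin step for
the one model that has no gradient. Dynamics here is a means to
equilibrium statistics, not a kinetic model.

Well-tempered hills (defaults h₀ = 0.3 kcal/mol, σ = 0.1 in the CV's
units, γ = 10 — standard magnitudes that converge on these systems in
seconds) are deposited every 4 ps; neighbour exchanges alternate even/odd
replica pairs every 10 ps, swapping configurations while biases stay put,
with acceptance `min(1, exp[(V_a(x_a)+V_b(x_b)−V_a(x_b)−V_b(x_a))/k_BT])`
and V ≡ 0 for the neutral replica. For speed, 1D biases keep V and dV/ds
cached on a grid (2001 points over the domain; exact 13- or 12-point
tables for the discrete CVs) updated at each deposit; the exact Gaussian
sum remains the reference implementation and the two agree to grid
interpolation error (~10⁻⁶ of h₀). The whole ensemble is a pure function
of (configuration, seed): per-replica generators are spawned from one seed
sequence, and the exchange stream has its own.

## Free-energy estimators

From hills, `F(s) = −(γ/(γ−1)) V(s, t_end)` (−V for γ = ∞), min-shifted
to 0. The instantaneous end-of-run bias is used as is: its fluctuations
are O(hill height) and averaging the bias over deposition times was
measured to trade those fluctuations for a larger early-run transient
bias, so it is not offered.

From a COLVAR record, last-bias reweighting: the `bias` column written by
the sampler holds the **final** bias re-evaluated at each frame's CV, each
retained frame gets weight ∝ exp(+V/k_BT) after discarding the first 20 %
(configurable) as equilibration, and the weighted histogram gives
F = −k_BT ln ρ. Bins visited fewer than 5 times (configurable) are masked,
never extrapolated. Profiles over a biased CV are reconstructed from the
replica biased on that CV — it is the one that visits the full range; the
neutral replica serves as an unbiased cross-check. A rigorous multi-replica
combination (WHAM/MBAR over cluster populations) is deliberately out of
scope.

Uncertainties come from block analysis with block size 100: contiguous
blocks each yield a block estimate (per-bin FES, or a weighted mean for a
scalar series) and the per-bin standard error of block means is reported.
On i.i.d. data this recovers σ/√n; on an AR(1) series with φ = 0.9 the
blocks are long against the ~10-step correlation time and recover the
autocorrelation-inflated closed form σ√((1+φ)/(1−φ))/√n.

Minima of a 1D profile are local minima of the unmasked grid (plateaus and
exact ties collapse deterministically to the lowest-CV bin), each reported
with ΔF to the global minimum and the barrier (max F on the grid path to
the global minimum). A `min_depth` filter drops basins whose topographic
prominence — depth below the lowest saddle separating them from deeper
territory — is smaller than the threshold, which suppresses
sampling-noise wiggles. 2D minima are reported without barriers.

## Trajectory statistics

A frame is hydrogen-bonded when any labelled donor–acceptor pair has
donor–acceptor distance ≤ 3.2 Å **and** D–H···A within 30° of linearity.
The angle cutoff is read as deviation from linearity with the vertex at
the hydrogen (D–H···A ≥ 150°): the phrasing "angle cut-off of 30°" does
not define the vertex, and this is the convention that phrasing usually
means. Boundaries are inclusive, with a 10⁻⁹ numerical slack so a pair
constructed exactly at the cutoff is classified bonded regardless of
floating-point representation. Occupancies aggregate across replicas as
mean ± population standard deviation.

Clustering is the deterministic leader algorithm — the first frame seeds
cluster 1, each frame joins the first centroid within 2 Å superposed RMSD
or seeds a new cluster — chosen because the named analysis tool specifies
a cutoff, not an algorithm, and leader clustering is reproducible from
frame order alone. Selections under 3 atoms are rejected (degenerate
superposition). Centers of mass are geometric unless masses are supplied.

## Validation scale and what it shows

The shipped studies use 10⁶ Langevin steps (2 ns at the toy timestep) per
double-well run and 2×10⁵ Metropolis steps per helix–coil replica,
problem sizes chosen so the full suite re-runs in about a minute while
leaving clear margin to the oracle tolerances (basin ΔF within
0.3 kcal/mol of quadrature; reweighted F(f_H) within 0.5 k_BT RMS of
enumeration on every model of the 3×3 (Δe, J) grid, over bins visited
more than 100 times).

Passing these checks shows the machinery is correct: the CVs implement
their defining formulas, the sampler is Boltzmann-faithful under frozen
bias, deposition follows the well-tempered schedule, exchanges obey their
Metropolis rule, and the estimators recover exactly known free energies.
It does not show that any particular force field, membrane environment or
real protein behaves a given way: the toy systems have no solvent, no
side-chain chemistry and low-dimensional landscapes, and kcal/mol values
from the real substrate–protease system are outside what desk-scale
synthetic systems can reproduce.

## Known limitations

* 2D barrier heights are not computed (1D paths only).
* Multi-replica reweighting is per-replica; no WHAM/MBAR combination.
* The PDB subset ignores altlocs, insertion codes and models beyond the
  coordinates themselves; occupancy/B-factor are written as 1.00/0.00.
* The helix–coil Metropolis kernel flips one site at a time; models with
  strong coupling (J ≫ k_BT) would need cluster moves for efficiency.
* Overdamped dynamics carries no kinetic information; rates and
  transition-state analyses are out of scope.
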