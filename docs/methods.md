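# Methods

## The hydraulic-circuit model

An osteon's lacunocanalicular network is represented as an undirected
spatial multigraph. Each canaliculus *j* is a hydraulic resistor: fluid
moves in the annulus between the osteocyte cell process (radius
CP.Rd = 73 nm = 0.073 µm) and the canalicular wall (Ca.Rd = 157.5 nm),
giving a flow cross section A = π(Ca.Rd² − CP.Rd²) = 0.0612 µm². The
annulus is filled with a pericellular fiber matrix, so flow through it is
Darcy-like with an effective permeability k_p,eff = 1.53×10⁻¹⁷ m² (a
Brinkman-model literature value consumed here as a parameter). A linear
pressure drop along a canaliculus of arc length l_j then gives the
conductivity C_jj = (k_p,eff/µ)·A/l_j.

Node pressures follow from Kirchhoff's current law, Aᵀq = −f, with the
oriented edge–node incidence matrix A (entries −1 at an edge's tail, +1 at
its head; the orientation is an arbitrary but fixed sign reference) and
Darcy's law q = C·Δp along edges. Combining them yields L p = f with the
weighted graph Laplacian L = AᵀCA. The Haversian canal is treated as a
constant low-pressure reservoir: every canal-touching node is merged into
one supernode i₀ whose pressure defines the zero, and the reduced Laplacian
L₀ (row and column i₀ removed) is symmetric positive definite on every
component connected to the canal. L₀ is factorized with a sparse LU
(SuperLU); an optional reverse Cuthill–McKee reordering is provided as a
bandwidth optimization and is verified by test to leave the solution
unchanged. Components with no path to the canal are excluded from the
solve and reported with *undefined* (NaN) pressure — grounding them would
fabricate flow paths — while structural densities still count them
(densities are geometric, flow is topological).

Sign convention: conductivities are stored positive and flows computed as
q_j = C_jj (p_tail − p_head), so fluid runs from high to low pressure along
the stored orientation; flipping any edge's orientation negates its signed
flow and changes nothing else (tested). Single-edge Darcy behavior, not
sign mimicry, fixes correctness.

## Loading modes

**Fixed trans-osteonal pressure (intrinsic permeability).** All
cement-line nodes are fixed at Δp_osteon = 13 kPa and the canal at 0
(Dirichlet conditions); interior pressures solve the reduced system with
zero sources. An alternative formulation would impose the cement pressure
through edge pressure sources b with f = 0, but combined with zero sources
at the dead-end cement terminals that admits the trivial uniform solution
and carries no flow through them; the Dirichlet reading reproduces the
intended continuous pressure decay and is the one implemented. With no
interior sources the discrete maximum principle guarantees every pressure
in [0, Δp]. The intrinsic permeability is recovered as
k_osteon = v̄·µ·ΔR/Δp with the length-weighted mean **absolute** velocity
v̄ = Σ|v_j|·l_j/Σl_j (signed averaging would cancel antiparallel flows and
break the analytic spoke limit) and ΔR = On.Rd − HCa.Rd from the metadata.

**Strain-driven sources (squeezed sponge).** Homogeneous volumetric
compression at strain rate ε̇ reduces every pore volume, so each
non-reference node injects f_i = ε̇·(deg_i/2·A + V_i^lacuna), where deg_i
is the weighted node degree (summed incident canalicular length; each
canaliculus is shared between its two end nodes) and lacuna nodes add a
fixed V_lacuna = 350 µm³ (a per-lacuna override is accepted). The canal
absorbs the total ε̇·V_OLCN, where V_OLCN sums pore volumes over connected
non-reference nodes; the supernode's own half-canaliculi volumes are not
injected anywhere, consistent with the closed-form chain solution
v_k = ε̇·l·(k − 1/2). The solve uses unit sources scaled by ε̇ afterwards,
making the solution *exactly* linear in the strain rate in floating point;
this is why rescaling ε̇ by 0.1 maps the shear-exceedance curve by τ → τ/10
exactly. Default rates: 0.015 s⁻¹ (peak during vigorous exercise) and
0.0015 s⁻¹ (walking).

**Leaking cement line.** Optionally, a seeded random fraction of
cement-line nodes is connected to an external zero-pressure reservoir
through a virtual canaliculus of standard conductivity (evaluated at the
network's mean edge length — a modeling choice; the real anatomy of
cement-line-crossing canaliculi is not resolved). Canal flux plus leak
flux always balance ε̇·V_OLCN, and the mean pressure decreases
monotonically with the leaked fraction.

## Units and tolerances

All internal computation uses µm–Pa–s (velocities in µm/s, conductivities
in µm³/(Pa·s)); permeabilities are converted to m² (×10⁻¹²) only at the
reporting surface. Kirchhoff residuals at solved interior nodes are held
below 10⁻⁹ of the total absolute edge flow; sparse solutions agree with a
dense reference-elimination solver to 10⁻¹⁰ relative on random small
graphs. Degenerate inputs are rejected explicitly: non-positive lengths,
self-loops, arc length below the endpoint chord, missing canal tags, zero
drainable volume.

## Downstream analytics

* **Pressure profiles**: node pressures against normalized radial distance
  x = (r − HCa.Rd)/(On.Rd − HCa.Rd) (0 at the canal surface, 1 at the
  cement line; for non-circular geometries this generalizes to the ratio
  of surface distances), smoothed by LOWESS — tricube kernel, local linear
  fits, nearest 10% of points, no robustness iterations — on a uniform
  grid. Local linear smoothing is exact on linear fields, which anchors the
  spoke-osteon reference line.
* **Angular heterogeneity**: 36 sectors of 10° around the canal center
  (half-open angular intervals; ties go to the higher sector), per-sector
  mean node pressure, and the population relative standard deviation of
  the sector means. Empty sectors are excluded and counted.
* **Shear exceedance**: τ_j = µ·K·|v_j| per canaliculus; per osteon the
  fraction of canaliculi with τ strictly above each grid threshold
  (count-weighted by default, matching "percentage of canaliculi";
  length-weighted optionally), averaged across osteons with a t-based 99%
  confidence band. Curve crossings are located by bracketing a sign change
  of the interpolated difference and bisecting.
* **Velocity vs path length**: under fixed pressure, v̄ = a/SPL
  (no-intercept least squares on 1/SPL — longer paths, higher resistance);
  under strain sources, v̄ = a·SPL + b (ordinary least squares — longer
  paths drain more volume; sealed chains give exactly v̄ = ε̇·SPL).
* **Group comparisons**: two-tailed Wilcoxon rank-sum (Mann–Whitney U),
  exact null distribution when both groups have n ≤ 20 without ties,
  normal approximation otherwise; descriptives as mean ± SD; p < 0.05
  called significant.

Whether path-length averages should include lacuna nodes is ambiguous;
they are averaged over **all** nodes reachable from the canal. Whether the
per-half and cohort velocity means are length-weighted is likewise open;
length weighting (consistent with the k_osteon definition) is the default,
with a count-weighted option.

## The synthetic osteon generator

No imaged LCN data ship with the package, so cohort-level analyses run on
synthetic networks whose defaults emulate published per-osteon statistics:
osteon radius 104 µm, Haversian canal radius 36 µm (ordinary) / 22 µm
(nested), 40 µm slab, canalicular length density 0.081 / 0.072 µm µm⁻³ and
mean node degree 3.6. The algorithm: (1) sample nodes uniformly in the
annular slab; (2) wire each node to its best nearest neighbours under a
score that penalizes distance and deviation from the radial direction
(radial_bias 0.6, reflecting the predominant radial alignment of
canaliculi); (3) add "portal" terminals projected onto both cylinder
surfaces (canal-touching nodes tagged `haversian`, cement-line dead ends
tagged `cement`); (4) prune or top-up edges to the target mean degree;
(5) reconnect stray components through their closest admissible node
pairs; (6) set arc length = chord × tortuosity_factor (1.15). The node
count is re-estimated (≤ 4 attempts, using the l ∝ n^(2/3) scaling of
total wired length) until the achieved length density lands within the
contract (15%); generation fails loudly with achieved-vs-target numbers
otherwise. The osteon-in-osteon variant removes nodes and edges in a gap
annulus (normalized radius 0.4, width 8 µm) outside `n_bridges = 3`
corridors of 10° opening, and the reconnection step is corridor-aware, so
inner and outer networks communicate only through the bridges. About 0.3%
of nodes are flagged as lacunae — an order-of-magnitude assumption from
lacunar spacing in osteonal bone, configurable, since the reference
statistics merge lacunae into total node density.

A single seed governs all randomness; identical seeds give byte-identical
serialized networks, and the pipeline derives per-osteon child seeds from
one global seed by a fixed (CRC-based) derivation.

What the generator does **not** emulate: spline curvature of real
canaliculi, diameter variation, z-direction anisotropy, the tree-like
radial thickening of real networks, or measured lacuna density. The
emergent node density (~0.010 µm⁻³) and mean weighted degree (~17 µm) sit
below/above the reference values (0.015 µm⁻³, ~12 µm) because the wiring
rule produces somewhat longer canaliculi than real osteons at matched
length density. Consequently, passing cohort tests demonstrates that the
*model implementation* reproduces topology-driven effects (direction of
velocity reversals, path-length scaling, angular heterogeneity ordering) —
not that synthetic magnitudes match specimen-level measurements; per-osteon
permeabilities here (~4×10⁻¹⁸ m² ordinary, ~9×10⁻¹⁹ m² nested) are lower
than values inferred from imaged networks, in the way expected from the
extra tortuosity.

## Problem sizes

Default synthetic osteons carry ~11,000 nodes and ~21,000 canaliculi
(~1.2×10⁶ µm³ evaluated volume); a full generate-and-solve of both loading
modes takes under a second of CPU. The test suite exercises cohorts of
8 + 9 such osteons (mirroring the reference group sizes) and a 28,000-edge
network for the boundary-fidelity check; oracle-equivalence suites use
100 random graphs of ≤ 12 nodes against a dense reference solver.

## Known limitations

Steady-state snapshots only — no poroelastic time dependence, no
saturation-pressure cap (the architecture leaves room for a post-pass
limiting pressures), no fluid–structure interaction, no image ingestion.
Lacuna identification is taken as given input. The exceedance confidence
band treats osteons as independent replicates. The leak model's virtual
conductivity is a convention, not an anatomical measurement.
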