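# Methods

This note documents the models and procedures implemented in `fvstates`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Featurization

Backbone torsions follow the IUPAC convention: φ(i) is the torsion
C(i−1)–N(i)–Cα(i)–C(i), ψ(i) is N(i)–Cα(i)–C(i)–N(i+1), signed by the
right-hand rule, in (−π, π]. Torsions whose defining atom is absent
(chain termini, incomplete residues) are NaN and their feature columns are
dropped with a warning — imputation would fabricate dynamics. Features are
the (sin, cos) pairs of each torsion so that distances in feature space are
continuous across the ±180° seam; both φ and ψ are used by default, with a
flag to restrict to ψ only (the ψ torsions are the classic
loop-transition coordinates and the basis of the enhanced-sampling
collective variable). The per-loop CV is the unweighted sum
Σᵢ (sin ψᵢ + cos ψᵢ) by default; weights are configurable per loop. The CV
is purely diagnostic here — no bias potential is ever constructed.

CDR spans are fixed IMGT position windows (27–38, 56–65, 105–117 on both
chains) intersected with a user-supplied numbering map
(chain, author residue id, IMGT position). Numbering is an *input*: the
package deliberately contains no sequence-based annotator, so any scheme
can be supplied through the same two-column map.

## Ensemble clustering

Pairwise frame distances are RMSDs over an analysis selection after
Kabsch superposition over an alignment selection. Per-pair alignment is
direction-dependent in principle, so the matrix is symmetrized by
averaging (i, j) and (j, i); observed asymmetries are ~1e-8 Å.
Agglomeration is unweighted average linkage, cut where the minimum
inter-cluster linkage distance exceeds the cutoff; the scipy
implementation is used, and an exhaustive O(n³) oracle in the test suite
confirms partition-identical behaviour on random matrices. Cluster
representatives are medoids (the member frame with minimal mean distance
to its cluster), so representatives are always real frames usable as
restart or report structures. Defaults: 1.2 Å for whole-paratope
clustering over all six loops' backbone atoms aligned on the Fv backbone;
per-loop counts use 2.5 Å (heavy loops) and 1.5 Å (light loops), clustering
loop backbone N/Cα/C/O aligned on the loop's own chain — heavy-chain
loops are systematically more flexible, hence the looser cutoff.

## Kinetics

**tICA.** Covariances are estimated over all (t, t+τ) pairs,
symmetrized: C₀ = ½(X₀ᵀX₀ + XτᵀXτ)/N, Cτ = ½(X₀ᵀXτ + XτᵀX₀)/N after
removing the pair-mean. C₀ is whitened through its eigendecomposition
with a relative floor of 1e-10 × trace; directions below the floor are
null space (sin/cos features can be exactly linearly dependent) and are
dropped rather than inverted. The whitened Cτ is then diagonalized;
eigenvectors are C₀-orthonormal, so projected training coordinates have
unit variance, and signs are fixed by making the largest-magnitude loading
positive. A direct `scipy.linalg.eigh(Cτ, C₀)` solve serves as the test
oracle.

**Free-energy surfaces.** 2-D histograms over (tIC1, tIC2), default
100×100 bins spanning the data range padded by 5%;
F = −k_B T ln(p/p_max) in kcal/mol (k_B = 0.0019872041 kcal/mol/K,
default T = 300 K, matching the simulation temperature convention). The
minimum bin is exactly 0; empty bins carry +∞.

**Microstates.** k-means (k-means++ initialization, Lloyd iterations to
tol 1e-6, max 500) with a mandatory seed; default k = 150. scikit-learn's
`KMeans` backs this step.

**MSM.** Sliding-window transition counts at lag τ, restricted to the
largest strongly connected component (largest by contained counts, so a
transient absorbing prefix is pruned). The reversible maximum-likelihood
transition matrix comes from the standard self-consistent fixed point on
the symmetric count surrogate, xᵢⱼ ← (cᵢⱼ + cⱼᵢ)/(cᵢ/xᵢ + cⱼ/xⱼ), iterated
to relative tolerance 1e-10; π = xᵢ/Σx. Detailed balance holds to 1e-10 by
construction. Eigenvalues/eigenvectors are computed on the
π^½-symmetrized matrix so the spectrum is exactly real. Implied
timescales are t_i(τ) = −τ/ln λᵢ(τ); non-positive or degenerate-unit
eigenvalues yield NaN with a logged warning, never a fabricated finite
value.

**PCCA+.** The inner-simplex construction on the first n dominant right
eigenvectors: the most extreme rows are taken as simplex vertices, the
membership matrix χ is the barycentric-coordinate transform clipped to
[0, 1] and row-renormalized. Crisp states are argmax memberships; both
crisp (Σπ over members) and fuzzy (πᵀχ) macrostate populations are
reported, since either convention is defensible. Coarse macrostate
transition matrices are the π-weighted aggregation χᵀ diag(π) T χ,
row-normalized; mean first-passage times between crisp macrostates are
also available, as no single aggregation convention is canonical.

**Chapman–Kolmogorov.** For each factor k, [T(τ)]ᵏ aggregated onto the
crisp macrostates is compared with a fresh estimate at lag kτ. The
confidence band on the re-estimate is a circular block bootstrap over
transition pairs (50 blocks, 100 resamples, central 95%). Factors whose
lag exceeds the data or disconnects a macrostate are skipped with a
warning.

## Interface orientation

Each domain carries a consensus core: a list of IMGT positions with
reference Cα coordinates. The plane basis is the first two principal
components of the reference cloud, with deterministic signs (PC1 points
from the first toward the last core position). Fitting superposes the
consensus onto the structure's matched core Cαs (≥ 80% coverage required)
and transports anchor (consensus centroid) and plane vectors through the
fitted transform. The distance vector C runs from the H anchor to the L
anchor; HL is the signed angle from the projected H plane-vector-1 to the
projected L plane-vector-1 about Ĉ; tilts are angles between each plane
vector and Ĉ (H side) or −Ĉ (L side); d_c = |C|. All measures are
invariant to global rigid motion by construction (verified to 1e-6 under
randomized transforms).

A relabeling subtlety: a four-point torsion is invariant under reversal
of its point order, so exchanging the two domains *including* the axis
yields the identical HL. The anti-symmetry that does hold — and is the
one asserted in the tests — is in the vector order at fixed axis:
signed_angle(u, v, n) = −signed_angle(v, u, n).

The published antibody consensus reference set is data, not code: any
conforming bundle (TSV of IMGT positions + coordinates per domain) can be
loaded. Tests and the synthetic system use a toy two-domain reference
emitted by the generator, keeping the build download-free; the crystal
worked example runs only if the published bundle and PDB entries are
supplied locally. Matching the published HL values additionally requires
calibrating the torsion sign convention against that reference
implementation.

KDE on angle series uses a Gaussian kernel with Silverman's-rule
bandwidth, floored at 0.05° for (near-)zero-variance samples. Angles are
treated as linear quantities: observed HL ranges sit far from the ±180°
wrap; a circular treatment was considered and deferred as unnecessary for
these ranges.

## Sidechain orientation

Per residue, the backbone triad (N, Cα, C) of every frame is superposed
onto the trajectory-average triad; the average is refined by a few
align–average iterations because the naive average of unaligned triads is
contaminated by global motion. (Whether the original procedure referenced
the first frame or the average is not fixed by the description; the
average is used here.) The standardized frame has x along the mean
Cα→Cβ vector, the mean Cα→C vector in the xy-plane with positive y, and
z = x × y. The per-frame orientation is the unit Cα→COM(sidechain)
vector in this frame, with the COM mass-weighted over Cβ and beyond,
hydrogens included when present (`heavy_only` flag for structures
without hydrogens). Spherical coordinates use the physics convention:
θ ∈ [0°, 180°] from z, φ ∈ (−180°, 180°] from x, φ ≡ 0 at the poles.
Glycine has no Cβ and is rejected explicitly.

Orientation states come from spherical k-means (cosine distance,
k-means++-style seeding, renormalized-mean updates) with k chosen by the
cosine silhouette over k = 2..max_states — accepted only if it beats the
best silhouette that *isotropic random unit vectors* of the same sample
size achieve (plus 0.02). This null calibration matters: partitioning any
sphere into cones scores ≈ 0.45 silhouette with no structure present, so
a fixed small threshold would hallucinate states. States are ranked by
population; per-state mean directions and mean angular deviations are
reported.

## Interface contacts

Hydrogen bond: donor-heavy-atom–acceptor distance ≤ 3.5 Å AND
donor–H–acceptor angle ≥ 120°, over N/O/S atoms, hydrogens assigned to
donors by a 1.3 Å intra-residue distance. These numeric criteria are the
common MD convention (the choice is configurable). Topologies without
hydrogens degrade to a polar heavy-atom distance criterion at 3.5 Å with
a logged downgrade. Distance contacts use any heavy-atom pair ≤ 4.5 Å.
Occupancy is the boolean mean, transitions are sign changes of the
series, lifetimes come from run-length encoding. The conserved
interdomain core pairs (L38–H39, H45–L98, L44–H103, L43–H91) ship as a
default spec list; the positions are kept as printed in the source
literature, which does not name their numbering scheme — they are not
converted, and the spec list documents this ambiguity.

## Synthetic ground-truth system

The generator replaces the MD engine for all validation. Two independent
24-residue chains ("domains" H and L) are built from ideal backbone
internal coordinates by sequential NeRF placement (N–Cα 1.458 Å,
Cα–C 1.525 Å, C–N 1.329 Å; angles 111.2°/116.2°/121.7°; ω = 180°; ideal
Cβ stubs). Three 4-residue "CDR loops" per chain occupy IMGT windows
27–30, 56–59, 105–108. Loop φ/ψ switch among K = 3 macrostates under a
reversible Markov chain with π = (0.45, 0.30, 0.25) (detailed balance
from symmetric flows 0.004/0.002/0.003; slowest relaxation 43.7 frames),
with wrapped-Gaussian noise σ = 0.03 rad about per-state means chosen so
all state pairs are far apart in loop RMSD (≥ 3.8 Å between states,
≤ 1.1 Å within, against cutoffs of 1.5/2.5 Å).

Loops are grafted branches on a rigid framework: each loop's NeRF
continuation is seeded on the preceding framework residue and overwrites
the loop residues' atoms plus the next residue's N. Consequences, both
deliberate: (i) φ/ψ recomputed from coordinates equal the drawn angles
exactly (the torsion series can therefore be generated directly, without
coordinates, for large-n kinetics runs — the two paths are verified
identical), and (ii) the framework Cα core never moves, so the interface
reference fit is exact and per-state measures have zero spread. The cost
is a broken covalent junction after each loop — irrelevant to every
analysis here, which never evaluates bonded geometry across that seam.

Per state the generator additionally applies: a rigid rotation of the L
domain about the axis through the two core centroids (0°, 8°, −5°), which
shifts HL by exactly that angle while leaving tilts and d_c unchanged; a
rotation of a designated two-atom sidechain stub about a fixed axis
through its Cα (0°, 40°, 20°, plus 2° jitter), with the stub COM
perpendicular to the rotation axis so the great-circle arc between state
means equals the set angle; and an engineered cross-domain CB pair placed
at 3.0/6.0/3.0 Å, so the 4.5 Å contact criterion has occupancy
1 − π(state 1) = 0.70 in expectation.

What the generator does *not* emulate: sterics, packing, solvent, real
loop lengths and sequence diversity, correlated loop–interface coupling
beyond the state labels, force-field energetics, and measurement noise in
the interface core (the core is exactly rigid). Passing tests therefore
demonstrate the *algorithms* recover known answers under controlled
conditions, not that real MD ensembles are this clean; on real data the
interface measures carry core-fit noise and the MSM rests on the usual
discretization and sampling caveats.

## Problem sizes and defaults used in the shipped analyses

The MSM-recovery computation uses 2×10⁵ frames via the direct torsion
path, lag 5 frames, 150 microstates, 3 macrostates — at this length the
recovered populations sit within ±0.02 of π and the slowest implied
timescale within a few percent of the closed form. Ground-truth rotation
recoveries and contact occupancy use a 3000-frame coordinate trajectory;
loop cluster counts use 400 frames (the O(n²) distance matrix is the
limiting factor, and counts are already exact there). The pipeline
default lag is 10 ns converted through the frame spacing (0.1 ns/frame by
default); the printed-protocol values (150 microstates, 1.2/1.5/2.5 Å
cutoffs, 300 K) are the defaults throughout and are config-exposed.

## Known limitations

* PCCA+ uses the optimization-free inner-simplex variant; for strongly
  overlapping macrostates the refined optimization variant can assign
  memberships more sharply.
* The CK bootstrap resamples transition-pair blocks, which neglects
  long-range correlation beyond the block length (3000 pairs per block at
  default sizes).
* Hydrogen-bond detection requires explicit hydrogens for the angular
  criterion; the fallback is purely distance-based.
* KDE treats angles as linear; distributions hugging ±180° need the
  circular option.
* The altloc policy (highest occupancy, first-listed on ties) follows the
  PDB reader and is not re-derived.
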