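# fvstates

Paratope-state analysis of antibody Fv conformational ensembles.

Antibody binding sites are better described as ensembles of interconverting
*paratope states* — correlated conformations of the six CDR loops together
with a characteristic relative orientation of the V<sub>H</sub> and
V<sub>L</sub> domains — than as single static structures. `fvstates`
implements the post-simulation analysis stack used to extract those states
from molecular-dynamics ensembles of Fv/Fab fragments, and a synthetic
trajectory generator with exactly known ground truth to validate every
stage. It is written for structural bioinformaticians and antibody
engineers who have MD trajectories (or want a tested reference
implementation of the analysis chain).

## What it computes

* **CDR torsion featurization** — per-residue φ/ψ over IMGT-defined CDR
  loops (CDR1 27–38, CDR2 56–65, CDR3 105–117), expressed as
  (sin θ, cos θ) pairs to remove the ±180° periodicity seam; the
  per-loop collective variable Σᵢ (aᵢ sin ψᵢ + bᵢ cos ψᵢ) is available as a
  diagnostic.
* **Ensemble clustering** — unweighted average-linkage agglomeration on
  pairwise-superposed coordinate RMSD with a distance cutoff (1.2 Å for the
  whole paratope; 1.5 Å / 2.5 Å for individual light / heavy loops,
  aligned on the loop's own chain), medoid representatives.
* **Kinetics** — tICA at a lag time τ (generalized eigenproblem
  C_τ v = λ C₀ v, default τ = 10 ns), free-energy surfaces
  F = −k_B T ln(p/p_max) over (tIC1, tIC2), k-means microstates (default
  150), reversible maximum-likelihood Markov-state model, implied
  timescales tᵢ(τ) = −τ/ln|λᵢ(τ)|, PCCA+ macrostates, and a
  Chapman–Kolmogorov test with bootstrap confidence bands.
* **Interface orientation** — the six plane-based V_H–V_L measures
  (HL torsion, HC1/HC2/LC1/LC2 tilts, distance d_c) from consensus cores
  fitted to each frame, per-macrostate Gaussian-KDE distributions of HL,
  and d_c-variance statistics.
* **Sidechain orientation** — per-residue backbone-aligned internal frames
  (x along the mean Cα→Cβ vector, mean Cα→C in the xy-plane), the
  Cα→sidechain-center-of-mass unit vector as spherical (θ, φ), and
  orientation-state populations via spherical k-means with a
  null-calibrated silhouette criterion.
* **Interface contacts** — hydrogen-bond (d ≤ 3.5 Å, ∠D–H–A ≥ 120°) and
  heavy-atom distance (≤ 4.5 Å) criteria, occupancy, transition counts and
  lifetimes, with the conserved interdomain core pairs shipped as a
  default spec list.
* **Synthetic ground truth** — an Fv-like two-domain system whose loop
  dihedrals jump between K metastable macrostates under an exactly
  Markovian chain, with per-state interdomain rotations, sidechain-stub
  rotations and contact distances, so every analysis above has a
  recoverable known answer.

The fittable pieces are scikit-learn-style estimators (`TICA`,
`MarkovStateModel`, `PCCAPlus`, `RMSDAgglomerative`, `SphericalKMeans`)
with `fit`/`transform`, `get_params` and trailing-underscore attributes;
module-level functions wrap them for one-shot use.

## Worked example

```python
import numpy as np
from fvstates import (SyntheticSystem, generate_trajectory, backbone_dihedrals,
                      torsion_features, TICA, kmeans_microstates, estimate_msm,
                      pcca, interface_measures)

system = SyntheticSystem()                       # 3 states, pi = (0.45, 0.30, 0.25)
result = generate_trajectory(system, 20_000, seed=1)

feats = torsion_features(backbone_dihedrals(result.trajectory))
proj = TICA(lag=5, n_components=2).fit(feats).transform(feats)
_, dtraj = kmeans_microstates(proj, k=150, seed=1)
msm = estimate_msm(dtraj, lag=5)
p = pcca(msm, 3)

print("macrostate populations:", np.round(np.sort(p.populations_)[::-1], 3))
print("slowest timescale (frames):", np.round(msm.timescales(1)[0], 1))

df = interface_measures(result.trajectory, result.reference)
st = result.state_labels
print("HL shift state1-state0 (deg):",
      round(df["HL"][st == 1].mean() - df["HL"][st == 0].mean(), 2))
```

prints

```
macrostate populations: [0.423 0.33  0.247]
slowest timescale (frames): 46.1
HL shift state1-state0 (deg): 8.0
```

The recovered macrostate populations approach the generator's stationary
distribution (0.45, 0.30, 0.25) — at 2×10⁵ frames they agree within
±0.02 — the slowest implied timescale estimates the true chain's
relaxation time (43.7 frames in closed form), and the mean HL interface
angle between macrostates shifts by exactly the 8° interdomain rotation
the generator applied.

A `fvstates` command-line tool exposes the same stages
(`fvstates synth`, `fvstates run --config analysis.yaml`,
`fvstates features|cluster|interface|sidechain|contacts ...`); the
pipeline writes TSV tables plus a `manifest.json` with checksums so runs
are byte-comparable.

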