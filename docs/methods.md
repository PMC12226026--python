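# Methods

## Model

A protein–ligand complex is reduced to the heavy-atom point cloud of atom
centers, each point labeled by chemical element and affiliation (protein or
ligand). Persistent homology of the Vietoris–Rips filtration is computed under
the opposition distance: Euclidean across the bipartition, infinite within a
side. Under this metric the filtration is a growing subgraph of the complete
bipartite graph, so homology is concentrated in dimensions 0 and 1 and each
class carries a single finite scalar:

* 0D classes are born at radius 0 and die at the weight of the cross edge that
  merges their component (death radii = Kruskal merge weights);
* 1D classes are born at the weight of the cross edge that closes a cycle and
  never die (no 2-simplex has finite diameter to fill them).

`persistence` is a union-find sweep over the `p·q` cross edges sorted by
(weight, protein id, ligand id). The reduction from boundary-matrix
persistence to this sweep is a derivation, not an assumption: the repository
carries an independent oracle (`persistence_oracle`, a full GF(2)
boundary-matrix reduction over all simplices of dimension ≤ 2 built from an
extended-real distance matrix, capped at 14 points) and the suite asserts
multiset equality on hundreds of random clouds, plus the structural facts the
sweep relies on (all 0D births at 0; all 1D deaths infinite; the counting
identities `p+q−1` / `pq−(p+q−1)`).

Critical values of one (protein element, ligand element, dimension) channel
are smoothed into an internuclear persistence contour — a sum of unit-mass
Gaussians — and integrated over half-open bins. All bin masses use the
Gaussian CDF (erf) in closed form; there is no quadrature, so mass
conservation (grid sum + analytic tails = number of critical values) holds to
1e-9 and is asserted at that tolerance.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| Gaussian σ | 0.1 | Å | the method's stated smoothing width; comparable to coordinate uncertainty in good crystal structures |
| bin width | 0.5 | Å | the width of every selected fingerprint bin |
| grid | [0, 15), 30 bins | Å | covers every fingerprint bin (max edge 10.5 Å) and the truncation cutoff; the method does not state a grid origin/extent, so this is a repository choice, config-overridable |
| protein elements | C,N,O,S | — | heavy atoms of standard residues |
| ligand elements | C,N,O,S,P,F,Cl,Br,I | — | drug-like heavy atoms; the 4×9 product gives the 36 channels |
| truncation cutoff | 15 | Å | stated preprocessing cutoff for binder/decoy scoring; 4.5 Å of Gaussian head-room beyond the largest bin edge |
| trees / depth / learning rate | 13 / 3 / 0.1 | — | tree count is the method's stated ensemble size; depth and rate are repository defaults recorded as unverified in the config provenance |
| clash floor | 0.7 | Å | report-only flag for physically implausible contacts |
| temperature for Kd→ΔG | 298.15 | K | standard laboratory temperature; ΔG = RT ln Kd with R = 1.98720425e-3 kcal/(mol·K) |

Half-open bins `[lo, hi)` are used so that the grid partitions the line
without double counting; with σ = 0.1 Å the mass ambiguity of a value exactly
on an edge is split evenly between neighbors by the erf form, and tests assert
that symmetry.

## Truncation approximation

Dropping protein atoms whose minimum ligand distance exceeds the cutoff `r`
only perturbs critical values that are ≥ `r`: a far atom's own 0D death is its
nearest cross edge (> r), and any change it induces in the join/cycle
classification of later edges concerns edges processed after it, hence also of
weight > r. Every affected Gaussian therefore sits at least `r − bin_hi`
(= 4.5 Å = 45σ at defaults) past the farthest bin edge, so each component
moves by far less than any practical ε. The bound is validated empirically:
over 100 random complexes of 50–300 protein atoms the maximum component
deviation at the 15 Å cutoff is at machine-precision level (≪ 1e-6), and the
deviation is non-increasing in the cutoff.

## Attribution

Each critical value contributing bin mass `w` to a component is realized by a
cross edge; `w/2` goes to each endpoint atom, so per-feature shares sum to the
component exactly. When several edges tie at the critical weight, the identity
of the realizing edge is a processing-order artifact (matroid exchange), so
the mass is symmetrized over all channel edges of equal weight (1e-9
tolerance). For generic weights this reduces to the plain critical-edge rule;
on the degenerate square it gives the four atoms equal shares. An alternative
— spreading 1D mass over a representative cycle — is non-unique and is not
implemented.

## Models

Both models are least-squares gradient-boosted regression trees fitted by
scikit-learn; the fitted trees are immediately extracted into an explicit
JSON-serializable structure whose traversal is the prediction path
(`base + learning_rate · Σ tree(x)`), asserted equal to the sklearn predictor
and to a manual traversal oracle. The affinity model regresses ΔG (kcal/mol)
on the 10-component fingerprint; the binder/decoy scorer regresses {0,1}
labels on the flattened 72-vector stack of the 15 Å-truncated complex, with
no calibration layer — thresholding and ROC construction are the caller's
concern.

Feature selection is two-stage: rank by mean decrease in impurity and keep the
top K (default 77; skipped when fewer columns exist), then iteratively drop
the least-important column and refit on a seeded 90:10 train/validation split
until validation RMSE degrades by more than 1 % relative to the best seen.

Recovery experiments (planted-response fitting, threshold extraction, feature
selection) use learning rate 0.5: with 13 trees the residual of a unit step
shrinks geometrically as (1 − η)^13, which is 25 % at η = 0.1 — a 13-tree
ensemble at the default rate cannot fit a unit step to below 5 % RMSE, so the
demonstrations of *capacity* use a rate where it can. The default rate remains
0.1 for data fitting.

## Synthetic study conditions

The generators emulate the geometry the featurization consumes, not
chemistry. Random complexes place ligand atoms in a 10 Å central cube and
protein atoms uniformly in a 40 Å box with a 1 Å minimum separation (the
fixed lower bound on interatomic distances that the truncation argument
assumes), so ligand–protein distances span contact range to far beyond the
cutoff. The binder/decoy benchmark surrounds an 8-atom ligand cluster with a
60-atom protein shell at radii 4–10 Å (binders) or 12–20 Å (decoys), making
contact-scale IPC bins the separating signal. Training tables plant a
piecewise-constant response `Σ amp_j · 1[x_j > thr_j]` plus Gaussian noise on
uniform features.

What passing tests show: the topology, vectorization, truncation, attribution
and model plumbing are correct, deterministic, and invariant where they should
be, and the models recover planted structure. What they do not show: predictive
accuracy on real crystal structures — there are no bonds, conformers,
resolution artifacts, or experimental affinity labels here, and the
binder/decoy benchmark is separable by construction (AUC near 1 is a property
of the benchmark, not a claim about screening hard decoys). The permutation
null evaluates the trained model's scores against permuted labels; retraining
on permuted labels is not used, because with class-clustered features its AUC
null is strongly overdispersed.

## Numerical choices and degenerate inputs

* Cross edges sort by (weight, protein id, ligand id); tie order does not
  affect the critical-value multisets (asserted on the degenerate square).
* Coincident atoms are legal; weight-0 deaths are legal critical values.
* Empty channels (an element absent on one side) yield empty multisets and
  zero feature vectors, never errors; an entirely empty protein or ligand side
  yields a zero fingerprint with a warning so batch screening proceeds.
* Altloc records keep the highest-occupancy conformer, ties toward 'A';
  waters are always excluded; hydrogens are dropped at parse time.
* File-backed equality tests use 1e-3 Å (PDB coordinate precision); in-memory
  tests use 1e-9 Å.
* The one essential 0D class (and any additional ones when a side is empty)
  has no finite death and is discarded — only finite critical values feed
  IPCs.

## Problem sizes

The suite and the reproduction script run the persistence oracle on ≤ 6+6
point clouds (200 random draws), truncation soundness on 100 complexes of
50–300 protein / 10–40 ligand atoms, model recovery at n = 2000 training rows,
screening at 500 complexes, and selection at n = 1000 rows × 72 columns —
sizes chosen so the full pipeline, including every refit of the ablation loop,
completes in seconds while keeping the statistical checks well-powered.

## Known limitations

* The 36-channel element-set convention is config-overridable but the default
  is a published convention, not re-derived here.
* Tree depth and learning rate for the published ensembles are not stated in
  the main method description; defaults are flagged as unverified.
* A tree ensemble outputs a finite set of values, so predicted affinities are
  quantized (at most ∏ leaf counts distinct outputs).
* Attribution for 1D classes assigns mass to the cycle-closing edge (with tie
  symmetrization), one of several defensible conventions.
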