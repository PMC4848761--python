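# Methods

## Statistical model of class analysis

All cross-assay comparisons are made *within* a ligand scaffold (chemical
class), over the ligands with complete observations in both assays; n is
reported with every result and missing values are never imputed.
Association is measured by the Pearson product-moment correlation r and
reported as r² for comparability with the regression analyses.
Significance is the F-test for nonzero regression slope,

    F = (n − 2) · r² / (1 − r²),   df = (1, n − 2),

whose upper-tail probability is identical to the two-tailed t-test on the
OLS slope (t² = F); the suite verifies this identity to 1e-12 over 1000
random data sets and checks the implementation against
`scipy.stats.pearsonr`. Perfect collinearity (r² = 1) is reported as
p = 0. A correlation is "significantly positive" when r > 0 and p ≤ α
(α = 0.05 by default, inclusive, per-comparison with no multiple-testing
correction; Benjamini–Hochberg can be layered on by the caller).

A note on the parametric p-value's relation to the conditional
(permutation) null: at n = 10 the t/F approximation to the exact
permutation distribution of r can deviate by up to ≈ 0.02 in absolute
p-value for mid-range p. Parametric p-values at such small n should be
read with that resolution in mind; the acceptance script measures and
reports the discrepancy on fresh data each run.

### Cluster assignment

Each scaffold receives three significance flags for the canonical
cross-cell-type comparisons (breast GREB1 vs endometrial E-Luc, GREB1 vs
liver L-Luc, E-Luc vs L-Luc), and the cluster label is a deterministic
function of the count k of significantly *positive* flags: k = 3 →
cluster 1 (consistent canonical signaling), k ∈ {1, 2} → cluster 2
(partial cell specificity), k = 0 → cluster 3 (fully cell-specific).
Grouping k = 2 with cluster 2 keeps the cluster 1 and cluster 3
definitions exact while covering the undiscussed two-of-three case; the
rule depends only on the multiset of flags, not their order, and is
configurable.

### Domain-deletion tests

AF-1 dependence is tested per scaffold by Student's t on wild-type vs
AB-deletion reporter activities. The default is the *paired* test (each
ligand is measured in both constructs; df = n − 1); a pooled-variance
two-sample mode (df = n₁ + n₂ − 2) is provided because panel designs
differ. Degenerate inputs are defined rather than erroring: identical
constructs give t = 0, p = 1, "unchanged"; a constant nonzero difference
is exact separation (p = 0). Correlation gain (+) / loss (−) under
deletion compares the wild-type and mutant significance flags of the same
comparison.

## Assay quality control

Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| with sample (n−1) SDs on both control
sets; the n−1 convention matches the panel summaries (SD with n−1,
SEM = SD/√n). The robustness gate is strict (Z′ > 0.5). Z′ is invariant
under a common affine rescaling of both control sets and symmetric under
label swap — both are property-tested. Time-course peaks are the sampled
argmax (no smoothing, earliest time on ties), appropriate for the sparse
sampling grids of kinetic occupancy assays.

## Normalization

Raw signals are mapped to percent-of-reference efficacy with control
*means*: 100·(raw − μ_vehicle)/(μ_reference − μ_vehicle). Vehicle maps to
0, the reference agonist to 100, inverse agonism is negative and
superagonism exceeds 100. The transform is equivariant under common
affine changes of scale (instrument gain/offset). Controls are supplied
per assay; a zero control window is a hard error.

## Structural ensemble analysis

Coordinates are read with gemmi from PDB or mmCIF; waters are dropped,
ligand (hetero) components are kept separate from protein chains,
alternate locations resolve to the highest-occupancy conformer (first on
ties), and author residue numbering is used as-is (ERα canonical
numbering in deposited LBD entries; ≈ 305–550).

Superposition is the Kabsch least-squares rigid alignment: SVD of the
cross-covariance of centered CA coordinates with a determinant sign
correction, guaranteeing a proper rotation (det = +1 within 1e-10,
verified against an independent quaternion-eigenvalue oracle to 1e-8 on
random instances). The default fitting core is CA atoms of residues
310–520 — deliberately *excluding* the helix-11 C-terminus / helix-12
region whose conformational variance is the object of measurement — and
is configurable. Ligand atoms are carried along by the protein's
transform; rigidity (no intra-structure distance changes > 1e-9 Å) is
asserted in the suite.

Distance features default to Cα–Cα for residue pairs (side-chain atoms
configurable). Because LBD crystals typically contain two or more copies
in the asymmetric unit and the measured copy is rarely recorded, the
default chain policy averages over chains; `named_chain` supports exact
single-copy measurements. Class comparisons use the pooled-variance
two-tailed Student t with per-class mean ± SEM; two zero-variance classes
at different values are flagged as exact separation instead of dividing
by zero. Distance→activity coupling is a simple OLS regression with the
distance as predictor; a constant distance explains nothing (slope 0,
r² = 0, p = 1).

## Coregulator-peptide fingerprints

The modulation index is MI = log2(mean(compound)/mean(vehicle)) per
peptide, replicates averaged before the ratio (scale-invariant; requires
positive means on the fluorescence scale). Compounds (or peptides) are
clustered agglomeratively with correlation distance (1 − Pearson r) and
average linkage by default — the common conventions for peptide-array
fingerprints; metric and linkage are configurable. The agglomeration is
implemented directly (naive O(n³), adequate for arrays of a few hundred
peptides) so that merge order is fully deterministic with ties broken by
the lowest index pair; heights agree with `scipy.cluster.hierarchy` on
tie-free inputs and the merge order is verified against an exhaustive
enumeration oracle that recomputes cluster distances from the original
pairwise matrix at every step.

## Synthetic data: what it emulates, and what it does not

`simulate_activity_panel` draws a latent AF-2 efficacy a_i per ligand,
uniform on [−20, 100] % of reference (covering inverse agonists through
full agonists at a single screening dose), and produces cell-type
readouts y = a·g_c + b + ε with gain g_c = 1, cell-specific component
SD τ = 30, and assay noise SD σ = 10 (all in % of reference). Archetypes
map onto expected clusters: *amplified* couples all three cell types to
the shared latent (b = 0 → cluster 1); *two_shared* couples two cell
types to the shared latent plus a shared N(0, τ²) AF-1 component and
gives the third its own independent latent (→ cluster 2); *independent*
gives every cell type its own latent plus i.i.d. N(0, τ²) (→ cluster 3);
*null* is pure noise (→ cluster 3). Treating "independent" as
independent-per-cell (rather than attenuating a shared latent) is what
makes cluster 3 a recoverable ground truth: a latent shared across all
archetypes at these variances would put cross-cell correlations near the
n = 12 significance boundary and make the archetype undetectable even in
principle. An AB-deletion reporter column scales the liver latent by the
AF-1 gain 0.2 (activity nearly lost without AF-1 amplification, as for
scaffolds with very small intrinsic AF-2 activity). With 12 ligands per
scaffold these defaults put cluster recovery at ≈ 94% over 200
scaffolds — near but not at ceiling, so regressions in test sensitivity
remain detectable. Per-scaffold generator sub-streams are spawned from a
single seed sequence, so enlarging a simulation never perturbs earlier
scaffolds.

`simulate_structure_ensemble` builds ideal α-helices (rise 1.5 Å/residue,
radius 2.3 Å, 100° twist): a fixed core (residues 310–360) and a probe
helix (residues 520–530, the "h11 tip") displaced along a fixed unit
vector by δ = δ0 + β·a + N(0, σ_δ) with β = 0.02 Å per % activity,
σ_δ = 0.1 Å, per-atom jitter 0.05 Å, and a random rigid motion per
structure; a two-oxygen ligand with a 12 Å span rides along. The defaults
give a distance→activity r² ≈ 0.97, comfortably above the 0.8 recovery
bar, with the slope sign carrying the coupling direction.

`simulate_fingerprints` gives each compound class a +1.5 MI signature on
its own peptide block (others 0) plus N(0, 0.2²) noise — cleanly
separable, so dendrogram cuts recover the planted partition exactly.

None of the generators emulate plate effects, dose–response shape,
heteroscedastic noise, correlated assay error, crystallographic disorder
or real helix packing. Passing tests therefore demonstrate the
*correctness of the statistical machinery and its ground-truth recovery
under the stated noise model*, not performance on raw screening or
diffraction data.

## Problem sizes and numerical choices

The default verification sizes are 200 scaffolds × 12 ligands for cluster
recovery, 1000 random data sets for the F ≡ t² identity (agreement
1e-12), 20 cases × 10,000 draws for the permutation comparison, 100
random instances for the superposition oracle (1e-8), and 20 structures
for ensemble recovery — chosen so the entire suite and the acceptance
script each complete in seconds while keeping Monte-Carlo error well
below the quantities measured. Correlations clamp r to [−1, 1] against
rounding; panels reject infinities but allow NaN (missing); TSV output
uses `repr` floats and reading uses round-trip float parsing, so panel
write/read is bit-exact.

## Known limitations

* Reproducing the published screening-data numbers requires the original
  source tables and deposited coordinate files as inputs; the package
  ships only the machinery plus synthetic generators.
* Cross-scaffold matched-analog comparisons require a user-supplied
  ligand-pairing table; no substructure matching is attempted.
* No plate-layout deconvolution, B-scoring or edge-well handling; QC is
  control-based only.
* Helix assignment, electron-density handling and structure refinement
  are out of scope; inputs are final coordinates.
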