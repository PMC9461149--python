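# Methods

This note records the model implemented by `kerndom`, the numerical and
design choices that were genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Contact graph

Residues are nodes; the edge weight between residues i and j is the number
of unordered heavy-atom pairs (one atom from each residue) within the
contact cutoff, 4 Å **inclusive**. Hydrogens are excluded (they are absent
from most crystal structures anyway), as are waters, heteroatoms, and
lower-occupancy alternate conformers. Contacts within a residue are not
counted, and sequence neighbours receive no special treatment. The
production implementation uses a k-d tree over all atoms; an O(n²a²)
brute-force counter is kept in the test suite as the oracle. A chain whose
contact graph is disconnected is processed anyway but flagged with a
warning, since domain assignment across components is ill-posed — the
diffusion kernels remain well defined (block-diagonal).

## Kernels and bandwidth

All four kernels operate on the weighted Laplacian L = D − A:

- **LED** K = exp(−βL), computed by symmetric eigendecomposition, not
  series summation; the truncated Maclaurin series is used only as a test
  oracle, restricted to β‖L‖ small enough that truncation and floating-
  point cancellation stay below the comparison tolerance.
- **MD** K = Z(t)Z(t)ᵀ with Z(t) = (1/t)Σ_{τ=1..t}Pᵀ and P = D⁻¹A on
  weighted degrees. Isolated nodes are rejected (P undefined).
- **MED** K = exp(−βM), M = (D − A − n*I)/n*, with n* the *de facto*
  maximum weighted degree plus one. For a regular graph this reduces to a
  rescaled LED (asserted on a cycle graph in the tests).
- **RL** K = (I + αL)⁻¹ by Cholesky solve. The formal equivalence to a
  walk-counting series is documentation only; the implemented definition
  is the inverse.

The bandwidth is η·R_g², where R_g is the root-mean-square distance of all
retained heavy atoms to their unweighted centroid. η defaults are keyed by
(kernel, clusterer): LED 6e-3/4e-3, MD 0.25/0.8, MED 0.4/0.35, RL
2.1e-2/2.2e-2 (kernel k-means / spectral). For MD the continuous value is
rounded to the nearest integer with a floor of 1, since t is a discrete
diffusion time; the rounding rule is a package choice, as is leaving RL's
α unclamped. Kernel-induced distances D_ij = √(K_ii − 2K_ij + K_jj) are
clamped at zero against round-off before the square root; they are the
Euclidean metric of the kernel's feature space, verified in the tests by
equality with full-rank kernel-PCA embedding distances. Kernel PCA clamps
negative eigenvalues of the double-centered kernel to zero.

## Clustering

**Kernel k-means** computes point-to-centroid feature-space distances
implicitly (K_ii − 2·mean_{j∈C}K_ij + mean_{j,j'∈C}K_jj'), starting from a
random partition (each restart seeded as seed + restart index, every
cluster forced non-empty) and iterating to label convergence or 300
iterations. An emptied cluster is repaired by moving the point currently
farthest from its own centroid. The best of 100 restarts by within-cluster
sum of squares is kept; ties keep the earliest restart.

**Spectral clustering** treats the kernel as a similarity (negative
entries clamped to zero with a warning), builds the symmetric-normalized
Laplacian, embeds by the m smallest-eigenvalue eigenvectors with row
normalization (the Ng–Jordan–Weiss variant; the unnormalized variant is
available by flag), and clusters the embedding with standard k-means, 100
restarts. Which spectral normalization to use was an open choice; NJW is
the field default for similarity matrices with heterogeneous degrees.

## Post-processing and model selection

For each m the raw labelling is post-processed in this order:

1. **Helix re-unification**: every maximal run of DSSP class H (classes
   G/I are not included by default) of length ≤ MHS carrying more than one
   label is relabelled to the run's majority label; ties take the label of
   the run's first residue.
2. **Segmentation** into maximal constant-label runs.
3. **Short-segment removal**: repeatedly merge the shortest segment below
   MSS (ties by chain order) into a neighbour — both neighbours sharing a
   label absorb it outright; otherwise the nearer neighbour by mean
   pairwise kernel distance wins; a chain-terminal segment merges inward.
   Afterwards, merging of the currently shortest segment continues while
   t/m > SDR. If merging eliminates one of the m labels the candidate is
   rejected — the merge-order and neighbour rules reconstruct behaviour
   that is only loosely constrained by prior art, and rejection keeps m
   meaningful.
4. **Acceptance**: a domain is the union of all segments sharing a label
   (domains may be discontinuous); the candidate is accepted only if every
   domain has ≥ MDS residues. MDS applies to total domain size, not
   per-segment size.

The loop starts at m = 2 and stops at the first MDS rejection, label
collapse, or merge infeasibility, or at floor(n/MDS) (user bounds may
tighten this). A silhouette degeneracy — some cluster containing fewer
than two hydrophobic residues — only skips that m, since it says nothing
about feasibility at larger m.

The silhouette is computed on **post-processed** labels, over hydrophobic
residues only (Kyte–Doolittle > 2, strict), with a(i) and b(i) restricted
to hydrophobic residues, using the kernel-induced distances of the same
kernel used for clustering. The candidate maximizing it is selected; ties
prefer smaller m. With no accepted candidate the chain is re-declared
single-domain even when the classifier said multi.

## Classifier

The single/multi-domain classifier is a bagging ensemble of 190 unpruned
decision trees. Each bootstrap has the size of the training set and is
balanced by SMOTE (synthetic minority points interpolated uniformly toward
one of the 5 nearest minority neighbours) before its tree is fitted; every
rebalanced bootstrap is exactly class-balanced. Prediction is a majority
vote; an exact tie votes *multi*, because the clustering stage can still
fall back to single-domain, making over-calling multi the recoverable
error. The 50-feature set covers the families a structure classifier of
this kind uses — biological (n, R_g, mean/variance of hydrophobicity and
relative accessibility, plus cross-weighted variances), network-based
(total edge weight and its ratio to n; mean/variance/max/skew of degree,
closeness and betweenness in weighted and unweighted forms, weighted paths
using distance 1/weight; global and average-local clustering
coefficients), and clusterability (CA-PCA variances, explained-variance
ratios and pairwise ratios, accessibility-weighted PCA variances, Hopkins
and dip statistics) — but its exact membership is a documented, fully
retrainable reconstruction, not a fixed artifact.

Two clusterability statistics deserve notes:

- **Hopkins statistic**: computed in the chain's own principal-axis frame
  with an intrinsic sign convention (positive third moment per axis),
  which makes it rigid-motion invariant; pseudo-points are uniform in that
  frame's bounding box, the sample fraction is 0.25, and plain (unpowered)
  nearest-neighbour distances are summed. Calibration: spatially uniform
  point sets average ≈ 0.56, well inside the accepted null band, while
  two-blob chains score > 0.95.
- **Dip statistic** (of the first principal-axis projection): computed
  *exactly* as the minimum sup-norm distance between the ECDF and any
  unimodal CDF. For each candidate mode position — each gap between
  adjacent data values and each data value itself (where the fitted CDF
  may jump) — the best unimodal fit is a small linear program in the
  fitted CDF values at the data points (band constraints against the pre-
  and post-jump ECDF, monotonicity, convex slopes left of the mode,
  concave right). Hull-based decoupled lower bounds prune almost all mode
  positions before any LP is solved, so the exact computation costs
  milliseconds at chain scale. Closed forms used as frozen test oracles:
  an evenly spaced n-point sample has dip 1/(2n); two equal point masses
  have dip 1/4; three equal point masses 1/6.

## Synthetic data generator

The generator emulates exactly what the method consumes and nothing else:
residues with heavy-atom coordinates, amino-acid identity (hence
Kyte–Doolittle hydrophobicity), secondary-structure labels and relative
accessibility. Each planted domain is a blob of residues on a jittered
cubic grid with 3.8 Å spacing — the real CA–CA step along a protein
backbone — ordered serpentine so sequence neighbours stay spatially close;
a backbone-like carbonyl atom midway to the next residue guarantees the
sequence-neighbour contact a peptide bond would provide, plus 1–3 random
side atoms at 1.2–1.8 Å. Blobs are separated by a 25 Å empty gap (surface
to surface), far beyond the 4 Å contact cutoff, so the planted partition
is unambiguous; an optional linker walks residues across the gap, labelled
with the nearer blob so a perfect assignment can reach ARI = 1. Amino
acids are drawn so each blob has ≥ 30% hydrophobic residues, guaranteeing
the silhouette is computable; accessibility is uniform noise and secondary
structure is coil unless helix runs are requested.

What passing these tests shows: the kernels, clustering, post-processing
and model selection interact correctly end-to-end, and the silhouette
criterion finds the planted domain count when domains are genuinely
compact and well separated. What it does not show: performance on real
proteins, whose domains share interfaces, exchange contacts, and disagree
between expert references — no claim about benchmark accuracy on curated
databases follows from these tests.

Default study conditions used by the test suite and the acceptance
script: two to four blobs of 60 residues, 25 Å gaps, silhouette selection
over 20 generator seeds per domain count; classifier checks use 600/400
imbalanced separable Gaussian features and 90 fixture-derived chains.
These sizes were chosen once as representative small-protein scales.

## Evaluation

The overlap score builds the q×q overlap table and maximizes the matched
residue count over one-to-one domain matchings with a linear-assignment
solve (exhaustive permutation search is the test oracle); it is undefined
— signalled, not padded — when domain counts differ. The ARI is computed
from the contingency table in its chance-corrected closed form; the
pair-counting definition and an independent library implementation serve
as oracles in the tests. When comparing assignments whose residue
universes differ, both are restricted to the common residue set. Verdicts
follow the benchmark convention: *correct* if agreement with any reference
reaches the threshold (OL 0.85, or ARI 0.50 in ARI mode), *overcut*/
*undercut* if the predicted count exceeds/undershoots every reference,
*boundary inconsistency* if the count matches some reference but the
agreement is below threshold, *other* otherwise.

## Known limitations

- Single chains only; no multi-chain assemblies, no missing-loop
  modelling, no structure quality checks.
- The shipped classifier framework is trained on synthetic fixtures in the
  tests; real-data use requires training on a curated feature table via
  `kerndom train-classifier`.
- Heavy-atom (rather than all-atom) contacts and R_g are a documented,
  configurable choice.
- DSSP annotations are consumed from pre-made classic-format files; the
  package does not run a DSSP binary.
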