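# kerndom

Assignment of structural domains in protein chains using diffusion kernels
on residue contact graphs.

## The problem

The first step in analysing a solved protein structure is usually to split
the chain into *domains* — compact, semi-independent folding units. Domains
are geometrically entangled, so clustering residues by plain Euclidean
distance works poorly. `kerndom` instead measures residue affinity by
**diffusion on the residue contact graph**: heat (or a random walker)
released at one residue reaches residues of the same domain quickly and
residues of other domains slowly, because inter-domain interfaces are
sparsely connected. Clustering in the kernel's feature space then separates
domains that are non-convex in 3-D.

## The method

1. **Contact graph.** Each residue is a node; two residues are joined when
   any pair of their heavy atoms lies within 4 Å (inclusive); the edge
   weight is the number of such atomic contacts. L = D − A is the weighted
   graph Laplacian.
2. **Diffusion kernel.** One of four node kernels, with bandwidth tied to
   the chain's radius of gyration R_g via η·R_g²:
   - LED, Laplacian exponential diffusion: K = exp(−βL)
   - MD, Markov diffusion: K = Z(t)Z(t)ᵀ, Z(t) = (1/t)·Σ_{τ≤t} Pᵀ, P = D⁻¹A
   - MED, Markov exponential diffusion: K = exp(−βM), M = (D−A−n*I)/n*,
     n* = max weighted degree + 1 (a degree-rebalanced LED)
   - RL, regularized Laplacian: K = (I + αL)⁻¹
3. **Single/multi-domain classifier.** A bagging ensemble of 190 decision
   trees over per-chain features (size, R_g, hydrophobicity and
   accessibility statistics, centrality statistics, CA-coordinate PCA
   spectrum, Hopkins and dip clusterability statistics, clustering
   coefficients), each tree trained on a SMOTE-balanced bootstrap.
4. **Candidate clusterings.** For m = 2, 3, …: kernel k-means or spectral
   clustering (100 restarts each), then structure-aware post-processing —
   split alpha-helices of length ≤ MHS are re-unified, segments shorter
   than MSS are merged into their nearest neighbour segment by the mean
   kernel-induced distance D_ij = √(K_ii − 2K_ij + K_jj), and merging
   continues until the segment/domain ratio is at most SDR. A candidate
   whose smallest domain falls below MDS residues stops the loop.
   Defaults: MDS 27, MHS 30, MSS 27, SDR 1.5.
5. **Domain count selection.** Among accepted candidates, the silhouette
   index over hydrophobic residues (Kyte–Doolittle index > 2), measured in
   the kernel-induced metric, picks m; with no surviving candidate the
   chain is single-domain.

Predictions are scored against references by the domain **overlap score**
(fraction of residues agreeing under the optimal one-to-one domain
matching; defined when domain counts agree) and the **adjusted Rand
index**.

## Worked example

Generate a synthetic 180-residue chain with three planted domains and
assign it:

```bash
kerndom make-fixture --domains 3 --sizes 60,60,60 --gap 25 --seed 7 \
    --out demo.pdb --labels demo_labels.txt --dssp demo.dssp
kerndom assign --structure demo.pdb --chain A --dssp demo.dssp \
    --kernel led --clusterer kernel-kmeans --force-multi --seed 1 \
    --emit-candidates
```

The report (abridged) is:

```json
{
  "assignment": "1-60|61-120|121-180",
  "bandwidth": 5.560501083337588,
  "candidates": [
    {"m": 2, "accepted": true,  "silhouette": 0.6672085082789588},
    {"m": 3, "accepted": true,  "silhouette": 0.9999660612362986},
    {"m": 4, "accepted": true,  "silhouette": 0.8899507298709938},
    {"m": 5, "accepted": false, "reason": "short-segment removal collapsed below 5 labels"}
  ],
  "n_domains": 3,
  "radius_of_gyration": 30.442571845300204,
  "silhouette": 0.9999660612362986
}
```

The realized LED bandwidth is β = η·R_g² = 0.006 × 30.44² ≈ 5.56. The
candidate loop accepted partitions into 2–4 clusters and rejected m = 5
(post-processing collapsed a label); the hydrophobic-residue silhouette
peaks at m = 3 (0.99997 vs 0.667 and 0.890), so the chain is split into
three domains, `1-60|61-120|121-180` — exactly the planted structure.
Domains may comprise several segments, written e.g. `1-60,121-180|61-120`.

Scoring against a reference:

```bash
echo "1-60|61-120|121-180" > ref.txt
echo "1-60|61-120|121-180" > pred.txt
kerndom evaluate --pred pred.txt --ref ref.txt
# -> {"category": "correct", "ol": {"0": 1.0}, "ari": {"0": 1.0}, ...}
```

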