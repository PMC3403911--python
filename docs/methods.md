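# Methods

## The model

seqspace treats a multiple sequence alignment as a cloud of points in an
abstract "sequence space". The pipeline has four stages.

**Distances.** For sequences *x*, *y* in one alignment of *L* columns,
three scorings are offered:

- *difference*: d(x,y) = (number of columns where x and y differ) / L.
  The gap is a 21st symbol: gap-vs-residue is a difference, gap-vs-gap a
  match, and every column counts in the denominator. This is the simplest
  convention consistent with d(x,x) = 0; nothing in the dissimilarity
  literature fixes one, and a config flag is not offered because the choice
  only shifts distances involving gappy sequences by a common, monotone
  amount.
- *sqrt_difference*: the square root of the difference score. Distances of
  this form are Euclidean, so the embedding below reproduces them exactly
  and the spectrum has no negative eigenvalue — this scoring is the
  recommended default and the package's internal reference for spectrum
  sanity.
- *dissimilarity*: for protein alignments, a substitution-matrix scoring.
  Per column the pair score s(a,b) is turned into the quadratic-form
  residue distance δ(a,b) = s(a,a) + s(b,b) − 2·s(a,b) (non-negative for
  every shipped matrix, zero on the diagonal), and the sequence distance is
  √(mean of δ over scored columns). Columns where either sequence carries a
  gap or an ambiguity code (B, Z, X) are skipped for that pair, because
  substitution matrices have no reliable scores for them; if no column
  survives, the distance is defined as 0. The δ transform is the standard
  way to convert a similarity table into a near-Euclidean distance; it is a
  design choice of this package — published descriptions of this style of
  analysis do not pin down a formula — and the resulting spectra carry a
  few percent of negative variance, consistent with that style of scoring.

Eleven canonical matrices are embedded as plain-text package data
(BLOSUM30/45/62/80, PAM40/80/120/160/250, GONNET, JTT), restricted to the
20 standard amino acids; a unit test cross-checks every embedded table
against the independent copies distributed with biotite and biopython.
The membrane-specific JTT_TM and PHAT names are recognized but raise an
informative error: no canonical data source for them is redistributable
here, and shipping approximate values would be worse than declining.

**Embedding (metric MDS / principal coordinate analysis).** Given the
square distance matrix D over n active elements, with J = I − (1/n)𝟙𝟙ᵀ:

    S = −½ · J · D∘D · J,   S = V Λ Vᵀ,   F = V Λ₊^{1/2}

Factor scores F are coordinates on the components with positive
eigenvalue; the full signed spectrum is kept because the negative part
measures the departure of D from Euclidean geometry. Variance shares are
|λᵢ| / Σ|λⱼ|; the same absolute-value denominator defines the
negative-variance fraction. (Using Σλ₊ instead would shift the reported
percentages by their own amount — the absolute total is used everywhere and
reported as such.)

**Projection of supplementary elements.** A supplementary element enters
only through its squared distances d² to the n actives:

    s_sup = −½ · J · (d² − r),   f_sup = s_supᵀ F Λ₊^{-1}

where r is the vector of row means of D∘D. Algebraically s_sup equals the
vector of inner products between the supplementary point and the centered
actives, so projecting an active element's own distance column returns its
row of F exactly, and on Euclidean data the result coincides with embedding
all points jointly (verified against that oracle to 1e-6 over random
configurations). An element equidistant from every active projects exactly
to the origin when the actives are themselves equidistant from their
centroid (s_sup reduces to ½·J·r, which vanishes iff r is constant — true
for regular simplices and any centered-sphere configuration); for general
active sets the image is near, but not exactly at, the centre. Both facets
are tested.

**Clustering.** K-means on the factor scores, repeated `runs` times with
per-run seeds `seed + run_index`. Each fit uses k-means++ seeding with a
single start and at most 100 Lloyd iterations. k-means++ was chosen over
uniform-random starts deliberately: random partitions place every initial
center near the grand centroid, and from there Lloyd's iterations converge
to merged-cluster local optima in a measurable fraction of runs even on
cleanly separated data, which would surface as spurious instability in the
consensus. Run labelings are reconciled to the first run by
maximum-agreement matching (Hungarian assignment on the K×K contingency
table); the consensus is the modal matched labeling, ties broken by lowest
within-cluster sum of squares; each element's membership is the fraction of
runs agreeing with its consensus label. Silhouette-based selection of K
averages the mean silhouette width of each run's partition over the same
kind of repeated fits and takes the argmax (ties toward smaller K).
Clustering defaults to all retained components, but for K planted groups
the informative subspace has K−1 dimensions, and restricting to the leading
components (e.g. `components=3` for four families) is the configuration the
package's own validation uses — in the full ~n-dimensional score space the
trailing noise axes occasionally derail even k-means++.

## Synthetic data

`synthetic_families(n_families, seqs_per_family, n_col, mutation_rate, seed)`
emulates paralogous sub-families: each family descends from an independent
random ancestor drawn from background globular-protein amino-acid
frequencies, and each member mutates every column independently with
probability `mutation_rate` (default 0.1, giving within-family difference
scores near 0.19 and between-family scores near 0.95 — well-separated
families of recognizably similar sequences). What it does *not* emulate:
phylogenetic correlation within families (members are star-shaped around
the ancestor, not tree-structured), column-specific conservation,
indels/gap structure, or between-family homology. Tests passing on these
data therefore demonstrate the algebra and the robustness machinery, not
performance on the subtler structure of real families.

`random_alignment` is the null model for the noise floor: same shape and
pooled character composition as a template (gaps sampled like residues, so
the gap fraction is preserved), with all column structure destroyed.
Composition is pooled over the whole alignment rather than per column,
since a per-column null would preserve exactly the structure the null is
meant to destroy. Its MDS cloud is diffuse and roughly isotropic
(λ₁/λ₂ < 2), against which the anisotropy of family data is judged.

## Numerical choices

- Components are retained when λ > 1e-8 · λ_max: separates rank from
  floating-point noise; negative eigenvalues are reported but never used
  for coordinates.
- Eigenvector signs are fixed so each column's largest-magnitude entry is
  positive, making plots reproducible across eigensolvers.
- Tied eigenvalues (e.g. the equilateral triangle's λ₁ = λ₂) leave the
  within-block component order solver-dependent; tests on tied spectra
  compare distances or subspaces, never individual axes.
- Distance matrices are validated (symmetry, zero diagonal, finiteness) to
  an absolute tolerance of 1e-8 before embedding; callers always supply
  plain distances, squaring happens internally.
- PDB export rescales coordinates by 99 / max|coordinate| so they fill the
  fixed-width 8.3 field; the factor is recorded in a REMARK 250 line and
  round-trips to 1e-3 of a scaled unit. Spaces with fewer than three
  retained components are zero-padded.

## Problem sizes used in validation

The shipped tests and the acceptance script run on synthetic alignments of
50–100 sequences × 100–200 columns and on random Euclidean configurations
of up to 60 points — sizes at which every closed form is checkable and the
full suite completes in seconds. The algorithms are dense-matrix
O(n² L + n³) and comfortably handle the hundreds-of-sequences scale the
method is typically applied to.

## Known limitations

- Difference-score gap handling and the dissimilarity transform are
  declared conventions (see above); other tools make other choices, so
  absolute distance values are not comparable across tools, though
  embeddings are typically very similar.
- JTT_TM and PHAT matrices are name-registered but carry no data.
- MSF reading is lenient: checksums are not enforced.
- The consensus is the modal complete labeling; for very unstable
  clusterings (no repeated labeling) it degenerates to the lowest-inertia
  run, which is reported honestly through low memberships.
- Projection treats the active space as fixed: supplementary elements do
  not influence the embedding, which is the point of the method but also
  means a supplementary set far outside the active cloud is summarized
  only by its (possibly tiny) shadow on the active components.
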