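# seqspace

Metric multidimensional scaling (principal coordinate analysis) of multiple
sequence alignments, with out-of-sample projection of orthologous sequence
sets onto a reference space.

Tree-based phylogenetics imposes a hierarchy on homologous sequences.
Space-based analysis makes no such assumption: from the matrix of pairwise
distances between aligned sequences, metric MDS embeds every sequence as a
point in a low-dimensional "sequence space" whose geometry shows
sub-family structure directly. Crucially, MDS supports *supplementary*
(out-of-sample) elements: sequences positioned in an existing space purely
from their distances to the *active* sequences that define it, without
influencing it. That turns one species' protein family into a fixed
reference frame onto which another species' orthologs can be projected —
a direct way to visualize the evolutionary drift of sub-families. seqspace
provides the whole pipeline: alignment I/O, distance scoring, embedding,
projection, consensus clustering, and plot/PDB export, as a Python library
with a matching command-line tool.

## The core computation

For n aligned sequences with distance matrix **D** (difference scores,
their square roots, or substitution-matrix dissimilarities — BLOSUM, PAM,
GONNET and JTT tables ship with the package):

```
S = -1/2 · J (D∘D) J        J = I - (1/n) 11ᵀ      (double centering)
S = V Λ Vᵀ                                          (eigen-decomposition)
F = V Λ₊^{1/2}                                      (factor scores)
```

Rows of **F** are the sequence coordinates on the principal components;
negative eigenvalues in Λ measure how non-Euclidean **D** is (zero for
square-root difference scores, a few percent of the variance for the other
scorings). A supplementary element with squared distances **d²** to the
actives gets coordinates

```
f_sup = [-1/2 · J (d² - r)]ᵀ F Λ₊⁻¹          r = row means of D∘D
```

which reproduces each active's own coordinates exactly and agrees with a
joint embedding of all points on Euclidean data. K-means consensus
clustering (repeated runs, Hungarian label matching, per-element membership
frequencies) and silhouette-based selection of K operate on **F**. See
`docs/methods.md` for conventions, assumptions and limitations.

## Worked example

```python
import seqspace as ss

# four synthetic protein families of 25 sequences, 100 columns
aln, families = ss.synthetic_families(
    n_families=4, seqs_per_family=25, n_col=100, mutation_rate=0.1, seed=11
)
dist = ss.distance_matrix(aln, scoring="sqrt_difference")
space = ss.mmds(dist)
print(ss.variance_summary(space).head(4).to_string(index=False))

result = ss.kmeans_run(space, K=4, runs=100, components=3, seed=2)
print("min membership:", min(result.membership.values()))
print("optimal K:", ss.sil_score(space, range(2, 9), runs=100,
                                 components=3, seed=2).optimal_K)
```

```
component  eigenvalue  pct_variance  cumulative_pct
      PC1   10.379178     27.751294       27.751294
      PC2    9.454832     25.279825       53.031119
      PC3    9.002355     24.070016       77.101135
      PC4    0.196770      0.526113       77.627248
min membership: 1.0
optimal K: 4
```

Three components carry 77% of the variance — four well-separated families
span a 3-dimensional simplex — and consensus K-means recovers them in all
100 runs (every membership 1.0), with the silhouette profile picking K=4.

Projecting a supplementary set that has *no* counterpart among the actives
sends it to the centre of the space, because its specific divergence lies
on dimensions perpendicular to the active components:

```python
orthologs, _ = ss.synthetic_families(4, 5, 100, 0.25, seed=99)
cross = ss.cross_distance_matrix(aln, orthologs, "sqrt_difference")
proj = ss.project(space, cross)
```

```
mean distance from origin (PC1-3): active 0.537, supplementary 0.029
```

The same workflow from the shell, split across invocations via the JSON
space file:

```
seqspace distance --in active.fasta --scoring sqrt_difference --out dist.csv
seqspace mds      --in dist.csv --out space.json --variance-out variance.csv
seqspace project  --space space.json --active active.fasta --sup orthologs.fasta \
                  --scoring sqrt_difference --out projected.csv
seqspace cluster  --space space.json --k 4 --runs 100 --seed 2 --out clusters.csv
seqspace plot2d   --space space.json --proj projected.csv --groups groups.csv \
                  --out space.png
seqspace pdb      --space space.json --out space.pdb
```

Plots draw actives as dots and supplementary elements as crosses, colored
by a user CSV of `id,group,color` rows (unannotated elements in black);
`pdb` exports PC1–PC3 as CA pseudo-atoms, one chain per group, for
molecular-graphics viewers.

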