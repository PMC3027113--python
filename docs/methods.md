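# Methods

## Contact network construction

A chain parsed from a PDB file becomes an undirected simple graph: one
vertex per standard residue, an edge whenever the Euclidean distance between
two residues' side-chain centroids is at most the cutoff (default 6.5 Å,
inclusive at the boundary). The centroid is the unweighted mean of the
side-chain heavy atoms, defined as all non-hydrogen atoms except the
backbone N/CA/C/O/OXT; glycine uses its Cα. These conventions resolve
ambiguities a structure file can present:

- alternate conformations: the highest-occupancy altloc is kept (ties go to
  the first listed), which is the Biopython parser's selection rule;
- selenomethionine (MSE) is read as methionine; other non-standard residues
  are skipped with a warning, as are waters and ligands;
- a disordered residue with no side-chain atoms falls back to its Cα rather
  than being dropped, so network indices stay aligned with sequence
  positions; a residue with no atoms at all is dropped;
- multi-model files use the first model unless another index is requested.

Variant positions are interpreted by default as the 1-based ordinal within
the parsed chain; author residue numbering (with insertion codes) is
available as an option since both conventions occur in practice. A record
whose stated wild-type residue disagrees with the structure is rejected and
logged, never silently accepted.

## Topology measures

Degree, clustering coefficient, closeness and betweenness are implemented
directly (BFS and Brandes-style accumulation) and validated in the test
suite against brute-force oracles (adjacency counting, triangle
enumeration, Floyd–Warshall, shortest-path counting) and against networkx.
Numerical conventions, each of which had to be fixed somewhere:

- clustering of a vertex with degree ≤ 1 is 0 (the formula is 0/0 there);
- closeness is computed within the vertex's connected component, with the
  component size in the numerator; isolated vertices score 0. Contact maps
  of chains with breaks can be disconnected, so the convention matters;
- betweenness sums over unordered pairs {j, k}, both distinct from the
  focal vertex; pairs in different components contribute nothing. The
  reported feature is B(i)/N with N the parsed chain length — the same N
  that appears in the closeness formula, keeping the two self-consistent;
- the distance comparison is inclusive (d ≤ cutoff adds the edge).

## Conservation features

Profiles are read from the iterated-search ASCII PSSM dialect (position,
residue, 20 log-odds scores, 20 weighted observed percentages per row); a
plain TSV fallback with the same 42 columns is accepted for synthetic
profiles. Frequencies are the percentages divided by 100 and renormalized
to sum to one (the ASCII output is rounded, so raw sums drift from 100);
an all-zero row — which real profile output can produce at positions with
no aligned sequences — is flagged and assigned entropy 0. Entropy is
Shannon entropy base 2 with 0·log₂0 := 0, so it lives in [0, log₂20 ≈ 4.32]
bits. No pseudo-counts are added: the observed-percentage column is used as
printed. Score and frequency differences are oriented mutant − wild.

## Environment encoding

The neighbours of a site are its direct contacts. They are ranked by
ascending entropy (most conserved first), ties broken by ascending sequence
index for determinism, and the top five each contribute the block
[degree, clustering, closeness, scaled betweenness, entropy]; sites with
fewer than five contacts are zero-padded to keep the block at 25 entries.
The environment, like all structural features, is computed on the wild-type
structure only — the mutant residue never enters the structural blocks.

## Feature schema

The full vector has 42 named entries: 7 conservation + 4 topology + 25
environment + PAM250 + accessible area + 3 aggregation + HLA flag. The
order is fixed and identical across runs, and prediction checks the schema
by name. The PAM250 table ships with the package as a plain-text asset
(the canonical Dayhoff log-odds rendering) and is cross-checked in the
tests against Biopython's copy. Accessible areas are taken from a supplied
per-residue table when available (the intended source is a DSSP run
exported to TSV); otherwise they are computed with the Shrake–Rupley
rolling-probe algorithm (probe 1.4 Å) on the wild-type structure.
Aggregation propensities are consumed from a table, never computed — the
reference tool is closed-source — and default to 0 with a warning when
missing. The HLA-family flag is configuration (a protein-id list), not
code, since family membership is an annotation question. A smaller
"top-k" feature set is obtained operationally by ranking permutation
importances, not from a hard-coded list.

## Classification protocol

The forest is tuned over ntree ∈ {100…500} and mtry ∈ {1…8} by default,
scored by the Matthews correlation coefficient of pooled out-of-fold
predictions under stratified 5-fold cross-validation with a fixed seed.
MCC is preferred to accuracy as the selection criterion because the class
balance is uneven; ties go to fewer trees, then smaller mtry, making the
selection deterministic. Folds stratify by class at the record level;
an optional grouping argument keeps all records of one protein in the same
fold to measure protein-level leakage. Reported metrics (sensitivity,
specificity, accuracy, MCC) come from the pooled out-of-fold confusion
matrix; per-fold values are also returned. MCC is defined as 0 whenever a
denominator factor vanishes.

Permutation importance follows the out-of-bag semantics of the classic R
randomForest implementation: for each tree, the accuracy on its out-of-bag
samples is compared with the accuracy after shuffling one feature column;
drops are averaged over trees, and the whole estimation is repeated
(default 100 times) with fresh permutations and averaged. Correlated
features share importance under this scheme — a known property, visible in
the synthetic studies where environment-closeness features trail the site's
own closeness.

## Synthetic data

The generator stands in for a curated variant compilation with mapped
structures, which requires external resources. It emulates the statistical
structure the method assumes, not protein physics:

- structures are self-avoiding biased random walks (Cα step 3.8 Å, clash
  distance 4 Å) compacted toward the origin by a packing-density parameter
  that tunes mean contact degree; side-chain pseudo-atoms are placed
  symmetrically around an intended centroid so parsed centroids equal the
  generator's records to within coordinate precision, and glycines are
  always present to exercise the Cα rule;
- profiles are per-position Dirichlet draws whose concentration on the
  wild-type residue grows with a conservation parameter and, optionally,
  with the position's closeness — encoding the empirical observation that
  topologically central residues tend to be conserved (default coupling 1);
- disease labels are Bernoulli draws from a logistic model on the site's
  standardized closeness, entropy and degree. Defaults: effect sizes
  (+2.5, −2.5, 0) per standard deviation — a strong, recoverable signal —
  and a disease fraction of 0.61, matching the composition of the curated
  datasets this field trains on (roughly 3950 disease vs 2570 polymorphic
  records). The intercept is solved by bisection so the expected disease
  fraction hits the target; the coefficients and standardization constants
  are saved as ground truth.

The default study uses 20 proteins of 60–120 residues and 2000 variants —
large enough for stable cross-validation estimates while a full pipeline
run (generation, featurization, grid search, importance) completes in about
a minute. What passing tests on this generator do *not* show: robustness to
real fold statistics (secondary structure, domain architecture), to profile
search artifacts, or to the label noise of curated variant databases. The
generator shares the pipeline's own feature definitions, so recovery tests
demonstrate internal consistency and statistical power, not external
validity.

## Known limitations

- Edges are unweighted and untyped; hydrogen bonds, hydrophobic and
  electrostatic contacts are not distinguished.
- Mutant structures are never modelled; all structural features are
  wild-type.
- The OOB permutation importance relies on scikit-learn's internal
  bootstrap bookkeeping; the pinned private helpers are verified at import.
- Accessibility of the mutant residue is not estimated; the wild-type area
  is used alone.
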