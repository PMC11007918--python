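# Methods

## The annotation-transfer model

`koassign` treats KEGG Orthology annotation as a two-stage decision over a
fixed-dimension embedding space:

1. **KO gating.** A sequence embedding `x ∈ Rⁿ` is scored by a binary
   classifier `p(KO | x) ∈ [0, 1]`; the sequence proceeds only if the score
   strictly exceeds the decision threshold (default 0.5).
2. **Nearest-neighbour transfer.** The gated embedding is compared to every
   embedding in an annotated reference set by Euclidean distance
   `d(x, y) = sqrt(Σᵢ (xᵢ − yᵢ)²)`. The K number(s) of the closest
   reference are transferred. All references tying for the minimum (within
   `tie_tol`, default 0 = exact equality) are reported, and the query
   receives the union of their K numbers.

The underlying assumption is that a good protein embedding places
functionally equivalent proteins close together even at low sequence
identity. The package does not test that assumption against real data; it
supplies the machinery plus synthetic conditions under which the
assumption holds by construction (see below).

An optional distance threshold turns the assigner itself into a gate:
queries whose nearest reference exceeds the threshold are returned as
"no assignment" and treated as non-KO. No default threshold is provided —
the production configuration deliberately avoids this extra
hyperparameter, so the CLI requires an explicit value when the variant is
used.

## Embedders

The embedder is a contract: deterministic, fixed output dimension, pooling
over per-residue representations (`mean` default, `max`, `first`).

* **Mock embedder** (`mock`, default; used by every test): each
  overlapping k-mer (default k = 3) is hashed with BLAKE2b — keyed by the
  seed, so platform-independent — to seed a PRNG that emits a fixed unit
  direction in Rⁿ (default n = 64). A residue's vector is the sum of the
  directions of the k-mers covering it; the sequence embedding pools those
  per-residue vectors. Shared subsequences therefore contribute identical
  directions, giving mutation-derived families nearby embeddings — the
  geometric premise the assigner needs — at zero model cost.
* **Protein-language-model adapter** (`plm`): mean-pools the final hidden
  states of a pre-trained ProtT5-style encoder behind the same contract.
  It requires `torch` and `transformers`, is imported lazily, and is not
  exercised in CI. The pooling operator and embedding dimension are
  configuration, not constants.

## Classifier

The production gate is an MLP over embeddings: two fully connected layers
(hidden size 100, ReLU) and a logistic output. Two token-level baselines
are included for architecture comparison: integer-encoded sequences
(A=1 … Y=20 alphabetically, zero-padded to 600) pass through a learned
128-dimensional token embedding, a 1-D convolution (64 filters, kernel 3),
and max pooling, feeding either an LSTM layer (100 units) or a single
additive attention layer, then a logistic output.

Training: binary cross-entropy, Adam (default learning rate 1e-3, batch
size 32), a seeded 20% validation split, early stopping on validation loss
with patience 5 (both configurable), and restoration of the
best-on-validation parameter snapshot. All parameters are float64 and all
randomness flows from one seed, so training is bit-reproducible.

The networks are implemented on a compact reverse-mode automatic
differentiation engine written for this package (`koassign._autodiff`):
~15 numpy operators (matmul, gather, slice, max-reduction, element-wise
nonlinearities, softmax) with exact gradients, verified against central
finite differences in the test suite. The engine is deliberately minimal —
no GPU, no graph optimization — because the supported problem sizes are
desk-scale.

Numerical and design choices worth knowing:

* **Amino-acid integer mapping** is alphabetical over the one-letter
  codes; any fixed bijection works, this one is reproducible by
  inspection.
* **Max pooling between convolution and recurrent/attention layer** is
  local (window 5, stride 5), matching the lineage of these baseline
  architectures and keeping a genuine sequence for the recurrent layer.
* **Decision threshold is strict** (`score > threshold`); a score exactly
  at the threshold is non-KO.
* **Metric conventions** (classifier precision*/recall*/F1*, starred to
  distinguish them from pipeline metrics): a zero denominator yields NaN
  (and NaN F1*); precision* = recall* = 0 yields F1* = 0.

## Dataset construction

* Length window [100, 600] residues, inclusive at both ends (strictly
  shorter/longer sequences are removed).
* Sequences containing any letter outside the 20 standard one-letter codes
  are removed.
* Duplicate sequences collapse to one record carrying the id of the first
  occurrence and the union of all K numbers seen; an annotated duplicate
  therefore always beats an unannotated one. For two *different* K numbers
  the union is kept — lossless and deterministic — and the evaluation
  treats truth as a set (a prediction matches if it intersects).
* **Length balancing** compares the KO and non-KO length histograms over
  50-residue bins; the deviation statistic is the maximum per-bin absolute
  difference of within-class proportions, and the check passes strictly
  below the tolerance (default 5%). Balancing is by seeded uniform
  down-sampling of the over-represented class in the worst bin, solving
  `n_bin − k = p_other · (M − k)` per step; layouts that would require
  emptying a class's bin raise an error naming the bin rather than
  silently discarding a length range.
* The train/test split is a seeded uniform shuffle cut at
  `floor(0.8·N)`, unstratified.
* Held-out-species exclusion drops records whose id starts with a given
  organism prefix (`bjp:` …) and any record with an identical sequence.

## Evaluation

Per sequence: *match* (truth and prediction intersect), *unmatch*
(disjoint), *missed* (truth annotated, no prediction), *added* (prediction
without truth annotation), *true negative* (neither; tallied separately
and excluded from all metric denominators). Pipeline metrics:

```
precision = match / (match + unmatch + added)
recall    = match / (match + unmatch + missed)
F1        = 2 / (recall⁻¹ + precision⁻¹)
```

Metrics are computed at full precision and display-rounded to three
decimals. Zero match with positive denominators yields zeros; a zero
denominator yields NaN. Multi-K predictions from tied assignments count
once per sequence.

## Structural validation (TM-score)

Given a target CA trace (length `L_target`), a template trace, and a fixed
residue correspondence (`L_common` pairs), the template is superposed onto
the target by least squares (Kabsch, proper rotation, det = +1) and scored

```
TM = (1 / L_target) · Σᵢ 1 / (1 + (dᵢ / d0)²),
d0(L) = 1.24 · ∛(L − 15) − 1.8 Å, floored at 0.5 Å.
```

The formal definition maximizes over superpositions; this package
approximates the maximum by iterative outlier rejection: pairs with
`dᵢ > 2·d0` are dropped from the superposition (never from the score sum),
the fit repeats up to 5 rounds or convergence, and the best score seen is
returned. The result is therefore a lower bound on what a full structural
aligner search would report. With fewer than 3 corresponding pairs no
superposition is possible and coordinates are scored as given. The d0
floor (the printed formula is non-positive below ~L = 27) follows common
practice and keeps the score finite for all lengths. Reported scores are
flagged "similar structural domains" at ≥ 0.5 and "highly similar" at
≥ 0.8.

Residue correspondences are **inputs**: producing them (circular-
permutation-aware structural alignment, structure prediction) is outside
this package's scope.

## Sequence validation (Smith–Waterman)

Local alignment with affine gaps (Gotoh), BLOSUM62, gap open 10 / extend
0.5 (first gap residue costs the open penalty, each further residue the
extension). Traceback tie-breaks are deterministic: diagonal, then up,
then left, starting from the first maximum cell in row-major order.
Percent identity is 100 × identical columns / alignment columns, gap
columns included in the denominator by default (`aligned_columns` and
`min_length` denominators are available — published identity figures
rarely state their convention, so it is explicit and configurable here).
With no positive-scoring path the alignment is empty and identity is 0.
The implementation is cross-checked against Biopython's `PairwiseAligner`
scores in the test suite.

## Synthetic fixtures and what passing tests mean

* **Sequence families**: per family, a uniform-random ancestor (lengths
  uniform in 100–600) and members derived by 5% per-site point
  substitution (no indels), all sharing one K number; non-KO sequences are
  i.i.d. uniform over the 20 letters. Undefined-letter and exact-duplicate
  injection exercise the dataset filters with predictable counts.
* **Embedding clusters**: one isotropic Gaussian cluster per family
  (σ = 0.5) around centroids placed at mutual distance ≥ 10 (separation /
  σ = 20); non-KO queries sit on a shell ≥ 3 separations from every
  centroid. Under these conditions nearest-neighbour label recovery is
  exact with overwhelming probability, and the test suite asserts
  accuracy 1.0 and end-to-end precision = recall = F1 = 1.
* **Toy structures**: 3.8 Å-bond random walks; templates are rigid motions
  plus optional Gaussian jitter, with identity correspondence.

These fixtures verify the *machinery* — filters, search, bookkeeping,
formulas — under conditions where the correct answer is known by
construction. They do not demonstrate that real protein-language-model
embeddings separate KO from non-KO sequences or cluster orthologs; that
property belongs to the embedding model, not to this package. Classifier
tests run at n = 400 embeddings (dimension 64) and the assigner oracle
checks at 200 queries × 100 references; these sizes make the full suite
run in seconds while leaving the asserted properties size-independent.

## Known limitations

* The nearest-neighbour search is exact and exhaustive (O(queries ×
  references)); an approximate backend would need to pass the oracle-
  equality tests before substitution.
* The LSTM/attention baselines are comparison-only; the MLP-over-
  embeddings path is the supported production configuration.
* Sequences longer than 600 residues are out of the supported window, in
  line with the training-corpus construction rules.
* The TM-score is a lower bound (fixed correspondence, least-squares
  superposition with outlier rejection), not a full alignment search.
* PDB input is read as first model, first chain, CA atoms, altloc
  blank/"A" only; mmCIF and multi-chain handling are out of scope.
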