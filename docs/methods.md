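# Methods

## Problem and model

A pre-miRNA candidate is a 70–150 nt RNA whose secondary structure,
composition and folding thermodynamics jointly distinguish genuine
precursors from hairpin-like background ("pseudo hairpins"). The package
represents each candidate as a 65-dimensional feature vector, selects
discriminative features by F-score, and classifies with an ensemble of RBF
support-vector machines designed for the strong class imbalance of
realistic corpora.

## Folding engine

The engine uses an additive pair-energy model: the energy of a nested
structure is the sum of its pair energies (defaults GC −3, AU −2, GU −1
kcal/mol; minimum hairpin loop 3 nt; T = 310.15 K). There are no stacking
or loop terms. This is a deliberate design choice, not an approximation
error: every downstream feature consumes only the MFE, the ensemble free
energy, and structure topology, so a self-contained model makes every
number in the package reproducible from the code alone, while the
`FoldingEngine` protocol allows substituting a full thermodynamic folder —
all features are then defined relative to whichever engine produced the
`FoldResult`.

* **MFE**: Nussinov-style O(L³) dynamic program
  `W(i,j) = min(W(i+1,j), min_k e(i,k) + W(i+1,k−1) + W(k+1,j))`.
  The traceback is deterministic: pairing i is preferred over leaving it
  unpaired, and among co-optimal partners the smallest j wins.
* **Partition function**: the same decomposition summed with Boltzmann
  weights, entirely in log space (a 55-pair GC stem has a Boltzmann factor
  near e³⁶⁵, far beyond double range). Base-pair probabilities come from an
  outside pass over interval contexts; the three context propagations are
  (i unpaired), (interior of a pair), and (suffix after a paired block).
  Ensemble diversity is 2·Σ p·(1−p); Freq = exp(−MFE/RT)/Z.
* **Exhaustive enumeration** of all legal structures is exposed as a
  first-class function. It is recursive, shares no code with the DPs, and
  serves as the independent oracle: on random sequences of length ≤ 20 the
  DP MFE must match enumeration exactly and Z to 1e-9 relative (the
  observed discrepancy is ~1e-14).
* **Topology**: a stem is a maximal run of stacked pairs; a (hairpin) loop
  is a pair enclosing no other paired position. Thus a single stem-loop has
  n_loops = 1 and a multi-branched fold n_loops ≥ 2, which is what the
  multi-loop features key on. Co-axial counting subtleties (bulges split
  stems but not loops) follow directly from these two definitions.

## Shuffle null

The null model preserves exactly what matters for folding-energy
significance: mononucleotide and dinucleotide count multisets. The
Altschul–Erickson Euler-path shuffle is used (random last out-edge per
vertex until the last-edge graph is an arborescence into the final
nucleotide, then a randomized Euler walk). Defaults: 300 shuffles per
sequence, matching the published null size; tests and examples use 10–25
for speed. z-scores use the sample (n−1) standard deviation with z = 0 on
a degenerate null; p-values are lower-tail add-one empirical estimates
p = (#{null ≤ obs}+1)/(n+1) — never exactly 0, and the lower tail is the
relevant one because genuine precursors fold unusually *low*.

## Features

Canonical order: 32 triplet, 15 base-pair, 18 thermodynamic names, frozen
in `ALL_FEATURE_NAMES` and used as TSV headers everywhere.

* Triplet elements collapse both bracket characters to '(' and classify
  every window of 3 adjacent positions (all L−2 windows; a variant
  excluding terminal-loop windows was considered and rejected as
  needless configuration surface) by pattern × middle base, normalized to
  frequencies.
* Base-pair features: G/C ratio, %C+G, dP = n_bp/L, Avg_BP_Stem,
  ensemble Diversity, |X−Y|/L, (X−Y)/n_stems, and the four multi-loop
  features dP/n_loops and %(X−Y)/n_loops, where %(X−Y) is the share of
  X−Y pairs among all pairs (normalized by n_bp, not by L — it is a ratio
  *of base pairs*).
* Thermodynamic features: dG = MFE/L, MFEI₁ = dG/%(C+G), MFEI₂ = dG/n_stems,
  MFEI₃ = dG/n_loops, MFEI₄ = MFE/n_bp, Freq, NEFE = EFE/L,
  Diff = |MFE−EFE|/L, dH, dS, Tm, dH/L, dS/L, Tm/L, and z/p of MFE and EFE
  against the shuffle null. The MFEI₃/MFEI₄ denominators are genuinely
  ambiguous in the literature this follows; `mfei34_swapped=True` exchanges
  them, and the default assigns the loop-normalized index to MFEI₃.
* dH sums nearest-neighbour stack enthalpies over consecutive stacked
  pairs using the Xia et al. (1998) Watson–Crick RNA values; stacks
  containing a GU wobble get a flat −7.5 kcal/mol. This table choice only
  shifts dH/dS/Tm jointly and monotonically; no claim of equality with any
  external melting-prediction program is made. dS = (dH − MFE)·1000/T
  (cal/mol/K) and Tm = 1000·dH/dS − 273.15 °C follow the two-state duplex
  relations.
* Degenerate denominators (n_stems, n_loops, n_bp, count(C) or %(C+G)
  equal to 0) resolve the affected feature to 0, keeping all vectors
  finite without sentinels; an unpairable sequence therefore has dG = 0,
  MFEI₁…₄ = 0, Freq = 1, NEFE = Diff = 0.
* Per-record shuffle RNG streams derive from (global seed, CRC-32 of the
  sequence), so extracted values are invariant to FASTA record order.

## Feature selection

F-score with the standard definition (between-class mean separation over
summed (n−1)-normalized within-class scatter); zero denominator gives
F = 0. Selection keeps the top m (default 32), ties broken by canonical
feature order. In cross-validation the ranking is computed per outer fold
by default (leakage-safe); `selection_mode="global"` ranks once on the full
matrix for reproducing the historical single-pass workflow. The selected
set is data-driven — no fixed feature list is hard-coded.

## Ensemble

Features are min–max scaled to [−1, 1] using training-split statistics
only (constant columns map to 0). Negatives are sorted by Euclidean
distance to the positive-class centroid in that scaled space and cut into
k contiguous blocks of near-equal size (sizes differ by ≤ 1; 5428
negatives at k = 3 give 1810/1809/1809); block 1 is the "closer set". Each
sub-classifier is an RBF SVC trained on all positives plus one block, with
an inner stratified 5-fold grid search over C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}
(coarse steps of 4 by default, configurable) scored by Gm — chosen over
accuracy because Gm is the metric of record under imbalance. Ties keep the
first grid point, making training deterministic given the seed.

Aggregation:

* *majority vote* — strict majority; on an exact tie (even k) the latter
  half of sub-classifiers takes priority (they were trained on negatives
  far from the positives and empirically vote more conservatively); if the
  latter half is itself tied, the largest partition index decides. The
  final fallback level is this package's documented extension — the
  behaviour is otherwise unspecified.
* *mean distance* — each sample is classified exactly once, by the
  sub-classifier whose training-subset centroid is nearest (Euclidean,
  scaled space; equidistant centroids go to the lowest partition index).
  Centroids average the full training subset by default;
  `centroid_on="negatives"` restricts them to the negative partition, the
  other defensible reading of "centre of the training set".

Models serialize to a single joblib archive (schema-versioned: scaling
parameters, selected feature names, k, aggregation, per-submodel
hyperparameters and fitted SVCs); a round-trip reproduces predictions
bit-for-bit.

## Evaluation

SE = 100·TP/(TP+FN), SP = 100·TN/(TN+FP), Acc over all samples,
Gm = √(SE·SP). Outer 3-fold stratified cross-validation (seeded) trains
the entire pipeline — scaling, selection, ensemble — inside each pair of
training folds and averages the three fold reports arithmetically (not by
pooling confusion matrices). Metrics print at 2 decimal places.

## Synthetic data

The generators target the package's energy model, not biological realism;
their role is to make the pipeline mechanics (multi-loop features,
imbalance handling, selection, aggregation) exercisable and provable.

* Positives: GC-biased stem-loops, stem 30–55 pairs, loop 4–8 nt, 5 %
  single-nucleotide bulge probability. The 5' arm draws only from {G, A}
  and the 3' arm from {C, U}, so no within-arm pair is legal and *every*
  structure of the sequence is a single hairpin — n_loops = 1 holds by
  construction, not by luck.
* Negatives: with probability 0.84 (the multi-branch fraction observed in
  the reference pseudo-hairpin corpus) a concatenation of two or three
  short stem-loops joined by unpairable {A,C} linkers, padded to ≥ 70 nt;
  otherwise an i.i.d. uniform sequence of 70–150 nt. Dataset-level class
  balance defaults to the corpus ratio 7.79:1.
* `make_separable_table` bypasses sequence space: informative columns are
  class-shifted normals (shift = 3 SD by default) next to pure-noise
  columns. All ensemble/CV recovery results quoted anywhere in this
  repository use n_pos = 30, n_neg = 90, effect_size = 3, five informative
  and five noise columns.

What passing tests do **not** show: that the feature set separates real
miRBase precursors from real 3'-UTR fragments. The synthetic positives are
far cleaner than biological hairpins (no internal loops beyond single
bulges, no AU-rich stems), the negatives are structurally cruder than real
UTR fragments, and the toy energies are not Turner energies. The tests
establish that the pipeline computes its published quantities correctly
and recovers known structure when it exists.

## Numerical choices and degenerate inputs

* All partition-function accumulation in log space; no scaling tricks.
* Co-optimal MFE tie-break: pair-first, smallest-partner (deterministic).
* Freq is clamped to ≤ 1 against rounding at the 1e-16 level.
* Empty/short intervals in the DPs have Z = 1 by construction.
* Problem sizes in tests and the acceptance script (sequences ≤ 20 nt for
  enumeration oracles, 200 oracle sequences, 1000 shuffle checks, 120-row
  CV tables) were chosen so that the full enumeration spaces stay in the
  10⁴–10⁵ structure range and a complete run finishes in seconds while
  still exercising every recursion branch.

## Known limitations

* The additive energy model ignores stacking, loop sizes and dangles;
  absolute energies are not comparable with thermodynamic folders.
* dH/dS/Tm depend on the stack-enthalpy table noted above; treat them as
  relative, engine-consistent quantities.
* The Euler-path shuffle retries uniformly over last-edge choices; for
  pathological compositions (very long near-homopolymers) the retry loop
  can iterate several times, though termination failures have not been
  observed.
* Mean-distance dispatch assumes centroids are informative; with k close
  to the imbalance ratio and tiny partitions, dispatch can starve some
  sub-classifiers.
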