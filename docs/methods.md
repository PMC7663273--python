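# Methods

This note records the model, its assumptions, the defaults that matter, the
numerical conventions, and the design choices made where the design was
genuinely open. Empirical statements here are limited to what the test
suite and `scripts/acceptance.py` themselves compute.

## Curation model

A protein–ligand pair's raw records (one parameter type at a time: IC50,
Ki or Kd; values in nmol/L) are integrated into one binary index against a
cutoff expressed in µmol (1 µmol = 1000 nmol/L; conventional choices 1.0
and 10.0 µmol):

1. **Fixed values dominate.** If any `=` record exists, interval records
   are ignored even when they contradict the fixed ones; index 1 iff the
   median of the fixed values does not exceed the cutoff (inclusive — "does
   not exceed"). Median of an even count is the mean of the two central
   values.
2. **Mixed bounds never resolve.** With only interval records and both
   `<` and `>` present, the pair is excluded: the bounds either lie in
   non-intersecting areas (`<100`, `>5000`), delimit a two-sided range
   (`>100`, `<5000`), or touch (`<100`, `>100`, treated as
   non-intersecting). These three cases exhaust all `<`/`>` mixtures, so
   exclusion needs no further case analysis.
3. **Lower bounds only:** index 0 if the maximal bound exceeds the cutoff,
   else excluded (the bounds are all compatible with binding).
4. **Upper bounds only:** index 1 if the minimal bound is below the cutoff,
   else excluded.

Structure filters reflect the applicability domain of descriptor-based
classification: any nonzero formal charge removes a molecule, mass
strictly above 1250 Da removes it, and identical (MNA set, molecular
weight) merges records as one compound (affinity records of merged
identifiers are pooled before integration). Chemistry normalization
(valence, aromaticity, canonicalization) is delegated to RDKit at default
parameters; the curator only applies the charge/mass/duplicate rules.

Eligibility (≥ 3 established ligands per protein, ≥ 3 established targets
per ligand — only index-1 links count as "established"; 0-entries face no
minimum) is enforced by iterative removal. Eligible sub-matrices are closed
under union, so the fixpoint is the unique maximal one, independent of
removal order and idempotent; the suite checks this against exhaustive
subset enumeration on small random matrices. Each (parameter, cutoff)
dataset is curated independently; a pair excluded under one parameter may
well appear under another.

## MNA descriptors

Level-0 label: element symbol + implicit hydrogen count (+ formal charge
marks); level-k: the atom's own label followed by the lexicographically
sorted multiset of its heavy-atom neighbors' level-(k−1) strings. The
molecule's descriptor set is the union over atoms and levels 0..L, default
**L = 2** — deep enough to separate constitutional isomers and ring
environments, shallow enough that desk-scale molecules keep set sizes in
the tens. Hydrogens live inside the labels rather than as graph nodes, so
the set is invariant under atom renumbering by construction (property-
tested via random RDKit atom permutations). Aromaticity carries no explicit
mark; hydrogen counts and topology already separate, e.g., benzene from
cyclohexane.

## Per-target naive Bayes (Pa, Pi)

Per target, the index-1 ligands form the active class and index-0 the
inactive class; the classifier must output two probabilities in [0, 1],
Pa (interaction) and Pi (non-interaction), that are estimated independently
rather than as complements. With n_a, n_i the class sizes and c_a(d),
c_i(d) the per-descriptor membership counts, the active-side posterior per
seen descriptor is

    q_d = (c_a(d) + α·p) / (c_a(d) + c_i(d) + α),   p = (n_a+1)/(n_a+n_i+2),

and Pa = expit( logit(p) + Σ_d [logit(q_d) − logit(p)] ) over the query's
training-seen descriptors; Pi symmetrically from the inactive side.
Smoothing default **α = 1** (Laplace).

Choices worth recording:

- The *posterior-odds* form above was chosen over the plain Bernoulli
  likelihood-ratio form because it makes evidence monotone: a descriptor
  found only in active training ligands satisfies q_d > p and can only
  raise Pa, regardless of class imbalance. The likelihood-ratio form
  violates this when the inactive class is very small.
- Descriptors unseen in a target's training data contribute no evidence;
  a query sharing nothing with the training set receives the bare priors.
- In the symmetric non-degenerate case this estimator happens to give
  Pi = 1 − Pa; the two become genuinely independent on *degenerate*
  targets (one class empty — common in sparse curated data), where the
  missing class's probability falls back to a dataset-wide Laplace prior
  while evidence still moves the other side.
- Leave-one-out refits are computed by decrementing the held-out ligand's
  contribution from the target's count table. Counts are additive and the
  held-out ligand touches exactly its own descriptors, so this equals a
  from-scratch refit bit-for-bit (asserted in the suite); a descriptor
  whose counts drop to (0, 0) is treated as unseen, exactly as a refit
  would.
- All accumulations run in lexicographic descriptor order: outputs are
  bit-stable with no randomness anywhere.

## Segment scoring

Frames of length F must lie fully inside both sequences — the segment sum
has exactly F terms and any overhang would need a padding convention the
model does not define. Every position of a test sequence with |Q| ≥ F still
receives a score, since at least one covering frame remains valid. Shifts
range over all offsets (both signs) keeping the frame inside the training
sequence. The identity metric scores 1 only for equal *standard* residues;
ambiguity codes (B, Z, X, …) are retained but never match, themselves
included. The similarity metric is a plug-in point, but identity is the
only shipped and tested metric. Public coordinates are 1-based inclusive.

The production implementation accumulates F shifted copies of the residue
match matrix into diagonal window sums and reduces with sliding maxima
(O(F·|Q|·|K|)); equality with the naive triple loop over (p, i, h) is
asserted exactly on randomized instances. All-vs-all comparisons compute
each unordered pair once: one match matrix serves both orientations
(row-wise maxima give one direction, column-wise the other).

Default frames: **7** (close inter-residue context) and **30** (distant
context); each frame is reported separately, no cross-frame ensembling.

## Score integration

Conventions where the equations are silent:

- Zero denominator in t_p or t0 (no weighted information) → the neutral
  value 0, consistent with "0 = undetermined".
- arcsin inputs are clipped to [−1, 1] after tolerating excursions up to
  1e−9; larger violations are errors, not clips.
- B: exactly equal t and t0 give 0 (including t = t0 = ±1); at the
  hyperbolic singularity |1 − t·t0| < 1e−12 with t ≠ t0, B saturates to
  sign(t − t0).
- Unmeasured pairs in binary mode carry (a_k, b_k) = (0, 0) and drop out of
  both sums; only established indices define the classes.
- Binary mode is the fuzzy computation with indicator coefficients — both
  modes share one code path, and forcing (Pa, Pi) to {0, 1} indicators
  reproduces binary results bit-for-bit (asserted in the suite).

## Evaluation

One pooled ROC per dataset (all scored pairs together), matching the
one-AUC-per-dataset reporting convention; per-ligand macro-averaging is
available behind a flag. AUC is the Mann–Whitney rank statistic with
midrank ties (computed via scikit-learn; the suite cross-checks against a
brute-force all-pairs count). Only pairs carrying a curated index are
scored — unmeasured pairs are never imputed as negatives. Scenario 1 ranks
by Pa − Pi (Pa-only behind a flag); scenario 3 is a strict double hold-out
(protein out of the sequence set *and* ligand out of every Bayes fit), with
ROC labels always the curated binary indices. A protein whose removal
empties a ligand's interactor set skips that pair with a warning.

## Synthetic benchmark

The generator emulates the *shape* of a curated bioactivity extract with a
planted, fully recoverable signal. Defaults (the study conditions for all
built-in evaluations): 5 classes, 40 proteins × 120 ligands, 300-residue
sequences, class templates mutated per protein at rate 0.1 with a
15-residue class motif protected (insertion rate 1.0), class-specific
heterocyclic cores decorated with 1–4 random aliphatic fragments, Ki
records with log-scale replicate jitter bounded to ±0.1 dex, 20% of pairs
converted to interval records, noise 0. Each ligand is measured against
all proteins of its class (values log-uniform in [10, 0.3·cutoff] nM) and
8 off-class proteins ([3·cutoff, 300·cutoff] nM) — sizes chosen so
eligibility (≥3/≥3) holds by construction and the three scenarios finish
in seconds on one CPU.

Interval conversion brackets the value without ever changing the intended
index (upper bound at 2× a binding value stays below the cutoff; lower
bound at ½ a non-binding value stays above), so noise-free curation is
*lossless* — the curated index map equals the generating truth exactly,
which the suite asserts.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: realistic affinity value distributions,
ChEMBL's assay heterogeneity and measurement error, real phylogenetic
structure (class templates are unrelated random sequences, so between-class
similarity is uniformly low), drug-like chemistry diversity, and the heavy
class imbalance of real extracts. The near-perfect AUCs on the noise-free
benchmark certify pipeline correctness and signal recovery, not expected
accuracy on experimental datasets.

## Package shape

The two genuinely fit/predict-shaped components are scikit-learn-style
estimators: `MNABayesClassifier` (fit(X, y) on descriptor sets / molecules
with binary labels; `predict_pa_pi`, `decision_function`) and
`ProteochemometricPredictor` (fit on a curated `InteractionDataset`,
predict over external (sequence, compound) queries). The predictor's
training object is the sparse index matrix plus sequences and structures,
which has no natural (X, y) feature-matrix form, so its `fit` takes the
dataset container directly while keeping the parameter/attribute
conventions. Module-level functions remain the stable functional surface,
and the CLI (`simulate` / `prepare` / `fit` / `predict` / `evaluate`) is a
thin layer over them.

## Known limitations

- The naive-Bayes surrogate is a documented, reproducible stand-in for the
  general PASS-style (Pa, Pi) contract; it does not reproduce any
  particular published probability calibration.
- Identity-only similarity ignores conservative substitutions; a
  substitution-matrix metric would slot into the existing plug-in point
  but is untested.
- No gapped alignment: an insertion inside an otherwise conserved region
  costs a whole frame.
- B is a ranking score, not a calibrated probability; no confidence
  intervals on AUC.
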