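# Methods

## Model

The predictor rests on one hypothesis: local interactions within a
7-residue fragment largely determine the secondary structure of a
residue inside it, so a fragment whose exact copies appear in many
deposited structures with *different* secondary structure is evidence
that the surrounding region can adopt more than one fold. A protein
with a contiguous stretch of such ambiguous fragments is a
fold-switching candidate; a protein whose fragments are structurally
unanimous is monomorphic.

The unit of evidence is the exact 7-mer match. No mismatches, no
position-specific scoring: exactness keeps the database lookup a pure
dictionary operation and makes every hit interpretable as "this exact
sequence has been seen in this conformation". The scored residue is the
third of the 7-mer (configurable), so a query of length L yields L − 6
scored positions running 3 … L − 7 + 3 in 1-based residue coordinates.

Two reliability gates precede scoring. First, a hit is discarded when
the scoring residue is untrustworthy: pLDDT < 70 for predicted
structures, unobserved for experimental ones. Encoding experimental
observation as 100/0 lets one numeric threshold serve both sources;
the boundary is strict (exactly 70 passes). Second, hits from
100%-identity sequence clusters collapse to a single representative,
because the PDB stores many redundant structures of popular proteins
and raw hit counts would be dominated by them. The representative is
the hit with the lexicographically smallest (protein id, start) — an
arbitrary but deterministic choice. The order of the two gates is
fixed (confidence, then dedup): swapping them could change which
cluster member survives.

## Scores

With n unique-cluster hits and class fractions h (helix = H/G/I),
e (strand = E/B), l (loop = T/S/−):

- **Diversity index** DI = 1/(h² + e² + l²). Range [1, 3]; the inverse
  Simpson index of the 3-class distribution.
- **Entropy** −h ln h − e ln e − l ln l with 0·ln 0 = 0. Natural
  logarithm, so the cap is ln 3 ≈ 1.0986.
- **Substitution score**: the mean over all unordered pairs of hits of
  a fixed dissimilarity matrix — helix–strand 0.7, helix–loop 0.3,
  strand–loop 1.0, zero diagonal. One hit means no pairs and scores 0.
  Unlike DI and entropy it weights *which* classes disagree:
  strand↔loop confusion counts more than helix↔loop.
- **Uncertainty** exp(−0.5 n): a Hoeffding-style sample-size penalty.
  It is 1.0 with no evidence and decays by ~40% per extra unique hit.

A hitless window takes the defaults (DI 1, entropy 0, substitution 0,
uncertainty 1): absence of evidence is scored as no diversity, which
deliberately biases the screen toward false negatives rather than false
positives for sparsely covered sequences.

Fold-switching needs *contiguous* ambiguity, so a moving mean of width
WW smooths the DI, entropy and substitution tracks before the maximum
is taken; WW is 8 for proteins of ≤ 251 residues and 18 beyond — the
wider window on long proteins suppresses isolated noisy windows that
would otherwise dominate the max. Uncertainty enters the feature vector
as the plain per-position mean, unrolled: it describes overall evidence
density, not a localized signal. Tracks shorter than WW are averaged in
a single whole-track window, so short designed proteins still score.

## Classifier

A degree-2 polynomial-kernel SVM on the four features, standardized to
zero mean and unit variance with parameters estimated from the training
split only. Fold-switching is the positive class; the reported
confidence is the signed decision-function value. Validation is
stratified six-fold cross-validation (stratified rather than plain
random: with ~190 examples per class, unstratified splits can starve a
fold of one class). Metric aggregation is the across-fold mean with the
across-fold standard deviation.

Hyperparameters (C, gamma, coef0) can be tuned by a Gaussian-process
expected-improvement loop over log₁₀C ∈ [−2, 3], log₁₀gamma ∈ [−3, 1],
coef0 ∈ [0, 5], seeded and deterministic, with accuracy ties broken
toward smaller C. The default evaluation mode uses fixed
hyperparameters in every fold; per-fold re-tuning is available
(`tune_per_fold=True`) but is not the default, since it multiplies cost
by the search budget and, on the well-separated data used for
verification, selects the same region of hyperparameter space anyway.
Undefined metric ratios (zero denominators, e.g. no positive
predictions in a fold) are reported as NaN with a warning and excluded
from across-fold means rather than silently coerced to 0.

## Post-prediction filters

For a positive call, the fold-switch region is the maximal contiguous
run of rolled-entropy windows at ≥ 80% of the track's rolled maximum
that contains the arg-max window, mapped back to residue coordinates.
The 80% fraction is a package choice (configurable); an all-default
track has no region and is an error, since a positive call without any
entropy signal is contradictory.

Disorder filter: intrinsically disordered segments also sample diverse
secondary structure across deposited models, so a region whose overlap
with the *consensus* of two disorder predictors exceeds 50% is
rejected. Consensus is read as intersection — a residue must be called
disordered by both predictors — which is the conservative reading
(union mode is available). The boundary keeps exactly-50% overlap.

Domain filter: a region that misses every annotated domain of a
protein that *has* domain annotation is excluded from the final set; a
protein with no annotation at all is retained but reported in its own
category. Overlap means any nonempty intersection. Annotations are
consumed as interval TSVs (1-based inclusive by default, 0-based
half-open behind a flag); the package never calls a disorder predictor
or annotation service itself.

Candidate shortlisting looks for a contiguous run (≥ 8 scored
positions) where helix and strand propensity are simultaneously
≥ 0.05 — a segment compatible with both folds at once, which
alternating pure-helix/pure-strand positions do not satisfy.

## Synthetic study conditions

The generator builds databases in which ground truth is exact by
construction, not approximately planted: every window of a planted
"plateau" occurs in exactly the planned number of distinct-cluster
records with the planned class letter at the scoring residue, filler
sequence is rejection-sampled against the full set of query 7-mers, and
redundant cluster copies are byte-identical sequences. Consequently the
pipeline must recover planted propensities *exactly* (integer counts
divided by integer totals), and any deviation is a defect, not noise.
Hit-record confidence defaults to pLDDT 100.

The labelled feature sets for classifier verification are
class-conditional Gaussians in the 4-feature space, 189 fold-switching
vs 198 monomorphic (the shape of the curated training corpus), with the
class-mean gap expressed in units of the per-feature noise SD via a
separation parameter: 0 gives identical distributions (the permutation
null), ~3 and above a cleanly separable set. Ten percent of monomorphic
examples sit exactly at the default vector (1, 0, 0, 1), emulating
proteins whose fragments find no database hits; this also pins the
all-default vector to the monomorphic side of the decision boundary.
Feature values are clipped to their analytic ranges.

What the synthetic conditions do *not* emulate: realistic amino-acid
composition and homology structure, correlated secondary structure
along real chains, the empirical hit-count distribution of a
200K-structure PDB + 1M-structure AlphaFold database, and annotation
noise in DSSP or pLDDT. Passing tests therefore demonstrate that the
machinery computes its definitions correctly and recovers planted
signal, not that real-proteome accuracy matches any published figure —
the headline cross-validation numbers of the original screen depend on
the full fragment database, which this package can ingest but does not
ship.

Problem sizes used by the verification script (`scripts/acceptance.py`):
one 80-residue query with a 25-residue planted plateau over a ~100-record
database; 387 labelled examples for CV; 120 examples × 50 seeds for the
permutation null; a 25-protein proteome at 20% planted positives. These
sizes make every quantity exact or tightly concentrated while keeping a
full run in seconds.

## Numerical choices and edge cases

- Natural log throughout; entropy's 0·ln 0 convention is implemented by
  summing only over strictly positive fractions.
- The rolling mean is `np.convolve` with a uniform kernel; its maxima
  are reversal-invariant up to floating-point summation order.
- Query fragments containing non-amino-acid letters return no hits with
  a warning rather than raising: proteome FASTA files routinely contain
  B/Z/U/*.
- Duplicate record ids are an error at index build; records failing an
  invariant at load are skipped with a warning naming the id, so one
  corrupt entry cannot abort a proteome-scale build.
- The index is serialized as JSON of its records and rebuilt on load;
  occurrence lists are cheap to reconstruct and the file stays
  human-readable.
- Scoring is resumable per protein: an existing per-protein score table
  is reused, and features are recomputed from it, so an interrupted
  batch continues without re-querying finished proteins and yields
  byte-identical feature tables.

## Known limitations

- Exact matching cannot see fold-switches driven by point mutations:
  two sequences differing at one residue share almost no 7-mers with
  each other's structures.
- Fold-switches that preserve secondary structure while rearranging
  tertiary contacts are invisible to all four scores.
- The disorder and domain filters are only as good as the interval
  tables supplied; the package deliberately performs no annotation
  lookups of its own.
- With an empty or tiny database the screen degenerates to "everything
  monomorphic" by the default-score rule; uncertainty near 1 flags
  this regime.
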