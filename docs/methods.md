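# Methods

## Problem and model

The package classifies protein sequences into pattern recognition receptors
(PRRs, the positive class) versus other proteins. Two evidence sources are
combined:

1. **Similarity**: a query that aligns significantly to a known PRR is almost
   certainly a PRR. This evidence is precise but has low coverage — most
   queries have no significant hit against a small labeled reference.
2. **Learned composition**: fixed-length encodings of the sequence (or of its
   evolutionary profile) feed a standard classifier, which covers every query
   but with a softer error rate.

The hybrid rule arbitrates by adding an offset to the model's positive-class
probability *p*: +0.5 for a positive similarity call, −0.5 for a negative
call, 0 for no hit. With any threshold in (0, 1) this makes the similarity
stage decisive whenever it speaks (p ∈ [0, 1], so p ± 0.5 crosses the
threshold regardless of p for thresholds in [0.5, 1] and [0, 0.5]
respectively) while leaving no-hit queries entirely to the model. AUROC is
computed on the fused score directly; ranks are unchanged by the monotone
offsets within each call group, and no renormalization is applied.

Assumptions worth stating: the similarity stage's positive-preference rule
(any positive hit outranks all negative hits) encodes the asymmetric belief
that positive similarity is near-certain evidence; a best-hit-wins variant is
available (`prefer_positive=False`). Self-hits are excluded by sequence id,
since evaluation folds are drawn from one labeled pool and a query finding
itself would trivially inflate sensitivity.

## Feature encodings

All encodings are on a percent scale and ordered by the fixed canonical
alphabet `ACDEFGHIKLMNPQRSTVWY` (alphabetical; any fixed order works, one is
needed for vectors to be comparable):

- **AAC** divides residue counts by sequence length L (sums to 100).
- **DPC** divides adjacent-pair counts by L − 1, the number of overlapping
  pairs, so the 400-vector also sums to exactly 100.
- **PSSM-400** squashes the integer log-odds of a PSI-BLAST ASCII PSSM through
  the logistic map σ(x) = 1/(1+e^(−x)) and sums the squashed rows per native
  residue type, dividing by the full length L. The logistic map is bounded,
  strictly monotone and parameter-free; per-matrix min–max scaling would make
  feature values depend on each matrix's score range, so it was not chosen as
  default. Dividing by L (rather than by the count of each residue type)
  keeps the 400 values a *composition*: blocks of rare residues are
  down-weighted in proportion to their rarity, and residues absent from the
  sequence contribute exact zeros.
- The 420-length combination is AAC followed by PSSM-400.

PSSM files are consumed, not produced: the parser accepts the PSI-BLAST
`-out_ascii_pssm` layout, takes the first 20 numeric columns as log-odds, and
remaps the file's column order (usually `ARNDCQEGHILKMFPSTWYV`) to the
canonical alphabet. An optional `run_psiblast` helper (3 iterations against a
user-supplied database) wraps profile generation; nothing else depends on it.

## Handling of non-canonical residues

Real sequence databases contain ambiguity codes (B, J, Z, X), non-standard
residues (O, U), stops and gaps. The default policy removes them with a
logged count (`SANITIZE`); `STRICT` rejects the record instead. Removal
changes L and therefore composition denominators; for typical contamination
(a few X per thousand residues) the effect is far below the class signal.

## Homology-aware partitioning

Clusters (from a CD-HIT `.clstr` file, or the internal greedy clusterer) are
dealt round-robin into k subsets in cluster order: cluster i goes to subset
((i − 1) mod k) + 1. Cluster order is the input order and is never re-sorted —
the numbering of any published split presumes a fixed order, and CD-HIT
already emits clusters by decreasing representative length. Positives and
negatives are clustered and dealt independently, then subset j of each class
is zipped into test fold j. k defaults to 5.

The internal greedy clusterer sorts records by length descending and joins a
record to the first cluster whose *representative* aligns at or above the
identity threshold (global alignment, match 1 / mismatch 0 / gap open −10 /
extend −1; identity = matches / alignment columns). It approximates CD-HIT
without its word filtering and banded alignment and is intended for fixtures
and fallback; parsing real CD-HIT output is the faithful route. The leakage
guarantee — no two sequences in different subsets above the threshold — holds
by construction on data whose families are mutually dissimilar below the
threshold, which the synthetic generator provides and the test suite audits
with an explicit all-pairs identity scan.

## Similarity engines

BLAST+ is the default engine (`makeblastdb -dbtype prot`, `blastp -outfmt 6`,
batched queries per fold). When the binaries are absent an in-process
Smith–Waterman engine is used: BLOSUM62 with gap open 11 / extend 1 (BLAST's
protein defaults), bit scores via the Karlin–Altschul transform with the
gapped defaults λ = 0.267, K = 0.041, and e-value = m·n·2^(−bits) with raw
(uncorrected) lengths. This is deliberately simple — no composition-based
statistics, no edge-effect corrections — so its e-values differ from BLAST's;
the two engines are required (and tested) to agree only on the POS/NEG call
for closely similar queries, and every result records its engine.

The e-value sweep searches once per fold at the loosest cutoff and filters
in memory for tighter cutoffs, which makes the nested-hit-set property exact
by construction. Note that under the positive-preference rule only some
tallies are monotone in the cutoff: positive calls accumulate in both classes
and no-hits only resolve, but a correctly-NEG negative query can flip to POS
when a looser cutoff admits a positive hit.

## Models and selection

The six wrapped families use scikit-learn estimators; SVM probabilities come
from the built-in Platt-style sigmoid fitted on internal training-fold splits.
Default grids cover tree-ensemble sizes 60–100, SVM C ∈ {2, 5, 10} with
γ ∈ {0.01, 0.5} (RBF), logistic-regression C ∈ {1, 1000}, k-NN with 6 or 20
distance-weighted neighbours (ball tree), and MLP widths 14/19/70 with tanh or
logistic activations (adam, 200 iterations). Grid search maximizes mean AUROC
over externally supplied folds (MCC selectable); inside `run_cv` those are the
leave-one-subset-out folds of the training subsets, so test rows never touch
selection — the per-fold training fingerprint is exposed and asserted in the
tests. Ties go to the earlier grid point. One global seed threads through
every stochastic learner (default 42).

## Thresholds and aggregation

Headline threshold-dependent metrics need one operating point. The default
rule picks the MCC-maximizing threshold on the training fold's own fused
scores (candidates: every distinct score plus 0.5; ties to the smallest) and
applies it unchanged to the test fold; a fixed threshold can be passed
instead, and the full pooled threshold sweep is part of every report.
Predicted positive means score ≥ t (ties positive). Per-fold metrics are
arithmetically averaged ("fold-mean"); a pooled confusion over all test
predictions is also reported. MCC is defined as 0 when any denominator factor
vanishes. AUROC uses the rank statistic with average ranks for ties, which
the tests verify against brute-force pair counting, trapezoidal integration
and an independent library implementation.

## Synthetic data: what it does and does not emulate

The generator's defaults are the package's study conditions: 20 families per
class, 5 members per family, lengths uniform in 80–300, per-site substitution
rate 0.1 within a family, and residue frequencies biased ×1.5 (then
renormalized) for L/N/S/Q in positives and A/D/E/K/V in negatives — the
directions observed between real PRRs and non-PRRs. Substituted residues are
redrawn from the class distribution so mutation preserves the bias. This
yields member-to-founder identity around 90% (member-to-member ≈ 81%) and
inter-family identity far below 40%, validating the clustering test bed.

Generated PSSMs make each position conserved with probability `conservation`;
a conserved position scores round(2 + 6·conservation) in the native column,
all else is clipped integer noise from Normal(−1, 2). At conservation 1 the
native residue is the strict per-position maximum; at 0 the profile carries no
sequence information, giving a clean informativeness gradient for tests.

What the generator does **not** emulate: real PRR domain architecture (LRR,
TIR, lectin motifs), length/composition confounds, database-scale negative
sets, phylogenetic correlation between families, and real PSI-BLAST profiles
(which depend on the search database and convergence). Passing tests
therefore demonstrate that the *protocol* behaves as designed — leakage-free
splits, correct fusion arithmetic, monotone sweeps, recoverable class signal —
not that any particular accuracy will transfer to real receptor data.

## Numerical and degenerate-input choices

- Feature extraction is deterministic and pure; AAC/DPC sum to 100 within
  1e-6 by construction.
- Length-1 sequences are valid for AAC, rejected for DPC (no pairs).
- An un-normalized profile (any cell outside [0, 1]) is rejected by the
  PSSM-400 aggregation rather than silently squashed twice.
- Empty hit lists are a first-class outcome (NO_HIT), not an error.
- `round_robin_split` warns (not errors) when k exceeds the cluster count,
  leaving surplus subsets empty.
- Problem sizes in the test suite are scaled to the generator defaults
  (200 sequences) and below; cross-validated runs with BLAST complete in
  seconds at that scale.

## Known limitations

- The greedy clusterer's identity is alignment-based and O(n²) in the worst
  case; it is not a CD-HIT replacement for large datasets.
- The in-process search engine's e-values are only roughly calibrated to
  BLAST's; operating-point sweeps on real data should use the BLAST engine.
- Exact reproduction of published receptor-prediction tables requires the
  original curated dataset and era-specific PSI-BLAST profiles; the package
  supports that workflow (`.clstr` ingestion, PSSM parsing, the same fold and
  fusion protocol) but ships no claim about those numbers.
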