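# Methods

## The model

`sitelogic` treats site prediction as the completion of a partially
specified boolean function. Every fixed-length sequence window is one-hot
encoded into a bit vector; the labeled training windows pin down the
function's value on a few hundred points of {0,1}ᵏ, and every unseen
pattern is a don't-care. Two-level logic minimization then rewrites the
positive region as a small sum-of-products cover, and each product term
(cube) is read back as a conjunction of interpretable conditions through
the one-hot layout. The classifier *is* the rule list: a window is
positive iff it satisfies at least one rule (optionally, enough rules by
score — see Cutoffs).

The central assumption is that the positive class is approximately a union
of low-order conjunctions over individual sequence positions. That holds
well for transcription-factor binding sites (a conserved core with
variable flanks) and for mucin-type O-glycosylation acceptors (periodic
threonine/proline context). It does not model position interactions
beyond conjunction, long-range dependencies, or anything the fixed window
cannot see.

## Encoding

* DNA: 4 bits/nucleotide, block order A, C, G, T. A 14-nt window → 56
  variables; variable index = 4·(position − 1) + rank.
* Protein: 21 bits/residue. Ranks 1–20 follow the alphabetical order of
  the *full* amino-acid names (Ala, Arg, Asn, Asp, Cys, Gln, Glu, Gly,
  His, Ile, Leu, Lys, Met, Phe, Pro, Ser, Thr, Trp, Tyr, Val — i.e.
  one-letter order A, R, N, D, C, Q, E, G, H, I, L, K, M, F, P, S, T, W,
  Y, V); rank 21 is UNKNOWN (`X`), used to pad windows truncated at
  protein ends. An 11-residue window (positions −5…+5 around the central
  S/T) → 231 variables.
* Continuous features can be thresholded: one threshold gives one bit
  (value > t); k increasing thresholds give k+1 one-hot interval bits.

Denser encodings (2 bits per nucleotide, say) would shrink the tables but
destroy the one-variable-one-fact reading, so they are deliberately not
offered.

Binary functions require one output per input pattern, so after
projection to the selected variables, duplicate patterns are collapsed
(multiplicities retained — rule scores need them) and contradictory
patterns are removed. The default policy drops the whole contradictory
group (conservative); a majority policy (keep the more frequent label,
remove ties) is available.

## Feature selection (SVM-RFE)

Two-level minimizers cap out around 22 inputs, and 56/231 variables also
invite overfitting, so a linear soft-margin SVM (C = 1.0, tolerance 1e-6,
labels mapped to ±1) is trained and the feature with the smallest w²ᵢ —
the standard surrogate for the margin change on removing feature i — is
eliminated; retrain; repeat until k survive. Ties break toward the lower
feature index; elimination is one feature per round by default, with an
optional chunk size (`rfe_step`) used for the 231-variable protein runs
(step 8: ~27 refits instead of ~211, with near-identical selections in
practice). Defaults: k = 22 for DNA, k = 20 for protein.

## Minimization

* **Exact (Quine–McCluskey)**, used when k ≤ `exact_limit` (default 16).
  Prime implicants come from a dynamic program over all 3ⁿ cubes (a cube
  is an implicant iff both halves of any split variable are) for n ≤ 12,
  falling back to classical pairwise merging above. The minimum cover is
  found by the standard unate-covering reductions — essential primes, row
  dominance, column dominance, iterated to a fixed point — followed by
  branch and bound on the cyclic core; cores wider than 18 columns are
  solved exactly as a binary integer program with HiGHS. Among equal-size
  covers the branch-and-bound path returns the lexicographically smallest
  cube list, so outputs are unique and testable.
* **Heuristic (ESPRESSO-style)**, used above `exact_limit` and capped at
  `heuristic_limit` (default 22, the input cap of the classic
  espresso-family tools). Deterministic EXPAND → IRREDUNDANT → REDUCE
  passes repeat until neither cover size nor literal count improves (max
  10 passes). EXPAND raises each cube's literals greedily, choosing at
  every step the safe raise that maximizes on-set coverage (ties: an
  optional per-variable preference, then fewest off-set minterms
  distinguished, then leftmost). REDUCE shrinks cubes sequentially
  against the current cover so coverage is never lost. No global
  minimality is claimed; covers are validated by equivalence and by
  never beating the exact minimizer on functions where both run.

Unspecified minterms default to don't-care throughout: the minimizer
assigns them whichever output yields the simpler cover, which is exactly
the mechanism by which the rule set generalizes to unseen windows.

### Variable-trust preference

When the pipeline calls the heuristic it passes a per-variable preference
— the absolute two-proportion z statistic of each selected column between
classes — so that EXPAND sheds literals on weakly class-associated
variables first, a coverage-preserving literal-exchange pass swaps locked
weak guards for unanimous trusted variables, and IRREDUNDANT keeps rules
built on trusted variables ahead of equally-covering rules that lean on
weak ones. This biases the learned rules toward the variables that carry
real signal without changing validity: every cover still exactly covers
the on-set and avoids the off-set. With small training sets a noise
column can still chance into genuine sample association that no
data-driven criterion can distinguish from signal, so occasional rules
retain a literal outside the true motif core (see Limitations).

## Rule scoring and cutoffs

A rule's score is the number of positive training patterns it covers,
counted with multiplicity. A test pattern's score is the sum over the
rules it satisfies. Cutoffs:

* `all_rules` — positive iff score ≥ 1 (the raw rule classifier);
* `min_score s` — positive iff score ≥ s (e.g. the sum of the top two
  rule scores demands both rules hold);
* `top_fraction f` — keep the f highest-scoring fraction of
  positive-scoring test examples, boundary ties all included (the
  threshold is the ⌈f·m⌉-th largest positive score, so at least a
  fraction f always survives; deterministic, favors sensitivity).

Raising any cutoff can only remove positives — sensitivity is monotone
non-increasing while PPV typically rises.

## Synthetic data

The curated site collections the method was designed around cannot be
redistributed, so seeded generators emulate their statistical shape:

* **Motif implants** (TFBS analogue): 14-nt instances with a single-base
  consensus core at positions 6–10 (G, C, A, A, T), each core position
  independently mutated with probability 0.05, implanted without overlap
  into i.i.d. uniform background DNA; 60 sites per experiment, 20 kb test
  sequences, 90/10 train/test splits with balanced random negative
  windows, ±2-nt tolerance when matching predicted to true starts.
* **Glycosylation windows**: 11-residue windows with the center fixed to
  T (or S), positive flanks drawn with enrichment weights echoing the
  threonine/proline periodicity of mucin-type acceptors — T favored at
  −4, −2, +2, +4 (weight 60, i.e. P(T) ≈ 0.76, so roughly a third of
  positives carry the full periodic pattern, matching the prevalence of
  the most popular rule on real threonine acceptor data), T suppressed
  and P favored at +1, +3, +5; negatives draw flanks uniformly. Defaults:
  500 positives + 500 negatives, 85/15 balanced splits.

What these generators do *not* emulate: real genomic base composition and
repeat structure, correlated motif positions, degenerate consensus
letters, protein-family redundancy between train and test, and the
class-imbalance of real candidate scans. Passing tests on this synthetic
structure therefore demonstrates that the machinery recovers planted
conjunction structure under realistic noise — not field performance on
curated databases.

## Numerical and design choices

* Minterm convention: the leftmost cube character is the most significant
  bit.
* All randomness flows through `numpy.random.Generator` seeds; every
  experiment function takes a seed and is bit-reproducible.
* The SVM is scikit-learn's `SVC(kernel="linear")` (libsvm), deterministic
  for fixed input.
* PLA interchange uses type `fr` (explicit on- and off-set lines, rest
  don't-care) — the only honest way to ship a 22-input function whose
  complete table would have 4,194,304 rows. An explicit materialization
  path exists for small widths, guarded by a row cap (default 2¹⁶).
* Window scan coordinates are 1-based inclusive; a length-L sequence has
  exactly L − w + 1 windows (a 20,000-nt sequence scans 19,987 windows of
  width 14; off-by-one bookkeeping differs in parts of the literature).
* Prediction-to-truth matching is greedy one-to-one, nearest pair first,
  ties to the lowest position.
* Degenerate inputs: empty on-set → empty cover; undefined
  sensitivity/PPV (zero denominator) report as missing, never as 0;
  single-class training data is rejected.

## Problem sizes

The shipped experiments use 60 binding sites in 20 kb × 10 replicates and
1,000 glycosylation windows × 10 replicates; the random-function property
suite draws 200 functions of 3–10 variables with ~35% on, ~35% off, ~30%
don't-care density, brute-force-verifying exact minimality up to 6
variables. These sizes exercise every code path, including the
4-million-pattern don't-care regime at k = 22, while keeping a full run
in minutes on one CPU.

## Known limitations

* The heuristic minimizer is one deterministic strategy; other raising
  orders produce different (equally valid) covers.
* With ~50 positive training examples, rule literals occasionally sit on
  chance-associated variables outside the planted signal (measured:
  roughly 2–4 replicates in 10 contain at least one such literal under
  the default synthetic conditions). More training data or stronger
  motif conservation removes the effect.
* Exact minimization above ~16 variables is refused rather than attempted.
* Forward strand only; no reverse-complement scanning.
* The fuzzy-logic extension of the rules and ensemble combination with
  other classifiers are out of scope.
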