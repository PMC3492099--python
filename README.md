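# sitelogic

Interpretable prediction of functional sites in molecular sequences by
two-level logic minimization.

Most sequence classifiers (SVMs, neural networks) predict well but explain
nothing. `sitelogic` takes the opposite bargain: it learns a small set of
human-readable boolean rules — *"If Nucleotide 9 is A and Nucleotide 8 is A
and Nucleotide 10 is T and Nucleotide 6 is G, then the window is a binding
site"* — whose joint predictions are competitive with black-box
classifiers, and whose conditions a biologist can read, question and test
at the bench. It is aimed at two site-prediction problems:

* **Transcription-factor binding sites (TFBS)**: 14-nt DNA windows scanned
  along a sequence,
* **Mucin-type O-glycosylation**: 11-residue windows centered on a serine
  or threonine,

but the machinery is generic for any fixed-length window classification.

## Method

1. **One-hot encoding.** Each nucleotide becomes 4 bits (A→1000, C→0100,
   G→0010, T→0001), each residue 21 bits (20 amino acids in full-name
   alphabetical order plus an UNKNOWN category), so every binary variable
   means exactly one thing: "position *p* is/is not symbol *s*". A 14-nt
   window yields 56 variables; an 11-residue window yields 231.
2. **SVM-RFE feature selection.** A linear soft-margin SVM is trained and
   the feature with the smallest squared weight w²ᵢ is discarded,
   repeatedly, until only the top *k* variables remain (k = 22 for DNA,
   20 for protein — the input scale classic two-level minimizers handle).
3. **Partially specified truth function.** The projected training patterns
   define the on-set (sites) and off-set (non-sites) of a boolean function
   f: {0,1}ᵏ → {0,1,−}; the astronomically many unseen patterns (2²² ≈
   4.2 million for k = 22) are don't-cares the minimizer may set freely.
   Duplicate patterns collapse (keeping multiplicities); contradictory
   patterns are removed.
4. **Two-level logic minimization.** Exact Quine–McCluskey (prime
   implicants + exact minimum cover) for small k, or a deterministic
   ESPRESSO-style EXPAND/IRREDUNDANT/REDUCE heuristic for k up to 22. The
   output is a sum-of-products cover: each cube (product term over
   {0,1,−}) is one rule; everything not matched by any rule is negative.
5. **Rule scoring.** Each rule's *score* is the number of positive training
   patterns it covers (with multiplicity). A test window's score is the sum
   over the rules it satisfies; a tunable cutoff (any rule / top fraction /
   minimum score) trades sensitivity against positive predictive value.

## Worked example

The classic 4-variable illustration: a 16-row truth table whose outputs are
1 for patterns {0000, 0010, 0011, 1000, 1010, 1011}, 0 for six others, and
unknown for the remaining four.

```python
>>> from sitelogic import TruthFunction, qm_minimize, score_rules
>>> import numpy as np
>>> from sitelogic.encoding import EncodedDataset
>>> on, dc = {0, 2, 3, 8, 10, 11}, {6, 7, 14, 15}
>>> f = TruthFunction(4, frozenset(on), frozenset(set(range(16)) - on - dc))
>>> cover = qm_minimize(f)
>>> [c.literals for c in cover]
['--1-', '-0-0']
>>> rows = [format(m, "04b") for m in sorted(on)]
>>> ds = EncodedDataset(np.array([[int(c) for c in r] for r in rows]),
...                     np.ones(6, dtype=int), meanings=[])
>>> [(r.cube.literals, r.score) for r in score_rules(cover, ds)]
[('--1-', 4), ('-0-0', 4)]
```

Sixteen rows reduce to two rules — *(B = 0 and D = 0) or (C = 1)* — and
each rule covers four of the six positive patterns, which is its score.

The sequence-level interface is a statsmodels-style model/results pair:

```python
from sitelogic import SiteRuleModel, MotifSpec, generate_background_dna, implant_motifs

model = SiteRuleModel(windows, labels, kind="tfbs", k=22)   # labeled 14-nt windows
results = model.fit()
print(results.summary())          # ranked variables + scored, rendered rules
hits = results.predict_sites(dna) # 1-based starts from a sliding-window scan
```

There is also a command line covering each stage
(`sitelogic simulate-tfbs / train / scan / classify / evaluate / minimize /
rank / encode`); `sitelogic train --help` etc. describe the options.

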