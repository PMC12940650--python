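# Methods note

## Model

A combinatorial analogue series is described by a **scaffold**: an ordered
list of substitution sites, site `k` carrying a finite alphabet of `m_k`
residue tokens.  A **compound** is one token per site; tokens are opaque and
never compared across sites.  A labelled **library** has `L` compounds, `I`
of them *of interest* (active).

A **rule** constrains a subset of sites and leaves the rest as wildcards
(`X`).  The constraint at a focused site is a **term**: a non-empty proper
subset of the site's residue universe, written `[A]`, `[B,C]`, …  The number
of focused sites is the rule's **order**; the subset size is the term's
**level** (level 1 = the classical single-residue method).  The full subset
equals the wildcard and is excluded, so fixing the order excludes hidden
wildcards.  Negation notation `[|A]` is input sugar that normalises to the
complement subset — every negation rule has an exact multilevel equivalent,
which the test suite verifies by direct matching.

With a level cap `l` the number of terms at a site with `m` residues is
`sum_{r=1..min(l, m-1)} C(m, r)`, i.e. `2^m − 2` at the exhaustive cap
`m − 1`.  The rules of order `r` are counted by summing, over every
`r`-subset of sites, the product of per-site term counts; over all orders and
exhaustive levels this telescopes to `prod_k (2^{m_k} − 1) − 1`.  Enumeration
is deterministic (ascending order, lexicographic site combinations, subsets
by level then alphabet position) and is tested against the closed forms.

## Significance and voting

A rule *embraces* the compounds it matches: `s` of the `L` training
compounds, `i` of them of interest.  Under the null hypothesis that the rule
is unrelated to activity, `i` follows the hypergeometric distribution of
drawing `s` from a library of `L` containing `I` of interest.  Both tails are
computed with exact integer arithmetic and converted to float once, so
threshold comparisons are deterministic:

* **enrichment**: `p(i+) = P(j ≥ i) ≤ θ` → the rule votes **+1**;
* **depletion**: `P(j ≤ i) ≤ θ` → the rule votes **−1**.

Both thresholds are inclusive and `θ` (percent) must lie in `(0, 50)`, which
makes the two conditions mutually exclusive (the tails overlap at `j = i`
and sum to more than 100 %).  The depletion criterion is the inclusive lower
tail by design: the exclusive variant `1 − p(i+) ≤ θ` would mark *every* rule
with `i = 0` significant at any threshold, flooding the system with
uninformative negative voters.

Rules embracing no training compound (`s = 0`, trivially `p = 100 %`) or all
of them (`s = L`, indistinguishable from the order-0 rule) are dropped before
significance assessment.  The surviving significant rules form the **voting
system**; a compound's score is the sum of the votes of the rules matching
it.  A compound carrying residues unseen in training is simply matched by
fewer rules — never an error.

By default terms are drawn from the **observed universe** (residues present
in the training split); rules over unseen residues embrace nothing and are
statistically vacuous, and restricting to observed residues keeps the rule
universe aligned with what the data can support.  The full scaffold alphabets
are available with `universe="full"`.

## Ranking, ROC, frontier

Scores define a ranking evaluated by the tie-corrected AU-ROC (the
Mann–Whitney statistic: ties between a positive and a negative count ½),
identical to the trapezoidal area under the threshold-sweep ROC curve, and
cross-checked in the tests against a brute-force pairwise oracle and
scikit-learn.  A hard classification uses an integer **voting frontier**:
predicted of interest iff score ≥ frontier.  `optimal_frontier` scans the
smallest integers realising each distinct classification and maximises
accuracy (or Youden's J), breaking ties toward the smaller frontier
(favouring sensitivity).

## Cross-validation

All schemes re-run the entire training block per fold — rule enumeration over
the fold's own observed universe, fresh significance against the fold's `I`
and `L` — so no information about held-out compounds leaks into selection:

* **L1O**: each compound scored by a system trained on the other `L − 1`.
* **Repeated stratified k-fold**: each class is shuffled (seeded generator)
  and dealt round-robin into `k` folds, so per-fold class counts are as even
  as arithmetic allows (61 = 21+40 into 10 folds gives one 3+4 fold and nine
  2+4 folds).  The AUC of a repetition is computed on the pooled held-out
  scores; the default benchmark run uses 20 repetitions (a 100-repetition run
  is a one-flag change: `--repetitions 100`).
* **BL2O** (balanced leave-two-out): every (active, inactive) pair is held
  out once — `I × (L − I)` runs, 840 for the packaged training set.  Each
  active is scored `L − I` times and each inactive `I` times; accumulated
  votes are multiplied by the compound's own class size so both classes weigh
  equally in the final ranking.

## Virtual screening

Candidates are generated from the Hamming neighbourhoods of the training
codes: a new code qualifies when it differs in at most `d*` sites from at
least `k*` training compounds.  Generation walks the exact-distance
neighbourhoods of each training compound (never the full product space), so
the per-code generation count *is* its support; the tests verify equivalence
with a brute-force product-space scan on small libraries.  Defaults:
`d* = 2`, `k* = 3`, generation over the observed training universe, and
exclusion of the training codes (`exclude="known"` additionally drops every
code of a supplied reference set).  Candidates are ranked by summed votes,
ties broken lexicographically.

## Numerical and engineering choices

* Hypergeometric tails use Python big-integer arithmetic (`math.comb`) and
  `Fraction`, converted to float once; p-value tables per `(I, L)` pair are
  cached.
* The exhaustive scan packs compound membership into little-endian bitsets
  and evaluates whole blocks of rules (cartesian products of term masks) with
  `numpy.bitwise_count`; blocks are chunked (~2 M rules) to bound memory.
  The training subset may be a boolean mask over a larger evaluation dataset,
  so held-out and external compounds are scored by the same scan for free —
  this is what makes per-fold re-selection cheap.
* Determinism: rule enumeration order is fixed; the only stochastic component
  (k-fold shuffling) uses `numpy.random.default_rng(seed)`; CLI outputs carry
  the seed and a configuration hash.

## Scope and limitations

* Binary labels only; no regression on potency values.
* Rules are conjunctions of per-site subset constraints; no cross-site
  disjunctions.
* The hypergeometric test treats rules independently; the voting system makes
  no multiple-testing correction — θ is a selection knob, not an error rate.
* Candidate generation is similarity-restricted by design; it does not
  attempt novelty beyond the `d*` neighbourhood of the training set.
* The packaged datasets are symbolic codifications; the package does not
  parse chemical structure formats.
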