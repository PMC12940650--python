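# ssir — Superposing Significant Interaction Rules

`ssir` models structure–activity relationships in combinatorial analogue
series: families of compounds sharing a molecular scaffold whose substitution
sites each carry one residue from a finite alphabet, so every compound is a
short symbolic code such as `ACB` or `FABKAIDLJ`.

Given a training library in which each compound is labelled *of interest* or
not, the package:

1. **enumerates every definable presence/absence rule** over the scaffold —
   a rule constrains some sites to residue subsets (*multilevel terms*) and
   leaves the rest as wildcards `X`;
2. **tests each rule for significance** with the exact hypergeometric tail:
   a rule embracing `s` of the `L` training compounds, `i` of them of
   interest, gets the enrichment p-value `p(i+, s; I, L)`.  Rules with
   `p ≤ θ` become **+1 voters**; rules whose depletion tail `P(j ≤ i) ≤ θ`
   become **−1 voters**;
3. **scores any compound** by the summed votes of the rules that match it,
   yielding a ranking evaluated by tie-corrected AU-ROC and, at an integer
   *voting frontier*, a confusion matrix;
4. **cross-validates** with full per-fold rule re-selection (leave-one-out,
   repeated stratified k-fold, balanced leave-two-out), and
5. **screens virtual candidates**: new codes within a Hamming-distance
   neighbourhood of the training set, ranked by votes.

Negation notation `[|A]` is accepted and normalised to the complement subset,
so every negation rule has an exact multilevel equivalent.

## Worked example

Two example datasets ship with the package: `load_toy()`, a nine-compound
illustrative series on the scaffold `{A,B,C,D} × {A,B,C,D} × {A,B,C}`, and
`load_antihiv()`, 132 anti-HIV nucleoside analogues on a nine-site scaffold
(61 training compounds `TRN`, external test sets `Ex1` and `Ex2`).

```python
from ssir import SSIRModel, load_toy

toy = load_toy()
res = SSIRModel(toy, orders=1, max_level=1, theta=5,
                universe="full", negative_votes=False).fit()
print(res.summary())
```

```
SSIR voting system
======================================================
training compounds               9  (of interest: 3)
rule orders                   (1,)
max term level                   1
p-value threshold               5%
residue universe              full
rules generated                 11
rules matchable                 11
voters (+1 / -1)                 2 / 0
training AU-ROC              1.000
```

```python
print(res.voting_system.report().to_string(index=False))
```

```
notation  s  i  p_percent  p_lower_percent  vote
   [A]XX  3  3   1.190476            100.0     1
   X[A]X  4  3   4.761905            100.0     1
```

With `θ = 5 %` exactly two classical rules are significant: an `A` at site 1
(3 embraced, all of interest, p = 1.19 %) and an `A` at site 2 (4 embraced,
3 of interest, p = 4.76 %).  Scoring the library by summed votes separates
the classes perfectly:

```python
print(res.score(toy).frame.to_string(index=False))
```

```
 id code  score  label
AAA  AAA      2   True
AAB  AAB      2   True
AAC  AAC      2   True
BCC  BCC      0  False
BDA  BDA      0  False
CDC  CDC      0  False
CAA  CAA      1  False
DBB  DBB      0  False
DDC  DDC      0  False
```

The same interface scales to the real dataset.  A multilevel model (order-3
rules, term levels up to 2) trained on the 61 `TRN` compounds:

```python
from ssir import SSIRModel, load_antihiv

hiv = load_antihiv()
trn, ex1 = hiv.subset("TRN"), hiv.subset("Ex1")
res = SSIRModel(trn, orders=3, max_level=2, theta=15).fit()
print(res.summary())
rep = res.evaluate(ex1)
print(f"Ex1 AUC {rep.auc:.3f}")
```

```
SSIR voting system
======================================================
training compounds              61  (of interest: 21)
rule orders                   (3,)
max term level                   2
p-value threshold              15%
residue universe          observed
rules generated            1745977
rules matchable             331060
voters (+1 / -1)             24620 / 4988
training AU-ROC              0.936

Ex1 AUC 0.863
```

Cross-validation and screening hang off the fitted results object:

```python
res.loo()                      # leave-one-out, per-fold rule re-selection
res.kfold(k=10, repetitions=20, seed=0)   # repeated stratified 10-fold
res.bl2o()                     # all 21 x 40 = 840 active/inactive pairs
df = res.screen(max_diff=2, min_support=3)  # 4760 virtual candidates
print(df.head(3).to_string(index=False))
```

```
 rank      code  votes  min_diff  support_at_2
    1 FABKBIDLJ   7413         1            25
    2 FBBKAIDLJ   7385         1             9
    3 FABKBIDLO   7050         1            17
```

## Command line

```bash
ssir train    --builtin antihiv --subset TRN --orders 3 --max-level 2 --threshold 15 --out run/
ssir evaluate --builtin antihiv --subset Ex1 --voting run/voting_system.json --out run/
ssir cv       --builtin antihiv --subset TRN --scheme kfold --repetitions 20 --seed 0 --out run/
ssir screen   --builtin antihiv --subset TRN --max-diff 2 --min-support 3 --out run/
ssir reproduce 4   # classical benchmark grid (orders x thresholds)
ssir reproduce 5   # multilevel grid
ssir reproduce 6   # ranked virtual candidates
```

Every output file carries a header with the seed and a hash of the effective
configuration; runs are deterministic given both.

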