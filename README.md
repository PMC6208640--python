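# traitforest

Predicting how microbes respond to each other in coculture — and *why* —
from nothing but binary trait profiles.

## The problem

For a community of N organisms, pairwise coculture experiments measure a
response matrix X: the entry X<sub>ij</sub> is the response of organism *i*
grown together with partner *j* (a relative yield
X<sub>ij</sub> = (B<sub>ij</sub> − B<sub>ii</sub>)/B<sub>ii</sub> against the
monoculture biomass B<sub>ii</sub>, a fold change, or a survival flag).
Measuring all N(N−1) ordered responses is expensive; `traitforest` learns to
predict them from cheap genome-derived traits.  Each organism gets an
*n*-long binary trait vector F<sup>(i)</sup> (presence/absence of exchange
reactions, biosynthetic capabilities, functional modules), and each ordered
pair (i, j) is represented by the responder-first composite vector
F<sup>(i,j)</sup> = [F<sup>(i)</sup>, F<sup>(j)</sup>] of length 2n, so that
(i, j) and (j, i) are distinct samples.

A from-scratch random forest classifies these composite vectors (negative
vs. nonnegative relative yield, weak vs. strong fold change, …), with
out-of-bag vote fractions for internal ROC/AUC estimation, balanced
accuracy, permutation variable importance, and learning curves under the
pairing constraint (X<sub>ij</sub> and X<sub>ji</sub> always split
together).

The distinctive part is mechanism ranking.  For a single sample, the
forest's score decomposes additively over features along each tree's
decision path: feature *f* accumulates the local increments
Y<sub>child</sub> − Y<sub>node</sub> (Y = positive-class fraction of
training samples at the node) at every node splitting on *f*, averaged over
the sample's out-of-bag trees into a contribution φ<sub>f</sub> with

    baseline + Σ_f φ_f = mean leaf positive fraction over counted trees.

Each candidate mechanism (say, a metabolite both partners might fight over)
maps to one responder-half and one partner-half feature; their summed *net
contribution* orders the candidates.  Reading competitive candidates from
the negative end (facilitative ones from the positive end) tells an
experimentalist which metabolite to test first.  Against the analytic
random-query baseline of (n_candidates + 1)/(n_true + 1) experiments, the
ranking typically finds the true mechanism within a handful of queries.

Because real mechanism ground truth is rarely available, the package ships
a toy dynamic-FBA batch coculture simulator: small linear-pathway
stoichiometric models solved by linear programming at each Euler step of a
shared, finite metabolite pool.  Competition and cross-feeding *emerge*
from the flux dynamics, and the ground-truth contended/facilitative
metabolites are read off the simulated exchange fluxes — never from the
construction — so the whole pipeline is testable end to end.  A rule-based
generator for amino-acid auxotroph panels covers the survival/fold-change
style of dataset.

## Worked example

```python
from traitforest.pipeline import mechanism_recovery_study
from traitforest.contributions import expected_random_rank

res = mechanism_recovery_study(7)   # 20 organisms, 50 metabolites, 500 trees
s = res.summary
print(f"samples with a single contended metabolite: {len(s.ranks)}")
print(f"median rank of the true metabolite: {s.median_rank:.1f}")
print(f"analytic random baseline: {expected_random_rank(res.n_candidates, 1):.1f}")
print(f"forest OOB AUC: {res.forest_auc:.3f}  Jaccard baseline AUC: {res.jaccard_auc:.3f}")
```

prints

```
samples with a single contended metabolite: 60
median rank of the true metabolite: 1.0
analytic random baseline: 25.5
forest OOB AUC: 0.951  Jaccard baseline AUC: 0.800
```

That is: the simulator produced 60 coculture responses that are negative
because the two organisms compete for exactly one metabolite; ranking the
50 candidate metabolites by net feature contribution puts the true one
first for at least half of those samples, where random querying would need
~25.5 experiments; and the forest's out-of-bag ROC clearly beats a naive
classifier thresholding the Jaccard distance between the two trait
vectors.

The same machinery is exposed as a command-line tool:

```bash
traitforest simulate --scenario single_competition --n-organisms 20 \
    --n-metabolites 50 --seed 7 --out sim/
traitforest train --traits sim/traits.tsv --interactions sim/interactions.tsv \
    --config cfg.yaml --n-trees 500 --seed 7 --out model.json
traitforest evaluate --model model.json --traits sim/traits.tsv \
    --interactions sim/interactions.tsv --config cfg.yaml --out eval/
traitforest explain --model model.json --traits sim/traits.tsv \
    --pair org00,org01 --candidates candidates.tsv --out contributions.tsv
```

where `cfg.yaml` holds the label rule, e.g.
`label: {mode: sign, tolerance: 1.0e-6}` plus
`response_mode: relative_yield`.  Every command writes a resolved config
and a SHA-256 manifest beside its outputs.

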