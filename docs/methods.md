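# Methods

## Composite representation and labels

An organism's traits are a binary vector F⁽ⁱ⁾ of length n; an ordered
coculture observation (i, j) is the concatenation F⁽ⁱ⁾ ∥ F⁽ʲ⁾ (responder
first, partner-half feature names suffixed `_p`).  The representation is
deliberately asymmetric: F⁽ⁱ'ʲ⁾ ≠ F⁽ʲ'ⁱ⁾ and X_ij ≠ X_ji in general, so a
fully measured N-organism community yields N(N−1) samples.  Traits must be
structural (derivable from genomes/annotations) and independent of the
measured responses.

Label rules map numeric responses to two classes:

* **sign** — negative vs. nonnegative; a response of exactly 0 is
  nonnegative (neutral coculture counts as "not harmed").  An optional
  tolerance treats |X| below it as zero; the simulation pipeline sets it
  to 1e−6 because the discretized batch solver leaves O(1e−13) substrate
  residues that would otherwise flip sign labels (see below).
* **cutoff c** — strong (X > c) vs. weak (X ≤ c); the boundary value is
  weak.  A fold-change cutoff of 2 is the convention for growth-rescue
  panels.
* **binary** — passthrough for survival-style data.

Missing responses (NA) simply drop the pair from the dataset; an explicit
manifest of included ordered pairs accompanies every assembled dataset.

## Random forest

Binary features make the trees simple: every split sends feature value 0
left and 1 right, no threshold search.  Each of the nTree trees draws a
bootstrap of the full training set (sampling rows with replacement — the
pairing of X_ij with X_ji constrains only cross-validation splits, not the
bootstrap) and grows greedily by Gini impurity decrease over mTry features
drawn without replacement at each node, stopping at purity, at fewer than
min_node samples, or when no sampled split reduces impurity.  Defaults
nTree = 500, mTry = ⌊√(2n)⌋, min_node = 1 mirror the classical
randomForest settings, which are near-optimal for this kind of data.

Deterministic tie-breaks replace the reference implementation's random
ones: equal-gain splits take the lowest feature index, and a forest vote
fraction of exactly 0.5 resolves to the negative class.  One seed expands
into an independent PCG64 stream per tree, so enlarging the forest never
reshuffles earlier trees.  Models serialize to versioned JSON
(per-node split feature, class counts, children; per-tree in-bag counts)
and round-trip bit-exactly.

Evaluation is out-of-bag: for each training sample, only the ~e⁻¹ ≈ 37% of
trees whose bootstrap missed it vote.  Reported metrics are balanced
accuracy [TP/(TP+FN) + TN/(TN+FP)]/2 and the ROC/AUC obtained by sweeping
the OOB positive-vote fraction as the classification threshold.  The AUC
is computed as an integer trapezoid sum divided once, so it equals the
concordant-pair (Mann–Whitney) statistic exactly, ties counted half.
Global variable importance is OOB permutation importance (mean decrease in
accuracy), averaged over all trees; features a tree never splits on score
exactly zero for that tree.

## Feature contributions and mechanism ranking

For one sample and one tree, every node on the root-to-leaf path that
splits on feature f contributes the local increment Y_child − Y_node to f,
where Y is the node's positive-class fraction of in-bag training samples.
The increments telescope to Y_leaf − Y_root.  Averaging per-tree totals
over the *counted* trees (OOB trees for a training sample; all trees for a
new sample) gives φ_f with the exact additivity identity
baseline + Σφ = mean leaf positive fraction.  The ensemble-average formula
can alternatively divide by the total tree count while counting only OOB
paths; that variant is exposed as `denominator="total"` for sensitivity
checks but breaks additivity, so the counted-tree denominator is the
default.

A candidate mechanism maps to one responder-half and one partner-half
feature; its net contribution is the sum of the two φ values.  Candidates
sort ascending and are read from the negative end for mechanisms of
negative outcomes (competition: both-halves uptake features of a
metabolite) and from the positive end for facilitation (responder uptake ×
partner secretion).  Ties order alphabetically.  Candidates whose features
are 0 in both halves of the sample are still ranked but flagged as
zero-presence.  The quality measure is the 1-based rank of the first true
mechanism; uniformly random querying without replacement needs
(n_candidates + 1)/(n_true + 1) queries in expectation, which serves as
the analytic baseline (cross-checked by permutation sampling).

## Evaluation protocols

Learning curves use the training fractions
r = 0.05, 0.1, 0.2, …, 0.9, 0.95 with at least 10 repeats per fraction;
every split operates on unordered pairs so X_ij and X_ji never straddle
the train/test boundary, and a split that isolates one class is redrawn
(up to 100 times).  The curve reports the median held-out balanced
accuracy per fraction.  The community-size sweep repeats the whole curve
on random organism subsets (c = 10, 20, …, truncated to N; subsets of
different draws may overlap) and reports per-size median curves.  For rare
classes, balanced-subsample training keeps all rare rows plus an equal
draw of majority rows per repeat and reports per-repeat OOB balanced
accuracies and their median.

## The toy dFBA simulator

Each organism is a linear-pathway stoichiometric model: exchange reactions
move external metabolites in (flux < 0) or out (flux > 0) of a shared
batch pool, a conversion reaction turns each growth substrate into biomass
precursor at a per-organism yield (uniform 0.08–0.12 gDW/mmol), optionally
co-producing γ = 0.5 mmol of a by-product per mmol substrate, and the
biomass reaction drains the precursor.  "Decoy" uptake exchanges are
structurally present (and hence 1 in the trait vector) but connect to no
pathway, so steady state pins their flux to zero — they blur
trait-similarity baselines without touching the dynamics.  FBA maximizes
the biomass flux subject to S·v = 0 and bounds via `scipy.optimize.linprog`
(HiGHS); v = 0 is always feasible, so the LP cannot fail on valid models.

The batch stepper (forward Euler, dt = 0.1 h, up to 240 steps,
Vmax = 10 mmol/gDW/h, initial biomass 0.01 gDW, 10 mmol of each substrate)
caps each organism's uptake of metabolite m at
min(Vmax, amount_m/(demanding biomass · dt)) — a scarce pool is split
among demanders in proportion to biomass ("proportional" sharing;
"sequential" draw-in-list-order is available as an alternative.  Who
demands is decided structurally, by uptake capability).  After each step,
biomass updates as B ← B(1 + μ·dt) and pools as m ← m + Σ v·B·dt; the
forward-Euler choice makes the bookkeeping identity
final = initial + Σ transfers hold to rounding (tested at 1e−6), and
biomass gain equals yield × substrate consumed exactly.  Runs stop early
once every growth rate falls below 1e−9/h.  Because the per-organism LP
depends only on the effective caps, the solver reuses the previous
solution whenever the caps repeat bitwise — a pure speed optimization.

A pairwise campaign runs N monocultures and C(N, 2) cocultures from the
identical initial medium, producing the relative-yield matrix (diagonal =
monoculture biomass; organisms whose monoculture fails to grow get NA
responses) and the mechanism ground truth read from fluxes: a metabolite
is **contended** for (i, j) if both organisms took it up in the same step,
and **facilitative** for (i, j) if j secreted and i took it up in the same
step, with a 1e−9 mmol/step mass threshold guarding LP float noise.
Degenerate alternative optima are avoided by construction (every generated
model has a unique optimal flux pattern), and truth depends only on
exchange fluxes.

### Community scenarios

* **single_competition** (default: 20 organisms, 50 metabolites, groups of
  4 sharing one substrate, 6 decoys each): a pair either competes over
  exactly one metabolite or not at all, yielding ≈60 single-mechanism
  negative responses out of 380 — the scaled-down stand-in for a
  genome-scale community campaign.
* **cross_feeding**: private substrates plus planted producer→consumer
  chains; chains reuse a small pool of by-products (default 2, think
  common fermentation products) so the secretion/uptake traits generalize
  across pairs rather than being unique to one chain.
* **mixed**: competition groups over ~60% of organisms, chains among the
  rest.

Decoys are drawn from metabolites unused as substrates or by-products, so
trait conjunctions remain faithful to the planted design, while Jaccard
similarity between trait vectors becomes an imperfect predictor — as it is
for real genomes.

What the simulator does *not* emulate: genome-scale network redundancy,
Michaelis–Menten uptake kinetics, lag phases and death, spatial structure,
pH/inhibition effects, and measurement noise.  Passing tests on these
communities therefore demonstrate the correctness of the pipeline's
machinery and its behavior when a clean mechanistic signal exists — not
performance on any real dataset.

### Auxotroph panel generator

The rule-based generator emulates engineered amino-acid auxotroph panels:
each of 14 strains (91 unordered pairs, 182 ordered responses at the
default size) lacks exactly one of 14 biosynthesis capabilities, knockouts
cycling through n_strains/2 amino acids so same-knockout pairs exist and
cannot rescue each other.  Fold changes are log-normal: around an
amino-acid-specific rescue magnitude (log-scale spread 0.6 around a mean
of 8) when the partner possesses the responder's missing capability, and
around 1.25 otherwise, with per-pair noise sd 0.3.  The per-amino-acid
magnitudes encode unequal biosynthetic costs, which is what makes
responder-half features (which amino acid is missing) more informative
than partner-half features (who provides it) — the asymmetry such panels
show in practice.

## Numerical choices and degenerate inputs

* Exact-zero responses are nonnegative; exactly-at-cutoff fold changes are
  weak; vote fraction exactly 0.5 is the negative class.
* Contribution additivity is exact up to float summation (tested at
  1e−9); zero-participation features have φ = 0 exactly.
* Single-class training sets, empty in-bag sets, all-zero Jaccard inputs,
  single-class ROC inputs, failed monocultures (B_ii ≤ 0) and empty truth
  sets raise errors (or, for monocultures and truths, flag/skip) rather
  than returning silent defaults.
* Samples that are in-bag for every tree are flagged as uncounted in OOB
  summaries, not errored.

## Problem sizes

The default verification workloads are sized for a laptop-class single
CPU: the standard community (20 organisms, 50 metabolites) runs 210 batch
simulations and trains a 500-tree forest on 380 composite samples in a few
seconds; learning-curve and null-control checks use 12–16-organism
communities with 100–150 trees.  All stochastic stages draw from named
substreams of one global seed, so every result in the test suite and the
acceptance script is reproducible bit for bit.
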