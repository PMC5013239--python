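# Methods

## Problem setting

Given a genes × samples expression matrix with two class labels, find a
small subset of genes on which a classifier separates the classes well. The
package implements a wrapper approach: candidate subsets are proposed by a
discrete stochastic search and scored by the classifier itself, so gene
interactions are taken into account (unlike per-gene filter scores). The
search space is first reduced by a filter step, because wrapper evaluation
at genome scale is computationally hopeless and most genes are uninformative.

## Pipeline

1. **Normalisation.** Every gene row is z-scored across samples (population
   standard deviation; zero-variance rows map to zero). z-scoring removes
   per-gene scale so that neither the t-statistics' ordering nor the RBF
   kernel is dominated by high-expression genes.
2. **Prefilter.** A pooled-variance two-sample t-test per gene, two-sided;
   genes ranked by ascending p-value (ties broken by input position, for
   deterministic reports) and the top k = 50 kept. k fixes the particle
   length of the search. A Welch option exists but is not the default: the
   classical protocol this package reproduces uses the traditional Student
   test. Degenerate rows with zero pooled variance get t = 0, p = 1.
3. **Search.** One of three optimizers over {0,1}^50, maximising the
   composite fitness below.
4. **Reporting.** Repeated runs with consecutive seeds; best / mean /
   population-std of per-run best accuracies, mean subset size over all
   runs, and per-gene selection counts over the runs that attained the
   maximum accuracy.

The filter is computed once on **all** samples, before LOOCV. This is how
the protocol we reproduce operates, and we kept it; note it leaks test-fold
information into the gene ranking, so the LOOCV accuracies are optimistic
relative to a fully nested protocol. This is a known property of the
protocol, not of the implementation.

## The objective

For a subset of size k ≥ 1 with LOOCV accuracy `acc` on the percent scale:

```
fitness = w_acc * acc + w_size * k_ref / k,   w_acc = 0.6, w_size = 0.4, k_ref = 50
```

LOOCV trains n independent SVMs (C-SVC, RBF kernel, C = 1,
γ = 1/k — the libsvm defaults), each on n−1 samples, and scores the held-out
sample; the value is deterministic given data and subset, so evaluations are
memoised by bitstring. A training fold containing a single class (possible
only when a class has exactly one sample) predicts that sole class, keeping
LOOCV total. The empty subset receives a −∞ sentinel: it is recorded with
accuracy 0 and can never displace a non-empty personal or global best.

**Accuracy scale.** `acc` enters in percent (0–100). On the 0–1 scale the
size term (up to 20 for a singleton) would dominate the objective outright
and the search would collapse to single-gene subsets regardless of accuracy.
Percent scaling is the only reading under which accuracy "takes precedence"
for subsets in the ~10-gene range the protocol reports. Even so, the size
term is aggressive for very small subsets: a single gene with accuracy
above 73.3% outscores a five-gene subset at 100% (0.6·73.3 + 20 > 64). See
*Known limitations*.

**Implementation note.** The inner LOOCV loop calls scikit-learn's
low-level libsvm bindings directly rather than constructing an `SVC`
estimator per fold; predictions are identical (a cross-check against
per-fold `SVC` fits is part of the test suite) and the loop is ~25× faster,
which is what makes repeated-run protocols affordable on one CPU. A
`backend="svc"` switch selects the plain estimator route.

## Optimizers

All three maximise an arbitrary fitness on fixed-length bitstrings, run a
fixed iteration budget (no early stopping), draw every random number from a
single per-run `numpy` generator in a fixed order, and count exactly
`swarm_size` evaluations at initialisation plus `swarm_size × iterations`
after. Positions are initialised Bernoulli(0.5). Global-best ties retain
the incumbent, which makes trajectories reproducible and monotone.

**BQPSO** (the subject of the package). Per iteration: `mbest` = per-bit
majority of personal bests (ties uniform at random, fresh each call); per
particle, local attractor = one-point crossover of `pbest_i` and `gbest`
with a uniform cut and a uniformly chosen offspring (a multipoint/two-point
mode is available by configuration); jump length
`b = ⌈ce · d_H(x_i, mbest) · ln(1/μ)⌉` with `μ ~ U(0,1)` drawn on the open
interval; mutation flips each attractor bit independently with probability
`min(b/l, 1)`. The flip semantics give expected displacement `b` and make
displacement Binomial(l, Pr) — the alternative "set bit to a fresh random
value" would halve the expected displacement and was rejected. The
contraction–expansion coefficient is constant (default 1) over all
iterations. When positions, personal bests and the global best all coincide
the update chain is the identity: full convergence is an absorbing state.

**BPSO** (baseline). Canonical sigmoid binary PSO: real velocities with
inertia 0.5 and cognitive/social coefficients 2, clamped to ±6, initialised
uniformly in [−6, 6]; bit j is set to 1 when a uniform draw falls below
sigmoid(v_j).

**GA** (baseline). Generational: raw fitness-proportional roulette (scores
are shifted only if negatives are present; −∞ sentinels get zero weight;
an all-zero weight vector falls back to uniform selection — this covers the
all-equal non-positive population), one-point crossover with probability
0.9, per-bit mutation 0.04, elitism 1. Tournament selection is available by
configuration. The full population, elites included, is re-evaluated each
generation so the evaluation budget matches the swarm loops; the objective
is deterministic, so this changes nothing but the bookkeeping.

## Synthetic data

The generator emulates the structure the wrapper assumes: `n_informative`
planted genes whose class means sit at ±effect/2 (in units of the noise sd),
all other genes i.i.d. Normal(0, sd²), labels balanced per the spec'd class
sizes, planted rows scattered at seeded-random positions and returned as
ground truth. Defaults — 500 genes, 20+20 samples, 5 planted genes, effect
size 2, sd 1 — give a dataset on which the t-filter retains all planted
genes with high probability and an SVM on the planted subset is usually
perfectly separable under LOOCV, while keeping a full 2,020-evaluation run
around 5–10 s on one CPU.

What it deliberately does **not** model: gene–gene correlation, heavy tails,
batch effects, probe-level artifacts, class-dependent variance. Passing
tests on this generator demonstrate that the machinery (filter, objective,
searches, reporting) behaves as specified under the assumed model — not that
the method recovers biologically true genes from real microarrays.

## Reporting conventions

- Standard deviation over repeated runs is the **population** formula
  (denominator n). The sample convention would differ slightly; the tests
  pin the choice by recomputation.
- Mean subset size averages over **all** runs of an arm; selection
  frequencies count only the runs that attained the arm's maximum accuracy.
- Run r of an arm uses seed `base_seed + r`, so every report number is a
  pure function of (data, configuration, base seed); reports serialise to
  JSON (and TSV tables) and round-trip losslessly.

## Numerical choices and degenerate inputs

- `μ` is drawn on the open interval (0,1), so `ln(1/μ)` is finite; the
  ceiling is applied to the full product `ce · d_H · ln(1/μ)`.
- `Pr = b/l` is capped at 1; `b = 0` exactly when a particle sits on
  `mbest`.
- Crossover on length-1 strings returns one parent uniformly at random.
- Rank ties (equal p-values) break by original gene index; gbest ties keep
  the incumbent.
- NaN or +∞ fitness raises immediately; only the −∞ empty-subset sentinel
  is tolerated.

## Known limitations

- **Size-term dominance for tiny subsets.** Because the size bonus is
  convex in 1/k, single- or two-gene subsets with moderate accuracy can
  outscore larger perfectly-accurate subsets (threshold: one gene above
  73.3% accuracy beats five genes at 100%). On data where individual genes
  classify moderately well, the objective's true optimum may be a one-gene
  subset with sub-maximal accuracy; reported "best accuracy" is the accuracy
  of the fitness-best subset, not the best accuracy seen.
- **Selection bias.** With ~40 samples and a 50-gene search space, many
  noise-gene combinations reach 100% LOOCV by chance; best subsets therefore
  mix truly informative genes with sample-specific noise genes, and
  selection frequencies across repeated runs are a more reliable signal of
  gene relevance than membership in any single best subset.
- **Needle-in-haystack landscapes.** On structureless objectives (i.i.d.
  random fitness tables) success probability equals state coverage, and any
  convergent search — these three included — covers fewer distinct states
  than uniform random sampling. That is a property of convergent
  metaheuristics, not a defect; on structured objectives (OneMax, the gene
  selection fitness) all three converge reliably.
- LOOCV accuracy has granularity 100/n; with small n, ties between subsets
  are common and the size term decides.
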