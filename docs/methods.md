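# Methods

## Model

A random forest `RF = {T_1, …, T_V}` is grown on an N×P matrix with binary
labels. Tree `T_z` sees `n` of the `N` cases (subsampled without
replacement by default, `n = ⌈0.632·N⌉`) and draws `m = max(1,
round(feature_fraction · P))` candidate features at each split. The indicator
`F_{j,z} = 1{root(T_z) = X_j}` is Bernoulli(`p_root`); under the global null
every feature is exchangeable with every other, and the two-stage draw
(m of P without replacement, then the best of the m, which under the null is
a uniform pick) gives

    p_root = (1/m) · (1 − Π_{g=1..m} (P−g)/(P−(g−1))) = 1/P.

The implementation evaluates the product form and asserts the telescoped
value `1/P` at run time; a two-stage Monte-Carlo sampler in the test suite
confirms the identity independently. Note the grouping matters: multiplying
the product by `1/m` *before* taking the complement does not produce a
uniform-null probability, so that reading is rejected.

The test statistic is `F_j = Σ_z F_{j,z}`. Trees are not independent — each
resamples from the same cases — so `F_j` is modelled as a sum of V
exchangeable, pairwise-correlated Bernoulli trials rather than a plain
binomial. The p-value is the one-sided upper tail `P(F ≥ F_j)`; only
over-selection is a discovery. All P features form the hypothesis family
(never-selected features enter with p = 1) and are adjusted by
Benjamini–Yekutieli, whose `c(M) = Σ 1/i` inflation keeps FDR control under
the arbitrary dependence created by `Σ_j F_j = V`.

## The correlated binomial null

Two formulations of an exchangeable correlated binomial on `k = 0..V` are
implemented, selected by `model=`:

**witt (default).** Joint success moments decay geometrically:
`E[X_1⋯X_j] = p·r^(j−1)` with `r = p + ρ(1−p)`. This is the unique
geometric-moment family matching the marginal `p` and pairwise correlation
`ρ`, and binomial inversion of the moment sequence collapses to a closed
form:

    P(F=k) = C(V,k) · p · r^(k−1) · (1−r)^(V−k)   (k ≥ 1)
    P(F=0) = 1 − (p/r)·(1 − (1−r)^V)

Evaluated in log space, it is exact at ρ = 0 (plain binomial), degenerates
correctly at ρ → 1 (mass p at V, 1−p at 0), is provably non-negative on the
whole parameter box, and preserves mean `Vp` and variance
`Vp(1−p)(1+(V−1)ρ)` exactly — the test suite verifies both numerically
rather than assuming them. V up to several thousand is unproblematic.

**kuk.** The q-power model for exchangeable binary data: the probability
that any `j` specified trials all fail is `q^(j^γ)`, `q = 1−p`, with
`γ ∈ (0,1]` solved from `ρ = (q^(2^γ) − q²)/(pq)`. The pmf is the
inclusion–exclusion sum `P(F=k) = C(V,k) Σ_i (−1)^i C(k,i) q^((V−k+i)^γ)`,
which cancels catastrophically in double precision at large V; it is
evaluated in multi-precision arithmetic (`precision` bits, default 1024).
The mean `Vp` is preserved; the variance follows the model's own
overdispersion and is not forced to the witt expression.

Every spec is validated at construction by a full-support scan: masses below
−1e−12 or a total off 1 by more than 1e−8 raise a degenerate-distribution
error instead of silently clipping (only |mass| < 1e−12 round-off is
clipped). In practice only the kuk path can trip this, when the requested
precision is too low for the alternating sum.

## Choice and effect of ρ

The tree-to-tree correlation is taken as known from the sampling design, not
estimated: the default is the case-overlap fraction `ρ = n/N` (≈ 0.63 for
the default subsample size), user-overridable per run. This is a
deliberately conservative upper bound, and its consequence should be
understood: any exchangeable model at ρ ≈ 0.6 concentrates ~98% of its mass
at F = 0 and spreads the rest near `rV`, so upper-tail p-values plateau
around `1 − P(F=0)` for any realistic frequency and BY-significant sets are
usually empty. The default therefore gives a test that is valid but nearly
powerless — appropriate when the cost of a false biomarker is high. With
`rho=0` the null is the independent-trees binomial, whose empirical
operating characteristics are good (pure-noise selection stays well under
α; see below) and which is the setting to use when a non-trivial selection
set is wanted. Both extremes, and anything between, are one flag apart; the
ranking of features (by p-value, then frequency) is essentially invariant
to ρ because the tail is monotone in F either way.

## Interactions

`enumerate_root_paths` walks each tree and emits the ordered split-feature
tuples along every chain of exactly K internal nodes starting at the root.
Tuples containing a repeated feature are discarded (X⊗X is a main effect,
not an interaction). Tuples are canonicalized by sorting (the interaction is
symmetric; an `ordered=True` diagnostic mode keeps direction), and each
distinct tuple counts at most once per tree, preserving the V-trial
Bernoulli framing; trees shallower than K simply contribute zero. Degenerate
single-leaf trees are excluded from the trial count exactly as for main
effects.

Null probabilities extend the root argument down the chain: after the root
consumes one feature, the next split draws from P−1 remaining, etc. A K-way
interaction can terminate in at most `2^(K−1)` depth-K nodes of a binary
tree, whence the `1/2^(K−1)` normalizer:

    p_2way = ½ · (1/P) · (1/(P−1))
    p_Kway = 1/2^(K−1) · Π_{k=1..K} 1/(P−k)    (K ≥ 3)

Two caveats are inherited deliberately rather than corrected. First, the
two formulas disagree at K = 2 (the general form starts its denominators at
P−1, the pair form at P); the pair form governs K = 2 and the general form
K ≥ 3. Second, dividing by the path-multiplicity count *lowers* the null
probability and therefore makes the test *less* conservative, not more —
the opposite of what "accounting for both ways" suggests. Both choices are
kept as the method defines them so that results are comparable with it, and
are documented here instead of silently altered.

The FDR family for interactions defaults to the tuples actually observed in
the forest: the full `C(P,K)` family is astronomically large, every
unobserved tuple has p = 1, and including them only explodes BY's `c(M)`
factor. The full-family adjustment is available via `universe="full"` for
users who want the stricter reading (its `c(M)` uses the asymptotic harmonic
expansion above 10⁶ terms, accurate to ~1/(12M²)).

## Synthetic data

The bench generates what it tests on: `X` ~ i.i.d. N(0,1) (N×P), a sparse
coefficient vector, `y ~ Bernoulli(expit(Xβ))`. Defaults: N = 100 subjects,
effect size 2.0, genome sizes and seeded-feature counts from the standard
grid (P ∈ {100, …, 2000}, 5–100 seeded, forests of 500/1000 trees, a third
of features per split). The pure-noise scenario sets β = 0 so `y` is an
independent fair coin and every selection is a false positive. The
interaction scenario seeds 4 mains plus all 6 pairwise products
(standardized so both enter at comparable scale) among P = 30 features.

What the generator does *not* emulate: correlated co-expression blocks,
heavy-tailed or count-distributed expression, batch effects, or class
imbalance. Passing benches therefore demonstrate calibration and power under
clean independence, not robustness to real transcriptomic structure; on real
data the ρ adjustment and BY correction are the safety margins.

Scoring per replicate: model size |selected|; precision TP/(TP+FP)
(1 − false-discovery proportion; 1.0 for empty-selected/empty-truth, NaN
for empty-selected/non-empty-truth); recall TP/(TP+FN); test error as
held-out misclassification rate (the agreement-count phrasing of the metric
is treated as a misprint for its complement); noise rate = selected noise
features over P, which under pure noise is the fraction of the genome
selected.

## Numerical and procedural choices

- Result ordering is fully deterministic: p-value ascending, then frequency
  descending, then feature index; stable mergesort throughout.
- The CV grid for the feature fraction is `{i/(folds+1)}`, stratified folds,
  ties to the smallest proportion.
- `quantile(q)` is the smallest k with `cdf(k) ≥ q` (with 1e−15 slack
  against float round-off), so the critical-value phrasing `F_j > Q_{1−α}`
  and the p-value phrasing agree feature-by-feature.
- Forest training is delegated to scikit-learn (per-split feature
  subsampling; one seeded `DecisionTreeClassifier` per row subset for the
  without-replacement mode, `RandomForestClassifier` for bootstrap); the
  split-structure adapter accepts any learner exposing per-node split
  feature, children and leaf flags, and round-trips through JSON.
- BY/BH adjustment delegates to statsmodels for same-size families; the
  extended-family step-up is the only hand-written multiplicity code and is
  cross-checked against statsmodels where they overlap.

## Problem sizes used by the benches

The packaged acceptance bench runs the pure-noise grid at P ∈ {100, 500}
with 20 replicates per size (forests of 500 trees, N = 100); larger genomes
(1000, 2000) behave identically in spot checks and are supported by the same
code path. Property benches (rank recovery, power monotonicity over effect
sizes {0.5, 1, 2, 4}, refit error) use P = 100 with 20 replicates. These
sizes are the package's declared study conditions.

## Known limitations

- Binary outcomes only; no missing-data handling (inputs are validated and
  rejected instead).
- Root-anchored screening favours large-impact features; features that only
  split deep in trees are invisible to it (precision over recall by design).
- The correlated null treats ρ as exactly known from the sampling design;
  no data-driven ρ estimation is offered.
- The kuk model at V ≳ 1000 is slow (multi-precision alternating sums);
  witt is the practical default at forest scale.
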