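# Methods

`causalbn` implements a hybrid causal-discovery pipeline for categorical
survey data — constraint-based initialisation, score-based refinement, and
do-calculus effect estimation — together with the synthetic machinery needed
to validate every stage against a known ground truth.

## Data model

All analyses consume a `SurveyTable`: an `n × p` matrix of 0-based level
codes over declared `VariableSchema`s (2–3 ordered levels each), optional
nonnegative row weights, and a reserved missing sentinel that is never a
level. Only complete-case analysis is supported; no imputation is attempted.
Raw numeric items are discretized through closed-interval bins declared in
the schema file — e.g. a 0–10 intent scale maps through
Low = [0, 3], Moderate = [4, 6], High = [7, 10]. Bins may not overlap and
must cover the declared range, so discretization is total, deterministic and
monotone. Non-integer raw values inside the range are binned by the same
closed intervals; values between bins (e.g. 3.5 on an integer-intended
scale) are rejected rather than silently rounded.

## Feature screening

A single weighted-least-squares regression `Y_i = a + X_i b + u_i` of the
outcome (on its raw/ordinal scale) on reference-coded indicators of every
candidate ranks variables by the smallest two-sided p-value among their
indicator columns (ties broken by schema order). The p-values are
deliberately unadjusted: the stage is a screen, not an inference, and
substantive selection criteria (literature support, intervenability) are
judgments the user expresses through the final variable list.

## Conditional independence and PC

Independence testing uses the G² likelihood-ratio statistic on the
stratified contingency table, `df = Σ_strata (|x|−1)(|y|−1)` over strata
with positive totals (floored at 1). Non-uniform weights enter as weighted
cell counts rescaled to the effective sample size `(Σw)²/Σw²`. Defaults:
α = 0.05 and conditioning sets up to size 3 — with 45 variables an unlimited
depth is neither feasible nor statistically sensible at survey n.

The skeleton phase is the *stable* PC variant: neighbour sets are frozen at
the start of each conditioning depth and pairs are processed in sorted name
order, so the output is invariant to column order. Separating sets are
recorded at first acceptance. Unshielded colliders are oriented from the
recorded sets; conflicting collider orientations are resolved
first-come-first-kept with a logged warning, and any orientation that would
close a directed cycle (possible on finite samples) is skipped. Meek's
rules R1–R3 are applied to closure. With background knowledge
(forbidden/required edges, tiers) the closure is conservative: it never
orients an inadmissible edge, at the price of occasionally leaving a
compelled edge undirected. Expert priors ship as a default tier constraint
forbidding edges into demographic variables from non-demographic ones.

`dag_extension` produces a consistent extension by Dor–Tarsi sink
elimination with seed-shuffled candidate order, honouring constraints, and
raises when none exists. Because a finite-sample PC pattern need not be
extendable, the search initialiser falls back to a greedy admissible
orientation in that case — the chain only needs a legal starting state.

## qNML score

The local score of child `X` with parents `Pa` is the quotient of
multinomial normalized-maximum-likelihood codelengths,

    s(X | Pa) = logNML(counts of {X} ∪ Pa flattened) − logNML(counts of Pa flattened),

with `logNML(c) = Σ_k c_k ln(c_k/n) − ln C(n, K)`. The parametric
complexity `C(n, K)` is computed *exactly* by the linear-time recurrence
`C(n, K) = C(n, K−1) + n/(K−2)·C(n, K−2)` from the closed binomial sum at
K = 2, evaluated in log space so large alphabets cannot overflow. No
asymptotic approximation is used: exactness at survey-scale n is cheap and
removes a knob.

Zero-count cells are dropped before scoring, i.e. the alphabet is the
observed support. This choice makes the score invariant to structurally
empty configurations — an all-constant parent contributes nothing — while
exact score equivalence across Markov-equivalent DAGs is preserved (the
codelength of a variable subset is a function of that subset alone, and
equivalent DAGs differ by covered edge reversals whose scores telescope
through the same subsets). At the intended scale (thousands of rows, ≤ 3
levels, ≤ 4 parents) every configuration is typically observed and the
choice coincides with the full-cell-set definition. Scores assume i.i.d.
multinomial counts; non-uniform sampling weights are ignored by the score
with a logged notice.

## Structure MCMC

The sampler is Metropolis–Hastings over DAGs with stationary density
∝ exp(network score). A proposal draws uniformly among currently valid
single-edge moves (add / delete / reverse preserving acyclicity, the parent
cap, and forbidden/required edges); the Hastings correction is the ratio of
valid-move counts, which makes the chain exactly reversible — verified
analytically in the tests and empirically by uniform visiting frequencies
under a constant score. Structure-MCMC was preferred over order-MCMC
because its stationary law is directly comparable with exact enumeration on
small instances; an order-MCMC backend is a possible extension.

Defaults: `max_parents = 4` (bounding the flattened family table at
3⁵ = 243 cells), 200,000 iterations with 50,000 burn-in for 45-variable
problems (config-overridable; the tests and the acceptance script use
15,000/5,000 on 10-node problems, which already mixes well there). The
reported structure is the best-scoring DAG visited; post-burn-in
edge-selection frequencies are exported as a stability diagnostic, since a
single DAG understates structural uncertainty.

## Interventions

CPTs are estimated by additive smoothing, `(count + κ)/(config + κ·levels)`
with κ = 1 by default; smoothing keeps all probabilities positive and hence
all odds ratios finite, and an unobserved parent configuration yields a
uniform conditional. Interventional queries follow the truncated
factorization: incoming edges of the intervened variable are removed, it is
clamped, and the target marginal is computed by exact variable elimination
(greedy smallest-factor order) over the ancestors of the target in the
surgered graph. The interventional odds ratio of a query contrasts the
target's high-vs-low odds under the two forced evidence settings:

    OR = [P(Y=hi | do(X=to)) / P(Y=lo | do(X=to))] /
         [P(Y=hi | do(X=from)) / P(Y=lo | do(X=from))].

Swapping the two do-levels maps OR to 1/OR exactly. Default contrasts pit
each lower outcome level against the top level (Low→High primary,
Moderate→High secondary for a 3-level outcome).

Uncertainty: a nonparametric bootstrap with the structure held fixed — rows
resampled with replacement (weights as resampling probabilities when
non-uniform), CPTs refit, OR recomputed per replicate; replicates are
evaluated in a single batched elimination pass. The 95% CI is the
percentile interval and the p-value the two-sided tail probability of the
log-OR against 0 with the (1 + count)/(B + 1) correction, so the smallest
attainable p is 2/(B+1). Structure uncertainty is deliberately excluded
from these intervals — they answer "given this graph, how certain is the
effect", and the edge-frequency export covers the other question. Scan
p-values are reported unadjusted (each query stands alone at the 5% level);
the CLI additionally emits a Benjamini–Hochberg column for transparency.

The causal-factor scan enumerates ancestors of the target — any variable
can be the target, which is how causes-of-cause questions are answered from
the same fitted model — and reports non-ancestors as non-causal.

## Correlational baseline

The contrast model is a maximum-likelihood multinomial logit of the outcome
on the same reference-coded discretized table, with the schema reference
level as baseline and Wald z tests per coefficient. A variable is a
*significant correlate* if any of its logit p-values is below 5%,
unadjusted — the conventional screen. Coefficients with |b| > 15 or
non-finite standard errors are flagged as separation-affected; when the
Hessian is singular the fit falls back to quasi-Newton and, failing that,
reports coefficients with p = 1 rather than fabricating standard errors.
`compare_reports` cross-tabulates correlational against causal significance
per variable.

## Synthetic ground truth

Random truths: a uniform topological order with independent edges at
`edge_prob` (in-degree capped), and CPTs built by exponentially tilting a
symmetric-Dirichlet base distribution with a fixed random unit-norm logit
direction per parent configuration, scaled by `effect_strength`. At
strength 0 children decouple from parents; the default 2.0 produces
per-edge effects strong enough to be detectable at n ≈ 5,000 without being
deterministic — "strong effects" in the recovery experiments means exactly
this setting.

The 45-variable fixture mirrors a published vaccine-hesitancy codebook
(variable names, levels, causal-factor categories) with a hand-encoded
plausible topology: beliefs in social responsibility, anticipated regret
and vaccine unsafety plus early-adopter willingness are the direct parents
of vaccine intention; demographics sit upstream and never receive edges
from non-demographic variables. CPTs come from a deterministic softmax
recipe over hard-coded signed edge weights with centred level scores; the
social-responsibility weight (2.6 on the logit scale) is deliberately the
largest, giving a true Low→High interventional OR of ≈ 19 that dominates
every other single-shift query. The fixture is a test harness with known
truth, not a reproduction of any empirically learned network.

What the generator does *not* emulate: panel raking weights, item
nonresponse mechanisms, respondent-level heterogeneity, latent confounding,
and measurement error. Passing recovery and coverage tests therefore shows
the algorithms are correct and well calibrated under the stated sampling
model — not that a real survey's learned graph is right.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen once: structure
recovery on 10-node, 3-level truths (edge probability 0.3, strength 2.0,
n = 5,000, 20 seeds); sampler checks on the 25 three-node DAGs (250,000
kept samples, thinned ×5 to decorrelate draws for the goodness-of-fit
comparison); do-calculus oracle checks on 100 random ≤ 4-node networks at
tolerance 1e-10; bootstrap coverage on the fixture at the survey size
n = 2,477 with B = 500 across 200 replicate datasets; calibration with 500
null simulations. CPT validation requires rows to sum to 1 within 1e-12;
score-equivalence assertions use 1e-9 on sums of ~1e4-magnitude
codelengths. All randomness flows through seeded `numpy` generators;
identical seeds reproduce every table, chain and interval bit-for-bit.

## Known limitations

- Orientation with background knowledge omits Meek's R4, so some compelled
  edges may stay undirected in constrained CPDAGs.
- The bootstrap CI ignores structure uncertainty by design.
- Laplace smoothing (κ = 1) trades a small attenuation bias for guaranteed
  finiteness. For moderate effects the bias is negligible (the designated
  coverage experiment estimates a true OR of 2.08 with mean 2.075 and 94.5%
  CI coverage), but for extreme odds ratios it matters: the fixture's
  dominant social-responsibility effect (true OR ≈ 19) is estimated around
  17.3 at n = 2,477, and percentile intervals inherit the bias (≈ 89%
  coverage). Very large estimated ORs should be read as order-of-magnitude
  statements, and smaller κ may be passed where bias matters more than
  variance.
- qNML scoring ignores sampling weights (the score's i.i.d. assumption);
  weighted analyses affect the G² tests, WLS screen and bootstrap only.
- Exact variable elimination is practical because learned survey graphs are
  sparse; a dense 45-node graph with large treewidth would require
  approximate inference, which is out of scope.
- No latent-confounder discovery: ancestors are "causal factors" only under
  the assumption that all relevant confounders are measured.
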