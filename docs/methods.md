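# Methods

This note documents the models implemented in `ivambn`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want written down.

## Knowledge-graph modules

The input graph is a typed directed multigraph (genes/proteins/RNA,
processes, pathologies, chemicals) with labelled relations. Only causal
relations (`increases`, `decreases`, `regulates`) between gene-level
entities are retained; gene, protein and RNA entities for the same symbol
collapse onto one gene node, since downstream they must map onto expression
features. The analysis then restricts to the largest weakly connected
component.

**Markov clustering.** MCL iterates expansion (matrix power `e`), inflation
(elementwise power `r`), pruning and column renormalisation on the
column-stochastic flow matrix of the undirected view with self-loops added.
Defaults: `e = 2`, `r = 2`, prune entries `< 1e-5`, convergence when
`max |M_{t+1} - M_t| < 1e-8`, hard iteration cap 200 (non-convergence is an
error reporting the residual). Clusters are read off attractor rows;
overlapping attractor systems merge. The procedure is fully deterministic
and invariant to node relabeling (tested). Inflation controls granularity:
the bundled scenario uses `r = 4` so that a gene bridging two modules with
balanced attachments stays unclustered instead of being absorbed — at
`r = 2` MCL assigns every pendant vertex to some cluster and the
"unclustered gene" category of the downstream merge rule would be empty.

**Merge rule.** Genes outside any multi-gene cluster join a cluster when
they are adjacent (undirected — direction is deliberately ignored here, it
encodes causal orientation rather than affiliation) to exactly one; genes
touching several clusters, or none, become single-gene modules.

**Module graph.** An edge `M1 -> M2` exists iff some gene of `M1` reaches a
gene of `M2` by a directed path whose interior stays inside `M1 ∪ M2`. The
unrestricted "any directed path" rule makes almost every module pair
adjacent on realistic graphs and cannot produce a sparse acyclic module
graph, so the two-module restriction is the package's declared reading.
Edge support counts the simple paths inside the induced two-module
subgraph, capped at length 6 (configurable) to bound enumeration; edge
existence itself uses exact reachability. Remaining cycles are broken by
repeatedly deleting the cycle edge with least support (ties: lexicographic
on the module-id pair); removals are logged and returned.

**Enrichment.** Upper-tail hypergeometric per (module, gene set) against a
universe defaulting to the genes of the filtered graph, BH-adjusted across
all tests. A module is labelled by its most significant adjusted-significant
set, otherwise by its gene symbols — small modules (2 genes) typically lack
power and keep symbol labels, which is expected behaviour, not a failure.

## Expression preprocessing

Counts are normalised to `log2((c + 0.5) / (libsize + 0.5·G) · 1e6)`
(log-CPM; base 2 and pseudocount 0.5 are package defaults, configurable).
Case samples are standardised per gene against healthy controls of the same
study — the *abnormality score* `(x - mean_ctrl)/sd_ctrl` — so a score of
+2 means two control standard deviations above the control mean. Genes with
zero control variance are dropped with a warning.

Cross-study batch effects are removed with a parametric empirical-Bayes
location/scale adjustment: per gene the data are standardised against the
grand mean and the pooled *within-batch* variance, per-batch location
(`gamma`) and scale (`delta^2`) estimates are shrunk toward cross-gene
priors (normal for location, moments-matched inverse-gamma for scale) by
iterating the posterior-mean equations to `1e-6`, then removed. The
implementation agrees elementwise (max difference ~5e-7 on a 30×50
fixture) with the canonical Bioconductor implementation, which the test
suite invokes through `Rscript` as an independent oracle. Note a property
of the algorithm itself: per-gene post-adjustment batch means are equal
only up to the shrunken estimator noise (`O(1/sqrt(n_batch))`), not
exactly; only the systematic offset is removed.

## The heterogeneous-incomplete autoencoder

Each module's features are encoded by a linear encoder producing
`mu(x)` and `log sigma(x)` (clipped to ±5) from batch-normalised inputs
(per-feature mean/SD computed over observed training entries; categorical
features enter one-hot). Missing entries are mean-imputed *in normalised
space* (zeros) on the encoder input and masked out of the reconstruction
term, so they contribute no gradient.

Decoder heads per modality:

* **real** — Gaussian; mean `w·z + b_s`, learned log-variance `rho`;
* **ordinal** — thermometer likelihood with thresholds parameterised as
  `theta_1` plus cumulative softplus increments, which enforces strict
  monotonicity by construction;
* **categorical** — softmax logits `W·z + b_s`.

`b_s` is component-conditional: with a `K`-component Gaussian-mixture prior
(uniform weights, unit component covariance) the head intercept is the
`p(s|z)`-weighted mixture of `K` per-component biases, so mixture
components can shift likelihood parameters, as in the original
heterogeneous-VAE architecture. For `K = 1` everything reduces to the
classical VAE with the analytic regulariser. For `K > 1` the categorical
posterior over components is the closed-form softmax of
`-||mu(x) - m_k||^2 / 2` (no Gumbel-softmax sampling); its gradient
contribution through the decoder path is computed exactly, while the
regulariser treats the responsibilities as constants — at their closed-form
optimum the envelope theorem makes that exact too, and the full gradient is
verified against central finite differences in the test suite at ~1e-7
relative error.

**Training.** Adam (0.9/0.999), learning rate 0.01, minibatch 32, up to 500
epochs with early stopping (patience 50 on the epoch-mean training ELBO,
best parameters restored), single reparameterisation draw per step.
Training is bit-reproducible given the seed. Divergence (non-finite ELBO)
aborts with diagnostics.

**Initialisation.** Real-feature loadings start at ~1 (inputs are
standardised) and the decoder log-variance at −3. This matters: for
few-feature modules the ELBO is *flat* along the trade-off between loading
magnitude and decoder noise (any split of the marginal variance yields the
same bound when the linear encoder can match the exact posterior), so the
optimiser stays near its initialisation along that direction. Starting at
the high-fidelity end makes module scores faithful encodings rather than
heavily shrunken ones; with these defaults decode∘encode RMSE is below
0.1 SD on clean linear-Gaussian modules.

**Hyperparameter search.** Seeded k-fold CV (default 3) maximising the
held-out reconstruction term `(1/L) sum_l log p(x_obs|z^(l))` (`L = 10`),
with the *same* training seed per fold across grid entries so comparisons
are paired. A consequence of selecting on reconstruction alone: a `K = 3`
model nests `K = 1`, so on unimodal data the two differ only by
optimisation noise and the selection between them is essentially arbitrary
— the tests assert near-equivalence there, and assert that `K = 2` wins
decisively on genuinely bimodal data. Latent dimension defaults to 1: the
network layer treats each module as a scalar activity score.

## The modular Bayesian network

Nodes are module scores (Gaussian) and raw demographic/phenotype features
(Gaussian or discrete). Local models: conditional linear Gaussians — one
OLS per discrete-parent configuration, residual SD the MLE with a 1e-9
floor, plus a pooled fallback used (with a warning) for configurations
unseen at fit time — and multinomial CPTs by relative frequency, uniform
rows for empty configurations, add-one smoothing only when an unseen level
must be scored. Discrete nodes never have Gaussian parents.

**Structure search** is first-ascent greedy hill climbing on
`BIC = loglik - d/2 · log n`: moves (add/delete/reverse) are scanned over
ordered node pairs in lexicographic order and the first strictly improving
move is applied; node scores are cached per parent set. First ascent with a
fixed scan order makes the search deterministic; a steepest-ascent variant
was evaluated and recovered true skeletons *less* often on chain
benchmarks, so determinism costs nothing here. Whitelisted edges are never
removed, blacklisted never added, and the search starts from the
constraint set's initial graph. Optional random restarts perturb the start
with admissible random edges and keep the best-scoring result.

A caveat documented by the benchmarks: BIC consistency is asymptotic. On
common-cause designs (two strongly driven children of one parent) the
*score itself* prefers a spurious child–child edge with probability ~1% per
candidate pair at n = 1000, so skeleton-recovery benchmarks use chain
graphs at that sample size; branching designs need larger n.

**Bootstrap confidence.** B row-resamples (with replacement), one structure
search each; strength of a pair = fraction of networks containing it in
either direction, direction = fraction oriented a given way among those.
The consensus keeps pairs with strength ≥ threshold (default 0.4, as in the
source analysis with B = 1000) at the majority orientation and breaks any
cycles by dropping the weakest cycle edge (ties lexicographic).

**Held-out validation.** The "marginal log-likelihood" is implemented as
the plug-in MLE log-likelihood (no parameter prior is defined for these
local models); it decomposes exactly over nodes. The permutation test
relabels nodes within classes (default: within node kind, which preserves
the logical constraints), refits parameters on training data and rescores
the held-out data; `p = (1 + #{perm >= true}) / (P + 1)`. When the class
structure admits fewer distinct permutations than requested, the whole
group is enumerated exactly (identity excluded). Two properties worth
knowing: label permutations that map the DAG onto a Markov-equivalent
relabelling tie with the true statistic, making the test conservative for
highly symmetric reference graphs; and under iid null data the statistic is
exchangeable, so the test is calibrated (verified over 200 repeats).

**Graph overlap** between two learned networks is the Jaccard index of edge
sets (directed and skeleton) with an upper-tail hypergeometric p-value over
the admissible-edge universe.

## Counterfactual simulation

A fold-`f` down-expression shifts the target feature by `-log2(f)` control
standard deviations in every sample (a per-sample constant shift, not a
redraw — this isolates the intervention from resampling noise; the
alternative is noted as a declared choice). Singleton-gene nodes take the
shifted values directly; genes inside multi-gene modules are shifted and
the whole module is re-encoded to obtain the intervened score. The module
node's incoming edges are deleted — the mutilated network of a
do-intervention, making the node independent of its former parents — and
all descendants are resampled in topological order; non-descendants are
copied from baseline so every downstream difference is causal. Decoding
draws from the feature likelihoods (mode `sample`) by default.

Downstream statistics: per-feature regression on the condition indicator
(equivalent to the pooled two-sample t-test; ordinal phenotype scores are
decoded to categories for reporting but tested as numeric, since mean score
shifts are the quantity of interest), BH-adjusted; and a gene-set score
test `Q_S = ||X_S' y||^2 / (m_S · sigma^2)` with column-standardised
expression, whose null is the permutation distribution of the condition
labels (default 10^4 permutations, add-one corrected) — the statistic is
invariant to gene-wise rescaling by construction. The target screen
enumerates genes in phenotype-ancestor modules only (others cannot move the
phenotype under the model and are excluded with a reason) and simulates
both directions of a 9-fold change.

On an all-linear system with identity encoders the mean downstream shift
equals the sum over directed paths of edge-coefficient products times the
shift; the implementation matches this oracle within Monte-Carlo error at
n = 10^4 (test and acceptance script).

## Synthetic data

`SyntheticScenario` defines the ground truth: module sizes, a linear-
Gaussian DAG over module activities with explicit coefficients and noise
SDs (continuous demographics act through standardised values), unit-loading
features with Gaussian noise (SD 0.3 default), ordinal scores generated
through the same thermometer link the decoder uses (logistic noise on a
weighted latent — making end-to-end recovery well-posed), MCAR missingness,
and additive batch offsets. Defaults mirror the cohort shape the method
targets: 200 subjects, modules of 1–4 genes plus a singleton "CD33", an
MMSE-like 0–30 score and a Braak-like 1–6 stage, ~70/30 sex split, binary
APOE, age 88 ± 3.4, education 16 ± 3, 5% missingness.

What it does *not* emulate: read-level count noise (negative-binomial
sequencing models), missing-not-at-random patterns, nonlinear gene–gene
regulation, and LD-like correlation between demographics. Passing tests
therefore demonstrate the machinery is correct under the model's own
assumptions, not that those assumptions hold in any particular cohort.

The `worked_example` fixture (seed 7, 200 subjects, HI-VAE 150 epochs,
bootstrap B = 30) runs the full pipeline and writes deterministic text
outputs; the committed golden copies are byte-compared on every test run.
In the planted system CD33 activates two cascades that suppress the
phenotype latent, so its down-expression raises the MMSE-like score
(~+4.5 points) and lowers the Braak-like stage (~−1).

## Known limitations

* BIC structure learning admits spurious edges between strongly confounded
  nodes at moderate n (see above); bootstrap strengths are the better
  instrument there.
* Reconstruction-based model selection cannot penalise mixture components
  that the data do not need; choose K by fit *and* parsimony.
* The permutation test is conservative for reference graphs with large
  Markov-equivalence orbits under relabeling.
* Module-graph path support is length-capped; on very dense two-module
  subgraphs the support counts (not the edge set) depend on that cap.
* Per-gene batch-mean residuals after empirical-Bayes adjustment scale as
  `1/sqrt(n_batch)`; the adjustment removes systematic, not sampling,
  differences.
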