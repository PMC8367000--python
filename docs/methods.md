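# Methods

## Model

Every biological element in the drought signaling pathway — gene,
transcription factor or kinase — is a binary random variable (1 =
activated, 0 = inhibited) in a directed acyclic graph whose joint
distribution factorizes into per-node conditionals given parents. The
structure is curated from the pathway literature, not learned: available
drought expression datasets are far too small to support structure
learning over 32 nodes, and the pathway interactions are comparatively
well established. Regulation signs (+/−/?) are carried as annotations for
documentation and for the sign-consistent synthetic generator; they never
enter a probability computation — all θ values come from data.

Curation choices where the literature is not explicit are recorded in the
bundled network file itself (`src/droughtbn/data/drought_network.yaml`):
the MAP-kinase cascade is taken as MAP3K15→MKK4→MPK6→WRKY59→DREB2A, all
four ABRE-family bZIP factors parent both DREB2A and DREB1D, and WRKY18/
WRKY40 are roots (hormones are not nodes — they have no expression
values — so hormone-induced factors start the graph). Users can amend the
YAML as ambiguities are resolved; loading re-validates every structural
invariant (acyclicity, declared endpoints, no self or duplicate edges).

## Preprocessing

Input is an n-samples × N-genes matrix of real-valued expression
measurements (rows = lines/samples). Each column is min-max scaled to
[0, 1] and binarized at the mean of its *normalized* values; a value equal
to the threshold maps to 1, a convention centralized in one constant
(`preprocess.BINARIZE_AT_MEAN`) so the opposite tie rule is a one-line
swap. The ≥ rule guarantees the column maximum is always scored active.
Constant columns are an error (their scale is undefined), as are missing
values — the pipeline performs no imputation.

## Estimation

For node X with parents Pa(X), observations are stratified by parent
configuration; in a stratum with n rows of which k have X = 1 the
likelihood is Binomial(n, θ) and the conjugate Beta(α, β) prior yields the
posterior Beta(α + k, β + n − k). The point estimate used everywhere
downstream is the posterior mean (α + k)/(α + β + n). Defaults: α = β = 1,
the uniform prior, chosen for the absence of per-node prior knowledge;
any positive (α, β) may be supplied. Consequences worth noting:

- θ̂ is strictly inside (0, 1), so likelihood weights are always positive
  and zero-probability evidence cannot arise from fitted tables;
- unobserved strata keep the prior and report θ̂ = prior mean (0.5 by
  default) rather than erroring — with ~100 observations and up to
  2^|Pa| strata (4096 for the 12-parent reporter RD29A), empty strata are
  the expected case, and estimates in thinly observed strata are
  dominated by the prior;
- tables are indexed densely by a parent-state bitmask with parents in
  network declaration order, parent 0 in the least-significant bit; the
  JSON serialization spells each configuration out explicitly and round-
  trips exactly.

## Inference

Likelihood weighting clamps evidence nodes, samples all other nodes
ancestrally in the network's deterministic topological order (ties broken
by declaration order), and weights each joint sample by the likelihood of
the evidence given its sampled parents. The estimator is the normalized
weighted indicator sum. Implementation and numerical conventions:

- Sampling is vectorized node-major: one `numpy.random.default_rng(seed)`
  stream, consumed node-by-node in topological order with all M draws for
  a node generated at once. A (seed, M) pair reproduces a run bit-for-bit
  on any platform; M = 600,000 is the default sample size, large enough
  that reporter-probability standard errors are ~10⁻³.
- Every estimate carries a Monte-Carlo standard error from the delta-
  method variance of the ratio estimator,
  SE² = Σ Wᵢ²(zᵢ − r̂)² / (Σ Wᵢ)², which is the basis of the 3-SE
  tolerance used in all sampling-vs-exact tests.
- "Intervention" here means conditioning — evidence inside LW — not a
  causal do-operation; incoming edges of clamped nodes are kept, matching
  the analysis this package implements. A do-style variant would cut
  parent edges and is deliberately out of scope.
- `exact_query` is a validation oracle, not a second inference engine: it
  prunes the network to the ancestral closure of query ∪ evidence (barren
  nodes marginalize out of a conditional exactly) and sums the factored
  joint over remaining states in 2¹⁸-state chunks, guarded at 25 nodes
  post-pruning. On the bundled network the largest such closure (RD29A
  with one extra evidence node) is ~23 nodes, so every reporter query is
  exactly checkable; full-network enumeration at 2³² states is not
  attempted.

## Intervention scoring

The composite score multiplies, over the four reporters, the probability
of each reporter's desired state (ERD1 active; RD29A, RD22, RD20
inhibited). All four terms for one evidence assignment are estimated from
a single shared weighted sample set: the sampling distribution depends
only on the evidence, so sharing is exact, halves no variance corners,
and makes the score invariant to the order of the component queries.
Sweeps clamp each non-reporter node in turn and use per-candidate seed
`base_seed + declaration_index`, so adding or removing a candidate never
perturbs other rows, and sweep CSVs are byte-reproducible.

## Synthetic data

The generators exist so every stage is testable without external data.

- `random_cpts` draws ground truth: `uniform` mode samples every θ from
  U(0.05, 0.95); `strong` mode makes effects large and sign-consistent —
  each parent votes for activation when its state agrees with its sign,
  and θ interpolates linearly from 0.1 (all against) to 0.9 (all for),
  with root θ from U(0.3, 0.7).
- `forward_sample_dataset` is ancestral sampling (LW with empty evidence,
  all weights 1) and serves as the parameter-recovery oracle.
- `continuous_emulation` emits an expression-like matrix: each cell is
  Normal(μ₀, σ) when the latent state is 0 and Normal(μ₁, σ) when it
  is 1. Defaults mirror the study scale — n = 104 lines — with μ₀ = 6,
  μ₁ = 12, σ = 1 (a 6σ separation in log-intensity-like units), under
  which mean-threshold binarization recovers ≥ 99% of latent states for
  roughly balanced columns.

What the emulator does *not* reproduce: the genetic structure of a
recombinant-inbred-line panel (genotype blocks, linkage), probe-level
noise, or any continuous dependence between genes beyond what the binary
network induces. Passing recovery tests therefore demonstrate correctness
of the pipeline's decoding and estimation logic under its own model
assumptions, not performance on real microarray data.

A real limitation the tests surface deliberately: the mean-threshold
decoder is only reliable for columns whose activation probability p is
not extreme. The threshold sits at the weighted mixture mean, a distance
of roughly min(p, 1−p) · (μ₁ − μ₀) from the nearer cluster, so as p → 0
or 1 it invades the majority cluster and flips a tail of its values no
matter how large n is. The end-to-end recovery test therefore holds
ground-truth θ in (0.3, 0.7) with strong separation; on heavily
imbalanced real genes, binarization error is irreducible by sample size.

## Test problem sizes

Test and example problem sizes are chosen to make each statistical claim
sharp at interactive runtimes: sampling-vs-exact agreement uses
M = 100,000 (reporter SEs ~1.5×10⁻³) over 40 seeded query/evidence pairs;
parameter recovery uses 10,000 forward samples on the four-gene network,
where every stratum holds ≳1,900 rows and the 0.03 recovery bound sits at
~3 binomial standard errors (on the 32-node network the same bound is
checked only in strata with ≥ 500 rows — high-arity reporter nodes
necessarily leave most of their 4096 strata empty or near-empty at any
realistic n); end-to-end recovery uses n = 5,000 emulated lines. Sweeps
in examples run at M = 20,000; the analysis default remains M = 600,000.

## Known limitations

- Conditioning, not causal intervention (see above): scores rank nodes by
  conditional association under the fitted joint, which coincides with
  interventional reasoning only for root evidence nodes.
- With 104 observations the fitted tables for high-arity nodes are
  prior-dominated; rankings on real data inherit that uncertainty.
- Structure is fixed; no feedback, no dynamics, no structure learning.
- LW convergence slows when conditional probabilities approach 0 or 1;
  the reported SE makes this visible but does not repair it.
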