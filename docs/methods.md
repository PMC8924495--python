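# Methods

## Scope

`relcat` implements a multi-module computational account of how background
knowledge enters categorization, combining a symbolic inference engine for
contextually controlled relational responding (Relational Frame Theory,
RFT) with the standard quantitative machinery around it: an exemplar model
for the physical-similarity (non-arbitrary) pathway, semantic networks for
learning relational knowledge from experience, graph-based interpretation
of what a trained network encodes, an unsupervised map for clustering
learning contexts, and a two-stage subgroup analysis for participant-style
confidence data. Every input the modules consume can be generated by the
`scenarios` module, seeded and deterministic.

## The relational-frame engine (`relnet`)

A `RelationalNetwork` stores stimuli, typed relations and stimulus
functions. Relation types carry an involutive inverse (comparison-more ↔
comparison-less, containment-includes ↔ containment-belongs-to; the
symmetric frames are self-inverse) and a composition table over chains.
The composition algebra is the minimal one consistent with the worked
examples the fixtures encode:

* coordination is the identity element,
* opposition is an involution (opposition ∘ opposition = coordination),
* comparison and containment compose transitively with themselves,
* distinction and deictic frames never compose (indeterminate), and
* every remaining pair is indeterminate.

Derivation has three parts. **Mutual entailment** emits the inverse of
every eligible relation. **Combinatorial entailment** is a semi-naive
fixed-point closure over chains of up to `max_path` underlying edges
(default 4): any chain whose types compose (under *some* bracketing — the
algebra is intentionally non-associative, e.g. more∘(opp∘opp) is
determinate while (more∘opp)∘opp is not) emits the composed relation and
its inverse. Derived strength is the product of the constituent strengths
times `ce_decay^(path_len − 1)`; mutual entailment multiplies by
`me_decay`. The test-suite oracle recomputes the closure by explicit path
enumeration with a CYK-style all-bracketings recursion — a structurally
different algorithm with the same semantics.

**Transformation of stimulus function** propagates each trained, eligible
function breadth-first over the derived network. Per hop the magnitude is
scaled by a type factor: coordination, opposition and member→container
containment multiply by `tof_decay` (default 0.8); opposition additionally
flips valence; comparison hops multiply by `comp_gain` (default 1.25) in
the "more" direction and divide by it in the "less" direction — the
comparison factors replace (not compound with) `tof_decay`, so a function
transferred up a comparison really is stronger at its destination.
Magnitudes are independent of relation strength; the maximum-magnitude
route wins; propagation is bounded by `max_hops` (default 6, warning on
truncation). Because transfer runs over the *closed* network, chains
collapse to single hops; the community-level transfer chain reported by
`cograph.relate_networks` therefore follows trained relations, where hop
distance is meaningful.

Contextual control is set-intersection gating on both relations (C_rel)
and functions (C_func): empty tags mean context-free; otherwise at least
one tag must be in the active context. C_func gates the transfer step
only, not the underlying derivation.

### HDML metrics

* **Coherence** = 1 − (contradictory ordered pairs / derived ordered
  pairs); a pair is contradictory when it carries clashing types
  (more+less, coordination+distinction, coordination+opposition,
  includes+belongs-to). Contradictions are reported, never auto-resolved;
  the negative-self worked network is *intentionally* incoherent
  (coherence ≈ 0.7) in the "I am a failure yet success-linked" sense.
* **Complexity** is a weighted count of the multi-level strata present
  (relations at all = 1; ≥2 frame types = +2; combinatorial chains = +3;
  cue-controlled relations = +4; relations crossing labelled communities =
  +5), so an empty network scores 0 and a full relating-relational-networks
  structure scores 15.
* **Derivation level** per derived relation is 1/(1 + emission count); a
  relation enters at count 1 and is bumped once per derivation pass that
  re-emits it, so a response derived in three passes sits at 0.25.
* **Flexibility** is the fraction of relations that are context-gated at
  all — one admissible operationalization of "modifiable by current
  contextual variables"; the dimension has no canonical formula.

Knowledge-driven categorization scores a candidate category by summed
derived coordination/containment strength from the query (distinction and
opposition count negatively) plus the alignment of signed transferred
function profiles (aversive = −magnitude, appetitive = +magnitude).

## Exemplar model (`gcm`)

Summed similarity is `η_XA = Σ_{j∈A} exp(−c·d_Xj^q)` with
`d_Xj = (Σ_k w_k |y_Xk − y_jk|^r)^{1/r}`; the `q` exponent applies outside
the 1/r root. Choice follows the biased-choice rule with a
category-specific bias in every denominator term, generalized to M ≥ 2
categories. Attention weights are normalized to sum to one; coordinates
are taken as given (an MDS solution is an input, not something fitted
here). All-zero evidence (possible at extreme sensitivity) falls back to a
uniform response with a warning.

## Semantic networks (`semnet`)

Architecture: one-hot concept input → sigmoid representation layer
(context-independent) → second hidden block, which also receives the
one-hot relation input → sigmoid attribute output. Weights initialize
uniform in ±0.1 (small values, seed-controlled); targets are multi-hot,
aggregated per (concept, relation) pair; a row counts as produced when its
own attribute unit exceeds 0.5.

**Backprop** minimizes the mean squared error. Training uses Fahlman's
flat-spot elimination (+0.1 on the output-layer sigmoid derivative) by
default: with sparse multi-hot targets the plain SSE gradient `(o−t)·o(1−o)`
vanishes for an output pinned near 0 whose target is 1, and training
stalls around 92% row accuracy; the constant removes the flat spot
(≥ 99% on the worked-example corpus). `SemNet.gradients` defaults to the
*exact* gradient so analyses that need it (finite-difference checks, the
predictive-coding comparison) are unaffected.

**Predictive coding** relaxes value nodes to the fixed point of
`dv_l ∝ −ε_l + W_{l+1}ᵀ(ε_{l+1} ⊙ σ′(z_{l+1}))` with the input and target
layers clamped (step 0.1–0.2, tolerance 1e−6; non-convergence warns and
proceeds), then applies the purely local update
`ΔW_l ∝ (ε_{l+1} ⊙ σ′(z_l)) v_lᵀ`. This approximates the backprop gradient
in the small-error regime: at the package's default initialization the
minimum correlation between relaxed updates and exact gradients over 20
random 5-8-4 networks is ≈ 0.998; with a large initialization (±0.5) the
fixed point visibly diverges from the gradient (min ≈ 0.983), which is a
property of predictive coding, not of this implementation.

The response rule `P_k = 1/(1 + e^{−θ·O_k})` (θ > 0) maps an output
activation to a response probability; a `bayes_posterior` helper exposes
the discrete Bayes identity. Layer-wise mutual information uses binned
plug-in estimates (equal-width, default 8 bins per unit; the layer symbol
is the tuple of bin indices). The data-processing inequality applies only
to architectures that form a Markov chain in the input — the standard
relation-injected architecture does not, since the relation input enters
at the second hidden block.

## Co-activation graphs (`cograph`)

`build_graph` computes Spearman rank correlations (average ranks for ties)
between the rows of an activations matrix; constant rows have undefined
correlations and lose their edges with a warning; `|w| < edge_threshold`
edges are dropped (default 0: keep all). Degree centrality is the
absolute-weight row sum of the thresholded adjacency; PageRank is a power
iteration with init 1/N, uniform dangling redistribution and a sum-to-1
contract; Louvain runs on absolute weights with seed-controlled
tie-breaking (signed weights are kept on edges for reporting).
`relate_networks` aggregates trained relations crossing community labels
(sorted by strength, so a strong self↔woods edge outranks a weak
woods→snake edge) and reports each function's transfer chain as the
breadth-first community order over trained transfer-capable relations.

## Self-organizing map (`som`)

Rectangular grid, Gaussian neighborhood over grid distance (exactly 1 at
the best-matching unit), linearly decaying learning rate and width. The
batch rule replaces each model by the kernel-weighted combination of
Voronoi-cell means; a unit with zero kernel mass keeps its vector. With
the kernel shrunk to a delta the batch iteration is exactly Lloyd's
k-means step, so delta-kernel fixed points coincide with k-means centroids
and the quantization-error trace of that iteration never rises. With a
*shrinking* kernel the early wide-kernel epochs pull models toward the
global mean, and the error trace need not be monotone — the monotonicity
guarantee is stated for the delta-kernel (Lloyd) regime.

## Subgroup analysis (`cohorts`)

z-scoring uses the sample convention (ddof = 1) and drops zero-variance
columns with a warning. Ward linkage (squared-Euclidean) supplies the
agglomeration schedule; the suggested k is the largest *relative* jump in
merge height (all-zero heights → k = 1), and the suggestion is
user-overridable. k-means is seeded at the Ward centroids with no random
restarts, making the pipeline deterministic. Effect sizes are
`d_gv = (mean_gv − grand mean_v) / pooled_sd_v` with the multi-group
pooled SD (n_g − 1 weights); zero pooled SD reports missing. Two caveats
the synthetic studies make explicit: z-scoring deflates a strongly
separated variable (its total SD includes the between-group part), so a
clustering driven by a single such variable can flip rare big-noise
outliers; and an effect-size variable that participates in the clustering
distance is inflated by assignment conditioning — calibration studies
should plant the effect on a variable separate from those driving the
clusters.

## Synthetic data (`scenarios`)

The worked networks encode the fixtures the rest of the package is
exercised on: the snake/woods/self network in negative- and positive-self
variants (three labelled communities of roughly 6/4/6 concepts; a weak
0.4 containment bridge woods→snake, a strong 0.9 coordination bridge
self↔woods, preserving the weak-vs-strong ordinal claim of the structure
it emulates; a trained fear function on the snake class gated by the
"snakes-in-woods" cue), the bachelor coordination/distinction frame, and
an illustrative jogger frame. Fixture strengths default to 1.0 where the
source material carries no numbers.

Random *consistent* networks are built from a latent class structure
(coordination within classes, comparison along a strict class rank,
opposition between polarity-paired equal-rank classes, containment along a
strict order in a disjoint class group, distinction elsewhere), so the
closure provably cannot derive a contradictory pair — these are the 8-ish
stimulus, 16-relation networks the closure oracle is checked on.

Triple corpora `(concept, relation-context, attribute)` are sampled from
the network's closure (relations plus function rows), with optional label
noise and class balancing; `network_triples` gives the exhaustive truth
table. Planted activation matrices draw from an equicorrelation block
Gaussian (PSD-checked) and push each neuron through a random strictly
monotone transform, so only rank structure survives — exactly what a
Spearman graph should recover. Confidence tables are Gaussian with planted
standardized group offsets (offsets in units of the noise SD).

What the generators do *not* emulate: real participant data has
heavy-tailed, bounded, often ordinal responses, correlated noise and
missingness; real relational learning histories are not consistent by
construction. Passing the planted-recovery studies shows the algorithms
are correctly implemented and calibrated on their own assumptions, not
that those assumptions hold in any particular dataset.

## The end-to-end analysis

The pipeline trains the semantic network on the exhaustive closure corpus
of the snake/woods fixture (trained functions only — transferred fear
spans all three communities by design and would blur the partition the
analysis is probing), to convergence (3000 epochs, lr 0.8, batch 32, at
which point the network asserts the corpus exactly). Each concept's
activation vector is its asserted knowledge profile: thresholded mean
output per observed relation context, concatenated, with all-zero feature
columns dropped (they carry no rank information). Graph nodes are
concepts; Louvain communities of this graph recover the fixture's
snake/woods/self partition at majority-vote purity ≈ 0.94 across seeds
(the woods hub itself joins the self cluster — faithfully reflecting its
strong coordination bridge — while the woods features, the snake class and
the stripe-snakes form their own communities).

## Problem sizes and determinism

The bundled studies use deliberately small problems: ≤8-stimulus networks
for the closure oracle (100 seeds), 5-8-4 networks for the
predictive-coding comparison (20 seeds), a 200-row corpus for the training
study, 60×200 planted matrices, 5 pipeline seeds, and 200-per-group
confidence tables (8 replicates for the effect-size calibration, whose
single-table sampling SD ≈ 0.1 is comparable to the stated ±0.15 band).
Every stochastic component takes an explicit seed; identically seeded CLI
runs produce byte-identical artifacts (sorted JSON keys, fixed float
formatting, no timestamps in outputs).

## Known limitations

* The composition algebra is minimal; richer frame families (temporal,
  conditional, analogical relating-of-relations as first-class objects)
  are annotated only through context tags and community labels.
* Function transfer magnitudes ignore relation strength; only the type
  factor and hop structure matter.
* Deictic frames are stored and gated but never composed or transferred.
* The predictive-coding/backprop agreement degrades outside the
  small-error regime, as the theory says it should.
* The plug-in MI estimator is biased at small sample sizes; its numbers
  are diagnostics, not calibrated information measures.
* No fitting to human data anywhere: GCM parameters, decays and gains are
  inputs, and the package makes no empirical claims beyond its synthetic
  studies.
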