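# relcat

Computational models of **background knowledge in categorization**, built
around Relational Frame Theory (RFT): category decisions are driven not
only by physical similarity but by *derived* relational knowledge —
contextually controlled relations between concepts and the behavioural
functions (fear, approach, avoidance) that travel along them.

The package is aimed at mathematical-psychology and computational
cognitive-science researchers who want a tested, seedable implementation
of the full modelling stack:

* **`relcat.relnet`** — the relational-frame inference engine. A trained
  relation `A R B` supports *mutual entailment* (derive `B R⁻¹ A`),
  *combinatorial entailment* (compose chains: `A > B`, `B > C` ⟹ `A > C`
  and `C < A`), and *transformation of stimulus function* (fear attached
  to "snake" climbs the containment relation to "woods"), all gated by
  contextual cues; plus the hyperdimensional metrics coherence,
  complexity, derivation level and flexibility.
* **`relcat.gcm`** — the Generalized Context Model for the
  physical-similarity pathway:
  `P(A|X) = β_A η_XA / Σ_M β_M η_XM` with
  `η_XA = Σ_{j∈A} exp(−c (Σ_k w_k |y_Xk − y_jk|^r)^{q/r})`.
* **`relcat.semnet`** — semantic networks with separate concept and
  relation input layers, trained by backpropagation or by a biologically
  plausible predictive-coding rule (local Hebbian updates at a relaxation
  fixed point, which track the exact gradient to correlation ≥ 0.99 at
  small weights), with a logistic response rule and layer-wise
  mutual-information diagnostics.
* **`relcat.cograph`** — co-activation graphs: Spearman rank-correlation
  edges, weighted degree and PageRank centralities, Louvain communities,
  and cross-community reports of how relational networks relate (e.g. the
  fear function transferring snake → woods → self).
* **`relcat.som`** — self-organizing map with online and batch updates;
  the delta-kernel batch iteration coincides with k-means.
* **`relcat.cohorts`** — two-stage subgroup analysis for confidence-scale
  tables: z-scoring, Ward agglomeration with an elbow-based k suggestion,
  k-means seeded at the Ward centroids, and per-cluster effect sizes
  against the grand mean with a pooled-SD denominator.
* **`relcat.scenarios`** — seeded generators for everything above: the
  snake/woods/self and bachelor worked networks, random *consistent*
  relational networks, training-triple corpora, planted block-correlated
  activation matrices and planted-subgroup confidence tables.

## Worked example

A participant is told that dangerous snakes live in the woods, and has a
learning history in which the verbal self is coordinated with failure.
Should the woods be categorized as "unsafe and to be avoided" or "unsafe
but walkable"?

```python
from relcat.relnet import categorize_by_knowledge, transform_function
from relcat.scenarios import build_fixture, SNAKE_WOODS_CONTEXT

net = build_fixture("snake-woods-negative-self")
transform_function(net, SNAKE_WOODS_CONTEXT)
print(net.functions[("woods", "fear")])

ranking = categorize_by_knowledge(
    build_fixture("snake-woods-negative-self"), "woods",
    ["unsafe-and-avoid", "unsafe-but-walk"], SNAKE_WOODS_CONTEXT)
print(ranking)
```

prints (values rounded):

```
fear(woods): transferred, magnitude 0.8, aversive
[('unsafe-and-avoid', 2.392), ('unsafe-but-walk', 1.898)]
```

Fear was never trained to the woods — it *transferred* there across the
containment relation (woods include snakes), at 0.8 of its trained
magnitude. With the negative-self history, the avoid category outranks
the walk category (2.392 vs 1.898); rebuilding the fixture with the
positive-self variant reverses the ranking. The same network's
hyperdimensional profile is `coherence 0.821, complexity 15.0,
flexibility 0.589` — the negative-self network is *measurably*
incoherent, because "self = failure" sits alongside a success relation.

The similarity pathway answers a different kind of question — e.g. a
probe at (0.4, 0.4) in a 2-D space with one "bird" exemplar and two "bat"
exemplars:

```python
from relcat.gcm import ExemplarSpace, choice_probability
space = ExemplarSpace(coords=[[0.2, 0.3], [0.8, 0.7], [0.7, 0.9]],
                      categories=["bird", "bat", "bat"], c=2.0, r=2, q=1)
print(choice_probability(space, [0.4, 0.4]))
# {'bat': 0.561, 'bird': 0.439}
```

The probe is nearer the single bird exemplar, but two moderately similar
bat exemplars sum to more evidence — the exemplar model's signature.

## Command line

```bash
relcat scenario --name snake-woods-negative-self --seed 1 --out net.json
relcat derive   --network net.json --context dangerous \
                --context snakes-in-woods --context walking --seed 1 --out derived.json
relcat pipeline --seed 1 --out run/        # scenario → training → communities
relcat gcm / semnet / som / cograph / cohorts ...
```

Every subcommand takes `--seed`, `--config`, `--out`; identically seeded
runs produce byte-identical artifacts. The `pipeline` command trains the
semantic network on the snake/woods corpus, builds the concept
co-activation graph from the trained network's knowledge profiles, and
reports Louvain communities alongside the fixture's snake/woods/self
partition and the fear-transfer chain.

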