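# miltext

Tools for assessing **Meaning in Life (MIL)** — the sense that one's life
has purpose, coherence, and significance — from short social-media posts,
and for analysing the psychological factors associated with it at group
level.

The package implements a three-part framework:

1. **Classifier cascade.** Three binary models share one architecture:
   a pluggable text encoder exposes the classification-token vector of
   each of its `L` blocks, stacked into an `L × d` matrix; convolution
   filters with window sizes `w ∈ {3, 4, 5}` (each `w × d`) slide over the
   block axis, every feature map of length `L − w + 1` is max-pooled to a
   scalar, the pooled features are concatenated, and a dense softmax layer
   emits class probabilities. Model 1 gates whether a post is MIL-related;
   Models 2 and 3 rate **search for meaning** (SFM, high/low) and
   **presence of meaning** (POM, high/low) on related posts only, so every
   related post lands in one of four POM×SFM quadrants.
2. **Factor extraction.** Each post is split into linguistic units; an
   external semantic-role parser supplies role triples
   `⟨(wordA, wordB), role⟩` over nine roles (REAS, AGT, EXP, PAT, CONT,
   DATV, LINK, TIME, LOC). A weighted lexical graph aggregates the triples,
   and candidate factor terms are collected by breadth-first expansion from
   the reason-role (REAS) anchors — Layer 0 — out to Layer 3. Terms are
   mapped to a closed-vocabulary category lexicon (52 categories in nine
   broader groups) and ranked Top-k per post.
3. **Subgroup networks.** Per POM×SFM subgroup (four quadrants plus four
   marginal groups), factor-count matrices feed a Gaussian graphical
   model: a graphical-lasso path proposes sparsity patterns for the
   Pearson correlation matrix and the extended Bayesian information
   criterion

       EBIC(λ) = −2·ℓ(K̂_λ) + E·log n + 4·E·γ·log p

   selects the network (γ = 0.5 by default). Downstream: expected-influence
   centrality `EI_i = Σ_j w_ij`, edge density `2E / (N(N−1))`, Newman
   modularity `Q`, Louvain communities, and a permutation network
   comparison test on global strength and maximum edge difference.

Supporting modules cover corpus cleaning and seed screening, two-annotator
consensus merging with Cohen's κ and dataset accounting, data augmentation
(random deletion, similarity-gated synonym replacement), and a synthetic
data generator that produces every fixture the pipeline needs.

## Worked example

```python
import numpy as np
from miltext import synthgen as syn
from miltext.network import GaussianGraphicalModel

# posts x factor-category counts sampled from a known sparse network
X, true_edges, K = syn.gen_gaussian(syn.make_precision(5, "chain", -0.4),
                                    n=2000, seed=7)
res = GaussianGraphicalModel(X, gamma=0.5).fit()
print(res.summary())
```

prints

```
Gaussian graphical model (EBIC-selected partial correlations)
==============================================================
subgroup: -            n obs: 2000
nodes: 5    edges: 4    density: 0.400
gamma: 0.50  selected alpha: 0.4270  EBIC: 8071.7
global strength: 1.601
top expected influence:
  x1               raw=+0.809 z=+0.86
  x2               raw=+0.802 z=+0.82
  x3               raw=+0.792 z=+0.77
  x0               raw=+0.417 z=-1.14
  x4               raw=+0.383 z=-1.31
```

The generator planted a 5-node chain (partial correlation ≈ 0.39 between
consecutive nodes); the fitted network recovers exactly those four edges
(`density 0.400`), and the interior chain nodes x1–x3, each with two
ties, dominate the expected-influence ranking — influence here is the
signed sum of a node's edge weights, so it rewards nodes whose
connections would propagate activation through the factor network.

A thin CLI mirrors the file-level steps:

```bash
mil synth posts --n 200 --seed 42 --out posts.jsonl
mil clean --posts posts.jsonl --noise src/miltext/data/noise_terms.txt --out clean.jsonl
mil screen --posts clean.jsonl --seeds src/miltext/data/mil_seeds.txt --out mil.jsonl
mil synth triples --n 100 --seed 42 --out triples.tsv
mil factors --triples triples.tsv --out factors.jsonl
mil network estimate --matrix counts.csv --gamma 0.5 --out edges.tsv
```

## Data and licensing notes

The proprietary LIWC Chinese dictionary is **not** shipped; the lexicon
interface accepts any `(category, term)` TSV plus a `(category, group)`
grouping map, and a generic 52-category toy lexicon is included for tests
and synthetic runs. Semantic-role parsing is an adapter boundary: the
package consumes role-triple files and never parses text itself.
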