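# Methods

This note documents the models and procedures miltext implements, the
choices made where the design was genuinely open, and what the synthetic
test conditions do and do not establish about real data.

## Corpus preparation

Posts are short social-media messages. Cleaning applies two rules in
order: (1) a post whose normalized text contains any term from a
noise/stop list (link markers, ad phrases, platform boilerplate) is
dropped whole; (2) among posts with identical normalized text strictly
longer than 10 characters, only the first occurrence survives. The strict
inequality deliberately spares short formulaic posts ("good night"),
which are legitimately repeated, while removing longer reposts. All
matching normalizes with Unicode NFKC and casefolding: Chinese has no
case, but NFKC collapses the full-width/half-width variants common in
microblog text, and the Latin-token fixtures exercise the casefold.
Seed screening then keeps posts containing at least one topical keyword
as a substring; it is a recall-oriented prefilter, so precision is left
to annotation and the relevance classifier.

Cleaning is idempotent and conserves counts (retained + removed = input,
per rule and in total); both are property-tested.

## Annotation consensus and agreement

Each post is labeled independently by n annotators (default 2) with an
explicit "unable to judge" option. Consensus requires unanimity: any
unable vote excludes the post (taking precedence over disagreement), any
disagreement among the rest marks it inconsistent, and only unanimous
posts carry a label forward. Cohen's κ = (p_o − p_e)/(1 − p_e) is
computed on the paired pre-consensus labels with UNABLE kept as a third
category by default — the agreement of the task as actually performed — 
with a flag to drop unable pairs instead, since published κ values do not
always state which convention was used. The degenerate case p_o = p_e = 1
(both annotators using a single shared category) is defined as κ = 1.

## Data augmentation

Two operations expand a labeled set to a target size, cycling source
posts round-robin: random deletion of one or two noncritical tokens
(tokens tagged adverb/intensifier/particle by a pluggable tag function;
content words are never deleted), and synonym replacement gated by
embedding cosine similarity strictly greater than 0.80. The embedding
provider is an adapter; the shipped provider hashes character n-grams
into a fixed-length vector, which is deterministic, dependency-free, and
rates orthographically close variants as similar — sufficient for the
gate's semantics in fixtures, though it measures form, not meaning.
Labels are inherited from the source post and every augmented item
carries provenance (source id, operation). The manual quality-control
step becomes an exported random sample (10% by default) for human review;
the package never discards items automatically. Class balance follows the
round-robin over sources, i.e. it is preserved approximately
proportionally; per-class augmented counts are otherwise unconstrained.

## Classifier cascade

Each stage consumes an `L × d` matrix of per-block summary
(classification-token) vectors from an encoder adapter — shallow blocks
carry lower-level semantics, deeper blocks higher-level ones — and applies
a convolutional head: for each window size `w`, `m` filters of shape
`w × d` slide over the block axis giving feature maps of length
`L − w + 1`; each map max-pools to a scalar; pooled features concatenate
to a `|windows|·m` vector; a dense softmax layer outputs class
probabilities. Production defaults mirror a 12-block, 768-dimensional
encoder with windows (3, 4, 5) and m = 128 filters per window; `m` is a
free capacity parameter. Token sequences are truncated/padded to 164.

The head is trained with Adam under class-weighted cross-entropy
(w_c = n/(K·n_c)), early stopping when validation accuracy has not
improved for a patience number of update steps, and the split/CV
protocol: a 10% test split held out once, k-fold cross-validation (k = 10
by default) over the remaining 90%, and final test metrics from a head
trained on the 80/10 train/validation split. The forward and backward
passes are implemented directly in numpy; the encoder is a frozen feature
extractor behind the adapter boundary, so fine-tuning a pretrained
encoder, where wanted, belongs to the adapter. A probability tie at 0.5
resolves to the positive class and is logged.

The cascade gates: Models 2 (SFM) and 3 (POM) run only on posts Model 1
judged related, and the result type makes an SFM/POM label on a gated
post unrepresentable. Stratified validation sampling draws
`max(floor, round(frac·N_q))` posts per POM×SFM quadrant without
replacement (floor 100 by default) and errors on quadrants below the
floor. Joint-label accuracy counts a post correct only when SFM and POM
are simultaneously right, which is why it runs well below the marginal
accuracies whenever the two errors are not perfectly correlated.

The shipped test adapter is a randomly initialized 4-block, 32-dimensional
encoder: token vectors from a hashed embedding table are mean-pooled and
passed through fixed random tanh layers, one summary vector per block. It
is deterministic per seed and keeps small class-conditional vocabularies
linearly separable, which is what the training-dynamics and gating tests
need. It is *not* a language model: its random mean-pooled features cap
out-of-sample accuracy well below what a pretrained encoder reaches
(roughly 0.9 relevance / 0.6–0.75 level accuracy on the synthetic
distribution, versus perfect training-set separation). Synthetic
accuracies therefore validate the pipeline's mechanics — optimization,
early stopping, gating, evaluation — not achievable real-data accuracy.

## Semantic graphs and factor extraction

Units are split at terminal punctuation (. ! ? and their CJK forms), with
trailing text forming a final unit. Role triples aggregate into an
undirected weighted graph: nodes are NFKC-casefolded surface forms (no
stemming), edge weight counts the triples linking a pair across all units
and posts, the linking roles and original directions are kept as edge
attributes, self-links are dropped, stop-node and punctuation-only tokens
are excluded, and edges below a minimum weight (default 2; "low
frequency" is inherently corpus-relative) are pruned. Expansion treats
links symmetrically: the source material draws directed arrows but
describes co-occurrence expansion, and undirected reach is the safer
reading.

Factor extraction is breadth-first from the REAS anchors: Layer 0 is the
endpoints of reason-labeled edges; Layer k collects nodes linked by any
of the nine roles to Layer k−1 and not yet assigned; expansion stops
after Layer 3, and a node reachable at several depths keeps its first
layer. A unit with no REAS triple yields nothing and is flagged
unextractable — on real corpora this anchor requirement is what caps the
extraction yield at a minority of posts. Candidates are ordered by
(layer, corpus frequency descending, name) for determinism.

Mapping to the category lexicon increments every category containing a
term (multi-category words inflate counts, never deflate); Top-k ranking
orders by count descending then category name. Group-level tables report
the percentage of a subgroup's posts touching each category; rows are
multi-label and need not sum to 100.

## Subgroup network estimation

Node values are per-post category counts (not binarized — the continuous
counts retain intensity information; the encoding is a package choice).
Each subgroup's network is a Gaussian graphical model on the Pearson
correlation matrix: a graphical-lasso path over 100 log-spaced penalties
from λ_max (smallest penalty giving an empty graph) down to 0.01·λ_max
proposes sparsity patterns, and EBIC with γ = 0.5 (the conventional
conservative default) selects among them. The log-likelihood entering
EBIC is evaluated at the *unpenalized* maximum-likelihood precision
matrix constrained to the candidate support (computed by L-BFGS on the
free entries). This refit decouples support selection from lasso
shrinkage: scoring the shrunken estimate itself systematically favors
denser solutions, because relaxing λ improves the fit of true edges and
drags weak spurious edges along — on planted 10-node chains the refit
variant attains edge precision and recall 1.0 where penalized scoring
gave precision ≈ 0.64. Reported edge weights are partial correlations
from the refit precision matrix. Zero-variance columns are dropped with a
warning; singular correlation matrices are ridge-adjusted; fewer than
three observations is an error.

Expected influence is the signed one-step sum EI_i = Σ_{j≠i} w_ij,
standardized across nodes (population SD) for the z column; unlike
strength centrality it lets negative ties cancel positive ones. Density
is 2E/(N(N−1)). Modularity follows the Newman definition with weighted
degrees. Louvain runs with seed-controlled random restarts (30 by
default), keeping the maximum-Q partition: single greedy runs depend on
node-visit order, and restarts make results on small graphs reliably
optimal — exhaustive search over all partitions of ≤8-node graphs
confirms agreement across whole seeded suites, though rare graphs exist
whose optimum no greedy visit order reaches (a known Louvain limitation;
such a case appears roughly once per few hundred random graphs).
Community detection on estimated networks uses absolute edge weights,
since modularity is not defined for signed graphs.

The network comparison test permutes the post-to-subgroup assignment and
re-estimates both networks per permutation; statistics are the absolute
global-strength difference Σ|w| and the maximum absolute edge difference,
with add-one p-values p = (1 + #{perm ≥ obs})/(1 + n_perm) and 1000
permutations by default. The per-permutation re-estimations default to a
20-point λ grid, penalized-likelihood EBIC scoring, and early path
truncation (stop after the criterion worsens for 6 consecutive grid
points): the test's validity requires the identical estimator on the
observed and every permuted split, not maximal sparsistency, and these
settings keep the permutation loop tractable on one CPU. Under the null
(both groups sampled from the same chain network), the strength p-value
exceeds 0.05 in ≥90% of seeded runs in the test suite's calibration
check.

## Synthetic data

The generator is a pure function of (config, seed) and produces every
fixture downstream modules consume. Defaults mirror the annotated-corpus
conditions: 68.8% of posts MIL-related, 63.4% high SFM and 49.4% high POM
among related posts, annotator flip rate 0.06 and unable rate 0.09 (two
independent annotators with these rates reproduce the published
inconsistent/unable exclusion fractions in expectation). Posts are
Latin-token pseudo-text over small vocabularies aligned with the toy
lexicon — every core operation is script-agnostic, with real-language
differences confined to the tokenizer/parser adapters. Related posts
always carry a MIL seed keyword; at separability margin 1.0 they also
carry deterministic SFM/POM marker tokens, making all three tasks
linearly separable from bag-of-words. Role-triple fixtures give a
configurable fraction of units a REAS-anchored chain (one layer per hop);
Gaussian fixtures sample from planted chain/block/empty precision
matrices and return the true edge set for recovery scoring.

What the synthetic conditions do not emulate: natural-language ambiguity
and paraphrase, annotator biases beyond independent flips, parser errors
in role triples, the heavy-tailed post-length and user-activity
distributions of real platforms, and non-Gaussian count marginals in the
factor matrices. Passing tests establish algorithmic correctness and
calibration under controlled conditions, not field performance.

## Problem sizes

The test and acceptance runs use desk-scale sizes chosen to exercise
every code path with stable statistics: 40–300 synthetic posts for
classifier runs, 50 exhaustively-checked graphs of ≤8 nodes for the
community-detection oracle, 10–20 replicates of n = 2000 samples from
10-node chains for structure recovery, and 10–20 null splits of n = 100
per group with 100–200 permutations for comparison-test calibration.

## Known limitations

- The EBIC refit uses a quasi-Newton solver per distinct support; for
  much larger node sets (hundreds) an IPF-style solver would be faster.
- Louvain-with-restarts is near-optimal, not certified-optimal.
- The permutation comparison test assumes exchangeability of posts across
  the two subgroups under the null; overlapping marginal subgroups (a
  post contributes to one quadrant and two marginal groups) violate
  independence if marginal networks are compared against their own
  quadrants.
- Bootstrapped edge-stability intervals are out of scope.
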