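# Methods

## Model

A compound is a heavy-atom graph G = (V, E): no hydrogens, no bond-order
information, no 3-D coordinates. Each atom carries a 78-d binary feature
vector of five blocks — atom symbol over a frozen 44-symbol vocabulary (43
elements plus "other"), number of adjacent heavy atoms, number of attached
hydrogens, and implicit valence each as 11 buckets (0–10, values above 10
clamped to the last bucket), plus one aromaticity bit. The vocabulary
follows the common graph-convolution featurizer convention and is frozen in
`mol_graph.ATOM_SYMBOLS` because reordering it silently changes feature
indices of saved models. Atoms are renumbered into RDKit's canonical order,
so different SMILES spellings of one molecule produce identical graphs.

The compound encoder stacks exactly one multi-head attention layer and one
graph convolution. Attention neighbourhoods include the atom itself
(self-loop), so isolated atoms are well defined and every attention row is
a proper distribution. The attention score for the directed pair i → j is
LeakyReLU(aᵀ[Wh_i ‖ Wh_j]) with slope 0.2; coefficients are
softmax-normalized over the neighbourhood, per head. Each head applies ReLU
before the K heads are concatenated. The following GCN uses the symmetric
normalization D̃^{-1/2}(A + I)D̃^{-1/2} with ReLU. The readout concatenates
column-wise max and mean over atoms; all three stages are permutation
equivariant/invariant, so the embedding does not depend on atom order.

The pathway dependence graph is directed. From training labels only:
co-occurrence counts U (diagonal zero — self-dependence is carried by the
identity term added during propagation, counting it twice would
double-weight it), conditionals p_ij = u_ij/N_i (rows with N_i = 0, a label
absent from a fold, are zeroed), hard threshold τ, and column-sum
re-weighting m^w_ij = m_ij / Σ_k m_kj (a row-sum switch is exposed; the
column form is the default). The label-GCN propagation operator
D_x^{-1}(α·M_w + I) is row-stochastic by construction for any α ∈ [0, 1]
and deliberately asymmetric, unlike the compound GCN's symmetric operator.
Its LeakyReLU slope is 0.01.

Node features are word vectors of the pathway names: lowercase, strip
punctuation, split on whitespace, unweighted mean of in-vocabulary token
vectors; names with no in-vocabulary token get a seeded Gaussian row. The
feature matrix is then standardized per dimension across labels. Pathway
names share generic tokens ("metabolism" appears in nearly every name), so
raw token means consist of a large shared offset plus small between-label
differences; standardization removes the offset, matches the feature scale
of the random-initialization ablation, and keeps only the between-label
similarity structure the embeddings are meant to contribute. Because the
features enter the encoder through a learnable linear map, any full-rank
feature matrix is equivalent up to rotation — conditioning, which
standardization fixes, is the practically relevant difference.

The predictor's adapter is input → hidden → output with ReLU on the hidden
layer; the output logit for pathway i is the bias-free inner product of the
pathway's embedding row with the adapted compound vector. The loss is the
mean per-label binary cross-entropy with logits, implemented with the
log1p-exp softplus guard (stable to |logit| ≈ 1e4); its gradient is
σ(ŷ_i) − y_i up to the 1/C factor. Decisions threshold σ(ŷ) at 0.5 by
default; ranking metrics use raw scores and never the threshold.

Defaults: K = 10 heads × 78 dims (→ 780), GCN 780, readout 1560, adapter
1560 → 1500 → 1024, pathway layers 300 → 1024 → 1024, τ = 0.5, α = 0.3,
Adam with lr 5e-4, 200 epochs, batch 256. No dropout, weight decay,
gradient clipping, learning-rate schedule or early stopping.

### Ablation switches

* `no_pathway_encoder` — the pathway embedding matrix O becomes a free
  learnable C×B parameter trained end-to-end (no dependence graph, no word
  vectors).
* `no_adapter` — compound embeddings are scored directly; the pathway
  output width is forced to 2t so the inner products are defined.
* `random_label_init` — node features are i.i.d. standard normal instead
  of word vectors; the dependence graph is unchanged.

## Metric conventions

Accuracy/precision/recall/F1 are micro label-based over all
(sample, label) cells, which makes accuracy + Hamming loss = 1 an exact
identity (asserted in tests). Zero-division in precision/recall yields 0
with a warning. Ranking ties break by ascending label index; a tied
true/false pair counts as mis-ordered in ranking loss; samples with no
(true, false) pair are skipped there. Coverage is 1-based (the rank of the
deepest true label) with a 0-based switch, since both conventions are in
circulation. The implementations are cross-checked against scikit-learn's
`hamming_loss`, `label_ranking_loss`, `coverage_error` and micro
precision/recall/F1 on tie-free scores.

## Synthetic data generator

`generate_fixture` emulates a pathway-annotated compound table at small
scale. Label vectors are drawn from a Gaussian copula whose pairwise
latent correlations are solved (bisection on the bivariate normal CDF) to
reproduce a requested matrix of pairwise joint probabilities with marginals
on its diagonal; infeasible requests (a joint above the smaller marginal or
below the Fréchet lower bound) raise. All-zero label rows are
rejection-resampled — every record keeps at least one label, which slightly
inflates marginals relative to the request — and pairs requested exactly at
the upper Fréchet bound are enforced deterministically (label containment).

The default spec gives six labels with marginals 0.25–0.35, one strongly
dependent pair p(l1 | l0) = 0.95, and independence elsewhere. SMILES are
assembled from a curated ~45-fragment vocabulary (alkanes, alcohols,
amines, carboxylic/amino acids, aromatics and heteroaromatics,
organophosphates, thiols), joined by single bonds at H-bearing atoms: a
small alkane backbone plus one fragment per positive label that has an
associated fragment class — alcohols for the carbohydrate-like label,
thiols/phosphates for the energy-like label, amines/acids for the
amino-acid-like label, (hetero)aromatics for the xenobiotics-like label,
long alkanes for the lipid-like label. The glycan-like label l1
deliberately has *no* fragments of its own; its only signal is its
dependence on l0, which is the case the pathway encoder exists for. With
probability 0.4 a compound additionally carries one fragment drawn from a
random class regardless of its labels, because real molecules contain
substructures unrelated to their pathways; without this confusable content
every model variant saturates and comparisons between variants are
uninformative.

The companion word-vector file (`write_demo_wordvec_file`) is *synthetic*,
not trained: token vectors are cluster centres (domain-related tokens such
as carbohydrate/glycan or amino/acid share a centre) plus token noise, all
hash-seeded and therefore byte-identical across runs. It emulates the one
property of pre-trained embeddings the model uses — semantically related
names get similar vectors.

What the generator does not emulate: real chemical diversity (fragments
come from a fixed vocabulary), label noise in curated databases, the
long-tail label-frequency distribution of real pathway data, and any
relationship between molecular size and annotation. Passing tests on this
fixture therefore demonstrate that the machinery learns planted
structure-label and label-label dependence, not real-data performance.

## Problem sizes and numerical choices

Experiments and tests run a reduced layout (`small_layout`): 4 heads × 16,
GCN 64 (embedding 128), adapter hidden 64, pathway width 64, word vectors
r = 50, batch 64 — the same architecture at widths where a training run on
a few hundred compounds takes seconds on one CPU core. The pathway width
and word-vector width are kept comparatively generous because narrowing
them bottlenecks exactly the component the ablations probe. Study sizes:
end-to-end learning uses a 500-compound fixture (100 held out, 50 epochs);
the stochastic ablation and attention comparisons use a 250-compound
fixture (70 held out), 90 epochs — past convergence at this scale — and 5
seeds.

All tensors are float64. Parameters initialize Glorot-uniform from a
seeded generator; biases at zero. Gradient routing through the max-pool
follows NumPy's first-argmax tie convention. Softmax rows are
max-shifted before exponentiation; empty attention neighbourhoods cannot
occur (self-loops). Training is deterministic given `random_state` on a
fixed platform.

At this synthetic scale the no-pathway-encoder ablation trails the full
model by only ~1 F1 point at convergence, and structured vs random label
initialization is a statistical tie (see the standardization note above:
with C = 6 labels any well-conditioned initialization spans the same
space). Both orderings match the expected direction, but their effect
sizes on synthetic data are much smaller than on real pathway data, where
the label structure is richer and co-occurrence statistics noisier.

## Known limitations

* Bond types, charges, stereochemistry and 3-D structure are not encoded;
  molecules differing only in those respects are indistinguishable.
* The dependence graph is estimated per training fold; with very small
  folds a label can vanish (its conditional row is zeroed) and the
  threshold τ acts on noisy conditionals.
* Attention weights are a heuristic attribution — they are what the model
  attends to, not a causal explanation; no faithfulness benchmarking is
  attempted.
* The decision threshold is global (0.5); per-label calibration is out of
  scope.
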