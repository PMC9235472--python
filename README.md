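# mlpathway

Multi-label prediction of the metabolic pathway classes a small-molecule
compound participates in, from its 2-D structure alone — with per-bond
attention weights that indicate *which substructures* drive each assignment.

Knowing the pathways a drug-like compound is metabolized by matters during
lead optimization, but assaying candidate compounds against every pathway
combination is slow and expensive. `mlpathway` treats the problem as
multi-label classification over C pathway classes (e.g. the 11 top-level
KEGG metabolism categories) and, unlike per-label classifiers, explicitly
models *pathway crosstalk*: pathways co-occur in asymmetric, directed ways
(a compound in glycan biosynthesis is very often also in carbohydrate
metabolism, but not vice versa), and exploiting that dependence improves
prediction for labels with weak structural signal.

## The model

Three jointly trained components:

**Compound encoder.** A molecule with N heavy atoms is a graph with 78-d
binary atom features h_i (symbol one-hot, degree, H count, implicit
valence, aromaticity). One multi-head graph-attention layer computes
normalized coefficients α_ij = softmax_j LeakyReLU(aᵀ[Wh_i ‖ Wh_j]) over
each atom's neighbourhood and aggregates h'_i = ReLU(Σ_j α_ij W h_j),
concatenating K heads. A graph-convolution layer follows,
H^c = ReLU(D̃^{-1/2} Ã D̃^{-1/2} H W), Ã = A + I, and a global max‖mean
readout yields the compound embedding z ∈ R^{2t} (1560-d at default
widths). The head- and direction-averaged α_ij score the importance of each
chemical bond.

**Pathway encoder.** From the *training* labels, pairwise co-occurrence
counts U and label totals N_i give the asymmetric conditional matrix
p_ij = u_ij / N_i, hard-thresholded at τ (m_ij = 1 iff p_ij ≥ τ) and
re-weighted by column sums, m^w_ij = m_ij / Σ_k m_kj. Node features Q are
word vectors of the pathway names (GloVe text format, token-mean,
standardized). Two GCN layers propagate with the row-stochastic operator
D_x^{-1}(α·M_w + I): O = σ(D_x^{-1}M_x σ(D_x^{-1}M_x Q W⁰) W¹), giving one
embedding row per pathway.

**Predictor.** A dense adapter (2t → 1500 → B) maps compounds into the
pathway space; the logit for pathway i is the plain inner product
ŷ_i = ⟨O_i, z̃⟩. Training minimizes the mean per-label binary cross-entropy
with logits under Adam (lr 5e-4, batch 256, 200 epochs, τ = 0.5, α = 0.3 by
default).

Evaluation covers eight multi-label metrics: micro accuracy / precision /
recall / F1 over all (sample, label) cells, Hamming loss, ranking loss,
coverage and one-error.

The neural layers run on a compact NumPy reverse-mode autodiff engine
(`mlpathway.autodiff`) whose gradients are verified against finite
differences in the test suite; molecular graphs come from RDKit.

## Worked example

```python
import numpy as np
from mlpathway import generate_fixture, evaluate
from mlpathway.dataset_io import write_demo_wordvec_file
from mlpathway.model import MetabolicPathwayClassifier, small_layout
from mlpathway.interpret import bond_importance

# synthetic 300-compound, 6-label dataset with planted co-occurrence
# (p(glycan | carbohydrate) = 0.95) and substructure-label associations
table = generate_fixture(300, n_pathways=6, seed=42)
wordvecs = write_demo_wordvec_file("demo_wordvecs.txt")

rng = np.random.default_rng(0)
perm = rng.permutation(len(table))
train, test = table.subset(perm[60:]), table.subset(perm[:60])

model = MetabolicPathwayClassifier(
    **small_layout(), epochs=60, random_state=0,
    pathway_names=table.pathway_names, wordvec_file=str(wordvecs))
model.fit(train.smiles, train.Y)
print(f"training loss: {model.loss_curve_[0]:.3f} -> {model.loss_curve_[-1]:.3f}")

for name, value in evaluate(model, test).items():
    print(f"{name:>13}: {value:.3f}")
```

```
training loss: 0.717 -> 0.186
     accuracy: 0.875
    precision: 0.847
       recall: 0.787
           f1: 0.816
 hamming_loss: 0.125
 ranking_loss: 0.070
     coverage: 2.467
    one_error: 0.133
```

Held-out micro-F1 is 0.816; accuracy and Hamming loss are exact complements
(both are computed over the same label cells); coverage 2.47 means the
ranked label list must be read 2–3 deep on average to cover every true
pathway. Querying a cysteine-like compound shows both prediction and
attribution:

```python
smiles = "SCC(N)C(=O)O"          # thiol + amino-acid fragment
proba = model.predict_proba([smiles])[0]
(graph, attn), = model.bond_attention([smiles])
```

```
Carbohydrate metabolism                       0.00
Glycan biosynthesis and metabolism            0.01
Energy metabolism                             0.75
Amino acid metabolism                         0.91
Xenobiotics biodegradation and metabolism     0.00
Lipid metabolism                              0.00
bond N0-C6: 0.369
bond O1-C5: 0.354
bond O2-C5: 0.344
bond S3-C4: 0.390
bond C4-C6: 0.227
bond C5-C6: 0.211
```

The model assigns the energy and amino-acid labels, and the sulfur-carbon
bond receives the highest attention while the carbon-carbon backbone bonds
receive the lowest — the substructures planted for those labels in the
generator are exactly the ones the attention highlights.

## Command line

```bash
mlpathway data fixture --n 500 --pathways 6 --seed 0 --out data.csv
mlpathway data stats data.csv
mlpathway train --data data.csv --config config.yaml --out model.npz
mlpathway cv --data data.csv --k 10 --seed 0         # eight metrics, mean ± sd
mlpathway eval --model model.npz --data data.csv
mlpathway grid --data data.csv --tau 0.3 --tau 0.5 --alpha 0.2 --alpha 0.4
mlpathway interpret --model model.npz --smiles "SCC(N)C(=O)O" --out bonds.csv
```

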