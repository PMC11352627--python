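# Methods

## Model

The regressor maps an ordered drug pair plus a cell line to a scalar
Loewe-style synergy score. Four SMILES-derived drug modalities are
encoded by separate branches and concatenated with a cell-line feature
before a three-layer fully connected head. Architectural constants that
define the method — 256-bit radius-2 Morgan fingerprints, the
3→32→64→128→160 point-cloud channel schedule, the 3/2/1-layer GCN parts
over power-graph supports of orders 1/2/3, the head whose second layer is
half the first and whose output is a single neuron — are fixed in code.
Everything the method leaves open is configuration with defaults
(`synergynet.config`).

Assumptions worth stating explicitly:

* **Power graphs are cumulative.** The order-k support connects atom
  pairs at shortest-path distance in [1, k], because each support serves
  as a standalone message-passing operator and should contain the bond
  graph. The exact-distance reading is available via
  `power_mode="exact"`.
* **No self-loops in normalisation.** `Â = D^{−1/2} A D^{−1/2}` is used
  literally; `add_self_loops=True` gives the common A+I variant.
  Zero-degree atoms (isolated ions) have their degree clamped to 1,
  producing a zero row rather than NaN.
* **Weight sharing.** The two drugs share the sequence encoder, and one
  GCN weight set encodes drug 1, drug 2 and the pair graph (Siamese
  reading); `share_weights` can untie them.
* **gMLP input** is the full 2·d_l BiLSTM output (information-
  preserving); `gmlp_input="forward_half"` restricts to the forward
  direction. The spatial gate is initialised near zero with bias one, so
  each block starts close to a plain linear map of Z₁.
* **Pooling.** Attention-fused sequence features are masked-mean-pooled
  over atom positions; the point-cloud stack is global-max-pooled over
  cloud positions (`cloud_pool`/`seq_pool` configurable). With max
  pooling, enlarging the zero padding of a cloud cannot change the
  output, a property the tests assert.
* **Point clouds are not centred or rotationally aligned**; the conformer
  (seeded ETKDG, optional MMFF relaxation) fixes the frame. The conv
  encoder is consequently not rotation-invariant — a caveat, not a bug.
* **Drug order.** Nothing in the architecture symmetrises the pair.
  Training augments each example with both orderings and prediction
  averages them (`order_augment`, default on), removing an arbitrary
  asymmetry without touching the branch structure.
* **Predictor input.** The fused drug feature is
  `H_m ‖ H_c ‖ H ‖ H_D1 ‖ H_D2` (fingerprint splice, attention-fused
  sequence feature, three-part graph feature, per-drug cloud features),
  concatenated with `F_cell`.

Activations: ReLU in GCN, conv and head layers; GELU inside gMLP.
BatchNorm uses batch statistics in training and running statistics in
evaluation, so single-example prediction is well defined.

The ablation variants `MMFSyn-CA`/`MMFSyn-SA` replace the concatenation
fusion with a minimal single-block cross-/self-attention over
per-modality tokens; they are interpretive reconstructions of a sketched
design and should be read as such.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `fp_bits`, `fp_radius` | 256, 2 | fingerprint length/radius (method constants) |
| `max_atoms` | 64 | atom-sequence capacity; gMLP spatial gate is (max_atoms)² |
| `cloud_points` | 100 | padded point-cloud length, ≥ largest drug |
| `lstm_units` d_l | 64 | BiLSTM width per direction |
| `gmlp_layers`, `gmlp_dim` | 3, 128 | depth and channel width of the gMLP stack |
| `heads`, `head_dim` | 4, 32 | attention fusion geometry |
| GCN `width` | 64 | per-layer width; graph feature is 9·width per pair |
| `predictor_width` | 1024 | first head layer; second is half by the halving rule |
| batch, lr0, gamma, step | 256, 1e-3, 0.9, 20 | the training protocol |
| weight decay | 0.01 | AdamW decoupled decay (protocol leaves it open) |
| epochs / patience | 100 / 20 | epoch budget with early stopping on validation MSE |

A scaled-down preset (`small_model_config`: d_l 24, gMLP 2×48, 2 heads of
16, GCN width 24, head 384, `max_atoms`/`cloud_points` 32) is what the
tests and the acceptance script train; it preserves every architectural
constant and is sized so a full training run fits in minutes on one CPU
core. Those are the problem sizes the reported numbers use.

## Numerical core

No deep-learning framework is a dependency: `synergynet.nn` is a small
reverse-mode autodiff engine over float64 NumPy arrays (dense dynamic
graphs; matmul with broadcasting, gather/scatter for the unique-entity
batching, masked reductions) with LSTM, Conv1d, BatchNorm1d and AdamW on
top. Gradient correctness is enforced by central finite differences in
the unit tests, and determinism is inherited from NumPy: identical seeds
give bitwise-identical splits, loss curves, predictions and checkpoints.

Batching exploits screen structure: encoders run once per unique drug,
unique pair and unique cell line in a batch, and outputs are gathered per
example (scatter-add in the backward pass). This is exact, not an
approximation, and is what makes CPU training practical.

## Synthetic screens

`synergynet.synthetic` generates complete screens: scaffold-decorated
drug-like SMILES (all parse and embed), correlated Gaussian expression
factors, Bernoulli(0.02) mutations, and scores from a documented
generating function of fingerprint overlap, atom-count interaction,
order-3 power-graph density and an expression projection, with a softplus
tail that skews the marginal positive. Components are standardised by
exact enumeration over the (pair × cell) grid, so the marginal mean and
signal variance are controlled by construction; the default noise level
puts the best achievable Pearson correlation near 0.95. The structural
pair term is deliberately *count-based* — the atom-count mismatch
|n_A − n_B| — over a vocabulary in which plain CH₂ chains drive much of
the size variation: repeated chain environments collapse onto the same
fingerprint bits (a binary fingerprint records presence, not
multiplicity) and a max-pooled convolution cannot count positions,
whereas a bidirectional recurrent encoder integrates over atom positions
and recovers counts directly.

The branch-ablation experiment (full model vs the fingerprint+cloud
baseline) is scored under **leave-drug-out** evaluation (80:20): whole
drugs are held out, so test pairs contain unseen chemistry and per-drug
memorisation — which any drug-identifying feature, including a hashed
fingerprint, supports when all drugs are seen — is useless. Two noise
reducers make the comparison measure representation rather than luck:
predictions are pooled over two rotated held-out-drug folds (the
dominant variance source is which handful of drugs is held out), and
each variant's prediction is the average of two independently seeded
training runs. Even so, the two models share most of their achievable
accuracy (the cell-line and fingerprint pathways are common), so the
measured ordering gap is a few hundredths of a correlation point —
consistent in direction across the seeds examined during design, but
small; the honest reading is a directional check, not a large effect.

What the generator does **not** emulate: real pharmacology (targets,
pathways, dose–response shapes), realistic mutation–drug interactions,
tissue-level score shifts, or assay noise structure. Passing the
learnability tests therefore demonstrates that the architecture,
optimisation and plumbing can recover a multimodal signal of the stated
form — not that the model predicts real synergy screens at any particular
accuracy.

## Degenerate inputs and tie-breaks

Unparseable SMILES, oversize molecules and failed conformer embeddings
raise typed errors naming the drug. Constant columns z-score to zeros.
Zero-variance prediction vectors mark correlations as undefined (`None`)
rather than propagating NaN. Max-pool gradient ties share gradient
equally. Duplicate (A,B,cell) rows — in either drug order — are rejected
at read time.

## Known limitations

* The atom feature set (width 27) is a documented, configurable choice;
  published variants of such featurizers differ in block composition.
* The cloud encoder sees absolute coordinates; two conformers of the same
  molecule give different features.
* `max_atoms` caps molecule size; screens with larger ligands need a
  larger preset (cost grows quadratically in the spatial gate).
* Expression standardisation uses all cell lines (cell-line covariates
  are shared across CV folds; example scores never enter the scaling), a
  deliberate simplification toggleable via `read_omics(standardize=...)`.
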