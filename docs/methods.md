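# Methods

## Problem and model

`convner` does character-level named-entity recognition for Chinese
clinical text. Each sentence is a sequence of characters
X = (x₁, …, xₙ); each character receives a BIO label (B-t / I-t for an
entity of type t, O otherwise). Two label schemes ship with the
package: a six-type clinical scheme (disease, position, LabCheck,
check, drug, method → 13 labels) and a seven-type stomatology scheme
(15 labels). In general a scheme with E entity types has 2E + 1 labels.

The full model is a four-stage pipeline:

1. **Embedding.** Either a trainable per-character lookup table
   (default; width 64) or a frozen pretrained contextual embedder
   consumed through an adapter (expected width 768). Before the
   convolutional stack the L × D embedding matrix gains a singleton
   leading axis, making it an image-like map of height 1 and width L so
   that 2-D convolutional operators act as 1-D sequence convolutions.
2. **Convolutional encoder.** A ConvNeXt-style stack adapted to
   sequences: a stem convolution (kernel 4, stride 1 → 128 channels,
   then layer norm), four stages of inverted-bottleneck blocks in the
   ratio 3:3:9:3 at widths 128/256/512/1024, and a layer-norm +
   kernel-2 stride-1 convolution downsampling layer between stages.
   Every operator is stride 1 with zero padding, so sequence length is
   preserved throughout — "downsampling" here only widens channels.
   The final map of each stage is recorded and the four maps are
   spliced (concatenated) along channels, giving L × 1920 features at
   the default widths. Each block is: depthwise convolution →
   layer norm → 1×1 convolution expanding channels 4× → GELU → 1×1
   convolution back → residual connection.
3. **BiLSTM.** A bidirectional LSTM (classic six-equation cell,
   per-gate weights on [h_{t−1}, x_t]; default width 256 per direction)
   concatenating forward and backward states per position, capturing
   long-range dependencies the convolutions miss.
4. **CRF.** A linear-chain conditional random field over label paths:
   S(X, y) = Σ A[yᵢ, yᵢ₊₁] + Σ P[i, yᵢ] with a (K+2)×(K+2) transition
   matrix (two extra states for start/stop) and emissions P produced by
   a single affine map from the previous layer. Training minimises
   −log p(y|X) = log Z − S(X, y) with the partition computed by the
   log-space forward recursion; prediction uses Viterbi decoding.

Five variants assemble subsets of these stages (conv-crf, bilstm-crf,
conv-bilstm-crf, contextual-conv-crf, contextual-conv-bilstm-crf); the
emission projection attaches to whatever encoder comes last.

## Numerical and design choices

**Autodiff.** All layers run on a small in-repo reverse-mode autodiff
engine over float64 numpy arrays. Float64 keeps the enumeration and
finite-difference checks meaningful at 1e−6/1e−4 tolerances; the
models at test scale are small enough that speed is acceptable.

**GELU** uses the exact erf form x·Φ(x), not the tanh approximation;
its gradient Φ(x) + x·φ(x) is likewise exact. **Layer norm**
normalises the channel vector of a single position (biased 1/n
variance, ε = 1e−6 default) followed by a learnable affine; the
pre-affine transform is exposed separately for testing.

**Depthwise kernels** are stored in their full Dk × Dk × M form even
though the height-1 map means only the centre row touches data (the
off-centre rows see the zero padding of the singleton axis). This
preserves the Dk·Dk·1·M parameter arithmetic of the 2-D formulation —
1/N of a standard convolution's Dk·Dk·M·N — at a negligible memory
cost. The closed-form `count_parameters` reproduces the instantiated
model's count exactly, including this convention. The block's
depthwise kernel size is 7 (the ConvNeXt default; configurable) and
the pointwise expansion factor is 4; both are inherited from the
ConvNeXt lineage of the block design. No stochastic depth or layer
scale is used.

**Padding.** Odd kernels get symmetric zero padding; even kernels
(stem 4, downsample 2) get one-sided right padding. Inputs are masked
to zero before the stem and outputs re-zeroed after every layer, so
padded positions can never influence real ones (tested by perturbing
padded cells). Zero-depth stages do not participate in the splice and
need no downsampling layer into them; an all-empty stack degenerates
to the stem output.

**CRF conventions.** Start/stop are two extra states of the transition
matrix; emissions never cover them. The BIO legality mask ("I-x only
after B-x or I-x") is applied at decode time by default and left out of
the partition during training (soft training, hard decoding).
Forbidden moves score −1e30 rather than −∞ to keep log-space
arithmetic NaN-free. Viterbi ties resolve to the lowest label index at
every backtrack step (numpy's argmax-first convention); the brute-force
oracle applies the same rule, so path equality — not just score
equality — is testable. Padded positions are excluded from both score
sums, with the stop transition taken from the last real position.

**Entity scoring** is exact-match at the (type, start, end) level — the
convention whose F1 magnitudes clinical NER evaluations report — with
micro-averaging for the comprehensive value and per-type rows
alongside. Zero denominators yield 0. An illegal I-continuation in a
predicted sequence is repaired by opening a new span at that position.

**Training** uses Adam (lr 0.001), batch 16, dropout keep-probability
0.5 on the embedding and final encoder outputs, gradient-norm clipping
at 5.0, and default 60 epochs with best-on-validation checkpointing
and no early stopping. A single seeded generator drives shuffling and
dropout, so single-threaded runs are bit-reproducible. LSTM forget
gates start with bias 1; other weights are Glorot-uniform.

## Synthetic corpus generator

Real clinical corpora in this area are restricted or external, so the
package generates BIO corpora that emulate their statistical shape:
sentences of CJK characters (length uniform on 10–30, the scale of EMR
phrases) containing non-overlapping multi-character entity mentions.
Mentions per sentence are Poisson with mean 2.0 (entity density of the
same order as annotated EMR lines), types drawn from uniform mixing
weights by default, surfaces from a per-type lexicon of 30 strings of
2–5 characters. Filler characters come from a fixed 200-character CJK
block disjoint from all lexicon characters, and each type's lexicon
draws on a private character pool, so entity membership and type are
learnable from characters alone. An `overlap` knob mixes filler
characters into the pools to harden the task.

What this does *not* emulate: real Chinese morphology and grammar,
ambiguous entity boundaries, type confusions between lexically similar
entities, nested or discontinuous mentions, annotation noise. Passing
the end-to-end test therefore shows the pipeline can learn and decode
a character-identifiable tagging task — it says nothing about F1 on
real clinical text, which is known to be far harder. In particular,
because entity membership here is decodable from single characters, a
plain bilstm-crf baseline can match or exceed the full model on this
corpus; the convolutional encoder's value lies in harder, context-
dependent data, which the synthetic study deliberately does not claim
to represent.

## The standard study and problem sizes

`convner.experiments.run_synthetic_study` fixes the study conditions:
2000 sentences over the six-type scheme (corpus seed 42), split 6:2:2,
and a reduced conv-bilstm-crf — lookup embeddings of width 64, conv
channels 16/32/64/128 (out width 240), BiLSTM width 64 — trained at
most 20 epochs with early stop once validation F1 clears 0.93 and
best-on-validation restoration. The reduced widths keep a single-CPU
run in the minutes range while exercising the full architecture
(3:3:9:3 stack, splicing, masked batching, CRF decode). The held-out
entity-level F1 of this study is the package's headline number;
`scripts/acceptance.py` recomputes it from scratch along with a
bilstm-crf baseline (capped at 12 epochs) and the deterministic
CRF/layer cross-checks.

## Known limitations

- No GPU path and no minibatch parallelism beyond numpy BLAS; the
  full-width encoder (1920 spliced channels) is instantiable and
  testable but not trainable at realistic corpus sizes here.
- The contextual-embedding adapter consumes locally stored static
  per-character vectors; it does not run a transformer forward pass,
  so "contextual" width is supported but true context dependence of
  the pretrained embeddings is up to the provider of the weights.
- The CoNLL-style dialect cannot represent a character equal to the
  column separator (rejected with an explicit error).
- Document-level splitting is not implemented; the splitter works at
  sentence granularity.
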