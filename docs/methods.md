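# Methods

## Model

The predictor is a multi-modal fusion network over protein sequence alone.
Per residue it combines three streams:

1. a contextual embedding from a protein language model (pLM), width 1280
   by default;
2. the five Atchley factors — standardized scores distilling ~500
   physicochemical amino-acid attributes into polarity, secondary-structure
   propensity, molecular volume, codon diversity and electrostatic charge;
3. the residue's 20 substitution scores against the standard alphabet from
   BLOSUM50, a log-odds matrix estimated from conserved alignment blocks
   clustered at 50% identity.

Streams 2 and 3 are projected (linear → ReLU → LayerNorm) to 512
dimensions, given fixed sinusoidal positional encodings, and refined by a
single 8-head self-attention layer with a residual connection. The pLM
stream is used unmodified (no normalization is applied to it by default).
The three streams are concatenated per residue in the fixed order (pLM,
Atchley, BLOSUM) to a 2304-wide vector and processed by a stack of post-norm
transformer encoder layers (8 heads, position-wise feed-forward, residual +
LayerNorm + dropout). Two MLP heads (ReLU, dropout) emit two-class logits:
per residue, and per protein after masked mean pooling. Binary calls use an
inclusive threshold (probability ≥ t, default 0.5); an optional
validation-MCC-maximizing threshold search is provided.

Assumptions worth stating: padding must never influence real positions
(enforced by additive attention masks and per-position normalization, and
property-tested); a two-class softmax head is used even though labels are
binary, so logits are shift-invariant; the protein-level and residue-level
tasks share one architecture but are trained as separate task modes.

### Design choices where the design was open

* **Pooling** for the protein head is a masked mean; CLS-style first-token
  pooling is available behind a config flag.
* **Positional encoding** is the fixed sinusoidal table, applied only to
  the two prior streams, not to the pLM stream.
* **Backbone width** equals the fused width (no down-projection); an
  optional input projection exists for small-compute runs.
* **Backbone depth** defaults to 2 layers and the head hidden widths to
  (512, 128); both are config-exposed, as are all optimizer
  hyperparameters.
* **Intra-modal refiner** is attention + residual only, without a
  feed-forward sub-block.
* **Nonstandard residues** (X, B, Z, U, O, J) encode as all-zero rows in
  both prior streams — a neutral prior; the pLM backend handles them by its
  own vocabulary.

## Embedding backends

Backends are pluggable through a registry. The default `stub` backend
produces deterministic pseudo-embeddings: each residue row is drawn from a
PRNG seeded by a hash of (seed, position, 5-residue local window), giving
contextual, reproducible rows with approximately unit variance per
dimension. The stub carries no learned knowledge: any sequence signal the
model extracts at desk scale therefore comes from the two prior streams and
from patch context, which is exactly what the synthetic experiments are
designed to probe. A real ESM-2 adapter (final-layer hidden states,
truncation at the context limit with a warning) registers itself when the
optional torch/fair-esm stack is importable; the core package neither
requires nor downloads it.

## LoRA

Adapters wrap the query and value projections of every attention module
(stream refiners and backbone; a finetune-capable pLM would be adapted in
its own integration). A is initialized from N(0, 1/r), B from zero, so the
adapted model is exactly the base model at injection; the update is scaled
by α/r so its magnitude is rank-independent. Merging replaces W with
W + (α/r)·B·A and removes the adapters. Contracts (identity at init, merge
equivalence ≤ 1e-5 relative, r·(d+k) trainable parameters per adapted
matrix, rank(ΔW) ≤ r, frozen bases) are tested directly.

## Training

Cross-entropy with AdamW (decoupled weight decay). Defaults: lr 1e-4,
batch 8 proteins, 20 epochs, weight decay 0.01, 10% seeded validation split
by protein. Residue losses are averaged over real positions only — loss
masking over padding is mandatory. Optional inverse-frequency class weights
are off by default. A run is deterministic given its seed, which fixes
initialization, the split, shuffling and dropout. `repeat_runs` executes
independent seeded repetitions (the benchmark protocol uses 10) and retains
per-seed metric reports for the Mann-Whitney/BH comparison.
`ablate_streams` returns a config with named streams zeroed at the fusion
stage, so ablated models keep identical tensor shapes.

The `small_config()` preset (stream widths 16/16/16, one backbone layer,
8 epochs, lr 3e-3) is the package's desk-scale configuration: it preserves
the architecture's shape while training in seconds on one CPU. Longer
training at desk scale starts to memorize the stub embeddings, which are
noise with respect to held-out sequences, so the preset favors a short
schedule.

## Numerical core

The network runs on a reverse-mode autodiff engine over numpy float64
arrays implementing exactly the required ops (broadcasted arithmetic,
batched matmul, softmax/log-softmax, reductions, reshape/transpose/concat).
Gradients of every composite block are verified against central finite
differences in the test suite. LayerNorm uses ε = 1e-5; attention masking
adds −1e9 to padded key scores; fully masked inputs are rejected up front.

## Structure-derived labels

`structlabel` reads PDB/mmCIF complexes (first model, highest-occupancy
altlocs, hydrogens excluded), flags nucleic chains by residue name
({A,C,G,U,T,DA,DC,DG,DT,DU}), and assigns Bondi-style van der Waals radii
by element (carbon-like 1.70 Å fallback with a warning for exotic
elements). A residue is labeled binding when any of its atoms lies within
margin + r_vdw + r_vdw of any nucleic atom, boundary inclusive, margin
0.5 Å by default. The implementation prunes with a KD-tree at the maximal
cutoff and then tests exact per-pair cutoffs; it is tested against a
brute-force all-pairs oracle and is monotone in the margin.

Sequence identity for redundancy filtering is computed from a global
alignment (match 1, mismatch 0, gap open −10, extend −1) as
matches / alignment length. This denominator is stated explicitly because
CD-HIT's convention (shorter-sequence denominator) differs; an external
CD-HIT can be substituted where exact parity matters. Greedy clustering
processes records longest-first and keeps one representative per cluster at
the chosen threshold (0.3 by convention); dataset assembly also removes
representatives within the threshold of a reference set, mirroring
cross-set overlap removal.

## Metrics and statistics

Precision, recall, F1 and MCC are computed exactly from confusion counts;
zero denominators return 0 with a warning. AUROC uses average ranks, equal
to the pair-counting probability with ties at ½. Relative improvements are
100·(a−b)/b, rounded half-up to two decimals only at the reporting layer.
The Mann-Whitney U test enumerates all label assignments exactly (with
midranks) for combined samples ≤ 12 and otherwise uses the tie-corrected
normal approximation; p-values are two-sided. Benjamini-Hochberg adjustment
is the standard step-up procedure (delegated to statsmodels) with
significance flags at adjusted p ≤ 0.05.

## Composition analyses

Site compositions are letter frequencies over called positions with
additive smoothing ε = 1e-6, renormalized. Enrichment is log₂(site /
background) per letter. KL divergence is computed in nats; *forward* means
KL(true ‖ predicted) and *reverse* KL(predicted ‖ true) — stated explicitly
because the direction labels are otherwise ambiguous. Feature export writes
per-residue or pooled per-protein rows (fused inputs or backbone hidden
states) with class labels as TSV/HDF5 for external t-SNE/UMAP tools; no
embedding is computed in-package.

## Synthetic benchmark

The generator emulates one robust statistical signature of nucleic-acid
binding: interfaces enriched in basic/aromatic residues. Positive proteins
carry 1–3 non-overlapping patches of 8–14 residues whose positions are
drawn from the planted alphabet (R/K/W in DNA mode, R/K/H in RNA mode) with
probability 0.85, on a uniform 20-letter background; lengths are 60–120;
residue labels mark patch membership with 2% flip noise; negatives are
patch-free. These defaults were chosen once as a realistic-but-detectable
regime: patch sizes and enrichment in the range reported for real
interfaces, label noise standing in for annotation error, and a uniform
background (rather than natural frequencies) to keep smoke tests fast and
interpretable. Sample sizes in the shipped experiments are 200 training and
100 held-out proteins with 3 seeds — small enough to run in about a minute
while leaving clear statistical margins.

`generate_toy_complex` writes a minimal PDB consistent with a record's
labels: one CA pseudo-atom per residue along a jittered line and one
phosphorus pseudo-atom near each labeled residue, placed strictly inside
that residue's contact cutoff and strictly outside every other residue's.
Toy complexes are always built from the labels as given, so the geometric
round-trip through the contact labeler is exact, not approximate;
noise-flipped datasets should generate complexes from noiseless labels.

What passing these experiments shows: the full pipeline (encodings,
embedding plumbing, fusion, attention, training, evaluation, labeling,
statistics) is internally consistent and can learn a composition-plus-
context rule from sequence alone. What it does not show: performance on
real proteins. Real binding sites depend on fold context, are not
contiguous in sequence, and the real pLM contributes most of the signal at
benchmark scale, whereas the stub contributes none; no number from the
synthetic experiments should be read as a benchmark estimate.

## Known limitations

* The stub backend makes the pLM stream uninformative by construction;
  desk-scale ablations therefore understate the pLM's real contribution
  (and overstate the priors').
* The identity filter is quadratic in dataset size (no k-mer prescreen);
  adequate for hundreds of sequences, slow for tens of thousands.
* The numpy engine is single-threaded per op and float64-only; the default
  2304-wide architecture is instantiable, but training it at benchmark
  scale is outside this package's intended use.
* Exact Mann-Whitney enumeration is limited to combined samples of 12; the
  10+10-run benchmark protocol uses the tie-corrected approximation.
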