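# nabind

Sequence-based prediction of protein–nucleic-acid binding at two
granularities: **protein-level** classification (does this protein bind
DNA/RNA?) and **residue-level** binding-site labeling (which residues touch
the nucleic acid?). The package is aimed at computational biologists who
want to screen or annotate protein sequences without structures, and at
method developers who need the full surrounding machinery — dataset
construction from complex structures, evaluation metrics, seeded-replication
statistics, and a synthetic benchmark generator — in one place.

## The model

Each residue of a protein of length *L* is described by three complementary
feature streams:

* **pLM stream** — contextual per-residue embeddings from a protein language
  model (*L* × 1280 by default). A deterministic desk-scale stub backend is
  built in; a real ESM-2 adapter can be plugged in as an optional extra.
* **Biophysical stream** — the five Atchley factors of each amino acid
  (polarity, secondary-structure propensity, molecular volume, codon
  diversity, electrostatic charge), projected to 512 dimensions by a linear
  layer with ReLU and LayerNorm.
* **Evolutionary stream** — the residue's 20 BLOSUM50 substitution scores,
  log-odds values score(A,B) = log₂ f(A→B) / (f(A)·f(B)), projected the
  same way.

The two prior streams receive sinusoidal positional encodings and pass
through an 8-head self-attention refinement layer with a residual
connection. The streams are then concatenated per residue
(1280 + 512 + 512 = **2304** dimensions) and fed to a multi-layer
transformer encoder. Two MLP heads emit two-class logits: one per residue,
and one per protein after masked mean pooling.

Fine-tuning uses **LoRA**: a frozen weight W (d × k) is adapted through a
low-rank update W + (α/r)·B·A with B ∈ ℝ^(d×r), A ∈ ℝ^(r×k), r ≪ min(d, k),
applied to the query and value projections of the attention modules. B is
zero-initialized, so injection is exactly identity; merging folds B·A back
into W.

Training minimizes cross-entropy with AdamW, repeated over seeds; models
are compared with two-sided Mann-Whitney U tests over per-seed metrics and
Benjamini-Hochberg adjustment (α = 0.05). Metrics are precision, recall,
F1, MCC and AUROC.

Residue-level ground truth is derived from protein–nucleic-acid complex
structures by the contact rule: a residue is *binding* when any heavy atom
lies within **0.5 Å plus the sum of the van der Waals radii** of any
nucleic-acid atom. Datasets are redundancy-filtered by greedy CD-HIT-style
clustering at 30% global-alignment identity.

The network, LoRA and the AdamW loop run on a compact numpy reverse-mode
autodiff engine inside the package (`nabind.nn`), which keeps the whole
stack dependency-light and exactly reproducible on a single CPU.

## Worked example

Train the desk-scale configuration on synthetic DNA-mode data (positives
carry sequence patches enriched in R/K/W — the residue types enriched at
real DNA interfaces) and evaluate on a held-out set:

```python
from nabind import analysis, synthetic, training
from nabind.model import predict

train_recs = synthetic.generate_dataset(synthetic.SyntheticSpec(n_proteins=200, seed=11))
test_recs  = synthetic.generate_dataset(synthetic.SyntheticSpec(n_proteins=100, seed=1011))

cfg = training.small_config(seed=0)
model, history = training.train(None, train_recs, cfg, val_data=test_recs)
report = training.evaluate_model(model, test_recs, cfg)
print(f"held-out AUROC={report.auroc:.3f}  MCC={report.mcc:.3f}  F1={report.f1:.3f}")

backend = cfg.make_backend()
calls = [predict(r, model, backend).residue_calls for r in test_recs]
site = analysis.site_composition(test_recs, calls)
bg = analysis.background_composition(test_recs)
enr = analysis.enrichment(site, bg)
top = analysis.top_enriched(enr, 3)
print("top-3 enriched letters at predicted sites:", top,
      " log2 ratios:", [round(enr[a], 2) for a in top])
```

Output:

```
held-out AUROC=0.868  MCC=0.514  F1=0.545
top-3 enriched letters at predicted sites: ['R', 'K', 'W']  log2 ratios: [2.13, 2.11, 2.0]
```

The model recovers the planted binding patches on unseen proteins (AUROC
0.87) and the residues it calls binding are strongly enriched in arginine,
lysine and tryptophan — the planted interface alphabet.

The same pipeline is available from the shell:

```bash
nabind simulate --n 200 --mode dna --seed 11 --out-prefix work/train
nabind train --data work/train.labels.tsv --task residue --seed 0 --out work/run
nabind predict --model work/run/model --fasta work/train.fasta --out work/pred
nabind evaluate --pred work/pred/predictions.tsv --truth work/train.labels.tsv --out work/eval.json
```

`nabind label-sites complex1.pdb complex2.cif --out-prefix work/sites`
derives residue labels from real complex structures, and `nabind compare`
runs the Mann-Whitney/BH comparison between two models' seeded runs.

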