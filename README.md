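# melmp

*De novo* prediction of moonlighting proteins from sequence-derived
features, with a stacked multimodal ensemble.

Moonlighting proteins (MPs) perform two or more independent biological
functions. Most computational MP predictors need omics annotation
(interaction networks, expression profiles) that is missing for much of any
proteome. `melmp` is a *de novo* predictor: every input is computable from
the protein sequence itself, so coverage is 100%. It is aimed at
computational biologists who want to rank candidate multifunctional
proteins, and at method developers who need a tested reference
implementation of the underlying encoders and statistics.

## The model

Each protein is encoded into four fixed-length views:

- **Seq** (400): 3-/2-/1-mer counts over the 20 amino acids (8,420 values)
  compressed by the autocorrelation coefficient function,
  r_j = Σᵢ(xᵢ−x̄)(xᵢ₊ⱼ−x̄) / Σᵢ(xᵢ−x̄)², j = 1…400.
- **PSSM** (400): a PSI-BLAST L×20 profile aggregated into a 20×20
  residue-by-column composition matrix, normalized by sequence length.
- **AA** (2P): mean and population variance of the protein's digitized
  series under each of P retained AAindex physicochemical scales
  (P = 553 for a full AAindex1 release).
- **SS** (584): 3-/2-/1-mer counts of the eight-state (SSpro8/DSSP)
  secondary-structure string.

A sub-model per view (Seq → bidirectional LSTM, PSSM → random forest,
AA → multilayer perceptron, SS → autoencoder + random forest) emits a
positive-class probability; a logistic meta-learner fuses them,

φ(z) = 1/(1+e^(−z)),  z = w₀ + Σᵢ wᵢ xᵢ,

trained on out-of-fold sub-model outputs so the stack never sees its own
training predictions. Negatives for training are screened from Gene
Ontology annotation via simRel semantic similarity and three selection
principles (≥8 GO terms; one BP cluster scoring in (0.1, 0.5); at most one
MF cluster in that band). Evaluation is stratified 10-fold CV with
support-weighted precision/recall/F and ROC/AUC; enrichment analyses use
the exact hypergeometric upper tail. See `docs/methods.md` for the full
account.

## Worked example

Everything runs on synthetic data — no downloads. In Python:

```python
from melmp.benchmark import stacked_cv, synthetic_dataset
from melmp.synthgen import SynthConfig

cfg = SynthConfig(n_per_class=(200, 200), seed=42)
data = synthetic_dataset(cfg)           # generate + featurize 400 proteins
result = stacked_cv(data, folds=5, seed=42)
print(f"stacked F = {result['f_stacked']:.3f}  (pooled AUC {result['auc_stacked']:.3f})")
for view, f in result["f_view"].items():
    print(f"  {view:4s} sub-model F = {f:.3f}")
```

prints

```
stacked F = 1.000  (pooled AUC 1.000)
  Seq  sub-model F = 0.745
  PSSM sub-model F = 1.000
  AA   sub-model F = 0.982
  SS   sub-model F = 0.847
```

The synthetic cohort plants class signal in all four views; the fused model
matches or beats the best single view, and the weaker views (here Seq, SS)
are lifted by fusion. With all signals set to 0 the same pipeline scores
F ≈ 0.5 — the stack invents no signal.

The same flow from the shell:

```bash
melmp simulate --seed 42 --out sim/
melmp featurize --fasta sim/sequences.fasta --pssm-dir sim/pssm \
    --aaindex sim/aaindex1.txt --ss sim/ss.fasta \
    --labels sim/labels.tsv --out features/
melmp train --features features/ --labels sim/labels.tsv \
    --strategy stacked --seed 42 --out model/
melmp predict --model model/ --fasta sim/sequences.fasta \
    --pssm-dir sim/pssm --aaindex sim/aaindex1.txt --ss sim/ss.fasta \
    --out predictions.tsv
```

`predictions.tsv` holds one `id / probability / label` row per protein.
`melmp negatives` runs the GO screen (`--obo`/`--edgelist`,
`--term-counts`, `--annotations`), and

```bash
melmp enrich --N 20354 --n 2894 --M 7250 --m 1112 --tail gt
# P = 0.000326571
```

prints the disease-association enrichment of predicted MPs in the human
proteome case study.

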