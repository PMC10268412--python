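# treetrigger

Recursive encoders for token-level event trigger detection in parsed
biomedical text:

* a **Child-Sum Tree-LSTM** over dependency trees (one forget gate per
  child, summed child hidden states), with an optional **softmax /
  LeakyReLU attention** over children replacing the plain sum;
* an **attentive graph encoder** over predicate–argument structure
  (PAS) graphs, run as synchronous message-passing layers with
  self-loops so it stays well-defined on cyclic graphs;
* **fusion** of the two branch representations by concatenation, a
  softmax classifier head, and Adam training of the regularized
  cross-entropy.

Everything (including gradients) is implemented in float64 NumPy on a
small reverse-mode autodiff core (`treetrigger.autodiff`), so the
package has no deep-learning framework dependency and every gradient is
checked against central finite differences in the test suite.

## Layout

| module | contents |
| --- | --- |
| `data_model` | `Token`, `DependencyTree`, `PASGraph`, `LabelSet`, `TriggerAnnotation`, `EmbeddingTable`, span alignment |
| `corpus_io` | CoNLL-X reader/writer, 4-column PAS TSV, BioNLP standoff (T/E lines), directory corpus loader |
| `attention` | attention coefficients and weighted aggregation shared by both encoders |
| `tree_encoders` | fully-connected recursive baseline, Child-Sum cell, plain/attentive tree encoding |
| `pas_encoder` | layered attentive PAS encoding, branch fusion |
| `training` | classifier, loss, Adam loop, span-level P/R/F1 metrics, model (de)serialization |
| `synthetic_data` | seeded corpus generator with a planted, recoverable trigger rule |
| `cli` | `treetrigger` console entry point and heatmap export |

## CLI

```sh
# write a synthetic corpus (train/ and test/ subdirectories)
treetrigger simulate --out corpus --seed 0 --n-sentences 200 --n-test 50

# fit the full model (scale hyperparameters down for the synthetic task)
treetrigger train --corpus corpus/train --out model.json \
    --epochs 15 --hidden 12 --embedding-dim 16 \
    --learning-rate 0.02 --dropout 0 --l2 0.0001 --seed 0

# predict standoff annotations and score them
treetrigger predict --corpus corpus/test --model model.json --out preds
treetrigger evaluate --gold corpus/test --pred preds --out metrics.json

# attention heatmaps (dep/pas, attentive or uniform rows)
treetrigger explain --corpus corpus/test --model model.json \
    --sentence-id td0000-s1 --variant dep-attn --out heat.tsv

# train/evaluate all eight component combinations
treetrigger ablate --corpus corpus/train --test corpus/test \
    --out ablation.tsv --epochs 10 --hidden 12 --embedding-dim 16 \
    --learning-rate 0.02 --dropout 0 --l2 0.0001
```

Ablation flags on `train` (`--no-pas`, `--no-attn-dep`, ...) disable a
branch or replace its attention with the plain/uniform aggregate; a
disabled branch contributes a zero block to the fused representation,
so the reduced models are exact sub-models of the full one.

Default hyperparameters in `TrainConfig` follow the published setup
(batch 32, dropout 0.2, lr 0.001, 50 epochs, L2 0.003, Adam with
beta1 = 0.88 / beta2 = 0.90, hidden 256, embeddings 720); the synthetic
experiments override them to run quickly at small dimension.

## File formats

* **CoNLL-X**: tab-separated `ID FORM LEMMA CPOSTAG POSTAG FEATS HEAD
  DEPREL [...]`, blank line between sentences, optional
  `# sent_id = ...` comments.
* **PAS TSV**: `sentence_id  predicate_index  argument_index  role`
  with roles `arg1..arg4`/`other`; the neighborhood view is
  symmetrized on load.
* **Standoff**: `.txt` plus `T<i><TAB><Type> <start> <end><TAB><surface>`
  lines; T-types in the configured label set become triggers, the rest
  entities; E-lines are validated and kept as metadata. Offsets are
  0-based, end-exclusive. Evaluation is exact-span, exact-type; micro
  scores exclude the reserved NONE class.
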