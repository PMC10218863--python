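# ncrclass

Multi-class classification of non-coding RNAs (ncRNAs) from primary sequence
and predicted secondary structure, with late integration of both information
layers in one neural model.

## The problem

Expressed ncRNAs found in high-throughput sequencing need to be assigned to
classes — lncRNA, miRNA, rRNA, snRNA, snoRNA, tRNA — before any functional
interpretation, but the classes are wildly heterogeneous: lengths span 15 to
almost 12,000 nt, some classes are defined by short conserved motifs (snoRNA
box elements, snRNA Sm sites), others mainly by structure (the tRNA
cloverleaf, the precursor-miRNA hairpin). `ncrclass` implements the full
stack for this task: dataset construction, structure prediction and
annotation, three model-ready encodings, four neural architectures, the
training/cross-validation protocol, and evaluation including cross-tool
benchmark harmonization. A synthetic generator emulates the class
heterogeneity so everything runs and is tested at desk scale with no
database downloads.

## Models and encodings

Each RNA sequence x of length L ≤ 12,000 is represented three ways:

* **ordinal sequence vector** — 17 integer tokens (16 IUPAC letters plus
  padding), right-padded to fixed length;
* **combined structure vector** — the sequence is folded (builtin
  Nussinov-style base-pair maximization, WC+GU, min hairpin 3; optional
  RNAfold adapter), every position annotated with a substructure state
  (F/T/S/M/H/I = 5′ end, 3′ end, stem, multi-loop, hairpin loop, internal
  loop), and each (nucleotide, state) pair mapped to one of 26 tokens;
* **hashed graph features** — per 150-nt window (shift 37 nt), up to 3
  suboptimal structures ("shreps") become graphs with backbone and base-pair
  edges; pairs of rooted neighborhood subgraphs (radius ≤ 1, root distance
  ≤ 4) hash into a weighted 32,768-dimensional feature vector.

Four architectures consume these inputs:

| model  | input            | architecture |
|--------|------------------|--------------|
| GrEnc  | graph vector     | dense(10, ReLU) → softmax(K) |
| SeqEnc | ordinal sequence | embed(17,4) → 4 conv blocks (2×64 kernels; sizes 3/7/11/17; pools 4/4/2/2) → dropout 0.5 → dense(10, ReLU) → softmax(K) |
| StrEnc | combined vector  | as SeqEnc with embed(26,4), kernel size 7 throughout |
| merged (MncR) | sequence + graph | SeqEnc and GrEnc branches in parallel, 10-wide penultimate layers concatenated to 20, → softmax(K) |

Training: Adam (lr 0.001), categorical cross-entropy (optionally
class-weighted, w_c = N/(K·n_c)), batch 100, early stopping after 5 epochs
without a new validation-loss minimum, best-checkpoint restore, and
class-balanced ten-fold cross-validation. Evaluation: per-class and macro
precision/recall/F1, the multi-category Matthews correlation coefficient,
row-normalized confusion matrices, correctness-overlap (Venn) counts, and
harmonization rules for comparing against tools with different label
schemes (label merging, 750-nt cap, similarity filtering against a
reference training set).

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

Generate a six-class synthetic dataset (100 sequences per class, lengths
capped at 300 nt), train a reduced sequence CNN, predict and score:

```bash
ncrclass simulate --profiles general --n-per-class 100 --max-length 300 \
    --seed 1 --out-prefix demo/toy
ncrclass train --fasta demo/toy.fasta --labels demo/toy.labels.tsv \
    --model seqenc --pad-to 300 --kernels 16 --n-blocks 2 \
    --batch-size 50 --max-epochs 40 --seed 1 --out-prefix demo/seqenc
ncrclass predict --fasta demo/toy.fasta --labels demo/toy.labels.tsv \
    --checkpoint demo/seqenc.ckpt.npz --out demo/predictions.tsv
ncrclass evaluate --predictions demo/predictions.tsv --out-prefix demo/eval
```

The run prints:

```
INFO ncrclass: wrote 600 records to demo/toy.fasta
INFO ncrclass: best epoch 39 (val loss 0.5392)
macro_f1        0.8334
macro_precision 0.8511
macro_recall    0.8367
mcc             0.8082
```

(last block from `evaluate`; the demo model is deliberately tiny). The
predictions TSV carries one row per sequence with the true label, the argmax
label and the per-class probabilities:

```
id                      true   predicted  lncRNA    miRNA     rRNA ...
syn_miRNA-mature_00000  miRNA  miRNA      0.000253  0.999109  0.000010 ...
```

`macro_f1` is the unweighted mean of the per-class F1 scores; `mcc` is the
multi-category Matthews correlation coefficient — both 1.0 for a perfect
classifier, and ~0 for an uninformative one. The same pipeline is available
as library calls (`ncrclass.synthetic.simulate`, `ncrclass.training.train`,
`ncrclass.evaluation.scores`, ...), which is what the test suite and the
acceptance script use.

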