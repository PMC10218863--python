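# Methods

## Problem and overall design

`ncrclass` classifies non-coding RNA sequences into six major classes
(lncRNA, miRNA, rRNA, snRNA, snoRNA, tRNA), or a ten-class fine-grained
scheme, from two information layers: the primary sequence and the predicted
secondary structure. Three encodings feed four architectures; the headline
model is a late-integration network that concatenates the penultimate
representations of a sequence CNN and a graph-feature network just before
the softmax output.

## Secondary structure

The builtin folding engine is a Nussinov-style base-pair maximization over
Watson–Crick plus GU wobble pairs with a minimum hairpin of 3 unpaired
nucleotides: every pair (i, j) must satisfy j − i − 1 ≥ 3, pseudoknots are
excluded by construction, and IUPAC ambiguity codes never pair. The
traceback is deterministic (a position is left unpaired on ties, otherwise
the smallest admissible partner is taken), so identical inputs always give
byte-identical structures. This is explicitly a combinatorial stand-in with
a clean dot-bracket contract, not a thermodynamic model; an adapter
(`engine="external_mfe"`) delegates to an RNAfold binary when one is on
PATH, and nothing downstream depends on which engine produced the structure.

Long sequences are folded in sliding windows of 150 nt shifted by
floor(150 × 0.25) = 37 nt, with the final window anchored at
`length − window_size` so all windows keep full width. Per window the engine
emits up to 3 distinct structure representatives ("shreps"): the optimum,
then re-runs with one pair of the optimum forbidden at a time (5′→3′ order),
keeping distinct outcomes. The published windowing tool ranks suboptimal
structures by an energy-like score; since the builtin engine has no energy
model, the forbidden-pair scheme is a declared substitute that preserves the
contract the encoders need (several near-optimal, mutually distinct, valid
structures per window).

Each dot-bracket position is annotated with one of six substructure states:
S (paired), H (unpaired inside a hairpin loop), I (unpaired in an internal
loop or bulge — exactly one stem inside the enclosing pair), M (unpaired in
a multi-loop — two or more enclosed stems), F/T (external unpaired positions
before the first / after the last paired position). Two conventions had to
be fixed because the six-state alphabet has no "external segment" state:
unpaired external positions *between* two top-level stems are annotated M
(the closest semantic), and a fully unpaired structure annotates as all F.

## Encodings

* **Ordinal sequence channel.** 17 tokens: padding `_` → 0, then
  A,C,G,T,U,R,Y,S,W,K,M,B,D,H,V,N → 1..16 (a frozen order; only the
  cardinality is externally fixed). Sequences are right-padded with 0 to
  12,000 positions (production default); encoding is injective on the
  unpadded prefix and decoding recovers the input exactly.
* **Combined structure channel.** 26 tokens: `_` (padding, 0), 24
  (nucleotide × state) pairs for {A,C,G,U} × {F,T,S,M,H,I} laid out
  row-major, and `N` for any ambiguous nucleotide regardless of state.
  (A,F) is displayed as 'Q'; the remaining display characters run Q..Z then
  a..n, skipping `_` (which a naive contiguous run would hit) and avoiding a
  clash with `N`. T normalizes to U in this channel (the sequence channel
  keeps T distinct).
* **Graph channel.** Per shrep, a graph over window positions labeled
  nucleotide+state with backbone edges between neighbors and edges between
  paired positions. Features are pairs of radius-bounded rooted neighborhood
  subgraphs (radius ≤ 1, root distance ≤ 4 by default): each root's
  neighborhood is canonicalized as BFS layers of sorted labels (exact for
  radius ≤ 1), hashed with CRC-32, and the unordered (hash, hash, distance)
  triple is mixed FNV-style into one of 2¹⁵ = 32,768 buckets. Weights are
  raw occurrence counts accumulated over all shreps of all windows — no
  per-shrep or per-window normalization, which is the declared contract.
  Hashing is pure integer arithmetic on canonical strings, hence identical
  across runs and platforms; collisions are allowed and deterministic.

## Architectures

All models end in a softmax output (6 or 10 classes) and are realized on a
compact NumPy layer stack written for this package (embedding, 1-D
convolution via im2col, max pooling, inverted dropout, dense, Adam,
softmax cross-entropy), validated by finite-difference gradient checks.

* **GrEnc** — dense(10, ReLU) → dense(K, softmax) on the 32,768-dim graph
  vector; 327,756 trainable parameters at the 6-class default. The raw
  accumulated counts span orders of magnitude, so a fixed parameter-free
  row-wise L2 normalization sits at the branch input (graph-kernel feature
  vectors are conventionally norm-scaled); without it the dense layer
  saturates and training stalls.
* **SeqEnc** — embedding(17, 4) → four blocks of two 64-kernel conv layers
  (kernel sizes 3/7/11/17, ReLU, zero padding preserving length) each
  followed by max pooling (4/4/2/2) → dropout 0.5 → flatten →
  dense(10, ReLU) → softmax. Pooling floors: 12,000 → 3,000 → 750 → 375 →
  187 positions, so the flatten width is 187 × 64 = 11,968.
* **StrEnc** — as SeqEnc with embedding(26, 4) and kernel size 7 in every
  block.
* **Merged (MncR)** — the SeqEnc and GrEnc branches run in parallel up to
  their 10-wide penultimate dense layers, concatenated to width 20 and fed
  directly into the softmax output. Trained from scratch; no weights are
  shared with or copied from the solo models.

Numerical conventions: pooling uses floor division and drops partial
windows; dropout acts only in training mode, so inference is deterministic;
the padding embedding row (index 0) is trainable like any other (no
masking); parameter counting is pure arithmetic on the spec and is asserted
equal to the realized network's own count.

## Training protocol

Adam (lr 0.001, β₁ 0.9, β₂ 0.999), categorical cross-entropy, batch size
100, shuffled each epoch from a seeded generator. Early stopping halts after
5 consecutive epochs without a *strict* new minimum of the validation loss
(ties are not improvements), bounded by `max_epochs` (default 500, a
termination guarantee the protocol itself does not state). Whenever the
validation loss improves, the weights are checkpointed; the returned model
is the overall-best checkpoint, never the last epoch. Optional class weights
w_c = N/(K·n_c) (inverse frequency normalized to mean 1 — the standard
choice; balanced data gives all 1, in which case the weighted loss equals
the unweighted loss) multiply the training loss only.

Ten-fold cross-validation builds deterministic class-balanced folds
(per-class counts differ by at most 1; round-robin assignment after a seeded
per-class shuffle), uses each fold once for validation, and reports the
per-epoch median validation loss across folds; folds that stopped early
carry their last loss forward so the median stays defined at every epoch.

## Dataset construction

Records are read from FASTA plus a tab-separated label sidecar (id, label,
optional subtype), uppercased, with DNA 'T' preserved (the vocabulary covers
it). The length filter keeps 15–11,922 nt inclusive. miRNAs split by length:
≤ 30 nt mature, ≥ 40 nt precursor, 31–39 nt excluded. Redundancy reduction
follows the CD-HIT-EST recipe at 90% identity with word length 7: greedy
longest-first clustering (lexicographic id tie-break, frozen for
reproducibility), a shared-7-mer prefilter, and identity defined as the
maximal number of aligned matches (global alignment scoring match 1,
mismatch and gaps 0) divided by the shorter sequence length. Splits draw a
fixed-size test set per class, then 90/10 train/validation from the
remainder, subtype-balanced with deterministic remainder handling; classes
short of the requested total contribute everything they have with a
warning. The ten-class relabeling maps snoRNA subtypes (C/D-Box, H/ACA-Box,
scaRNA), rRNA subtypes (5S/5.8S short; 23S/25S/28S/SSU long) and miRNA
length classes; coarsening inverts it exactly.

## Evaluation

Confusion matrices use a frozen class order (rows true, columns predicted);
the row-normalized view's diagonal equals per-class recall, and rendering
omits cells below 0.005 (display only). Per-class precision/recall/F1 come
from the matrix; macro scores are unweighted means over classes that occur
at all (a class absent from both truth and predictions is excluded from the
macro mean rather than counted as 0). The Matthews correlation coefficient
uses the standard multi-category generalization
(cov(t,p) / √((s²−Σp²)(s²−Σt²)) over marginals), which reduces exactly to
the classical binary formula for K = 2; a degenerate denominator yields 0.
Overlap (Venn) counts enumerate, per test id, exactly which models got it
right, yielding one count per model combination plus the none-correct
region.

Benchmark harmonization maps each tool's label scheme onto a common one:
DROP-labeled records, records longer than the comparison cap (default
750 nt), optionally mature-length miRNAs, and records above 90% identity to
a reference training set are removed; surviving predictions score as correct
when the mapped labels agree, and a prediction mapping to DROP is incorrect.
The operation is idempotent.

## Synthetic data generator

Each class profile fixes a length range, motif list and structure template;
background nucleotides are i.i.d. uniform A/C/G/U. Defaults (production
scale): mature-miRNA-like 20–24 nt with a let-7-style 5′ seed motif;
precursor-miRNA-like 60–120 nt hairpin (3′ arm = reverse complement of the
5′ arm with 5% per-base mismatches, 4–8 nt loop); tRNA-like 70–90 nt
cloverleaf (acceptor stem plus three designed stem-loops) with T-loop
GUUCRAUU and 3′ CCA motifs; snoRNA-like 70–250 nt with C box RUGAUGA and D
box CUGA; snRNA-like 100–300 nt with an Sm-site motif; lncRNA-like
200–4,000 nt motif-free; rRNA-like 1,400–3,000 nt with three fixed conserved
15-mers. The six-class list holds seven profiles — the miRNA class is an
equal mixture of the mature- and precursor-like profiles, reflecting its
bimodal length composition — and a ten-profile fine-grained list splits
snoRNA/rRNA/miRNA accordingly. IUPAC degeneracies in motifs are sampled per
insertion; motif positions are fractional preferences along the sequence.
Generation is fully reproducible from (profiles, n, seed), to the byte in
the emitted FASTA.

What the generator does *not* emulate: covariance/phylogenetic structure,
database noise and label errors, GC-skew (available per profile but off by
default so the learning signal stays attributable to motifs and structure),
and realistic within-class diversity. Passing the desk-scale experiments
therefore shows that the pipeline wires the signal through correctly — not
that the models would reach comparable accuracy on curated database
sequences.

## Desk-scale experiment sizes

Full-scale training (60,000 database sequences, 12,000-nt padding, four
models) is far beyond a single-CPU desk run, and padding length is a
constant multiplier on compute, not on logic. The packaged experiments
therefore use 6 classes × 300 synthetic sequences, 500-nt padding (long
classes capped to ≤ 500 nt), and a reduced sequence CNN that keeps the
published layer pattern (two conv layers per block, ReLU, growing kernels,
10-wide penultimate dense) at three blocks × 32 kernels. The sequence-CNN
recovery run expects held-out macro F1 ≥ 0.90; the structure-dominated
variant (motifs stripped from precursor-miRNA and tRNA profiles, structure
templates kept) trains the graph-only and merged models on one shared split
and expects merged ≥ graph-only, echoing the qualitative ordering of the
full-scale models. Both experiments finish in minutes on one CPU;
`scripts/acceptance.py` re-runs them from scratch.

## Known limitations

* The builtin folding engine maximizes pair counts; its structures can
  differ from thermodynamic MFE structures, and shrep ranking is a declared
  substitute for the published windowing tool's scoring.
* Only the (A,F)→'Q' cell of the combined-alphabet character table is
  externally fixed; the remaining 23 display characters are this package's
  own frozen convention.
* The graph feature grammar is NSPDK-style but not bit-compatible with
  EdeN; only the contract (deterministic, 32,768-dim, weighted,
  structure-aware) is guaranteed.
* Neighborhood canonicalization is exact for radius ≤ 1 (the default);
  larger radii use a deterministic layered approximation.
* Training reproducibility is guaranteed per platform/thread configuration,
  not bit-exact across BLAS implementations.
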