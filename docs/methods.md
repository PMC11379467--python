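# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `hmcnet`, and what the synthetic benchmark does and does not
demonstrate.

## Problem setting

5hmC enrichment sequencing yields peaks (here standardized to 1 kb around
the peak center) and per-region read counts. The toolkit treats three
supervised problems on 1 kb windows: peak vs background classification,
log-count regression, and case-control differential classification — plus
two derived analyses (gene-body aggregation, SNP enrichment). All
coordinates are 0-based half-open throughout; 1-based dialects are converted
at the parsing boundary. Strand is ignored for feature extraction
(enrichment coverage is unstranded) and sequence is read from the forward
strand.

## Features

- **Sequence**: one-hot `(1000, 4)` in channel order A, C, G, T; ambiguous
  bases are all-zero rows (not 0.25 smearing), which preserves the row-sum
  invariant and matches common practice for sequence CNNs.
- **Epigenetic profile**: per mark, read counts in 1 kb windows sliding by
  500 bp over the region extended 10 kb both ways — 41 windows, anchored at
  `region.start − flank` so window 21 (index 20) is exactly the
  peak-centered window. Reads are assigned to windows by their midpoint
  base, so a read lands in exactly one window of a non-overlapping tiling;
  `any_overlap` counting is available where double-counting is acceptable.
  Counts are depth-normalized to counts per 10 million reads
  (`norm_scale=1e7`); the normalization constant is configurable since only
  relative scale matters downstream (inputs are standardized before the
  network). Replicates stack as rows (`n_h × 41`); averaging them into one
  row is available as `replicate_collapse`.
- **3-mer baseline**: 64 lexicographic 3-mer frequencies over valid windows
  only; retained as the classical baseline representation.

## Labeling

Positives are peaks with peak-caller FDR < 0.05 (strict). Negatives are
1 kb windows on a 100 bp lattice near positives — edge-to-edge gap at most
10 kb — that overlap no positive (and no sub-threshold peak when a full
peak list is supplied, to avoid label noise), GC-matched to the positives by
stratified sampling over ten equal GC bins and drawn one per positive. A bin
short of candidates borrows from its nearest neighbours with a warning;
sampling is bit-exact reproducible under a seed. Distances are edge-to-edge;
the lattice spacing and bin count are configurable.

Continuous targets are `log(1 + normalized count)` (natural log, pseudocount
one), invariant to jointly doubling counts and depth. Differential labels
come from a consumed differential-analysis table: FDR < 0.1 positive,
FDR > 0.5 negative, the interval between dropped as ambiguous. Splits are by
chromosome only — chr8/chr9 test, chr7 validation, remainder training — so
no positional information leaks across sets.

## Network

Unimodal encoders: the sequence branch is conv(8)/pool(4)/conv(8)/pool(4)/
conv(8) with 64/128/256 filters (feature map 256×53 = 13568 for 1 kb input)
followed by fully connected 13568→512→256; the epigenetic branch applies,
per mark, three padded 3×3 convolutions with 32/64/128 filters and two
poolings of kernel 1×2 (single replicate) or 2×2 (stride = kernel; the
kernel height is clamped to the current map height so small replicate
counts remain valid), flattening to 1280 for a 1×41 input, then 1280→256→128;
mark outputs are concatenated. Fusion is MFB pooling with factors
`k = 5`, `o = 500`, signed-sqrt and ℓ2 normalization (ε-guarded: a zero
fused vector stays zero). The head is 256→64→output; two softmax nodes for
classification (class-1 probability reported — two independent sigmoid
nodes would not yield normalized probabilities), one linear node for
regression. ReLU everywhere except the output; dropout 0.5 in the fully
connected parts only (not inside MFB). Unimodal configurations bypass
fusion and feed the single embedding to the head.

The FC widths, MFB factors and head sizes are implementation defaults, all
configurable via `ModelSpec`; the convolutional geometry is fixed by the
architecture.

### Implementation and initialization

The network, MFB layer, losses and Adam are implemented in NumPy with
explicit backpropagation (im2col + GEMM convolutions in float32); gradients
are verified against finite differences in the test suite. Weights are
He-normal; **biases are initialized to 0.1**. The positive bias offset is
load-bearing: with zero biases and Adam at step sizes around 1e-3, the deep
ReLU stack reproducibly collapses — an entire convolutional layer's output
reaches the dead-ReLU state within the first epochs and the model degenerates
to a constant predictor. MFB factors are initialized at scale `1/√fan_in` to
keep the pooled products O(1).

The power-normalization derivative `0.5/√|z|` is clamped at `|z| = 1e-12`
(forward) and `1e-6` (backward) to avoid the singularity at zero.

### Training protocol

Adam with learning rate 1e-3 (library default), minibatches (default 64),
cross-entropy or MSE, at most 200 epochs with early stopping after 10
epochs without validation-loss improvement; the parameters of the best
validation epoch are restored. Validation loss (not AUROC) is the stopping
metric. Optional linear warm-up and exponential learning-rate decay are off
by default. One integer seed drives initialization, batch shuffling and
dropout; runs are bit-exact reproducible at a fixed thread count. Epigenetic
inputs are standardized per mark using training-set mean/sd (stored with
the fit for prediction).

For the bundled synthetic demonstrations the driver uses `lr = 3e-4` and
3-6 epochs: at a few thousand examples the default 1e-3 is unstable for the
sequence branch (the collapse described above can recur mid-training),
while 3e-4 converges monotonically; real-scale datasets (tens of thousands
of peaks) are the regime the default protocol targets.

## Downstream analyses

- **Gene expression**: gene bodies are cut into consecutive 1 kb windows
  from the gene start, `ceil(length/1000)` of them, the last padded
  downstream to full width; the continuous model predicts each window's log
  count and the gene score is `Σ expm1(prediction)` — aggregation on the
  count scale, since predictions are log1p-scale.
- **Differential scan**: every contig is tiled with non-overlapping 1 kb
  windows from coordinate 0 (terminal partial windows dropped); the
  epigenetics-only case/control model assigns each window a probability,
  called differential above 0.5. Case and control marks enter as separate
  modalities (2·n_marks branches); difference-based encodings were
  considered but stacking preserves per-condition shape information.
- **SNP enrichment**: positive SNPs are restricted to the noncoding mask;
  negative controls are sampled uniformly from noncoding positions
  excluding positive sites at 10:1, deterministically under a seed. The
  2×2 table (SNP class × region class) is tested with Fisher's exact test;
  the odds ratio uses Haldane's 0.5 correction when a cell is empty and the
  95% CI is the Woolf log-OR normal approximation. Feature-class assignment
  for calls uses the largest-overlap rule with the fixed tie-break priority
  Promoter > 5UTR > Exon > Intron > 3UTR > Downstream > Intergenic.

## Synthetic data

The generator emulates the statistical structure of a tissue-specific 5hmC
study: an i.i.d. genome (default ten 3 Mb chromosomes at GC 0.5, named
chr1..chr10 so the chromosome split applies unchanged), 2000 positive 1 kb
peaks placed on a jittered lattice at least 21 kb from contig edges, per-mark
read sets, 5hmC reads, genes, a case/control design and SNP sets. Key
choices:

- **Sequence signal.** With probability 0.9 a positive carries (i) one copy
  of an 8-bp motif, (ii) 35 existing "GC" dinucleotides swapped to "CG" —
  raising CpG-dinucleotide density at *identical* base composition, the
  CpG-island-like character of 5hmC targets, invisible to GC-content
  matching — and (iii) 25 G→C conversions (GC skew, the strand asymmetry
  seen around transcribed and regulatory regions, also GC-content-neutral).
  The composite signal exists because a single exact motif copy is, at a
  few thousand training examples, demonstrably not learnable by this
  architecture before its fully connected layers memorize the training set;
  real peaks carry exactly this kind of distributed compositional signal on
  top of motifs. Sequence-only held-out AUROC on these defaults lands near
  0.88, close to what sequence-only models achieve on real 5hmC data.
- **Epigenetic signal.** Each mark is a flat Poisson background (15
  reads/kb) plus Gaussian read bumps (sd 1 kb) of gamma-distributed
  amplitude (CV 0.5, expected 25 reads) anchored on positive peaks
  (`pos_up`, enhancer-like) or on decoy sites 6 kb away (`neg_up`,
  promoter-like) — reproducing the directional enrichment contrast between
  positives and matched background.
- **Counts.** 5hmC reads are background (10 reads/kb) plus per-peak bumps
  (sd 500 bp) whose expected read number (200) is scaled by a per-peak
  gamma amplitude — a gamma-Poisson mixture, i.e. negative-binomially
  overdispersed window counts tied to the latent rate.
- **Genes.** 300 genes of 2-10 kb placed freely (gene bodies may contain
  peaks, as in vivo — this overlap is what makes expression predictable);
  expression = α·(gene-body normalized 5hmC + 1)·lognormal(0, 0.3) noise.
- **Differential design.** 45% of peaks are differential: the case bump is
  2.5× the control bump; the consumed differential table gives planted
  windows FDR ~ U(0, 0.08) and the rest U(0.55, 0.98), with a 10% ambiguous
  fraction in between (dropped by labeling and from the planted truth).
- **SNPs.** 400 positive SNPs placed so their odds of falling in a
  noncoding planted differential window is 4× the uniform-noncoding odds;
  the noncoding mask is the complement of gene bodies.

A fixed 3-chromosome, 12-peak micro example (chr1/chr7/chr8) uses
hand-countable read layouts — one read midpoint per 100 bp plus 20 reads on
each peak center, so every profile window holds 10 background reads and the
peak-centered window 30 — and regenerates byte-identically; it anchors
golden tests and the CLI smoke test.

**What passing on synthetic data shows — and does not.** The planted
signals are cleaner than reality: i.i.d. background sequence, unimodal
Gaussian enrichment, no mappability/GC bias, no replicate batch effects, no
correlated marks. Success here demonstrates that the implementation wires
features, fusion, training and downstream analyses correctly and that the
model recovers signal of the planted kinds; it does not predict real-data
accuracy, which depends on data scale and biology the generator does not
emulate.

## Problem sizes and schedules in the bundled checks

The demonstration experiments run on one CPU: the ablation fits nine models
(three modalities × three seeds) on the 2000-peak dataset at 3 epochs,
lr 3e-4; the continuous model uses 4 epochs; the differential model 6. The
acceptance driver completes in roughly five minutes, the full test suite in
about fifteen. These schedules are deliberately short — the planted signal
is strong and the point is verification, not benchmark accuracy.

## Known limitations

- No GPU path and no BAM/CRAM input (convert reads to BED upstream); bigWig
  output is out of scope.
- The NumPy network is single-threaded GEMM-bound; real-scale training
  (10^5 examples, 200 epochs) is impractical in it — the design goal is a
  faithful, testable reference implementation, not a production trainer.
- Replicate handling averages depth-normalized profiles or keeps them as
  rows; no further batch correction is attempted.
- Real-data benchmarks at published scale (public 5hmC-seq repositories,
  per-tissue AUROC in the mid-0.9s) require the original sequencing data
  and are outside the package's test surface.
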