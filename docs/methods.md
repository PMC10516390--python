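# Methods

## Problem setting

Spatiotemporal Hi-C experiments capture one contact matrix per
developmental time-step — for instance six stages of mouse
preimplantation embryogenesis, over which topologically associating
domains (TADs) are progressively established.  `hicforecast` treats the
series as a video-prediction problem: given the binned, rescaled contact
matrices of the first three time-steps (t1–t3), forecast the matrices of
the last three (t4–t6).

## Preprocessing model

Valid intra-chromosomal read pairs (HiC-Pro `allValidPairs`-style text)
are filtered to genomic separations strictly greater than 20 kb,
optionally downsampled without replacement to equalize depth across
time-steps, and binned at a fixed resolution (40 kb default; bin
`k = floor((pos−1)/res)`, 0-based half-open bins).  Raw counts are used
throughout — no ICE/KR balancing.  Counts are mapped into [0, 1] by
clipping at a dataset-level cap (`maxHiC`) and dividing.  The cap is
depth-adaptive: by default the 99.9th percentile of nonzero entries
pooled over all time-steps of the training chromosomes, so at most
≈0.1 % of nonzero entries saturate.  The percentile definition is this
package's choice of a single interpretable knob; it can be overridden
with an explicit value.

## Windowing

Training samples are 50×50-bin submatrices sliding along the main
diagonal with a step of 3 bins, stacked across time into an
`n × t × 1 × 50 × 50` tensor.  Trailing bins that do not admit a full
window are dropped (fixed-size inputs; no partial-window rule exists).
Windows are read from the full symmetric matrix — they straddle the
diagonal and the lower triangle is not masked.  At prediction time each
pixel is covered by up to ⌈50/3⌉ windows; the genome-scale forecast is
the arithmetic mean of all window predictions covering a pixel.
Predictions are clamped to [0, 1] before averaging (MSE-trained linear
outputs can overshoot the rescaled range slightly) and the reassembled
matrix is symmetrized as (M + Mᵀ)/2; pixels outside the covered diagonal
band are reported as missing (NaN), never imputed.

## Network architectures

All recurrences use stride-1, same-padding convolutions (3×3 default),
so the 50×50 spatial extent survives every layer.  States are
initialized to zero at t1.  Weight initialization is uniform with
fan-in scaling, from a seed recorded in the model configuration.

* **ConvLSTM stack** — 4 layers (default) of ConvLSTM cells plus a 1×1
  linear projection to one channel.  Three cell variants are provided:
  ConvLSTM-1 with Hadamard peephole couplings of the gates to the cell
  memory (peephole weights are full channels×H×W grids, matching the
  elementwise product of the original formulation), ConvLSTM-2 without
  peepholes, and ConvLSTM-3 with the peepholes replaced by
  convolutions.
* **ResConvLSTM** — a 3×3 convolution lifting 1→32 channels, 25
  residual blocks, and a 3×3 convolution reducing 32→1.  Each block
  feeds its input through two ConvLSTM-1 cells and adds the input back:
  `H^i = H^{i−1} + H^{i_2}`.  The layer census counts the two outer
  convolutions plus both cell layers of every block — 52 layers at
  25 blocks.  Variants: **ResConvGRU** and **ResConvMUT** swap the inner
  cells for a convolutional GRU / MUT1 cell; **ResConvLSTM2** feeds the
  output convolution with the channel concatenation of every fifth
  block's output (blocks 5, 10, 15, 20, 25).
* **ST-LSTM stack** — 4 layers of spatiotemporal-memory cells.  Besides
  the per-layer hidden/cell states, a memory M zigzags bottom-up through
  the layers within a time-step and returns from the top layer to the
  bottom layer at the next step.  The output gate reads both memories
  through convolutions and a 1×1 convolution W₁ reduces the [C, M]
  concatenation back to the hidden width.
* **NaiveNet** (three-step baseline) — three 3D convolutions with 7×7
  spatial and 1 temporal kernel extent, the first two followed by group
  normalization (2 groups) and LeakyReLU (slope 0.2).  Because the
  temporal extent is 1, each layer is implemented as one shared 2D
  convolution applied per frame — exactly equivalent — and the network
  maps frame k to output slice k with no temporal mixing.

The exact convolutional GRU/MUT1 gate equations are not published for
this setting; the package substitutes the standard formulations (GRU
blend `H_t = (1−z)∘H_{t−1} + z∘candidate`; MUT1 with an input-only
update gate and a tanh-squashed input projection in the candidate) and
flags ResConvMUT as experimental.

## Training schemes

*Next-frame* models reconstruct each frame from its predecessor; frames
t1–t3 are fed from the data, and from t4 on the model's own output is
fed back (autoregressive rollout).  The MSE loss pools reconstructions
of steps 2–6.  *Three-step* models map the three observed frames to the
three future frames in one pass, with MSE over steps 4–6 only.  The two
losses live on different supports and are never compared across
schemes.

Optimization is Adam, learning rate 1e-4, batch 32 by default, with
global-norm gradient clipping at 1.0 to stabilize deep residual
recurrences (epochs with clipping are recorded in the history).  When
validation data is supplied, the checkpoint of the epoch with the best
validation loss is retained.  An optional memory-decoupling penalty
(`loss = MSE + 0.1 × decouple`) is available for ST-LSTM training but
off by default; its cosine-similarity form between C and M increments is
an interpretation of the published idea and is labelled as such.

All arithmetic is single precision by default (double available via the
model configuration); runs are bit-reproducible single-threaded given
the seeds.

The networks and the training loop run on the package's own
reverse-mode autodiff core (`hicforecast.autodiff`): a small tape-based
engine over numpy arrays providing convolution (im2col forward, col2im
backward), the elementwise gate algebra (with a fused LSTM gate block
for speed — verified against both the primitive-op composition and
finite differences), group normalization and the reductions.

## Evaluation metrics

* **Stratified Pearson** — the Pearson correlation of
  `{A[i, i+d]}` vs `{B[i, i+d]}` at each genomic distance d of 10–30
  bins.  Constant strata are reported as undefined (NaN), never as 0.
* **SCC** (HiCRep) — both matrices are mean-smoothed with a
  (2h+1)-square filter (h = 5), shrunk at the matrix borders (HiCRep
  dialects differ here; the shrink-at-edges choice is pinned by a
  brute-force oracle in the tests).  Per-diagonal Pearson coefficients
  over distances 400 kb–1.6 Mb are combined with weights
  `N_d · sqrt(var(rank(a)) · var(rank(b)))`; undefined strata are
  excluded from the weighting.
* **Insulation score** — `log2` of the mean contact in a w×w square
  below the diagonal over the chromosome-wide mean of such squares
  (w = 10 bins = 400 kb at 40 kb).  The square is the half-open
  `[b−w, b) × [b, b+w)`: it collects the contacts crossing the bin edge
  just before bin b, so a boundary indexed as the first bin of a new
  domain scores its unique minimum exactly at that index.  (A square
  that skips bin b and straddles both sides is mirror-symmetric about
  the bin edge and ties bins b−1 and b on ideal block matrices.)
  Constant matrices score exactly 0; the first w and last w−1 bins are
  masked.
* **Strong boundaries** — local minima of the insulation track with
  prominence above a threshold (default 0.2); valley ("pileup")
  profiles average the track around a boundary set.  The insulation
  window and prominence defaults are this package's declared choices,
  not reconstructions of any published supplementary values.

Both correlation metrics and the insulation score are invariant to
scaling both inputs by a positive constant.

## Synthetic data model

The generator emulates a single chromosome's embryogenesis-like series:
contact intensity `(1 + |i−j|)^(−a)` (power-law distance decay, a = 1
by default), multiplied by `(1 + s_t)` for bin pairs within the same
TAD, where the strength schedule `s_t` ramps linearly 0→2 across the
six time-steps (TADs absent early, established late).  TADs are the
half-open intervals between consecutive boundary indices (defaults at
the quartiles of the chromosome).  Counts are Poisson draws on the
upper triangle (mirrored, so symmetry is exact) with rates scaled so the
expected matrix total equals the configured depth.  The diagonal is
included — real pipelines keep it and the maxHiC cap must see it.

What the generator does *not* emulate: A/B compartment checkerboards,
loop dots, inter-chromosomal contacts, coverage (mappability) biases,
and distance-decay changes over time.  Tests passing on this synthetic
regime therefore demonstrate that the machinery is correct and that the
networks can learn a TAD-establishment signal at small scale; they do
not certify forecasting accuracy on real embryogenesis data.

## Scaled-down benchmark

The self-contained benchmark (`hicforecast.benchmark`) trains a 2-block,
8-channel ResConvLSTM for 30 epochs on one simulated 120-bin chromosome
at depth 1e5 (24 windows), then forecasts a second, independently
simulated chromosome and compares the t6 forecast against the
persistence baseline (repeat t3).  Two optimization settings depart
from the full-scale defaults, fixed once for this setting: minibatch 8
(batch 32 would be a single full batch over 24 samples) and Adam
learning rate 3e-3 (the ~90 updates of this short schedule barely move
a fresh network at 1e-4).  The benchmark also reports the SCC and mean
stratified Pearson of the t4 forecast and the fraction of configured
TAD boundaries recovered within ±1 bin from the t6 forecast's
insulation minima.

## Numerical and degenerate-input choices

* Matrix text formats (dense and upper-triangle COO) print `%.17g`, so
  read(write(M)) reproduces M bit-exactly.
* `reassemble` marks never-covered pixels NaN; downstream metrics either
  receive `filled()` copies or fail loudly.
* Pearson of a constant vector is undefined → NaN, excluded from SCC
  weights; an all-constant comparison yields an undefined (NaN) SCC.
* Insulation of a matrix with nonpositive chromosome mean is an
  all-undefined track.
* Residual networks with `n_blocks = 0` degenerate to conv→conv and
  still run.
* Downsampling more pairs than available, windows larger than the
  matrix, and mismatched shapes raise errors naming both quantities.

## Known limitations

* The SA-LSTM self-attention variant and the SimVP comparison
  architecture are out of scope; the ResConvMUT gate wiring is a
  standard-formulation substitute.
* Full-scale training (128 hidden channels, genome-wide data) is out of
  desk-scale reach; the package is exercised end to end at reduced
  sizes, and published full-scale scores are not reproduced.
* Determinism is guaranteed only single-threaded; multi-threaded BLAS
  may reorder floating-point sums.
* The `.cool` reader handles single-resolution files only and requires
  the optional h5py dependency.
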