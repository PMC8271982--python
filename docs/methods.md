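# Methods

## Problem setting

Children on the autism spectrum often display stereotypies — repetitive,
invariant motor patterns such as hand flapping, body rocking, or covering
the ears. A support system (for instance a social robot in a therapy
session) that recognizes these behaviors in real time can adapt its own
behavior to the child. `skelact` implements a lightweight recognition
pipeline for this setting: a depth-sensor SDK supplies per-frame 3D
coordinates of 15 body joints, short joint-coordinate sequences are
encoded as small RGB images, and a compact convolutional network
classifies each image into one of nine behavior classes — six typical
actions (idle, standing, clap, hand raise, pointing, turn) and three
stereotypies (hand wave/flapping, covering the ears, rocking).

## Image encoding

A sequence of N = 32 frames (one to two seconds of movement at typical
depth-sensor frame rates) of J = 15 joints is mapped to a 15 × 32 × 3
8-bit image: row r is the r-th joint of the chosen *joint ordering*,
column f is frame f, and the channels carry the three coordinates
(x→R, y→G, z→B). Each coordinate k is min-max normalized to 0–255,

    k' = 255 · (k − min_c) / (max_c − min_c),

where min_c and max_c are taken over all joints and frames of the
sequence.

Numerical choices:

- **Per-axis pooling.** min_c/max_c are computed separately for x, y and
  z. Pooling all three axes together would break invariance under
  arbitrary 3D translation of the skeleton; the per-axis form is exactly
  invariant to translating the whole skeleton and to positively
  rescaling any axis, which is what lets a model trained on seated
  children generalize across body sizes and sensor placements. The
  property is asserted bit-exactly in the test suite.
- **Quantization.** The continuous value is rounded half-up to an
  integer. This makes encodings bit-reproducible, exportable as lossless
  PNG, and independent of floating-point display pipelines. The network
  consumes the integer image rescaled by 1/255.
- **Degenerate ranges.** If an axis is constant over the window
  (max_c = min_c, e.g. a frozen depth channel), that channel is set to 0
  and a warning is logged rather than failing — a live stream should
  keep flowing.
- **Windowing.** Streams longer than 32 frames are cut into sliding
  windows (default stride 1 frame, configurable); stored samples are
  encoded from their central 32-frame window, where the action core
  lies. Normalization uses the current window only, never running
  stream statistics, so every emitted image is self-contained.

## Joint orderings

The 15 joints form five anatomical groups: P1/P2 left/right arm
(shoulder, elbow, wrist), P3 torso (head, neck, spine), P4/P5 left/right
leg (hip, knee, ankle). The registry contains ten orderings: B1–B6
permute whole groups (B1 = P1 P2 P3 P4 P5 is the anatomical control),
and C2–C5 are fixed fully random joint orders. Because the normalization
statistics do not depend on row order, encoding under two orderings
differs exactly by a row permutation — which is why the ordering
experiments isolate the effect of row adjacency on the convolutional
classifier and nothing else. Storage order is always canonical 1–15;
orderings are applied only at encoding time.

## Network and training

The classifier is a six-convolution CNN: three blocks of two 3×3
convolutions (stride 1, pad 1) with 64, 128 and 256 filters, each
convolution followed by batch normalization then ReLU; 2×2 max pooling
after the second and fourth convolutions; global average pooling (GAP)
after the sixth; and a single fully connected softmax head. The
feature-map width follows 32 → 16 → 8; the odd height 15 pools with
floor semantics (15 → 7 → 3). GAP instead of wide FC layers keeps the
parameter count small and enables class activation maps.

Training uses SGD with momentum 0.9, batch size 64, initial learning
rate 0.01 decayed ×0.1 every 50 epochs, L2 weight decay 1e-4 on
convolution and FC kernels, and categorical cross-entropy, for 200
epochs by default; experiments repeat training over 20 seeded runs and
report mean ± s.d. Convolutions are initialized He-uniform and carry no
bias (batch normalization absorbs it). The momentum value and the
BN-before-ReLU order are conventional choices where the recipe is
otherwise silent.

The network is implemented directly in numpy (float32, channels-last):
convolutions run as im2col + GEMM in both passes, so training and
inference are single-threaded BLAS and fully deterministic given the
seed — the same seed and configuration reproduce a fit to the last bit
on the same platform; across BLAS builds tests compare final metrics
within 1e-6.

### Class activation maps

For a class c with FC weight vector w^c, the raw CAM is Σ_k w_k^c · F_k
over the 256 final feature maps F_k (spatial size 3×8). It is linear in
w^c and is checked against a brute-force per-pixel triple loop. For
display it is bilinearly upsampled to 15×32 and min-max scaled to [0,1];
overlaid on the action image it shows which joint rows and frame spans
drove the decision.

## Synthetic behavior generator

The original clinical recordings (32 children, 9 classes, 3 frontal + 2
side repetitions each, seated, three camera placements) are private, so
the package ships a kinematic simulator that reproduces the *protocol*
and the *statistical structure* of the data: 32 subjects × 9 classes ×
5 samples = 1440 sequences, 160 per class.

Each subject has a body scale (uniform 0.80–1.05, child-sized), constant
per-joint posture offsets (σ = 8 mm), and amplitude/frequency style
multipliers (uniform 0.85–1.15). A fixed seated base posture is animated
by class-specific trajectories built from rigid sub-rotations — arm
rotations about the shoulder and elbow, trunk pitch about the hip line,
upper-body yaw about the vertical axis, and constant-length leg
re-orientation for standing up — so within-limb bone lengths are exactly
constant in a noiseless sequence. Oscillatory classes use sinusoids
(hand wave ~4 Hz at the wrist, matching the 3–5 Hz character of hand
flapping; rocking ~0.8 Hz; clapping ~2 Hz anti-phase), held postures use
smoothstep ramps (~0.4 s) into a sustained pose, and idling is a slow
0.25 Hz postural sway. Viewpoints apply a 0/+90/−90° yaw before
isotropic Gaussian sensor noise (σ = 10 mm, bounded at 20 mm) is added
per coordinate. Samples are 64 frames at a nominal 30 fps so that
windowing is exercised; the encoder takes the central 32 frames.

A single master seed fans out to per-sample seeds through
`SeedSequence(master, subject, class, repetition)`, so datasets are
bit-reproducible and any individual sample can be regenerated alone.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: depth-sensor tracking artifacts
(jitter correlated across joints, occlusion dropouts, swapped limbs),
the kinematic signatures of actual ASD stereotypies beyond their
periodicity and location, within-sample behavioral variability
(hesitation, partial executions), and adult or standing subjects beyond
the standing-up action itself. Accuracy on the synthetic task is a
functional test of the pipeline, not a clinical performance claim.

## Evaluation and the ordering experiments

Splits are by subject: subjects are shuffled with a seed and dealt to
train/validation/test (the reference protocol uses 20/5/7 of 32), so no
child contributes samples to more than one split; because every subject
contributes identical per-class counts, subject-level assignment is
automatically class-balanced. Metrics are overall accuracy (percent),
per-class accuracy (diagonal over row sum; empty classes reported as
missing, not zero), and the multiclass Matthews correlation coefficient
in Gorodkin's R_K form, with a degenerate denominator mapped to 0.

Experiment E1 compares the control ordering B1 with the five group
permutations B2–B6; E2 compares B1 with the random orders C2–C5. Every
ordering is trained on identical splits over `runs` seeded fits
(default 20), so the ordering is the only varying factor; the 20 runs
re-seed training only, not the split. Accuracies are compared with a
classic one-way ANOVA (df = g−1, N−g; six orderings of 20 runs give
F(5, 114)) and pairwise pooled-variance Student's t-tests against B1
(df = n1+n2−2 = 38 for 20+20 runs). The t-tests are one-sided by default
— the hypothesis of interest is directional, control ≥ alternative — and
configurable to two-sided. No multiple-testing correction is applied;
the report states the number of uncorrected comparisons so readers can
apply their own.

## Problem sizes used by the shipped tests

The test suite runs the full pipeline at desk scale: the protocol
arithmetic generates the complete 1440-sample dataset; training-based
checks use 4–18 subjects. The cross-subject recognition check trains the
full network for 40 epochs on a 12/3/3-subject split under B1 and
averages test accuracy over 3 seeds; the experiment-harness check runs
2 orderings × 3 runs × 5 epochs. These sizes were chosen as the smallest
at which each property is meaningfully exercised.

## Known limitations

- The CNN is numpy-based and single-threaded; it is ample for 15×32
  images but not a general-purpose deep-learning stack.
- The simulator's subjects differ only in scale, posture offsets and
  motion style; it cannot probe robustness to sensor artifacts or to
  genuinely novel movement styles.
- Real-time throughput is hardware-dependent and deliberately not
  asserted anywhere; the stream classifier can log per-window latency
  for information only.
- The optional reader for the public Kinect activity dataset (KARD,
  15-joint text files) maps hands/feet onto the wrist/ankle slots;
  benchmark-scale reproduction on KARD is out of scope for the test
  suite.
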