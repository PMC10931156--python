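# Methods

`optonose` models an artificial-olfaction ("opto-nose") workflow for fruit
ripeness: a 25-dye colorimetric sensor array photographed before and after
exposure to fruit volatiles, summarized by colour-difference statistics, and
classified either by ED reference ranges or by a small dense-block CNN.
Because no public image corpus exists for this measurement setup, every
input is produced by the package's own synthetic generator; this note
records the models, the defaults, and what they do and do not emulate.

## Sensor model

**Dye library.** The array carries a fixed panel of 25 dyes (two
aldehyde/ketone-sensitive dyes, three solvatochromic, three redox, three
Lewis-acidic, fourteen pH indicators) in a 5 × 5 grid, row-major from the
top left. Each dye has an 8-bit baseline colour and, per volatile, a
saturating colour response with maximum shift `max_drgb` (signed counts per
channel) and half-saturation concentration `k_ppm`. Libraries are drawn per
seed under a cross-reactivity constraint: every volatile draws a strong
response (dominant channel ≥ 40 counts at saturation) from 5–9 dyes and a
weak one (≤ 6 counts) from the rest, so each gas has a distinctive spot
fingerprint. Half-saturation constants are drawn from 30–300 ppm for strong
responders; this keeps responses discriminative across the 25–700 ppm
emission range rather than fully saturated at the top of it.

**Dose response.** The colour shift of dye *i* under a gas mixture is a
channel-wise sum of Hill terms (coefficient 1 by default),
Δ·c/(c+K), clipped to the dye's per-channel saturation envelope.
Additivity of co-emitted volatiles is an assumption of the model, not a
measured fact. Response is exactly zero at zero concentration and monotone
in every concentration.

**Blank drift.** Blank controls are not perfectly stable between the two
photographs, so the generator applies a small per-spot integer colour drift
to the post image whose 25-spot total ED is driven (by a ±1-count repair
loop, to within 0.6 counts) to a target drawn from N(47.75, 2²). These
defaults reproduce a blank control with mean total ED 47.75 and 3σ = 6,
the reference blank statistics used for detection limits. Setting both to
zero disables the drift entirely.

## Image model

Images are uint8 rasters (default 120 px for dose-response work, 96 px for
dataset images): a textured membrane background, 25 uniform filled disks of
radius 0.35 × pitch, and white/black calibration patches painted at
references (200, 200, 200) and (20, 20, 20). The white reference is kept
below 255/1.25 so realistic illumination gains cannot clip it — a clipped
patch would make two-point calibration unrecoverable. Scene perturbation is
applied to the whole composite in the order geometry (small rotation plus
mild perspective warp) → per-channel illumination gain → additive Gaussian
pixel noise; the canonical scene (gains 1, no jitter, no noise) is the
identity, under which the mean colour inside every spot equals the
ground-truth spot colour exactly. Spot centres and conservative inner patch
boxes are carried through the geometric transform in the image metadata.

Two scene presets are used: **easy** (gains 0.98–1.02, ≤ 1° rotation,
noise σ 0.5) approximates laboratory capture; **hard** (gains 0.80–1.20,
≤ 5° rotation, perspective, noise σ 3) emulates in-container photography
under arbitrary light and angles. Under hard gains, bright spot channels
can clip at 255 — deliberate, as overexposure is one of the things
calibration cannot undo and the CNN must tolerate.

## Ripening trajectories and datasets

Stage boundaries in storage days: banana 2/6 of 0–8, mango 3/8 of 0–10,
peach 2/7 of 0–10, half-open intervals with the final day inclusive.
Each fruit emits its three marker volatiles with Hill-in-time curves
(exponent 3) on top of a basal emission (25/45/65 ppm; bursts of
300/500/700 ppm). Burst centres are staggered across the trajectory — one
volatile rises around the unripe/ripe boundary, one mid-ripe, one around
the ripe/overripe boundary — so the concentration *ratios* keep evolving
even after early curves saturate; this is what makes late stages
distinguishable and mirrors the stage-dependent VOC balance that headspace
analysis of ripening fruit reports. Specimen-to-specimen variability is a
multiplicative jitter on all curve parameters; test batches ("different
fruit lots") redraw amplitudes by U(0.7, 1.3) and shift burst centres by up
to 15 % of the span.

Datasets sample the 12-hour monitoring grid within each stage, with two
difficulty presets:

* **easy** — scene preset easy, 2 % specimen variability, and sampling at
  least 1 day away from internal stage boundaries. Classes are then well
  separated by construction (a linear probe already exceeds 95 %), which is
  the intended regime for learning-sanity checks.
* **hard** — scene preset hard, 8 % variability, the full stage interval.
  Samples adjacent to a boundary are genuinely ambiguous, which is the
  realistic regime for the ED-versus-CNN comparison.

The ten labels are {banana, mango, peach} × {unripe, ripe, overripe} plus
blank; blanks are unreacted arrays photographed under the same scene
variation. Train/validation splits are seeded random partitions at 17:3,
rounding toward train (20 → 17/3, 21 → 18/3).

## ED analysis

Per-spot ED is √(ΔR²+ΔG²+ΔB²) of the calibrated post−pre colour
difference; the array total is the arithmetic sum over the 25 spots (a
root-sum-of-squares aggregate is available via `total_mode="rss"`). The
differential map stretches |Δ| linearly from 3–10 counts onto 0–255,
clipping outside. The detection limit is the smallest *tested*
concentration whose total ED exceeds blank mean + 3σ (grid semantics: a
crossing between grid points reports the next grid point); "not reached"
is encoded as `None`. Sensitive dyes are ranked by per-spot ED at the
highest tested concentration (peak-ED ranking; a slope-based statistic
would also be defensible, but peak ED is what an intensity heatmap read-off
gives). Reference ranges are min–max intervals of the calibration samples
per class; overlapping hits are resolved to the narrowest interval and
flagged ambiguous. Ward-linkage HCA runs on Euclidean distances via SciPy;
rows are replicate means by default (the 9 × 3 condition panel gives the
27 × 25 matrix), with replicate-level rows available. Cluster success at a
cut of k is the fraction of samples whose cluster's majority label matches
their own.

## Classifier

Five dense blocks of three 3 × 3 conv layers (BN → ReLU → conv), growth
rate 32, so a block maps C channels to C + 96; transitions
(BN → ReLU → 1 × 1 conv at compression 0.5 → 2 × 2 average pool) halve
both channels and side. The stem — unconstrained by the reference
description — is a single 3 × 3 convolution to 32 channels, stride 1. The
head applies spatial pyramid pooling at grids {1, 2, 4} and one fully
connected layer to 10 scores; the final layer starts near zero so an
untrained balanced model scores ln 10 cross-entropy. Everything runs on
NumPy with im2col + BLAS matrix products and hand-written backward passes;
gradients are verified against central differences in the test suite.

Training follows the standard protocol: cross-entropy, SGD momentum 0.9,
weight decay 1e-4, learning rate 0.01 → 0.005 → 0.001 with breakpoints at
60 % and 90 % of the epoch budget (the proportions of epochs 300/450 out
of 500). Desk-scale defaults — input side 32, batch 32, single-digit
epochs — are sized for a single CPU core; the full-scale protocol
(255 × 255 input, 500 epochs, batch 256) is expressed by the same configs
and reachable via `--full-scale`. Note that early-epoch validation
accuracy lags training accuracy until batch-norm running statistics catch
up with the quickly moving parameters; this resolves within 2–3 epochs.

Grad-CAM backpropagates one class score to the last dense block's feature
maps, weights each channel by its spatially averaged gradient, rectifies
the weighted sum and upsamples to the input extent.

## Numerical and design choices

* ΔRGB is kept signed (post − pre); magnitudes are used only where
  rendering requires them. Whether the original convention was signed or
  absolute is not determinable; totals are unaffected.
* Total ED = sum of per-spot EDs; configurable, see above.
* Calibration is two-point per-channel affine from the patch means — a
  3 × 3 colour matrix is out of scope by design. It is exactly idempotent
  and undoes any non-clipping per-channel gain to within quantization.
* Grid localization defaults to generator metadata; a template-lattice fit
  (translation search maximizing spot saturation, plateau ties resolved to
  the smallest shift) handles images without metadata but not rotated ones.
* Exposure time is treated as equilibrium: the 30-minute exposure is
  assumed long enough that colour change has saturated, so concentration is
  the only dose variable.
* Blank-class images are modelled as unreacted arrays under scene
  perturbation, not as empty containers.
* All randomness flows from one top-level seed through
  `numpy.random.SeedSequence` children; renders, manifests and training
  histories are bit-reproducible for a fixed seed (training within the
  determinism of single-threaded BLAS).

## What the generator does not emulate

Real dye spectra and their chemistry, humidity/temperature kinetics,
exposure-time dynamics, membrane ageing, camera optics (lens distortion,
chromatic aberration), and GC-MS spectra. Passing tests therefore
demonstrate that the *pipeline* is correct and that the statistical
machinery behaves as specified on data with known ground truth — not that
the specific accuracy figures would transfer to photographs of physical
arrays.

## Problem sizes

Test-suite and demo runs use deliberately small problem sizes chosen for a
single CPU core: 120-px dose-response images with 1–3 replicates,
learning-sanity training on 200 images per class at input side 32 for a
few epochs, and the ED-versus-CNN comparison trained on 60 images per
class. The HCA separation study uses the full 27-condition panel at 100
seeds, matching the scale of the reference analysis.
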