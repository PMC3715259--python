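# Methods

`geomexpr` implements a purely geometric pipeline for classifying
expression image sequences that run from a neutral first frame to an
apex: landmark tracking by Gabor-jet phase displacement, translation
normalization, per-landmark and pairwise displacement features, feature
selection by multi-class AdaBoost over DTW nearest-prototype weak
classifiers, and final classification by either the boosted vote or an
RBF SVM on collapsed boosted features. This note records the model, the
defaults and their rationale, the numerical conventions, and what the
synthetic data does and does not establish.

## Landmark tracking

A Gabor jet at image point `p` is the vector of complex responses of the
DC-free Gabor family

    psi_k(x) = (k^2/sigma^2) exp(-k^2|x|^2 / 2 sigma^2) (exp(i k.x) - exp(-sigma^2/2))

over 5 frequencies `k_nu = (pi/2) / sqrt(2)^nu` and 8 orientations
(40 coefficients), with `sigma = 2*pi` — the classic elastic-bunch-graph
configuration. Discrete kernels are truncated at `2.5 sigma / k`,
renormalized by their in-window envelope mass near borders, and
projected to exact zero sum so constant images give exactly zero
magnitudes.

Between a stored jet and a jet extracted at the same position in the
next frame, each coefficient's phase difference rotates approximately as
`k . d` for a local image displacement `d`. The estimator minimizes the
magnitude-weighted squared error between wrapped phase differences and
`k . d`, solving the 2x2 normal equations. Of the several published
flavors of this solve, we use the *focused* variant: coefficients enter
coarse-to-fine one frequency level at a time, phase differences are
re-unwrapped toward the current estimate at each step, and three full
refinement passes follow. The result is clamped to half the largest
kernel wavelength, beyond which phase is uninformative.

Tracking proceeds frame by frame: extract a jet at the previous position
in the new frame, estimate the residual displacement against the stored
jet, move, and repeat up to 3 times (re-extracting at the refined
position) before storing the jet at the final position for the next
frame. Re-extraction at the refined position also cancels most of the
systematic underestimate the linear phase model produces for narrowband
textures. Positions that would leave the image are clamped to the
border and reported with a warning.

Known limitation: the coarsest kernels span a radius of ~40 px, so
landmarks closer than ~20-25 px whose neighborhoods move differently
contaminate each other's low-frequency coefficients and degrade
accuracy. Closed-loop tests therefore use scenes with >= 25 px landmark
spacing; on such scenes the tracker recovers trajectories with motions
up to 2 px/frame to well under 0.1 px RMS. Landmark *initialization* in
frame 0 (face/eye detection, bunch-graph matching) is outside this
package; initial positions are supplied by the caller or the generator.

## Normalization and resampling

The reference frame is the arithmetic mean of frame-0 landmark positions
over the *training* sequences; each sequence (train or test) is
translated per landmark so its frame 0 coincides with the reference
exactly. Translation-only normalization preserves all inter-frame motion
bit-for-bit; no Procrustes/affine registration is applied. For prototype
construction, sequences are linearly interpolated in normalized time to
16 frames, giving feature vectors with N = 15 non-neutral elements.
Normalization and linear resampling commute, so their order is
immaterial; we normalize first. Test sequences on the DTW path are *not*
resampled — warping absorbs length differences (7-60 frames).

## Features

* type-1 (one per landmark): `(dx_l, dy_l) = p_i(l) - p_i(0)`, pixels.
* type-2 (one per pair i < j): change in pair distance and pair angle
  relative to frame 0, `(d_l - d_0, wrap(theta_l - theta_0))`, pixels and
  radians; angle differences wrapped to `(-pi, pi]`, so the i < j
  ordering convention is immaterial (swapping shifts every angle by pi,
  which cancels). A pair that coincides in frame 0 is an error; later
  coincidences carry the previous frame's angle forward with a warning.

The zero neutral-frame element is excluded, so vectors have F-1
elements. The pool enumerates all L type-1 then all L(L-1)/2 type-2
descriptors lexicographically: 1378 descriptors for L = 52. Both feature
types are invariant to global translation; type-2 is additionally
invariant to global rotation applied identically to all frames.

## Prototypes and the DTW weak classifier

Each class is summarized per descriptor by the elementwise **median** of
its training feature vectors (outlier robustness; the class-conditional
distributions are assumed unimodal). Even cardinalities take the mean of
the two middle values.

DTW uses the classic dynamic program with steps {(1,0),(0,1),(1,1)},
anchored endpoints, no slope weights, and Euclidean local cost on the
2-vector elements. The two type-2 channels have mixed units (px, rad);
we keep the raw Euclidean cost as the default and expose per-channel
scaling only as an explicit option, since the pairwise-angle range
(order 1 rad) and distance range (order 1-10 px) are comparable at face
scale. A Sakoe-Chiba band is available purely as a speed optimization;
with radius >= max sequence length it is exact, and the default is
unconstrained. The inner loop is numba-compiled because boosting
evaluates every (sequence, descriptor, class prototype) triple — about
2 million small DTW problems per training fold at the default sizes.

A weak classifier is one descriptor: vote for the class whose prototype
is DTW-nearest (ties to the smallest class index). The one-vs-all binary
variant keeps all K prototypes and declares "positive" iff the positive
class attains the minimum.

## Boosting (SAMME)

Standard SAMME with the round weight
`alpha = log((1-err)/err) + log(K-1)`; the `log(K-1)` term admits weak
classifiers that merely beat random K-class guessing. Because weak
outputs are independent of sample weights, all votes are precomputed
into an (n x D) matrix and each round is a weighted column scan.
Conventions where the procedure is underdetermined:

* err is clamped below at 1e-10 so a perfect weak classifier gets a
  large finite alpha instead of an infinite one;
* training stops early when no remaining descriptor has
  `err < (K-1)/K - 1e-12` (alpha would be non-positive);
* descriptors are selected **without replacement**, so "number of
  selected features" equals the number of rounds;
* per-round ties in weighted error go to the lowest descriptor index.

With K = 2 the loop is exactly classic discrete AdaBoost, which the
tests verify against an independent reference loop. The strong
classifier is the alpha-weighted vote argmax (ties to the smallest
class). Accuracy-vs-rounds curves are prefixes of a single run, not
retrained per M.

## SVM on collapsed features

Each selected descriptor's feature vector collapses to its per-channel
**signed maximum** over the sequence (max dx and max dy, or max dd and
max dtheta), concatenated in selection order: 2x|selected| dimensions
(800 for 400 descriptors). The signed maximum truncates predominantly
downward/leftward motions; an absolute-value variant exists
(`collapse_features_abs`) but the signed form is the default. The
collapse is frame-count independent and is applied to unresampled
sequences. Classification is a one-vs-one RBF SVM; (C, gamma) are chosen
by 5-fold cross-validated grid search over `C in 2^-5..2^15`,
`gamma in 2^-15..2^3` (step 2 in the exponent), with per-dimension
[-1, 1] scaling fit inside the CV pipeline so the scaler never sees
validation folds.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not face appearance. A sequence of F ~ U{7..60} frames places landmark i
of class c at

    template_i + subject_offset + ramp(t^g) * apex_{c,i} + jitter

with a 52-landmark schematic face template (brows, eyes, nose, mouth,
contour; a default 7-region grouping ships with it), a per-sequence
global Gaussian offset (SD 3 px) standing in for subject placement, a
normalized logistic ramp (class-specific steepness 6-10) so motion
accelerates into the apex, a per-sequence monotone time warp
`t -> t^g`, `g = exp(U(-0.5, 0.5))`, so same-class sequences are out of
phase, and i.i.d. Gaussian per-frame jitter (SD 0.3 px, a plausible
tracking-noise scale). The six class models are sparse apex patterns
(8-25 active landmarks, 4-12 px) organized around different face
regions — brow-dominant, mouth-dominant, opening vs compression. They
are fixtures with the right *structure* (sparse, unimodal, regionally
organized), not claims about real expressions.

What passing tests on this data do **not** show: robustness to the
shape idiosyncrasies of real faces (per-subject geometry is an offset
here, not a deformation), to correlated tracking failures, to head pose,
or to the much smaller between-class margins of real expression data.
They do show that every stage — normalization, feature construction,
prototype medians, DTW voting, SAMME selection, both classifier paths,
and the fold protocol — composes correctly and recovers planted
structure.

The renderer draws each landmark as a unique Gaussian-windowed sinusoid
(distinct orientation/frequency/phase per landmark index, window sigma
3 px) on a static smoothed-noise background, with patch centers
following the trajectory at sub-pixel resolution; it exists to close the
loop between the generator and the tracker.

## Evaluation protocol

Stratified 5-fold cross-validation with a logged fold seed. Per fold,
the reference frame, prototypes, boosted selection, feature scaler and
SVM are fit on the four training folds only (verified by a
leakage test comparing fold fits with and without the test sequences
present). Reported accuracy is the mean over folds; pooled confusion
matrices give per-class rates (rows = actual, in percent).

## Problem sizes

Defaults used by the test suite and the acceptance script: 6 classes x
40 sequences (240 total), 1378-descriptor pool, M = 60 boosting rounds,
full SVM grid; one such end-to-end evaluation of both paths takes well
under a minute on one CPU. Tracking checks use 9 textured landmarks over
7 frames at >= 25 px spacing. DTW is validated against exhaustive path
enumeration on 200 random pairs of length <= 6, and the boosting loop
against hand-computed ledgers and a reference binary AdaBoost.

## Known limitations

* No landmark initialization; frame-0 positions must be supplied.
* Tracking degrades for landmarks closer than ~25 px with discordant
  motion (coarse-kernel overlap) and for per-frame motions beyond half
  the finest kernel wavelength (~2 px) unless the coarse levels catch
  them.
* Single median prototype per class: strongly multimodal classes would
  need a mixture extension, deliberately out of scope.
* The signed-max collapse discards motion direction information for
  negative-going channels; use the absolute variant if that matters.
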