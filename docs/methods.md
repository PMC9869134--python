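# Methods

`bifuse` implements a complete hybrid brain-computer-interface pipeline for
left- vs. right-hand motor-imagery classification from simultaneous EEG and
fNIRS recordings: preprocessing for both modalities, sliding-window trial
augmentation, six Y-shaped convolutional fusion networks, training with a
progress-based early-stopping rule, leave-one-trial-out evaluation with
majority voting, and classical CSP / mean-slope + shrinkage-LDA baselines.
Because the open 29-participant dataset the design targets must be
downloaded separately, the package ships a synthetic bimodal generator that
reproduces the statistical structure the pipeline exploits; every stage is
tested against it.

## The synthetic bimodal generator

One synthetic "participant" is a pair of continuous recordings with aligned
cue events: EEG at 200 Hz and chromophore (HbO/HbR) traces at 10 Hz, eight
channels per modality over the sensorimotor cortex, 30 trials per class by
default, 10-s trials separated by 10-12 s rest, matching the emulated
protocol. Hemisphere membership is carried by the channel names (10-05
convention: odd position digits = left, even = right).

* **EEG.** Each channel is 1/f-amplitude broadband noise (white noise
  shaped in the frequency domain, sd `noise_sd`, default 1) plus a 10 Hz mu
  oscillation of unit amplitude with random phase. During a trial the mu
  amplitude on channels contralateral to the imagined hand is multiplied by
  `1 - erd_depth` — event-related desynchronization. `erd_depth` defaults
  to 0.5 (a responsive but not extreme participant); the recovery
  experiments below use 0.8.
* **fNIRS.** A canonical double-gamma hemodynamic response (peak ~6 s,
  undershoot ~16 s, ratio 1/6, unit peak) scaled by `hemo_amplitude`
  (default 0.5) adds to HbO on contralateral channels; HbR receives -0.4
  times the same response, the typical empirical ratio. All channels carry
  sinusoidal physiological confounds (cardiac 1 Hz, respiratory 0.3 Hz,
  Mayer 0.1 Hz, amplitudes 0.2/0.15/0.1) plus white noise at one tenth of
  `noise_sd`.

All randomness flows through one `numpy` generator seeded from the spec, so
an identical spec reproduces an identical dataset bit for bit.

What the generator does **not** emulate: volume conduction and realistic
spatial mixing, non-stationary artifacts (EMG, EOG, motion), optode
sensitivity profiles, trial-to-trial hemodynamic variability, or
participant heterogeneity. Passing tests therefore demonstrate that the
pipeline detects lateralized mu suppression and contralateral hemodynamic
responses when present and stays at chance when absent — not that the
real-data accuracies would be reproduced.

## Preprocessing

EEG: polyphase downsampling 200 -> 128 Hz, EOG channel removal, common
average reference (computed over all retained channels, before montage
selection), zero-phase 4th-order Butterworth band-pass 8-25 Hz, selection
of the eight sensorimotor electrodes, 0-10 s cue-locked epoching, and
per-channel normalization to max |x| = 1.

fNIRS: modified Beer-Lambert conversion when the input is raw two-wavelength
intensity (ΔOD = -log10(I/I0); per channel and time point the 2x2 system
ΔOD = E Δc · d · DPF is solved; defaults: extinction coefficients at
760/850 nm, DPF 6.0, separation 3 cm, all exposed), zero-phase band-pass
0.01-0.1 Hz, upsampling 10 -> 128 Hz, montage selection, epoching with the
[-5, -2] s pre-cue window subtracted as baseline, cropping to 0-10 s, and
per-channel normalization.

Choices the band/rate constants do not determine, fixed here: filters are
4th-order Butterworth run forward-backward (zero phase, no cue-locked
latency distortion); the fNIRS band-pass runs at the native 10 Hz *before*
upsampling (numerically better behaved for a 0.01 Hz corner; the
upsample-first ordering is available via `filter_first=False`);
normalization is per channel per trial (preserves within-channel dynamics;
whole-trial scope via `scope="trial"`). The cue sits at t = 0, epochs are
half-open `[t_start, t_start + duration)`, sample indices are 0-based.

## Augmentation and splitting

Each 10-s trial is cut into 3-s sub-trials: strategy A steps by 3 s (three
non-overlapping sub-trials, so 30 trials per class become 90), strategy B
by 1 s (eight overlapping sub-trials). Window counts follow
`floor((span - window)/step) + 1`. The default train/test split operates on
parent trials, never on sub-trials, so overlapping siblings cannot straddle
the boundary; a literal shuffle-then-split over sub-trials is available for
strategy-A replication where that looser behaviour is wanted. Fractional
test sizes round down to whole parent trials, minimum one.

## The six fusion networks

Both branches are EEGNet-style: the EEG branch has a temporal convolution
(8 filters, kernel (1, 54) by default, 'same' padding, batch-normalized), a
depthwise spatial convolution ((8, 1), depth multiplier 2) with ELU,
average pooling and dropout (p = 0.2), and a separable convolution
(depthwise (1, 8) then pointwise) with batch norm, ELU, pooling and
dropout. The fNIRS branch omits the temporal convolution — its depthwise
layer maps the single input plane to 16 feature maps directly. The head is
flatten -> bias-free dense -> softmax over two classes.

Fusion concatenates branch tensors along the feature-map axis ("depth",
digit 0) or the spatial-row axis ("channel", digit 1), at one of three
points: before the depthwise block (**early**: E_0, E_1), before the
separable block (**middle**: M_0, M_1), or before the flatten (**late**:
L_0, L_1). For early fusion the raw fNIRS plane is broadcast to the width
of the EEG filter bank so both axes are well defined.

The stack is a compact numpy implementation with hand-written backward
passes (im2col + GEMM convolutions, batch-norm with running statistics,
inverted dropout, Adam); every layer is verified against central finite
differences, and full networks against end-to-end finite differences, in
`tests/test_network.py`.

### The parameter-count disambiguation

The published totals for the six configurations (E 3,792 / 3,792; M 8,880
/ 4,172; L 4,176 / 4,176) are the only machine-checkable record of the
architecture's unstated details, so they were treated as an oracle: a
constrained search over input duration, kernel length, per-layer bias use,
batch-norm presence and counting convention, separable sizing (depth
multiplier, pointwise width, kernel), fNIRS-branch widths, early-fusion
shape matching, concatenation-axis semantics and pool lengths (global and
per configuration) was run over roughly 10^5 combinations. No resolution
reproduces all six totals; in particular the two middle-stage totals are
jointly unreachable with any early/late match — the printed value 4,172
sits 4 below the late-stage 4,176, a gap no configuration of this family
can produce — so the middle row appears internally inconsistent.

The frozen resolution (the closest match, exact on E_0, E_1, L_0 and L_1)
is: totals counted as trainable parameters plus batch-norm running
statistics (the convention of framework model summaries); convolutions and
the dense head bias-free; batch norm after the temporal and the pointwise
convolutions only; separable depth multiplier 2 with 32 pointwise filters;
fNIRS depthwise 1 -> 16; kernel (1, 54); 10-s inputs (1280 samples at
128 Hz); pool pairs per configuration E_0 (12, 16), E_1 (4, 12), M_0
(4, 4), M_1 (6, 12), L (16, 16). Under this build `bifuse count-params`
reports E_0 3,792 ✓, E_1 3,792 ✓, M_0 8,528 (-352, -4.0%), M_1 4,304
(+132, +3.2%), L_0/L_1 4,176 ✓. The residuals are reported as measured;
no alternative resolution in the search space reduces them without losing
an exact early/late match.

The table build exists for counting; training uses the 3-s sub-trial
geometry (384 samples) with the same layer family and Table-style pools
(4, 16).

## Training and early stopping

Cross-entropy is minimized with Adam (learning rate 1e-3, batch size 16 by
default — the optimizer is not fixed by the published constants and Adam is
the field default), for at most 500 epochs. No validation set is used.
Training halts when the training progress

    P_k(t) = 1000 · ( Σ_{t'=t-k+1..t} E_tr(t') / (k · min E_tr(t')) − 1 )

falls below α, with k = 10 and α = 0.001. `E_tr` is the epoch-mean
training loss (continuous, which keeps the ratio well behaved; the rule is
agnostic to the error definition). Strips are overlapping — the criterion
is evaluated every epoch over the trailing k epochs, matching the trailing
index range of the formula; non-overlapping strips are available via
`EarlyStopState(overlapping=False)`. A strip whose minimum error is zero
means training has solved the problem and is treated as P = 0 (stop).
P is invariant to positive rescaling of the strip and non-negative by
construction (clamped against float round-off on perfectly flat strips).

## Evaluation

Leave-one-trial-out: one fold per parent trial; the held-out trial's eight
sub-trials form a vote pool, all other trials' sub-trials train a fresh
network. The pool reduces to a trial decision by majority (1 if n1 > n0,
0 if n1 < n0); the rule is silent on ties of the eight-member pools, so
ties default to the class with the larger summed softmax probability, with
a deterministic class-0 fallback available. Sub-trial (pooled) and voted
(trial) accuracies are reported side by side. A hard leakage check fails
any fold in which the held-out parent id reaches the training side.

Paired comparisons across fusion configurations use the two-sided Wilcoxon
signed-rank test (zero differences dropped; exact null for up to 25 untied
pairs, tie-corrected normal approximation otherwise — the scipy
implementation behind a thin policy wrapper, verified against full
sign-assignment enumeration). The comparison table has one row per
stage/axis contrast and one column per temporal-kernel length; reported
"average accuracy" is the mean of per-participant (per-replicate)
accuracies, not pooled trials. Raw p-values are reported.

## Baselines

CSP filters solve the generalized eigenproblem of the trace-normalized
trial-averaged class covariances (`scipy.linalg.eigh(C0, C0 + C1)`), keeping
two filters per spectral extreme (4 components for 8 channels — the
conventional choice); features are log normalized variances of the
projections. fNIRS features are per-channel mean and least-squares slope.
The classifier is LDA with Ledoit-Wolf analytic shrinkage (scikit-learn).
The sliding-window evaluation covers [-5, 20] s around the cue with 3-s
windows stepping by 1 s (23 windows), scores each window by repeated
stratified cross-validation (10 x 5-fold, seeded), and takes the maximum
over windows as the final score.

## Problem sizes for the shipped experiments

The desk-scale experiments (acceptance tests and `compact_config()`) use a
reduced network — 4 temporal filters, kernel (1, 16), separable multiplier
1 with 8 pointwise filters, pools (8, 8), no dropout — trained 6 epochs at
learning rate 0.01, batch 64. On strongly lateralized synthetic data
(`erd_depth` 0.8, `hemo_amplitude` 1.0, 30 trials per class) the early
depth-axis network under full leave-one-trial-out with voting reaches a
mean voted accuracy above 0.85 across five seeds (seed 0 alone recovers
every trial), and stays inside the 95% binomial chance interval when both
effect sizes are zero. These sizes are
the package's own choice of a problem small enough to sweep exhaustively
while still exercising every pipeline stage; the full-size configuration
(8 filters, kernel 54, 500 epochs with early stopping) is the default for
real experiments.

## Known limitations

* The numpy network stack targets clarity and small models; it has no GPU
  path and no graph optimization.
* The open-dataset MAT reader expects the documented per-participant
  variable layout (`x`, `fs`, `clab`, `mrk_pos`, `mrk_y`) and maps event
  codes {1, 2} to left/right; other layouts need a manifest adapter.
* Middle-stage parameter totals cannot be reconciled exactly with the
  published table (see the disambiguation section); the shipped middle
  networks are honest members of the same architecture family with their
  true counts reported.
* The synthetic generator's effect sizes are not calibrated to any real
  participant; accuracies on it say nothing quantitative about real-data
  performance.
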