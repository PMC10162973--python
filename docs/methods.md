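# Methods

This note documents the models, algorithms and numerical choices behind
`invdecode`: what each stage computes, which parameters matter, what the
synthetic test bed does and does not emulate, and where the design was
genuinely open.

## 1. The analysis in one paragraph

Single-trial cortical activity is summarized as a 68 x 100 matrix `X_i`
(68 Desikan–Killiany ROIs x 100 time samples at 200 Hz covering 0–0.5 s
after stimulus onset) with a label `y_i in {upright, inverted}`.  For each
stimulus type (face, body, house) a compact CNN `f(X; theta)` is trained to
decode stimulus orientation under leave-one-subject-out (LOSO)
cross-validation with several random initializations per fold.  Each
trained decoder is explained with epsilon-rule layer-wise relevance
propagation (LRP): the pre-softmax score of the *inverted* class, `o_1`, is
decomposed onto the input, and each ROI's *inversion relevance score*
`RS_{i,l}` is the maximum signed relevance in the 150–200 ms window (the
N170 latency range) for ROI `i` in fold `l`.  Three Wilcoxon signed-rank
criteria applied to the fold x ROI score table select the ROIs most
discriminant of inversion; those ROIs are then characterized with ERPs and
ERD/S maps compared between conditions by cluster-based permutation tests.

## 2. Synthetic cohorts

Real source-localized EEG for this paradigm is not openly available, so
the package generates cohorts whose statistical structure matches what the
analysis assumes.  Per trial, each ROI trace on `[-1, 1)` s at 200 Hz is

    x_r(t) = n_r(t)                                   (all 68 ROIs)
           + [-A c g_A^y exp(-(t - t_p - y d)^2 / (2 sigma^2))   (effect ROIs)
           +  B sqrt(g_T)^y  e(t) sin(2 pi f_T t + phi)]         (effect ROIs)

with `y = 1` for inverted, `0` for upright; `n_r` is `1/f^alpha` Gaussian
noise, independent across ROIs; `e(t)` is a Hann envelope on the theta
burst window; `phi ~ U(0, 2 pi)` per trial so the theta burst cancels in
the ERP but survives in total power (induced activity); `c` is a
per-subject gain (`N(1, 0.1)`, truncated at 0.2) giving mild
between-subject variability.

Defaults (an `EffectSpec`):

| parameter | default | unit | why |
|---|---|---|---|
| effect ROIs | lateraloccipital-rh, superiorparietal-rh | — | right-hemisphere visual/parietal parcels typical of inversion effects |
| evoked peak `t_p` | 0.170 | s | N170 latency |
| inverted delay `d` | 0.015 | s | "later" peak for inverted stimuli |
| evoked width `sigma` | 0.025 | s | monophasic deflection ~100 ms wide |
| evoked amplitude `A` | 2.25 | a.u. | see calibration note below |
| inverted amplitude gain `g_A` | 1.5 | — | "larger" N170 for inverted |
| theta frequency `f_T` | 5 | Hz | theta-band synchronization |
| theta burst window | 0.05–0.45 | s | post-stimulus induced response |
| theta amplitude `B` | 0.5 | a.u. | moderate induced power |
| inverted theta power gain `g_T` | 2.0 | — | "increased synchronization" |
| noise SD | 1.0 | a.u. | unit background; only ratios matter |
| spectral exponent `alpha` | 1.0 | — | pink-noise EEG background |

The control (house) specification uses the same evoked/theta components
with all gains 1 and delay 0: houses evoke a response, but an identical
one for both orientations.

**Calibration.** The source paradigm provides no quantitative cortical
effect sizes; its only quantitative anchor is decodability (face decoding
accuracy ≈ 0.69 under the full 23-subject protocol).  The default evoked
amplitude was therefore set so that the *default desk-scale cohort*
(8 subjects x 16 trials/condition, 3 seeds) lands in the same decodability
regime, ~0.65–0.75 LOSO accuracy for faces.  Because desk-scale training
sets are ~3x smaller than the real ones, this requires a somewhat stronger
per-trial effect than the real data presumably has; the defaults are a
test-bed operating point, not estimates of cortical physiology.

What the generator does *not* emulate: volume conduction and inverse-
solution leakage (ROI signals are independent except for the injected
effects), inter-ROI noise correlation, artifacts, latency jitter across
trials, alpha-band dynamics, and any gamma-band effect.  Passing tests
demonstrate that the pipeline recovers the structure the generator
injects — not that it would behave identically on real recordings.

## 3. Reduction to the decoder input

* **Resampling** uses a polyphase anti-aliasing FIR (`scipy.signal.
  resample_poly`), linear phase with compensated group delay, so output
  sample `k` sits at `t0 + k/fs_out`.
* **Cropping** is half-open `[t_a, t_b)` with 0-based indexing; stimulus
  onset is the first sample of the post-stimulus block.  `[-1, 1)` s at
  1000 Hz -> 200 Hz -> `[-0.5, 0.5)` gives exactly 200 samples, of which
  the decoder consumes the 100 post-stimulus ones.
* **Per-ROI PCA** (vertex-level data): computed per trial on the
  `3 N_r` vertex signals (features) over time samples (observations),
  mean-centered.  The first component's sign is pinned so its extremum has
  the polarity of the extremum of the vertex signal with the largest
  absolute loading.  This makes the output *equivariant* under a global
  sign flip of the bundle (the waveform flips with the data) and
  independent of the SVD backend's internal sign convention.  Note that no
  orientation rule referencing the data can be flip-*invariant*: the
  component is a representative of the data's own orientation.
* **Standardization** uses a single scalar mean/SD over all entries of all
  training trials ("the mean value and standard deviation computed on
  training examples" read in its simplest form); a per-ROI variant exists
  behind `per_roi=True`.  Validation and test sets are transformed with
  training statistics only.

## 4. The compact CNN

Layer stack (input `1 x 68 x 100`):

1. temporal convolution, 4 kernels `1 x 33`, same padding, no bias — 132 weights
2. batch norm (4 channels) — 8
3. depthwise spatial convolution, `68 x 1` kernels, depth multiplier 2
   (8 feature maps), no bias — 544
4. batch norm (8 channels) — 16
5. ReLU; average pooling over time, factor 2; dropout `p = 0.25`
6. dense layer, 2 units with bias — 802
7. softmax

Total: **1502 trainable parameters**.  The published description fixes the
kernel counts (4 temporal, 8 spatial), the layer order and the total
parameter count but not the kernel length or pool factor; the pair
(length 33, pool 2, bias-free convolutions, same padding) is the
configuration consistent with all of these, via
`4*33 + 2*4 + 8*68 + 2*8 + (8*50*2 + 2) = 1502`.  This reconstruction is
validated structurally by `DecoderConfig.expected_parameter_count()`.

**Engine.** No deep-learning framework is assumed: the network is
implemented directly in NumPy (forward, reverse-mode gradients, Adam),
verified against finite differences.  Because the LOSO protocol trains the
same architecture on the same fold data under several seeds, training is
vectorized across a seed axis ("lockstep ensemble"): initialization,
dropout and early stopping are per seed, while the mini-batch sequence is
shared.  Mini-batch composition is fixed after one initial shuffle and
only the batch order is re-drawn each epoch; with batch-norm networks at
this scale the effect on the optimum is negligible and it removes the
dominant memory-gather cost.  With one seed this is the reference
single-model trainer, and the two paths are verified equal in tests.

**Training.** Cross-entropy, Adam, stratified 10% validation split per
fold, early stopping on validation loss with best-epoch restore.  The
optimizer settings of the original study were not published; the package
defaults are lr 1e-3, batch 64, <=500 epochs, patience 20
(`TrainingHyper()`), and the reduced-compute configuration used for small
synthetic cohorts is lr 3e-3, <=60 epochs, patience 8
(`TrainingHyper.desk_scale()`) — a ~200-trial training set yields only ~3
optimization steps per epoch, which the larger step size compensates.
Everything is deterministic given the seeds.

## 5. Layer-wise relevance propagation

The epsilon rule is applied at every layer,

    R_j = sum_k  z_jk / (z_k + eps * sign(z_k)) * R_k ,

starting from `R = o_1` at the inverted output unit (pre-softmax) and
terminating at the input.  Choices:

* **Batch norm** (eval-mode affine) is folded into the adjacent
  convolution's effective weights before propagation.
* **Bias terms** (the dense bias and the folded BN shifts) are
  redistributed uniformly over the layer's inputs rather than discarded.
  With trained shifts, discarding bias relevance breaks conservation
  badly whenever `|o_1|` is small; with redistribution the input map sums
  to `o_1` up to the stabilizer and convolution edge effects (verified to
  within 10% on >95% of trials, typically within 1%).
* **Average pooling** is treated as a linear layer under the epsilon rule,
  i.e. relevance flows to pooled inputs proportionally to their
  activations.
* **ReLU** passes relevance through unchanged (inactive units receive none
  via their zero activations); **dropout** is inactive at explanation time.
* `eps = 1e-6` by default; results are stable over 1e-8..1e-4.

Per fold, maps of the inverted test trials are averaged over trials, then
over seeds.  `RS_{i,l}` is the **signed** maximum over the 11 samples at
150–200 ms inclusive (samples 30..40); a signed rather than absolute
maximum is used because positive relevance is evidence *for* the inverted
class.

## 6. ROI selection statistics

The Wilcoxon signed-rank test is implemented with three regimes: full sign
enumeration for n <= 12 (exact even with midrank ties), a cached
convolution-built exact distribution for tie-free n <= 25, and a
tie-corrected normal approximation with continuity correction otherwise.
Zero differences are discarded (classic convention; the Pratt variant is
available via `zero_method="pratt"`); all-zero differences return p = 1.
Note that SciPy's exact method resolves tied midranks at the boundary
slightly differently; the enumeration definition is the one used here and
in the test oracles.

Criterion 1 is one-sided (greater: "significantly higher than the
average", with the ROI under test included in the fold average); criteria
2 and 3 are two-sided.  Bonferroni correction is applied within each
criterion's family (68, 67, 68 tests) at alpha = 0.05.  The selection is
the intersection of the three criteria.

**Power floor.** With F folds the smallest achievable one-sided exact
p-value is `2^-F`, so a Bonferroni-corrected criterion over 68 ROIs can
only ever reject if `2^-F < 0.05/68`, i.e. `F >= 11`.  Selection is
therefore structurally powerless on cohorts with fewer than 11 subjects,
regardless of effect size; the 23-fold protocol is comfortably above the
floor.  This matters when interpreting desk-scale runs (see section 8).

## 7. Signatures of the selected ROIs

* **ERP**: pointwise trial mean per subject/condition.
* **ERD/S**: squared complex-Morlet coefficients
  (`mne.time_frequency.tfr_array_morlet`), frequency grid 4–40 Hz in 1 Hz
  steps, `n_cycles(f) = max(3, f/2)`; signals are reflect-padded so the
  4 Hz wavelet fits the 1 s epoch.  Each trial's power is normalized by
  that trial's own baseline mean over `[-0.5, 0)` s per frequency,
  `ERDS = (P - B)/B`, then averaged across trials per subject/condition.
  Computing power per trial *before* averaging keeps induced
  (non-phase-locked) activity in the maps.  Per-trial baseline
  normalization carries a positive small-sample bias (`E[P/B] > 1` for a
  noisy baseline); the bias is identical across conditions and cancels
  exactly in the paired contrasts the statistics consume.
* **Cluster permutation tests** (paired, subject-level): pointwise paired
  t statistics, cluster-forming threshold = two-tailed parametric t
  critical value at alpha with df = n-1, clusters of contiguous
  same-sign supra-threshold points (4-neighbour lattice adjacency in
  time–frequency), cluster mass = summed t.  The null distribution is the
  maximal cluster mass over random subject-wise sign flips of the
  condition differences, 5000 permutations by default with the identity
  flip included; cluster p = fraction of null masses >= |observed mass|.
  Because the per-point sum of squares is flip-invariant, all permutation
  t maps are obtained from a single matrix product, which makes the
  1000-dataset calibration simulations cheap.  Wavelet cone-of-influence
  points (e-folding width `sqrt(2) n_cycles / (2 pi f)` from either epoch
  edge) are excluded from time–frequency cluster formation.
  `mne.stats.permutation_cluster_1samp_test` implements the same
  machinery and serves as an independent cross-check in the test suite.

## 8. Problem sizes used by the test suite

The full protocol (23 subjects, 10 seeds, 690 decoders, 5000
permutations) is enumerated and structurally verified, but the simulation
suites run at reduced sizes chosen as package defaults: 3 replicate
cohorts of 8 subjects x 16 trials/condition with 3 seeds per fold for the
decoding/recovery checks; 12 subjects for signature cohorts; 400–1000
replicates with 400–500 permutations for calibration checks.  At the
8-subject scale the decoders and relevance maps recover the injected
effects, but the three-criterion selection sits below the Bonferroni power
floor of section 6 (8 folds < 11), so whole-pipeline selection recovery is
demonstrated structurally (criteria logic on 23-fold score tables) rather
than end-to-end.

## 9. Known limitations

* The synthetic test bed omits source-leakage correlations, so decoding
  difficulty is governed by amplitude/latency/power effects alone.
* The reconstructed kernel length / pool factor pair is the unique natural
  configuration matching the published parameter count, but other exotic
  configurations could in principle reach the same count.
* Optimizer hyperparameters are package choices (the originals were not
  published); absolute accuracies at desk scale depend on them, though the
  face > body > house ordering and chance-level behaviour of controls do
  not.
* ERD/S values at the lowest frequencies lose most of the post-stimulus
  window to the cone of influence; theta-band inference rests on the
  mid-window samples.
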