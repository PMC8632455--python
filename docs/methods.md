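# Methods

This note records the models implemented in `ramanff`, the parameter
defaults and why they were chosen, and what the synthetic cohorts do and do
not establish about real follicular-fluid spectra.

## Spectra and grids

A spectrum is an intensity vector on a uniform, closed wavenumber grid;
the acquisition default is 50–2,000 cm⁻¹ at 1 cm⁻¹ (1,951 points) and all
analysis runs on the 600–1,800 cm⁻¹ fingerprint (1,201 points, endpoints
inclusive). Zones are closed intervals `[lo, hi]`; a grid point belongs to
a zone iff `lo ≤ w ≤ hi`. Five replicate acquisitions per biological sample
are carried as first-class data and collapsed to their pointwise mean
before any per-sample statistic, so that (a) boxplot-style group statistics
have one value per biological sample and (b) train/test splits can never
place replicates of one sample on both sides.

Files are deliberately vendor-neutral: two-column CSV spectra plus a
CSV/JSON manifest. Vendor formats (SPC/WDF, JCAMP-DX) are out of scope.

## Preprocessing

Fixed order: background subtraction (supplied background, pointwise,
negatives floored at 0 for physical non-negativity) → fingerprint crop →
vector normalization → wavelet denoising (classification path only) →
grand-mean centering (discovery path only).

*Vector normalization* is Euclidean: the fingerprint vector is scaled to
unit L2 norm. This reading is fixed by the magnitudes of the reported zone
quantifications (~0.027–0.034): a flat unit-norm 1,201-point spectrum has
value 1/√1201 ≈ 0.02886 everywhere, exactly the scale observed, whereas
area normalization would put quantifications near 1/1200. A consequence
worth keeping in mind throughout: after L2 normalization the spectrum is
compositional — raising one zone necessarily lowers the rest.

*Wavelet denoising* uses a multilevel DWT (haar or db4, default db4 at
level 4), soft-thresholding all detail levels at the universal threshold
σ√(2 ln n) with σ = MAD(finest details)/0.6745. The spectrum is
re-normalized afterwards so downstream quantifications stay on the
unit-norm scale. Denoising is applied only on the classification path;
discovery statistics use un-denoised normalized spectra. Note the
universal threshold's known bias: on spectra whose noise is below ~1% of
peak intensity, soft thresholding shrinks genuine sharp-band detail by
about as much error as it removes (haar additionally staircases smooth
regions), so RMS improvement is only guaranteed at moderate noise; the
tests exercise denoising at 3% additive noise, where both families reduce
RMS error with a wide margin.

## Zone discovery

Per-sample preprocessed spectra are column-mean-centered and decomposed by
PCA (no variance scaling — all columns share units). Loadings follow a
deterministic sign convention (largest-magnitude element positive).
Candidate zone anchors are the local extrema of |PC-1 loading| with
prominence ≥ `min_prominence` × max|loading| (default 0.08). Candidate
zones are all anchor pairs at least `min_width` = 30 cm⁻¹ apart; each is
scored by the two-sided Welch *t*-test on per-sample quantifications,
ranked by ascending *p* (ties: wider first, then lower `lo`), and retained
greedily subject to non-overlap until `max_zones` = 2. No multiple-testing
correction is applied — *p*-values rank zones, they are not inferential
claims — and this is recorded in report metadata.

The anchor-pair enumeration is a reconstruction of a procedure described
only loosely in the literature ("scanning all available zones based on the
bands"); the prominence default matters and 0.08 was chosen during
development: a stricter cutoff drops the weaker zone-A bands (1003,
1156 cm⁻¹) from the anchor set, while a looser one admits anchors at
758/852/936 cm⁻¹ whose wide pairings outrank the true zones purely by
averaging down per-band noise.

*Quantification* is the trapezoidal integral over the zone divided by the
zone width — a width-averaged normalized intensity. Dividing by width keeps
values comparable across zones of different widths and on the printed
~0.03 scale.

*Welch's test* is implemented from the defining formulas
(Welch–Satterthwaite df) and cross-checked against
`scipy.stats.ttest_ind(equal_var=False)` in the tests. Zero variance in
both groups degenerates to p = 1 (equal means) or p = 0 (unequal).

## Synthetic cohorts

The generator emulates the study conditions: 150 + 150 samples for the
PCOS comparison, 75 + 75 for blastocyst quality, 85 + 65 for pregnancy
outcome, five replicates per sample.

Each noiseless class-mean spectrum is a baseline plus pseudo-Voigt bands
(default FWHM 12 cm⁻¹, Lorentzian fraction 0.7 — typical solution-phase
Raman linewidths) at the assigned positions 758, 852, 936, 1003, 1156,
1516, 1518, 1590, 1627, 1668 cm⁻¹ plus broad filler bands; the baseline is
a gentle exponential fluorescence tail over a constant floor, standing in
for residual background after subtraction. Band heights were set so the
two discriminative-zone marker bands dominate their neighbourhoods (these
are, by construction, the cohort's discriminative bands and hence its
loading anchors).

Stochastic structure, all per sample unless noted:

| source | default | emulates |
|---|---|---|
| per-band log-normal amplitude scatter (`sample_gain_sd`) | 0.10 | biological variation; yields per-sample quantification SD ≈ 0.001, the printed spread |
| linear baseline tilt (`baseline_tilt_sd`) | 0.05 | droplet-to-droplet fluorescence differences |
| per-replicate multiplicative jitter (`replicate_jitter_sd`) | 0.02 | focus/power variation between spots |
| additive Gaussian noise (`noise_sd`) | 0.5% of max peak | shot/detector noise |

Class effects are multiplicative gains on bands whose center lies in a
target zone. Calibration solves, per class, the 2 × 2 system "zone-A and
zone-B noiseless post-normalization means = targets" by alternating 1-D
Brent root-finding on the two gains (each zone mean is monotone in its own
gain); the two classes decouple. A global `peak_scale` exists as a config
field but is not a calibration unknown — L2 normalization cancels any
global scale. Calibration reproduces the four targets to < 1e-6 and the
generated cohorts' group means land within ~1e-4 of them at n = 150.

What the synthetic cohorts do **not** contain: photobleaching dynamics,
cosmic-ray spikes, etaloning, correlated metabolite co-variation, or any
real biochemical covariance structure. Consequently, passing tests show
that the *algorithms* behave as specified under the stated statistical
structure — not that real FF spectra reach any particular accuracy. The
published classifier accuracies (90%/74%) and AUCs (0.89/0.72) were
obtained on undeposited clinical spectra and are replaced here by
property-based controls: perfect performance on separable cohorts,
chance-level performance under label permutation, and an operating point
(zone gains ≥ 1.3 at low noise) where held-out accuracy ≥ 0.85.

## Classifier

Architecture fixed at 1201 → 64 → 64 → 2 with relu, dropout (0.2) after
each hidden layer, softmax output, cross-entropy loss, Adam
(lr 0.001, batch 16). Dropout rate, learning rate, batch size and the
epoch cap (500) are conventional small-MLP settings; the architecture
itself (64 + 64, relu, softmax, cross-entropy, Adam) is fixed by the
protocol being reimplemented. "Error threshold 1%" is read as a stopping
rule on full-training-set loss (≤ 0.01); an alternative reading (1%
training error rate) is selectable via `threshold_mode="error_rate"`.
Training is fully deterministic given the seed (weight init, batch order
and dropout masks all come from one `numpy` Generator); the implementation
is plain numpy with hand-written backprop, which keeps the loss history
and stopping rule exactly as specified.

Input rows are replicate-averaged preprocessed spectra. Sample identity is
used only for grouping in splits; outcome labels are never inputs (a
protocol description listing them "as features" would leak the target and
is deliberately not followed). Decision threshold 0.5 for
sensitivity/specificity; ROC sweeps all thresholds and its AUC equals the
Mann–Whitney concordance statistic (tested against a brute-force pairwise
oracle). Three evaluation modes coexist without privilege: stratified 4:1
hold-out (optionally with fixed per-class training counts, e.g. a balanced
50 + 50 training set drawn from an 85 + 65 cohort), leave-one-out CV, and
stratified five-fold CV summarized as mean ± SD of AUC, sensitivity and
specificity.

## Problem sizes in the test suite

The suite runs calibration round-trips at n = 150 per group over 5 seeds,
zone recovery on 20 cohorts of 60 + 60 (recovery at 150 + 150 was verified
to behave identically; 60 + 60 keeps the property test brisk), the
permutation classifier control at 75 + 75, and small (10 + 10) separable
cohorts for the exact-performance controls. The acceptance script always
uses the full 150 + 150 cohort.

## Known limitations

* The zone-scan enumeration explores only anchor-pair windows; a true
  discriminative zone without a loading extremum near each edge cannot be
  found.
* Under strong normalization coupling, broad out-of-zone windows can rival
  narrow true zones when between-sample variation is dominated by
  independent per-band noise; the generator's smooth baseline variability
  mitigates but does not abolish this.
* Welch *p*-values from the scan are selection-biased (minimum over many
  candidate windows) and must not be quoted as calibrated significance.
* The MLP has no early stopping on held-out data; with the loss-threshold
  rule it can overfit small noisy cohorts, which the permutation control
  makes visible.
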