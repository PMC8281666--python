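# Methods

`imhcmr` is an in-silico re-enactment of a head-to-head comparison between
bright-blood and DIR-prepared dark-blood T2\*-weighted cardiovascular MR
(CMR) for detecting intramyocardial hemorrhage (IMH). Because no image data
are publicly deposited for this problem, a generative cardiac phantom stands
in for the patients/animals; every quantification step downstream of the
images is the one a clinical reader workflow would apply, so the package can
also analyze real NIfTI volumes.

## Phantom

Each subject is a stack of short-axis slices on a square grid (default
192 px at 1 mm, 6 slices): background air, an LV blood pool inside the
endocardial radius, a myocardial annulus, an infarct (MI) sector of given
angular span and transmurality, and a hemorrhagic (IMH) core nested in the
infarct, emanating from the sub-endocardium. Blood within a thin layer
adjacent to the MI endocardial border is labelled *stagnant*: it fails to
wash out between the two DIR pulses, so it experiences both inversions and
mimics tissue — the border-obscuring artifact seen clinically. Pixel
membership is decided at pixel centers (0-based, row-major); angles run
counter-clockwise from the anterior RV insertion reference.

Geometry invariants: IMH ⊂ MI ⊂ myocardium; the stagnant layer ⊂ blood
pool. Degenerate geometry (endo ≥ epi, negative spans, etc.) is rejected at
construction.

### Hemorrhage severity rim

Real hemorrhage is not a binary tissue: the local iron concentration decays
from the core outward. The phantom models this with a per-pixel *severity*
s ∈ [floor, 1] inside the IMH region: the effective decay rate interpolates
linearly in R2\* between the remote-myocardium value (s → 0) and the IMH
core value (s = 1), with

    s = floor + (1 - floor) * (1 - u)^p,   u = max(u_angular, u_radial)

where u is the normalized distance to the IMH boundary. Defaults: floor
0.15 (every IMH pixel is strictly hypointense, so noise-free segmentation
recovers the truth exactly) and exponent p = 2 (a diffusion-like rim: a
sizable outer shell is only weakly hypointense, which is what makes
detection noise-limited and reproduces the clinically observed 10–25%
dark-arm underestimation; a linear rim leaves < 3% of the hemorrhage in the
ambiguous band and essentially no underestimation). `build_label_map`
defaults to a uniform core (floor = 1); the subject simulator switches the
rim on.

The chronic phase reuses the same subject geometry with the IMH angular span
scaled by 0.6 and radial span by 0.7 (residual iron core smaller than the
acute hemorrhage) and a shorter IMH T2\*.

## Signal model

Bright-blood: spoiled gradient echo at steady state with TR = RR,

    S = PD sin(a) (1 - E1) / (1 - E1 cos a) exp(-TE/T2*),  E1 = exp(-RR/T1).

Dark-blood: the double-inversion-recovery pair at the R-wave leaves a
longitudinal fraction P = κ(1 − 2η_ns)(1 − 2η_sel) for in-slice tissue and
stagnant blood, and P = κ(1 − 2η_ns) for inflowing blood (replaced between
the pulses). After recovery over TI the preparation multiplies the
bright-blood signal by

    f(TI) = 1 - (1 - P) exp(-TI/T1).

For perfect pulses (η = κ = 1) and long TI, f → 1 and the dark arm equals
the bright arm; any imperfection gives f < 1, monotonically increasing in η
and κ. Ideal inflowing blood nulls at TI = T1 ln 2. Magnitude images are
|S|; Rician noise is the magnitude of (S + g₁, g₂) with independent
zero-mean Gaussians of SD `noise_sigma` (equal in both arms: matched
readout, so the relative metrics isolate the preparation).

No slice profile, k-space, motion or off-resonance physics is simulated;
off-resonance exclusion is a downstream mask flag. There is no MVO class.

### Presets

| parameter | 1.5 T | 3 T | note |
|---|---|---|---|
| TE / flip | 14.5 ms / 18° | 12.7 ms / 10° | clinical T2\*w protocols |
| RR / TI | 857 ms / 600 ms | 857 ms / 600 ms | 70 bpm; TI mid 550–700 ms range |
| η (both pulses) | 0.89 | 0.83 | lumped inversion efficiency |
| κ | 0.92 | 0.85 | lumped preparation attenuation |
| noise σ | 0.7 | 0.38 | bright remote SNR ≈ 22 |
| T1 myo / blood | 950 / 1550 ms | 1200 / 1900 ms | literature-typical |
| T2\* remote / MI / blood | 33 / 40 / 50 ms | 25 / 30 / 35 ms | |
| T2\* IMH acute / chronic | 12 / 9 ms | 8 / 6 ms | iron shortens T2\* |
| proton density myo / blood | 80 / 100 | 80 / 100 | relative units |

η and κ are *calibrated*, not measured: they are chosen so the noiseless
dark/bright remote-myocardium ratio f equals 0.766 at 1.5 T and 0.618 at
3 T, inside the clinically observed relative-SNR ranges; the 3 T preset is
lower because the adiabatic pulse duration is typically doubled at 3 T. The
three myocardial classes share one T1 per field — myocardial T1 differences
(edema) are second order for T2\*-weighted contrast at these TEs, and a
uniform T1 makes f spatially constant over myocardium, which in turn makes
noise-free dark-arm segmentation exactly covariant with the bright arm.

### Tissue texture

On top of the class-wise signal, each subject carries a multiplicative
intrinsic-heterogeneity field (Gaussian, SD 5% of the local signal, one
realization shared by all modalities, since it models the tissue rather than
the acquisition). It gives the remote ROI a realistic COV (~7–9%), gives
the two synthetic readers a reason to disagree (different ROIs sample
different texture), and feeds the SD-inflation mechanism by which the 2-SD
rule underestimates low-contrast hemorrhage. Texture, like thermal noise,
is a stochastic component: a render with `noise_sigma = 0` is fully
deterministic and piecewise-ideal (this degenerate case is what the
recovery checks and the ex-vivo stand-in use).

## Quantification chain

* Remote reference ROI: a myocardial sector diametrically opposite the
  infarct center (estimated from the detected MI mask), default width 60°,
  always excluding the MI mask. Reader jitter rotates (±20°) and resizes
  (±10°) it.
* MI zone: myocardial pixels with LGE signal ≥ remote mean + 5·SD
  (inclusive, per "at least"). A provisional MI mask from a robust
  median/MAD threshold anchors the ROI placement.
* IMH core: pixels inside the MI zone with T2\*w signal ≤ remote mean −
  2·SD; per-slice 4-connected components smaller than `min_core_pixels`
  (default 2) are discarded as speckle. The 2-SD rule is applied per pixel —
  this guarantees each retained core's *mean* also satisfies the criterion
  and matches standard practice; whether the original analysis thresholded
  pixels or core means is not determinable.
* Region SDs use the population (n) divisor. With a zero remote SD (the
  noise-free degenerate case) the inclusive rules would flag the reference
  region itself, so the comparison falls back to strict inequality and the
  result is flagged degenerate.
* IMH extent = 100 × IMH voxels / myocardial voxels over the imaged stack.
* σ_air is the raw SD of the magnitude image over a corner air ROI (default
  40×40 px per slice); no Rayleigh correction, because the relative metrics
  are ratios of like quantities and the factor cancels.

Relative SNR, relative CNR (each arm normalized by its own σ_air, reported
in percent) and COV = σ/SI follow the standard definitions; SI_IMH is
measured on each arm's own detected core, as readers contour per image.

## Segmental diagnosis

Six equal angular sectors per slice (the basal/mid AHA convention; 4-sector
apical variant available), counter-clockwise from the reference insertion
angle, boundary pixels to the lower-indexed segment. A segment is positive
when its hypointense area *exceeds* 1% of its cross-sectional area (strict).
Excluded segments (the off-resonance flag) are dropped from all counts.
Dark-blood calls are scored against bright-blood calls: sensitivity,
specificity, accuracy = (TP+TN)/total evaluated, and AUC from the continuous
per-segment hypointense fraction via the rank-sum (Mann–Whitney) identity
with midrank ties (validated against an exhaustive ROC-sweep oracle). With
no reference positives, sensitivity and AUC are NaN, never 0. Diagnostics
use reader 1's segmentations; extents and signal metrics average the two
readers.

## Agreement statistics

* ICC(2,1): two-way random effects, absolute agreement, single measure, from
  the two-way ANOVA mean squares; 95% CI by the McGraw–Wong F construction
  (cross-checked against pingouin and a brute-force ANOVA oracle). A
  constant matrix has undefined ICC (NaN).
* Bland–Altman on (bright − dark) extents, so positive bias = dark
  underestimates; limits = bias ± 1.96 × sample SD (n−1).
* In-vivo vs ex-vivo: OLS with R² = squared Pearson r. The "ex-vivo" scan is
  emulated as a noise-free render of the same phantom at `fine_factor`× the
  in-plane resolution, re-quantified — a stand-in for fixation imaging, with
  no fixation physics.

## Study runner and reproducibility

`run_study` simulates each cell, runs both arms × two readers, and emits
per-subject rows plus per-cell summary tables (signal metrics, extent,
Bland–Altman, ICC, diagnostics, ex-vivo regression) and a run log echoing
every preset and the full configuration. All randomness descends from one
master seed through `SeedSequence` spawning (per field/subject/phase/
modality/reader), so re-running a config reproduces every table exactly.
Group-level p-values (paired t) are reported descriptively; the package's
claims rest on effect directions, not hypothesis tests.

Synthetic readers are a deliberately weak model of human variability (ROI
jitter + ±0.1-SD threshold perturbation, identical process in both arms):
they produce ICCs of ~0.98–0.999, far tighter than the 0.6–0.95 of human
readers, because contour disagreement and perceptual factors are not
modelled. The dark-vs-bright ICC *ordering* is nevertheless systematic
(the dark arm's compressed signal axis amplifies threshold perturbations by
1/f in signal units), and that ordering — not the ICC magnitude — is the
claim the package tests. For the same reason the per-cell ICC gap (~10⁻³)
can flip sign in a single small cell; the pooled-across-cells comparison is
the stable statement.

## What the synthetic data do not show

Passing tests demonstrate that the *quantification chain and the DIR signal
penalty* jointly produce the reported qualitative findings; they do not
validate tissue parameter values, reader behavior, motion/off-resonance
robustness, or any absolute magnitude measured on real scanners. Cohort
sizes (default 10, 20 in the acceptance run, per cell), grid size and seed
counts were chosen to keep a full run in seconds-to-minutes on one CPU while
leaving the directional effects far above sampling noise.
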