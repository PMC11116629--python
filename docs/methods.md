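# Methods

## The measurement problem

Genetic ablation of first-heart-field (FHF) ventricular cardiomyocytes in
zebrafish larvae produces a robust, reproducible cardiac injury: after
tamoxifen-induced Cre recombination, FHF cells express mCherry fused to
nitroreductase and are killed by metronidazole, while second-heart-field
(SHF) cells keep expressing BFP and regrow the ventricle over the following
days. Regeneration kinetics are read out by imaging each larva ventrally at
three timepoints (0, 1 and 3 days post injury), measuring the BFP+
ventricular area at systole, and normalising to unrecombined negative
controls. This package implements the desk side of that workflow — video
simulation, segmentation, kinetics, cardiac-function metrics and statistics
— so the whole chain can be validated against known ground truth.

## Synthetic beating-heart model

The ventricle is a 2-D ellipse whose semi-axes contract sinusoidally:

    a(t) = a0 · (1 − c · (1 + sin(2π f t + φ)) / 2)

and likewise b(t), with f the beat frequency and c the contraction
fraction. The minimum over a period is a0(1 − c), so diameter-based
readouts have closed forms. The FHF/SHF partition is a chord perpendicular
to the long axis placed so the FHF sector holds a configurable fraction
(default 0.55) of the ellipse area; the true anatomy is 3-D and
interdigitated, so this is a declared simplification. Regeneration state is
geometric: the BFP+ region is the part of the ellipse on the SHF side of a
moving chord whose area fraction equals the larva's BFP+/control ratio, and
ablation leaves a compact disc of surviving mCherry+ cells (area =
survival fraction × sector area, default 3%) at the sector centroid, at
full fluorophore intensity. Encoding survival as area rather than as dimmed
intensity matters: the measured quantity downstream is a thresholded area,
and a 97% loss of mCherry+ *area* is only recoverable by thresholding if
the surviving signal keeps its brightness, which is also what surviving
cells do.

Key defaults, chosen once:

| parameter | default | why |
|---|---|---|
| frame rate / duration / pixel size | 96.8 fps, 2.8 s, 1.3 µm | the acquisition geometry of the automated imaging platform |
| heart rate | 214.3 bpm | ten full beats per 2.8 s acquisition |
| contraction fraction | 0.2 | gives EF = 1 − 0.8² = 0.36, a realistic larval value |
| diastolic semi-axes | 40 × 30 px (52 × 39 µm) | larval ventricle scale at 1.3 µm/px, fits a 128×128 frame |
| FHF area fraction | 0.55 | FHF share of the ventricle at 6 dpf |
| mCherry survival after ablation | 0.03 | 97% loss of the mCherry+ ventricle |
| BFP ratio trajectory (ablated) | 0.45 / 0.65 / 0.85 | regeneration from 45% to 85% of control by 3 dpi |
| n per group | 24 | the per-plate condition size of the screening format |
| inter-larva area CV | 10% (lognormal) | no variance components are published; mild, realistic |
| heart-rate CV | 5% (lognormal) | same rationale |
| intensities / noise | compartment 3000 AU, background 200 AU, Gaussian SD 150 AU (5% of compartment), on 16-bit | no published intensity model; SNR high enough that segmentation, not detection, is the hard part |
| distractors | 6 static Gaussian blobs, σ 3 px, 1500 AU, ≥12 px apart, outside the ventricle | the "nearby autofluorescent structures" thresholds must exclude |
| bulbus arteriosus | disc r = 9 px, offset 43 px, weak BFP (1500 AU) | occasional BFP+ bulbus signal that must be discarded |

Determinism: all per-larva draws come from `numpy` generators keyed on
(seed, group, larva, timepoint), so identical (scenario, seed) reproduce
byte-identical TIFFs regardless of iteration order. Effect modifiers
(drugs, crispants) multiply the TP1→TP2 and TP2→TP3 increments of the
configured trajectory.

What the generator does **not** emulate: optics (PSF, depth, photobleaching),
pericardial edema or any gross morphology outside the heart ROI, larva
dropout across timepoints, motion other than the heartbeat, and intensity
heterogeneity within a compartment. Passing tests therefore show the
measurement chain is correct on data whose difficulty is calibrated
(noise, distractors, nuisance structures, inter-individual variability),
not that it is robust to every real-microscopy artefact.

## Segmentation

Per video: stack-wide min–max rescale to an 8-bit-equivalent range
(mirroring the manual workflow's 8-bit conversion; documented lossy), then
the systole frame is the one whose σ = 2 px Gaussian-smoothed,
above-threshold largest connected component is smallest (ties go to the
earliest frame). The threshold is calibrated per timepoint and channel as
the between-class-variance (Otsu) split of the pooled smoothed provisional
systole frames (dimmest frames) of the control group — negative controls
for BFP, not-ablated controls for mCherry — automating the stated intent of
manually chosen thresholds; a manual override is accepted everywhere. After
binarisation, an optional user polygon is subtracted and only the largest
connected component is kept, which discards bulbus-arteriosus signal and
autofluorescent distractors without manual ROI editing. Areas are reported
in pixels and in µm² (area_px × pixel_size²). An empty mask is a flagged
area-0 result, not an error: a fully ablated mCherry channel legitimately
has almost no signal.

Numerical notes: σ is in pixels of the stored (binned) image; the smoothing
moves the 50%-crossing of an edge to the true boundary, so thresholds near
the mid-intensity of the compartment are area-unbiased, and biases that do
remain cancel in the control normalisation. On noiseless renders the chain
recovers analytic ellipse/sector areas within 2% (pixelation); with default
noise, within 5%.

## Kinetics

ROUT (Q = 1%) is applied per group × timepoint *before* normalisation;
normalised area = 100 × area / mean(non-outlier negative-control areas at
that timepoint), so the control mean is exactly 100 by construction.
Trajectories are tracked by well (the platform returns each larva to its
well), gaps from dropout are kept and counted, never imputed. Summaries are
mean, SEM = sd/√n and n per group × timepoint.

## Cardiac function

A kymograph is built by bilinear resampling of each frame along a
user-supplied chamber line (ceil(L)+1 samples at unit spacing); the
diameter trace is the distance between the outermost above-threshold
samples per column, median-filtered over 3 frames. Beats are diastolic
peaks found with prominence ≥ 25% of the trace amplitude and minimum
separation 0.4 × the dominant period (first off-zero autocorrelation
maximum), so mild arrhythmia does not halve the count;
bpm = 60(n−1)/(t_last − t_first). Diameter extrema are the robust 2nd/98th
percentiles of the trace. Two readouts are declared substitutes for
unpublished proprietary formulas, not reproductions: ejection fraction uses
the single-plane approximation EF = (Dmax² − Dmin²)/Dmax², and the
rate-corrected contraction ("QT-like") interval uses an additive linear
correction QTc = QT + 0.154 × (1 − RR) with a configurable slope, where QT
is the mean per-beat time spent below 90% of the local diastolic diameter.

## Statistics

ROUT is implemented for the constant model: robust location by iteratively
reweighted averaging with Lorentzian weights 1/(1 + (r/s)²); RSDR = 68.27th
percentile of |residuals| × n/(n−1); two-tailed t-probabilities of
residual/RSDR with n−1 df; Benjamini–Hochberg step-up at level Q flags from
the most extreme residual inward. All-identical input yields RSDR 0 and no
outliers without division blow-ups. Full nonlinear-regression ROUT is out
of scope. The two-way ANOVA uses Type-II sums of squares by default
(Type III behind a flag) because group sizes are unbalanced in practice;
Tukey–Kramer comparisons use the studentized-range distribution with the
(1/nᵢ + 1/nⱼ)/2 small-sample adjustment, computed within each timepoint
against the full-model MSE. The unpaired t-test is pooled-variance by
default (the Prism convention), Welch behind a flag; zero-variance input
returns the analytic limits. Normality checks (Anderson–Darling with
estimated parameters, Shapiro–Wilk) are advisory only and report missing
below n = 8.

## Problem sizes

The recovery benchmark (tests and acceptance script) runs the full default
scenario: 3 groups × 24 larvae × 3 timepoints × 2 channels of
271-frame 128 × 128 videos — 432 videos, the size of one screening plate
condition set — which keeps a complete simulate→segment→normalise round
trip in the minutes range on one core. Unit tests use a shrunken cohort
(64 × 64 frames, 1 s, n = 3) with identical structure.

## Known limitations

- The 2-D single-plane phantom cannot probe out-of-focus or 3-D effects;
  real ventricles are neither elliptical nor uniformly bright.
- Otsu calibration assumes the control frames are bimodal; very low SNR or
  dominant distractors would need the manual threshold override.
- The largest-component rule fails if the bulbus touches the ventricle in
  the mask; the polygon override covers that case.
- EF and QTc formulas are declared approximations (see above) and should
  not be compared quantitatively against other tools' definitions.
- Unrecombined (negative-control) mCherry channels contain only background
  and autofluorescence; segmenting them measures distractors, so mCherry
  analyses are only meaningful for recombined groups.
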