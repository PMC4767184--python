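# Methods

## Scope and data model

The pipeline starts at per-ROI signal intensities — image reconstruction
and ROI drawing are upstream of it. One subject's raw record is a
(scan × ROI) grid: `n_pre = 2` pre-contrast repetitions and
`n_post = 39` post-contrast scans, each measured in 3 ROIs (one per
imaging plane). The time–signal intensity curve (TIC) averages the three
ROIs per scan; the baseline S_0 averages all six pre-contrast values.
All kinetic formulas use scan *completion* times,
T_n = t_offset + n·t_acq (defaults 50 s + n·29 s), while the simulator
evaluates the underlying signal at mid-acquisition time
t_offset + (n − ½)·t_acq; the distinction matters only because an
acquisition integrates over 29 s, and completion-time indexing is the
convention the descriptor formulas are defined in.

Missing replicates are a hard error. Imputing a replicate would bias
every ratio built from S_0 and the per-scan means, so rows are rejected
with the subject and scan named instead.

## Simulator

Plasma concentration follows a biexponential population AIF,
Cp(t) = D·(a₁e^(−m₁t) + a₂e^(−m₂t)) with the classical Gd-DTPA values
a₁ = 3.99, a₂ = 4.78 kg/L, m₁ = 0.144, m₂ = 0.0111 min⁻¹, and D the
dose in mmol/kg — concentration is exactly linear in dose. Injection is
treated as an instantaneous bolus at t = 0: the first sample lies at
≥ 50 s, so the shape of a sub-minute infusion is absorbed into the AIF
amplitudes.

Tissue concentration is the single-compartment (Tofts) model,
Ct(t) = Ktrans ∫₀ᵗ Cp(τ)e^(−kep(t−τ))dτ, in closed form for the
biexponential AIF:
Ct = D·Ktrans·Σᵢ aᵢ(e^(−mᵢt) − e^(−kep t))/(kep − mᵢ). The form has a
pole at kep = mᵢ; values within 10⁻⁶ min⁻¹ of a decay rate raise an
error telling the caller to jitter kep (the cohort generator nudges
drawn values automatically). The closed form is verified against a
brute-force trapezoidal convolution (0.01 s steps) in the tests and the
acceptance script; agreement is ~10⁻⁸ relative.

Signal conversion uses the spoiled-gradient-echo steady state,
S = S_eq·sinα·(1−E₁)/(1−cosα·E₁), E₁ = e^(−TR·R₁),
R₁ = r₁₀ + r₁·Ct, with TR = 29 ms and α = 30° matching the dynamic
sequence modelled. TE/T2* decay is neglected (TE = 4.3 ms is short).
The saturation of S in R₁ is the physical reason peak-signal
enhancement grows sublinearly with dose — the tests assert dose
linearity in concentration space and sublinearity in signal space.

### Default population (the simulated study conditions)

| parameter | default | units | why |
|---|---|---|---|
| doses | 0.2 / 0.3 / 0.5 | mmol/kg | the three dose groups under comparison |
| n_per_group | 7 | subjects | the stated cohort design |
| Ktrans | 0.50, CV 15% | min⁻¹ | aggressive, well-perfused tumour |
| kep | 2.0, CV 15% | min⁻¹ | ≫ terminal AIF decay → early peak + washout |
| r₁₀ | 0.7, CV 5% | s⁻¹ | tumour T₁ ≈ 1.4 s at high field |
| r₁ relaxivity | 3.6 | L·mmol⁻¹·s⁻¹ | literature Gd-DTPA value at 7 T |
| S_eq | 98 000, CV 5% | a.u. | places the baseline near 6.5·10³ a.u. |
| noise | gaussian, σ = 2% of baseline | — | triplicate-ROI scatter |
| ROI bias | log-normal, 2% | — | ROI placement differences between planes |

These values were fixed once, before the statistical tests were wired
up, by checking the noiseless curve shape: peak at the second–third
post-contrast scan (108–137 s completion time), E_max ≈ 1.4 at
0.2 mmol/kg, washout type at every dose, and timing parameters
independent of dose. Population variability is log-normal
(positivity-preserving, parameterised by arithmetic mean and CV). All
groups share one PK population; dose is the only systematic difference.

Randomness: the cohort seed expands to one substream per subject via a
counter scheme keyed by (group index, subject index)
(`SeedSequence(entropy=seed, spawn_key=(g, s))`), so enlarging a group
or appending a group never reshuffles existing subjects.

Noise enters as clean·bias + η with η ~ N(0, σ·S₀_clean): σ is defined
relative to the noiseless baseline, which keeps the noise floor
signal-independent the way magnitude-MR background noise is. A Rician
option applies the same σ to real and imaginary channels; the default
is Gaussian because at the simulated SNR (~50 at baseline) the two are
indistinguishable and Gaussian noise keeps the mean unbiased.

## Curve descriptors

Ties for the maximum are broken by first occurrence — T_peak is the time
the maximum is *achieved*. The washout slope regresses post-peak signal
on scan count from the peak (peak at x = 0), in units of signal per
scan; anchoring the peak at x = 0 makes the intercept of an exactly
linear decay equal S_max. A seconds-abscissa variant
(`washout_slope_per_second`) is provided under a distinct name; on the
uniform 29 s grid it is the per-scan slope divided by 29.

Degenerate cases are flagged, not raised, so cohort tables keep all
rows: a peak on the last scan gives V_wash = 0 with
`washout_degenerate=True` (and a NaN slope if fewer than 3 post-peak
points remain); S_39 = S_0 gives SER = NaN with `ser_defined=False`;
a constant post-peak segment gives slope 0 with undefined r.

Curve-type classification compares the last scan with a reference scan
because peak-relative rules degenerate for persistent curves that peak
at the last scan. The reference is the post-scan completing nearest
137 s (scan 3, ≈ 2 min — inside the observed T_peak range), and the
decision band is ±10%: Δ = (S_39 − S_ref)/S_ref > +0.10 → type I,
|Δ| ≤ 0.10 → type II, Δ < −0.10 → type III. Window and tolerance are
parameters; the defaults follow the conventional breast-MRI reading of
late-phase change relative to the early post-contrast signal.

## Statistics

Per parameter, a mean-centered Levene test at α = 0.05 routes between
one-way ANOVA (homogeneous) and Kruskal–Wallis (not). LSD pairwise
tests use the pooled within-group variance and are deliberately
unadjusted for multiplicity — that is the LSD procedure; the report
records the routing decision and the homogeneity p that produced it.
Zero within-group variance with unequal means is reported as an
infinite-F flag rather than a division error.

Summary-statistic reconstruction is exact for ANOVA: the F statistic
depends on the data only through group means, SDs and sizes. For
Kruskal–Wallis, mean ranks determine H up to the tie correction, which
summaries cannot supply; the reconstructed H is therefore the
uncorrected statistic (a lower bound under ties), and rank-sum
conservation ΣnᵢR̄ᵢ = N(N+1)/2 is enforced on input.

The packaged reference summaries carry one notable subtlety: the source
study's text states 7 subjects per group, but every printed F statistic
is reproducible only with n = 4 per group (at n = 7 each reconstruction
is ~75% off), and the printed mean ranks conserve rank sums only at
N = 12. The fixture therefore records the *implied* n = 4 alongside the
stated 7, and `reproduce_tables` accepts an override to demonstrate the
discrepancy. One row (washout fraction) has a printed SD an order of
magnitude out of scale for a fraction, is not reproducible under any n,
and is flagged non-reconstructible. The printed p for the reconstructed
H = 1.423 is also inconsistent with the χ²(2) tail (0.491, not the
printed 0.319); the reconstruction reports the computed value and
carries the printed one as-is.

## What the synthetic cohorts do and do not show

The generator reproduces the *structure* the analysis assumes: washout
kinetics, amplitude parameters rising with dose, timing parameters
invariant to dose, triplicate-ROI noise. Passing tests on it demonstrate
the pipeline's correctness and calibration, not biological truth: real
tumours add heterogeneity the simulator omits (necrosis, spatially
varying perfusion, respiratory motion, baseline drift, inter-scanner
gain differences). Two known behavioural differences from real data:
the simulated washout velocity and slope scale with dose (they are
amplitude-derived in a noiseless compartment model), whereas empirically
they can be dose-stable; and simulated E_wash (~0.25) sits below typical
reported values (~0.4) because the slow AIF elimination phase limits
late-time concentration decay under a bolus AIF.

Statistical calibration is checked end to end: 500 cohorts simulated
from a single population at one dose, split into three arbitrary groups
of 7, pushed through the full pipeline; each parameter's omnibus
rejection rate at α = 0.05 lands near nominal (measured level of the
routed procedure ≈ 0.046 — slightly conservative because the
asymptotic χ² Kruskal–Wallis tail is conservative at n = 7 per group).
The 500-replicate size keeps the whole check under a minute while
bounding the Monte-Carlo SE of each rate at about 0.01.

## Numerical choices

- Convolution oracle: trapezoid at 0.01 s; closed form agrees to
  < 10⁻⁵ relative (measured ~10⁻⁸).
- Summary/raw ANOVA equivalence asserted to 10⁻¹⁰, mean-rank/raw
  Kruskal–Wallis equivalence (tie-free) to 10⁻¹².
- Signals are clipped at 10⁻⁹ a.u. after noise injection — the positive-
  signal invariant; at default SNR the clip is never active.
- CSV round-trips use shortest-repr float writing and round-trip float
  parsing, so simulate → write → read → analyze is bit-exact and a fixed
  seed yields byte-identical artifacts.
- The report JSON layout is fixed by a shipped schema document and
  checked by a structural validator at pipeline exit.

## Limitations

- Single-compartment Tofts only; no plasma-volume term, no
  multi-compartment or shutter-speed effects.
- Population AIF shared by all subjects; no per-subject AIF variation.
- No image domain: ROI segmentation quality, partial-volume and motion
  effects are out of scope.
- The per-scan signal is a point evaluation at mid-acquisition, not an
  integral over the 29 s acquisition window.
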