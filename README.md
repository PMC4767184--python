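# dcekinetics

Dose-aware analysis of dynamic contrast-enhanced (DCE) MRI time–signal
intensity curves: cohort simulation, semi-quantitative kinetic
parameters, curve-type classification, and homogeneity-routed group
statistics — including exact reconstruction of published ANOVA and
Kruskal–Wallis statistics from summary tables alone.

## The problem

Semi-quantitative DCE parameters (enhancement percentages, velocities,
time-to-peak, washout measures) are widely used to characterise tumour
perfusion and to monitor neoadjuvant-chemotherapy response, but many of
them depend on the injected contrast-agent (CA) dose. When scanning
protocols differ in dose, only the dose-*independent* parameters
(time-to-peak, washout velocity and slope, and the curve type itself)
remain comparable. This package implements the full analysis chain used
to establish which parameters those are, for anyone who wants to run the
same pipeline on ROI signal exports or to study its behaviour on
synthetic cohorts with known ground truth.

## What it computes

A subject's curve is built from triplicate-ROI signals on a serial
schedule (2 pre-contrast scans, then 39 post-contrast scans of 29 s
starting 50 s after injection; post-scan *n* completes at
T_n = 50 + 29·n s, so T_1 = 79 s and T_39 = 1181 s). With baseline S_0
(mean of the 6 pre-contrast ROI values) and per-scan means S_1…S_39, the
ten descriptors are

- E_first = (S_1 − S_0)/S_0,  V_first = (S_1 − S_0)/T_1
- S_max, T_peak (first scan attaining the maximum),
  E_max = (S_max − S_0)/S_0,  V_max = (S_max − S_0)/T_peak
- E_wash = (S_max − S_39)/S_max,  V_wash = (S_max − S_39)/(T_39 − T_peak)
- SER = (S_1 − S_0)/(S_39 − S_0)
- Slope_wash: OLS slope of S against scan count after the peak
  (peak at x = 0), in signal units per scan

plus the curve type (I persistent / II plateau / III washout). Group
comparison routes each parameter through a Levene homogeneity test to
one-way ANOVA with Fisher-LSD pairwise tests, or to Kruskal–Wallis.
`anova_from_summary` and `kw_from_mean_ranks` rebuild F = MS_between/MS_within
from group means/SDs/sizes and H = 12/(N(N+1))·Σ nᵢ(R̄ᵢ−(N+1)/2)² from
mean ranks, so published tables can be verified without raw data.

The simulator drives a spoiled-gradient-echo (FLASH, TR 29 ms, flip 30°)
signal model with single-compartment Tofts kinetics
Ct(t) = Ktrans ∫ Cp(τ)e^(−kep(t−τ))dτ under a biexponential population
AIF whose amplitude is linear in dose — so concentration scales with
dose but signal saturates, exactly the mechanism that makes amplitude
parameters dose-dependent and timing parameters not.

## Worked example

```python
from dcekinetics import (CohortSpec, simulate_cohort, build_tic,
                         classify_tic, all_params)

cohort = simulate_cohort(CohortSpec(seed=7))   # 3 doses x 7 subjects
tic = build_tic(cohort[0])                     # subject g1s01, 0.2 mmol/kg
print(classify_tic(tic))                       # TICType.III_washout
p = all_params(tic)
print(f"S0={p.s0:.1f}  E_first={p.e_first:.3f}  S_max={p.s_max:.1f}  "
      f"T_peak={p.t_peak:.0f}s  E_wash={p.e_wash:.3f}  SER={p.ser:.3f}  "
      f"Slope_wash={p.slope_wash:.1f}  r_wash={p.r_wash:.3f}")
```

prints

```
TICType.III_washout
S0=6832.9  E_first=1.420  S_max=16957.9  T_peak=137s  E_wash=0.244  SER=1.620  Slope_wash=-111.9  r_wash=-0.981
```

a washout-type curve: the signal more than doubles by the first
post-contrast scan (E_first = 1.42), peaks at the third scan (137 s),
then declines nearly linearly with scan count (r = −0.98), losing 24% of
its peak by the last scan.

The same pipeline is available from the shell:

```bash
dcekinetics simulate --seed 3 --out-dir out          # signals.csv + manifest
dcekinetics analyze --input-csv out/signals.csv --out-dir out
dcekinetics reproduce-tables                         # printed vs rebuilt stats
```

`reproduce-tables` rebuilds every published omnibus statistic from the
packaged group summaries, e.g. F = 0.065 for T_peak and H = 1.423 for
V_wash, and flags the one row whose printed SD is internally
inconsistent.

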