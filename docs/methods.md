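# Methods

## Scope

ojipkit implements the photosynthetic-function side of a flooding-stress
phenotyping study on mulberry (*Morus alba* L.) seedlings: four treatment
groups (an unflooded control CK and 5/10/15-day flooding treatments D5,
D10, D15), five replicate leaves per group, each measured for a
dark-adapted fast chlorophyll-*a* fluorescence transient (OJIP), a
modulated 820 nm reflection curve (MR820), chlorophyll extract
absorbances, and gas-exchange parameters. No raw instrument data is
distributed with such studies, so the package pairs the analysis chain
with a synthetic-data generator whose ground truth is known exactly; the
generator's defaults encode the reported treatment-response structure, and
the tests verify that the full pipeline recovers what was injected.

## OJIP analysis

Cardinal times follow the usual instrument convention: O = 0.01 ms,
L = 0.15 ms, K = 0.3 ms, J = 2 ms, I = 30 ms, P = 1000 ms. Each cardinal
is read off the sampled curve by interpolation linear in log10(time)
(OJIP sampling is log-uniform, and all induction structure lives on a log
axis, so log-linear interpolation keeps relative error uniform across the
five decades). F_P defaults to the value at the P time (`at_P_time`);
`curve_max` is available for transients that peak before 1 s. No smoothing
is applied before extraction by default; a 3-point median filter is
available behind a flag for spiky inputs. Parameters are computed per
replicate and summarized afterwards — replicate curves are never averaged
before extraction.

Double normalizations V_O-P, V_O-J, V_O-K rescale each window so the O
point is 0 and the window end (P, J or K) is 1. The band-scale relative
variable fluorescence values are

    V_L = (F_L - F_o)/(F_K - F_o),  V_K = (F_K - F_o)/(F_J - F_o),
    V_J = (F_J - F_o)/(F_P - F_o),

with V_I = (F_I - F_o)/(F_P - F_o) computed additionally because the
PSI-end efficiency delta_Ro — and hence PI_total — needs it. Difference
kinetics delta-V(t) subtract the control group's mean normalized curve
from a treatment group's on a common log grid (100 points per decade,
matching the generator default); replicates are normalized first and
averaged afterwards, which preserves endpoint pinning exactly.

The JIP-test cascade (quantum yields, specific fluxes per reaction
centre, PI_ABS, PI_total) is the standard formulation listed in
`ojipkit/jip.py`'s module docstring. M_o uses F_K at 0.3 ms and is quoted
in ms^-1. Internal identities (DI_o/RC = ABS/RC - TR_o/RC,
phi_Eo = phi_Po psi_Eo, PI_total = PI_ABS * delta_Ro/(1 - delta_Ro)) hold
to machine precision by construction and are asserted in the tests, as is
exact invariance of every ratio parameter under rescaling of the raw
signal. Out-of-range but finite values (e.g. PI_ABS > 100) are flagged,
never clamped; the group statistics decide what to do with them.

## MR820 analysis

The headline PSI-activity statistic is the relative decline amplitude
dI/I_o with I_o the curve maximum and I_min the minimum. Extrema of a
noisy curve are biased outward by extreme order statistics (the max of
~400 noisy samples sits ~3 sd above the signal), which would wreck the
amplitude of a nearly flat stressed-leaf curve, so extrema are located on
a lightly Savitzky–Golay-smoothed copy (window = min(31, n/5), order 2).
The initial slope of the decline (a least-squares fit of reflection vs
time from the maximum to the first local minimum, capped at 30% of the
samples) is computed and reported separately; the decline end is detected
as a rebound of more than 5% of the amplitude above the running minimum,
so noise wiggles on the way down do not truncate the segment. A curve
whose maximum falls outside the first 10% of samples is flagged
"atypical"; a flat curve yields the exact degenerate result
dI = ratio = slope = 0 with a "no PSI signal" flag.

## Pigments

Chlorophyll concentrations come from extract absorbances at 663 and
646 nm via a *named, user-overridable* coefficient set; the default is the
classical 80%-acetone pair (Chl a = 12.25 A663 - 2.55 A646,
Chl b = 20.31 A646 - 4.91 A663, µg mL^-1). The study's actual solvent
(acetone:ethanol 1:1) has no canonical published coefficients, which is
exactly why the set in use is recorded in every result. Concentrations are
reported as mg g^-1 fresh mass (absorbance × dilution → µg mL^-1 ×
extract volume / fresh mass). Negative computed concentrations are floored
at zero and flagged; absorbances ≥ 2 are flagged as outside the linear
range.

## Group statistics

All derived parameters flow through one tidy table
(sample × parameter × value) into classical equal-variance one-way ANOVA
(statsmodels OLS under the hood) followed by Fisher's least significant
difference, LSD = t(1-α/2, df_err) · sqrt(2·MSE/n) (harmonic-mean n when
group sizes differ, logged). Compact letters are assigned greedily in
descending-mean order: a group joins every existing letter class whose
members it does not differ from, else starts a new letter. The LSD step is
**protected** — when the ANOVA p exceeds α all groups share one letter.
Unprotected LSD on four groups has a familywise null error rate of
roughly 4α; the protected form keeps the null rate of "any letter
difference" near α (verified at 0.02–0.10 for α = 0.05 over 500 null
simulations in the acceptance tests). No correction is applied across
parameters, matching per-parameter reporting practice; this is a known
caveat for anyone reading many parameters at once. Percent change vs
control is 100·(mean_group − mean_control)/mean_control, decreases
negative.

## Synthetic transients

The generator writes F(t) = F_o + (F_m − F_o) Σ_i A_i S̃(t; τ_i, h) where
S(t) = t^h/(t^h + τ^h) is a Hill sigmoid and S̃ is S rescaled to be 0 at
the O time and 1 at the P time. Targets are the relative variable
fluorescence on the O-P scale at the K, J, I times (optionally also L).
Rather than a square solve over one component per target — whose unique
solution has negative amplitudes for most realistic target patterns, and
whose renormalization to F(P) = F_m shifts the achieved targets — the
amplitudes are solved by **non-negative least squares** over a bank of 12
log-spaced half-times (0.03–500 ms, h = 5) against the anchor equations
plus Σ A_i = 1. When the residual is at machine precision (the case for
every monotone target pattern used anywhere in the package) the anchors
are hit exactly and the curve is monotone because all amplitudes are
nonnegative; a residual above 1e-8 raises "unreachable target
combination" (e.g. non-monotone targets). The steep exponent and dense
bank are what make sharp features such as a strong K-band rise
representable with nonnegative weights.

Replicate noise has two multiplicative parts, both with sd proportional
to F at every point:

* a single per-curve **gain** draw (default CV 0.02) — leaf-to-leaf
  optics, chlorophyll content and clip positioning, the dominant
  between-replicate variation in practice. It cancels exactly in every
  double-normalized ratio, which is why V and PI parameters are far more
  reproducible across replicates than raw fluorescence;
* iid pointwise **detector** noise (default CV = gain CV / 4, i.e. 0.005).
  This is the part that limits recovery of the normalized parameters; at
  0.005 the extracted V values carry per-replicate sds of a few times
  1e-3, consistent with the recovery tolerances the tests enforce. A
  single iid interpretation at CV 0.02 was rejected at design time: it
  makes per-replicate PI_total at the strongest treatment level
  unmeasurable (its denominator V_I − V_J ≈ 0.053 drowns in cardinal
  noise, giving a several-fold Jensen bias), which no amount of averaging
  over five replicates repairs.

MR820 curves follow I_o − dI[(1 − e^(−t/τ_ox)) − r(1 − e^(−t/τ_red))]
with τ_ox = 10 ms, τ_red = 150 ms, recovery fraction 0.3 by default
(fast P700 oxidation, slower partial re-reduction, minimum near 40 ms),
with the same gain + pointwise noise decomposition (0.02 / 0.005; the
modulated channel averages many pulses, hence low pointwise noise).

## The flooding preset

Treatment effects are injected as per-group multipliers: on the O-P-scale
anchor targets, on F_m with F_o fixed (how a pure Fv/Fm effect enters), on
the MR820 amplitude, and directly on pigment and gas-exchange means. The
preset encodes the study's reported percent changes — at D15: Fv/Fm
−22.13%, PI_ABS −96.99%, PI_total −91.72%, dI/I_o −92.36%, and band-scale
V_J/V_K/V_L +63.49/+151.37/+34.43% (D5: +16.39/+19.86/+2.46;
D10: +43.98/+84.25/+10.86); Chl a/b −25.06% (D10) and −37.02% (D15); Pn,
Gs, Tr −94.23/−93.18/−89.49% and Ci −85.30% (D10), −17.83% (D15).

These numbers are not independent: PI_ABS is a function of phi_Po, V_J
and the K-band slope (PI_ABS = phi_Po² (1 − V_J) / (4 v_K (1 − phi_Po))
with v_K the band-scale V_K), so a control baseline cannot be chosen
freely if all the quoted changes are to hold at once. The preset therefore
*solves* for the control V_J from the PI_ABS consistency equation given
phi_Po = 0.8, band V_K = 0.35, band V_L = 0.30 (typical unstressed-leaf
values), yielding V_J ≈ 0.492; the D15 V_I is likewise solved from the
quoted PI_total/PI_ABS ratio through the delta_Ro odds (V_I: 0.75 →
0.858). At D5/D10, where no PI values are quoted, delta_Ro is held at its
control value. Quantities the study reports only qualitatively (MR820
amplitude, Pn/Gs/Tr/Chl at D5/D10) carry round-number multipliers with
the reported direction and ordering. Baseline records are typical for a
broadleaf seedling: Chl a 1.8, Chl b 0.6 mg g^-1 FM (extract 25 mL per
0.1 g, keeping absorbances inside the linear range), Pn 12 µmol CO₂
m⁻² s⁻¹, Gs 0.25 mol m⁻² s⁻¹, Tr 3.5 mmol m⁻² s⁻¹, Ci 280 µmol mol⁻¹,
with replicate CVs of 0.02 (pigments) and 0.05 (gas exchange).

Ground truth (noise-free parameter values per group) is written beside
every generated dataset as `ground_truth.csv`.

## What the simulations do and do not show

The generator reproduces the *shape* of OJIP and MR820 kinetics, the
injected effect structure, and instrument-like noise, so passing tests
demonstrate that the analysis chain is algebraically correct, unbiased at
the stated noise levels, and sensitive enough to recover effects of the
reported size with n = 5. They do not validate against real instrument
quirks the model omits: detector nonlinearity and saturation near P,
actinic-intensity drift, baseline offsets at O (the model pins F(O) = F_o
exactly), non-monotone transients with K-peaks *above* J under extreme
stress, or biological covariance between parameters across leaves (all
injected effects are group-level shifts with independent replicate
noise). Band-scale percent-change estimates inherit ratio-of-means noise:
at the default noise level their sampling sd is 1–3 percentage points,
and for heavily derived indices (PI_total) the estimator is noticeably
right-skewed; medians would be more robust but means are used to match
standard reporting.

## Numerical choices

* Interpolation: linear in log10(t) everywhere; exact at sample points;
  no extrapolation.
* NNLS residual tolerance 1e-8 separates "solved exactly" from
  "unreachable targets".
* Flat-curve guards: F_P < 1.05 F_o flags "no variable fluorescence" and
  excludes the sample from parameter tables; MR820 amplitude below 0.1%
  of I_o is an exact-zero degenerate result.
* ANOVA degeneracies: zero variance everywhere → F = 0, p = 1 (flagged);
  zero within-group variance with separated means → F = ∞, p = 0
  (flagged), and letters then split by distinct means.
* Floats are written with 17 significant digits; every reader/writer pair
  round-trips exactly, and seeded runs are byte-identical (manifests and
  run logs deliberately carry no wall-clock timestamps).
* Default problem sizes: 100 samples per decade per curve (501 points per
  transient), 4 groups × 5 replicates; the statistical null-rate check
  uses 500 simulated tables.
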