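# ojipkit

Analysis of plant photosynthetic function under stress from fast
chlorophyll-*a* fluorescence (OJIP), modulated 820 nm reflection (MR820),
chlorophyll content and gas exchange — for phenotyping experiments that
compare treatment groups against a control, such as a flooding time-course
on mulberry (*Morus alba* L.) seedlings (control CK vs 5/10/15-day
flooding groups D5/D10/D15). Written for plant-stress physiologists who
export instrument curves as plain text and want per-replicate parameters,
group statistics and reproducible simulated datasets from one toolkit.

## What it computes

From each dark-adapted OJIP transient (log-sampled, 0.01–1000 ms) the
package extracts the cardinal points F_o, F_L, F_K, F_J, F_I, F_P by
log-time interpolation and derives:

* **Double normalizations** V_O-P, V_O-J, V_O-K with
  V = (F_t − F_o)/(F_end − F_o), and difference kinetics ΔV(t) versus the
  control group (L-band and K-band analysis).
* **Relative variable fluorescence** V_L = (F_L−F_o)/(F_K−F_o),
  V_K = (F_K−F_o)/(F_J−F_o), V_J = (F_J−F_o)/(F_P−F_o) — markers of
  antenna connectivity, donor-side (OEC) damage and acceptor-side
  blockage, respectively.
* **The JIP-test cascade**: φPo = F_v/F_m = 1 − F_o/F_m,
  M_o = 4(F_K−F_o)/(F_m−F_o), ψEo = 1 − V_J, δRo = (1−V_I)/(1−V_J),
  specific fluxes ABS/RC, TR_o/RC, ET_o/RC, DI_o/RC, and the performance
  indices
  PI_ABS = (RC/ABS)·[φPo/(1−φPo)]·[ψEo/(1−ψEo)] and
  PI_total = PI_ABS·δRo/(1−δRo).
* **MR820 kinetics**: ΔI/I_o (PSI activity proxy) and the initial decline
  slope.
* **Pigments**: Chl a, Chl b, Chl a+b (mg g⁻¹ FM) and Chl a/b from
  extract absorbances via a named, overridable coefficient set.
* **Group statistics**: one-way ANOVA, protected-LSD compact letters, and
  percent change versus the control for every parameter, from one tidy
  table that also carries gas-exchange records (Pn, Gs, Tr, Ci).

A synthetic-data generator produces complete studies (transients, MR820
curves, pigment and gas records, sample sheet, ground truth) from sums of
Hill sigmoids whose amplitudes are solved by non-negative least squares so
the ground-truth V values are hit exactly; treatment effects are injected
as multipliers. See `docs/methods.md` for models, assumptions and design
choices.

## Worked example

```sh
ojipkit simulate -o demo/study --seed 1          # 4 groups x 5 replicates
ojipkit analyze demo/study/sample_sheet.csv -o demo/analysis
ojipkit compare demo/analysis/tidy_parameters.csv -o demo/comparison
```

The analyze step reports `tidy table: demo/analysis/tidy_parameters.csv
(320 rows)` — 20 samples × 16 parameters. The comparison report prints,
per parameter, group means ± sd, LSD letters and percent change vs CK;
for this seed the fluorescence section contains:

```
Fv/Fm:  F=1.589e+04  p=5.355e-28
      CK       0.79982 +- 0.0009192  n=5  a       +0.00%
     D10       0.79946 +- 0.001558   n=5  a       -0.05%
     D15       0.62287 +- 0.002412   n=5  b      -22.12%
      D5       0.80004 +- 0.0008707  n=5  a       +0.03%

PI_ABS:  F=4415  p=1.498e-23
      CK        2.4058 +- 0.0547     n=5  a       +0.00%
     D10       0.51275 +- 0.01815    n=5  c      -78.69%
     D15      0.072179 +- 0.005838   n=5  d      -97.00%
      D5        1.4216 +- 0.03861    n=5  b      -40.91%

V_K:  F=5275  p=3.616e-24
      CK        0.3489 +- 0.005061   n=5  d       +0.00%
     D10       0.64871 +- 0.007063   n=5  b      +85.93%
     D15       0.88356 +- 0.01176    n=5  a     +153.24%
      D5       0.41827 +- 0.003017   n=5  c      +19.88%
```

Read: maximum PSII efficiency (Fv/Fm) only drops at day 15 (−22%), while
the performance index PI_ABS — far more sensitive — already falls 41% at
day 5 and collapses by 97% at day 15, with every group statistically
distinct (letters a–d); the K-band rise (V_K, +153% at D15) points at
donor-side OEC damage. These estimates match the scenario's injected
ground truth (written in `demo/study/ground_truth.csv`) within replicate
noise.

Real instrument exports enter at the `analyze` step: two-column delimited
text curves (time in ms, signal) plus a sample sheet mapping
`sample_id,group,replicate,curve_path[,mr820_path]`, with optional
`pigments.csv` and `gas_exchange.csv` beside it.

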