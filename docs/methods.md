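# Methods

This note documents the models implemented in `rumenserial`, the
assumptions behind them, the defaults of the synthetic-data generator, and
the numerical choices that were genuinely open.

## The experimental system

A serially transferred rumen mixed culture is a chain of 72-h batch
incubations: each 100-mL bottle holds 40 mL of buffered medium plus ~401 mg
DM of milled substrate under a 60-mL CO₂ headspace at 39 °C, and at the end
of each batch 1, 2, or 4 mL of vortexed culture fluid inoculates the next
bottle. The "dilution rate" of such a scheme is an *average transfer rate*,
not a chemostat constant:

```
D (h⁻¹) = (V_inoculum + V_medium) / (V_inoculum × 72 h)
```

which gives 0.5556, 0.2778, and 0.1389 h⁻¹ (presented as 0.56, 0.28, 0.14)
for the 1-, 2-, and 4-mL treatments. Presentation rounding is half-to-even
at two decimals; internal arithmetic is never rounded. Per-day rates, when
displayed, are 24 × the hourly rate (13.33, 6.67, 3.33 d⁻¹); source
material for this design quotes 13.2/6.6/3.3 d⁻¹, which is not 24 × the
hourly values — we display the arithmetically consistent numbers and note
the discrepancy here rather than reproducing it.

## Headspace gas

Absolute pressure is gauge + 101,325 Pa; total headspace moles follow the
ideal gas law (R = 8.314 J mol⁻¹ K⁻¹) at the incubation temperature
(312.15 K) and the nominal 60-mL gas volume. Exetainer subsamples retain
residual air; its share is estimated from the measured O₂ fraction divided
by 0.2095. The adjustment of CH₄/H₂ for that air is not uniquely specified
by the source protocol; we renormalize measured fractions over the non-air
portion, `x_corr = x_meas / (1 − f_air)`, which is the exact inverse of
diluting a CH₄/H₂-free air share into the sample (air contributes no CH₄ or
H₂ at relevant levels). Subtracting air partial pressures instead would
differ only through N₂ bookkeeping; the chosen convention is documented,
not asserted as the original authors' exact method. H₂ partial pressure is
the corrected H₂ fraction × absolute pressure, reported in atm because the
thresholds discussed in this field (~0.04 atm) live on that scale. A
missing O₂ channel falls back to `f_air = 0` with a logged warning.

## Net metabolite production

Each bottle inherits dissolved metabolites from its donor, so per-transfer
net production is `C_final × 40 mL − C_donor × V_inoc` (mM × mL = µmol),
chained along the lineage with the rumen inoculum as transfer 1's donor.
Negative values are net consumption and are kept. The fresh medium's own
VFA content is assumed zero by default (it was measured but its entry into
the arithmetic is unspecified); an optional `medium_conc` subtracts
`C_medium × V_medium` when provided. Ammonium is reported as concentration
only. Apparent DM disappearance, `100 × (substrate − residue)/substrate`,
may be negative because the lyophilized residue includes microbial biomass.
Redox potentials carry a reference-frame tag (`AgAgCl` or `SHE`); the
+197 mV re-referencing refuses to run twice.

## Replication kinetics

Gene copies per bottle across t transfers are modelled as
`N_t = N₀ (1 + R − D)^(t·72)` with a constant average replication rate R.
The estimator is the closed-form inverse; the 576-h exponent at t = 8 makes
it strongly noise-damped (lognormal σ = 0.2 on copies moves R by a median
of ~2 × 10⁻⁴ h⁻¹). Doubling time uses the reciprocal definition `1/R`
deliberately; the conventional `ln 2 / R` is available behind
`conventional=True` but is never the default, and the ~31 % difference
between the two should be kept in mind when comparing to other literature.
N₀ is assembled from inoculum copies per gram of solids × solids content ×
inoculated volume; the solids content is not reported upstream and is
exposed as a parameter (default 0.05 g/mL, an explicit assumption).
`1 + R − D ≤ 0` (possible only when D − R ≥ 1 h⁻¹, far outside this
system) is rejected as out of the model's domain; `N_t = 0` is reported as
a washout limit (R = NaN, trend `washing_out`) rather than an estimate.

## ¹³C isotopolog enrichment

Isotope ratios weight the M+0/M+1/M+2 peak intensities by their ¹³C count
in the numerator and ¹²C count in the denominator,
`IR = Σ k·AIₖ / Σ (n−k)·AIₖ`, truncated at M+2 because higher isotopologs
are undetected. For the 2-carbon acid this is `(AI₁ + 2AI₂)/(2AI₀ + AI₁)`
and is algebraically exact for binomial labelling: IR = p/(1−p). For 3- and
4-carbon acids the truncation biases IR low by a relative p² (n = 3,
exact: truncated IR = p(1+p)) and ≈ 3p²(1−p) (n = 4). At the tracer
strength this design uses (5 % above the 0.0107 natural abundance,
p ≈ 0.0112) the bias is ≤ 4 × 10⁻⁴ relative and is cancelled almost
entirely by the paired-standard delta, but the ratio should not be trusted
to better than ~1 % for hypothetical p near 0.1. Derivative (TBDMS) carbons
are not modelled: the m/z 117–119, 131–133, 145–147 ions are treated as the
VFA isotopologs, and background is removed by the treatment-matched
unlabeled standard rather than by a natural-abundance correction matrix.
δ¹³C = (IR_sample/IR_standard − 1) × 1000.

## qPCR quantification

Standards are dsDNA fragments, so copies/µL = conc × 10⁻⁹ /
(length × 660 g mol⁻¹ bp⁻¹) × 6.02214 × 10²³ — the standard dsDNA
computation with end-group mass ignored (the upstream formula is printed
garbled; this is the reconstruction). The eluate volume enters the chain
explicitly (copies/µL → eluate → per-gram via 1000/aliquot-mg → per-bottle
via residue mass) rather than being folded into another constant. log₁₀ is
the reporting transform. Standard-curve fitting and amplification
efficiency are instrument-side and out of scope.

## Statistics

The factorial mixed model has fixed S + D + T + S×D + S×T + D×T + S×D×T
and random incubation, sequence-in-incubation, I×S×T, and I×D×T. REML
fitting is delegated to `statsmodels` MixedLM with incubation as the
grouping factor and the remaining random terms as variance components;
per-term p-values are Wald chi-square tests on groups of fixed-effect
coefficients. This is an approximation to the reference JMP F-tests
(no Kenward–Roger/Satterthwaite denominator df), adequate for the
simulation-scale designs here; with only two incubations the incubation
variance is weakly identified, and with a single incubation the term is
dropped (with a warning) and sequence becomes the grouping factor.
Significance is declared at p < 0.05 and tendencies at 0.05 ≤ p < 0.10,
with no multiplicity correction, matching the reference analysis.

Because the dilution levels are unequally spaced, the linear contrast is
the centered level vector reduced to smallest integers (exact rational
arithmetic). On the inoculum-volume scale (4, 2, 1 mL) this reproduces the
published coefficients (5, −1, −4); on the h⁻¹ rate scale it gives
(−4, −1, 5). The volume scale is the default because it reproduces the
printed coefficients; that correspondence is an inference about how they
were derived, documented as such.

Outliers are |studentized residual| beyond the central 99.9 % band —
z = 3.2905 under the default standard-normal reference (an
externally-studentized t reference is available via `reference="t"`).
Flagged rows that cluster within a substrate × dilution cell in the same or
consecutive transfers, or within one sequence, are marked retained as
biological results. Remaining flags are judged by leave-one-out refits: a
row is influential only if dropping it changes which terms are significant.

## The synthetic-data generator

The simulator's purpose is to make every pipeline stage testable with known
ground truth, not to be a mechanistic fermentation model. Its fixed frame
is the study design itself (grid, volumes, interval, substrate mass,
headspace, temperature). Choices made once, on realism grounds:

- **Growth** is closed-form logistic per guild within each transfer —
  analytically invertible and deliberately *not* the constant-average-rate
  model the kinetics estimator assumes, so the estimator is stress-tested
  against model mismatch. Bacteria: µ_max 0.35–0.40 h⁻¹, K 1–1.2 × 10¹⁰
  copies/bottle. Archaea: µ_max 0.12 h⁻¹ (high forage; outpaces even the
  40-fold dilution) vs 0.03 h⁻¹ (high concentrate; e^(0.03×72) ≈ 8.7 < 10,
  so washout at every dilution rate), K 10⁸.
- **Inoculum**: 10^10.6 16S and 10^7.8 mcrA copies per g of solids,
  0.05 g solids/mL, and typical rumen-fluid VFA (60 mM acetate, 20 mM
  propionate, 12 mM butyrate, minor acids ~0.1–1.5 mM).
- **Fermentation** products scale with the bacterial biomass increment;
  yields at full growth give ~100 mM total VFA by late transfers. H₂ is
  routed to CH₄ at 4:1 in proportion to min(1, archaea/10⁸); unused H₂
  accumulates. The high-concentrate scenario produces more H₂ and formate
  and less acetate, reproducing the qualitative washout/H₂ signature
  (≳ 10-fold H₂ excess) — a demonstration, not a numeric reproduction of
  any measured effect size.
- **Observables** are generated by the exact inverses of the analysis
  steps: gauge pressure from total moles (headspace starts as pure CO₂ at
  1 atm), fractions from amounts, concentrations from carryover +
  production, copies/g from copies/bottle ÷ residue mass. Air
  contamination f_air ~ U[0, 0.1] exercises the O₂ correction path.
- **Noise**: multiplicative lognormal σ = 0.05 on concentrations, gas
  fractions, and isotopolog intensities (GC/HPLC-scale CV), σ = 0.2 on
  qPCR copies, Gaussian σ = 500 Pa on gauge pressure, σ = 0.05 pH units
  and 5 mV on pH/Eh. All randomness derives from one seed through
  per-lineage labelled streams, so outputs are byte-reproducible and
  insensitive to iteration order.

What a green end-to-end test establishes: the pipeline's algebra exactly
inverts the stated generative model (zero noise), and its estimators are
stable under the stated noise. What it does not establish: behaviour under
real instrument drift, chromatographic interference, non-binomial
labelling, pH-dependent growth inhibition, or electron-balance
constraints — none of which are modelled.

## Known limitations

- The mixed model's Wald tests are asymptotic; small-sample denominator-df
  corrections are not implemented.
- The isotope ratio is truncation-biased for ≥ 3-carbon acids at label
  strengths far above those used here (see above).
- The gas module applies no water-vapour correction and the air correction
  convention is a documented choice among near-equivalent alternatives.
- The simulator has no within-transfer time course; metabolite production
  is attributed to the transfer as a whole, matching the measurement
  cadence but not the underlying dynamics.
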