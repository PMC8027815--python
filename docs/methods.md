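# Methods

## Measurement model

A tissue sample is confined in an insulating cylindrical mold (radius
r = 3 mm, thickness L = 0.56 cm by default) between parallel-plate
electrodes. Two approximations define the whole analysis:

* **Uniform field**: E = V / L between the plates; no fringing-field or
  contact-impedance correction. Plate coverage of the full mold face is
  assumed.
* **Ohmic bulk**: during the flat top of a pulse the sample behaves as a
  resistor, so σ = K / R with the geometric cell constant K = L / (π r²)
  and R the ratio of plateau voltage to plateau current.

Internally everything is SI (m, V, A, S/m, Hz). Field strengths are
accepted and reported in the literature's V/cm at interface boundaries only
(`FieldStrength`), eliminating factor-of-100 mistakes.

## Pulsed-field pipeline

1. **DC-offset removal.** Per-channel means over a pre-pulse quiet window
   (everything before the first detected rising edge, minus a 4-sample
   guard) are subtracted. The window is validated against overlapping any
   detected pulse.
2. **Smoothing.** Low-pass Butterworth, order 4, cutoff = sampling rate /
   20 by default, applied forward and backward (`filtfilt`) so edges are
   not delayed and DC gain is exactly 1. On noiseless data this stage is
   provably neutral for the resistance estimate: voltage and current of a
   single-amplitude train are proportional, linear filtering preserves
   proportionality, and the plateau median of proportional series has the
   same ratio. `apply_filter=False` skips it.
3. **Segmentation.** Pulses are maximal runs with |V| ≥ 0.5 · max|V|
   (threshold samples included); runs shorter than 5 samples are discarded
   as glitches. Indices are 0-based, half-open throughout.
4. **Plateau estimation.** Median of the central 50% of each segment
   (edges trimmed symmetrically). The median tolerates isolated corrupted
   samples; the trim excludes charging transients and filter edge response.
   The intra-pulse window is a package choice — the field reports
   "intra-pulse conductivity" without defining it — and is configurable.
5. **Conductivity.** Baseline σ₀ from the single diagnostic pulse
   (required: exactly one detected pulse); one intra-pulse σ per train
   pulse, summarized by the mean over all pulses. Per-pulse values are
   retained, so first- or last-pulse summaries are a one-line change.
6. **Aggregation.** Per field: mean, sample SD (n−1) and n over per-sample
   train means; SD is reported as 0 and flagged when n = 1 (the standard
   one-sample-per-field design). The group baseline σ̄₀ pools all samples'
   baselines across fields. Percent increase defaults to the per-sample
   reading — each sample against its own baseline, then averaged — with a
   labelled `ratio_of_means` alternative (per-field mean against σ̄₀),
   since printed group means only support the latter. Adjusted
   conductivity is σ_adj = σ̄₀ (1 + %Δ/100), the exact algebraic inverse
   of the percent increase, so σ_adj at 0% equals σ̄₀ by construction.
7. **Joule-heating QC.** A temperature trace fails iff max(T) − T(0)
   strictly exceeds the budget (default 10 °C; boundary passes).

A detected pulse count differing from the declared protocol raises by
default; a warn-and-proceed policy is available for real recordings with
dropped pulses.

## Impedance spectroscopy

σ(f) = K / Re Z(f) pointwise — only the real part enters, with no
complex-permittivity decomposition. Point queries interpolate σ
piecewise-linearly in log10(f) (spectra are log-sampled in this field), are
exact at grid points, and refuse to extrapolate outside the measured range.
Defaults report 10 kHz and 1 MHz. Welch comparison against reference
values matches on tissue label and frequency; pairs without a usable
reference (missing n, zero variance) are reported uncompared rather than
failing the run. Cole–Cole parameter *fitting* to measured spectra is out
of scope; the model is used for generation only.

## Group statistics

Welch's unpaired two-sided t-test, computed from summary statistics:

t = (m_a − m_b) / √(s_a²/n_a + s_b²/n_b), with Welch–Satterthwaite degrees
of freedom. The from-values route is defined as the from-summary route
applied to the computed summaries, so the two cannot disagree; tests verify
both against `scipy.stats.ttest_ind(equal_var=False)` independently.
Printed "±" dispersions are treated as SD (this reading reproduces the
published pancreas comparison at p ≈ 0.02; an SEM reading would not);
`GroupSummary.from_sem` converts when a source states SEM. No
multiple-testing correction is applied — comparisons are reported as raw
per-pair p-values. The caliper transform √(d₁·d₂) (geometric mean of the
widest and perpendicular diameters) is included for tumor sizing.

## Synthetic generator

The generator emulates the study design, not tissue microphysics:

* **σ(E) ground truth**: sigmoid σ(E) = σ₀ + (σ_max − σ₀) / (1 +
  exp(−(E − E_del)/Δ)), defaults 0.24 → 0.40 S/m, E_del = 1000 V/cm,
  Δ = 300 V/cm — magnitudes representative of pancreatic tumor tissue.
  The sigmoid is a modelling choice that gives recovery tests realistic
  monotone structure; real tissue need not follow it.
* **Waveforms**: ideal square pulses, V = E·L, I = σ(E)·V·A/L during the
  pulse, ~0 between pulses. Protocol defaults: 100 pulses of 100 µs at a
  1 s repetition period, sampled at 1 MHz; diagnostic pulse 20 V. The
  recording emulates triggered acquisition: 400 µs of quiet signal is
  stored per repetition (plus a 400 µs lead-in) on a uniform time base, as
  a scope would capture; the full 1 s gaps carry no electrical information
  and are not materialized. The physical repetition period still drives
  the thermal model.
* **Noise**: multiplicative Gaussian on current (default 1% in simulated
  cohorts) and additive DC offsets on both channels — precisely the
  artifacts the conditioning stage removes. All draws flow from a single
  seed; per-recording seeds are derived via `numpy` seed sequences, so a
  cohort is bit-reproducible.
* **Spectra**: single-dispersion Cole–Cole, Z(ω) = R∞ + (R₀ − R∞)/(1 +
  (jωτ)^α), defaults R₀ = 1366 Ω, R∞ = 534 Ω, τ = 1.6 µs, α = 0.85 —
  chosen so the default geometry yields tissue-like σ ≈ 0.15 S/m at
  10 kHz rising toward ≈ 0.37 S/m, with the β-dispersion centered between
  the two query frequencies.
* **Temperature**: each pulse deposits an adiabatic step ΔT = σE²t_p /
  (ρc_p) (defaults ρc_p = 3.6 × 10⁶ J·m⁻³·K⁻¹) that relaxes exponentially
  to ambient with a lumped loss coefficient; sampled at 2 Hz. Steps
  register strictly after their delivery time.

What passing tests therefore show: the pipeline inverts its own forward
model exactly when noiseless and to well under 2% under 1% current noise,
and every derived statistic is internally consistent. What they do not
show: correctness on real tissue, which exhibits pulse-to-pulse memory,
electrode polarization, arcing, drift and non-square generator waveforms —
none of which are modelled.

## Numerical choices and problem sizes

* Plateau statistic: median (not mean) for outlier robustness; central
  fraction 0.5; threshold ties included in a pulse; minimum run width 5
  samples.
* Sample-interval uniformity is enforced to 1e-9 relative on ingestion;
  non-uniform recordings are rejected rather than resampled.
* Recovery validation uses 20 seeded cohorts of the full 7-field,
  100-pulse design (≈ 50 k samples per train under triggered acquisition),
  which keeps the complete suite and the acceptance script in the
  seconds-to-a-minute range on a single CPU while exercising every stage
  at the study's actual protocol size.
* Degenerate inputs are errors, not silent results: empty groups,
  non-positive baselines, zero plateau current, cutoff at Nyquist,
  frequency queries outside the spectrum.

## Known limitations

* No temperature-coefficient correction of conductivity and no parametric
  fit of σ(E) to measured curves (both are natural extensions).
* The baseline diagnostic pulse is assumed strictly non-electroporating;
  no correction is attempted if it is not.
* Whether published intra-pulse percent increases average per-sample
  ratios or ratios of group means is genuinely ambiguous; both are
  implemented and labelled, defaulting to per-sample.
* Reference (literature) conductivities are ingested as free-form CSV;
  no unit harmonization beyond S/m is attempted.
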