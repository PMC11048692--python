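# Methods

This note records the scientific and numerical choices behind `mfescreen`:
what is computed, which conventions were adopted where the underlying method
leaves room, and what the synthetic-data tests do and do not establish.

## Preprocessing

Fixed order, logged in each epoch stack's provenance:
resample → epoch → normalize → filter → trim.

- **Resampling** to 200 Hz uses a polyphase anti-aliased resampler
  (`scipy.signal.resample_poly`). Targets ≤ 60 Hz are rejected (Nyquist for
  the 13–30 Hz β band).
- **Epoching** takes the first 15 consecutive non-overlapping 3-s windows
  unless explicit window offsets are supplied. Clinical practice selects
  clean epochs by hand; explicit offsets reproduce such a selection, the
  default is a deterministic stand-in.
- **Normalization** maps each channel affinely into the [−10, 10] frame set
  by the *medians over epochs* of the per-epoch maxima and minima. Medians
  are not global extrema, so samples may land outside the frame; they are
  **not clipped** — clipping would distort entropy, and fuzzy entropy is
  invariant under the affine map anyway (the tolerance is defined relative to
  the epoch SD). Normalization frame medians are computed after resampling.
  A flat channel (median max = median min) is a hard error.
- **Filtering** uses a linear-phase Hamming-window FIR band-pass of order 600
  (one epoch of taps), applied *causally once* to the concatenated 15-epoch
  series per channel; after re-epoching, the first epoch — which contains the
  filter's start-up transient — is dropped, leaving 14 analysis epochs. The
  "all" band is the 0.5–30 Hz filter output, not the raw signal, so every
  band passes through an identical filtering stage.

## Fuzzy entropy and the MFE tensor

FuzzyEn(m, n, r) = ln Φ_m − ln Φ_{m+1}. Conventions (the canonical fuzzy
entropy definition; some presentations leave them implicit):

- Templates of length m and m+1 are both drawn from the first N − m start
  positions, so the two means run over the same pair count.
- Each template has its own mean removed (baseline removal); distances are
  Chebyshev; self-matches are excluded.
- Membership exponent **n = 2** (smooth Gaussian-like membership) — the
  method's description never fixes n; it is exposed in `MFEConfig`.
- Tolerance r = 0.20 is a fraction of the **scale-1 epoch SD** (sample SD,
  N−1 denominator) and the resulting absolute tolerance is held fixed across
  scale factors, following standard multiscale-entropy practice.
- Coarse-graining at scale s defaults to the **overlapping moving average**
  (window sum divided by s, output length N − s + 1). The literal overlapping
  moving *sum* and the classic non-overlapping average are selectable. A
  sum's variance grows with s, which interacts badly with a fixed absolute
  tolerance; dividing by s keeps amplitudes comparable across scales while
  preserving the overlapping-window structure.
- A constant epoch has zero entropy at every scale. If the dimension-(m+1)
  membership mean underflows to zero, the epoch's value is +∞ ("saturated");
  saturated values are excluded from the epoch average, and a cell where all
  epochs saturate becomes NaN and is skipped in scoring.

The numba kernel skips membership terms whose exponent argument exceeds 60
(contribution < 9·10⁻²⁷); the kernel is verified against a brute-force
double-loop oracle to 10⁻¹⁰.

## Reference model

Per (band, channel, scale) cell: group means (Eq.-style arithmetic mean),
uncertainties u = 1.96·s/√N (sample SD — the cohort is a sample), symmetric
intervals [m ± u], overlap length ol (the intervals live on the 1-D entropy
axis), and penalty factor Pf = 1 + ln(u + ol + 1) with **u = (u_HS +
u_AD)/2** — the penalty is a property of the cell, and the arithmetic mean is
the simplest symmetric choice for "the mean uncertainty". Orientation is
*direct* when m_HS > m_AD, *inverse* otherwise; exact equality of the means
(a measure-zero event) invalidates the cell rather than picking an arbitrary
orientation. Cells lacking two finite values in either group are likewise
invalid; invalid cells are stored, flagged, and skipped by scoring.

Models serialize to JSON (schema version 1) with interval extremes stored
explicitly; loading validates the schema and refuses unknown versions or
incomplete grids.

## Scoring

Zone assignment for a test value x: inside exactly one interval → that zone;
inside both (overlapping intervals — the method's description does not
address this case) → nearest group mean, exact tie → intermediate; in the gap
between facing edges → intermediate; beyond the outermost extremes → the
adjacent group's zone. ϕ0 is the zone's affine map (means ↦ ±2, facing edges
↦ ±1, outer extremes ↦ ±3), **clamped to [−3, +3]** so extrapolated values
stay on the stated scale. With a degenerate (zero-uncertainty) interval the
only point in the zone is the mean, which maps to ±2. ϕ = ϕ0/Pf.

Index aggregation: the denominator is Σ|ϕ| over non-skipped cells. The
default **zone mode** restricts the numerators to AD-zone and HS-zone cells,
so intermediate-zone cells dilute both indices and I_AD + I_HS ≤ 100 % — this
reproduces the stated non-complementarity of the two indices. The literal
**sign mode** (numerators split by sign of ϕ, indices summing to 100 %)
remains available as a flag. The predicted label is the greater index; an
exact tie is "indeterminate" and counts as an error in evaluation. The 50 %
threshold sometimes used for visualization does not affect the label rule.

## Synthetic data

Each channel is Σ_b amp_b·[√λ_b·tone + √(1−λ_b)·band-noise] + 1/f broadband
noise (fraction ρ = 0.3 shared across channels), with per-subject lognormal
amplitude jitter (σ = 0.10) and Gaussian regularity jitter (σ = 0.05). λ_b is
the fraction of band energy from a drift-free oscillator, the direct dial on
band regularity and hence fuzzy entropy.

Two generator findings shaped the frozen presets:

- **Oscillators sit near the low edge of each band** (1.5, 4.5, 8.5,
  14.5 Hz), not the center: at 200 Hz a θ-center tone (6 Hz) has fuzzy
  entropy nearly equal to 4–8 Hz noise (the tone and noise entropy curves
  cross there), so a center-tone regularity dial has no monotone effect in θ.
  A low-edge tone is unambiguously more regular at all scales used.
- **Slow-band amplitudes are equal across groups** (δ, θ: 1.0/1.0): unequal
  amplitudes change the relative in-band share of broadband noise and can
  invert the intended entropy ordering. The AD-like preset's higher
  *relative* slow power instead comes from its reduced α/β amplitudes
  (α 1.5 → 0.7, β 0.9 → 0.45). Regularities: HS λ = 0.75 (δ, θ) / 0.20
  (α, β); AD mirrored. These presets were calibrated once by simulation and
  frozen; they yield band-wise group separations of Cohen's d ≈ 7–8.

What the generator does **not** emulate: biophysical EEG (neural mass
dynamics), artifacts (blinks, EMG), non-stationarity across epochs, realistic
inter-channel topography, or intermediate (MCI-like) severity. A green
end-to-end test therefore establishes that the pipeline's statistics behave
as designed on a world with the stated entropy structure — not clinical
performance.

## Scaled-down end-to-end experiment

Full-default MFE (15 epochs × 20 scales × 5 bands × 19 channels) costs
roughly half a minute per subject even with the jitted kernel, so the
end-to-end acceptance experiment (reference from synthetic cohorts, held-out
scoring, ≥ 90 % accuracy, band-wise direction-of-effect) runs at a reduced
but structurally identical configuration: 5 recorded epochs (4 analysed),
scales 1–5, all bands and channels, 12+12 reference and 10+10 held-out
subjects. With the frozen presets it classifies 20/20 held-out subjects
correctly.

## Numerical conventions

- Sample SD (N−1) everywhere.
- Tiny negative entropies from floating round-off (> −10⁻¹²) are clamped
  to 0.
- DOR with a zero denominator cell: +∞ if TP·TN > 0, NaN for 0/0; an
  optional Haldane (+0.5 per cell) correction is available. MCC with an
  empty marginal is 0. Both conventions are irrelevant for non-degenerate
  test sets.
- Configuration fingerprints (SHA-256 of the canonicalized preprocessing +
  MFE configuration) are embedded in tensors, reference models and reports;
  mixing artifacts across fingerprints is a hard error.

## Known limitations

- EDF support is a minimal built-in reader/writer (uniform rate, int16,
  continuous records); EDF+ discontinuous files and per-signal rates are out
  of scope. CSV is the primary interchange format.
- Epoch selection is deterministic (first windows) unless offsets are given;
  no automated artifact rejection.
- Reference models are not age- or sex-stratified.
- The scorer happily scores any input against any compatible reference;
  interpretation for conditions other than the two reference groups (e.g.
  mixed or intermediate presentations) is outside the model.
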