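# Methods

## The measurement problem

Dissolution dynamic nuclear polarization (dDNP) boosts the 13C NMR signal of
[1-13C]pyruvate ~10,000-fold, enough to watch lactate dehydrogenase (LDH)
convert it to [1-13C]lactate in real time in viable, perfused tumor tissue
slices.  The hyperpolarized magnetization is a non-renewable resource: it
decays irreversibly with T1 (tens of seconds) and every RF excitation of
nutation angle θ consumes a further factor cos θ while emitting a signal
proportional to sin θ.  Extracting an enzymatic rate from the observed peak
intensities therefore requires undoing both loss channels.  This package
implements that analysis for the three acquisition designs used with
tissue-slice perfusion:

1. **Arrested perfusion, non-selective pulses** — bolus injection, flow
   stopped, both resonances read with a small hard pulse (12° every 5 s);
   the rate constant comes from a kinetic-model fit.
2. **Arrested perfusion, selective pulses** — a shaped pulse reads (and
   saturates) lactate at ~90° while pyruvate, 214 Hz away, is barely
   excited; each acquisition measures only newly produced lactate, so rates
   follow from per-excitation arithmetic with no kinetic model.
3. **Continuous flow, selective pulses** — hyperpolarized medium infused at
   constant rate; analysis is restricted to the window where the
   probe-visible pyruvate concentration is constant.

## Two-pool kinetic model (design 1)

State variables are the longitudinal magnetizations P (pyruvate) and
L (lactate).  Between excitations

    dP/dt = −P / T1_pyr
    dL/dt = k_1st · P − L / T1_lac

and at each excitation both pools lose cos θ while emitting sin θ · (pool)
as signal.  Pyruvate consumption is omitted from the precursor equation:
pyruvate is present in large excess (14 mM) and the fraction metabolized
over the acquisition is of order k_1st · t ≈ 10⁻², so the precursor channel
is independent of k_1st.  Two consequences are worth stating: the
closed-form first-order exhaustion law A_lac = Pyr·(1 − exp(−k t)) and the
lossless conservation of P + L hold only to O(k·t) in this model, and the
tests exercise them in that regime.

Because the inter-pulse equations are linear, the simulator propagates them
exactly (matrix exponential in closed form, with a confluent branch when
the two relaxation rates coincide); it is validated against `solve_ivp`
integration to 10⁻⁴ relative.

**Fitting.**  Sequential by default, matching the structure of the model:
the precursor channel (which does not depend on k_1st) determines M0 and
T1_pyr; the product channel then determines k_1st and T1_lac with the
precursor chain fixed.  The product signal is linear in k_1st, so k_1st is
profiled out analytically (variable projection) and only the product
relaxation rate is searched — this is faster, makes the noiseless round
trip exact to optimizer tolerance, and returns k = 0 identically for an
empty product channel instead of wandering a degenerate ridge.  A joint
mode (all four parameters against both channels, each channel scaled by its
peak) is available via `mode="joint"`.  Relaxation rates are bounded to
[0, 100] s⁻¹ (T1 ≥ 0.01 s, a physical cap that removes the ridge where a
huge rate constant is cancelled by an instantly relaxing product pool);
amplitudes and k are bounded below by zero.  Default initial values
(T1_pyr = 55 s, T1_lac = 20 s, k = 10⁻⁴ s⁻¹, M0 = peak precursor signal)
sit near the physiological range for these preparations.  Sample 0 is
dropped from the residuals by default (`drop_first`): the injection is
typically still ongoing during the first spectrum.  R² is reported per
channel, computed over the fitted samples.

## Pulsed decay law and concentration window (designs 2–3)

With perfusion arrested and a selective readout, the pyruvate signal decays
only through T1 and pulsation:

    M(t) = M0 · exp(−t/T1) · cos θ^(t/TR)

`T1DecayModel` fits this with θ and TR known, parametrizing the decay by
the rate 1/T1 (lower bound 0) so an RF-loss-only decay is reported as a
very large T1 rather than a failed fit.  A 90° readout with more than one
sample is rejected as structurally unidentifiable.

The T1 obtained from arrested-perfusion runs is then used to compensate the
continuously measured pyruvate signal: dividing by the envelope
exp(−t/T1)·cos θ^(t/TR) maps a constant concentration to a constant
corrected signal (a flag restricts the envelope to the T1 term alone).
Correction factors above a configurable ceiling (default 20×) are flagged
unreliable — beyond that amplification the corrected values are noise.

The **constant-concentration window** is the contiguous run of corrected
points within 10% of the first maximum.  "First maximum" is the first
running maximum not exceeded within the next 2 samples (the guard absorbs
single-point noise spikes), and the run extends both backward and forward
from it until the first 10% violation: for a bolus-and-arrest series the
maximum is the first point and the window runs forward, while for a
continuous-flow series the corrected signal approaches its plateau from
below, the maximum sits late in the plateau, and the backward extension
picks up the rise edge — so the window starts at the steady-phase onset,
as intended.

## Per-excitation rate and its compensation factor

For each windowed excitation

    v = (S_lac / S_pyr) · ρ · ([Pyr] · V_medium) / (TR · ATP) · 60

in nmole·min⁻¹ per nmole ATP, with [Pyr] in mM and V_medium in mL (their
product, ×10³, is the probe-visible pyruvate amount in nmole).  The factor
ρ converts the *observed* signal ratio into a *magnetization* ratio: the
precursor is read through the selective pulse's off-resonance response
while the product is read at full excitation, so the compensation is the
precursor-to-product response ratio (≤ 1 for a selective pulse; exactly 1
for non-selective acquisition).  `excitation_compensation` computes it from
a Bloch simulation of the stated pulse; a calibrated per-experiment scalar
can be supplied instead and takes precedence — recommended, because the
selectivity of a shaped pulse depends strongly on details (lobe count,
apodization, transmitter placement) that are rarely fully recorded.  For
reference, a plain 3-lobe 2.5 ms sinc has a multi-kHz passband and
therefore almost no contrast at 214 Hz; strong pyruvate suppression at that
offset implies a narrower-band pulse than the nominal parameters suggest.

Per-point rates are aggregated as mean ± SD over the *stabilized* points:
the trailing contiguous run within 15% (two-sided, configurable) of the
median per-point rate.  The median, not the maximum, defines the level
because the last windowed point is often inflated by wash-out onset (the
lactate integrates over the preceding TR while the pyruvate has already
started to drop) and a maximum-keyed rule can collapse onto that outlier.

Note an intrinsic property of the selective readout: the lactate measured
at each pulse accumulated over one TR while relaxing with T1_lac, so the
observed plateau rate underestimates the instantaneous production rate by
(T1_lac/TR)·(1 − exp(−TR/T1_lac)) ≈ 0.82 at TR = 8 s, T1_lac = 20 s.  The
package reports the observed rate without compensating this loss (the
convention of the source protocol); the synthetic-flow truth record carries
the noiseless observed-plateau rate so recovery tests compare like with
like.

## 31P ATP normalization

Tissue viability and the amount of enzymatically active tissue are
quantified from the γ-ATP integral of a thermal-equilibrium 31P spectrum,
referenced to an external ATP standard (111 mM in D2O) measured the same
day.  Each integral is reduced to a fully-relaxed-equivalent per-scan
integral by dividing by the scan count and the steady-state saturation
factor sin θ·(1−E)/(1−E·cos θ), E = exp(−TR/T1) (validated against a
10⁴-pulse recursion to 10⁻⁶).  T1 is mandatory metadata on every
measurement — the correction is refused rather than silently assumed.  The
per-ATP rate converts to a per-mass rate through the literature factor
0.86 µmole ATP per gram of tissue, and `signal_equivalence` expresses a
hyperpolarized concentration as its molar-equivalent signal
(conc × enhancement, default 10⁴).

## Pulse response simulation

The Bloch propagator discretizes the envelope into piecewise-constant steps
(default 2,000; doubling changes responses by < 10⁻⁴) and composes the
exact rotation generated by the instantaneous effective field (B1 along x,
offset along z).  Relaxation during the 2.5 ms pulse is neglected (error
< 0.02% against T1 ≈ 20–60 s).  The sinc envelope is truncated at a zero
crossing with a configurable number of side-lobe pairs (default 3, a common
spectrometer default, stated so ρ values are reproducible), and the
amplitude is scaled so the on-resonance flip equals the calibrated angle.
Checks: on-resonance response equals sin(angle) exactly (rotations about a
common axis commute); the profile is even in offset for symmetric
envelopes; for small calibrated angles it matches the Fourier transform of
the envelope to 2% over the excitation band; off-resonance values match an
independent fine-step scipy-rotation composition to 10⁻⁴.

## Synthetic data

The generators emit the statistical and kinetic structure of the three
designs with a machine-readable truth record.  Default conditions follow
the study geometry: probe-visible medium 0.5 mL, tissue 0.9 mL, total
1.4 mL, [Pyr] = 14 mM; non-selective scheme 12° / TR 5 s / 66 samples;
selective scheme 90° product readout, small precursor angle, TR 8–16 s,
preceded by a quench block (default 4 pulses at TR 2 s) that resets product
accumulated during the injection period (default 5 s).  The continuous-flow
design drives a single well-mixed probe compartment (time constant
V_total/flow = 1.4 mL ÷ 4 mL/min = 21 s) with a 12 mL ÷ 4 mL/min = 180 s
steady inflow; the mixing time constant alone reproduces the ~50 s interval
between first detection and the concentration plateau, so the explicit
inflow ramp defaults to zero.  An optional inflow spike at the end of the
steady phase emulates the arrival of less-depolarized material from the
perfusion line, for testing window-selector robustness.

Noise is additive Gaussian with a fixed seed (bit-identical datasets per
seed).  Where a test specifies data quality as an SNR, the noise sigma is
scaled per channel (sigma_c = peak_c/SNR): the two channels differ by
~500× in these data and are handled in per-channel display units, so a
common absolute sigma would not represent "data at SNR 50".

**What the generators do not emulate:** rician/spectral-baseline noise
structure, B0/B1 drift, pyruvate-hydrate and impurity resonances, partial
saturation transfer, transport heterogeneity within the slice stack, or
inter-experiment biological variability.  Passing recovery tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to every artifact of real spectra.

## Problem sizes and numerical choices

Test and acceptance runs use the study-scale problem sizes: 66-sample
non-selective series, 10–40-sample selective series, 100-replicate
Monte-Carlo recovery studies, 10⁵-step Bloch oracles, and fine-grid ODE
oracles at rtol 10⁻¹¹.  Optimizer tolerances are set to 10⁻¹⁵ so noiseless
round trips recover parameters to ≤ 0.1%.  Degenerate inputs are handled
explicitly: empty product channel → k = 0; 90° decay fit → error;
precursor response below a floor (default 10⁻⁶) → degenerate-ratio error;
fewer than 3 corrected points or no positive maximum → no-plateau error;
missing 31P T1 → error.

## Known limitations

* The kinetic fit neglects pyruvate consumption and reverse (lactate →
  pyruvate) flux, alanine/bicarbonate channels, and hydrate exchange.
* ρ from simulation is only as good as the pulse description; a measured
  per-experiment ρ should be preferred.
* The per-excitation rate is reported uncompensated for product T1 decay
  within TR (see above); comparisons across TRs must account for it.
* The well-mixed-compartment flow model ignores spatial transport in the
  slice stack.
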