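# hpkinetics

Kinetic analysis of hyperpolarized [1-13C]pyruvate → [1-13C]lactate
conversion in perfused tissue slices, measured by dissolution-DNP 13C NMR.

Hyperpolarized magnetization is a one-shot resource: it relaxes with T1
and every excitation of nutation angle θ spends a further factor cos θ
while reading out sin θ of the pool.  `hpkinetics` turns peak-intensity
time series acquired under such schemes into lactate-dehydrogenase (LDH)
activity, normalized to viable tissue via 31P ATP quantification.  It is
written for spectroscopists running tissue-slice perfusion experiments and
for anyone who needs a tested reference implementation of the underlying
arithmetic.

## What it computes

**Non-selective acquisition (bolus + arrested perfusion).**  A two-pool
model with first-order production and per-pulse RF losses,

    dP/dt = −P/T1_pyr,    dL/dt = k_1st·P − L/T1_lac,

plus a cos θ loss and sin θ readout at every TR, is fitted to the two
channels (precursor first — it is independent of k_1st — then product).
The fitted k_1st extrapolates to produced amounts via
A_lac = Pyr·(1 − exp(−k_1st·t)).

**Selective acquisition (arrested or continuous flow).**  A shaped pulse
reads lactate at ~90° while pyruvate (214 Hz away) is barely excited, so
each excitation measures only newly made lactate.  The chain is:
T1 of pyruvate from the pulsed decay law
M(t) = M0·exp(−t/T1)·cos θ^(t/TR); decay compensation of the pyruvate
channel; selection of the constant-concentration window (points within 10%
of the first maximum of the corrected signal); and the per-excitation rate

    v = (S_lac/S_pyr) · ρ · ([Pyr]·V_medium) / (TR·ATP) · 60   [nmole/min per nmole ATP]

where ρ compensates the two species' different responses to the selective
pulse (Bloch-simulated from the pulse shape, or supplied as a calibrated
scalar).  ATP comes from a γ-ATP 31P integral referenced to an external
standard with flip-angle/TR/scan-count corrections, and 0.86 µmole ATP/g
converts per-ATP rates to per-mass rates.

Synthetic-data generators reproduce the three experimental designs
(arrest + non-selective, arrest + selective with quench block, continuous
flow with build-up/steady/wash-out) with machine-readable ground truth, so
the whole chain is testable without any external data.

## Worked example

```python
import numpy as np
from hpkinetics import (AcquisitionScheme, KineticParams, NoiseModel,
                        extrapolate_amount, fit_two_pool,
                        generate_arrest_nonselective, per_mass_rate)

params = KineticParams(k1st=1.55e-4, t1_precursor=64.5, t1_product=20.0, m0=1.0)
scheme = AcquisitionScheme.nonselective(tr=5.0, nutation=12.0, n_samples=66)
series, truth = generate_arrest_nonselective(params, scheme,
                                             noise=NoiseModel(sigma=2e-5, seed=0))
fit = fit_two_pool(series, scheme)
print(f"k_1st      = {fit.params.k1st:.3e} /s")
print(f"T1(pyr)    = {fit.params.t1_precursor:.1f} s   (R2 = {fit.r2_precursor:.3f})")
print(f"T1(lac)    = {fit.params.t1_product:.1f} s   (R2 = {fit.r2_product:.3f})")
amount = extrapolate_amount(fit.params.k1st, 14.0 * 0.5 * 1e3, 60.0)
print(f"lactate in 1 min = {amount:.1f} nmole")
print(f"per ATP    = {amount / 11.4:.2f} nmole/min per nmole ATP")
print(f"per mass   = {per_mass_rate(amount / 11.4):.2f} umole/g/min")
```

Output:

```
k_1st      = 1.556e-04 /s
T1(pyr)    = 64.5 s   (R2 = 1.000)
T1(lac)    = 20.1 s   (R2 = 0.969)
lactate in 1 min = 65.0 nmole
per ATP    = 5.71 nmole/min per nmole ATP
per mass   = 4.91 umole/g/min
```

The fit recovers the generating rate constant and both T1s from the noisy
series; 65 nmole of lactate per minute from the 7 µmole of probe-visible
pyruvate, normalized to a typical tissue ATP content of 11.4 nmole, gives
an LDH activity of ~5.7 nmole/min per nmole ATP, i.e. ~4.9 µmole per gram
of tissue per minute.

## Command line

```bash
hpkinetics synth --design continuous_flow --out flow.csv     # + truth sidecar
hpkinetics fit-kinetics series.csv --tr 5 --angle 12
hpkinetics fit-t1 decay.csv --tr 8 --angle 5
hpkinetics rate flow.csv --design continuous_flow --t1 53.4 \
    --rho 0.087 --tr 8 --angle 5 --atp 11.4
hpkinetics pulse-profile --kind sinc --duration 2.5e-3 --angle 90
hpkinetics run --config run.yaml --out report.yaml
```

Series files are plain CSV, either wide (`time_s,pyruvate,lactate`) or
long (`time_s,species,intensity`); configs are YAML.  Reports carry units
on every number and list every default that was applied.

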