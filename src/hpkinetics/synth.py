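"""Synthetic datasets with the structure of the three experimental designs.

No public hyperpolarized tissue-slice dataset exists, so every pipeline
stage is exercised against generated data with a known ground truth:

1. **Arrested perfusion, non-selective pulses** — a bolus of hyperpolarized
   medium replaces the probe volume, perfusion is stopped, and both
   resonances are read with a small hard pulse every TR.  The signals are
   exactly the two-pool model of :mod:`hpkinetics.kinetics`.
2. **Arrested perfusion, selective pulses** — the product is read (and
   reset) at 90 degrees while the precursor sees only a small effective
   angle.  An initial block of rapid "quench" excitations nulls the
   product-region impurities before the analysis train starts.
3. **Continuous flow, selective pulses** — hyperpolarized medium is infused
   at a constant rate, so the probe-visible precursor concentration shows
   build-up, steady state and wash-out.  The probe volume is modelled as a
   single well-mixed compartment with time constant V_total / flow.

Each generator returns the series plus a truth record (plain dict) holding
every parameter, so recovery tests can compare estimates against it.
Fixed seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atp import P31Measurement, saturation_factor
from .exceptions import InvalidParameterError
from .kinetics import (
    AcquisitionScheme,
    HyperpolarizedSeries,
    KineticParams,
    _transfer_kernel,
    propagate_pulse_train,
    simulate_two_pool,
)

__all__ = [
    "ExperimentGeometry",
    "FlowProfile",
    "NoiseModel",
    "generate_arrest_nonselective",
    "generate_arrest_selective",
    "generate_continuous_flow",
    "generate_p31_pair",
]


@dataclass(frozen=True)
class ExperimentGeometry:
    """Probe-visible volumes (mL) and the hyperpolarized pyruvate concentration (mM)."""

    v_medium: float = 0.5
    v_tissue: float = 0.9
    v_total: float = 1.4
    pyr_conc: float = 14.0

    def __post_init__(self) -> None:
        if min(self.v_medium, self.v_tissue, self.v_total, self.pyr_conc) <= 0:
            raise InvalidParameterError("geometry values must be positive")
        if abs(self.v_medium + self.v_tissue - self.v_total) > 1e-9:
            raise InvalidParameterError("v_medium + v_tissue must equal v_total")


@dataclass(frozen=True)
class FlowProfile:
    """Inflow timing of the continuous-flow design.

    The default steady duration follows from infusing 12 mL of
    hyperpolarized medium at 4 mL/min (180 s); the default wash-out rate is
    the mixing rate of the probe compartment, flow / V_total =
    (4/60) / 1.4 per second (time constant ~21 s), which also produces the
    ~50 s build-up seen between first detection and the concentration
    plateau — ``buildup_duration`` adds an explicit linear inflow ramp on
    top and defaults to zero.
    """

    arrival_time: float = 10.0
    buildup_duration: float = 0.0
    steady_duration: float = 180.0
    washout_rate: float = (4.0 / 60.0) / 1.4

    def __post_init__(self) -> None:
        if self.arrival_time < 0 or self.buildup_duration < 0 or self.steady_duration < 0:
            raise InvalidParameterError("flow durations must be non-negative")
        if not (self.washout_rate > 0):
            raise InvalidParameterError("washout_rate must be positive")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian intensity noise (same sigma on both channels)."""

    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _add_noise(series: HyperpolarizedSeries, noise: NoiseModel) -> HyperpolarizedSeries:
    if noise.sigma == 0.0:
        return series
    rng = noise.rng()
    return HyperpolarizedSeries(
        times=series.times,
        precursor=series.precursor + rng.normal(0.0, noise.sigma, series.times.size),
        product=series.product + rng.normal(0.0, noise.sigma, series.times.size),
    )


def generate_arrest_nonselective(
    params: KineticParams,
    scheme: AcquisitionScheme,
    geometry: ExperimentGeometry | None = None,
    noise: NoiseModel | None = None,
):
    """Design 1: constant precursor concentration, small-angle readout of both pools."""
    geometry = geometry or ExperimentGeometry()
    noise = noise or NoiseModel()
    clean = simulate_two_pool(params, scheme)
    series = _add_noise(clean, noise)
    truth = {
        "design": "arrest_nonselective",
        "k1st": params.k1st,
        "t1_precursor": params.t1_precursor,
        "t1_product": params.t1_product,
        "m0": params.m0,
        "tr": scheme.tr,
        "nutation_precursor": scheme.nutation_precursor,
        "nutation_product": scheme.nutation_product,
        "pyr_conc_mm": geometry.pyr_conc,
        "v_medium_ml": geometry.v_medium,
        "sigma": noise.sigma,
        "seed": noise.seed,
    }
    return series, truth


def generate_arrest_selective(
    params: KineticParams,
    scheme: AcquisitionScheme,
    geometry: ExperimentGeometry | None = None,
    noise: NoiseModel | None = None,
    n_quench: int = 4,
    quench_tr: float = 2.0,
    injection_delay: float = 5.0,
):
    """Design 2: bolus + arrest, 90-degree product readout after a quench block.

    The product accumulated during ``injection_delay`` (between arrival of
    the hyperpolarized medium and the first pulse) sits in the product pool
    at the first excitation; the quench block resets it so the analysis
    train reads only freshly produced material.  Returns the series (quench
    and analysis samples) and a truth record carrying ``analysis_mask``.
    """
    geometry = geometry or ExperimentGeometry()
    noise = noise or NoiseModel()
    if n_quench < 0 or quench_tr <= 0 or injection_delay < 0:
        raise InvalidParameterError("invalid quench/delay parameters")

    a_p = 1.0 / params.t1_precursor
    a_l = 1.0 / params.t1_product
    p_first = params.m0 * np.exp(-a_p * injection_delay)
    l_first = params.k1st * params.m0 * _transfer_kernel(injection_delay, a_p, a_l)

    quench_times = np.arange(n_quench) * quench_tr
    start = quench_times[-1] + scheme.tr if n_quench > 0 else 0.0
    analysis_times = start + np.arange(scheme.n_samples) * scheme.tr
    pulse_times = np.concatenate([quench_times, analysis_times])

    P, L = propagate_pulse_train(
        params,
        pulse_times,
        scheme.nutation_precursor,
        scheme.nutation_product,
        p0=p_first,
        l0=l_first,
    )
    sp = np.sin(np.deg2rad(scheme.nutation_precursor)) * P
    sl = np.sin(np.deg2rad(scheme.nutation_product)) * L
    series = _add_noise(
        HyperpolarizedSeries(times=pulse_times, precursor=sp, product=sl), noise
    )
    analysis_mask = np.zeros(pulse_times.size, dtype=bool)
    analysis_mask[n_quench:] = True
    truth = {
        "design": "arrest_selective",
        "k1st": params.k1st,
        "t1_precursor": params.t1_precursor,
        "t1_product": params.t1_product,
        "m0": params.m0,
        "tr": scheme.tr,
        "nutation_precursor": scheme.nutation_precursor,
        "nutation_product": scheme.nutation_product,
        "n_quench": n_quench,
        "quench_tr": quench_tr,
        "injection_delay": injection_delay,
        "analysis_mask": analysis_mask,
        "pyr_conc_mm": geometry.pyr_conc,
        "v_medium_ml": geometry.v_medium,
        "sigma": noise.sigma,
        "seed": noise.seed,
    }
    return series, truth


def _inflow(t: np.ndarray, flow: FlowProfile) -> np.ndarray:
    """Normalized inflow concentration (steady level = 1)."""
    u = np.zeros_like(t)
    t0 = flow.arrival_time
    t1 = t0 + flow.buildup_duration
    t2 = t1 + flow.steady_duration
    if flow.buildup_duration > 0:
        ramp = (t - t0) / flow.buildup_duration
        u = np.where((t >= t0) & (t < t1), np.clip(ramp, 0.0, 1.0), u)
    u = np.where((t >= t1) & (t < t2), 1.0, u)
    return u


def generate_continuous_flow(
    params: KineticParams,
    scheme: AcquisitionScheme,
    geometry: ExperimentGeometry | None = None,
    flow: FlowProfile | None = None,
    noise: NoiseModel | None = None,
    spike_amplitude: float = 0.0,
    spike_width: float = 5.0,
    dt: float = 0.05,
):
    """Design 3: continuous infusion with build-up / steady state / wash-out.

    The probe-visible precursor concentration c(t) follows a single
    well-mixed compartment driven by the inflow profile; the precursor
    magnetization is c(t) scaled by global T1 decay and the per-excitation
    cos losses, and the product is integrated from the instantaneous
    precursor over each TR (90-degree readout resets it every pulse).

    ``spike_amplitude`` adds an optional Gaussian bump to the inflow at the
    end of the steady phase, emulating the arrival of less-depolarized
    material from the perfusion line between plateau and wash-out.
    """
    geometry = geometry or ExperimentGeometry()
    flow = flow or FlowProfile()
    noise = noise or NoiseModel()

    pulse_times = scheme.times
    t_fine = np.arange(0.0, pulse_times[-1] + dt, dt)
    u = _inflow(t_fine, flow)
    if spike_amplitude > 0.0:
        spike_t = flow.arrival_time + flow.buildup_duration + flow.steady_duration
        u = u + spike_amplitude * np.exp(-0.5 * ((t_fine - spike_t) / spike_width) ** 2)

    # exact exponential stepping of dc/dt = washout_rate * (u - c)
    c = np.empty_like(t_fine)
    c[0] = u[0]
    decay = np.exp(-flow.washout_rate * dt)
    for i in range(t_fine.size - 1):
        c[i + 1] = u[i] + (c[i] - u[i]) * decay

    a_p = 1.0 / params.t1_precursor
    a_l = 1.0 / params.t1_product
    th_p = np.deg2rad(scheme.nutation_precursor)
    th_l = np.deg2rad(scheme.nutation_product)
    # pulses experienced before each fine-grid time point
    n_pulses = np.searchsorted(pulse_times, t_fine, side="right")
    p_fine = params.m0 * c * np.exp(-a_p * t_fine) * np.cos(th_p) ** n_pulses

    pulse_idx = np.rint(pulse_times / dt).astype(int)
    s_pyr = np.empty(pulse_times.size)
    s_lac = np.empty(pulse_times.size)
    for n, (t_n, j) in enumerate(zip(pulse_times, pulse_idx)):
        # pre-pulse precursor: n pulses have happened strictly before t_n
        s_pyr[n] = np.sin(th_p) * params.m0 * c[j] * np.exp(-a_p * t_n) * np.cos(th_p) ** n
        if n == 0:
            s_lac[n] = 0.0
            continue
        j0 = pulse_idx[n - 1]
        seg_t = t_fine[j0 : j + 1]
        seg_p = p_fine[j0 : j + 1]
        integrand = seg_p * np.exp(-a_l * (t_n - seg_t))
        s_lac[n] = np.sin(th_l) * params.k1st * np.trapezoid(integrand, seg_t)

    series = _add_noise(
        HyperpolarizedSeries(times=pulse_times, precursor=s_pyr, product=s_lac), noise
    )

    # truth-side observables for recovery tests
    plateau = c >= 0.9 * c.max()
    steady_onset = float(t_fine[np.argmax(plateau)]) if plateau.any() else np.nan
    in_steady = (pulse_times >= steady_onset) & (
        pulse_times <= flow.arrival_time + flow.buildup_duration + flow.steady_duration
    )
    if np.any(in_steady & (s_pyr > 0)):
        sel = in_steady & (s_pyr > 0)
        pyr_nmole = geometry.pyr_conc * geometry.v_medium * 1e3
        # noiseless per-point rate arithmetic at the plateau, using the true
        # excitation compensation sin(theta_p)/sin(theta_l); divide by the
        # tissue ATP amount (nmole) for a per-ATP rate
        ratios = s_lac[sel] / s_pyr[sel] * (np.sin(th_p) / np.sin(th_l))
        expected_rate = float(
            np.mean(ratios[1:] if ratios.size > 1 else ratios)
            * pyr_nmole / scheme.tr * 60.0
        )
    else:
        expected_rate = np.nan

    truth = {
        "design": "continuous_flow",
        "k1st": params.k1st,
        "t1_precursor": params.t1_precursor,
        "t1_product": params.t1_product,
        "m0": params.m0,
        "tr": scheme.tr,
        "nutation_precursor": scheme.nutation_precursor,
        "nutation_product": scheme.nutation_product,
        "arrival_time": flow.arrival_time,
        "buildup_duration": flow.buildup_duration,
        "steady_duration": flow.steady_duration,
        "washout_rate": flow.washout_rate,
        "steady_onset": steady_onset,
        "steady_amplitude": float(np.sin(th_p) * params.m0 * c.max()),
        "expected_rate_nmole_per_min": expected_rate,
        "pyr_conc_mm": geometry.pyr_conc,
        "v_medium_ml": geometry.v_medium,
        "sigma": noise.sigma,
        "seed": noise.seed,
    }
    return series, truth


_DEFAULT_SAMPLE_META = dict(flip_angle=50.0, tr=1.1, n_scans=3600, t1=1.0)
_DEFAULT_STANDARD_META = dict(flip_angle=90.0, tr=30.0, n_scans=16, t1=7.0)


def generate_p31_pair(
    true_amount: float,
    sample_meta: dict | None = None,
    standard_meta: dict | None = None,
    standard_amount: float = 1110.0,
    noise: NoiseModel | None = None,
    spectrometer_scale: float = 1.0,
):
    """Synthetic 31P sample/standard measurement pair with known ATP amount.

    Integrals are ``amount * n_scans * saturation_factor * scale`` with
    optional relative Gaussian noise (``noise.sigma`` interpreted as a
    relative sigma); the same arbitrary spectrometer scale multiplies both
    measurements, as for acquisitions on the same day.
    """
    if not (true_amount > 0):
        raise InvalidParameterError("true_amount must be positive")
    noise = noise or NoiseModel()
    smeta = dict(_DEFAULT_SAMPLE_META, **(sample_meta or {}))
    tmeta = dict(_DEFAULT_STANDARD_META, **(standard_meta or {}))
    rng = noise.rng()

    def integral(amount, meta):
        f = saturation_factor(meta["flip_angle"], meta["tr"], meta["t1"])
        value = amount * meta["n_scans"] * f * spectrometer_scale
        if noise.sigma > 0:
            value *= 1.0 + rng.normal(0.0, noise.sigma)
        return value

    sample = P31Measurement(integral=integral(true_amount, smeta), **smeta)
    standard = P31Measurement(integral=integral(standard_amount, tmeta), **tmeta)
    truth = {
        "true_amount_nmole": true_amount,
        "standard_amount_nmole": standard_amount,
        "sigma": noise.sigma,
        "seed": noise.seed,
    }
    return sample, standard, truth
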