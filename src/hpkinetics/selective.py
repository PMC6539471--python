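"""Selective-excitation rate analysis.

With a product-selective ~90-degree readout, every excitation measures only
the [1-13C]lactate produced since the previous pulse, so enzymatic rates
follow from per-excitation arithmetic instead of a kinetic model fit.  The
chain is:

1. estimate the precursor T1 from an arrested-perfusion decay
   (``fit_t1_eq1``: M(t) = M0 * exp(-t/T1) * cos(theta)^(t/TR));
2. divide a continuously measured precursor series by its decay envelope
   (``correct_precursor_eq2``), so constant concentration maps to a
   constant corrected signal;
3. select the contiguous window of points within 10% of the first maximum
   of the corrected signal (``select_constant_window``) — the
   constant-concentration phase;
4. convert each windowed lactate/pyruvate signal pair into a production
   rate per nmole of tissue ATP (``rate_eq3``), and aggregate the plateau
   (``aggregate_rates``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateModelError,
    FitError,
    InvalidParameterError,
    NoPlateauError,
)
from .kinetics import AcquisitionScheme, _r_squared, _TIGHT

__all__ = [
    "T1Estimate",
    "CorrectedSeries",
    "RateResult",
    "T1DecayModel",
    "fit_t1_eq1",
    "correct_precursor_eq2",
    "select_constant_window",
    "rate_eq3",
    "aggregate_rates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class T1Estimate:
    """Fitted precursor decay: T1 (s), signal amplitude M0, and R2."""

    t1: float
    m0: float
    r2: float


@dataclass
class CorrectedSeries:
    """Decay-compensated precursor intensities.

    ``unreliable`` flags points whose correction factor exceeded the
    amplification ceiling (t >> T1); ``window`` holds the selected
    constant-concentration sample indices once computed.
    """

    times: np.ndarray
    corrected: np.ndarray
    unreliable: np.ndarray
    window: np.ndarray | None = None


@dataclass(frozen=True)
class RateResult:
    """Per-excitation production rates, nmole/min per nmole ATP.

    ``mean_rate``/``sd_rate`` are computed over ``stabilized_indices`` only
    (the upper plateau of the per-point rates).
    """

    per_point_rates: np.ndarray
    mean_rate: float
    sd_rate: float
    stabilized_indices: np.ndarray
    units: str = field(default="nmole/min per nmole ATP")


class T1DecayModel(BaseEstimator):
    """Estimator for the pulsed hyperpolarized decay law.

    ``fit(X, y)`` with ``X`` the times (s, t = 0 at the first excitation)
    and ``y`` the precursor intensities fits

        M(t) = M0 * exp(-t / T1) * cos(theta)^(t / TR)

    with theta (the precursor's effective nutation under the selective
    pulse) and TR known.  Internally the decay is parametrized by the rate
    1/T1 with a lower bound of zero, so an RF-loss-only decay is recovered
    as a very large T1 instead of a failed fit.

    Fitted attributes: ``t1_``, ``m0_``, ``r2_``.
    """

    def __init__(self, tr: float, nutation: float, m0_init: float | None = None,
                 t1_init: float = 50.0, max_nfev: int = 10000):
        self.tr = tr
        self.nutation = nutation
        self.m0_init = m0_init
        self.t1_init = t1_init
        self.max_nfev = max_nfev

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.size != y.size:
            raise InvalidParameterError("times and intensities differ in length")
        if t.size < 5:
            raise InvalidParameterError("need at least 5 samples to fit the decay")
        if self.nutation >= 90.0 and t.size > 1:
            raise DegenerateModelError(
                "a 90-degree readout nulls the signal after one pulse; the decay is unidentifiable"
            )
        log_cos = np.log(np.cos(np.deg2rad(self.nutation)))
        rf = np.exp(log_cos * t / self.tr)  # cos(theta)^(t/TR)
        m0_0 = self.m0_init if self.m0_init is not None else max(float(y.max()), 1e-12)
        a0 = 1.0 / self.t1_init

        def resid(x):
            return x[0] * np.exp(-x[1] * t) * rf - y

        res = least_squares(
            resid,
            x0=[m0_0, a0],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            x_scale=[m0_0, a0],
            max_nfev=self.max_nfev,
            **_TIGHT,
        )
        if not res.success:
            raise FitError("T1 decay fit did not converge", last_params=res.x)
        m0, a = res.x
        self.m0_ = float(m0)
        self.t1_ = float(1.0 / max(a, 1e-15))
        self.r2_ = _r_squared(y, m0 * np.exp(-a * t) * rf)
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        log_cos = np.log(np.cos(np.deg2rad(self.nutation)))
        return self.m0_ * np.exp(-t / self.t1_) * np.exp(log_cos * t / self.tr)


def fit_t1_eq1(times, intensities, scheme: AcquisitionScheme) -> T1Estimate:
    """Fit the pulsed decay law to an arrested-perfusion precursor series."""
    est = T1DecayModel(tr=scheme.tr, nutation=scheme.nutation_precursor)
    est.fit(times, intensities)
    return T1Estimate(t1=est.t1_, m0=est.m0_, r2=est.r2_)


def correct_precursor_eq2(
    times,
    intensities,
    t1: float,
    scheme: AcquisitionScheme | None = None,
    include_rf: bool = True,
    max_amplification: float = 20.0,
) -> CorrectedSeries:
    """Divide the precursor signal by its decay envelope.

    The envelope is exp(-t/T1), and — when ``include_rf`` and a scheme are
    given — additionally cos(theta_p)^(t/TR) for the per-excitation losses
    of the precursor under the selective pulse.  A series at truly constant
    concentration maps to a constant within noise.  Points whose correction
    factor exceeds ``max_amplification`` (t >> T1, where noise is blown up)
    are flagged unreliable but still returned.
    """
    t = np.asarray(times, dtype=float).reshape(-1)
    y = np.asarray(intensities, dtype=float).reshape(-1)
    if t.size != y.size:
        raise InvalidParameterError("times and intensities differ in length")
    if not (t1 > 0):
        raise InvalidParameterError("T1 must be positive")
    envelope = np.exp(-t / t1)
    if include_rf and scheme is not None:
        log_cos = np.log(np.cos(np.deg2rad(scheme.nutation_precursor)))
        envelope = envelope * np.exp(log_cos * t / scheme.tr)
    amplification = 1.0 / envelope
    unreliable = amplification > max_amplification
    if np.any(unreliable):
        logger.info(
            "%d corrected points exceed the %gx amplification ceiling",
            int(unreliable.sum()), max_amplification,
        )
    return CorrectedSeries(times=t, corrected=y / envelope, unreliable=unreliable)


def select_constant_window(corrected, tol: float = 0.10, guard: int = 2) -> np.ndarray:
    """Indices of the constant-concentration window.

    Finds the first maximum of the corrected series — the first running
    maximum not exceeded within the next ``guard`` samples (the guard
    protects against single-point noise spikes) — then keeps the contiguous
    run of points around that maximum whose relative deviation from it is
    at most ``tol`` (10% by default), stopping at the first violation in
    each direction.  A bolus-and-arrest series starts at its maximum, so
    its window starts at the first point; a continuous-flow series reaches
    its maximum late in the concentration plateau, and the backward
    extension picks up the rise edge of the plateau.
    """
    if isinstance(corrected, CorrectedSeries):
        v = corrected.corrected
    else:
        v = np.asarray(corrected, dtype=float).reshape(-1)
    n = v.size
    if n < 3:
        raise NoPlateauError("need at least 3 corrected points")
    run_max = -np.inf
    m = None
    for i in range(n):
        if v[i] >= run_max:
            run_max = v[i]
            if np.all(v[i + 1 : i + 1 + guard] <= v[i]):
                m = i
                break
    if m is None or v[m] <= 0:
        raise NoPlateauError("no positive first maximum found")
    lo = m
    while lo > 0 and abs(v[lo - 1] - v[m]) / v[m] <= tol:
        lo -= 1
    hi = m
    while hi < n - 1 and abs(v[hi + 1] - v[m]) / v[m] <= tol:
        hi += 1
    window = np.arange(lo, hi + 1)
    if isinstance(corrected, CorrectedSeries):
        corrected.window = window
    return window


def rate_eq3(
    s_lac,
    s_pyr,
    pyr_conc: float,
    rho: float,
    tr: float,
    v_medium: float,
    atp: float,
    noise_floor: float = 0.0,
):
    """Per-excitation lactate production rate, nmole/min per nmole ATP.

    v = (S_lac / S_pyr) * rho * ([Pyr] * V_medium) / (TR * ATP) * 60

    with [Pyr] in mM, V_medium in mL (so [Pyr]*V_medium is the
    probe-visible pyruvate amount, converted to nmole), TR in s and the
    tissue ATP content in nmole.  ``rho`` is the excitation-compensation
    factor — the precursor's response to the selective pulse relative to
    the product's — which converts the observed signal ratio into a
    magnetization (concentration) ratio; it is 1 when both species are
    excited equally.

    Accepts scalars or arrays for ``s_lac``/``s_pyr``.  Points whose
    precursor signal is at or below ``noise_floor`` are returned as NaN and
    logged.
    """
    for name, val in (("pyr_conc", pyr_conc), ("rho", rho), ("tr", tr),
                      ("v_medium", v_medium), ("atp", atp)):
        if not (val > 0):
            raise InvalidParameterError(f"{name} must be positive")
    sl = np.asarray(s_lac, dtype=float)
    sp = np.asarray(s_pyr, dtype=float)
    if np.any(sl < 0):
        raise InvalidParameterError("product signals must be non-negative")
    pyr_nmole = pyr_conc * v_medium * 1e3  # mM * mL = umole -> nmole
    bad = sp <= noise_floor
    if np.any(bad):
        logger.info("excluding %d points with precursor signal at/below the noise floor",
                    int(np.sum(bad)))
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(bad, np.nan, (sl / sp) * rho * pyr_nmole / (tr * atp) * 60.0)
    if v.ndim == 0:
        return float(v)
    return v


def aggregate_rates(per_point_rates, plateau_tol: float = 0.15) -> RateResult:
    """Mean and SD of the stabilized (upper-plateau) per-point rates.

    The early windowed excitations can read lactate that accumulated before
    the first selective pulse train settled, and the last windowed point can
    be inflated by the onset of wash-out, so the per-point rates rise, hold,
    and may spike at the end.  The plateau is the trailing contiguous run of
    points within ``plateau_tol`` (two-sided, relative) of the median
    per-point rate — the median is a robust estimate of the stabilized
    level.  NaN points (excluded by the noise floor) never enter the
    plateau.
    """
    r = np.asarray(per_point_rates, dtype=float).reshape(-1)
    finite = np.isfinite(r)
    if not np.any(finite):
        raise NoPlateauError("no finite per-point rates to aggregate")
    level = np.median(r[finite])
    ok = finite & (np.abs(r - level) <= plateau_tol * np.abs(level))
    # trailing contiguous run of qualifying points
    end = r.size
    start = end
    for i in range(end - 1, -1, -1):
        if ok[i]:
            start = i
        else:
            break
    if start == end:  # last point disqualified: fall back to the last run anywhere
        idx_ok = np.flatnonzero(ok)
        last = idx_ok[-1]
        start = last
        while start > 0 and ok[start - 1]:
            start -= 1
        end = last + 1
    stabilized = np.arange(start, end)
    vals = r[stabilized]
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RateResult(
        per_point_rates=r,
        mean_rate=mean,
        sd_rate=sd,
        stabilized_indices=stabilized,
    )
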