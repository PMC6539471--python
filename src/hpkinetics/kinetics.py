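"""Two-pool kinetic model for hyperpolarized precursor/product time series.

The model describes non-selective acquisition of hyperpolarized
[1-13C]pyruvate and the [1-13C]lactate produced from it in perfused tissue
slices:

* the precursor's longitudinal magnetization decays exponentially with its
  T1 and loses a factor cos(theta) at each excitation; its consumption by
  metabolism is neglected (pyruvate is in large excess);
* the product pool is fed at first-order rate ``k_1st`` from the
  instantaneous precursor magnetization, decays with its own T1, and loses
  cos(theta) per excitation;
* each excitation reads a signal proportional to sin(theta) times the
  pre-pulse longitudinal magnetization.

Between excitations both pools evolve analytically (linear ODEs), so the
discrete-sample simulator is exact for the stated model.  Fitting is
sequential by default: the precursor channel determines M0 and the
precursor T1 (it does not depend on the rate constant), after which the
product channel determines ``k_1st`` and the product T1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from .exceptions import FitError, InvalidParameterError

__all__ = [
    "AcquisitionScheme",
    "KineticParams",
    "HyperpolarizedSeries",
    "KineticFitResult",
    "propagate_pulse_train",
    "two_pool_longitudinal",
    "simulate_two_pool",
    "TwoPoolKineticModel",
    "fit_two_pool",
    "extrapolate_amount",
]


@dataclass(frozen=True)
class AcquisitionScheme:
    """Excitation scheme of a hyperpolarized acquisition.

    ``nutation_precursor`` / ``nutation_product`` are the effective flip
    angles (degrees) experienced by the two resonances.  Non-selective
    schemes use the same small angle for both (12 degrees at TR = 5 s in
    the arrested-perfusion design); selective schemes read the product at
    90 degrees while barely touching the precursor.
    """

    tr: float
    nutation_precursor: float
    nutation_product: float
    n_samples: int

    def __post_init__(self) -> None:
        if not (self.tr > 0):
            raise InvalidParameterError("TR must be positive")
        for ang in (self.nutation_precursor, self.nutation_product):
            if not (0.0 <= ang <= 90.0):
                raise InvalidParameterError("nutation angles must be in [0, 90] degrees")
        if self.n_samples < 1:
            raise InvalidParameterError("need at least one sample")

    @classmethod
    def nonselective(cls, tr: float = 5.0, nutation: float = 12.0,
                     n_samples: int = 66) -> "AcquisitionScheme":
        return cls(tr=tr, nutation_precursor=nutation,
                   nutation_product=nutation, n_samples=n_samples)

    @classmethod
    def selective(cls, tr: float = 12.0, precursor_nutation: float = 5.0,
                  n_samples: int = 20) -> "AcquisitionScheme":
        return cls(tr=tr, nutation_precursor=precursor_nutation,
                   nutation_product=90.0, n_samples=n_samples)

    @property
    def times(self) -> np.ndarray:
        """Sample times, t = n * TR with t = 0 at the first excitation."""
        return np.arange(self.n_samples) * self.tr


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the two-pool model.

    k1st : first-order production rate constant, 1/s
    t1_precursor, t1_product : longitudinal relaxation times, s
    m0 : initial precursor magnetization, arbitrary units
    """

    k1st: float
    t1_precursor: float
    t1_product: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k1st", "t1_precursor", "t1_product", "m0"):
            if not (getattr(self, name) >= 0):
                raise InvalidParameterError(f"{name} must be non-negative")
        for name in ("t1_precursor", "t1_product", "m0"):
            if getattr(self, name) == 0:
                raise InvalidParameterError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class HyperpolarizedSeries:
    """Time-stamped precursor/product intensity vectors (arbitrary units).

    Intensities may be negative (additive noise is not clipped).
    """

    times: np.ndarray
    precursor: np.ndarray
    product: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        p = np.asarray(self.precursor, dtype=float)
        l = np.asarray(self.product, dtype=float)
        if not (t.ndim == p.ndim == l.ndim == 1 and t.size == p.size == l.size):
            raise InvalidParameterError("times/precursor/product must be equal-length 1-D")
        if not np.all(np.isfinite(t)):
            raise InvalidParameterError("times must be finite")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "precursor", p)
        object.__setattr__(self, "product", l)

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class KineticFitResult:
    """Outcome of a two-pool fit: parameters, per-channel R2, residuals."""

    params: KineticParams
    r2_precursor: float
    r2_product: float
    residuals: dict


def _transfer_kernel(dt: float, a_p: float, a_l: float) -> float:
    """integral_0^dt exp(-a_p * tau) * exp(-a_l * (dt - tau)) d tau.

    Switches to the confluent limit when the two rates are numerically
    indistinguishable over the interval.
    """
    if abs(a_l - a_p) * dt < 1e-9:
        return dt * np.exp(-0.5 * (a_p + a_l) * dt)
    return (np.exp(-a_p * dt) - np.exp(-a_l * dt)) / (a_l - a_p)


def propagate_pulse_train(
    params: KineticParams,
    pulse_times,
    nutation_precursor: float,
    nutation_product: float,
    p0: float | None = None,
    l0: float = 0.0,
):
    """Longitudinal magnetization of both pools just before each pulse.

    Works for arbitrary (strictly increasing) pulse times, so the same
    propagator serves the uniform non-selective train and the
    quench-then-analyze selective train (where a 90-degree product readout
    resets the product pool via cos(90) = 0).

    Returns ``(P_pre, L_pre)`` arrays.
    """
    t = np.asarray(pulse_times, dtype=float)
    a_p = 1.0 / params.t1_precursor
    a_l = 1.0 / params.t1_product
    cp = np.cos(np.deg2rad(nutation_precursor))
    cl = np.cos(np.deg2rad(nutation_product))
    n = t.size
    P = np.empty(n)
    L = np.empty(n)
    P[0] = params.m0 if p0 is None else p0
    L[0] = l0
    for i in range(n - 1):
        dt = t[i + 1] - t[i]
        p_post = P[i] * cp
        l_post = L[i] * cl
        P[i + 1] = p_post * np.exp(-a_p * dt)
        L[i + 1] = l_post * np.exp(-a_l * dt) + params.k1st * p_post * _transfer_kernel(
            dt, a_p, a_l
        )
    return P, L


def two_pool_longitudinal(params: KineticParams, scheme: AcquisitionScheme):
    """Pre-pulse longitudinal magnetization on the scheme's uniform grid."""
    return propagate_pulse_train(
        params, scheme.times, scheme.nutation_precursor, scheme.nutation_product
    )


def simulate_two_pool(
    params: KineticParams, scheme: AcquisitionScheme
) -> HyperpolarizedSeries:
    """Noiseless signals of the two-pool model under ``scheme``.

    The signal at sample n is sin(theta) times the pre-pulse longitudinal
    magnetization; the pool then keeps cos(theta) of it.
    """
    P, L = two_pool_longitudinal(params, scheme)
    sp = np.sin(np.deg2rad(scheme.nutation_precursor)) * P
    sl = np.sin(np.deg2rad(scheme.nutation_product)) * L
    return HyperpolarizedSeries(times=scheme.times, precursor=sp, product=sl)


def _r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


_TIGHT = dict(xtol=1e-15, ftol=1e-15, gtol=1e-15)

#: physical cap on relaxation rates (T1 >= 0.01 s) removes the degenerate
#: ridge where a huge rate constant is cancelled by an instantly relaxing
#: product pool.
_A_MAX = 100.0


class TwoPoolKineticModel(BaseEstimator):
    """Least-squares estimator for the two-pool hyperpolarized model.

    scikit-learn style: ``fit(X, y)`` with ``X`` the sample times (shape
    ``(n,)`` or ``(n, 1)``, multiples of TR from the first excitation) and
    ``y`` a two-column array ``[precursor, product]``.

    Parameters
    ----------
    tr, nutation, nutation_product:
        Acquisition scheme.  ``nutation_product=None`` means both channels
        share ``nutation`` (the non-selective case).
    drop_first:
        Exclude sample 0 from the residuals (the injection is typically
        still ongoing during the first spectrum).  The model itself still
        starts at sample 0.
    mode:
        ``"sequential"`` (default; precursor channel first, then product)
        or ``"joint"`` (all four parameters against both channels, each
        channel scaled by its peak).
    k_init, t1_precursor_init, t1_product_init, m0_init:
        Optimizer starting values.  ``m0_init=None`` uses the peak
        precursor signal.

    Fitted attributes: ``k1st_``, ``t1_precursor_``, ``t1_product_``,
    ``m0_``, ``r2_precursor_``, ``r2_product_``, ``residuals_``.
    """

    def __init__(
        self,
        tr: float = 5.0,
        nutation: float = 12.0,
        nutation_product: float | None = None,
        drop_first: bool = True,
        mode: str = "sequential",
        k_init: float = 1e-4,
        t1_precursor_init: float = 55.0,
        t1_product_init: float = 20.0,
        m0_init: float | None = None,
        max_nfev: int = 10000,
    ):
        self.tr = tr
        self.nutation = nutation
        self.nutation_product = nutation_product
        self.drop_first = drop_first
        self.mode = mode
        self.k_init = k_init
        self.t1_precursor_init = t1_precursor_init
        self.t1_product_init = t1_product_init
        self.m0_init = m0_init
        self.max_nfev = max_nfev

    # -- internal model pieces ------------------------------------------------

    def _angles(self):
        th_p = self.nutation
        th_l = self.nutation if self.nutation_product is None else self.nutation_product
        if th_p <= 0:
            raise InvalidParameterError("precursor nutation must be positive to fit")
        return th_p, th_l

    def _grid(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        idx = np.rint(t / self.tr).astype(int)
        if np.max(np.abs(t - idx * self.tr)) > 1e-6 * self.tr:
            raise InvalidParameterError("sample times must be multiples of TR")
        if idx[0] != 0:
            raise InvalidParameterError("series must start at the first excitation (t = 0)")
        return idx

    @staticmethod
    def _precursor_model(t, idx, amp, a_p, cos_p):
        return amp * np.exp(-a_p * t) * cos_p**idx

    @staticmethod
    def _product_chain(n_grid, tr, m0, a_p, cos_p, k, a_l, cos_l):
        """Pre-pulse product magnetization on the full grid 0..n_grid-1."""
        L = np.empty(n_grid)
        L[0] = 0.0
        decay = cos_l * np.exp(-a_l * tr)
        kern = _transfer_kernel(tr, a_p, a_l)
        for i in range(n_grid - 1):
            p_post = m0 * np.exp(-a_p * i * tr) * cos_p ** (i + 1)
            L[i + 1] = L[i] * decay + k * p_post * kern
        return L

    # -- estimator API --------------------------------------------------------

    def fit(self, X, y):
        idx = self._grid(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2 or y.shape[0] != idx.size:
            raise InvalidParameterError("y must be an (n_samples, 2) array")
        th_p, th_l = self._angles()
        sp, sl = np.sin(np.deg2rad(th_p)), np.sin(np.deg2rad(th_l))
        cp, cl = np.cos(np.deg2rad(th_p)), np.cos(np.deg2rad(th_l))

        mask = np.ones(idx.size, dtype=bool)
        if self.drop_first:
            mask[idx == 0] = False
        if np.count_nonzero(mask & (y[:, 0] > 0)) < 6:
            raise InvalidParameterError("need at least 6 samples with positive precursor signal")

        t_fit = idx[mask] * self.tr
        i_fit = idx[mask]
        y_prec = y[mask, 0]
        y_prod = y[mask, 1]
        n_grid = int(idx.max()) + 1

        amp0 = self.m0_init * sp if self.m0_init is not None else max(float(y_prec.max()), 1e-12)
        a_p0 = 1.0 / self.t1_precursor_init
        a_l0 = 1.0 / self.t1_product_init

        if self.mode == "sequential":
            res_p = least_squares(
                lambda x: self._precursor_model(t_fit, i_fit, x[0], x[1], cp) - y_prec,
                x0=[amp0, a_p0],
                bounds=([0.0, 0.0], [np.inf, _A_MAX]),
                x_scale=[amp0, a_p0],
                max_nfev=self.max_nfev,
                **_TIGHT,
            )
            if not res_p.success:
                raise FitError("precursor fit did not converge", last_params=res_p.x)
            amp, a_p = res_p.x
            m0 = amp / sp

            # the product signal is linear in k, so k is profiled out
            # (variable projection) and only the relaxation rate is searched
            def prod_basis(a_l):
                L = self._product_chain(n_grid, self.tr, m0, a_p, cp, 1.0, a_l, cl)
                return sl * L[i_fit]

            def k_opt(a_l):
                b = prod_basis(a_l)
                bb = float(b @ b)
                return max(float(b @ y_prod) / bb, 0.0) if bb > 0 else 0.0

            def prod_resid(x):
                b = prod_basis(x[0])
                return k_opt(x[0]) * b - y_prod

            res_l = least_squares(
                prod_resid,
                x0=[a_l0],
                bounds=([0.0], [_A_MAX]),
                x_scale=[a_l0],
                max_nfev=self.max_nfev,
                **_TIGHT,
            )
            if not res_l.success:
                raise FitError("product fit did not converge", last_params=res_l.x)
            a_l = float(res_l.x[0])
            k = k_opt(a_l)
        elif self.mode == "joint":
            w_p = 1.0 / max(np.max(np.abs(y_prec)), 1e-12)
            w_l = 1.0 / max(np.max(np.abs(y_prod)), 1e-12)

            def joint_resid(x):
                amp, a_p, k, a_l = x
                prec = self._precursor_model(t_fit, i_fit, amp, a_p, cp)
                L = self._product_chain(n_grid, self.tr, amp / sp, a_p, cp, k, a_l, cl)
                return np.concatenate(
                    [(prec - y_prec) * w_p, (sl * L[i_fit] - y_prod) * w_l]
                )

            res = least_squares(
                joint_resid,
                x0=[amp0, a_p0, self.k_init, a_l0],
                bounds=(np.zeros(4), [np.inf, _A_MAX, np.inf, _A_MAX]),
                x_scale=[amp0, a_p0, self.k_init, a_l0],
                max_nfev=self.max_nfev,
                **_TIGHT,
            )
            if not res.success:
                raise FitError("joint fit did not converge", last_params=res.x)
            amp, a_p, k, a_l = res.x
            m0 = amp / sp
        else:
            raise InvalidParameterError(f"unknown fit mode {self.mode!r}")

        self.k1st_ = float(k)
        self.t1_precursor_ = float(1.0 / max(a_p, 1e-15))
        self.t1_product_ = float(1.0 / max(a_l, 1e-15))
        self.m0_ = float(m0)

        prec_hat = self._precursor_model(t_fit, i_fit, m0 * sp, a_p, cp)
        L = self._product_chain(n_grid, self.tr, m0, a_p, cp, k, a_l, cl)
        prod_hat = sl * L[i_fit]
        self.r2_precursor_ = _r_squared(y_prec, prec_hat)
        self.r2_product_ = _r_squared(y_prod, prod_hat)
        self.residuals_ = {
            "precursor": y_prec - prec_hat,
            "product": y_prod - prod_hat,
        }
        return self

    def predict(self, X):
        """Model signals at the requested times (multiples of TR)."""
        idx = self._grid(X)
        th_p, th_l = self._angles()
        sp, sl = np.sin(np.deg2rad(th_p)), np.sin(np.deg2rad(th_l))
        cp, cl = np.cos(np.deg2rad(th_p)), np.cos(np.deg2rad(th_l))
        a_p = 1.0 / self.t1_precursor_
        a_l = 1.0 / self.t1_product_
        n_grid = int(idx.max()) + 1
        t = idx * self.tr
        prec = self._precursor_model(t, idx, self.m0_ * sp, a_p, cp)
        L = self._product_chain(n_grid, self.tr, self.m0_, a_p, cp, self.k1st_, a_l, cl)
        return np.column_stack([prec, sl * L[idx]])


def fit_two_pool(
    series: HyperpolarizedSeries,
    scheme: AcquisitionScheme,
    init: KineticParams | None = None,
    drop_first: bool = True,
    mode: str = "sequential",
) -> KineticFitResult:
    """Fit the two-pool model to a measured series.  Thin estimator wrapper."""
    est = TwoPoolKineticModel(
        tr=scheme.tr,
        nutation=scheme.nutation_precursor,
        nutation_product=scheme.nutation_product,
        drop_first=drop_first,
        mode=mode,
    )
    if init is not None:
        est.set_params(
            k_init=init.k1st,
            t1_precursor_init=init.t1_precursor,
            t1_product_init=init.t1_product,
            m0_init=init.m0,
        )
    est.fit(series.times, np.column_stack([series.precursor, series.product]))
    params = KineticParams(
        k1st=max(est.k1st_, 0.0),
        t1_precursor=est.t1_precursor_,
        t1_product=est.t1_product_,
        m0=est.m0_,
    )
    return KineticFitResult(
        params=params,
        r2_precursor=est.r2_precursor_,
        r2_product=est.r2_product_,
        residuals=est.residuals_,
    )


def extrapolate_amount(k1st: float, pyr_total: float, t: float) -> float:
    """Product amount after time ``t`` from a first-order conversion.

    A_lac = Pyr * (1 - exp(-k1st * t)); monotone in ``t`` and bounded by the
    available precursor amount ``pyr_total`` (any amount unit; the result is
    in the same unit).
    """
    if k1st < 0 or pyr_total < 0 or np.any(np.asarray(t) < 0):
        raise InvalidParameterError("extrapolation arguments must be non-negative")
    return pyr_total * -np.expm1(-k1st * np.asarray(t, dtype=float))
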