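"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's own closed-form propagators:
the Bloch oracle composes scipy rotation objects step by step, the kinetic
oracle integrates the two-pool ODE with ``solve_ivp`` between pulses, and
the saturation oracle iterates the pulse-train recursion to steady state.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.spatial.transform import Rotation

from hpkinetics import AcquisitionScheme, KineticParams

# ground-truth parameters of the worked single-experiment kinetic fit
FIG_PARAMS = KineticParams(k1st=1.55e-4, t1_precursor=64.5, t1_product=20.0, m0=1.0)


@pytest.fixture
def fig_params():
    return FIG_PARAMS


@pytest.fixture
def nonselective_scheme():
    return AcquisitionScheme.nonselective(tr=5.0, nutation=12.0, n_samples=66)


# --------------------------------------------------------------------------
# oracle: fine-step Bloch rotation via scipy Rotation composition
# --------------------------------------------------------------------------

def bloch_rotation_oracle(shape, offset_hz, steps=100_000):
    """Transverse response by composing scipy rotation objects."""
    omega1 = shape.envelope(steps)
    dt = shape.duration / steps
    dw = 2.0 * np.pi * offset_hz
    m = np.array([0.0, 0.0, 1.0])
    rotvecs = np.column_stack(
        [omega1 * dt, np.zeros_like(omega1), np.full_like(omega1, dw * dt)]
    )
    # rotation generated by the constant effective field over each step
    for rv in rotvecs:
        m = Rotation.from_rotvec(rv).apply(m)
    return float(np.hypot(m[0], m[1]))


def envelope_fourier_profile(shape, offsets_hz, steps=20_000):
    """Small-tip-angle profile: |FT of the envelope| normalized on-resonance."""
    omega1 = shape.envelope(steps)
    dt = shape.duration / steps
    t = (np.arange(steps) + 0.5) * dt
    offs = np.atleast_1d(offsets_hz)
    ft = np.array(
        [np.abs(np.sum(omega1 * np.exp(-2j * np.pi * f * t)) * dt) for f in offs]
    )
    return ft


# --------------------------------------------------------------------------
# oracle: two-pool ODE integration between pulses
# --------------------------------------------------------------------------

def two_pool_ode_oracle(params, scheme, rtol=1e-11, atol=1e-14):
    """Pre-pulse signals by solve_ivp integration with discrete RF losses."""
    th_p = np.deg2rad(scheme.nutation_precursor)
    th_l = np.deg2rad(scheme.nutation_product)
    a_p, a_l = 1.0 / params.t1_precursor, 1.0 / params.t1_product

    def rhs(_t, y):
        p, l = y
        return [-a_p * p, params.k1st * p - a_l * l]

    p, l = params.m0, 0.0
    sig_p, sig_l = [], []
    for _ in range(scheme.n_samples):
        sig_p.append(np.sin(th_p) * p)
        sig_l.append(np.sin(th_l) * l)
        p *= np.cos(th_p)
        l *= np.cos(th_l)
        sol = solve_ivp(rhs, (0.0, scheme.tr), [p, l], rtol=rtol, atol=atol,
                        method="DOP853")
        p, l = sol.y[:, -1]
    return np.asarray(sig_p), np.asarray(sig_l)


# --------------------------------------------------------------------------
# oracle: steady-state saturation by pulse-train recursion
# --------------------------------------------------------------------------

def saturation_recursion_oracle(flip_angle, tr, t1, n_pulses=10_000):
    """Signal per scan after a long pulse train, relative to relaxed 90 deg."""
    th = np.deg2rad(flip_angle)
    e = np.exp(-tr / t1)
    mz = 1.0
    for _ in range(n_pulses):
        mz = 1.0 - (1.0 - mz * np.cos(th)) * e
    return float(np.sin(th) * mz)
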