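"""Tissue ATP quantification from thermal-equilibrium 31P spectra.

The gamma-ATP integral of the tissue is referenced to an external ATP
standard acquired on the same day.  Because sample and standard are
measured with different flip angles, repetition times and scan counts, the
per-scan integrals are first divided by the steady-state saturation factor
of each acquisition before taking their ratio.  The resulting ATP amount
(nmole in the probe-visible volume) normalizes the hyperpolarized
production rates to viable tissue, and a literature ATP-per-tissue-mass
factor converts the per-ATP rates to per-gram rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "P31Measurement",
    "ATPQuantification",
    "saturation_factor",
    "quantify_atp",
    "standard_amount",
    "per_mass_rate",
    "signal_equivalence",
]

#: literature conversion factor, umole ATP per gram of tissue.
ATP_PER_GRAM_DEFAULT = 0.86


@dataclass(frozen=True)
class P31Measurement:
    """A 31P integral with the acquisition metadata needed to correct it.

    ``t1`` is the longitudinal relaxation time of the observed species
    under the field used.  It has no default: quantification refuses to
    run without it rather than silently assuming a value.
    """

    integral: float
    flip_angle: float
    tr: float
    n_scans: int
    t1: float | None = None

    def __post_init__(self) -> None:
        if not (self.integral > 0):
            raise InvalidParameterError("integral must be positive")
        if not (0.0 < self.flip_angle <= 90.0):
            raise InvalidParameterError("flip angle must be in (0, 90] degrees")
        if not (self.tr > 0):
            raise InvalidParameterError("TR must be positive")
        if self.n_scans < 1:
            raise InvalidParameterError("need at least one scan")
        if self.t1 is not None and not (self.t1 > 0):
            raise InvalidParameterError("T1 must be positive when given")


@dataclass(frozen=True)
class ATPQuantification:
    """ATP amount (nmole) in the probe-visible volume."""

    atp_amount: float
    standard_conc: float | None = None  # mM
    standard_volume: float | None = None  # mL


def saturation_factor(flip_angle: float, tr: float, t1: float) -> float:
    """Steady-state signal per scan relative to a fully relaxed 90° scan.

    f = sin(theta) * (1 - E) / (1 - E cos(theta)),  E = exp(-TR/T1).
    """
    if not (flip_angle > 0 and tr > 0 and t1 > 0):
        raise InvalidParameterError("saturation_factor needs positive arguments")
    th = np.deg2rad(flip_angle)
    e = np.exp(-tr / t1)
    return float(np.sin(th) * (1.0 - e) / (1.0 - e * np.cos(th)))


def quantify_atp(
    sample: P31Measurement,
    standard: P31Measurement,
    standard_amount: float,
) -> ATPQuantification:
    """ATP amount of the sample, referenced to an external standard.

    Both integrals are reduced to fully-relaxed-equivalent per-scan
    integrals (divide by scan count and saturation factor); the sample
    amount is the standard amount scaled by their ratio.

    Raises if either measurement lacks its T1 — the saturation correction
    cannot be applied without it.
    """
    for name, m in (("sample", sample), ("standard", standard)):
        if m.t1 is None:
            raise InvalidParameterError(
                f"{name} measurement lacks a T1; the saturation correction requires one"
            )
    if not (standard_amount > 0):
        raise InvalidParameterError("standard amount must be positive")
    per_scan_sample = sample.integral / sample.n_scans / saturation_factor(
        sample.flip_angle, sample.tr, sample.t1
    )
    per_scan_standard = standard.integral / standard.n_scans / saturation_factor(
        standard.flip_angle, standard.tr, standard.t1
    )
    return ATPQuantification(
        atp_amount=float(standard_amount * per_scan_sample / per_scan_standard)
    )


def standard_amount(conc_mm: float, volume_ml: float) -> float:
    """nmole of standard from its concentration (mM) and probe-visible volume (mL)."""
    if not (conc_mm > 0 and volume_ml > 0):
        raise InvalidParameterError("standard concentration and volume must be positive")
    return conc_mm * volume_ml * 1e3


def per_mass_rate(per_atp_rate: float, atp_per_gram: float = ATP_PER_GRAM_DEFAULT) -> float:
    """Convert a per-ATP rate to a per-tissue-mass rate.

    nmole/min per nmole ATP  x  umole ATP per g  =  umole/g/min.
    """
    if per_atp_rate < 0 or atp_per_gram < 0:
        raise InvalidParameterError("rates and conversion factors must be non-negative")
    return float(per_atp_rate * atp_per_gram)


def signal_equivalence(conc_mm: float, enhancement: float = 1e4) -> float:
    """Molar-equivalent signal of a hyperpolarized concentration.

    A dissolution-DNP enhancement of ~10,000-fold makes a millimolar pool
    signal like a molar one: conc (mM) x enhancement / 1000 -> M.
    """
    if conc_mm < 0 or enhancement < 0:
        raise InvalidParameterError("concentration and enhancement must be non-negative")
    return float(conc_mm * enhancement / 1e3)
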