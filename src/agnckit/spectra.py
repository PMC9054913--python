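"""Steady-state spectral utilities: maxima, Stokes shift, quantum yield."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tres import NM_CM, SpectrumRecord, interpolate_spectrum

__all__ = [
    "SteadyStateRecord",
    "stokes_shift",
    "find_emission_max",
    "quantum_yield_relative",
]

logger = logging.getLogger(__name__)


@dataclass
class SteadyStateRecord:
    """Absorption/emission pair for one sample.

    ``absorbance_at_excitation`` should be in the linear regime (< 0.1) for
    relative quantum-yield work.
    """

    absorption: SpectrumRecord
    emission: SpectrumRecord
    excitation_wavelength: float  # nm
    absorbance_at_excitation: float
    refractive_index: float = 1.333  # water default
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.absorbance_at_excitation < 0:
            raise ValueError("absorbance must be non-negative")
        if self.absorption.axis.size == 0 or self.emission.axis.size == 0:
            raise ValueError("spectra must be non-empty")


def stokes_shift(lambda_abs_max: float, lambda_em_max: float,
                 rounded: bool = True) -> float:
    """Stokes shift in cm^-1 between absorption and emission maxima.

    ``10^7/lambda_abs - 10^7/lambda_em`` for wavelengths in nm, rounded to
    integer cm^-1 for reporting (pass ``rounded=False`` for the raw value).
    Antisymmetric under swapping the two wavelengths.
    """
    if lambda_abs_max <= 0 or lambda_em_max <= 0:
        raise ValueError("wavelengths must be positive")
    shift = NM_CM / lambda_abs_max - NM_CM / lambda_em_max
    return float(round(shift)) if rounded else float(shift)


def find_emission_max(spectrum: SpectrumRecord):
    """Emission maximum in nm via dense spline interpolation.

    Monotone spectra yield a boundary maximum with a logged warning; exact
    ties report the leftmost position with ``ambiguous_max`` set. Returns an
    :class:`~agnckit.tres.InterpolatedSpectrum`; its ``max_position_nm`` is
    the reported maximum.
    """
    interp = interpolate_spectrum(spectrum)
    dense = interp.spectrum
    imax = int(np.argmax(dense.intensity))
    if imax in (0, dense.axis.size - 1):
        logger.warning("find_emission_max: maximum at the spectrum boundary "
                       "(%g); band may be truncated", interp.max_position_nm)
    if interp.ambiguous_max:
        logger.warning("find_emission_max: tied maxima; reporting leftmost")
    return interp


def quantum_yield_relative(sample: SteadyStateRecord, reference: SteadyStateRecord,
                           q_ref: float) -> float:
    """Relative fluorescence quantum yield against a reference dye.

    Standard single-point method:
    ``Q = q_ref (F_s/F_r) (A_r/A_s) (n_s^2/n_r^2)`` with F the integrated
    corrected emission, A the absorbance at the excitation wavelength and n
    the solvent refractive indices. Absorbances above 0.1 trigger an
    inner-filter warning.
    """
    if not 0 < q_ref <= 1:
        raise ValueError("reference quantum yield must lie in (0, 1]")
    a_s, a_r = sample.absorbance_at_excitation, reference.absorbance_at_excitation
    if a_r == 0:
        raise ValueError("reference absorbance at excitation is zero")
    if a_s == 0:
        raise ValueError("sample absorbance at excitation is zero")
    for label, a in (("sample", a_s), ("reference", a_r)):
        if a > 0.1:
            logger.warning("quantum_yield_relative: %s absorbance %.3f > 0.1; "
                           "outside the linear (inner-filter-free) regime", label, a)
    f_s = sample.emission.area()
    f_r = reference.emission.area()
    if f_r == 0:
        raise ValueError("reference emission integral is zero")
    n_ratio2 = (sample.refractive_index / reference.refractive_index) ** 2
    return float(q_ref * (f_s / f_r) * (a_r / a_s) * n_ratio2)
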