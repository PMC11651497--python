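"""Blood-gas arithmetic: bicarbonate from pH/PCO2 and the base-excess family.

The base excess (BE) quantifies the metabolic component of an acid-base
disturbance as the strong-acid dose (mmol/L, negative for a base dose)
needed to titrate blood back to the reference state pH 7.40 / PCO2 40 mmHg.
Its computational form is

    BE = (HCO3 - 24.8) + (pH - 7.40) * beta

where ``beta`` (mmol/L per pH unit) is the buffer power of non-bicarbonate
buffers resisting pH change during a CO2 titration.  The conventional
standard base excess (SBE) fixes beta at 16.2, modelling the whole
extracellular fluid at a diluted effective hemoglobin; the Schlichtig
variant uses 0.9287 * [(HCO3 - 24.8) + (pH - 7.40) * 14.83].

Bicarbonate, when not reported, follows from the Henderson-Hasselbalch
relation HCO3 = S * PCO2 * 10**(pH - pK'), with the standard 37 degC
clinical-chemistry constants pK' = 6.1 and CO2 solubility
S = 0.0307 mmol/L/mmHg.

All functions accept scalars or numpy arrays and are pure; no I/O here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "AcidBaseConstants",
    "BufferPower",
    "BloodGasObservation",
    "PlausibilityError",
    "hco3_from_ph_pco2",
    "base_excess",
    "sbe_standard",
    "sbe_schlichtig",
]

logger = logging.getLogger(__name__)

ArrayLike = Union[float, np.ndarray]


class PlausibilityError(ValueError):
    """An input lies outside the physiologically plausible range."""

    def __init__(self, fieldname: str, value, bounds) -> None:
        self.fieldname = fieldname
        self.value = value
        self.bounds = bounds
        super().__init__(
            f"{fieldname}={value!r} outside plausible range "
            f"[{bounds[0]}, {bounds[1]}]"
        )


@dataclass(frozen=True)
class AcidBaseConstants:
    """Reference values and physical constants for base-excess arithmetic.

    Defaults are the conventional clinical values: the reference state
    (24.8 mmol/L bicarbonate at pH 7.40), the standard buffer power 16.2,
    the Schlichtig scale/buffer-power pair (0.9287, 14.83), and the 37 degC
    Henderson-Hasselbalch constants (pK' 6.1, solubility 0.0307 mmol/L/mmHg).
    Plausibility bounds guard against corrupt rows; they are deliberately
    generous (pH 6.5-8.0, PCO2 5-250 mmHg).
    """

    hco3_ref: float = 24.8
    ph_ref: float = 7.40
    pk_prime: float = 6.1
    co2_solubility: float = 0.0307
    schlichtig_scale: float = 0.9287
    schlichtig_beta: float = 14.83
    standard_beta: float = 16.2
    ph_bounds: tuple[float, float] = (6.5, 8.0)
    pco2_bounds: tuple[float, float] = (5.0, 250.0)
    hco3_consistency_tol: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "hco3_ref",
            "ph_ref",
            "pk_prime",
            "co2_solubility",
            "schlichtig_scale",
            "schlichtig_beta",
            "standard_beta",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def check_ph(self, ph: ArrayLike) -> None:
        lo, hi = self.ph_bounds
        if np.any(np.asarray(ph) < lo) or np.any(np.asarray(ph) > hi):
            raise PlausibilityError("ph", ph, self.ph_bounds)

    def check_pco2(self, pco2: ArrayLike) -> None:
        lo, hi = self.pco2_bounds
        if np.any(np.asarray(pco2) < lo) or np.any(np.asarray(pco2) > hi):
            raise PlausibilityError("pco2", pco2, self.pco2_bounds)


DEFAULT_CONSTANTS = AcidBaseConstants()


@dataclass(frozen=True)
class BufferPower:
    """Buffer power coefficient, mmol/L per pH unit."""

    beta: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be strictly positive")


def _beta_value(beta: Union[float, BufferPower]) -> float:
    return beta.beta if isinstance(beta, BufferPower) else float(beta)


@dataclass
class BloodGasObservation:
    """One arterial sample tagged with its study/subject/exposure labels.

    ``hco3`` may be None on construction; it is then derived from
    (pH, PCO2) via :func:`hco3_from_ph_pco2`.
    """

    study_id: str
    subject_id: str
    exposure_id: str
    pco2: float
    ph: float
    hco3: float | None = None
    constants: AcidBaseConstants = field(default=DEFAULT_CONSTANTS, repr=False)

    def __post_init__(self) -> None:
        self.constants.check_pco2(self.pco2)
        self.constants.check_ph(self.ph)
        if self.hco3 is None:
            self.hco3 = float(
                hco3_from_ph_pco2(self.ph, self.pco2, self.constants)
            )
        elif not self.hco3 > 0:
            raise PlausibilityError("hco3", self.hco3, (0.0, np.inf))
        else:
            derived = hco3_from_ph_pco2(self.ph, self.pco2, self.constants)
            if abs(self.hco3 - derived) > self.constants.hco3_consistency_tol:
                logger.warning(
                    "measured hco3 %.2f differs from pH/PCO2-derived %.2f "
                    "by more than %.1f mmol/L (%s/%s/%s); keeping measured",
                    self.hco3,
                    derived,
                    self.constants.hco3_consistency_tol,
                    self.study_id,
                    self.subject_id,
                    self.exposure_id,
                )


def hco3_from_ph_pco2(
    ph: ArrayLike,
    pco2: ArrayLike,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Bicarbonate (mmol/L) from the Henderson-Hasselbalch relation.

    HCO3 = S * PCO2 * 10**(pH - pK'); strictly increasing in both
    arguments.  Raises :class:`PlausibilityError` outside the bounds.
    """
    constants.check_ph(ph)
    constants.check_pco2(pco2)
    return constants.co2_solubility * np.asarray(pco2) * np.power(
        10.0, np.asarray(ph) - constants.pk_prime
    )


def base_excess(
    hco3: ArrayLike,
    ph: ArrayLike,
    beta: Union[float, BufferPower],
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Generalized base excess (HCO3 - 24.8) + (pH - 7.40) * beta, mmol/L.

    Exactly linear in ``beta``; zero at the reference point for any beta.
    """
    b = _beta_value(beta)
    hco3 = np.asarray(hco3, dtype=float)
    ph = np.asarray(ph, dtype=float)
    if not (np.all(np.isfinite(hco3)) and np.all(np.isfinite(ph))):
        raise ValueError("hco3 and ph must be finite")
    out = (hco3 - constants.hco3_ref) + (ph - constants.ph_ref) * b
    return out if out.ndim else float(out)


def sbe_standard(
    hco3: ArrayLike,
    ph: ArrayLike,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Standard base excess: the generalized equation at beta = 16.2."""
    return base_excess(hco3, ph, constants.standard_beta, constants)


def sbe_schlichtig(
    hco3: ArrayLike,
    ph: ArrayLike,
    constants: AcidBaseConstants = DEFAULT_CONSTANTS,
) -> ArrayLike:
    """Schlichtig SBE: 0.9287 * [(HCO3 - 24.8) + (pH - 7.40) * 14.83]."""
    be = base_excess(hco3, ph, constants.schlichtig_beta, constants)
    return constants.schlichtig_scale * be
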