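"""Linear-quadratic dose algebra for genomic adjusted radiation dose (GARD).

The radiosensitivity index (RSI) estimates a tumor's surviving fraction
after a single 2 Gy fraction.  Under the linear-quadratic cell-survival
model ``S = exp(-alpha*D - beta*D^2)`` with a fixed quadratic coefficient
``beta``, RSI back-solves to a patient-specific linear coefficient

    alpha_g = -ln(RSI) / (n * d) - beta * d        (n = 1, d = 2 Gy)

which, combined with the clinically delivered fractionation (``n_c``
fractions of ``d_c`` Gy), yields the dimensionless treatment-effect metric

    GARD = n_c * d_c * (alpha_g + beta * d_c).

This module provides the forward map, its inverses (RSI from alpha_g,
alpha_g from a delivered GARD, and the minimum dose achieving a target
GARD), EQD2 conversion, and the GARD-group classifier.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainError",
    "UnreachableTargetError",
    "LQParameters",
    "FractionationSchedule",
    "GardPrescription",
    "DEFAULT_LQ",
    "STANDARD_SCHEDULE",
    "DEESCALATED_SCHEDULE",
    "alpha_g_from_rsi",
    "rsi_from_alpha_g",
    "gard_from_schedule",
    "alpha_g_from_gard",
    "eqd2",
    "dose_for_target_gard",
    "classify_gard_group",
    "fraction_delta",
]


class DomainError(ValueError):
    """An input lies outside the model's physical/mathematical domain."""


class UnreachableTargetError(DomainError):
    """No finite dose can achieve the requested GARD for this patient."""


@dataclass(frozen=True)
class LQParameters:
    """Linear-quadratic constants shared across the cohort.

    Parameters
    ----------
    beta : float
        Quadratic radiosensitivity coefficient, Gy^-2. Fixed at 0.05 by
        convention for the GARD framework.
    reference_dose : float
        Dose per fraction (Gy) at which RSI is defined; 2 Gy.
    reference_fractions : int
        Number of fractions in the RSI definition; 1.
    alpha_beta_eqd2 : float
        alpha/beta ratio (Gy) used for EQD2 conversion; 10 Gy is the
        standard tumor assumption.
    """

    beta: float = 0.05
    reference_dose: float = 2.0
    reference_fractions: int = 1
    alpha_beta_eqd2: float = 10.0

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise DomainError(f"beta must be > 0, got {self.beta}")
        if self.reference_dose != 2.0:
            raise DomainError("reference_dose is fixed at 2 Gy by the RSI definition")
        if self.reference_fractions != 1:
            raise DomainError("reference_fractions is fixed at 1 by the RSI definition")
        if not self.alpha_beta_eqd2 > 0:
            raise DomainError(f"alpha_beta_eqd2 must be > 0, got {self.alpha_beta_eqd2}")


DEFAULT_LQ = LQParameters()


@dataclass(frozen=True)
class FractionationSchedule:
    """A radiotherapy schedule: ``n_fractions`` fractions of ``dose_per_fraction`` Gy."""

    n_fractions: int
    dose_per_fraction: float

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise DomainError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if not self.dose_per_fraction > 0:
            raise DomainError(f"dose_per_fraction must be > 0 Gy, got {self.dose_per_fraction}")

    @property
    def total_dose(self) -> float:
        return self.n_fractions * self.dose_per_fraction

    @classmethod
    def from_total_dose(cls, total_dose: float, dose_per_fraction: float) -> "FractionationSchedule":
        n = total_dose / dose_per_fraction
        n_int = round(n)
        if abs(n - n_int) > 1e-9:
            raise DomainError(
                f"total dose {total_dose} Gy is not an integer number of "
                f"{dose_per_fraction} Gy fractions"
            )
        return cls(int(n_int), dose_per_fraction)


#: Standard-of-care schedule: 70 Gy in 35 fractions of 2 Gy.
STANDARD_SCHEDULE = FractionationSchedule(35, 2.0)
#: Uniform de-escalation schedule: 60 Gy in 30 fractions of 2 Gy.
DEESCALATED_SCHEDULE = FractionationSchedule(30, 2.0)


@dataclass(frozen=True)
class GardPrescription:
    """Minimum-dose prescription achieving a target GARD at a given dose/fraction.

    ``required_dose_continuous`` is the exact dose solving
    ``target = D * (alpha_g + beta*d)``; ``required_dose_integer`` is its
    integer part (Gy); ``required_fractions`` rounds the fraction count up
    so the achieved GARD never undershoots the target. ``dose_delta`` and
    ``fraction_delta`` are signed savings relative to the delivered plan /
    35-fraction reference (positive = spared).
    """

    target_gard: float
    alpha_g: float
    dose_per_fraction: float
    required_dose_continuous: float
    required_fractions: int
    required_dose_integer: int = field(init=False)
    dose_delta: float | None = None
    fraction_delta: int | None = None
    patient_id: object | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "required_dose_integer", int(math.floor(self.required_dose_continuous)))

    # beta is carried so achieved_gard is self-contained
    _beta: float = 0.05

    @property
    def achieved_gard(self) -> float:
        d = self.dose_per_fraction
        return self.required_fractions * d * (self.alpha_g + self._beta * d)


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def alpha_g_from_rsi(rsi, params: LQParameters = DEFAULT_LQ):
    """Back-solve the genomic linear coefficient alpha_g (Gy^-1) from RSI.

    alpha_g = -ln(rsi)/(n*d) - beta*d with the RSI reference n=1, d=2 Gy;
    for the default beta this is -ln(rsi)/2 - 0.1.

    A warning (not an error) is emitted when alpha_g < 0, i.e. when
    rsi > exp(-2*beta*d*... ) = exp(-0.2): such tumors are modeled as more
    radioresistant than the pure quadratic term allows.
    """
    r = _as_array(rsi)
    if np.any(~np.isfinite(r)) or np.any(r <= 0) or np.any(r > 1):
        bad = r[(~np.isfinite(r)) | (r <= 0) | (r > 1)]
        raise DomainError(f"rsi must lie in (0, 1]; offending value(s): {bad.tolist()}")
    d = params.reference_dose
    n = params.reference_fractions
    alpha = -np.log(r) / (n * d) - params.beta * d
    if np.any(alpha < 0):
        warnings.warn(
            "alpha_g < 0 for rsi > exp(-0.2); proceeding (value retained, not clipped)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(alpha) if np.isscalar(rsi) else alpha


def rsi_from_alpha_g(alpha_g, params: LQParameters = DEFAULT_LQ):
    """Inverse of :func:`alpha_g_from_rsi`: rsi = exp(-n*d*(alpha_g + beta*d))."""
    a = _as_array(alpha_g)
    d = params.reference_dose
    r = np.exp(-params.reference_fractions * d * (a + params.beta * d))
    return float(r) if np.isscalar(alpha_g) else r


def gard_from_schedule(alpha_g, schedule: FractionationSchedule, params: LQParameters = DEFAULT_LQ):
    """Clinical GARD for a delivered schedule: n_c * d_c * (alpha_g + beta * d_c).

    For d_c = 2 Gy this equals -n_c * ln(rsi) exactly.
    """
    a = _as_array(alpha_g)
    if np.any(~np.isfinite(a)):
        raise DomainError("alpha_g must be finite")
    g = schedule.n_fractions * schedule.dose_per_fraction * (a + params.beta * schedule.dose_per_fraction)
    return float(g) if np.isscalar(alpha_g) else g


def alpha_g_from_gard(gard, schedule: FractionationSchedule, params: LQParameters = DEFAULT_LQ):
    """Invert GARD at a known schedule: alpha_g = GARD/(n_c*d_c) - beta*d_c."""
    g = _as_array(gard)
    a = g / (schedule.n_fractions * schedule.dose_per_fraction) - params.beta * schedule.dose_per_fraction
    return float(a) if np.isscalar(gard) else a


def eqd2(schedule: FractionationSchedule, alpha_beta: float = 10.0) -> float:
    """Equivalent total dose in 2 Gy fractions: D*(d + a/b)/(2 + a/b)."""
    if not alpha_beta > 0:
        raise DomainError(f"alpha/beta must be > 0 Gy, got {alpha_beta}")
    d = schedule.dose_per_fraction
    return schedule.total_dose * (d + alpha_beta) / (2.0 + alpha_beta)


def dose_for_target_gard(
    alpha_g: float,
    target_gard: float,
    dose_per_fraction: float = 2.0,
    params: LQParameters = DEFAULT_LQ,
    delivered_total_dose: float | None = None,
    reference_fractions: int = 35,
    patient_id: object | None = None,
) -> GardPrescription:
    """Minimum total dose (at a fixed dose/fraction) achieving ``target_gard``.

    Solving target = D * (alpha_g + beta*d) gives the continuous dose; the
    fraction count is rounded up (ceiling) so the delivered GARD is >= the
    target, while the reported integer dose is the floor of the continuous
    solution.

    Raises
    ------
    UnreachableTargetError
        If alpha_g + beta*d <= 0, in which case no finite dose reaches a
        positive target.
    """
    if not target_gard > 0:
        raise DomainError(f"target_gard must be > 0, got {target_gard}")
    if not dose_per_fraction > 0:
        raise DomainError(f"dose_per_fraction must be > 0, got {dose_per_fraction}")
    d = dose_per_fraction
    effect_per_gray = alpha_g + params.beta * d
    if effect_per_gray <= 0:
        raise UnreachableTargetError(
            f"target GARD {target_gard} unreachable for patient "
            f"{patient_id!r}: alpha_g + beta*d = {effect_per_gray:.6g} <= 0"
        )
    dose = target_gard / effect_per_gray
    n_req = int(math.ceil(dose / d - 1e-12))  # guard FP noise on exact multiples
    dose_delta = None if delivered_total_dose is None else delivered_total_dose - dose
    return GardPrescription(
        target_gard=target_gard,
        alpha_g=alpha_g,
        dose_per_fraction=d,
        required_dose_continuous=dose,
        required_fractions=n_req,
        dose_delta=dose_delta,
        fraction_delta=reference_fractions - n_req,
        patient_id=patient_id,
        _beta=params.beta,
    )


def classify_gard_group(gard, cutpoint: float = 42.0):
    """Dichotomize GARD: ``"high"`` iff gard >= cutpoint (boundary is high)."""
    if not np.isfinite(cutpoint):
        raise DomainError(f"cutpoint must be finite, got {cutpoint}")
    g = _as_array(gard)
    labels = np.where(g >= cutpoint, "high", "low")
    return str(labels) if np.isscalar(gard) else labels


def fraction_delta(prescription: GardPrescription, reference_fractions: int = 35) -> int:
    """Signed fractions spared (+) or added (-) versus a reference count."""
    return reference_fractions - prescription.required_fractions
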