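"""Conversions between fraction modern (F14C) and conventional radiocarbon age.

Conventional ages use the Libby mean life (8033 yr): age = -8033 * ln(F14C),
uncalibrated years BP. Symmetric uncertainty on F14C maps to asymmetric age
errors because of the log transform (the upward error is always the larger
one).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = ["LIBBY_MEAN_LIFE", "Fm", "RadiocarbonAge", "fm_to_age", "age_to_fm"]

logger = logging.getLogger(__name__)

#: Libby mean life in years; fixed by the conventional-age definition.
LIBBY_MEAN_LIFE = 8033.0


@dataclass(frozen=True)
class Fm:
    """A fraction-modern radiocarbon measurement.

    Parameters
    ----------
    value
        Fraction modern (dimensionless; 1.0 = 1950 atmospheric standard).
    sigma
        Optional 1-s.d. uncertainty, same units.
    """

    value: float
    sigma: float | None = None

    def __post_init__(self) -> None:
        if not (self.value > 0):
            raise ValueError(f"F14C must be > 0, got {self.value}")
        if self.sigma is not None and not (self.sigma >= 0):
            raise ValueError(f"F14C sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class RadiocarbonAge:
    """A conventional radiocarbon age with asymmetric 1-s.d. offsets.

    ``err_plus``/``err_minus`` are positive offsets (years); the interval is
    ``[age - err_minus, age + err_plus]``. They are ``None`` when the source
    measurement carried no uncertainty.
    """

    age: float
    err_plus: float | None = None
    err_minus: float | None = None

    def __post_init__(self) -> None:
        for name in ("err_plus", "err_minus"):
            v = getattr(self, name)
            if v is not None and not (v >= 0):
                raise ValueError(f"{name} must be >= 0, got {v}")


def _age(value: float) -> float:
    return -LIBBY_MEAN_LIFE * math.log(value)


def fm_to_age(fm: Fm, rounding: str | None = "year") -> RadiocarbonAge:
    """Convert fraction modern to a conventional radiocarbon age.

    Parameters
    ----------
    fm
        The measurement; ``fm.value`` must be positive and, when ``fm.sigma``
        is given, ``fm.value - fm.sigma`` must stay positive (otherwise the
        1-s.d. interval spans non-physical F14C and no age error exists).
    rounding
        ``"year"`` (default) rounds age and errors to the nearest year;
        ``None`` returns them unrounded.

    Returns
    -------
    RadiocarbonAge
        ``age = -8033 * ln(value)``; when sigma is present,
        ``err_plus = age(value - sigma) - age(value)`` and
        ``err_minus = age(value) - age(value + sigma)``.

    Notes
    -----
    F14C > 1 (post-bomb carbon) is allowed and yields a negative age,
    returned as-is and logged as modern.
    """
    if rounding not in ("year", None):
        raise ValueError(f"rounding must be 'year' or None, got {rounding!r}")
    age = _age(fm.value)
    if fm.value > 1:
        logger.info("F14C=%g > 1: modern, post-bomb; age %g yr", fm.value, age)
    err_plus = err_minus = None
    if fm.sigma is not None:
        if fm.value - fm.sigma <= 0:
            raise ValueError(
                f"F14C uncertainty interval reaches non-physical values: "
                f"{fm.value} - {fm.sigma} <= 0"
            )
        err_plus = _age(fm.value - fm.sigma) - age
        err_minus = age - _age(fm.value + fm.sigma)
    if rounding == "year":
        age = float(round(age))
        if err_plus is not None:
            err_plus = float(round(err_plus))
            err_minus = float(round(err_minus))
    return RadiocarbonAge(age=age, err_plus=err_plus, err_minus=err_minus)


def age_to_fm(age: float) -> Fm:
    """Convert a conventional radiocarbon age (years BP) to fraction modern.

    Inverse of :func:`fm_to_age` (with ``rounding=None``) to within 1e-9
    relative.
    """
    if not math.isfinite(age):
        raise ValueError(f"age must be finite, got {age}")
    return Fm(value=math.exp(-age / LIBBY_MEAN_LIFE))
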