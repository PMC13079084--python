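"""Miller-Tans regression: estimate the d13C of an added carbon source.

Regresses concentration x d13C on concentration by ordinary least squares;
the slope estimates the source's d13C and the intercept carries the
background term. The intercept is retained (no suppression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = ["ConcentrationDeltaSeries", "MillerTansFit", "fit_miller_tans"]


@dataclass(frozen=True)
class ConcentrationDeltaSeries:
    """Paired concentration / d13C observations of one pool.

    Concentrations in any consistent units (e.g. umol L-1), d13C in permil
    VPDB. Requires >= 3 samples, positive concentrations, and non-constant
    concentration (the slope is undefined otherwise, checked at fit time).
    """

    conc: np.ndarray
    d13c: np.ndarray
    label: str = "series"

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc, dtype=float)
        d13c = np.asarray(self.d13c, dtype=float)
        object.__setattr__(self, "conc", conc)
        object.__setattr__(self, "d13c", d13c)
        if conc.ndim != 1 or d13c.ndim != 1 or conc.shape != d13c.shape:
            raise ValueError(
                f"conc and d13c must be equal-length 1-D arrays, got shapes "
                f"{conc.shape} and {d13c.shape}"
            )
        if conc.shape[0] < 3:
            raise ValueError(f"need >= 3 samples, got {conc.shape[0]}")
        if not (conc > 0).all():
            raise ValueError("all concentrations must be > 0")
        if not (np.isfinite(conc).all() and np.isfinite(d13c).all()):
            raise ValueError("conc and d13c must be finite")


@dataclass(frozen=True)
class MillerTansFit:
    """OLS fit of conc*d13C on conc.

    ``slope`` is the source d13C estimate (permil), ``slope_se`` its 1-s.e.;
    ``intercept`` is in permil x concentration units.
    """

    slope: float
    slope_se: float
    intercept: float
    r2: float
    n: int
    flavor: str = "ols"

    def as_dict(self) -> dict:
        return {
            "slope_permil": self.slope,
            "slope_se_permil": self.slope_se,
            "intercept": self.intercept,
            "r2": self.r2,
            "n": self.n,
            "regression_flavor": self.flavor,
        }


def fit_miller_tans(series: ConcentrationDeltaSeries) -> MillerTansFit:
    """Fit the Miller-Tans regression to a concentration/d13C series.

    Raises
    ------
    ValueError
        If the concentrations have zero variance (slope undefined).
    """
    conc = series.conc
    if np.ptp(conc) == 0:
        raise ValueError(
            f"{series.label}: concentrations are all identical; "
            f"Miller-Tans slope is undefined"
        )
    y = conc * series.d13c
    X = sm.add_constant(conc)
    res = sm.OLS(y, X).fit()
    return MillerTansFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        r2=float(res.rsquared),
        n=int(conc.shape[0]),
    )
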