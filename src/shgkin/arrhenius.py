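"""Activation energies from temperature-dependent transport rates.

The transport rate obeys ``ln k = lnA - Ea/(R T)``, so the activation energy
is read off the slope of the linear regression of ``ln k`` on ``1/T``
(``Ea = -slope * R``).  The regression is unweighted by default; weighting by
the delta-method variance of ``ln k`` (``(stderr_k / k)^-2``) is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .kinetics_model import GAS_CONSTANT

__all__ = ["RateSeries", "ArrheniusFit", "fit_arrhenius", "compare_barriers"]


@dataclass(frozen=True)
class RateSeries:
    """Per-temperature transport rates for one sample."""

    temperature: np.ndarray  # K
    k: np.ndarray  # 1/s
    stderr_k: np.ndarray | None = None  # 1/s
    label: str = ""
    source: tuple = ()  # fit identifiers, carried through for provenance

    def __post_init__(self) -> None:
        T = np.asarray(self.temperature, dtype=float)
        k = np.asarray(self.k, dtype=float)
        if T.shape != k.shape or T.ndim != 1:
            raise ValueError("temperature and k must be 1-d, equal length")
        if np.unique(T).size < 3:
            raise ValueError("need >= 3 distinct temperatures")
        if np.any(k <= 0):
            bad = T[k <= 0]
            raise ValueError(f"non-positive rate constant(s) at T = {bad.tolist()} K")
        if self.stderr_k is not None:
            se = np.asarray(self.stderr_k, dtype=float)
            if se.shape != k.shape or np.any(se < 0):
                raise ValueError("stderr_k must be nonnegative and match k")


@dataclass(frozen=True)
class ArrheniusFit:
    """Activation energy and pre-exponential factor from the linearized fit."""

    Ea: float  # kJ/mol
    stderr_Ea: float  # kJ/mol
    lnA: float
    stderr_lnA: float
    r_squared: float
    n: int
    label: str = ""
    weighted: bool = False


def fit_arrhenius(series: RateSeries, weighted: bool = False) -> ArrheniusFit:
    """Regress ``ln k`` on ``1/T`` and convert the slope to kJ/mol.

    With ``weighted=True`` each point is weighted by ``(k / stderr_k)^2``,
    the inverse delta-method variance of ``ln k``; this requires stderr_k.
    """
    T = np.asarray(series.temperature, dtype=float)
    x = 1.0 / T
    y = np.log(np.asarray(series.k, dtype=float))
    X = sm.add_constant(x)
    if weighted:
        if series.stderr_k is None:
            raise ValueError("weighted fit requires stderr_k on the rate series")
        se = np.asarray(series.stderr_k, dtype=float)
        if np.any(se == 0):
            raise ValueError("weighted fit requires strictly positive stderr_k")
        w = (np.asarray(series.k, dtype=float) / se) ** 2
        res = sm.WLS(y, X, weights=w).fit()
    else:
        res = sm.OLS(y, X).fit()
    slope = float(res.params[1])
    slope_se = float(res.bse[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(res.rsquared)
    if not np.isfinite(r_squared):
        # constant ln k: the centered total sum of squares vanishes and the
        # ratio is undefined; report 1 for a perfect fit, 0 otherwise
        r_squared = 1.0 if float(res.ssr) < 1e-30 else 0.0
    # Ea = -slope * R, J/mol -> kJ/mol exactly once, at this reporting boundary
    return ArrheniusFit(
        Ea=-slope * GAS_CONSTANT / 1000.0,
        stderr_Ea=slope_se * GAS_CONSTANT / 1000.0,
        lnA=float(res.params[0]),
        stderr_lnA=float(res.bse[0]),
        r_squared=r_squared,
        n=int(T.size),
        label=series.label,
        weighted=weighted,
    )


def compare_barriers(fits: list[ArrheniusFit]) -> pd.DataFrame:
    """Pairwise activation-energy differences with combined standard errors.

    Fits are ordered by ascending Ea (ties broken by label); each row holds
    one pair, its difference ``Ea_b - Ea_a`` and the propagated uncertainty
    ``sqrt(se_a^2 + se_b^2)``.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ordered = sorted(fits, key=lambda f: (f.Ea, f.label))
    rows = []
    for a, b in combinations(ordered, 2):
        rows.append(
            {
                "label_a": a.label,
                "label_b": b.label,
                "Ea_a_kJ_mol": a.Ea,
                "Ea_b_kJ_mol": b.Ea,
                "delta_Ea_kJ_mol": b.Ea - a.Ea,
                "stderr_delta_kJ_mol": float(np.hypot(a.stderr_Ea, b.stderr_Ea)),
            }
        )
    return pd.DataFrame(rows)
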