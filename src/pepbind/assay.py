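"""Assay-side computations: viability percentages and one-site KD fits."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ViabilityRecord",
    "BindingCurveFit",
    "DegenerateFitError",
    "viability",
    "fit_kd",
]


class DegenerateFitError(ValueError):
    """The curve carries no information about KD."""


@dataclass
class ViabilityRecord:
    od_test: float
    od_blank: float
    od_control: float

    @property
    def viability(self) -> float:
        return viability(self.od_test, self.od_blank, self.od_control)


@dataclass
class BindingCurveFit:
    kd: float  # uM
    a_max: float
    baseline: float
    rss: float
    conf_half_widths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("fitted kd must be > 0")


def viability(od_test: float, od_blank: float, od_control: float) -> float:
    """Percent viability: 100 * (OD_test - OD_blank) / (OD_control - OD_blank)."""
    denom = od_control - od_blank
    if abs(denom) < 1e-12:
        raise ZeroDivisionError("od_control equals od_blank")
    return 100.0 * (od_test - od_blank) / denom


def _one_site(c: np.ndarray, kd: float, a_max: float, baseline: float) -> np.ndarray:
    return baseline + a_max * c / (kd + c)


def fit_kd(curve: pd.DataFrame, model: str = "one_site") -> BindingCurveFit:
    """Nonlinear least-squares one-site saturation fit.

    ``curve`` needs columns (concentration_uM, response).  Initialization is
    a deterministic multi-start over a log-spaced KD grid covering the
    concentration range; the best residual sum of squares wins.  Fitting is
    done on the linear-concentration model (a log axis changes the display,
    not the likelihood).
    """
    if model != "one_site":
        raise ValueError(f"unsupported model {model!r}")
    c = np.asarray(curve["concentration_uM"], dtype=float)
    y = np.asarray(curve["response"], dtype=float)
    distinct = np.unique(c[c > 0])
    if len(distinct) < 2 or np.allclose(y, y[0]):
        raise DegenerateFitError(
            "need >= 2 distinct positive concentrations and varying responses"
        )
    if len(distinct) < 4 or distinct.max() / distinct.min() < 100.0:
        warnings.warn(
            "fewer than 4 distinct concentrations or <2 orders of magnitude span; "
            "KD may be poorly determined"
        )

    kd_grid = np.geomspace(distinct.min() / 10.0, distinct.max() * 10.0, 12)
    base0 = float(y.min())
    amax0 = float(y.max() - y.min()) or 1.0
    best = None
    for kd0 in kd_grid:
        try:
            popt, pcov = curve_fit(
                _one_site, c, y, p0=[kd0, amax0, base0],
                bounds=([1e-12, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((_one_site(c, *popt) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        raise DegenerateFitError("fit did not converge from any start")
    rss, popt, pcov = best
    with np.errstate(invalid="ignore"):
        half = 1.96 * np.sqrt(np.diag(pcov))
    return BindingCurveFit(
        kd=float(popt[0]),
        a_max=float(popt[1]),
        baseline=float(popt[2]),
        rss=rss,
        conf_half_widths={
            "kd": float(half[0]), "a_max": float(half[1]), "baseline": float(half[2]),
        },
    )
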