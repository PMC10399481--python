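"""Assay-readout arithmetic: inhibition rates, IC50 fitting, potency ratios,
and the calliper tumour-volume formula.

The dose-response model is the four-parameter logistic on log
concentration,

    response(c) = bottom + (top - bottom) / (1 + (IC50 / c)^hill),

with responses in percent inhibition and concentrations in molar.  At
c = IC50 the response is exactly the midpoint (top + bottom) / 2.  The
fit is ordinary least squares with multi-start initialisation; the
``converged`` flag is honest (degenerate, unidentifiable data comes back
unconverged rather than with a fabricated IC50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass
class DoseResponseData:
    """Concentrations (molar, ascending by level) with replicate responses (%).

    Stored flat: ``concentrations[i]`` pairs with ``responses[i]``;
    replicates simply repeat a concentration.  Fitting requires at least
    four distinct concentrations.
    """

    concentrations: np.ndarray
    responses: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses differ in length")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive (molar)")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("non-finite response values")

    @property
    def n_levels(self) -> int:
        return len(np.unique(self.concentrations))

    @classmethod
    def from_csv(cls, path: str | Path) -> "DoseResponseData":
        """Read a dose-response CSV (columns concentration_M, response_pct[, replicate])."""
        df = pd.read_csv(path)
        for col in ("concentration_M", "response_pct"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(df["concentration_M"].to_numpy(), df["response_pct"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "concentration_M": self.concentrations,
                "response_pct": self.responses,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class SigmoidFit:
    ic50: float  # molar
    hill: float
    top: float  # percent
    bottom: float  # percent
    rss: float
    converged: bool


def four_parameter_logistic(
    c: np.ndarray, ic50: float, hill: float, top: float, bottom: float
) -> np.ndarray:
    """The 4PL dose-response curve (concentration and IC50 in molar)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ic50 / c) ** hill)


def inhibition_rate(test: float, control: float, blank: float = 0.0) -> float:
    """Percent inhibition from raw plate signals.

    ``100 * (1 - (test - blank) / (control - blank))``; applies equally to
    fluorescence and absorbance readouts.  The result is affine-invariant:
    rescaling all three signals identically leaves it unchanged.
    """
    if control == blank:
        raise ZeroDivisionError("control equals blank; inhibition rate undefined")
    return 100.0 * (1.0 - (test - blank) / (control - blank))


_HILL_STARTS = (0.5, 1.0, 2.0)


def fit_sigmoid(
    data: DoseResponseData,
    constrain_top: float | None = None,
    constrain_bottom: float | None = None,
) -> SigmoidFit:
    """Least-squares 4PL fit on log concentration with multi-start initialisation.

    IC50 is seeded at the concentration whose mean response is nearest
    half-maximal; hill starts at 0.5, 1 and 2; the best residual sum of
    squares wins.  ``constrain_top`` / ``constrain_bottom`` pin the
    asymptotes (e.g. 100/0).  Requires >= 4 distinct concentrations.
    """
    if data.n_levels < 4:
        raise ValueError("need at least 4 distinct concentrations to fit")
    conc = data.concentrations
    resp = data.responses

    levels = np.unique(conc)
    level_means = np.array([resp[conc == c].mean() for c in levels])
    lo, hi = float(level_means.min()), float(level_means.max())
    if hi - lo < 1e-8:
        # flat curve: IC50 unidentifiable
        return SigmoidFit(
            ic50=float(np.median(levels)),
            hill=1.0,
            top=hi,
            bottom=lo,
            rss=float(np.sum((resp - resp.mean()) ** 2)),
            converged=False,
        )

    half = (lo + hi) / 2.0
    ic50_seed = float(levels[np.argmin(np.abs(level_means - half))])

    fixed_top = constrain_top is not None
    fixed_bottom = constrain_bottom is not None

    def model(log_c: np.ndarray, log_ic50: float, hill: float, *rest) -> np.ndarray:
        i = 0
        if fixed_top:
            top = constrain_top
        else:
            top = rest[i]
            i += 1
        bottom = constrain_bottom if fixed_bottom else rest[i]
        c = 10.0**log_c
        return four_parameter_logistic(c, 10.0**log_ic50, hill, top, bottom)

    log_c = np.log10(conc)
    log_lo = math.log10(levels[0]) - 3
    log_hi = math.log10(levels[-1]) + 3

    p0_extra = []
    lower_extra: list[float] = []
    upper_extra: list[float] = []
    if not fixed_top:
        p0_extra.append(hi)
        lower_extra.append(-np.inf)
        upper_extra.append(np.inf)
    if not fixed_bottom:
        p0_extra.append(lo)
        lower_extra.append(-np.inf)
        upper_extra.append(np.inf)

    best: SigmoidFit | None = None
    for hill0 in _HILL_STARTS:
        p0 = [math.log10(ic50_seed), hill0, *p0_extra]
        bounds = (
            [log_lo, 0.05, *lower_extra],
            [log_hi, 10.0, *upper_extra],
        )
        try:
            popt, _ = curve_fit(model, log_c, resp, p0=p0, bounds=bounds, maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        pred = model(log_c, *popt)
        rss = float(np.sum((resp - pred) ** 2))
        i = 2
        top = constrain_top if fixed_top else float(popt[i])
        if not fixed_top:
            i += 1
        bottom = constrain_bottom if fixed_bottom else float(popt[i])
        fit = SigmoidFit(
            ic50=float(10.0 ** popt[0]),
            hill=float(popt[1]),
            top=float(top),
            bottom=float(bottom),
            rss=rss,
            converged=top > bottom,
        )
        if best is None or fit.rss < best.rss:
            best = fit
    if best is None:
        return SigmoidFit(
            ic50=ic50_seed, hill=1.0, top=hi, bottom=lo, rss=math.inf, converged=False
        )
    return best


def potency_ratio(reference_ic50: float, candidate_ic50: float) -> float:
    """Fold-potency of a candidate versus a reference: reference / candidate, 1 dp.

    A ratio above 1 means the candidate is more potent (lower IC50) than
    the reference compound.
    """
    if reference_ic50 <= 0 or candidate_ic50 <= 0:
        raise ValueError("IC50 values must be positive")
    return round(reference_ic50 / candidate_ic50, 1)


def tumour_volume(c: float, d: float) -> float:
    """Xenograft tumour volume (mm^3) from calliper diameters: c^2 * d / 2.

    ``c`` is the smallest and ``d`` the largest diameter in mm; passing
    them swapped raises.
    """
    if c < 0 or d < 0:
        raise ValueError("diameters must be non-negative")
    if c > d:
        raise ValueError("smallest diameter exceeds largest; arguments swapped?")
    return c * c * d / 2.0
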