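"""53BP1 focus-kinetics analysis: one-phase decay fits and repair summaries.

Mean foci per cell after a 2 Gy exposure decay approximately as
``y(t) = plateau + (y0 - plateau) * exp(-k t)``: a fast-clearing repaired
component on top of a persistent residual plateau. Two model-free summaries
are used alongside the fit: the *induced* focus count (the earliest
timepoint, nominally 1 h) and the *percent residual* at a late horizon
(nominally 24 h), whose complement is the percent repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .survival import LinearFit, fit_linear

__all__ = [
    "FociTimeCourse",
    "DecayFit",
    "fit_one_phase_decay",
    "induced_foci",
    "percent_residual",
    "percent_repaired",
    "residual_vs_let_fit",
]


@dataclass(frozen=True)
class FociTimeCourse:
    """Mean foci per cell versus time after irradiation.

    Times are hours post-exposure, strictly increasing, first >= 0.
    """

    times: np.ndarray
    mean_foci: np.ndarray
    sem: np.ndarray | None = None
    dose: float = 2.0
    quality_label: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.mean_foci, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "mean_foci", y)
        if self.sem is not None:
            object.__setattr__(self, "sem", np.asarray(self.sem, dtype=float))
        if len(t) != len(y):
            raise ValueError("times and mean_foci must have equal length")
        if len(t) and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be strictly increasing and non-negative")
        if np.any(y < 0):
            raise ValueError("mean_foci must be non-negative")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class DecayFit:
    """One-phase exponential decay fit: y(t) = plateau + (y0-plateau) e^{-kt}."""

    y0: float
    plateau: float
    k: float
    converged: bool
    k_se: float = float("nan")
    plateau_se: float = float("nan")
    identifiable: bool = True

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.plateau + (self.y0 - self.plateau) * np.exp(-self.k * t)


def fit_one_phase_decay(tc: FociTimeCourse) -> DecayFit:
    """Least-squares one-phase decay fit with k >= 0 and plateau >= 0.

    When the course carries per-timepoint SEMs the fit is weighted by them
    (``absolute_sigma``), which keeps the parameter standard errors honest
    under count-type noise. A flat time course (zero amplitude) leaves the
    rate unidentifiable; the fit then returns the mean level as plateau
    with ``identifiable`` cleared rather than raising.

    Raises
    ------
    ValueError
        Fewer than 4 timepoints.
    """
    if len(tc) < 4:
        raise ValueError("one-phase decay fit requires at least 4 timepoints")
    t = tc.times
    y = tc.mean_foci
    if np.ptp(y) == 0:
        return DecayFit(y0=float(y[0]), plateau=float(y[0]), k=0.0,
                        converged=True, identifiable=False)

    def model(t, y0, plateau, k):
        return plateau + (y0 - plateau) * np.exp(-k * t)

    y0_guess = float(y[0])
    plateau_guess = float(max(y[-1], 1e-6))
    span = max(t[-1] - t[0], 1e-6)
    k_guess = max(np.log(max(y0_guess, 1e-6) / plateau_guess) / span, 0.1)
    sigma = None
    absolute_sigma = False
    if tc.sem is not None and np.all(tc.sem > 0):
        sigma = tc.sem
        absolute_sigma = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=(y0_guess, plateau_guess, k_guess),
                sigma=sigma, absolute_sigma=absolute_sigma,
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        return DecayFit(y0=float("nan"), plateau=float("nan"), k=float("nan"),
                        converged=False, identifiable=False)
    perr = np.sqrt(np.diag(pcov))
    return DecayFit(
        y0=float(popt[0]), plateau=float(popt[1]), k=float(popt[2]),
        converged=converged, k_se=float(perr[2]), plateau_se=float(perr[1]),
    )


def induced_foci(tc: FociTimeCourse) -> tuple[float, float | None]:
    """Foci per cell at the earliest timepoint (nominally the 1 h count).

    Returns ``(mean, sem)``; the SEM is None when unavailable. If the
    earliest timepoint is later than 1.5 h the value is still returned but
    a warning flags that it underestimates true induction.
    """
    if len(tc) == 0:
        raise ValueError("empty time course")
    if tc.times[0] > 1.5:
        warnings.warn(
            f"earliest timepoint {tc.times[0]:g} h is later than 1.5 h; "
            "induced focus count will underestimate induction",
            stacklevel=2,
        )
    sem = float(tc.sem[0]) if tc.sem is not None else None
    return float(tc.mean_foci[0]), sem


def percent_residual(tc: FociTimeCourse, horizon: float = 24.0) -> float:
    """Percent of induced foci remaining at the horizon (nearest within 1 h).

    ``100 * foci(horizon) / foci(first timepoint)``. Values above 100 are
    possible with noise and are flagged with a warning.
    """
    if len(tc) < 2:
        raise ValueError("need at least 2 timepoints")
    idx = int(np.argmin(np.abs(tc.times - horizon)))
    if abs(tc.times[idx] - horizon) > 1.0:
        raise ValueError(f"no timepoint within 1 h of the {horizon:g} h horizon")
    induction = tc.mean_foci[0]
    if induction <= 0:
        raise ValueError("zero induction; percent residual undefined")
    pct = 100.0 * float(tc.mean_foci[idx]) / float(induction)
    if pct > 100.0:
        warnings.warn(f"residual {pct:.1f}% exceeds induction (noise)", stacklevel=2)
    return pct


def percent_repaired(tc: FociTimeCourse, horizon: float = 24.0) -> float:
    """Percent of induced foci cleared by the horizon (100 - percent residual)."""
    return 100.0 - percent_residual(tc, horizon)


def residual_vs_let_fit(points) -> LinearFit:
    """OLS fit of percent-residual against LET over >= 3 radiation qualities.

    ``points`` is an iterable of (LET, percent_residual) pairs; the slope
    has units of % per keV/um.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least 3 qualities")
    let = [p[0] for p in pts]
    res = [p[1] for p in pts]
    return fit_linear(let, res)
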