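"""Clonogenic survival statistics: LQ fitting, mean inactivation dose, RBE, SER.

The linear-quadratic (LQ) model describes clonogenic surviving fraction as
``SF(D) = exp(-(alpha*D + beta*D^2))``. Overall radiosensitivity is summarised
by the mean inactivation dose (MID), the area under the survival curve
``MID = integral SF(D) dD``; for an exact LQ curve this has the closed form
``sqrt(pi/(4 beta)) * exp(alpha^2/(4 beta)) * erfc(alpha/(2 sqrt(beta)))``.
For tabulated data the MID is computed by exponential (log-linear)
interpolation between measured dose points, with a log-linear tail beyond
the last dose.

Two dimensionless ratios of MIDs are used throughout:

* RBE_MID = MID(reference X-rays) / MID(test radiation) - relative
  biological effectiveness of a particle beam.
* SER = MID(wild-type) / MID(repair-deficient line) - sensitiser
  enhancement ratio of a gene knockout, at fixed radiation quality.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

__all__ = [
    "DoseResponse",
    "LQFit",
    "MIDResult",
    "RatioResult",
    "LinearFit",
    "fit_lq",
    "lq_mid_closed_form",
    "compute_mid",
    "compute_rbe",
    "compute_ser",
    "apply_mylar_correction",
    "fit_linear",
]


@dataclass(frozen=True)
class DoseResponse:
    """Per-dose surviving fractions with optional replicate structure.

    Doses must be strictly increasing and start at 0; surviving fractions
    are normalised so ``sf_mean[0] == 1`` and must be strictly positive.
    """

    doses: np.ndarray
    sf_mean: np.ndarray
    sf_err: np.ndarray | None = None
    replicates: list[np.ndarray] | None = None  # per-dose replicate SF values
    colony_counts: list[np.ndarray] | None = None  # per-dose replicate colony counts

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        s = np.asarray(self.sf_mean, dtype=float)
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "sf_mean", s)
        if self.sf_err is not None:
            object.__setattr__(self, "sf_err", np.asarray(self.sf_err, dtype=float))
        if len(d) != len(s):
            raise ValueError("doses and sf_mean must have equal length")
        if len(d) == 0:
            raise ValueError("empty dose response")
        if d[0] != 0:
            raise ValueError("dose grid must start at 0")
        if np.any(np.diff(d) <= 0):
            raise ValueError("doses must be strictly increasing")
        if np.any(s <= 0):
            raise ValueError("surviving fractions must be strictly positive")
        if abs(s[0] - 1.0) > 1e-9:
            raise ValueError("sf_mean[0] must be 1 after normalisation")

    def __len__(self) -> int:
        return len(self.doses)


@dataclass(frozen=True)
class LQFit:
    """Result of a constrained LQ fit: alpha (Gy^-1), beta (Gy^-2) >= 0."""

    alpha: float
    beta: float
    covariance: np.ndarray
    converged: bool

    @property
    def alpha_se(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def beta_se(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def survival(self, dose):
        d = np.asarray(dose, dtype=float)
        return np.exp(-(self.alpha * d + self.beta * d**2))


@dataclass(frozen=True)
class MIDResult:
    """Mean inactivation dose (Gy) with provenance of the integration."""

    mid: float
    method: str  # "exponential_interpolation" or "lq_closed_form"
    tail_fraction: float
    se: float | None = None

    def __post_init__(self) -> None:
        if not self.mid > 0:
            raise ValueError("MID must be positive")
        if not 0.0 <= self.tail_fraction < 1.0:
            raise ValueError("tail_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class RatioResult:
    """A ratio of two MIDs (RBE_MID or SER), with optional propagated SE."""

    value: float
    numerator_mid: float
    denominator_mid: float
    se: float | None = None


@dataclass(frozen=True)
class LinearFit:
    """Ordinary least-squares line fit."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_lq(data: DoseResponse) -> LQFit:
    """Fit the LQ model to a dose response by constrained least squares.

    The fit is performed on ``ln(SF)`` against dose, which is linear in the
    parameters and variance-stabilised for clonogenic counts, with both
    coefficients constrained to be non-negative.

    When per-replicate colony counts are available the fit runs at
    replicate level with counting-statistics weights
    (``var(ln SF) ~ 1/colonies + 1/colonies_at_0Gy``), which keeps the
    parameter standard errors honest for binomial colony noise. Otherwise,
    replicate SF values (when present) supply empirical variance weights;
    failing both, the fit is unweighted.

    Raises
    ------
    ValueError
        Fewer than 3 dose points. Non-convergence is flagged, not raised.
    """
    if len(data) < 3:
        raise ValueError("LQ fit requires at least 3 dose points including 0")

    def model(dose, alpha, beta):
        return -(alpha * dose + beta * dose**2)

    kwargs: dict = {}
    if data.colony_counts is not None and data.replicates is not None:
        # replicate-level observations with Poisson-approximation weights;
        # 0 Gy points are identically ln(1)=0 and carry no information
        d_obs, y_obs, sig = [], [], []
        c0 = np.asarray(data.colony_counts[0], dtype=float)
        for i in range(1, len(data)):
            sf = np.asarray(data.replicates[i], dtype=float)
            counts = np.asarray(data.colony_counts[i], dtype=float)
            ref = c0 if len(c0) == len(counts) else np.full_like(counts, c0.mean())
            for s, c, c_ref in zip(sf, counts, ref):
                if s > 0 and c > 0 and c_ref > 0:
                    d_obs.append(data.doses[i])
                    y_obs.append(np.log(s))
                    sig.append(np.sqrt(1.0 / c + 1.0 / c_ref))
        d, y = np.asarray(d_obs), np.asarray(y_obs)
        kwargs = {"sigma": np.asarray(sig), "absolute_sigma": True}
    else:
        d = data.doses
        y = np.log(data.sf_mean)
        if data.replicates is not None:
            var = []
            for reps in data.replicates:
                reps = np.asarray(reps, dtype=float)
                reps = reps[reps > 0]
                v = np.var(np.log(reps), ddof=1) / len(reps) if len(reps) > 1 else 0.0
                var.append(v)
            var = np.asarray(var)
            if np.any(var > 0):
                floor = var[var > 0].min()
                kwargs = {"sigma": np.sqrt(np.maximum(var, floor))}

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(
                model, d, y, p0=(0.1, 0.01),
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000, **kwargs,
            )
        converged = bool(np.all(np.isfinite(popt)))
    except RuntimeError:
        popt, pcov = (np.nan, np.nan), np.full((2, 2), np.nan)
        converged = False
    return LQFit(alpha=float(popt[0]), beta=float(popt[1]),
                 covariance=np.asarray(pcov), converged=converged)


def lq_mid_closed_form(alpha: float, beta: float) -> float:
    """Exact MID of an LQ curve integrated to infinite dose.

    ``integral exp(-aD - bD^2) dD = sqrt(pi/(4b)) * erfcx(a / (2 sqrt(b)))``,
    evaluated with the scaled complementary error function for stability;
    reduces to ``1/alpha`` as beta -> 0.
    """
    if alpha < 0 or beta < 0 or (alpha == 0 and beta == 0):
        raise ValueError("need alpha, beta >= 0 and not both zero")
    if beta == 0:
        return 1.0 / alpha
    return math.sqrt(math.pi / (4.0 * beta)) * float(
        special.erfcx(alpha / (2.0 * math.sqrt(beta)))
    )


_FLAT_EPS = 1e-12


def compute_mid(data: DoseResponse) -> MIDResult:
    """MID by piecewise exponential interpolation of the measured points.

    On each segment ``[D_i, D_{i+1}]`` the survival is taken as exponential
    with rate ``lambda_i = ln(S_i/S_{i+1}) / (D_{i+1}-D_i)``, giving segment
    area ``(S_i - S_{i+1}) / lambda_i`` (limit ``S_i * dD`` for flat
    segments). Beyond the last dose the final segment's rate is extrapolated
    log-linearly; if the curve is not decaying there the tail is truncated
    to zero and the result carries ``tail_fraction = 0``. A warning is
    emitted when the tail contributes more than 20% of the MID.
    """
    d = data.doses
    s = data.sf_mean
    if len(d) < 2:
        raise ValueError("MID requires at least 2 dose points")

    area = 0.0
    lam = 0.0
    for i in range(len(d) - 1):
        dd = d[i + 1] - d[i]
        lam = math.log(s[i] / s[i + 1]) / dd
        if abs(lam) < _FLAT_EPS:
            area += s[i] * dd
        else:
            area += (s[i] - s[i + 1]) / lam

    tail = s[-1] / lam if lam > _FLAT_EPS else 0.0
    mid = area + tail
    tail_fraction = tail / mid if mid > 0 else 0.0
    if tail_fraction > 0.2:
        warnings.warn(
            f"MID tail beyond the last dose contributes {tail_fraction:.0%}; "
            "consider extending the dose range",
            stacklevel=2,
        )
    return MIDResult(mid=float(mid), method="exponential_interpolation",
                     tail_fraction=float(tail_fraction))


def _mid_ratio(numerator: MIDResult, denominator: MIDResult) -> RatioResult:
    if numerator.mid <= 0 or denominator.mid <= 0:
        raise ValueError("MIDs must be positive")
    value = numerator.mid / denominator.mid
    se = None
    if numerator.se is not None and denominator.se is not None:
        # first-order delta method for a ratio of independent estimates
        se = value * math.sqrt(
            (numerator.se / numerator.mid) ** 2
            + (denominator.se / denominator.mid) ** 2
        )
    return RatioResult(value=float(value), numerator_mid=numerator.mid,
                       denominator_mid=denominator.mid, se=se)


def compute_rbe(mid_reference: MIDResult, mid_test: MIDResult) -> RatioResult:
    """RBE_MID: ratio of the reference (X-ray) MID to the test-radiation MID."""
    return _mid_ratio(mid_reference, mid_test)


def compute_ser(mid_wildtype: MIDResult, mid_knockout: MIDResult) -> RatioResult:
    """SER: ratio of the wild-type MID to the repair-deficient MID."""
    return _mid_ratio(mid_wildtype, mid_knockout)


def apply_mylar_correction(dose_plate: float, factor: float = 1.22):
    """Scale plate doses onto the Mylar dose axis.

    Cells grown on Mylar (the alpha-particle dish geometry) show reduced
    plating efficiency and survival relative to standard plates; reference
    X-ray doses measured on plates are multiplied by this factor before the
    X-ray MID enters an alpha-particle RBE. The canonical direction scales
    plate doses *up*; pass ``1/factor`` to go the other way.
    """
    dose = np.asarray(dose_plate, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    if factor <= 0:
        raise ValueError("correction factor must be positive")
    out = dose * factor
    return float(out) if out.ndim == 0 else out


def fit_linear(x, y) -> LinearFit:
    """Ordinary least-squares line through (x, y).

    Degenerate x (zero variance) raises; constant y returns slope 0 with
    R^2 = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    if np.ptp(y) == 0:
        return LinearFit(slope=0.0, intercept=float(y[0]), r_squared=0.0, slope_se=0.0)
    from scipy import stats

    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
    )
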