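"""Quantal dose-response curves for honey bee toxicity data.

Two parametric families are supported, in the parameterization used by
benchmark-dose fitting tools for quantal endpoints:

* log-logistic:  ``P(d) = gamma + (1 - gamma) / (1 + exp(-alpha - beta * ln d))``
  for ``d > 0`` and ``P(0) = gamma``; ``alpha`` is the intercept and ``beta``
  the slope on log dose.
* Weibull:       ``P(d) = gamma + (1 - gamma) * (1 - exp(-beta * d**alpha))``;
  ``alpha`` is the shape and ``beta`` the scale.

``gamma`` is the background (control) mortality fraction.  Doses are
cumulative ingested amounts of active ingredient per bee (ng/bee) over a
stated exposure window.  Curves are fitted to quantal laboratory data
(dose, n tested, n dead) by maximizing the binomial log-likelihood.

Lethal concentrations/doses are expressed on the *corrected* mortality
scale: ``lc(curve, p)`` returns the dose at which the background-corrected
mortality ``(P - gamma) / (1 - gamma)`` equals ``p``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

__all__ = [
    "DOSE_FLOOR",
    "DoseResponseCurve",
    "QuantalDataset",
    "FitResult",
    "evaluate_mortality",
    "fit_curve",
    "lc",
    "curve_from_anchor",
]

#: Doses below this floor are treated as zero (avoids ln 0 in the
#: log-logistic form).
DOSE_FLOOR = 1e-12

_FAMILIES = ("loglogistic", "weibull")


@dataclass(frozen=True)
class DoseResponseCurve:
    """A fitted or configured mortality-vs-dose curve.

    Parameters
    ----------
    family:
        ``"loglogistic"`` or ``"weibull"``.
    background:
        Control mortality ``gamma`` in ``[0, 1)``.
    alpha:
        Intercept (log-logistic) or shape (Weibull).  The Weibull shape
        must be positive.
    beta:
        Slope (log-logistic) or scale (Weibull); must be positive.
    window_days:
        Length of the cumulative-exposure window the curve applies to
        (6 for larval chronic, 2 for adult acute, 10 for adult chronic).
    endpoint:
        Free-text label, e.g. ``"larval_chronic"``.
    dose_units:
        Units of the dose axis; cumulative ng active ingredient per bee.
    """

    family: str
    background: float
    alpha: float
    beta: float
    window_days: int
    endpoint: str = ""
    dose_units: str = "ng/bee"

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        if not 0.0 <= self.background < 1.0:
            raise ValueError(f"background must be in [0, 1), got {self.background}")
        if self.beta <= 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if self.family == "weibull" and self.alpha <= 0:
            raise ValueError(f"Weibull shape alpha must be > 0, got {self.alpha}")
        if self.window_days < 1:
            raise ValueError(f"window_days must be >= 1, got {self.window_days}")

    # Convenience wrappers -------------------------------------------------
    def mortality(self, dose):
        return evaluate_mortality(self, dose)

    def lc(self, p: float) -> float:
        return lc(self, p)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "background": self.background,
            "alpha": self.alpha,
            "beta": self.beta,
            "window_days": self.window_days,
            "endpoint": self.endpoint,
            "dose_units": self.dose_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoseResponseCurve":
        return cls(**d)


@dataclass
class QuantalDataset:
    """Laboratory quantal toxicity data: (dose, n tested, n dead) rows."""

    doses: np.ndarray
    n_tested: np.ndarray
    n_dead: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.n_tested = np.asarray(self.n_tested, dtype=int)
        self.n_dead = np.asarray(self.n_dead, dtype=int)
        if not (self.doses.shape == self.n_tested.shape == self.n_dead.shape):
            raise ValueError("doses, n_tested and n_dead must have identical shapes")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")
        if np.any(self.n_dead < 0) or np.any(self.n_dead > self.n_tested):
            raise ValueError("need 0 <= n_dead <= n_tested")

    @classmethod
    def from_records(cls, rows) -> "QuantalDataset":
        rows = list(rows)
        return cls(
            doses=np.array([r[0] for r in rows], dtype=float),
            n_tested=np.array([r[1] for r in rows], dtype=int),
            n_dead=np.array([r[2] for r in rows], dtype=int),
        )

    def __len__(self) -> int:
        return len(self.doses)


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit, with diagnostics."""

    curve: DoseResponseCurve
    log_likelihood: float
    aic: float
    converged: bool
    message: str = ""
    boundary_warning: bool = False
    n_params: int = 3


def evaluate_mortality(curve: DoseResponseCurve, dose):
    """Mortality fraction ``P(d)`` for scalar or array doses.

    Raises on negative doses.  ``P(0) = gamma``; P is non-decreasing in
    dose and bounded by 1.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ValueError("dose must be >= 0")
    g = curve.background
    if curve.family == "loglogistic":
        positive = d > DOSE_FLOOR
        p = np.full(d.shape, g, dtype=float)
        if np.any(positive):
            z = curve.alpha + curve.beta * np.log(d[positive])
            p[positive] = g + (1.0 - g) * expit(z)
    else:  # weibull
        p = g + (1.0 - g) * (-np.expm1(-curve.beta * np.power(d, curve.alpha)))
    if np.ndim(dose) == 0:
        return float(p)
    return p


def lc(curve: DoseResponseCurve, p: float) -> float:
    """Dose at which corrected mortality ``(P - gamma)/(1 - gamma)`` equals ``p``.

    ``p`` must lie strictly between 0 and 1.  Closed forms exist for both
    families; the round trip ``evaluate_mortality(curve, lc(curve, p))``
    reproduces ``gamma + (1 - gamma) * p`` to high precision.
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1) on the corrected scale, got {p}")
    if curve.family == "loglogistic":
        return float(math.exp((logit(p) - curve.alpha) / curve.beta))
    return float((-math.log1p(-p) / curve.beta) ** (1.0 / curve.alpha))


def curve_from_anchor(
    family: str,
    anchor_dose: float,
    anchor_p: float,
    steepness: float,
    background: float = 0.0,
    window_days: int = 1,
    endpoint: str = "",
) -> DoseResponseCurve:
    """Construct a curve passing through one (dose, corrected mortality) anchor.

    ``steepness`` is the log-logistic slope ``beta`` or the Weibull shape
    ``alpha``; the remaining parameter is solved so that the corrected
    mortality at ``anchor_dose`` equals ``anchor_p``.  This is how default
    curves are pinned to published lethal-concentration summaries when the
    full fitted parameter sets are not available.
    """
    if anchor_dose <= 0:
        raise ValueError("anchor_dose must be > 0")
    if not 0.0 < anchor_p < 1.0:
        raise ValueError("anchor_p must be in (0, 1)")
    if family == "loglogistic":
        alpha = float(logit(anchor_p) - steepness * math.log(anchor_dose))
        beta = float(steepness)
    elif family == "weibull":
        alpha = float(steepness)
        beta = float(-math.log1p(-anchor_p) / anchor_dose**steepness)
    else:
        raise ValueError(f"unknown family {family!r}")
    return DoseResponseCurve(
        family=family,
        background=background,
        alpha=alpha,
        beta=beta,
        window_days=window_days,
        endpoint=endpoint,
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _neg_loglik(theta: np.ndarray, data: QuantalDataset, family: str) -> float:
    g = expit(theta[0])
    if family == "loglogistic":
        alpha, beta = theta[1], math.exp(theta[2])
    else:
        alpha, beta = math.exp(theta[1]), math.exp(theta[2])
    try:
        curve = DoseResponseCurve(family, g, alpha, beta, window_days=1)
    except ValueError:
        return 1e12
    p = evaluate_mortality(curve, data.doses)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    ll = data.n_dead * np.log(p) + (data.n_tested - data.n_dead) * np.log1p(-p)
    return float(-np.sum(ll))


def _start_values(data: QuantalDataset, family: str) -> np.ndarray:
    n = np.maximum(data.n_tested, 1)
    frac = data.n_dead / n
    ctrl = data.doses <= DOSE_FLOOR
    g0 = float(np.clip(frac[ctrl].mean() if np.any(ctrl) else 0.02, 1e-3, 0.5))
    pos = data.doses > DOSE_FLOOR
    d = data.doses[pos]
    f = np.clip((frac[pos] - g0) / max(1.0 - g0, 1e-6), 1e-3, 1 - 1e-3)
    if d.size >= 2 and np.ptp(np.log(d)) > 0:
        if family == "loglogistic":
            b, a = np.polyfit(np.log(d), logit(f), 1)
            b = max(b, 0.1)
            return np.array([logit(g0), a, math.log(b)])
        # Weibull: -log(1-f) = beta * d^alpha  =>  log-log regression
        y = np.log(np.maximum(-np.log1p(-f), 1e-9))
        a, lb = np.polyfit(np.log(d), y, 1)
        a = min(max(a, 0.2), 10.0)
        return np.array([logit(g0), math.log(a), np.clip(lb, -30, 30)])
    return np.array([logit(g0), 0.0 if family == "loglogistic" else math.log(1.5), 0.0])


def fit_curve(
    data: QuantalDataset,
    family: str,
    window_days: int = 1,
    endpoint: str = "",
) -> FitResult:
    """Fit a curve to quantal data by maximizing the binomial log-likelihood.

    Requires at least 3 distinct doses including a control (dose 0).
    Returns the fitted curve together with the log-likelihood and AIC so
    that the two families can be compared on the same data.  Degenerate
    data (all dead or all alive) and non-convergence are flagged on the
    result, never silently ignored.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    distinct = np.unique(data.doses)
    if distinct.size < 3:
        raise ValueError("need at least 3 distinct doses")
    if not np.any(data.doses <= DOSE_FLOOR):
        raise ValueError("need a control group (dose 0)")

    boundary = bool(np.all(data.n_dead == data.n_tested) or np.all(data.n_dead == 0))
    if boundary:
        warnings.warn(
            "quantal data lie on the boundary (all dead or all alive); "
            "fitted parameters are not identifiable",
            stacklevel=2,
        )

    theta0 = _start_values(data, family)
    res = minimize(
        _neg_loglik,
        theta0,
        args=(data, family),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    g = float(expit(res.x[0]))
    if family == "loglogistic":
        alpha, beta = float(res.x[1]), float(math.exp(res.x[2]))
    else:
        alpha, beta = float(math.exp(res.x[1])), float(math.exp(res.x[2]))
    curve = DoseResponseCurve(
        family, g, alpha, beta, window_days=window_days, endpoint=endpoint
    )
    ll = -float(res.fun)
    return FitResult(
        curve=curve,
        log_likelihood=ll,
        aic=2 * 3 - 2 * ll,
        converged=bool(res.success),
        message=str(res.message),
        boundary_warning=boundary,
    )


def simulate_quantal(
    curve: DoseResponseCurve,
    doses,
    n_per_dose: int,
    rng: np.random.Generator,
) -> QuantalDataset:
    """Draw binomial deaths from a known curve (parameter-recovery harness)."""
    doses = np.asarray(doses, dtype=float)
    p = np.atleast_1d(evaluate_mortality(curve, doses))
    dead = rng.binomial(n_per_dose, p)
    return QuantalDataset(doses, np.full(doses.shape, n_per_dose), dead)
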