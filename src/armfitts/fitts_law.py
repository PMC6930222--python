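"""Fitts'-law regression and the logarithmic linearization of W = gamma/D.

Fitts' law relates movement duration to the index of difficulty,

    D = a + b log2(2 A / W) = a' + b log2(1 / W),
    a' = a + b (log2 A + 1),

with distance ``A`` and endpoint error (target width) ``W``.  The
dynamics-based model predicts the hyperbola D = gamma / W; a first-order
Taylor expansion of ln(1 + x) around x = 0 with x = c/W - 1 turns 1/W into
an affine function of log2(1/W),

    1/W ~= p1 + p2 log2(1/W),   valid for W >= c/2,
    p1 = (1 + ln c) / c,        p2 = 1 / (c log2 e),

so the model itself takes Fitts'-law form with

    a_model = p1 * gamma,   b_model = p2 * gamma.

Because c > 0 implies p2 > 0, any increase of gamma (more noise, stronger
dynamics coupling) steepens the Fitts'-law slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FittsFit",
    "LinearizationCoeffs",
    "FittsLawRegression",
    "fit_fitts_regression",
    "linearization_coeffs",
    "model_fitts_coeffs",
    "choose_c",
]


@dataclass
class FittsFit:
    """Ordinary-least-squares Fitts'-law fit.

    ``a_prime`` and ``b`` are the intercept (s) and slope (s/bit) of
    D on log2(1/W); ``a`` is the distance-form intercept recovered via
    a = a' - b (log2 A + 1).
    """

    a_prime: float
    b: float
    r2: float
    A: float
    a: float


@dataclass
class LinearizationCoeffs:
    """Coefficients of the 1/W linearization at centre ``c``."""

    c: float
    p1: float
    p2: float
    a_model: float
    b_model: float
    valid_W_min: float


class FittsLawRegression(BaseEstimator, RegressorMixin):
    """Least-squares Fitts'-law fit, scikit-learn style.

    Parameters
    ----------
    A : float
        Movement distance (m), used to convert between the distance form
        (intercept ``a``) and the accuracy form (intercept ``a'``).

    Attributes
    ----------
    a_prime_, b_, r2_, a_ : float
        Fitted intercept, slope, coefficient of determination and the
        distance-form intercept.
    """

    def __init__(self, A: float = 0.15):
        self.A = A

    def fit(self, W, D):
        """Fit D = a' + b log2(1/W) by ordinary least squares."""
        W = np.asarray(W, dtype=float).ravel()
        D = np.asarray(D, dtype=float).ravel()
        if W.size != D.size:
            raise ValueError("W and D must have the same length")
        if W.size < 2:
            raise ValueError("need at least 2 points")
        if np.any(W <= 0):
            raise ValueError("all W must be > 0")
        x = np.log2(1.0 / W)
        res = stats.linregress(x, D)
        self.b_ = float(res.slope)
        self.a_prime_ = float(res.intercept)
        self.r2_ = float(res.rvalue ** 2) if np.ptp(D) > 0 else 1.0
        self.a_ = self.a_prime_ - self.b_ * (np.log2(self.A) + 1.0)
        return self

    def predict(self, W):
        W = np.asarray(W, dtype=float)
        return self.a_prime_ + self.b_ * np.log2(1.0 / W)

    def to_result(self) -> FittsFit:
        return FittsFit(a_prime=self.a_prime_, b=self.b_, r2=self.r2_,
                        A=self.A, a=self.a_)


def fit_fitts_regression(points, A: float) -> FittsFit:
    """Fit Fitts' law to (D, W) pairs (one per duration condition)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return FittsLawRegression(A=A).fit(pts[:, 1], pts[:, 0]).to_result()


def linearization_coeffs(c: float) -> tuple[float, float, float]:
    """(p1, p2, valid_W_min) of the logarithmic linearization at centre c."""
    if c <= 0:
        raise ValueError("c must be > 0")
    p1 = (1.0 + np.log(c)) / c
    p2 = 1.0 / (c * np.log2(np.e))
    return float(p1), float(p2), c / 2.0


def model_fitts_coeffs(gamma_bar: float, c: float) -> LinearizationCoeffs:
    """Fitts'-law coefficients implied by the model, a = p1*gamma, b = p2*gamma."""
    if gamma_bar < 0:
        raise ValueError("gamma_bar must be >= 0")
    p1, p2, wmin = linearization_coeffs(c)
    return LinearizationCoeffs(
        c=float(c), p1=p1, p2=p2,
        a_model=p1 * gamma_bar, b_model=p2 * gamma_bar, valid_W_min=wmin,
    )


def choose_c(w_values, rule: str = "harmonic") -> float:
    """Default linearization centre from observed endpoint errors.

    ``harmonic`` (default) takes the harmonic mean of the observed W,
    clamped to the validity bound 2*min(W); for points on the model curve
    W = gamma/D this centres the linearization at the mean duration, where
    the affine approximation tracks the hyperbola best.  ``minimum``
    returns 2*min(W), which saturates the validity bound W >= c/2.
    """
    w = np.asarray(w_values, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("need at least one W value")
    if np.any(w <= 0):
        raise ValueError("all W must be > 0")
    if rule == "minimum":
        return float(2.0 * w.min())
    if rule != "harmonic":
        raise ValueError("rule must be 'harmonic' or 'minimum'")
    h = w.size / np.sum(1.0 / w)
    return float(min(h, 2.0 * w.min()))
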