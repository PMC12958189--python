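"""Scalar liability-scale math for the threshold model.

An ordinal score k in 1..K is generated by an unobserved Gaussian liability
lambda ~ N(eta, 1) falling between cutpoints t_{k-1} and t_k, with
t_0 = -inf and t_K = +inf.  The residual standard deviation is fixed at 1,
so all quantities here are functions of the record mean ``eta`` and the
cutpoint vector alone.  Both solver families consume this module: the EM
solver needs the truncated-normal conditional mean (imputed liability), the
Newton-Raphson solver needs the score (first derivative of the record
log-likelihood in eta) and the expected-information weight.

All functions accept scalars or numpy arrays for ``eta`` (and ``k``) and
broadcast; cutpoints are a small fixed vector per model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtr

__all__ = [
    "Thresholds",
    "CategoryProbabilities",
    "InvalidThresholdError",
    "category_probabilities",
    "em_imputed_liability",
    "gf_score",
    "gf_weight",
]

# smallest interval probability treated as numerically meaningful
_P_UNDERFLOW = 1e-300
# weight floor guarding against degenerate (flat-likelihood) records
_W_FLOOR = 1e-12
# offset from the truncation boundary returned when the interval mass underflows
_BOUNDARY_EPS = 1e-8


class InvalidThresholdError(ValueError):
    """Raised when a cutpoint vector is not strictly increasing."""


@dataclass(frozen=True)
class Thresholds:
    """Ordered cutpoints on the liability scale.

    ``cuts`` has K-1 elements for K ordinal categories.  The last cutpoint
    is conventionally fixed at 0 for identifiability in national evaluations
    (an equivalent alternative fixes the first at 0); only strict
    monotonicity is enforced here so that rescaled or toy vectors remain
    usable.
    """

    cuts: np.ndarray

    def __init__(self, cuts) -> None:
        arr = np.asarray(cuts, dtype=float).ravel()
        if arr.size == 0:
            raise InvalidThresholdError("at least one cutpoint is required")
        if not np.all(np.diff(arr) > 0):
            raise InvalidThresholdError(
                f"cutpoints must be strictly increasing, got {arr.tolist()}"
            )
        arr.setflags(write=False)
        object.__setattr__(self, "cuts", arr)

    @property
    def n_categories(self) -> int:
        return self.cuts.size + 1

    def scaled(self, factor: float) -> "Thresholds":
        """Return the cutpoints multiplied by a positive scale factor."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Thresholds(self.cuts * factor)

    def bounds(self, k) -> tuple[np.ndarray, np.ndarray]:
        """Lower and upper cutpoints (with infinities) of category ``k`` (1-based)."""
        k = np.asarray(k)
        if np.any((k < 1) | (k > self.n_categories)):
            raise ValueError(f"category out of range 1..{self.n_categories}")
        padded = np.concatenate(([-np.inf], self.cuts, [np.inf]))
        return padded[k - 1], padded[k]


@dataclass(frozen=True)
class CategoryProbabilities:
    """Per-category probabilities for one record given its liability mean."""

    probs: np.ndarray = field()

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.probs, dtype=dtype)

    def __getitem__(self, item):
        return self.probs[item]


def _phi(x):
    """Standard normal density, with density 0 at +/- infinity."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    finite = np.isfinite(x)
    out[finite] = np.exp(-0.5 * x[finite] ** 2) / np.sqrt(2.0 * np.pi)
    return out


def _interval_prob(a, b):
    """Phi(b) - Phi(a) with a complementary-CDF branch for deep upper tails.

    When both bounds sit far in the upper tail, Phi(b) and Phi(a) are both
    ~1 and their difference cancels catastrophically; computing it as
    Phi(-a) - Phi(-b) keeps full relative precision there.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    upper = (a + b) > 0
    out = np.where(upper, ndtr(-a) - ndtr(-b), ndtr(b) - ndtr(a))
    return np.maximum(out, 0.0)


def category_probabilities(eta, t: Thresholds) -> CategoryProbabilities:
    """Probability of each ordinal category given liability mean ``eta``.

    probs[k] = Phi(t_k - eta) - Phi(t_{k-1} - eta), unit residual variance.
    For array ``eta`` of shape (n,) the result has shape (n, K).
    """
    if not isinstance(t, Thresholds):
        t = Thresholds(t)
    eta = np.asarray(eta, dtype=float)
    scalar = eta.ndim == 0
    eta = np.atleast_1d(eta)
    padded = np.concatenate(([-np.inf], t.cuts, [np.inf]))
    a = padded[:-1][None, :] - eta[:, None]
    b = padded[1:][None, :] - eta[:, None]
    p = _interval_prob(a, b)
    return CategoryProbabilities(p[0] if scalar else p)


def _score_terms(eta, k, t: Thresholds):
    """Common pieces: boundary z-values, interval probability, density difference."""
    if not isinstance(t, Thresholds):
        t = Thresholds(t)
    eta = np.asarray(eta, dtype=float)
    k = np.asarray(k, dtype=int)
    lo, hi = t.bounds(k)
    a = lo - eta
    b = hi - eta
    p = _interval_prob(a, b)
    num = _phi(a) - _phi(b)
    return a, b, p, num


def em_imputed_liability(eta, k, t: Thresholds):
    """Conditional mean of the liability given the observed category.

    Returns eta + (phi(a) - phi(b)) / (Phi(b) - Phi(a)) with
    a = t_{k-1} - eta, b = t_k - eta: the mean of a N(eta, 1) variable
    truncated to the category's interval.  Serves as the pseudophenotype in
    the EM solver's next linear round.

    If the interval mass underflows (record mean absurdly far from its
    category) the nearer boundary offset by a small epsilon is returned and
    a warning emitted.
    """
    eta_arr = np.asarray(eta, dtype=float)
    scalar = eta_arr.ndim == 0 and np.asarray(k).ndim == 0
    a, b, p, num = _score_terms(eta_arr, k, t)
    bad = p < _P_UNDERFLOW
    safe_p = np.where(bad, 1.0, p)
    out = eta_arr + num / safe_p
    if np.any(bad):
        warnings.warn(
            f"{int(np.sum(bad))} record(s) with interval probability below "
            f"{_P_UNDERFLOW:g}; imputing the nearer category boundary",
            RuntimeWarning,
            stacklevel=2,
        )
        # mean below the interval -> clamp just inside the lower bound, and
        # symmetrically above; infinite bounds fall back to the finite one
        lo = np.where(np.isfinite(a), a, b) + eta_arr
        hi = np.where(np.isfinite(b), b, a) + eta_arr
        nearer = np.where(np.asarray(a) > 0, lo + _BOUNDARY_EPS, hi - _BOUNDARY_EPS)
        out = np.where(bad, nearer, out)
    return float(out) if scalar else out


def gf_score(eta, k, t: Thresholds):
    """Working score v = (phi(a) - phi(b)) / p_k(eta).

    This is the first derivative of the record's log-likelihood with respect
    to eta, and identically equals ``em_imputed_liability(eta, k, t) - eta``.
    """
    lam = em_imputed_liability(eta, k, t)
    if isinstance(lam, float):
        return lam - float(eta)
    return lam - np.asarray(eta, dtype=float)


def gf_weight(eta, t: Thresholds):
    """Expected-information weight w(eta) = sum_k (phi(a_k)-phi(b_k))^2 / p_k.

    The negative expected second derivative of the record log-likelihood;
    always positive, which keeps the Newton-Raphson system positive
    definite.  Degenerate (numerically flat) records are floored at 1e-12
    with a warning.
    """
    if not isinstance(t, Thresholds):
        t = Thresholds(t)
    eta_arr = np.asarray(eta, dtype=float)
    scalar = eta_arr.ndim == 0
    eta2 = np.atleast_1d(eta_arr)
    padded = np.concatenate(([-np.inf], t.cuts, [np.inf]))
    a = padded[:-1][None, :] - eta2[:, None]
    b = padded[1:][None, :] - eta2[:, None]
    p = _interval_prob(a, b)
    num = _phi(a) - _phi(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, num**2 / np.where(p > 0, p, 1.0), 0.0)
    w = terms.sum(axis=1)
    low = w < _W_FLOOR
    if np.any(low):
        warnings.warn(
            "degenerate record weight floored at 1e-12", RuntimeWarning, stacklevel=2
        )
        w = np.maximum(w, _W_FLOOR)
    return float(w[0]) if scalar else w
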