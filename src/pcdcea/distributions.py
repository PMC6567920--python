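"""Parameter distributions: specification, fitting, and quantile sampling.

Each model input is described by a :class:`DistributionSpec` (family, best
estimate, 95 % interval and family-specific extras).  :func:`fit_distribution`
turns a spec into a :class:`FittedDistribution` exposing ``quantile(u)``, which
is the only primitive the Latin-Hypercube sampler needs.

Fitting conventions
-------------------
* ``beta`` / ``gamma``: the mean is matched exactly to the central estimate and
  a single spread parameter is chosen by least squares so that the 2.5 % and
  97.5 % quantiles reproduce the stated interval as closely as the
  two-parameter family allows; the residual is reported on the fitted object.
* ``normal``: mean = central estimate; ``sd`` is used when given, otherwise it
  is derived from the interval half-width.
* ``lognormal``: parameterized by ``median`` and geometric standard deviation
  ``gsd``; when only an interval is given the spread is fitted.
* ``point``: a degenerate constant; interval fields are ignored.

Draws may be truncated to a support (e.g. probabilities to [0, 1]) by
restricting the uniform input to the feasible quantile range, which preserves
Latin-Hypercube stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Family",
    "DistributionSpec",
    "FittedDistribution",
    "ParameterValidationError",
    "fit_distribution",
]

#: two-sided 95 % normal quantile
Z975 = stats.norm.ppf(0.975)


class ParameterValidationError(ValueError):
    """Raised when a distribution spec is internally inconsistent."""

    def __init__(self, name: str, message: str):
        self.parameter = name
        super().__init__(f"parameter {name!r}: {message}")


class Family(str, Enum):
    BETA = "beta"
    GAMMA = "gamma"
    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    POINT = "point"


@dataclass(frozen=True)
class DistributionSpec:
    """One tabulated model input: family, central estimate and 95 % interval.

    Parameters
    ----------
    family:
        Distribution family (``beta``, ``gamma``, ``normal``, ``lognormal`` or
        ``point``).
    best:
        Best (central) estimate, in the parameter's natural units.  Used
        directly in deterministic runs.
    ci_low, ci_high:
        95 % interval bounds.  Required for every family except ``point``.
    sd:
        Standard deviation (normal family only; optional).
    median, gsd:
        Median and geometric standard deviation (lognormal family).
    mean:
        Optional override of the mean targeted when fitting.  Defaults to
        ``best``; needed when the best estimate sits on the support boundary
        (e.g. a sensitivity of 1.0 with a beta uncertainty distribution).
    bounds:
        Hard support bounds applied to draws, e.g. ``(0.0, 1.0)`` for
        probabilities; ``None`` entries are unbounded.
    """

    family: Family
    best: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    sd: Optional[float] = None
    median: Optional[float] = None
    gsd: Optional[float] = None
    mean: Optional[float] = None
    bounds: Optional[Tuple[Optional[float], Optional[float]]] = None
    name: str = field(default="", compare=False)

    def __post_init__(self):
        object.__setattr__(self, "family", Family(self.family))

    @property
    def is_point(self) -> bool:
        return self.family is Family.POINT

    @property
    def fit_mean(self) -> float:
        return self.best if self.mean is None else self.mean

    def validate(self) -> None:
        label = self.name or "<unnamed>"
        if not np.isfinite(self.best):
            raise ParameterValidationError(label, "best estimate is not finite")
        if self.is_point:
            return
        if self.family is Family.LOGNORMAL and self.median is not None:
            if self.gsd is None or self.gsd <= 1.0:
                raise ParameterValidationError(label, "lognormal gsd must be > 1")
        else:
            if self.ci_low is None or self.ci_high is None:
                raise ParameterValidationError(label, "95% interval required")
            if not (self.ci_low <= self.best <= self.ci_high):
                raise ParameterValidationError(
                    label,
                    f"interval ({self.ci_low}, {self.ci_high}) does not bracket "
                    f"best estimate {self.best}",
                )
        if self.family is Family.BETA:
            m = self.fit_mean
            if not (0.0 < m < 1.0):
                raise ParameterValidationError(
                    label,
                    f"beta mean {m} must lie strictly inside (0, 1); "
                    "use the `mean` override for boundary best estimates",
                )
        if self.family is Family.GAMMA and self.fit_mean <= 0:
            raise ParameterValidationError(label, "gamma mean must be positive")
        if self.bounds is not None:
            lo, hi = self.bounds
            if lo is not None and hi is not None and lo >= hi:
                raise ParameterValidationError(label, "empty support bounds")


class FittedDistribution:
    """A fitted marginal supporting ``quantile(u)`` for u in (0, 1).

    Wraps a frozen scipy distribution (or a constant) with optional support
    truncation implemented by mapping the uniform input into the feasible CDF
    range — a strictly monotone transform, so stratified uniforms stay
    stratified.
    """

    def __init__(self, spec: DistributionSpec, frozen=None, value: float = None,
                 fit_residual: float = 0.0):
        self.spec = spec
        self._frozen = frozen
        self._value = value
        self.fit_residual = float(fit_residual)
        self.truncated = False
        if frozen is not None and spec.bounds is not None:
            lo, hi = spec.bounds
            self._u_lo = float(frozen.cdf(lo)) if lo is not None else 0.0
            self._u_hi = float(frozen.cdf(hi)) if hi is not None else 1.0
            self.truncated = self._u_lo > 0.0 or self._u_hi < 1.0
        else:
            self._u_lo, self._u_hi = 0.0, 1.0

    @property
    def is_point(self) -> bool:
        return self._frozen is None

    def quantile(self, u):
        """Inverse CDF, vectorized; constant for point families."""
        u = np.asarray(u, dtype=float)
        if np.any((u < 0.0) | (u > 1.0)):
            raise ValueError("quantile input must lie in [0, 1]")
        if self._frozen is None:
            out = np.full_like(u, self._value, dtype=float)
            return float(out) if out.ndim == 0 else out
        v = self._u_lo + u * (self._u_hi - self._u_lo)
        x = self._frozen.ppf(v)
        # guard against ppf round-off straying outside the support
        if self.spec.bounds is not None:
            lo, hi = self.spec.bounds
            x = np.clip(x, lo if lo is not None else -np.inf,
                        hi if hi is not None else np.inf)
        return float(x) if np.ndim(x) == 0 else x

    def mean(self) -> float:
        """Analytic mean of the (untruncated) fitted distribution."""
        if self._frozen is None:
            return float(self._value)
        return float(self._frozen.mean())

    def __repr__(self):  # pragma: no cover
        return (f"FittedDistribution({self.spec.family.value}, "
                f"mean={self.mean():.6g}, residual={self.fit_residual:.3g})")


def _quantile_sse(frozen, ci_low: float, ci_high: float) -> float:
    q = frozen.ppf([0.025, 0.975])
    return float((q[0] - ci_low) ** 2 + (q[1] - ci_high) ** 2)


def _fit_spread(make_frozen, ci_low, ci_high, lo=-8.0, hi=18.0):
    """1-D least-squares fit of a log-spread parameter to the 95 % interval."""
    res = optimize.minimize_scalar(
        lambda t: _quantile_sse(make_frozen(t), ci_low, ci_high),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    frozen = make_frozen(res.x)
    return frozen, math.sqrt(_quantile_sse(frozen, ci_low, ci_high))


def fit_distribution(spec: DistributionSpec) -> FittedDistribution:
    """Fit a spec to a sampling-ready distribution (see module docstring).

    Raises
    ------
    ParameterValidationError
        If the spec is inconsistent (e.g. interval not bracketing the mean).
    """
    spec.validate()
    fam = spec.family
    if fam is Family.POINT:
        return FittedDistribution(spec, value=float(spec.best))

    m = spec.fit_mean
    if fam is Family.BETA:
        # alpha = m*nu, beta = (1-m)*nu: mean exact, concentration nu fitted
        def make(t):
            nu = math.exp(t)
            return stats.beta(m * nu, (1.0 - m) * nu)
        frozen, resid = _fit_spread(make, spec.ci_low, spec.ci_high)
    elif fam is Family.GAMMA:
        # shape k, scale m/k: mean exact, shape fitted
        def make(t):
            k = math.exp(t)
            return stats.gamma(k, scale=m / k)
        frozen, resid = _fit_spread(make, spec.ci_low, spec.ci_high)
    elif fam is Family.NORMAL:
        sd = spec.sd if spec.sd is not None else (spec.ci_high - spec.ci_low) / (2 * Z975)
        if sd <= 0:
            raise ParameterValidationError(spec.name or "<unnamed>",
                                           "normal sd must be positive")
        frozen = stats.norm(m, sd)
        resid = (math.sqrt(_quantile_sse(frozen, spec.ci_low, spec.ci_high))
                 if spec.ci_low is not None and spec.ci_high is not None else 0.0)
    elif fam is Family.LOGNORMAL:
        if spec.median is not None:
            frozen = stats.lognorm(math.log(spec.gsd), scale=spec.median)
            resid = (math.sqrt(_quantile_sse(frozen, spec.ci_low, spec.ci_high))
                     if spec.ci_low is not None and spec.ci_high is not None else 0.0)
        else:
            if spec.best <= 0:
                raise ParameterValidationError(spec.name or "<unnamed>",
                                               "lognormal median must be positive")
            def make(t):
                return stats.lognorm(math.exp(t), scale=spec.best)
            frozen, resid = _fit_spread(make, spec.ci_low, spec.ci_high, lo=-10.0, hi=3.0)
    else:  # pragma: no cover
        raise ParameterValidationError(spec.name or "<unnamed>",
                                       f"unknown family {fam}")
    return FittedDistribution(spec, frozen=frozen, fit_residual=resid)
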