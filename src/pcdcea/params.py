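"""Model parameter set: schema, config I/O, fitting and Latin-Hypercube draws.

The parameter set mirrors the published input table: cohort size and disease
prevalence, per-test sensitivity/specificity, and per-test cost inputs, each
carrying a probability distribution.  A flat registry maps dotted parameter
names (``"nno.sensitivity"``, ``"tem_cost.test_duration"``, ...) to
:class:`~pcdcea.distributions.DistributionSpec` objects; everything downstream
(deterministic runs, PSA, tornado) works off that flat namespace.

The shipped default configuration (``data/default_params.yaml``) encodes the
published best estimates, intervals and distribution families verbatim.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .costing import COST_FIELDS, TestCostParams
from .distributions import (DistributionSpec, Family, FittedDistribution,
                            ParameterValidationError, fit_distribution)

__all__ = [
    "TestAccuracy",
    "CohortSpec",
    "ModelParameters",
    "load_config",
    "default_config_path",
    "latin_hypercube_uniforms",
    "sample_lhs",
]

_PROB_BOUNDS = (0.0, 1.0)
_NONNEG_BOUNDS = (0.0, None)


@dataclass(frozen=True)
class TestAccuracy:
    """Sensitivity/specificity for one test, with optional conditional
    (post-positive-screen) variants used when the test confirms a screen."""

    sensitivity: DistributionSpec
    specificity: DistributionSpec
    conditional_sensitivity: Optional[DistributionSpec] = None
    conditional_specificity: Optional[DistributionSpec] = None

    def items(self):
        for name in ("sensitivity", "specificity",
                     "conditional_sensitivity", "conditional_specificity"):
            spec = getattr(self, name)
            if spec is not None:
                yield name, spec

    def validate(self) -> None:
        for name, spec in self.items():
            spec.validate()
            if not (0.0 <= spec.best <= 1.0):
                raise ParameterValidationError(
                    spec.name or name, "probability best estimate outside [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Annual referral cohort: size and disease prevalence."""

    n_referrals: int
    prevalence: DistributionSpec

    def validate(self) -> None:
        if self.n_referrals < 1:
            raise ValueError("n_referrals must be >= 1")
        self.prevalence.validate()

    @property
    def expected_cases(self) -> float:
        """Expected diseased patients at the best-estimate prevalence."""
        return self.n_referrals * self.prevalence.best


@dataclass
class ModelParameters:
    """The full validated parameter set driving every analysis."""

    cohort: CohortSpec
    nno: TestAccuracy
    hsvm: TestAccuracy
    tem: TestAccuracy
    nno_cost: TestCostParams
    hsvm_cost: TestCostParams
    tem_cost: TestCostParams
    n_iterations: int = 3000
    overhead_per_patient: DistributionSpec = field(
        default_factory=lambda: DistributionSpec(
            Family.POINT, 0.0, bounds=_NONNEG_BOUNDS, name="overhead_per_patient"))
    _fitted: Dict[str, FittedDistribution] = field(
        default_factory=dict, repr=False, compare=False)

    TESTS = ("nno", "hsvm", "tem")

    def validate(self) -> None:
        self.cohort.validate()
        for t in self.TESTS:
            self.accuracy(t).validate()
            self.cost(t).validate()
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")

    def accuracy(self, test: str) -> TestAccuracy:
        return getattr(self, test)

    def cost(self, test: str) -> TestCostParams:
        return getattr(self, f"{test}_cost")

    def distributions(self) -> Dict[str, DistributionSpec]:
        """Flat ordered registry of every parameter distribution."""
        reg: Dict[str, DistributionSpec] = {"prevalence": self.cohort.prevalence}
        for t in self.TESTS:
            for name, spec in self.accuracy(t).items():
                reg[f"{t}.{name}"] = spec
        for t in self.TESTS:
            for name, spec in self.cost(t).items():
                reg[f"{t}_cost.{name}"] = spec
        reg["overhead_per_patient"] = self.overhead_per_patient
        return reg

    def fitted(self) -> Dict[str, FittedDistribution]:
        """Fit (and cache) every distribution in the registry."""
        if not self._fitted:
            for name, spec in self.distributions().items():
                self._fitted[name] = fit_distribution(spec)
        return self._fitted

    def uncertain(self) -> Dict[str, FittedDistribution]:
        """Non-degenerate fitted distributions only (the PSA columns)."""
        return {k: d for k, d in self.fitted().items() if not d.is_point}

    def point_values(self) -> Dict[str, float]:
        """Best-estimate value of every parameter (deterministic run)."""
        return {name: spec.best for name, spec in self.distributions().items()}


# ---------------------------------------------------------------------------
# configuration I/O

def default_config_path():
    """Path-like handle on the shipped default parameter file."""
    return resources.files("pcdcea").joinpath("data/default_params.yaml")


_DIST_KEYS = {"family", "best", "ci_low", "ci_high", "sd", "median", "gsd", "mean"}


def _parse_dist(block, name: str, bounds=None) -> DistributionSpec:
    if not isinstance(block, Mapping):
        raise ParameterValidationError(name, "expected a mapping with a 'family' key")
    extra = set(block) - _DIST_KEYS
    if extra:
        raise ParameterValidationError(name, f"unknown keys {sorted(extra)}")
    if "family" not in block or "best" not in block:
        raise ParameterValidationError(name, "keys 'family' and 'best' are required")
    kwargs = {k: block[k] for k in block}
    try:
        spec = DistributionSpec(bounds=bounds, name=name, **kwargs)
    except ValueError as exc:
        raise ParameterValidationError(name, str(exc)) from exc
    spec.validate()
    return spec


def _parse_accuracy(block, test: str) -> TestAccuracy:
    kwargs = {}
    for key in ("sensitivity", "specificity"):
        if key not in block:
            raise ParameterValidationError(f"{test}.{key}", "missing required block")
        kwargs[key] = _parse_dist(block[key], f"{test}.{key}", bounds=_PROB_BOUNDS)
    for key in ("conditional_sensitivity", "conditional_specificity"):
        if key in block and block[key] is not None:
            kwargs[key] = _parse_dist(block[key], f"{test}.{key}", bounds=_PROB_BOUNDS)
    return TestAccuracy(**kwargs)


def _parse_costs(block, test: str) -> TestCostParams:
    kwargs = {}
    for key in COST_FIELDS:
        if key not in block:
            raise ParameterValidationError(f"{test}_cost.{key}", "missing required block")
        kwargs[key] = _parse_dist(block[key], f"{test}_cost.{key}",
                                  bounds=_NONNEG_BOUNDS)
    return TestCostParams(**kwargs)


def load_config(path=None) -> ModelParameters:
    """Load and validate a parameter config (YAML); default when ``path`` is None.

    Raises :class:`ParameterValidationError` naming the offending key on any
    schema violation.
    """
    if path is None:
        raw = default_config_path().read_text()
    else:
        with open(path) as fh:
            raw = fh.read()
    doc = yaml.safe_load(raw)
    if not isinstance(doc, Mapping):
        raise ParameterValidationError("<root>", "config must be a mapping")
    for section in ("cohort", "tests", "costs"):
        if section not in doc:
            raise ParameterValidationError(section, "missing required section")
    cohort_block = doc["cohort"]
    if "n_referrals" not in cohort_block or "prevalence" not in cohort_block:
        raise ParameterValidationError(
            "cohort", "requires 'n_referrals' and 'prevalence'")
    cohort = CohortSpec(int(cohort_block["n_referrals"]),
                        _parse_dist(cohort_block["prevalence"], "prevalence",
                                    bounds=_PROB_BOUNDS))
    tests, costs = {}, {}
    for t in ModelParameters.TESTS:
        if t not in doc["tests"]:
            raise ParameterValidationError(f"tests.{t}", "missing required block")
        if t not in doc["costs"]:
            raise ParameterValidationError(f"costs.{t}", "missing required block")
        tests[t] = _parse_accuracy(doc["tests"][t], t)
        costs[t] = _parse_costs(doc["costs"][t], t)
    overhead = doc.get("overhead_per_patient")
    kwargs = {}
    if overhead is not None:
        kwargs["overhead_per_patient"] = _parse_dist(
            overhead, "overhead_per_patient", bounds=_NONNEG_BOUNDS)
    params = ModelParameters(
        cohort=cohort,
        nno=tests["nno"], hsvm=tests["hsvm"], tem=tests["tem"],
        nno_cost=costs["nno"], hsvm_cost=costs["hsvm"], tem_cost=costs["tem"],
        n_iterations=int(doc.get("n_iterations", 3000)),
        **kwargs,
    )
    params.validate()
    return params


def config_hash(path=None) -> str:
    """SHA-256 of the raw config text (for run manifests)."""
    raw = (default_config_path().read_text() if path is None
           else open(path).read())
    return hashlib.sha256(raw.encode()).hexdigest()


# ---------------------------------------------------------------------------
# Latin-Hypercube sampling

def latin_hypercube_uniforms(n_iter: int, n_params: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Stratified uniforms: one draw per equal-probability stratum per column.

    Each column is an independently permuted set of ``(perm + U)/n`` values,
    so exactly one draw lands in each of the ``n_iter`` strata.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    u = np.empty((n_iter, n_params))
    for j in range(n_params):
        perm = rng.permutation(n_iter)
        u[:, j] = (perm + rng.random(n_iter)) / n_iter
    return u


def sample_lhs(params: ModelParameters, n_iter: Optional[int] = None,
               seed: Optional[int] = None) -> pd.DataFrame:
    """Latin-Hypercube draw table: one column per uncertain parameter.

    Degenerate (point) parameters carry no uncertainty and are omitted; the
    same seed reproduces the table bit for bit.
    """
    if seed is None:
        raise ValueError("an explicit seed is required")
    n_iter = params.n_iterations if n_iter is None else int(n_iter)
    uncertain = params.uncertain()
    rng = np.random.default_rng(seed)
    u = latin_hypercube_uniforms(n_iter, len(uncertain), rng)
    cols = {}
    for j, (name, dist) in enumerate(uncertain.items()):
        cols[name] = dist.quantile(u[:, j])
    frame = pd.DataFrame(cols, index=pd.RangeIndex(n_iter, name="iteration"))
    return frame
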