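"""Expected-value classification of a referral cohort under each algorithm.

A cohort of ``n`` referrals with disease prevalence ``p`` is pushed through a
decision tree in expectation: test outcomes are conditionally independent
given disease status, so each branch probability is a product of
sensitivities/specificities (or their complements).  Counts are kept as real
expected persons; rounding happens only in report writers.

Two derivations of the sequential tree are provided — direct probability-tree
expansion and chained Bayes posteriors — and must agree to float precision;
the second exists as an internal consistency check mirroring how posterior
probabilities propagate through staged testing.

All arithmetic is plain numpy, so every function accepts scalars or aligned
arrays (used by the probabilistic sensitivity analysis engine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "Topology",
    "AlgorithmSpec",
    "ClassificationCounts",
    "NetAccuracy",
    "posterior_positive",
    "posterior_negative",
    "classify_sequential",
    "classify_sequential_bayes",
    "classify_parallel_arbiter",
    "classify_algorithm",
    "net_metrics",
    "test_volumes",
    "PRESETS",
    "DO_NOTHING",
]


class Topology(str, Enum):
    SEQUENTIAL = "sequential"
    PARALLEL_ARBITER = "parallel_arbiter"
    DO_NOTHING = "do_nothing"


@dataclass(frozen=True)
class AlgorithmSpec:
    """Topology of one diagnostic algorithm.

    ``sequential``: ``first_test`` screens everyone, ``second_test`` confirms
    only after a positive screen; a positive call requires both positives.
    ``parallel_arbiter``: ``test_a`` and ``test_b`` run on everyone;
    concordant results decide directly, the ``arbiter`` settles discordance.
    ``do_nothing``: no tests, everyone called negative.
    """

    name: str
    topology: Topology
    first_test: Optional[str] = None
    second_test: Optional[str] = None
    test_a: Optional[str] = None
    test_b: Optional[str] = None
    arbiter: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "topology", Topology(self.topology))
        need = {
            Topology.SEQUENTIAL: ("first_test", "second_test"),
            Topology.PARALLEL_ARBITER: ("test_a", "test_b", "arbiter"),
            Topology.DO_NOTHING: (),
        }[self.topology]
        for f in need:
            if getattr(self, f) is None:
                raise ValueError(f"{self.topology.value} algorithm requires {f}")

    def tests(self) -> Tuple[str, ...]:
        if self.topology is Topology.SEQUENTIAL:
            return (self.first_test, self.second_test)
        if self.topology is Topology.PARALLEL_ARBITER:
            return (self.test_a, self.test_b, self.arbiter)
        return ()

    def shared_brushing_tests(self) -> FrozenSet[str]:
        """Tests whose physician sampling is already covered by another test.

        In the parallel arm the arbiter works on the brushing taken for
        ``test_b``, so its sampling cost is suppressed.
        """
        if self.topology is Topology.PARALLEL_ARBITER:
            return frozenset({self.arbiter})
        return frozenset()


#: the three evaluated algorithms plus the no-testing baseline
PRESETS: Dict[str, AlgorithmSpec] = {
    "nNO+TEM": AlgorithmSpec("nNO+TEM", Topology.SEQUENTIAL,
                             first_test="nno", second_test="tem"),
    "nNO+HSVM": AlgorithmSpec("nNO+HSVM", Topology.SEQUENTIAL,
                              first_test="nno", second_test="hsvm"),
    "nNO/HSVM+TEM": AlgorithmSpec("nNO/HSVM+TEM", Topology.PARALLEL_ARBITER,
                                  test_a="nno", test_b="hsvm", arbiter="tem"),
}
DO_NOTHING = AlgorithmSpec("Do nothing", Topology.DO_NOTHING)


@dataclass(frozen=True)
class ClassificationCounts:
    """Expected persons in each cell of the final 2x2 classification."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def n(self):
        return self.tp + self.fp + self.tn + self.fn

    def check_conservation(self, n, prevalence, atol: float = 1e-9) -> None:
        """Assert cells sum to ``n`` and split exactly by prevalence."""
        np.testing.assert_allclose(self.n, n, atol=atol, rtol=0)
        np.testing.assert_allclose(self.tp + self.fn, np.asarray(n) * prevalence,
                                   atol=atol, rtol=0)
        np.testing.assert_allclose(self.fp + self.tn, np.asarray(n) * (1 - np.asarray(prevalence)),
                                   atol=atol, rtol=0)


@dataclass(frozen=True)
class NetAccuracy:
    """Whole-algorithm accuracy of the final call.

    Metrics with a zero denominator are NaN and listed in ``undefined``
    rather than silently coerced to a number.
    """

    net_sensitivity: float
    net_specificity: float
    ppv: float
    npv: float
    undefined: FrozenSet[str] = field(default_factory=frozenset)


def _check_prob(name, *vals):
    for v in vals:
        if np.any((np.asarray(v) < 0) | (np.asarray(v) > 1)):
            raise ValueError(f"{name} must lie in [0, 1]")


def posterior_positive(prior, sensitivity, specificity):
    """P(disease | test positive) by Bayes' rule.

    Returns 0 where both numerator and denominator vanish (zero prior with a
    perfectly specific test); raises if the denominator alone vanishes.
    """
    _check_prob("posterior_positive arguments", prior, sensitivity, specificity)
    num = np.asarray(prior, dtype=float) * sensitivity
    den = num + (1.0 - np.asarray(prior)) * (1.0 - np.asarray(specificity))
    zero = den == 0.0
    if np.any(zero & (num != 0.0)):  # pragma: no cover - unreachable: num<=den
        raise ZeroDivisionError("positive-test probability is zero")
    if np.any(zero):
        den = np.where(zero, 1.0, den)
        out = num / den
    else:
        out = num / den
    return float(out) if np.ndim(out) == 0 else out


def posterior_negative(prior, sensitivity, specificity):
    """P(disease | test negative) by Bayes' rule (same conventions)."""
    _check_prob("posterior_negative arguments", prior, sensitivity, specificity)
    num = np.asarray(prior, dtype=float) * (1.0 - np.asarray(sensitivity))
    den = num + (1.0 - np.asarray(prior)) * np.asarray(specificity)
    zero = den == 0.0
    if np.any(zero & (num != 0.0)):  # pragma: no cover
        raise ZeroDivisionError("negative-test probability is zero")
    if np.any(zero):
        den = np.where(zero, 1.0, den)
    out = num / den
    return float(out) if np.ndim(out) == 0 else out


def classify_sequential(n, prevalence, sens1, spec1, sens2, spec2) -> ClassificationCounts:
    """Expected 2x2 counts for screen-then-confirm testing.

    A positive call requires both tests positive; a negative screen exits
    without the second test.
    """
    _check_prob("accuracies", prevalence, sens1, spec1, sens2, spec2)
    n = np.asarray(n, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    tp = n * p * sens1 * sens2
    fp = n * (1.0 - p) * (1.0 - np.asarray(spec1)) * (1.0 - np.asarray(spec2))
    fn = n * p - tp
    tn = n * (1.0 - p) - fp
    return ClassificationCounts(_s(tp), _s(fp), _s(tn), _s(fn))


def classify_sequential_bayes(n, prevalence, sens1, spec1, sens2, spec2) -> ClassificationCounts:
    """Same counts derived by chaining posteriors (consistency oracle).

    The posterior after a positive screen becomes the pre-test probability
    for the confirmatory test; marginal branch probabilities recompose the
    expected cell counts.
    """
    _check_prob("accuracies", prevalence, sens1, spec1, sens2, spec2)
    n = np.asarray(n, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    p_pos1 = p * sens1 + (1.0 - p) * (1.0 - np.asarray(spec1))
    post1 = posterior_positive(p, sens1, spec1)
    p_pos2_given_pos1 = np.asarray(post1) * sens2 + (1.0 - np.asarray(post1)) * (1.0 - np.asarray(spec2))
    post2 = posterior_positive(post1, sens2, spec2)
    n_called = n * p_pos1 * p_pos2_given_pos1
    tp = n_called * post2
    fp = n_called - tp
    fn = n * p - tp
    tn = n * (1.0 - p) - fp
    return ClassificationCounts(_s(tp), _s(fp), _s(tn), _s(fn))


def classify_parallel_arbiter(n, prevalence, sens_a, spec_a, sens_b, spec_b,
                              sens_arb, spec_arb) -> ClassificationCounts:
    """Expected counts for parallel testing with an arbiter on discordance.

    Concordant positives are called positive, concordant negatives negative;
    the arbiter's result decides discordant pairs.
    """
    _check_prob("accuracies", prevalence, sens_a, spec_a, sens_b, spec_b,
                sens_arb, spec_arb)
    n = np.asarray(n, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    sa, sb = np.asarray(sens_a, float), np.asarray(sens_b, float)
    ca, cb = np.asarray(spec_a, float), np.asarray(spec_b, float)
    # diseased branch
    disc_d = sa * (1 - sb) + (1 - sa) * sb
    p_call_d = sa * sb + disc_d * np.asarray(sens_arb)
    # non-diseased branch (positive rates are 1-specificity)
    disc_nd = (1 - ca) * cb + ca * (1 - cb)
    p_call_nd = (1 - ca) * (1 - cb) + disc_nd * (1 - np.asarray(spec_arb))
    tp = n * p * p_call_d
    fp = n * (1 - p) * p_call_nd
    fn = n * p - tp
    tn = n * (1 - p) - fp
    return ClassificationCounts(_s(tp), _s(fp), _s(tn), _s(fn))


def _s(x):
    return float(x) if np.ndim(x) == 0 else x


def _accuracy(values: Mapping[str, float], test: str, conditional: bool = False):
    """Look up (sensitivity, specificity), preferring post-positive-screen
    conditional values when requested and present."""
    if conditional:
        s = values.get(f"{test}.conditional_sensitivity")
        c = values.get(f"{test}.conditional_specificity")
        if s is not None and c is not None:
            return s, c
    return values[f"{test}.sensitivity"], values[f"{test}.specificity"]


def classify_algorithm(algorithm: AlgorithmSpec, values: Mapping[str, float],
                       n, prevalence) -> ClassificationCounts:
    """Dispatch classification for any topology from a flat value mapping.

    ``values`` maps parameter names (``"nno.sensitivity"``, ...) to scalars
    or draw vectors.  Sequential second-stage tests use conditional accuracy
    values when configured.
    """
    if algorithm.topology is Topology.DO_NOTHING:
        n = np.asarray(n, dtype=float)
        p = np.asarray(prevalence, dtype=float)
        zero = n * 0.0
        return ClassificationCounts(_s(zero), _s(zero), _s(n * (1 - p)), _s(n * p))
    if algorithm.topology is Topology.SEQUENTIAL:
        s1, c1 = _accuracy(values, algorithm.first_test)
        s2, c2 = _accuracy(values, algorithm.second_test, conditional=True)
        return classify_sequential(n, prevalence, s1, c1, s2, c2)
    s_a, c_a = _accuracy(values, algorithm.test_a)
    s_b, c_b = _accuracy(values, algorithm.test_b)
    s_x, c_x = _accuracy(values, algorithm.arbiter)
    return classify_parallel_arbiter(n, prevalence, s_a, c_a, s_b, c_b, s_x, c_x)


def net_metrics(counts: ClassificationCounts) -> NetAccuracy:
    """Net sensitivity/specificity and predictive values of the final call."""
    pairs = {
        "net_sensitivity": (counts.tp, counts.tp + counts.fn),
        "net_specificity": (counts.tn, counts.tn + counts.fp),
        "ppv": (counts.tp, counts.tp + counts.fp),
        "npv": (counts.tn, counts.tn + counts.fn),
    }
    out, undef = {}, set()
    for name, (num, den) in pairs.items():
        if np.ndim(den) == 0 and den == 0:
            out[name] = float("nan")
            undef.add(name)
        else:
            out[name] = _s(np.asarray(num, float) / den)
    return NetAccuracy(undefined=frozenset(undef), **out)


def test_volumes(algorithm: AlgorithmSpec, values: Mapping[str, float],
                 n, prevalence) -> Dict[str, float]:
    """Expected number of each test performed per year.

    Sequential: screen on everyone, confirmation on expected screen
    positives.  Parallel: both first-line tests on everyone, arbiter on the
    expected discordant mass.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(prevalence, dtype=float)
    if algorithm.topology is Topology.DO_NOTHING:
        return {}
    if algorithm.topology is Topology.SEQUENTIAL:
        s1, c1 = _accuracy(values, algorithm.first_test)
        pos1 = n * (p * np.asarray(s1) + (1 - p) * (1 - np.asarray(c1)))
        return {algorithm.first_test: _s(n + 0.0 * pos1),
                algorithm.second_test: _s(pos1)}
    s_a, c_a = _accuracy(values, algorithm.test_a)
    s_b, c_b = _accuracy(values, algorithm.test_b)
    sa, sb = np.asarray(s_a, float), np.asarray(s_b, float)
    ca, cb = np.asarray(c_a, float), np.asarray(c_b, float)
    disc = n * (p * (sa * (1 - sb) + (1 - sa) * sb)
                + (1 - p) * ((1 - ca) * cb + ca * (1 - cb)))
    full = _s(n + 0.0 * disc)
    return {algorithm.test_a: full, algorithm.test_b: full,
            algorithm.arbiter: _s(disc)}
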