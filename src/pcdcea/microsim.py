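"""Patient-level Bernoulli microsimulation of the diagnostic pathways.

Serves two roles: a synthetic-data generator (per-patient disease states,
test results and final calls) and a brute-force oracle whose empirical cell
frequencies must converge to the analytic expected-value tree — the central
cross-check between the two computation routes.

Random streams are keyed hierarchically by (seed, test name), so every
algorithm sharing a test sees identical per-patient results for it and
adding a strategy never perturbs another's draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .decision import AlgorithmSpec, ClassificationCounts, Topology, _accuracy

__all__ = ["SyntheticCohort", "generate_cohort", "simulate_algorithm"]


@dataclass
class SyntheticCohort:
    """Per-patient simulation record for one algorithm."""

    disease: np.ndarray            # bool, True = diseased
    results: Dict[str, np.ndarray]  # test -> bool result (only where administered)
    administered: Dict[str, np.ndarray]  # test -> bool mask
    call: np.ndarray               # bool final call

    @property
    def n(self) -> int:
        return self.disease.size

    def counts(self) -> ClassificationCounts:
        """Integer classification cell counts."""
        d, c = self.disease, self.call
        return ClassificationCounts(
            tp=int(np.sum(c & d)), fp=int(np.sum(c & ~d)),
            tn=int(np.sum(~c & ~d)), fn=int(np.sum(~c & d)))

    def volumes(self) -> Dict[str, int]:
        """Number of each test actually administered."""
        return {t: int(m.sum()) for t, m in self.administered.items()}

    def to_frame(self) -> pd.DataFrame:
        """Per-patient table for export/debugging (NA = not administered)."""
        out = pd.DataFrame({"patient": np.arange(self.n),
                            "disease": self.disease})
        for t, mask in self.administered.items():
            col = pd.array(self.results[t], dtype="boolean")
            col[~mask] = pd.NA
            out[t] = col
        out["call"] = self.call
        return out


def generate_cohort(n: int, prevalence: float, seed: int) -> np.ndarray:
    """i.i.d. Bernoulli(prevalence) disease states for ``n`` patients."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _key("disease"))))
    return rng.random(n) < prevalence


def _key(label: str) -> int:
    # stable across processes (unlike hash())
    return zlib.crc32(label.encode())


def _test_stream(seed: int, test: str, n: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), _key(test))))
    return rng.random(n)


def _result(u: np.ndarray, disease: np.ndarray, sens, spec) -> np.ndarray:
    # one uniform per patient per test; positive with P=sens (diseased)
    # or P=1-spec (healthy)
    return np.where(disease, u < sens, u < (1.0 - spec))


def simulate_algorithm(disease: np.ndarray, algorithm: AlgorithmSpec,
                       values: Mapping[str, float], seed: int) -> SyntheticCohort:
    """Simulate every patient through one algorithm's decision tree.

    ``values`` is the flat parameter mapping used by the analytic model;
    conditional (post-positive-screen) accuracies apply to sequential
    second-stage tests exactly as in the analytic route.
    """
    disease = np.asarray(disease, dtype=bool)
    n = disease.size
    results: Dict[str, np.ndarray] = {}
    administered: Dict[str, np.ndarray] = {}
    if algorithm.topology is Topology.DO_NOTHING:
        call = np.zeros(n, dtype=bool)
    elif algorithm.topology is Topology.SEQUENTIAL:
        t1, t2 = algorithm.first_test, algorithm.second_test
        s1, c1 = _accuracy(values, t1)
        s2, c2 = _accuracy(values, t2, conditional=True)
        r1 = _result(_test_stream(seed, t1, n), disease, s1, c1)
        r2 = _result(_test_stream(seed, t2, n), disease, s2, c2)
        administered = {t1: np.ones(n, dtype=bool), t2: r1.copy()}
        r2 &= r1  # second test only meaningful after a positive screen
        results = {t1: r1, t2: r2}
        call = r1 & r2
    else:
        ta, tb, tx = algorithm.test_a, algorithm.test_b, algorithm.arbiter
        sa, ca = _accuracy(values, ta)
        sb, cb = _accuracy(values, tb)
        sx, cx = _accuracy(values, tx)
        ra = _result(_test_stream(seed, ta, n), disease, sa, ca)
        rb = _result(_test_stream(seed, tb, n), disease, sb, cb)
        rx = _result(_test_stream(seed, tx, n), disease, sx, cx)
        discordant = ra ^ rb
        administered = {ta: np.ones(n, dtype=bool),
                        tb: np.ones(n, dtype=bool),
                        tx: discordant}
        rx &= discordant
        results = {ta: ra, tb: rb, tx: rx}
        call = (ra & rb) | (discordant & rx)
    return SyntheticCohort(disease=disease, results=results,
                           administered=administered, call=call)
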