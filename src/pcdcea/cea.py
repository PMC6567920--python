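"""Cost-effectiveness statistics: CER/ICER, dominance frontier, CEAC, tornado.

Estimator note: with Monte-Carlo output a cost-effectiveness ratio can be
computed as ratio-of-means or as the mean of per-iteration ratios; the two
differ for skewed draws.  Both are reported — mean-of-ratios (with percentile
interval) as the headline figure, ratio-of-means alongside — because the
choice is consequential and should be visible.  Per-iteration ratios with a
zero effect difference are undefined; they are excluded from the mean and
counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .psa import PSAResult

__all__ = [
    "ZeroEffectDifferenceError",
    "icer",
    "StrategyOutcome",
    "DominanceStatus",
    "FrontierEntry",
    "build_frontier",
    "CEACCurve",
    "ceac",
    "RatioSummary",
    "ratio_summary",
    "cer_table",
    "TornadoEntry",
    "tornado",
]


class ZeroEffectDifferenceError(ZeroDivisionError):
    """An ICER is undefined when the strategies' effects coincide."""


def icer(cost_a, cost_b, effect_a, effect_b) -> float:
    """Incremental cost per incremental unit of effect, A versus B."""
    de = effect_a - effect_b
    if de == 0:
        raise ZeroEffectDifferenceError(
            "effect difference is zero; ICER undefined")
    return (cost_a - cost_b) / de


@dataclass(frozen=True)
class StrategyOutcome:
    """A strategy's (mean) cost and effect point for frontier analysis."""

    name: str
    cost: float
    effect: float


class DominanceStatus(str, Enum):
    ON_FRONTIER = "on_frontier"
    SIMPLY_DOMINATED = "simply_dominated"
    EXTENDEDLY_DOMINATED = "extendedly_dominated"


@dataclass(frozen=True)
class FrontierEntry:
    strategy: str
    status: DominanceStatus
    icer_vs_previous: Optional[float]  # None for the frontier's first entry


def _simply_dominated(s: StrategyOutcome, others: Sequence[StrategyOutcome]) -> bool:
    for t in others:
        if t.name == s.name:
            continue
        if t.cost < s.cost and t.effect >= s.effect:
            return True
        if t.cost <= s.cost and t.effect > s.effect:
            return True
        # exact tie: keep the lexicographically first name
        if t.cost == s.cost and t.effect == s.effect and t.name < s.name:
            return True
    return False


def build_frontier(strategies: Sequence[StrategyOutcome]) -> List[FrontierEntry]:
    """Dominance-pruned cost-effectiveness frontier.

    Simple dominance (costlier, no more effective) is removed first; then
    strategies breaking the strictly-increasing ICER order along the
    effect-sorted remainder are removed iteratively (extended dominance).
    Returned entries are sorted by increasing effect, dominated strategies
    included with their status; ``icer_vs_previous`` links adjacent frontier
    members.
    """
    if len(strategies) < 2:
        raise ValueError("need at least two strategies")
    status: Dict[str, DominanceStatus] = {}
    for s in strategies:
        if _simply_dominated(s, strategies):
            status[s.name] = DominanceStatus.SIMPLY_DOMINATED
    frontier = sorted((s for s in strategies if s.name not in status),
                      key=lambda s: (s.effect, s.cost, s.name))
    # iteratively drop the interior point that breaks strict ICER increase
    while True:
        icers = [icer(b.cost, a.cost, b.effect, a.effect)
                 for a, b in zip(frontier, frontier[1:])]
        drop = None
        for k in range(len(icers) - 1):
            if icers[k] >= icers[k + 1]:
                drop = k + 1
                break
        if drop is None:
            break
        status[frontier[drop].name] = DominanceStatus.EXTENDEDLY_DOMINATED
        del frontier[drop]
    entries: List[FrontierEntry] = []
    prev: Optional[StrategyOutcome] = None
    for s in sorted(strategies, key=lambda s: (s.effect, s.cost, s.name)):
        st = status.get(s.name, DominanceStatus.ON_FRONTIER)
        ic = None
        if st is DominanceStatus.ON_FRONTIER:
            if prev is not None:
                ic = icer(s.cost, prev.cost, s.effect, prev.effect)
            prev = s
        entries.append(FrontierEntry(s.name, st, ic))
    return entries


@dataclass(frozen=True)
class CEACCurve:
    """P(strategy cost-effective vs comparator) over a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def ceac(psa: PSAResult, strategy: str, comparator: str,
         wtp_grid: Sequence[float]) -> CEACCurve:
    """Acceptability curve from incremental net monetary benefit.

    At each threshold λ the probability is the fraction of iterations with
    ``λ·Δeffect − Δcost >= 0`` (ties count as cost-effective).
    """
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid is empty")
    for s in (strategy, comparator):
        if s not in psa.strategies:
            raise KeyError(f"strategy {s!r} not in PSA table")
    d_cost = (psa.costs[strategy] - psa.costs[comparator]).to_numpy()
    d_eff = (psa.effects[strategy] - psa.effects[comparator]).to_numpy()
    nmb = grid[:, None] * d_eff[None, :] - d_cost[None, :]
    prob = (nmb >= 0).mean(axis=1)
    return CEACCurve(grid, prob)


@dataclass(frozen=True)
class RatioSummary:
    """Both estimators of a cost-per-effect ratio over PSA iterations."""

    mean_of_ratios: float
    ratio_ci: Tuple[float, float]
    ratio_of_means: float
    n_excluded: int  # iterations with zero effect difference


def ratio_summary(d_cost: np.ndarray, d_effect: np.ndarray) -> RatioSummary:
    d_cost = np.asarray(d_cost, float)
    d_effect = np.asarray(d_effect, float)
    keep = d_effect != 0
    ratios = d_cost[keep] / d_effect[keep]
    if ratios.size == 0:
        raise ZeroEffectDifferenceError("every iteration has zero effect difference")
    mean_de = d_effect.mean()
    rom = d_cost.mean() / mean_de if mean_de != 0 else float("nan")
    return RatioSummary(
        mean_of_ratios=float(ratios.mean()),
        ratio_ci=(float(np.percentile(ratios, 2.5)),
                  float(np.percentile(ratios, 97.5))),
        ratio_of_means=float(rom),
        n_excluded=int((~keep).sum()),
    )


def cer_table(psa: PSAResult, comparator: str = "Do nothing") -> pd.DataFrame:
    """Cost-per-case-identified of each strategy versus the baseline."""
    rows = []
    for s in psa.strategies:
        if s == comparator:
            continue
        summ = ratio_summary(
            (psa.costs[s] - psa.costs[comparator]).to_numpy(),
            (psa.effects[s] - psa.effects[comparator]).to_numpy(),
        )
        rows.append({
            "strategy": s,
            "cer_mean_of_ratios": summ.mean_of_ratios,
            "cer_lo": summ.ratio_ci[0],
            "cer_hi": summ.ratio_ci[1],
            "cer_ratio_of_means": summ.ratio_of_means,
            "n_excluded": summ.n_excluded,
        })
    return pd.DataFrame(rows).set_index("strategy")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_low: float
    icer_at_high: float

    @property
    def span(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


def tornado(params, strategy, comparator,
            parameters: Optional[Sequence[str]] = None) -> List[TornadoEntry]:
    """One-way sensitivity of the deterministic ICER between two strategies.

    Each uncertain parameter is set in turn to its interval endpoints with
    everything else at the best estimate; entries come back sorted by
    descending span.  ``strategy``/``comparator`` are algorithm specs.
    """
    from .psa import evaluate_strategy  # local import to keep module surface flat

    registry = params.distributions()
    if parameters is None:
        parameters = [name for name, spec in registry.items() if not spec.is_point]
    base = params.point_values()
    overhead = base.pop("overhead_per_patient", 0.0)
    n = params.cohort.n_referrals

    def _icer_at(values) -> float:
        a = evaluate_strategy(strategy, values, n, overhead)
        b = evaluate_strategy(comparator, values, n, overhead)
        return icer(a.total_cost, b.total_cost, a.effect, b.effect)

    entries = []
    for name in parameters:
        spec = registry[name]
        lows, highs = spec.ci_low, spec.ci_high
        if spec.is_point or lows is None or highs is None:
            lo = hi = _icer_at(base)
        else:
            lo = _icer_at({**base, name: lows})
            hi = _icer_at({**base, name: highs})
        entries.append(TornadoEntry(name, lo, hi))
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries
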