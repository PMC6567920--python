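"""Report writers shaping results into publication-style tables."""

from __future__ import annotations

from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from . import cea
from .decision import net_metrics
from .psa import PSAResult, StrategyResult, summarize_draws

__all__ = ["format_percent", "classification_table", "outcomes_table"]


def format_percent(p: float) -> str:
    """Percentage rounded the way the accuracy table prints it:
    whole percent, except one decimal in the 99–100 % band."""
    if not np.isfinite(p):
        return "undefined"
    pct = p * 100.0
    if 99.0 <= pct < 99.95:
        return f"{pct:.1f}%"
    return f"{pct:.0f}%"


def classification_table(results: Mapping[str, StrategyResult]) -> pd.DataFrame:
    """Accuracy table: one column per algorithm, cells + net metrics."""
    rows: Dict[str, Dict[str, str]] = {}
    for name, res in results.items():
        c = res.counts
        m = net_metrics(c)
        diseased = c.tp + c.fn
        healthy = c.tn + c.fp
        col = {
            "diseased called positive": f"{c.tp:.1f} ({format_percent(c.tp / diseased)})",
            "diseased called negative": f"{c.fn:.1f} ({format_percent(c.fn / diseased)})",
            "healthy called negative": f"{c.tn:.1f} ({format_percent(c.tn / healthy)})",
            "healthy called positive": f"{c.fp:.1f} ({format_percent(c.fp / healthy)})",
            "net sensitivity": format_percent(m.net_sensitivity),
            "net specificity": format_percent(m.net_specificity),
            "net PPV": format_percent(m.ppv),
            "net NPV": format_percent(m.npv),
        }
        rows[name] = col
    return pd.DataFrame(rows)


def outcomes_table(psa: PSAResult, comparator: str = "Do nothing") -> pd.DataFrame:
    """Cost/effect summary with CERs, frontier ICERs and dominance flags."""
    summary = summarize_draws(psa)
    cers = cea.cer_table(psa, comparator=comparator)
    outcomes = [cea.StrategyOutcome(s, summary.loc[s, "mean_cost"],
                                    summary.loc[s, "mean_effect"])
                for s in psa.strategies]
    frontier = {e.strategy: e for e in cea.build_frontier(outcomes)}
    rows = []
    for s in psa.strategies:
        entry = frontier[s]
        row = {
            "strategy": s,
            "mean_cost": summary.loc[s, "mean_cost"],
            "cost_lo": summary.loc[s, "cost_lo"],
            "cost_hi": summary.loc[s, "cost_hi"],
            "mean_effect": summary.loc[s, "mean_effect"],
            "effect_lo": summary.loc[s, "effect_lo"],
            "effect_hi": summary.loc[s, "effect_hi"],
            "dominance": entry.status.value,
            "icer_vs_previous": (np.nan if entry.icer_vs_previous is None
                                 else entry.icer_vs_previous),
        }
        if s in cers.index:
            row["cer_mean_of_ratios"] = cers.loc[s, "cer_mean_of_ratios"]
            row["cer_lo"] = cers.loc[s, "cer_lo"]
            row["cer_hi"] = cers.loc[s, "cer_hi"]
            row["cer_ratio_of_means"] = cers.loc[s, "cer_ratio_of_means"]
        else:
            row.update({"cer_mean_of_ratios": np.nan, "cer_lo": np.nan,
                        "cer_hi": np.nan, "cer_ratio_of_means": np.nan})
        rows.append(row)
    return pd.DataFrame(rows).set_index("strategy")
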