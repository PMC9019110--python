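"""Tissue-specificity index τ over a tissue panel.

τ summarizes how concentrated a gene's expression is across tissues:

    x_i   = log2(value_i + pseudocount)
    x̂_i  = x_i / max_j(x_j)
    τ     = Σ_i (1 − x̂_i) / (n − 1)

τ = 1 means expression confined to a single tissue, τ = 0 uniform
expression.  Values enter on the linear scale after replicate averaging;
several brain sub-regions may first be collapsed into one panel entry by
averaging on the log scale (mean of log2(TPM+1), not log of the mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["TissuePanel", "SpecificityResult", "collapse_brain", "tau", "specificity_report"]


@dataclass(frozen=True)
class TissuePanel:
    """Log-scale per-tissue values for one metric, after optional collapsing."""

    metric: str
    values: Mapping[str, float]  # tissue -> log2(value + pseudocount)
    pseudocount: float = 1.0
    collapsed_brain: bool = False

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SpecificityResult:
    metric: str
    tau: float
    n_tissues: int
    pseudocount: float
    collapsed_brain: bool
    silent: bool = False  # gene unexpressed in every tissue (tau conventionally 0)


def collapse_brain(
    linear_values: Mapping[str, float],
    brain_tissues: set[str] | frozenset[str],
    pseudocount: float = 1.0,
    metric: str = "",
    brain_label: str = "brain",
) -> TissuePanel:
    """Log-transform a linear tissue→value map and collapse brain tissues.

    Every tissue value becomes log2(value + pseudocount); the named brain
    tissues are replaced by a single entry holding their arithmetic mean
    on the log scale.  An empty brain set leaves the panel unchanged
    except for the log transform.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    brain = set(brain_tissues)
    missing = brain - set(linear_values)
    if missing:
        raise KeyError(f"brain tissue(s) absent from panel: {sorted(missing)}")
    logged = {t: float(np.log2(v + pseudocount)) for t, v in linear_values.items()}
    if brain:
        brain_mean = float(np.mean([logged.pop(t) for t in sorted(brain)]))
        logged = {brain_label: brain_mean, **logged}
    return TissuePanel(
        metric=metric, values=logged, pseudocount=pseudocount, collapsed_brain=bool(brain)
    )


def tau(panel: TissuePanel) -> SpecificityResult:
    """Tissue-specificity index of a log-scale panel.

    Requires at least two tissues.  A gene silent in every tissue
    (max x_i = 0) has τ defined as 0 and flagged ``silent``.
    """
    x = np.asarray(list(panel.values.values()), dtype=float)
    if x.size < 2:
        raise ValueError("tau needs a panel of at least two tissues")
    if np.any(x < 0):
        raise ValueError("log-scale panel values must be non-negative")
    xmax = float(x.max())
    if xmax == 0:
        return SpecificityResult(
            metric=panel.metric,
            tau=0.0,
            n_tissues=panel.n,
            pseudocount=panel.pseudocount,
            collapsed_brain=panel.collapsed_brain,
            silent=True,
        )
    t = float(np.sum(1.0 - x / xmax) / (x.size - 1))
    return SpecificityResult(
        metric=panel.metric,
        tau=t,
        n_tissues=panel.n,
        pseudocount=panel.pseudocount,
        collapsed_brain=panel.collapsed_brain,
    )


def specificity_report(panels: Mapping[str, TissuePanel]) -> pd.DataFrame:
    """One τ per metric over identically-collapsed panels, plus pairwise
    differences (columns ``delta_vs_<metric>``)."""
    if not panels:
        raise ValueError("no panels given")
    tissue_sets = {frozenset(p.values) for p in panels.values()}
    if len(tissue_sets) > 1:
        raise ValueError("panels have mismatched tissue sets")
    results = {name: tau(p) for name, p in panels.items()}
    rows = []
    for name, res in results.items():
        row = {
            "metric": name,
            "tau": res.tau,
            "n_tissues": res.n_tissues,
            "pseudocount": res.pseudocount,
            "collapsed_brain": res.collapsed_brain,
        }
        for other, ores in results.items():
            if other != name:
                row[f"delta_vs_{other}"] = res.tau - ores.tau
        rows.append(row)
    return pd.DataFrame(rows).sort_values("tau", ascending=False).reset_index(drop=True)
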