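"""Proportion statistics and run reporting.

Apoptotic fractions are compared across scenarios with pairwise Pearson
chi-square tests on 2x2 tables (no continuity correction; at ensemble
sizes of thousands the Yates correction is immaterial) with Bonferroni
adjustment over the stated comparison family, and summarized with
asymptotic-normal (Wald) 95% confidence intervals.  The Wald interval
collapses to zero width at k = 0 or k = n; this boundary behavior is a
documented property of the method, not a bug.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from itertools import combinations
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.proportion import proportion_confint

if TYPE_CHECKING:  # pragma: no cover
    from .experiments import ScenarioResult

__all__ = [
    "proportion_ci",
    "significance_tier",
    "ProportionComparison",
    "pairwise_chisq",
    "build_report",
    "write_report",
]


def proportion_ci(k: int, n: int, level: float = 0.95,
                  method: str = "normal") -> tuple[float, float]:
    """Confidence interval for a proportion, clipped to [0, 1].

    Default is the asymptotic-normal (Wald) interval
    p_hat +/- z * sqrt(p_hat (1 - p_hat) / n); ``method="wilson"``
    selects the score interval for callers worried about boundary
    pathologies (never the default).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1.0 - level, method=method)
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def significance_tier(p: float) -> str:
    """Figure-legend style tier: *** / ** / * / n.s."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


@dataclasses.dataclass(frozen=True)
class ProportionComparison:
    """One pairwise chi-square comparison of apoptotic proportions."""

    pair: tuple[str, str]
    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_raw: float
    p_adjusted: float
    tier: str


def pairwise_chisq(results: Sequence["ScenarioResult"],
                   correction_family_size: int | None = None,
                   ) -> list[ProportionComparison]:
    """All pairwise Pearson chi-square tests on the scenario 2x2 tables.

    Bonferroni multiplier defaults to the number of pairs actually
    tested; pass ``correction_family_size`` to use a pre-registered
    family size instead.
    """
    if len(results) < 2:
        raise ValueError("need at least two scenario results")
    pairs = list(combinations(results, 2))
    m = correction_family_size if correction_family_size is not None \
        else len(pairs)
    out = []
    for a, b in pairs:
        table = np.array([[a.n_apoptotic, a.n - a.n_apoptotic],
                          [b.n_apoptotic, b.n - b.n_apoptotic]])
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            warnings.warn(f"zero-margin table for {a.name} vs {b.name}; "
                          "reporting p = 1", stacklevel=2)
            stat, p = 0.0, 1.0
        elif (table[0] == table[1]).all():
            stat, p = 0.0, 1.0  # identical counts: no association
        else:
            stat, p, _, _ = chi2_contingency(table, correction=False)
        p_adj = min(1.0, m * p)
        out.append(ProportionComparison(
            pair=(a.name, b.name),
            table=tuple(map(tuple, table.tolist())),
            statistic=float(stat), p_raw=float(p), p_adjusted=p_adj,
            tier=significance_tier(p_adj)))
    return out


def comparisons_frame(comparisons: Sequence[ProportionComparison],
                      ) -> pd.DataFrame:
    return pd.DataFrame([
        {"scenario_a": c.pair[0], "scenario_b": c.pair[1],
         "chi2": c.statistic, "p_raw": c.p_raw,
         "p_adjusted": c.p_adjusted, "tier": c.tier}
        for c in comparisons])


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if isinstance(obj, float) and not np.isfinite(obj):
        return str(obj)
    return obj


def build_report(stages: dict, seed: int | None = None) -> dict:
    """Machine-readable summary of a pipeline run.

    ``stages`` maps stage names (e.g. ``scenarios``, ``windows``,
    ``goldenhour``, ``sensitivity``, ``perturbation``) to their result
    objects; at least one completed stage is required.
    """
    if not stages:
        raise ValueError(
            "no completed stages to report; expected at least one of "
            "scenarios/windows/goldenhour/sensitivity/perturbation")
    from . import __version__

    report: dict = {"version": __version__, "seed": seed, "stages": {}}
    for name, obj in stages.items():
        entry = _jsonable(obj)
        # Scenario runs carry large per-variant tables; keep the summary.
        if hasattr(obj, "results") and hasattr(obj, "degenerate_counts"):
            comps = pairwise_chisq(list(obj.results))
            entry = {
                "fractions": {r.name: {"n": r.n, "k": r.n_apoptotic,
                                       "fraction": r.fraction,
                                       "ci": list(r.ci)}
                              for r in obj.results},
                "n_total": obj.n_total,
                "n_excluded": len(obj.excluded),
                "degenerate_counts": obj.degenerate_counts,
                "comparisons": _jsonable(comparisons_frame(comps)),
                "attribution": _jsonable(obj.attribution()),
            }
        report["stages"][name] = entry
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
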