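"""In-silico experiments: scenario ensembles, viability windows,
knockdown/overexpression populations, local sensitivity, and the
golden-hour (stress-duration threshold) analysis.

Unless stated otherwise every experiment uses the standard protocol —
ischemic stress applied from 0 to 24 h of a 48 h simulation, each cell
started from its own unstressed steady state — and classifies a cell as
apoptotic when its Caspase-3 level exceeds 0.5 at 48 h.

Degenerate variants (no resting autophagosome balance) are excluded from
ensemble denominators, identically across paired scenarios, and their
counts are reported.  Cells with zero resting autophagic flux (possible
only in noise-truncated perturbation populations, where basal Beclin-1
expression can be driven to zero) are counted as apoptotic: without any
flux, damaged mitochondria accumulate without bound and Caspase-3
commitment is inevitable.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _kernels, stats_io
from .ensemble import (CANONICAL_SCENARIOS, ScenarioSpec, VariantEnsemble,
                       apply_scenario, perturbed_population)
from .model_core import (PARAM_NAMES, ParameterSet, StressProtocol,
                         classify_apoptosis, simulate,
                         unstressed_steady_state, DegenerateVariantError)

__all__ = [
    "APOPTOSIS_THRESHOLD",
    "ScenarioResult",
    "ScenarioRun",
    "ViabilityWindow",
    "GoldenHourResult",
    "NonContiguousSurvivalError",
    "STRESS_BANDS",
    "scenario_fractions",
    "stratified_apoptosis",
    "viability_window",
    "perturbation_experiment",
    "local_sensitivity",
    "duration_threshold",
    "intervention_panel",
]

APOPTOSIS_THRESHOLD = 0.5

#: Stress-severity bands used for stratified summaries; sampling extends
#: to S = 10, so variants beyond the severe band are reported in an
#: explicit extra band rather than dropped.
STRESS_BANDS: tuple[tuple[str, float, float], ...] = (
    ("mild", 0.0, 1.0),
    ("moderate", 1.0, 2.5),
    ("severe", 2.5, 5.0),
    ("extreme", 5.0, 10.0),
)

#: Integration tolerances for large ensemble sweeps (the compiled
#: adaptive RK integrator); classification is insensitive to a further
#: tightening, which the test suite verifies.
ENSEMBLE_RTOL = 1e-6
ENSEMBLE_ATOL = 1e-9


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    """Apoptotic fraction of one scenario with a 95% Wald interval."""

    name: str
    n: int
    n_apoptotic: int
    fraction: float
    ci: tuple[float, float]


@dataclasses.dataclass(frozen=True)
class ScenarioRun:
    """Paired multi-scenario ensemble run.

    ``outcomes`` holds the per-variant apoptosis calls (rows = variants
    retained after exclusion, columns = scenarios) so that systematic
    differences between scenarios can be attributed to per-variant
    outcome flips.
    """

    results: tuple[ScenarioResult, ...]
    outcomes: pd.DataFrame
    variants: pd.DataFrame  # S and alpha_B of the retained variants
    n_total: int
    excluded: tuple[int, ...]
    degenerate_counts: dict[str, int]

    def result(self, name: str) -> ScenarioResult:
        for r in self.results:
            if r.name == name:
                return r
        raise KeyError(name)

    def fractions(self) -> dict[str, float]:
        return {r.name: r.fraction for r in self.results}

    def attribution(self, reference: str = "wild-type") -> pd.DataFrame:
        """Per-variant outcome flips of every scenario vs. a reference.

        ``rescued`` counts variants apoptotic under the reference but
        surviving under the scenario; ``sensitized`` the reverse.  Under
        the paired design the scenario-level fraction differences are
        exactly (rescued - sensitized) / n.
        """
        ref = self.outcomes[reference]
        rows = []
        for r in self.results:
            out = self.outcomes[r.name]
            rows.append({
                "scenario": r.name,
                "rescued": int((ref & ~out).sum()),
                "sensitized": int((~ref & out).sum()),
                "net_fraction_change": float((out.mean() - ref.mean())),
            })
        return pd.DataFrame(rows).set_index("scenario")


def _batch_apoptosis(P: np.ndarray, levels: np.ndarray,
                     protocol: StressProtocol,
                     rtol: float, atol: float,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Run the compiled steady-state + protocol sweep.

    Returns (apoptotic, status).  Integrator failures raise with the
    offending variant ids; zero-flux degenerates (status 2) are counted
    apoptotic, flux-saturated degenerates (status 1) are left to the
    caller.
    """
    Y, status = _kernels.batch_protocol_final(
        np.ascontiguousarray(P, dtype=float),
        np.ascontiguousarray(levels, dtype=float),
        protocol.t_on, protocol.t_off, protocol.horizon, rtol, atol)
    failed = np.flatnonzero(status == 3)
    if failed.size:
        raise RuntimeError(
            f"integrator failure (step-size collapse) for variants "
            f"{failed[:20].tolist()}")
    apoptotic = Y[:, 4] > APOPTOSIS_THRESHOLD
    apoptotic[status == 2] = True
    return apoptotic, status


def scenario_fractions(ensemble: VariantEnsemble,
                       scenarios: Sequence[ScenarioSpec] = CANONICAL_SCENARIOS,
                       protocol: StressProtocol | None = None,
                       rtol: float = ENSEMBLE_RTOL,
                       atol: float = ENSEMBLE_ATOL) -> ScenarioRun:
    """Apoptotic fraction per scenario on a shared (paired) ensemble.

    Every variant is simulated from its own unstressed steady state with
    its sampled S as the protocol level.  Variants that are degenerate in
    *any* scenario are excluded from all scenarios, keeping numerators
    and denominators paired.
    """
    if protocol is None:
        protocol = StressProtocol(level=0.0)  # level ignored; per-variant S
    levels = ensemble.variants["S"].to_numpy(dtype=float)
    n_total = ensemble.n

    per_scenario: dict[str, np.ndarray] = {}
    degenerate_counts: dict[str, int] = {}
    excluded_mask = np.zeros(n_total, dtype=bool)
    for spec in scenarios:
        P = apply_scenario(ensemble, spec).to_array()
        apoptotic, status = _batch_apoptosis(P, levels, protocol, rtol, atol)
        degenerate = status == 1
        degenerate_counts[spec.name] = int(degenerate.sum())
        excluded_mask |= degenerate
        per_scenario[spec.name] = apoptotic

    keep = ~excluded_mask
    outcomes = pd.DataFrame(
        {name: calls[keep] for name, calls in per_scenario.items()},
        index=ensemble.variants.index[keep])
    results = []
    n_kept = int(keep.sum())
    for spec in scenarios:
        k = int(outcomes[spec.name].sum())
        results.append(ScenarioResult(
            name=spec.name, n=n_kept, n_apoptotic=k,
            fraction=k / n_kept if n_kept else math.nan,
            ci=stats_io.proportion_ci(k, n_kept) if n_kept else
            (math.nan, math.nan)))
    variants = ensemble.variants.loc[keep, ["S", "alpha_B"]].copy()
    return ScenarioRun(results=tuple(results), outcomes=outcomes,
                       variants=variants, n_total=n_total,
                       excluded=tuple(np.flatnonzero(excluded_mask)),
                       degenerate_counts=degenerate_counts)


def stratified_apoptosis(variants: pd.DataFrame, apoptotic: Sequence[bool],
                         bands: Sequence[tuple[str, float, float]]
                         = STRESS_BANDS,
                         bins: int | Sequence[float] = 10,
                         quantile_bins: bool = False) -> pd.DataFrame:
    """Apoptosis fraction per (stress band, Beclin-1 expression bin).

    ``variants`` must carry columns S and alpha_B.  Stress bands are
    half-open (lo, hi].  Empty cells are reported as NaN, not zero.
    ``quantile_bins`` bins alpha_B by within-band quantiles (equal
    occupancy), which stabilizes shape summaries at small n.
    """
    df = variants[["S", "alpha_B"]].copy()
    df["apoptotic"] = np.asarray(apoptotic, dtype=bool)
    tables = {}
    for name, lo, hi in bands:
        sub = df[(df.S > lo) & (df.S <= hi)]
        if sub.empty:
            continue
        if quantile_bins:
            cut = pd.qcut(sub.alpha_B, q=bins, duplicates="drop")
        else:
            cut = pd.cut(sub.alpha_B, bins=bins)
        frac = sub.groupby(cut, observed=False)["apoptotic"].mean()
        frac.index = [iv.mid for iv in frac.index]
        tables[name] = frac
    out = pd.DataFrame(tables).T
    out.index.name = "stress_band"
    out.columns.name = "alpha_B_bin_mid"
    return out


@dataclasses.dataclass(frozen=True)
class ViabilityWindow:
    """Range of Beclin-1 expression rates compatible with survival."""

    S: float
    theta_L: float | None
    theta_H: float | None
    empty: bool
    grid: np.ndarray | None = None
    survived: np.ndarray | None = None


class NonContiguousSurvivalError(RuntimeError):
    """The survival set over alpha_B is not a single interval."""

    def __init__(self, mask: np.ndarray, grid: np.ndarray):
        super().__init__(
            "survival set over alpha_B is non-contiguous: "
            f"{np.flatnonzero(mask).tolist()} of {len(grid)} grid points")
        self.mask = mask
        self.grid = grid


def _survives(params: ParameterSet, alpha_B: float, S: float,
              protocol: StressProtocol, rtol: float, atol: float) -> bool:
    p = params.replace(alpha_B=alpha_B, S=S)
    try:
        init = unstressed_steady_state(p)
    except DegenerateVariantError:
        # No resting balance: either damaged mitochondria (zero flux) or
        # autophagosomes (saturated flux) accumulate without bound, and
        # Caspase commitment follows; not compatible with survival.
        return False
    y, status = _kernels.protocol_final(
        init, S, protocol.t_on, protocol.t_off, protocol.horizon,
        p.to_array(), rtol, atol)
    if status != 0:
        raise RuntimeError(f"integrator failure at alpha_B={alpha_B}")
    return y[4] <= APOPTOSIS_THRESHOLD


def viability_window(base: ParameterSet, S: float,
                     grid: Sequence[float] | None = None,
                     protocol: StressProtocol | None = None,
                     refine_tol: float = 1e-3,
                     rtol: float = ENSEMBLE_RTOL,
                     atol: float = ENSEMBLE_ATOL) -> ViabilityWindow:
    """Survival thresholds (theta_L, theta_H) over the Beclin-1
    expression rate alpha_B at a given stress level.

    Scans a log-spaced alpha_B grid on [0.1, 10] (thresholds span two
    decades), verifies the survival set is one contiguous interval, and
    refines both edges by bisection to ``refine_tol``.  Edges coinciding
    with the scan boundary are reported at the boundary value.
    """
    if grid is None:
        grid = np.geomspace(0.1, 10.0, 100)
    grid = np.asarray(grid, dtype=float)
    if protocol is None:
        protocol = StressProtocol.standard(S)
    mask = np.array([_survives(base, a, S, protocol, rtol, atol)
                     for a in grid])
    if not mask.any():
        return ViabilityWindow(S=S, theta_L=None, theta_H=None, empty=True,
                               grid=grid, survived=mask)
    idx = np.flatnonzero(mask)
    if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
        raise NonContiguousSurvivalError(mask, grid)

    def bisect(lo: float, hi: float, survive_high: bool) -> float:
        # Invariant: survival holds at exactly one end of (lo, hi).
        while hi - lo > refine_tol:
            mid = 0.5 * (lo + hi)
            s = _survives(base, mid, S, protocol, rtol, atol)
            if s == survive_high:
                hi = mid
            else:
                lo = mid
        return 0.5 * (lo + hi)

    lo_i, hi_i = idx[0], idx[-1]
    theta_L = grid[0] if lo_i == 0 else bisect(grid[lo_i - 1], grid[lo_i],
                                               survive_high=True)
    theta_H = grid[-1] if hi_i == len(grid) - 1 else \
        bisect(grid[hi_i], grid[hi_i + 1], survive_high=False)
    return ViabilityWindow(S=S, theta_L=theta_L, theta_H=theta_H,
                           empty=False, grid=grid, survived=mask)


def perturbation_experiment(base: ParameterSet, S: float,
                            folds: Sequence[float] = (0.5, 1.0, 2.0),
                            n: int = 1000, noise_sd: float = 0.5,
                            seed: int = 0,
                            protocol: StressProtocol | None = None,
                            rtol: float = ENSEMBLE_RTOL,
                            atol: float = ENSEMBLE_ATOL,
                            ) -> pd.DataFrame:
    """Apoptotic fraction per Beclin-1 expression fold under noise.

    Each fold gets an independent population (deterministic sub-seed per
    fold derived from ``seed``).  Cells whose truncated expression rate
    is zero have no autophagic flux and are counted apoptotic.
    """
    if any(f <= 0 for f in folds):
        raise ValueError("folds must be positive")
    if protocol is None:
        protocol = StressProtocol.standard(S)
    sub_seeds = np.random.SeedSequence(seed).generate_state(len(folds))
    rows = []
    for fold, sub in zip(folds, sub_seeds):
        pop = perturbed_population(base, fold, n, noise_sd=noise_sd,
                                   seed=int(sub % (2 ** 31)))
        P = pop[list(PARAM_NAMES)].to_numpy(dtype=float)
        P[:, 0] = S
        levels = np.full(n, S)
        apoptotic, status = _batch_apoptosis(P, levels, protocol, rtol, atol)
        if np.any(status == 1):
            raise RuntimeError("unexpected flux-saturated degenerate in "
                               "perturbation population")
        k = int(apoptotic.sum())
        rows.append({"fold": fold, "n": n, "n_apoptotic": k,
                     "fraction": k / n,
                     "n_zero_expression": int((status == 2).sum())})
    return pd.DataFrame(rows).set_index("fold")


def local_sensitivity(base: ParameterSet, S: float, fold: float = 2.0,
                      parameters: Sequence[str] | None = None,
                      grid: Sequence[float] | None = None,
                      refine_tol: float = 1e-3) -> pd.DataFrame:
    """Shift of the viability-window thresholds under single-parameter
    perturbations (x fold and / fold per parameter)."""
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if parameters is None:
        parameters = [p for p in PARAM_NAMES
                      if p not in ("S", "mu_C", "gamma_C", "phi_C")]
    ref = viability_window(base, S, grid=grid, refine_tol=refine_tol)
    rows = []
    for name in parameters:
        for direction, f in (("up", fold), ("down", 1.0 / fold)):
            pert = base.replace(**{name: getattr(base, name) * f})
            w = viability_window(pert, S, grid=grid, refine_tol=refine_tol)
            rows.append({
                "parameter": name, "direction": direction, "factor": f,
                "empty": w.empty,
                "theta_L": w.theta_L, "theta_H": w.theta_H,
                "theta_L_shift": (None if w.empty or ref.empty
                                  else w.theta_L - ref.theta_L),
                "theta_H_shift": (None if w.empty or ref.empty
                                  else w.theta_H - ref.theta_H),
            })
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class GoldenHourResult:
    """Minimal stress duration committing a cell to apoptosis."""

    name: str
    overrides: dict[str, float]
    t_star: float  # hours; inf when no duration <= horizon commits
    fold: float | None = None  # t_star / baseline t_star
    horizon: float = 48.0

    @property
    def unbounded(self) -> bool:
        return math.isinf(self.t_star)

    @property
    def t_star_censored(self) -> float:
        """Duration threshold right-censored at the simulation horizon:
        when no duration up to the horizon commits the cell, the
        threshold is reported as the horizon itself (a lower bound)."""
        return min(self.t_star, self.horizon)


def duration_threshold(params: ParameterSet, S: float = 8.0,
                       resolution: float = 0.05, horizon: float = 48.0,
                       name: str = "baseline",
                       overrides: Mapping[str, float] | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10,
                       ) -> GoldenHourResult:
    """Bisection on the stress duration d (stress on [0, d], horizon
    48 h) for the survival/apoptosis boundary of the end-point
    classification.

    ``overrides`` model an *acute* intervention: the cell starts from
    the resting steady state of ``params`` (its pre-treatment state) and
    the overridden dynamics apply from t = 0, as for a drug given at
    stress onset.  To study a chronically altered cell instead, bake the
    change into ``params`` and pass no overrides.

    The bistable commitment assumption (outcome monotone in d) is
    enforced: survival at full-horizon stress with apoptosis at a
    shorter probe duration raises.  Returns t_star = inf when even
    d = horizon does not commit the cell.
    """
    if resolution > 0.1:
        raise ValueError("resolution must be <= 0.1 h")
    init = unstressed_steady_state(params)
    if overrides:
        params = params.replace(**overrides)

    def apoptotic(d: float) -> bool:
        proto = StressProtocol(level=S, t_on=0.0, t_off=d, horizon=horizon)
        traj = simulate(params, proto, init=init, grid=[0.0, horizon],
                        rtol=rtol, atol=atol)
        return classify_apoptosis(traj)

    if not apoptotic(horizon):
        if apoptotic(0.5 * horizon):
            raise RuntimeError(
                "non-monotone outcome in stress duration: apoptotic at "
                f"{0.5 * horizon} h but surviving at {horizon} h")
        return GoldenHourResult(name=name, overrides=dict(overrides or {}),
                                t_star=math.inf, horizon=horizon)
    if apoptotic(0.0):
        return GoldenHourResult(name=name, overrides=dict(overrides or {}),
                                t_star=0.0, horizon=horizon)
    lo, hi = 0.0, horizon
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if apoptotic(mid):
            hi = mid
        else:
            lo = mid
    return GoldenHourResult(name=name, overrides=dict(overrides or {}),
                            t_star=0.5 * (lo + hi), horizon=horizon)


#: The intervention panel explored for golden-hour extension: halved
#: Beclin-1 expression, no Caspase-mediated cleavage, 5-fold enhanced
#: autophagic flux (countering autophagosome accumulation), and 10-fold
#: reduced IAP degradation efficiency.  The direct knockout of
#: autophagosome-mediated Caspase activation (sigma_C = 0) is included
#: as an extra arm.
INTERVENTIONS: tuple[tuple[str, dict[str, float]], ...] = (
    ("alphaB-0.5", {"alpha_B": 0.5}),
    ("betaB-0", {"beta_B": 0.0}),
    ("betaA-5", {"beta_A": 5.0}),
    ("sigmaJ-0.001", {"sigma_J": 0.001}),
    ("sigmaC-0", {"sigma_C": 0.0}),
)


def intervention_panel(base: ParameterSet | None = None, S: float = 8.0,
                       resolution: float = 0.05,
                       interventions: Sequence[tuple[str, dict[str, float]]]
                       = INTERVENTIONS,
                       saturation_relief_fold: float = 10.0,
                       ) -> tuple[GoldenHourResult, ...]:
    """Duration thresholds and fold-extensions for the intervention
    panel, each also combined with a ``saturation_relief_fold`` higher
    autophagic-flux saturation threshold phi_A."""
    if base is None:
        base = ParameterSet.representative()
    baseline = duration_threshold(base, S=S, resolution=resolution)
    results = [dataclasses.replace(baseline, fold=1.0)]
    phi_A_relief = base.phi_A * saturation_relief_fold
    for ko_name, ko in interventions:
        for suffix, extra in (("", {}), ("+phiA-x10", {"phi_A":
                                                       phi_A_relief})):
            overrides = {**ko, **extra}
            r = duration_threshold(base, S=S, resolution=resolution,
                                   name=ko_name + suffix,
                                   overrides=overrides)
            fold = (math.inf if r.unbounded
                    else r.t_star / baseline.t_star)
            results.append(dataclasses.replace(r, fold=fold))
    return tuple(results)
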