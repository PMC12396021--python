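"""Analysis of the isolated bistable Caspase-3 switch.

Freezing the slow drives (damaged mitochondria M, autophagosomes A and
autophagic flux J) reduces the Caspase-3 equation to a one-dimensional
system dC/dt = f_act(C) - f_inact(C) with

    f_act(C)   = (alpha1 + mu_C * C / (phi_C + 1 - C)) * (1 - C)
    f_inact(C) = gamma_C * C / (phi_C + C + alpha2)

where alpha1 = alpha_C*M + sigma_C*A lumps the activation drives and
alpha2 = sigma_J*J the IAP-depletion drive.  With alpha1 = alpha2 = 0 the
net rate factorizes as g1(C) * g2(C), g1 < 0 on (0, 1], so bistability
(three critical points 0 < gamma1 < gamma2 < 1, pattern
stable/unstable/stable) holds iff the quadratic g2 has two roots in
(0, 1]; this is COND1: Delta > 0 and g2(0) > 0.

Raising either drive destroys the survival state through a saddle-node
bifurcation, located here both by continuation (per-grid root finding
plus bisection on branch existence) and by directly solving the tangency
system f_act - f_inact = 0, d/dC (f_act - f_inact) = 0.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

__all__ = [
    "SwitchParams",
    "CriticalPoint",
    "CriticalPointSet",
    "BifurcationDiagram",
    "activation_rate",
    "inactivation_rate",
    "net_rate",
    "net_rate_derivative",
    "g1",
    "g2",
    "discriminant",
    "cond1",
    "critical_points",
    "bifurcation_scan",
    "fold_point_tangency",
]


@dataclasses.dataclass(frozen=True)
class SwitchParams:
    """Intrinsic Caspase parameters plus the two lumped drives."""

    mu_C: float = 1.0
    gamma_C: float = 0.3
    phi_C: float = 0.15
    alpha1: float = 0.0
    alpha2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mu_C", "gamma_C", "phi_C", "alpha1", "alpha2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.phi_C <= 0:
            raise ValueError("phi_C must be > 0")

    def with_drive(self, drive: Literal["alpha1", "alpha2"],
                   value: float) -> "SwitchParams":
        return dataclasses.replace(self, **{drive: float(value)})


def _check_C(C) -> np.ndarray:
    C = np.asarray(C, dtype=float)
    if np.any((C < 0) | (C > 1)):
        raise ValueError("C must lie in [0, 1]")
    return C


def activation_rate(C, p: SwitchParams):
    """f_act(C) = (alpha1 + mu_C*C/(phi_C+1-C)) * (1-C); vanishes at C=1."""
    C = _check_C(C)
    return (p.alpha1 + p.mu_C * C / (p.phi_C + 1.0 - C)) * (1.0 - C)


def inactivation_rate(C, p: SwitchParams):
    """f_inact(C) = gamma_C*C/(phi_C+C+alpha2); vanishes at C=0."""
    C = _check_C(C)
    return p.gamma_C * C / (p.phi_C + C + p.alpha2)


def net_rate(C, p: SwitchParams):
    return activation_rate(C, p) - inactivation_rate(C, p)


def net_rate_derivative(C, p: SwitchParams):
    """d/dC of the net rate (closed form); used for stability and folds."""
    C = _check_C(C)
    q = p.phi_C + 1.0
    u = p.alpha1 + p.mu_C * C / (q - C)
    du = p.mu_C * q / (q - C) ** 2
    dact = du * (1.0 - C) - u
    dinact = p.gamma_C * (p.phi_C + p.alpha2) / (p.phi_C + p.alpha2 + C) ** 2
    return dact - dinact


def g1(C, p: SwitchParams):
    """g1(C) = -mu_C*C / ((phi_C+1-C)(phi_C+C)); < 0 on (0, 1]."""
    C = np.asarray(C, dtype=float)
    return -p.mu_C * C / ((p.phi_C + 1.0 - C) * (p.phi_C + C))


def g2(C, p: SwitchParams):
    """Quadratic factor whose roots in (0, 1] are the nonzero critical
    points of the intrinsic (alpha1 = alpha2 = 0) switch."""
    C = np.asarray(C, dtype=float)
    r = p.gamma_C / p.mu_C
    return C ** 2 + (p.phi_C - 1.0 - r) * C + (-p.phi_C + r * p.phi_C + r)


def discriminant(p: SwitchParams) -> float:
    """Half the discriminant of g2 (the factor 1/2 follows the printed
    convention; only the sign enters the bistability condition)."""
    r = p.gamma_C / p.mu_C
    b = p.phi_C - 1.0 - r
    c = -p.phi_C + r * p.phi_C + r
    return 0.5 * (b * b - 4.0 * c)


@dataclasses.dataclass(frozen=True)
class Cond1Result:
    bistable: bool
    discriminant: float
    g2_at_zero: float


def cond1(p: SwitchParams) -> Cond1Result:
    """Bistability test for the intrinsic switch: Delta > 0 and g2(0) > 0."""
    if p.alpha1 != 0 or p.alpha2 != 0:
        raise ValueError("cond1 applies to the intrinsic switch "
                         "(alpha1 = alpha2 = 0)")
    d = discriminant(p)
    g20 = float(g2(0.0, p))
    return Cond1Result(bistable=bool(d > 0 and g20 > 0), discriminant=d,
                       g2_at_zero=g20)


@dataclasses.dataclass(frozen=True)
class CriticalPoint:
    C: float
    stability: Literal["stable", "unstable"]


@dataclasses.dataclass(frozen=True)
class CriticalPointSet:
    """All critical points of the frozen-drive switch on [0, 1]."""

    points: tuple[CriticalPoint, ...]
    bistable: bool
    discriminant: float
    roots: tuple[float, float] | None  # gamma1, gamma2 of g2 when real

    @property
    def stable(self) -> tuple[float, ...]:
        return tuple(pt.C for pt in self.points if pt.stability == "stable")

    @property
    def unstable(self) -> tuple[float, ...]:
        return tuple(pt.C for pt in self.points if pt.stability == "unstable")


def _g2_roots(p: SwitchParams) -> tuple[float, float] | None:
    r = p.gamma_C / p.mu_C
    b = p.phi_C - 1.0 - r
    c = -p.phi_C + r * p.phi_C + r
    disc = b * b - 4.0 * c
    if disc < 0:
        return None
    s = np.sqrt(disc)
    return ((-b - s) / 2.0, (-b + s) / 2.0)


def critical_points(p: SwitchParams, n_scan: int = 400,
                    xtol: float = 1e-12) -> CriticalPointSet:
    """Roots of f_act - f_inact on [0, 1] with stability labels.

    Works for arbitrary nonnegative drives via a dense sign scan plus
    Brent refinement; for alpha1 = 0 the exact root at C = 0 is included
    explicitly (the scan cannot see it as a sign change).
    """
    f = lambda c: float(net_rate(c, p))
    grid = np.linspace(0.0, 1.0, n_scan + 1)
    vals = net_rate(grid, p)
    roots_found: list[float] = []
    if p.alpha1 == 0.0:
        roots_found.append(0.0)
    for i in range(n_scan):
        a, b = grid[i], grid[i + 1]
        fa, fb = vals[i], vals[i + 1]
        if a == 0.0 and p.alpha1 == 0.0:
            continue  # endpoint root handled above
        if fa == 0.0 and a not in roots_found:
            roots_found.append(float(a))
        elif fa * fb < 0:
            try:
                r = brentq(f, a, b, xtol=xtol)
            except ValueError as exc:  # pragma: no cover - diagnostics
                raise RuntimeError(
                    f"root bracketing failed on [{a}, {b}] "
                    f"(f(a)={fa}, f(b)={fb})") from exc
            roots_found.append(float(r))
    if vals[-1] == 0.0:
        roots_found.append(1.0)

    # Deduplicate near-identical roots (tangencies straddling grid nodes).
    roots_found = sorted(roots_found)
    dedup: list[float] = []
    for r in roots_found:
        if not dedup or r - dedup[-1] > 1e-9:
            dedup.append(r)

    pts = []
    for r in dedup:
        if r == 0.0 and p.alpha1 == 0.0:
            # One-sided stability: stable iff the flow just above 0 points
            # back down.
            stable = f(min(1e-9, 0.5 / n_scan)) < 0
        else:
            stable = float(net_rate_derivative(r, p)) < 0
        pts.append(CriticalPoint(C=r, stability="stable" if stable
                                 else "unstable"))
    return CriticalPointSet(
        points=tuple(pts),
        bistable=sum(pt.stability == "stable" for pt in pts) >= 2,
        discriminant=discriminant(p),
        roots=_g2_roots(p),
    )


@dataclasses.dataclass(frozen=True)
class BifurcationDiagram:
    """One-parameter branch structure over a lumped drive."""

    drive: Literal["alpha1", "alpha2"]
    grid: np.ndarray
    branches: tuple[CriticalPointSet, ...]
    fold: float | None  # smallest drive at which the survival branch is lost

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"drive": self.drive, "value": float(v), "C": pt.C,
             "stability": pt.stability}
            for v, cps in zip(self.grid, self.branches)
            for pt in cps.points
        ]
        return pd.DataFrame(rows, columns=["drive", "value", "C",
                                           "stability"])


def _survival_branch_exists(p: SwitchParams, n_scan: int = 6000) -> bool:
    # Near the saddle-node the merging roots are ~sqrt(drive offset)
    # apart, so branch detection needs a much denser scan than the
    # default critical-point search.
    return critical_points(p, n_scan=n_scan).bistable


def bifurcation_scan(p: SwitchParams, drive: Literal["alpha1", "alpha2"],
                     grid: Sequence[float],
                     refine_tol: float = 1e-9) -> BifurcationDiagram:
    """Critical points along a drive grid plus the saddle-node location.

    The fold is bracketed on the grid by loss of the low-C (survival)
    branch and refined by bisection on branch existence.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonnegative and ascending")
    branches = tuple(critical_points(p.with_drive(drive, v)) for v in grid)
    fold = None
    exists = [cps.bistable for cps in branches]
    for i in range(len(grid) - 1):
        if exists[i] and not exists[i + 1]:
            lo, hi = grid[i], grid[i + 1]
            while hi - lo > refine_tol:
                mid = 0.5 * (lo + hi)
                if _survival_branch_exists(p.with_drive(drive, mid)):
                    lo = mid
                else:
                    hi = mid
            fold = 0.5 * (lo + hi)
            break
    return BifurcationDiagram(drive=drive, grid=grid, branches=branches,
                              fold=fold)


def fold_point_tangency(p: SwitchParams, drive: Literal["alpha1", "alpha2"],
                        guess: tuple[float, float] | None = None,
                        ) -> tuple[float, float]:
    """Saddle-node location by solving the tangency system
    f(C) = 0, f'(C) = 0 for (drive value, C).  Independent of the
    continuation path; returns (drive*, C*)."""
    if guess is None:
        # The survival state sits below the unstable threshold; the fold
        # forms between them.  gamma1 of the intrinsic system is a robust
        # starting point.
        r = _g2_roots(p)
        c0 = r[0] if r is not None else 0.2
        guess = (0.05, c0)

    def system(x):
        d, c = x
        c = min(max(c, 0.0), 1.0)
        q = p.with_drive(drive, max(d, 0.0))
        return [float(net_rate(c, q)), float(net_rate_derivative(c, q))]

    sol = root(system, x0=[guess[0], guess[1]], method="hybr", tol=1e-13)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(f"tangency solve failed: {sol.message}")
    d_star = float(sol.x[0])
    # With alpha1 = 0 the survival state sits exactly at C = 0 and the
    # branch is lost through a tangency *at* the boundary; report the
    # clamped collision point.
    c_star = float(min(max(sol.x[1], 0.0), 1.0))
    return d_star, c_star
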