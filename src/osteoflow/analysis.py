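"""Downstream analytics of LCN flow solutions.

Shear stresses at the cell-process membrane, the intrinsic permeability of
the osteon, LOWESS pressure profiles over normalized radial distance,
angular (sector) heterogeneity, cumulative shear-exceedance distributions,
velocity/path-length relations across osteon cohorts, and rank-sum group
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from .hydraulics import FlowSolution, HydraulicParams, M2_PER_UM2
from .network import (
    OsteonNetwork,
    StructuralSummary,
    normalized_distance,
    sector_partition,
)

__all__ = [
    "shear_stress",
    "PermeabilityResult",
    "intrinsic_permeability",
    "mean_velocity",
    "pressure_profile",
    "SectorStats",
    "sector_heterogeneity",
    "ShearDistribution",
    "exceedance_distribution",
    "exceedance_intersection",
    "velocity_by_half",
    "VelocityPathFit",
    "velocity_pathlength_relation",
    "GroupComparison",
    "compare_groups",
]


def shear_stress(
    velocity: float | np.ndarray, params: HydraulicParams | None = None
) -> np.ndarray:
    """Wall shear stress at the cell-process membrane, τ = µ·K·|v| (Pa).

    With v in µm/s and K in µm⁻¹ the product µ·K·v is directly in Pa.
    """
    params = params or HydraulicParams()
    return params.mu * params.shear_constant * np.abs(np.asarray(velocity, dtype=float))


@dataclass(frozen=True)
class PermeabilityResult:
    """Intrinsic (Darcy) permeability of a whole osteon.

    k_osteon = v̄·µ·ΔR/Δp with v̄ the length-weighted mean of absolute
    canalicular velocities and ΔR the wall thickness.  Tortuosity and
    network detours can only lower k_osteon below the canalicular k_p,eff.
    """

    mean_velocity: float  # µm/s, length-weighted
    wall_thickness: float  # µm
    applied_pressure: float  # Pa
    k_osteon: float  # m²


def mean_velocity(
    net: OsteonNetwork, solution: FlowSolution, weighting: str = "length"
) -> float:
    """Mean absolute canalicular velocity (µm/s), length-weighted by default."""
    v = np.abs(solution.edge_velocity)
    ok = np.isfinite(v)
    if not ok.any():
        return 0.0
    if weighting == "length":
        w = net.lengths[ok]
        return float(np.sum(v[ok] * w) / np.sum(w))
    if weighting == "count":
        return float(v[ok].mean())
    raise ValueError("weighting must be 'length' or 'count'")


def intrinsic_permeability(
    net: OsteonNetwork,
    solution: FlowSolution,
    delta_p: float | None = None,
    params: HydraulicParams | None = None,
) -> PermeabilityResult:
    """Infer the osteon's intrinsic permeability from a fixed-pressure solve."""
    if delta_p is None:
        delta_p = solution.applied.get("delta_p")
    if not delta_p:
        raise ValueError("applied pressure difference must be nonzero")
    params = params or HydraulicParams()
    v_bar = mean_velocity(net, solution, weighting="length")
    dr = net.metadata.wall_thickness
    k_um2 = v_bar * params.mu * dr / delta_p
    return PermeabilityResult(
        mean_velocity=v_bar,
        wall_thickness=dr,
        applied_pressure=float(delta_p),
        k_osteon=k_um2 * M2_PER_UM2,
    )


def pressure_profile(
    net: OsteonNetwork,
    solution: FlowSolution,
    span: float = 0.10,
    grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """LOWESS-smoothed pressure vs normalized distance (canal = 0, cement = 1).

    Locally weighted scatterplot smoothing with a tricube kernel, local
    linear fits over the nearest ``span`` fraction of the data, and no
    robustness iterations; evaluated on a uniform grid (default 101 points).
    Returns ``(grid, smoothed_pressure)``.
    """
    p = solution.node_pressure
    ok = np.isfinite(p)
    if ok.sum() < 10:
        raise ValueError("need at least 10 solved nodes for a pressure profile")
    x = normalized_distance(net)[ok]
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 101)
    smoothed = sm_lowess(p[ok], x, frac=span, it=0, xvals=grid)
    return grid, np.asarray(smoothed)


@dataclass(frozen=True)
class SectorStats:
    """Angular heterogeneity of the nodal pressure field."""

    sector_means: np.ndarray  # NaN for empty sectors
    relative_std: float  # population std of sector means / their mean
    n_empty: int


def sector_heterogeneity(
    net: OsteonNetwork, solution: FlowSolution, n_sectors: int = 36
) -> SectorStats:
    """Relative standard deviation of per-sector mean node pressures.

    The osteon is cut into ``n_sectors`` equal angular sectors around the
    canal center; empty sectors are excluded (and counted).
    """
    sectors = sector_partition(net, n_sectors)
    p = solution.node_pressure
    ok = np.isfinite(p)
    means = np.full(n_sectors, np.nan)
    for s in range(n_sectors):
        sel = ok & (sectors == s)
        if sel.any():
            means[s] = p[sel].mean()
    filled = means[np.isfinite(means)]
    if len(filled) == 0:
        raise ValueError("all sectors are empty")
    rel = float(np.std(filled) / np.mean(filled)) if np.mean(filled) != 0 else 0.0
    return SectorStats(
        sector_means=means, relative_std=rel, n_empty=int(n_sectors - len(filled))
    )


@dataclass
class ShearDistribution:
    """Cumulative shear-exceedance curves across a cohort of osteons.

    ``exceedance[i, j]`` is the fraction of canaliculi of osteon i whose
    wall shear stress exceeds ``thresholds[j]`` (strictly); ``mean`` and the
    confidence band aggregate across osteons.
    """

    thresholds: np.ndarray  # Pa
    exceedance: np.ndarray  # (n_osteons, n_thresholds)
    mean: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    weighting: str
    confidence: float


def exceedance_distribution(
    solutions: list[FlowSolution],
    params: HydraulicParams | None = None,
    nets: list[OsteonNetwork] | None = None,
    weighting: str = "count",
    thresholds: np.ndarray | None = None,
    n_thresholds: int = 256,
    confidence: float = 0.99,
) -> ShearDistribution:
    """Fraction of canaliculi with shear stress above each threshold.

    ``weighting='count'`` treats every canaliculus equally (the reported
    "percentage of canaliculi"); ``'length'`` weights by arc length and then
    requires ``nets``.  The band is the t-based confidence interval of the
    cohort mean at each threshold.
    """
    if not solutions:
        raise ValueError("need at least one solution")
    if weighting not in ("count", "length"):
        raise ValueError("weighting must be 'count' or 'length'")
    if weighting == "length" and nets is None:
        raise ValueError("length weighting requires the networks")
    params = params or HydraulicParams()

    taus = []
    for sol in solutions:
        t = shear_stress(sol.edge_velocity, params)
        taus.append(t)
    if thresholds is None:
        top = max(float(np.nanmax(t)) for t in taus)
        thresholds = np.linspace(0.0, top, n_thresholds)
    thresholds = np.asarray(thresholds, dtype=float)

    curves = np.empty((len(solutions), len(thresholds)))
    for i, t in enumerate(taus):
        ok = np.isfinite(t)
        if weighting == "count":
            w = np.ones(int(ok.sum()))
        else:
            w = nets[i].lengths[ok]
        tv = t[ok]
        order = np.argsort(tv)
        tv, w = tv[order], w[order]
        cum = np.concatenate([[0.0], np.cumsum(w)])
        total = cum[-1]
        # weight with tau <= thr, via rightmost insertion
        below = cum[np.searchsorted(tv, thresholds, side="right")]
        curves[i] = 1.0 - below / total

    mean = curves.mean(axis=0)
    n = len(solutions)
    if n > 1:
        se = curves.std(axis=0, ddof=1) / np.sqrt(n)
        tq = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
        lo, hi = mean - tq * se, mean + tq * se
    else:
        lo = hi = mean.copy()
    return ShearDistribution(
        thresholds=thresholds,
        exceedance=curves,
        mean=mean,
        band_lower=lo,
        band_upper=hi,
        weighting=weighting,
        confidence=confidence,
    )


def exceedance_intersection(
    dist_a: ShearDistribution, dist_b: ShearDistribution
) -> tuple[float, float]:
    """Locate the crossing of two mean exceedance curves.

    Returns (τ*, exceedance at τ*), found by bracketing a sign change of the
    interpolated difference of the mean curves and bisecting with brentq.
    Raises ValueError when the curves do not cross.
    """

    def diff(t: float) -> float:
        a = np.interp(t, dist_a.thresholds, dist_a.mean)
        b = np.interp(t, dist_b.thresholds, dist_b.mean)
        return a - b

    lo = max(dist_a.thresholds[0], dist_b.thresholds[0])
    hi = min(dist_a.thresholds[-1], dist_b.thresholds[-1])
    ts = np.linspace(lo, hi, 512)
    vals = np.array([diff(t) for t in ts])
    sign = np.sign(vals)
    change = np.flatnonzero((sign[:-1] != sign[1:]) & (sign[:-1] != 0))
    if len(change) == 0:
        raise ValueError("exceedance curves do not intersect on the common grid")
    i = change[0]
    tau = optimize.brentq(diff, ts[i], ts[i + 1])
    frac = float(np.interp(tau, dist_a.thresholds, dist_a.mean))
    return float(tau), frac


def velocity_by_half(
    net: OsteonNetwork, solution: FlowSolution
) -> tuple[float, float]:
    """Length-weighted mean |v| in the inner (canal-side) and outer halves.

    Edges are assigned by the normalized distance of their midpoint
    (< 0.5 → inner half).  Returns ``(inner_mean, outer_mean)`` in µm/s.
    """
    idx = net.edge_indices
    mid = 0.5 * (net.positions[idx[:, 0]] + net.positions[idx[:, 1]])
    d = normalized_distance(net, mid)
    v = np.abs(solution.edge_velocity)
    ok = np.isfinite(v)

    def _mean(sel: np.ndarray) -> float:
        sel = sel & ok
        if not sel.any():
            return 0.0
        return float(np.sum(v[sel] * net.lengths[sel]) / np.sum(net.lengths[sel]))

    return _mean(d < 0.5), _mean(d >= 0.5)


@dataclass(frozen=True)
class VelocityPathFit:
    """Fitted velocity / shortest-path-length relation for one approach.

    ``model='inverse'`` fits v̄ = a / SPL (fixed-pressure loading: longer
    paths mean higher resistance and slower flow); ``model='linear'`` fits
    v̄ = a·SPL + b (strain-driven loading: longer paths drain more volume).
    """

    model: str
    a: float
    b: float
    r_value: float
    p_value: float


def velocity_pathlength_relation(
    cohort: list[tuple[StructuralSummary, float]], approach: str
) -> VelocityPathFit:
    """Fit the cohort-level relation between mean velocity and mean shortest
    path length; ``cohort`` pairs each osteon's structural summary with its
    mean velocity (µm/s) under the given approach."""
    if len(cohort) < 4:
        raise ValueError("need at least 4 osteons for a cohort fit")
    spl = np.array([s.mean_shortest_path_to_canal for s, _ in cohort])
    v = np.array([vb for _, vb in cohort])
    if np.allclose(spl, spl[0]):
        raise ValueError("degenerate cohort: constant shortest path length")
    if approach == "fixed_pressure":
        x = 1.0 / spl
        a = float(np.sum(v * x) / np.sum(x * x))  # no-intercept least squares
        r, p = stats.pearsonr(x, v)
        return VelocityPathFit("inverse", a, 0.0, float(r), float(p))
    if approach == "strain_sources":
        fit = stats.linregress(spl, v)
        return VelocityPathFit(
            "linear", float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue)
        )
    raise ValueError(f"unknown approach {approach!r}")


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison with descriptive statistics."""

    p_value: float
    mean_a: float
    std_a: float
    mean_b: float
    std_b: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-tailed Wilcoxon rank-sum (Mann–Whitney U) test between two groups.

    Uses the exact null distribution for small samples (both n ≤ 20, no
    ties) and the normal approximation otherwise; identical constant groups
    return p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        p = 1.0
    else:
        method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
        )
    return GroupComparison(
        p_value=p,
        mean_a=float(a.mean()),
        std_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        std_b=float(b.std(ddof=1)),
        n_a=len(a),
        n_b=len(b),
    )
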