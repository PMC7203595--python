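"""End-to-end pipeline: generate (or load) → solve → analyze → report.

One global seed fans out to per-osteon child seeds through a fixed
derivation, so whole cohorts are reproducible and each osteon can be
regenerated on its own.  With an output directory, every stage serializes
its intermediates (networks, solutions, report, manifest) and can be
resumed from them with identical final outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io
from .analysis import (
    compare_groups,
    exceedance_distribution,
    intrinsic_permeability,
    mean_velocity,
    sector_heterogeneity,
    velocity_by_half,
)
from .hydraulics import (
    HydraulicParams,
    leaky_cement_variant,
    solve_fixed_pressure,
    solve_strain_sources,
)
from .network import structural_summary, validate_network
from .synthetic import GeneratorParams, generate_osteon

__version__ = "0.1.0"

__all__ = ["CohortSpec", "RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and offending osteon."""


@dataclass(frozen=True)
class CohortSpec:
    """One group of osteons: either ``count`` synthetic networks generated
    from ``params`` (with per-osteon child seeds), or networks loaded from
    ``paths`` (LCN-JSON)."""

    name: str
    count: int = 0
    params: GeneratorParams | None = None
    paths: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.count > 0 and self.params is None and not self.paths:
            raise ValueError(f"cohort {self.name!r}: generated cohorts need params")
        if self.count <= 0 and not self.paths:
            raise ValueError(f"cohort {self.name!r} is empty")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``strain_rates`` defaults to peak exercise (0.015 s⁻¹) and walking
    (0.0015 s⁻¹); the first entry is the primary rate used for per-osteon
    velocity statistics.
    """

    cohorts: tuple[CohortSpec, ...]
    hydraulics: HydraulicParams = field(default_factory=HydraulicParams)
    approaches: tuple[str, ...] = ("fixed_pressure", "strain_sources")
    strain_rates: tuple[float, ...] = (0.015, 0.0015)
    delta_p: float = 13_000.0
    leak_fraction: float = 0.0
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if not self.approaches:
            raise ValueError("need at least one approach")
        for a in self.approaches:
            if a not in ("fixed_pressure", "strain_sources"):
                raise ValueError(f"unknown approach {a!r}")
        if any(s <= 0 for s in self.strain_rates):
            raise ValueError("strain rates must be positive")


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s) % 2**31 for s in state]


def _stage(stage: str, osteon: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(
                    f"stage {stage!r} failed for osteon {osteon!r}: {exc}"
                ) from exc
            return False

    return _Ctx()


def run_pipeline(config: RunConfig, resume: bool = False) -> dict:
    """Run the full generate → solve → analyze → report pipeline.

    Returns the analysis report as a JSON-serializable dict; with
    ``config.outdir`` set, also writes networks, solutions, ``report.json``
    and a ``manifest.json`` recording parameter provenance.  Deterministic
    given ``config.seed``.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        (outdir / "networks").mkdir(parents=True, exist_ok=True)
        (outdir / "solutions").mkdir(parents=True, exist_ok=True)

    # ---- stage: generate / load -----------------------------------------
    osteons: list[tuple[str, str, object]] = []  # (cohort, osteon name, net)
    for cohort in config.cohorts:
        if cohort.paths:
            for k, p in enumerate(cohort.paths):
                name = f"{cohort.name}_{k:02d}"
                with _stage("generate", name):
                    net = validate_network(io.read_network_json(p))
                osteons.append((cohort.name, name, net))
        else:
            cohort_tag = zlib.crc32(cohort.name.encode()) % 2**31
            seeds = _child_seeds((config.seed ^ cohort_tag) % 2**31, cohort.count)
            for k, s in enumerate(seeds):
                name = f"{cohort.name}_{k:02d}"
                path = outdir / "networks" / f"{name}.json" if outdir else None
                with _stage("generate", name):
                    if resume and path and path.exists():
                        net = io.read_network_json(path)
                    else:
                        net = generate_osteon(replace(cohort.params, seed=s))
                        if path:
                            io.write_network_json(net, path)
                osteons.append((cohort.name, name, net))

    # ---- stage: solve ----------------------------------------------------
    primary_rate = config.strain_rates[0]
    solutions: dict[tuple[str, str, float | None], object] = {}
    for cohort_name, name, net in osteons:
        for approach in config.approaches:
            if approach == "fixed_pressure":
                keys = [(name, approach, None)]
            else:
                keys = [(name, approach, rate) for rate in config.strain_rates]
            for key in keys:
                _, _, rate = key
                tag = approach if rate is None else f"{approach}_{rate:g}"
                path = outdir / "solutions" / f"{name}_{tag}.json" if outdir else None
                with _stage("solve", name):
                    if resume and path and path.exists():
                        sol = io.read_solution_json(path)
                    elif approach == "fixed_pressure":
                        sol = solve_fixed_pressure(
                            net, config.hydraulics, config.delta_p
                        )
                    elif config.leak_fraction > 0:
                        sol = leaky_cement_variant(
                            net,
                            config.hydraulics,
                            config.leak_fraction,
                            rate,
                            seed=config.seed,
                        )
                    else:
                        sol = solve_strain_sources(net, config.hydraulics, rate)
                    if path and not (resume and path.exists()):
                        io.write_solution_json(sol, net, path)
                solutions[key] = sol

    # ---- stage: analyze --------------------------------------------------
    per_osteon: dict[str, dict] = {}
    for cohort_name, name, net in osteons:
        with _stage("analyze", name):
            entry: dict = {
                "cohort": cohort_name,
                "structure": structural_summary(net).to_dict(),
            }
            if "fixed_pressure" in config.approaches:
                sol = solutions[(name, "fixed_pressure", None)]
                perm = intrinsic_permeability(net, sol, params=config.hydraulics)
                inner, outer = velocity_by_half(net, sol)
                entry["fixed_pressure"] = {
                    "mean_velocity": perm.mean_velocity,
                    "k_osteon": perm.k_osteon,
                    "sector_rsd": sector_heterogeneity(net, sol).relative_std,
                    "velocity_inner_half": inner,
                    "velocity_outer_half": outer,
                }
            if "strain_sources" in config.approaches:
                sol = solutions[(name, "strain_sources", primary_rate)]
                inner, outer = velocity_by_half(net, sol)
                entry["strain_sources"] = {
                    "mean_velocity": mean_velocity(net, sol),
                    "boundary_flux": sol.boundary_flux,
                    "sector_rsd": sector_heterogeneity(net, sol).relative_std,
                    "velocity_inner_half": inner,
                    "velocity_outer_half": outer,
                }
            per_osteon[name] = entry

    report: dict = {
        "per_osteon": per_osteon,
        "cohorts": {},
        "comparisons": {},
    }

    by_cohort: dict[str, list[str]] = {}
    for cohort_name, name, _ in osteons:
        by_cohort.setdefault(cohort_name, []).append(name)

    # cohort-level exceedance distributions (strain-driven shear stimulation)
    if "strain_sources" in config.approaches:
        for cohort_name, names in by_cohort.items():
            curves = {}
            for rate in config.strain_rates:
                sols = [solutions[(n, "strain_sources", rate)] for n in names]
                dist = exceedance_distribution(sols, config.hydraulics)
                curves[f"{rate:g}"] = {
                    "thresholds": dist.thresholds.tolist(),
                    "mean": dist.mean.tolist(),
                    "band_lower": dist.band_lower.tolist(),
                    "band_upper": dist.band_upper.tolist(),
                }
            report["cohorts"][cohort_name] = {"exceedance": curves, "n": len(names)}

    # group comparisons (rank-sum) between the first two cohorts
    def _collect(names: list[str], approach: str, field_: str) -> list[float]:
        return [per_osteon[n][approach][field_] for n in names if approach in per_osteon[n]]

    cohort_names = list(by_cohort)
    if len(cohort_names) >= 2:
        a_names, b_names = by_cohort[cohort_names[0]], by_cohort[cohort_names[1]]
        if len(a_names) >= 2 and len(b_names) >= 2:
            comps: dict = {}
            spl_a = [per_osteon[n]["structure"]["mean_shortest_path_to_canal"] for n in a_names]
            spl_b = [per_osteon[n]["structure"]["mean_shortest_path_to_canal"] for n in b_names]
            comps["shortest_path_length"] = _comparison_dict(compare_groups(spl_a, spl_b))
            for approach in config.approaches:
                va = _collect(a_names, approach, "mean_velocity")
                vb = _collect(b_names, approach, "mean_velocity")
                if len(va) >= 2 and len(vb) >= 2:
                    comps[f"mean_velocity_{approach}"] = _comparison_dict(
                        compare_groups(va, vb)
                    )
            if "fixed_pressure" in config.approaches:
                ka = _collect(a_names, "fixed_pressure", "k_osteon")
                kb = _collect(b_names, "fixed_pressure", "k_osteon")
                comps["k_osteon"] = _comparison_dict(compare_groups(ka, kb))
            report["comparisons"] = comps

    # angular heterogeneity: strain-driven vs fixed-pressure across all osteons
    if set(config.approaches) >= {"fixed_pressure", "strain_sources"}:
        all_names = [n for _, n, _ in osteons]
        h1 = _collect(all_names, "fixed_pressure", "sector_rsd")
        h2 = _collect(all_names, "strain_sources", "sector_rsd")
        if len(h1) >= 2 and len(h2) >= 2:
            report["comparisons"]["sector_rsd_approach2_vs_approach1"] = (
                _comparison_dict(compare_groups(h2, h1))
            )

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        manifest = {
            "software": {"name": "osteoflow", "version": __version__},
            "seed": config.seed,
            "approaches": list(config.approaches),
            "strain_rates": list(config.strain_rates),
            "delta_p": config.delta_p,
            "leak_fraction": config.leak_fraction,
            "cohorts": [
                {
                    "name": c.name,
                    "count": c.count,
                    "paths": list(c.paths),
                    "generator": None
                    if c.params is None
                    else {k: getattr(c.params, k) for k in c.params.__dataclass_fields__},
                }
                for c in config.cohorts
            ],
            "hydraulics": {
                k: getattr(config.hydraulics, k)
                for k in config.hydraulics.__dataclass_fields__
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True)
        )
    return report


def _comparison_dict(c) -> dict:
    return {
        "p_value": c.p_value,
        "mean_a": c.mean_a,
        "std_a": c.std_a,
        "mean_b": c.mean_b,
        "std_b": c.std_b,
        "n_a": c.n_a,
        "n_b": c.n_b,
    }
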