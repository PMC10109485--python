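"""End-to-end orchestration: sample -> simulate -> surrogate -> UQ -> optimize.

A single :class:`PipelineConfig` (loadable from YAML) drives every stage and
every intermediate artifact is a plain CSV or JSON file, so any stage can be
re-run or inspected in isolation.  All randomness flows from one root seed
through named per-stage substreams; re-running with the same config
reproduces every numeric artifact, and a manifest records the config, the
derived seeds and the wall clock of each run.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bioheat import coarse_config, default_config, simulate_indicators
from .doe import DesignTable, evaluate_responses, fit_metrics, latin_hypercube, train_rbnn
from .interval_opt import (
    GASettings,
    IntervalOptimizationProblem,
    ProblemVariable,
    rpdi_sweep,
)
from .intervals import interval_from_bounds
from .synthetic import (
    ALLOWABLE_ST,
    DESIGN_DOMAIN,
    INTERVAL_RADII,
    design_domain_box,
    make_pseudo_simulator,
)
from .uq import UncertaintyScenario, analyze_uncertainty

__all__ = ["PipelineConfig", "run_pipeline", "report", "stage_seed", "build_problem"]


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the root seed."""
    return int(
        np.random.SeedSequence([base_seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % 2**31
    )


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (see YAML keys of the same names)."""

    seed: int = 42
    outdir: str = "results"
    simulator: str = "pseudo"          # "pseudo" | "pde"
    pde_preset: str = "coarse"         # "coarse" | "fine"
    n_train: int = 50
    n_validation: int = 20
    lhs_candidates: int = 100
    surrogate_width: float | None = None
    surrogate_regularization: float = 0.0
    allowable_st: float = ALLOWABLE_ST
    lambdas: tuple[float, ...] = (0.8, 0.9, 1.0, 1.1)
    omega_c_midpoint: float = 40.5     # percent, uncontrolled uncertainty
    ga_population: int = 40
    ga_generations: int = 100
    scalarization: str = "midpoint"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {k: v for k, v in payload.items() if k in cls.__dataclass_fields__}
        unknown = set(payload) - set(known)
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "lambdas" in known:
            known["lambdas"] = tuple(known["lambdas"])
        return cls(**known)


def _make_simulator(cfg: PipelineConfig) -> Callable[..., tuple[float, float]]:
    if cfg.simulator == "pseudo":
        return make_pseudo_simulator(seed=stage_seed(cfg.seed, "pseudo-simulator"))
    if cfg.simulator == "pde":
        sim_cfg = coarse_config() if cfg.pde_preset == "coarse" else default_config()
        return lambda t1, d, h, wc: simulate_indicators(t1, d, h, wc, config=sim_cfg)
    raise ValueError(f"unknown simulator backend {cfg.simulator!r}")


def build_problem(
    model, cfg: PipelineConfig, reliability: float = 1.0
) -> IntervalOptimizationProblem:
    """The operating-parameter interval program on a trained surrogate.

    Design variables: midpoints of (t1, d, h) with their fixed operating
    radii; omega_c is an uncontrolled interval at ``cfg.omega_c_midpoint``.
    """
    variables = []
    for name in DESIGN_DOMAIN:
        dom = interval_from_bounds(*DESIGN_DOMAIN[name])
        if name == "omega_c":
            variables.append(
                ProblemVariable(name, INTERVAL_RADII[name], dom, design=False,
                                fixed_midpoint=cfg.omega_c_midpoint)
            )
        else:
            variables.append(ProblemVariable(name, INTERVAL_RADII[name], dom))
    cols = [model.response_names.index("HPM"), model.response_names.index("ST")]
    return IntervalOptimizationProblem(
        objective=model.response("HPM"),
        constraint=model.response("ST"),
        variables=tuple(variables),
        allowable=cfg.allowable_st,
        reliability=reliability,
        scalarization=cfg.scalarization,  # type: ignore[arg-type]
        joint_response=lambda pts: model.predict(pts)[:, cols],
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order, writing artifacts under ``cfg.outdir``.

    Artifacts: design.csv / responses.csv (training), validation_*.csv,
    model.json, metrics.json, uq_report.json, sweep.csv, results.json and
    manifest.json.  Returns the run report as a dict.  A stage failure
    raises with the stage name; earlier artifacts are left on disk.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    stage = "init"
    try:
        stage = "doe"
        domain = design_domain_box()
        names = tuple(DESIGN_DOMAIN)
        design = latin_hypercube(
            cfg.n_train, domain, stage_seed(cfg.seed, "lhs-train"),
            names=names, candidates=cfg.lhs_candidates,
        )
        design.to_csv(out / "design.csv")
        validation = latin_hypercube(
            cfg.n_validation, domain, stage_seed(cfg.seed, "lhs-validation"),
            names=names, candidates=cfg.lhs_candidates,
        )
        validation.to_csv(out / "validation_design.csv")

        stage = "evaluate"
        simulator = _make_simulator(cfg)
        responses = evaluate_responses(design, simulator)
        responses.to_csv(out / "responses.csv", index=False)
        val_responses = evaluate_responses(validation, simulator)
        val_responses.to_csv(out / "validation_responses.csv", index=False)

        stage = "train"
        model = train_rbnn(
            design, responses,
            width=cfg.surrogate_width, regularization=cfg.surrogate_regularization,
        )
        model.save(out / "model.json")
        metrics = {}
        for split, dsg, resp in (
            ("training", design, responses),
            ("validation", validation, val_responses),
        ):
            pred = model.predict(dsg.values)
            metrics[split] = {
                rname: fit_metrics(
                    resp[rname].to_numpy(), pred[:, model.response_names.index(rname)]
                ).to_json_dict()
                for rname in model.response_names
            }
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2)

        stage = "uq"
        scenario = UncertaintyScenario(
            box=domain,
            hpm=model.response("HPM"),
            st=model.response("ST"),
            allowable_st=cfg.allowable_st,
            seed=stage_seed(cfg.seed, "uq"),
        )
        uq_report = analyze_uncertainty(scenario)
        with open(out / "uq_report.json", "w") as fh:
            json.dump(uq_report.to_json_dict(), fh, indent=2)

        stage = "optimize"
        problem = build_problem(model, cfg)
        ga = GASettings(population=cfg.ga_population, generations=cfg.ga_generations)
        sweep_table, results = rpdi_sweep(
            problem, cfg.lambdas, ga=ga, seed=stage_seed(cfg.seed, "ga")
        )
        sweep_table.to_csv(out / "sweep.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump([r.to_json_dict() for r in results], fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "config": asdict(cfg),
        "stage_seeds": {
            s: stage_seed(cfg.seed, s)
            for s in ("pseudo-simulator", "lhs-train", "lhs-validation", "uq", "ga")
        },
        "wall_clock_s": time.time() - t_start,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "outdir": str(out),
        "metrics": metrics,
        "uq": uq_report.to_json_dict(),
        "sweep": sweep_table,
        "manifest": manifest,
    }


def report(outdir) -> str:
    """Human-readable summary of a run directory's artifacts.

    Renders the reliability-sweep comparison and the surrogate-accuracy
    block; missing artifacts are listed rather than fatal.
    """
    out = Path(outdir)
    lines: list[str] = []
    missing: list[str] = []

    mpath = out / "metrics.json"
    if mpath.exists():
        with open(mpath) as fh:
            metrics = json.load(fh)
        lines.append("Surrogate accuracy:")
        for split, block in metrics.items():
            for rname, m in block.items():
                re_lo, re_hi = m["RE_percent"]
                r2 = m["R2"]
                lines.append(
                    f"  {split:<10s} {rname:<4s} RE [{re_lo:+.3f}%, {re_hi:+.3f}%]  "
                    f"R^2 = {r2:.4f}" if r2 is not None else
                    f"  {split:<10s} {rname:<4s} R^2 undefined"
                )
    else:
        missing.append("metrics.json")

    upath = out / "uq_report.json"
    if upath.exists():
        with open(upath) as fh:
            uq = json.load(fh)
        st_lo, st_hi = uq["ST_interval"]
        hpm_lo, hpm_hi = uq["HPM_interval"]
        verdict = "reliable" if uq["reliable"] else "UNRELIABLE"
        lines.append(
            f"Uncertainty over the design domain: ST [{st_lo:.2f}, {st_hi:.2f}] degC, "
            f"HPM [{hpm_lo:.2f}, {hpm_hi:.2f}] degC -> {verdict} "
            f"(allowable {uq['allowable_ST']} degC, RPDI {uq['ST_rpdi']:.3f})"
        )
    else:
        missing.append("uq_report.json")

    spath = out / "sweep.csv"
    if spath.exists():
        sweep = pd.read_csv(spath)
        lines.append("Optimal solutions by reliability level:")
        lines.append(
            sweep.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
                columns=[c for c in sweep.columns if c != "objective"],
            )
        )
    else:
        missing.append("sweep.csv")

    if not lines:
        return "nothing to summarize"
    if missing:
        lines.append(f"Missing artifacts: {', '.join(missing)}")
    return "\n".join(lines)
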