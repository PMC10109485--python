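"""Shared fixtures.

``pde_study`` is the expensive one: the full reduced-fidelity study
(50 training + 20 validation bioheat runs, surrogate fit, domain-wide
interval analysis and the reliability-level sweep).  It is session-scoped so
the indicator-level acceptance tests share a single computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from moxiopt.bioheat import coarse_config, simulate_indicators
from moxiopt.doe import DesignTable, SurrogateModel, evaluate_responses, fit_metrics, latin_hypercube, train_rbnn
from moxiopt.interval_opt import GASettings, rpdi_sweep
from moxiopt.pipeline import PipelineConfig, build_problem
from moxiopt.synthetic import DESIGN_DOMAIN, design_domain_box, make_pseudo_simulator
from moxiopt.uq import response_interval


@pytest.fixture(scope="session")
def pseudo_sim():
    return make_pseudo_simulator(seed=0)


@pytest.fixture(scope="session")
def pseudo_surrogate(pseudo_sim):
    """Surrogate trained on the pseudo-simulator (cheap, shared)."""
    domain = design_domain_box()
    names = tuple(DESIGN_DOMAIN)
    design = latin_hypercube(50, domain, 42, names=names)
    responses = evaluate_responses(design, pseudo_sim)
    return train_rbnn(design, responses)


@dataclass
class PdeStudy:
    design: DesignTable
    responses: pd.DataFrame
    validation: DesignTable
    validation_responses: pd.DataFrame
    model: SurrogateModel
    validation_r2: dict[str, float]
    max_st: float
    sweep: pd.DataFrame


@pytest.fixture(scope="session")
def pde_study() -> PdeStudy:
    """The reduced-fidelity surrogate study behind the indicator-level checks."""
    domain = design_domain_box()
    names = tuple(DESIGN_DOMAIN)
    sim_cfg = coarse_config()
    simulator = lambda t1, d, h, wc: simulate_indicators(t1, d, h, wc, config=sim_cfg)

    design = latin_hypercube(50, domain, 42, names=names)
    responses = evaluate_responses(design, simulator)
    validation = latin_hypercube(20, domain, 43, names=names)
    val_responses = evaluate_responses(validation, simulator)
    model = train_rbnn(design, responses)

    pred = model.predict(validation.values)
    r2 = {
        name: fit_metrics(val_responses[name].to_numpy(), pred[:, i]).r2
        for i, name in enumerate(model.response_names)
    }

    st_grid = response_interval(model.response("ST"), domain, "grid-oracle")
    st_local = response_interval(model.response("ST"), domain, "multistart-local", seed=42)
    max_st = max(st_grid.upper, st_local.upper)

    problem = build_problem(model, PipelineConfig())
    sweep, _ = rpdi_sweep(problem, [0.8, 0.9, 1.0, 1.1], ga=GASettings(), seed=42)

    return PdeStudy(
        design=design,
        responses=responses,
        validation=validation,
        validation_responses=val_responses,
        model=model,
        validation_r2=r2,
        max_st=max_st,
        sweep=sweep,
    )
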