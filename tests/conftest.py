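"""Shared fixtures.

The expensive study-condition experiments (cross-validated signal recovery,
the stack-vs-virtual ablation, the end-to-end smoke run) are computed once
per session and shared between the acceptance tests and the property tests
that examine different aspects of the same runs.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from stackmil.config import ablation_scale, desk_scale
from stackmil.evaluate import cross_validate, stack_vs_virtual_experiment
from stackmil.simulate import MARKERS, SpecimenBag, SynthConfig, generate_cohort
from stackmil.utils import derive_rng


@pytest.fixture(scope="session")
def desk_cfg():
    return desk_scale(seed=11)


@pytest.fixture(scope="session")
def small_cohort(desk_cfg):
    """12 specimens at desk scale, morphology-labelled."""
    bags, table = generate_cohort(desk_cfg.synth, 12, 0.5, seed=11)
    return bags, table


def _cv_kwargs(cfg):
    return dict(encoder_spec=cfg.encoder, ssl_config=cfg.ssl,
                aug_config=cfg.augment, zspec=cfg.zintegrator,
                clf_config=cfg.classifier)


@pytest.fixture(scope="session")
def signal_recovery():
    """100-specimen morphology-signal cohort: 5-fold CV with fold-consistent
    contrastive pretraining, plus a label-permuted null control."""
    cfg = desk_scale(seed=5)
    bags, _ = generate_cohort(cfg.synth, 100, 0.5, seed=5)
    report = cross_validate(bags, marker="ER", mode="attention", k=5, seed=5,
                            use_ssl=True, **_cv_kwargs(cfg))

    rng = derive_rng(5, "label-permutation")
    labels = [b.labels["ER"] for b in bags]
    permuted = [int(labels[i]) for i in rng.permutation(len(labels))]
    null_bags = [
        SpecimenBag(specimen_id=b.specimen_id, tiles=b.tiles,
                    labels={m: lab for m in MARKERS})
        for b, lab in zip(bags, permuted)
    ]
    null_report = cross_validate(null_bags, marker="ER", mode="attention", k=5,
                                 seed=5, use_ssl=True, **_cv_kwargs(cfg))
    return {"report": report, "null_report": null_report}


@pytest.fixture(scope="session")
def ablation():
    """Stack-vs-virtual ablation under the frozen study conditions: signal
    arm over 5 seeds (with the 2D best-focus baseline), negative-control arm
    (signal in the best-focus plane) over 3 seeds."""
    cond = ablation_scale(seed=0)
    signal = stack_vs_virtual_experiment(
        cond["synth_signal"], cond["n_specimens"], seeds=[1, 2, 3, 4, 5],
        include_best_focus_2d=True, **cond["cv_kwargs"])
    control = stack_vs_virtual_experiment(
        cond["synth_control"], cond["n_specimens"], seeds=[1, 2, 3],
        **cond["cv_kwargs"])
    return {"signal": signal, "control": control}


@pytest.fixture(scope="session")
def smoke_runs(tmp_path_factory):
    """Two fresh end-to-end pipeline runs with the same seed, plus a cached
    rerun of the first."""
    import time

    from stackmil.pipeline import run_pipeline

    cfg = desk_scale(seed=7, n_specimens=20)
    cfg = dataclasses.replace(cfg, evaluate=dataclasses.replace(cfg.evaluate, k=3))
    t0 = time.time()
    out_a = tmp_path_factory.mktemp("run_a")
    res_a = run_pipeline(cfg, out_root=out_a, log=lambda *a: None)
    elapsed = time.time() - t0
    res_cached = run_pipeline(cfg, out_root=out_a, log=lambda *a: None)
    out_b = tmp_path_factory.mktemp("run_b")
    res_b = run_pipeline(cfg, out_root=out_b, log=lambda *a: None)
    return {"config": cfg, "elapsed_first": elapsed, "out_a": out_a,
            "out_b": out_b, "res_a": res_a, "res_b": res_b,
            "res_cached": res_cached}
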