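import numpy as np
import pytest

from empatch import cohort, pipeline, sensors, workflow
from empatch.nn import MTLConfig


@pytest.fixture(scope="session")
def device_params():
    return sensors.device_channel_params()


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured chronic cohort (12 animals/group)."""
    cfg = cohort.CohortConfig(n_per_group=12, seed=101)
    return cfg, cohort.simulate_chronic(cfg)


def tiny_mtl_config(**overrides) -> MTLConfig:
    """A miniature network config for fast property-level training runs."""
    base = dict(conv_channels=(8, 8, 8, 8, 8), epochs=40, batch_size=16,
                lr=3e-3, seed=7)
    base.update(overrides)
    return MTLConfig(**base)


@pytest.fixture(scope="session")
def tiny_trained():
    """A quick end-to-end training run on a reduced cohort (shared)."""
    cfg = cohort.CohortConfig(n_per_group=15, seed=202)
    panels = cohort.simulate_chronic(cfg)
    ws = pipeline.build_windows(panels, T=8, seed=203)
    folds = pipeline.make_stratified_folds(
        ws.y_class, ws.y_degree, k=5, seed=204, subject_ids=ws.subject_ids
    )
    models, metrics, history = pipeline.train_mtl(ws, folds, tiny_mtl_config())
    return {"windows": ws, "folds": folds, "models": models,
            "metrics": metrics, "history": history}


@pytest.fixture(scope="session")
def default_run():
    """The full default cross-validation experiment (the headline run).

    Session-scoped because it trains five networks on 1500 windows; every
    test that needs a competent model shares it.
    """
    return workflow.default_cv_experiment(seed=0)
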