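"""Shared fixtures.

``study`` runs the full reference analysis once per session (default
generator conditions: 400 HC / 116 BP / 94 SZ, ~3,800-voxel mask): healthy
10-fold cross-validated Z-maps, patient transfer Z-maps, the all-healthy
normative fit, and the generator's ground truth.  The heavier end-to-end
checks all share it.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from normdev import (
    GeneratorConfig,
    compute_z,
    crossvalidated_z,
    fit_normative,
    generate_cohort,
    generate_voxel_data,
)

STUDY_SEED = 101


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Small grid / cohort for fast unit tests (~330 voxels)."""
    return GeneratorConfig(
        n_hc=60, n_bp=16, n_sz=16, dims=(10, 12, 10), seed=5,
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    cohort = generate_cohort(small_config)
    space, Y, truth = generate_voxel_data(cohort, small_config)
    return SimpleNamespace(
        config=small_config, cohort=cohort, space=space, Y=Y, truth=truth,
        X=cohort[["age", "sex"]].to_numpy(float),
        groups=cohort["group"].to_numpy(),
    )


@pytest.fixture(scope="session")
def study():
    cfg = GeneratorConfig(seed=STUDY_SEED)
    cohort = generate_cohort(cfg)
    space, Y, truth = generate_voxel_data(cohort, cfg)
    X = cohort[["age", "sex"]].to_numpy(float)
    groups = cohort["group"].to_numpy()
    healthy = groups == "HC"

    model = fit_normative(Y[healthy], X[healthy], seed=STUDY_SEED + 1)
    cv, cv_pred = crossvalidated_z(
        Y[healthy], X[healthy], k=10, seed=STUDY_SEED + 2,
        return_predictions=True,
    )
    pred_pat = model.predict(X[~healthy], warn_extrapolation=False)
    transfer = compute_z(Y[~healthy], pred_pat)

    Z = np.empty_like(Y)
    Z[healthy] = cv.Z
    Z[~healthy] = transfer.Z

    return SimpleNamespace(
        config=cfg, cohort=cohort, space=space, Y=Y, truth=truth, X=X,
        groups=groups, healthy=healthy, model=model, cv=cv, cv_pred=cv_pred,
        Z=Z,
    )
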