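"""Shared fixtures.

The heavy objects (trained directional ensemble, reference set, RL banks) are
session-scoped: one desk-scale pipeline is trained once and shared by every
test that flies missions.
"""

from __future__ import annotations

import numpy as np
import pytest

from cropscout.experiment_runner import Pipeline, desk_scale_spec, prepare_pipeline
from cropscout.neighbor_models import (
    ConstantBackend,
    DirectionalEnsemble,
    DirectionalPredictor,
    ReferenceSet,
    ScoutingModels,
)
from cropscout.grid_core import Direction
from cropscout.synthetic_field import make_field


@pytest.fixture(scope="session")
def pipeline() -> Pipeline:
    """Desk-scale pipeline: quarter-scale fields, trained ensemble, RL banks."""
    return prepare_pipeline(desk_scale_spec(), seed=1)


@pytest.fixture(scope="session")
def test_field(pipeline):
    """One held-out synthetic field (not part of training or reference)."""
    return make_field(desk_scale_spec(seed=424242))


def stub_models(p: float = 0.9, reference: ReferenceSet | None = None) -> ScoutingModels:
    """ScoutingModels whose eight backends all return a constant probability."""
    ens = DirectionalEnsemble(
        predictors={d: DirectionalPredictor(d, ConstantBackend(p)) for d in Direction}
    )
    models = ScoutingModels(ens, reference)
    # constant backends need no field cache; give lookups a direct route
    models.source_dir_prob = lambda source, d, _p=p: _p  # type: ignore[assignment]
    return models


def stub_reference(confidences) -> ReferenceSet:
    """Reference set of black 2x2 tiles with prescribed confidences."""
    confs = np.asarray(confidences, dtype=float)
    tiles = [np.zeros((2, 2, 3), dtype=np.uint8) for _ in confs]
    return ReferenceSet(tiles=tiles, confidences=confs, dir_probs=np.tile(confs[:, None], (1, 8)))
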