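"""Desk-scale experimental sweeps.

Reproduces, on synthetic fields, the shape of the method's evaluation:
coverage x window-size accuracy surfaces, a largely-healthy vs
largely-unhealthy case study, and multi-policy economics comparisons.
Everything is deterministic under the seed; run metadata records the
desk-scale shrinkage relative to the full-scale configuration (1000 paths per
combination, 73k-record RL banks).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assessment
from .grid_core import FieldGrid
from .mission import POLICIES, BatteryModel, run_mission
from .neighbor_models import ReferenceSet, ScoutingModels, build_reference, train_directional
from .rl_pathfinder import RLDataset, build_rl_dataset
from .synthetic_field import SyntheticFieldSpec, make_dataset, make_field

#: Full-scale configuration, reachable via config (desk defaults are far smaller).
FULL_STUDY_SCALE = {
    "coverages": (0.1, 0.2, 0.3, 0.4, 0.5, 0.6),
    "window_sizes": (7, 11, 15, 19, 23),
    "n_paths": 1000,
    "n_train_fields": 30,
    "n_test_fields": 6,
    "n_reference_fields": 14,
}


def desk_scale_spec(seed: int = 0, **overrides) -> SyntheticFieldSpec:
    """Quarter-scale replica of the full-scale field used for desk-scale runs.

    16 x 21 zones with correlation length 2 preserves the full field's
    cluster-to-field ratio (scale 4 on 32 rows); all other generator
    parameters keep their defaults.
    """
    params = {"rows": 16, "cols": 21, "cluster_scale": 2.0, "seed": seed}
    params.update(overrides)
    return SyntheticFieldSpec(**params)


@dataclass
class Pipeline:
    """Trained models plus RL banks, ready to fly missions."""

    spec: SyntheticFieldSpec
    models: ScoutingModels
    ref: ReferenceSet
    rl_datasets: dict  # (coverage, w) -> RLDataset (window encoding)
    local_datasets: dict  # (coverage, w) -> RLDataset (local encoding)
    train_fields: list
    test_fields: list

    def rl_for(self, coverage: float, w: int) -> RLDataset:
        return _closest(self.rl_datasets, coverage, w)

    def local_for(self, coverage: float, w: int) -> RLDataset:
        return _closest(self.local_datasets, coverage, w)


def _closest(datasets: dict, coverage: float, w: int) -> RLDataset:
    key = min(datasets, key=lambda k: (abs(k[0] - coverage), abs(k[1] - w)))
    return datasets[key]


def prepare_pipeline(
    spec: SyntheticFieldSpec,
    seed: int,
    n_train_fields: int = 3,
    n_test_fields: int = 1,
    n_reference_tiles: int = 300,
    rl_coverages=(0.4,),
    rl_window_sizes=(7,),
    n_paths: int = 40,
    k: int = 11,
) -> Pipeline:
    """Generate data, train the directional ensemble, score the reference set
    and build the RL experience banks (both encodings)."""
    spec = spec.with_seed(seed)
    train, test, ref_tiles = make_dataset(spec, n_train_fields, n_test_fields, n_reference_tiles)
    ensemble = train_directional(train, seed=seed)
    ref = build_reference([t for t, _ in ref_tiles], ensemble)
    models = ScoutingModels(ensemble, ref)
    rng = np.random.default_rng([seed % (2**31), 77])
    rl = build_rl_dataset(
        train, rl_coverages, rl_window_sizes, n_paths, models, ref, rng, k=k
    )
    rng_local = np.random.default_rng([seed % (2**31), 78])
    local = build_rl_dataset(
        train, rl_coverages, rl_window_sizes, n_paths, models, ref, rng_local, k=k,
        encoding="local",
    )
    return Pipeline(spec, models, ref, rl, local, train, test)


def evaluate_mission(result, grid: FieldGrid, econ=None, hours_per_charge=None) -> dict:
    """Metrics + economics for one mission on one field."""
    c = assessment.confusion(result.predicted_map, grid.truth_labels)
    m = assessment.metrics(c)
    kwargs = {} if hours_per_charge is None else {"hours_per_charge": hours_per_charge}
    labor = assessment.labor_cost(result.policy, result.charges, econ, **kwargs)
    return {
        **m,
        "charges": result.charges,
        "n_steps": result.n_steps,
        "labor_cost": labor,
        "net_revenue": assessment.net_revenue(c, labor, econ),
        "runoff_risk": assessment.runoff_risk(c),
    }


def sweep(
    policies,
    coverages,
    window_sizes,
    n_fields: int,
    seed: int,
    spec: SyntheticFieldSpec | None = None,
    pipeline: Pipeline | None = None,
    battery: BatteryModel | None = None,
) -> pd.DataFrame:
    """One row per (policy, coverage, window size, field): metrics + economics.

    Fields are fresh synthetic draws (seeded); the pipeline (models + RL
    banks) is built once and shared across the sweep.
    """
    if spec is None:
        spec = desk_scale_spec(seed)
    if pipeline is None:
        pipeline = prepare_pipeline(spec, seed, rl_window_sizes=tuple(window_sizes))
    rows = []
    for f_idx in range(n_fields):
        grid = make_field(spec.with_seed(900_000 + seed * 1000 + f_idx))
        for coverage in coverages:
            for w in window_sizes:
                for policy in policies:
                    rng = np.random.default_rng(
                        [seed % (2**31), f_idx, int(coverage * 100), w, POLICIES.index(policy)]
                    )
                    rl = None
                    if policy == "whole_field":
                        rl = pipeline.rl_for(coverage, w)
                    elif policy == "local_field":
                        rl = pipeline.local_for(coverage, w)
                    result = run_mission(
                        policy,
                        grid,
                        coverage,
                        rng,
                        models=pipeline.models,
                        ref=pipeline.ref,
                        rl_dataset=rl,
                        battery=battery,
                        window_size=w,
                    )
                    rows.append(
                        {
                            "policy": policy,
                            "coverage": coverage,
                            "window_size": w,
                            "field": f_idx,
                            "seed": seed,
                            **evaluate_mission(result, grid),
                        }
                    )
    return pd.DataFrame(rows)


def case_study(
    healthy_spec: SyntheticFieldSpec,
    unhealthy_spec: SyntheticFieldSpec,
    coverages=(0.2, 0.4),
    n_fields: int = 3,
    seed: int = 0,
    pipeline: Pipeline | None = None,
    window_size: int = 7,
) -> pd.DataFrame:
    """Whole-field scouting on a largely healthy vs largely unhealthy field.

    Reports accuracy per field type per coverage plus the accuracy delta from
    doubling coverage (the low end of ``coverages`` to the high end).
    """
    if pipeline is None:
        pipeline = prepare_pipeline(healthy_spec, seed, rl_window_sizes=(window_size,))
    rows = []
    for type_idx, (name, spec) in enumerate(
        (("healthy", healthy_spec), ("unhealthy", unhealthy_spec))
    ):
        for f_idx in range(n_fields):
            grid = make_field(spec.with_seed(700_000 + seed * 100 + f_idx))
            for coverage in coverages:
                rng = np.random.default_rng(
                    [seed % (2**31), f_idx, int(coverage * 100), type_idx]
                )
                result = run_mission(
                    "whole_field",
                    grid,
                    coverage,
                    rng,
                    models=pipeline.models,
                    ref=pipeline.ref,
                    rl_dataset=pipeline.rl_for(coverage, window_size),
                    window_size=window_size,
                )
                c = assessment.confusion(result.predicted_map, grid.truth_labels)
                rows.append(
                    {
                        "field_type": name,
                        "field": f_idx,
                        "coverage": coverage,
                        "accuracy": assessment.metrics(c)["accuracy"],
                    }
                )
    df = pd.DataFrame(rows)
    summary = df.groupby(["field_type", "coverage"], as_index=False)["accuracy"].mean()
    lo, hi = min(coverages), max(coverages)
    deltas = []
    for name in ("healthy", "unhealthy"):
        sub = summary[summary.field_type == name].set_index("coverage")["accuracy"]
        deltas.append(
            {"field_type": name, "coverage": np.nan, "accuracy": np.nan,
             "doubling_gain": float(sub[hi] - sub[lo])}
        )
    summary["doubling_gain"] = np.nan
    return pd.concat([summary, pd.DataFrame(deltas)], ignore_index=True)
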