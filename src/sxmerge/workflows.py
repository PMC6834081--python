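"""End-to-end convenience workflows: simulate/load -> correct -> group ->
initialize -> refine.

These wrappers chain the module-level operations in the standard order and
are what the command-line interface, the examples and the acceptance
checks drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_model import ReflectionGroup, group_by_miller, iter_groups
from .ev11 import (
    ErrorModelParams,
    NormalProbabilityPlot,
    PreparedGroups,
    RefinementResult,
    deviations_for_plot,
    initialize_params,
    normal_probability_plot,
    prepare_groups,
    refine_error_model,
)
from .scaling import apply_corrections
from .synthetic_data import SimulatedDataset, SimulationConfig, get_preset, simulate_dataset

__all__ = ["RefinedSimulation", "correct_and_group", "refine_groups", "refine_simulated"]


def correct_and_group(
    measurements: pd.DataFrame,
    images: pd.DataFrame,
    space_group: str = "P1",
    anomalous: bool = True,
) -> list[ReflectionGroup]:
    """Scale partial measurements to full equivalents and group by ASU index."""
    corrected = apply_corrections(measurements, images)
    return list(iter_groups(group_by_miller(corrected, space_group, anomalous)))


@dataclass
class RefinedSimulation:
    """Everything produced by a simulate -> refine chain."""

    dataset: SimulatedDataset
    groups: list[ReflectionGroup]
    prepared: PreparedGroups
    plot: NormalProbabilityPlot
    init: ErrorModelParams
    result: RefinementResult


def refine_groups(
    groups: list[ReflectionGroup],
    n_bins: int = 100,
    max_iter: int = 200,
) -> tuple[NormalProbabilityPlot, ErrorModelParams, RefinementResult, PreparedGroups]:
    """Normal-probability initialization followed by L-BFGS refinement."""
    plot = normal_probability_plot(deviations_for_plot(groups))
    init = initialize_params(plot.slope, plot.offset)
    prepared = prepare_groups(groups, n_bins=n_bins)
    result = refine_error_model(prepared, init, max_iter=max_iter)
    return plot, init, result, prepared


def refine_simulated(
    config: SimulationConfig | str,
    seed: int | None = None,
    n_bins: int = 100,
) -> RefinedSimulation:
    """Simulate a dataset (preset name or config) and refine its error model."""
    if isinstance(config, str):
        config = get_preset(config, seed)
    ds = simulate_dataset(config)
    groups = correct_and_group(ds.measurements, ds.images)
    plot, init, result, prepared = refine_groups(groups, n_bins=n_bins)
    return RefinedSimulation(
        dataset=ds, groups=groups, prepared=prepared, plot=plot,
        init=init, result=result,
    )
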