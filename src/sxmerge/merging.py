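"""Merging of corrected still-image measurements under three error protocols.

Protocol 1 (unweighted): the merged intensity is the plain mean and the
merged error is the standard error of the mean computed from the observed
spread of the measurements (sample standard deviation with n - 1).

Protocol 2 (counting-weighted): inverse-variance weights from the
photon-counting sigmas; merged error is the propagated weighted-mean error
(sum of weights)^(-1/2). Because counting sigmas know nothing about the
scatter introduced by imperfect partiality correction, these merged errors
can be far smaller than the protocol-1 spread-based ones.

Protocol 3 (Ev11): identical machinery to protocol 2 but with weights from
the inflated error model sigma_Ev11 (see :mod:`sxmerge.ev11`); with identity
parameters (s_fac, s_B, s_add) = (1, 0, 0) it reduces to protocol 2 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .data_model import MergedReflection, ReflectionGroup, ValidationError
from .ev11 import ErrorModelParams, sigma_ev11

__all__ = [
    "MergePolicy",
    "merge_unweighted",
    "counting_weights",
    "merge_weighted",
    "merge_group",
    "merge_dataset",
    "merged_to_dataframe",
]

Protocol = Literal["unweighted", "counting_weighted", "ev11"]


@dataclass
class MergePolicy:
    """Which merge protocol to run and with what settings.

    ``weighted_sem`` selects the weighted merged-error form: "propagated"
    (default, (sum w)^(-1/2)) or "spread" (weighted spread about the weighted
    mean, for sensitivity analysis).
    """

    protocol: Protocol = "unweighted"
    params: ErrorModelParams | None = None
    min_multiplicity: int = 1
    weighted_sem: Literal["propagated", "spread"] = "propagated"

    def __post_init__(self) -> None:
        if self.protocol == "ev11" and self.params is None:
            raise ValidationError("protocol 'ev11' requires error-model params")


def merge_unweighted(group: ReflectionGroup) -> MergedReflection:
    """Protocol 1: mean intensity, spread-based standard error of the mean.

    For n = 1 the spread is undefined (0/0); the measurement's own counting
    sigma is emitted and flagged, since spread-based errors are unreliable at
    low redundancy anyway.
    """
    i = np.asarray(group.intensities, dtype=float)
    n = len(i)
    mean = float(i.mean())
    if n == 1:
        return MergedReflection(
            hkl=group.hkl, i_merged=mean, sigma_merged=float(group.sigmas[0]),
            multiplicity=1, mean_raw=mean, stol2=_mean_stol2(group),
            sigma_is_fallback=True,
        )
    sigma_res = float(np.sqrt(np.sum((i - mean) ** 2) / (n - 1)))
    return MergedReflection(
        hkl=group.hkl, i_merged=mean, sigma_merged=sigma_res / np.sqrt(n),
        multiplicity=n, mean_raw=mean, stol2=_mean_stol2(group),
    )


def counting_weights(sigmas: np.ndarray) -> np.ndarray:
    """Inverse-variance weights w = 1/sigma^2."""
    s = np.asarray(sigmas, dtype=float)
    if (s <= 0).any():
        raise ValidationError("all sigmas must be > 0 to form weights")
    return 1.0 / s**2


def merge_weighted(
    group: ReflectionGroup,
    weights: np.ndarray,
    sem: Literal["propagated", "spread"] = "propagated",
) -> MergedReflection:
    """Weighted mean with weighted standard error of the mean."""
    i = np.asarray(group.intensities, dtype=float)
    w = np.asarray(weights, dtype=float)
    if len(w) != len(i):
        raise ValidationError(f"{len(w)} weights for {len(i)} measurements")
    if (w <= 0).any():
        raise ValidationError("weights must be > 0")
    sw = float(w.sum())
    mean_w = float(np.sum(w * i) / sw)
    n = len(i)
    if sem == "spread" and n > 1:
        sigma = float(np.sqrt(np.sum(w * (i - mean_w) ** 2) / ((n - 1) * sw)))
    else:
        sigma = float(sw ** -0.5)
    return MergedReflection(
        hkl=group.hkl, i_merged=mean_w, sigma_merged=sigma, multiplicity=n,
        mean_raw=float(i.mean()), stol2=_mean_stol2(group),
    )


def _mean_stol2(group: ReflectionGroup) -> float:
    return float(np.mean(group.stol2)) if group.stol2 is not None else np.nan


def merge_group(group: ReflectionGroup, policy: MergePolicy) -> MergedReflection:
    """Merge one reflection group under the policy's protocol."""
    if policy.protocol == "unweighted":
        return merge_unweighted(group)
    if policy.protocol == "counting_weighted":
        return merge_weighted(group, counting_weights(group.sigmas), policy.weighted_sem)
    sig = sigma_ev11(group.sigmas, group.mean, policy.params)
    return merge_weighted(group, counting_weights(sig), policy.weighted_sem)


def merge_dataset(
    groups: Iterable[ReflectionGroup], policy: MergePolicy
) -> list[MergedReflection]:
    """Merge every group, dropping those below the policy's min multiplicity."""
    return [
        merge_group(g, policy) for g in groups if g.n >= policy.min_multiplicity
    ]


def merged_to_dataframe(merged: Iterable[MergedReflection]) -> pd.DataFrame:
    """Tabulate merged reflections in the merged-table column layout."""
    rows = [
        {
            "h": m.hkl[0], "k": m.hkl[1], "l": m.hkl[2],
            "i_merged": m.i_merged, "sigma_merged": m.sigma_merged,
            "multiplicity": m.multiplicity, "mean_raw": m.mean_raw,
            "stol2": m.stol2,
        }
        for m in merged
    ]
    return pd.DataFrame(
        rows,
        columns=["h", "k", "l", "i_merged", "sigma_merged", "multiplicity",
                 "mean_raw", "stol2"],
    )
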