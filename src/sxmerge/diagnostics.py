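"""Merged-data quality statistics: CC1/2, resolution-binned I/sigma, 2-D
intensity/signal-to-noise histograms.

All outputs are machine-readable tables/arrays; plotting is left to the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import ReflectionGroup, ValidationError
from .merging import MergePolicy, merge_group

__all__ = [
    "ResolutionBinnedStats",
    "cc_half",
    "i_over_sigma_table",
    "i_vs_isigma_histogram",
]


@dataclass
class ResolutionBinnedStats:
    """Per-resolution-shell means of merged I, sigma and I/sigma."""

    d_edges: np.ndarray      # shell boundaries in d-spacing (A), low to high res
    mean_i: np.ndarray
    mean_sigma: np.ndarray
    mean_i_over_sigma: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "d_low": self.d_edges[:-1], "d_high": self.d_edges[1:],
            "mean_i": self.mean_i, "mean_sigma": self.mean_sigma,
            "mean_i_over_sigma": self.mean_i_over_sigma, "count": self.counts,
        })


def cc_half(
    groups: Sequence[ReflectionGroup],
    seed: int = 0,
    policy: MergePolicy | None = None,
) -> float:
    """Half-dataset correlation coefficient.

    Each group's measurements (n >= 2) are split randomly into two halves,
    each half is merged under ``policy`` (default: unweighted mean), and the
    Pearson correlation of the two half-dataset intensities is returned.
    Returns NaN with a warning when fewer than 3 groups are usable.
    """
    import warnings

    policy = policy or MergePolicy(protocol="unweighted")
    rng = np.random.default_rng(seed)
    a_vals, b_vals = [], []
    for g in groups:
        if g.n < 2:
            continue
        perm = rng.permutation(g.n)
        half = g.n // 2
        if g.n % 2 == 1:  # odd measurement joins a random half
            half += int(rng.integers(0, 2))
        ia, ib = perm[:half], perm[half:]
        if len(ia) == 0 or len(ib) == 0:
            continue
        for idx, dest in ((ia, a_vals), (ib, b_vals)):
            sub = ReflectionGroup(
                hkl=g.hkl,
                intensities=g.intensities[idx],
                sigmas=g.sigmas[idx],
                stol2=g.stol2[idx] if g.stol2 is not None else None,
            )
            dest.append(merge_group(sub, policy).i_merged)
    if len(a_vals) < 3:
        warnings.warn("fewer than 3 usable groups; CC1/2 undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(np.corrcoef(a_vals, b_vals)[0, 1])


def i_over_sigma_table(merged: pd.DataFrame, n_bins: int = 10) -> ResolutionBinnedStats:
    """Equal-volume resolution shells (uniform in 1/d^3) of merged statistics.

    Expects the merged table to carry a ``stol2`` column
    (1/d^3 = (4 stol2)^(3/2)).
    """
    stol2 = merged["stol2"].to_numpy(dtype=float)
    i = merged["i_merged"].to_numpy(dtype=float)
    s = merged["sigma_merged"].to_numpy(dtype=float)
    vol = stol2 ** 1.5
    edges = np.linspace(vol.min(), vol.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, vol, side="right") - 1, 0, n_bins - 1)
    mean_i = np.full(n_bins, np.nan)
    mean_s = np.full(n_bins, np.nan)
    mean_isig = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    with np.errstate(divide="ignore", invalid="ignore"):
        isig = np.where(s > 0, i / s, np.nan)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = int(mask.sum())
        if counts[b]:
            mean_i[b] = float(i[mask].mean())
            mean_s[b] = float(s[mask].mean())
            mean_isig[b] = float(np.nanmean(isig[mask]))
    stol2_edges = edges ** (2.0 / 3.0)
    with np.errstate(divide="ignore"):
        d_edges = np.where(stol2_edges > 0, 1.0 / (2.0 * np.sqrt(stol2_edges)), np.inf)
    return ResolutionBinnedStats(
        d_edges=d_edges, mean_i=mean_i, mean_sigma=mean_s,
        mean_i_over_sigma=mean_isig, counts=counts,
    )


def i_vs_isigma_histogram(
    intensities: np.ndarray,
    sigmas: np.ndarray,
    i_edges: np.ndarray,
    isig_edges: np.ndarray,
) -> np.ndarray:
    """2-D histogram of (I, I/sigma) over a fixed grid; total count conserved.

    Values outside the grid are clipped into the edge cells so the grid total
    always equals the number of measurements.
    """
    i = np.asarray(intensities, dtype=float)
    s = np.asarray(sigmas, dtype=float)
    if (s <= 0).any():
        raise ValidationError("sigmas must be > 0")
    isig = i / s
    i_edges = np.asarray(i_edges, dtype=float)
    isig_edges = np.asarray(isig_edges, dtype=float)
    eps_i = np.finfo(float).tiny
    i_c = np.clip(i, i_edges[0], np.nextafter(i_edges[-1], -np.inf))
    isig_c = np.clip(isig, isig_edges[0], np.nextafter(isig_edges[-1], -np.inf))
    hist, _, _ = np.histogram2d(i_c, isig_c, bins=[i_edges, isig_edges])
    return hist
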