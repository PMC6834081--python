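"""Scaling of partial still-image intensities to full equivalents.

Each partial observation I^P_hj is converted to its full-intensity
equivalent by a multiplicative factor

    K_hj = [ G_c * exp(-2 * B_c * sin^2(theta)/lambda^2) * P_hj ]^-1

where G_c and B_c are the per-image scale and Wilson B factor from
post-refinement and P_hj is the partiality fraction. Since partial
observations are smaller than their full equivalents, K >= 1 whenever
P < 1 at G = 1, B = 0. The same factor is applied to the counting sigma,
so per-measurement I/sigma is preserved exactly.

A per-image resolution filter removes the high-resolution tail of each
image where the mean signal-to-noise ratio drops below a threshold; when
intensities are rescaled from detector units to photons by a gain factor
and sigmas are recomputed from the photon counts, I/sigma shrinks by
sqrt(gain) and the threshold must shrink with it (0.5 -> 0.1 for gain 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ImageModel, Measurement, ValidationError

__all__ = [
    "CorrectionFactor",
    "gain_correct",
    "gain_correct_table",
    "rescaled_filter_threshold",
    "correction_factor",
    "apply_corrections",
    "per_image_resolution_filter",
    "filter_dataset",
]


@dataclass
class CorrectionFactor:
    """Partial-to-full correction K_hj with its constituent factors."""

    value: float
    scale: float
    wilson_term: float
    partiality: float


def gain_correct(
    intensities: np.ndarray,
    sigmas: np.ndarray,
    gain: float,
    recompute_sigma: bool = False,
    sigma_floor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert detector-unit intensities to photons by dividing by ``gain``.

    By default sigmas are divided by the same factor (pure unit change,
    I/sigma preserved).  With ``recompute_sigma=True`` the counting sigma is
    re-derived as sqrt(photon count) — floored at ``sigma_floor`` photons —
    which is how a gain correction reduces I/sigma by sqrt(gain).
    """
    if gain <= 0:
        raise ValidationError(f"gain must be > 0, got {gain}")
    i = np.asarray(intensities, dtype=float) / gain
    if recompute_sigma:
        s = np.sqrt(np.maximum(i, sigma_floor))
    else:
        s = np.asarray(sigmas, dtype=float) / gain
    return i, s


def gain_correct_table(
    measurements: pd.DataFrame, gain: float, recompute_sigma: bool = False
) -> pd.DataFrame:
    """Apply :func:`gain_correct` to the i_partial/sigma_partial columns."""
    df = measurements.copy()
    i, s = gain_correct(
        df["i_partial"].to_numpy(), df["sigma_partial"].to_numpy(), gain,
        recompute_sigma=recompute_sigma,
    )
    df["i_partial"] = i
    df["sigma_partial"] = s
    return df


def rescaled_filter_threshold(threshold: float, gain: float) -> float:
    """Rescale an I/sigma filter threshold after a gain correction.

    I/sigma decreases with the square root of the gain, so a threshold chosen
    in detector units must be divided by sqrt(gain) once the data are in
    photons (e.g. 0.5 / sqrt(25) = 0.1).
    """
    if gain <= 0:
        raise ValidationError(f"gain must be > 0, got {gain}")
    return threshold / np.sqrt(gain)


def correction_factor(image: ImageModel, m: Measurement) -> CorrectionFactor:
    """Compute K_hj for one measurement against its image model."""
    if image.image_id != m.image_id:
        raise ValidationError(
            f"image model {image.image_id!r} does not match measurement {m.image_id!r}"
        )
    if m.partiality <= 0:
        raise ValidationError("partiality must be > 0 for a defined correction")
    wilson = float(np.exp(-2.0 * image.wilson_b * m.stol2))
    value = 1.0 / (image.scale * wilson * m.partiality)
    return CorrectionFactor(
        value=value, scale=image.scale, wilson_term=wilson, partiality=m.partiality
    )


def apply_corrections(
    measurements: pd.DataFrame, images: pd.DataFrame
) -> pd.DataFrame:
    """Set i_full = K_hj * i_partial and sigma_full = K_hj * sigma_partial.

    K_hj is treated as an exact constant: the error in the post-refined
    parameters behind it is not propagated. Raises a lookup error naming the
    image_id if any measurement has no matching image model.
    """
    img = images.set_index("image_id")
    missing = set(measurements["image_id"]) - set(img.index)
    if missing:
        raise KeyError(f"no image model for image_id(s): {sorted(missing)[:5]}")
    g = img.loc[measurements["image_id"], "scale"].to_numpy(dtype=float)
    b = img.loc[measurements["image_id"], "wilson_b"].to_numpy(dtype=float)
    p = measurements["partiality"].to_numpy(dtype=float)
    stol2 = measurements["stol2"].to_numpy(dtype=float)
    if (p <= 0).any():
        raise ValidationError("partiality must be > 0 for a defined correction")
    k = 1.0 / (g * np.exp(-2.0 * b * stol2) * p)
    df = measurements.copy()
    df["i_full"] = k * df["i_partial"].to_numpy(dtype=float)
    df["sigma_full"] = k * df["sigma_partial"].to_numpy(dtype=float)
    return df


def per_image_resolution_filter(
    measurements: pd.DataFrame,
    threshold: float = 0.1,
    n_bins: int = 10,
    use_corrected: bool = False,
) -> tuple[pd.DataFrame, float | None]:
    """Apply the per-image I/sigma resolution cutoff to one image's rows.

    The measurements (all sharing one image_id) are binned into ``n_bins``
    equal-volume resolution shells (uniform in 1/d^3, low to high resolution).
    The cutoff is the low-resolution edge of the first shell whose mean
    I/sigma falls below ``threshold``; everything at that resolution or higher
    is removed. Returns the retained rows and the cutoff d-spacing in
    Angstroms (None if no shell fell below threshold).
    """
    if n_bins < 1:
        raise ValidationError(f"n_bins must be >= 1, got {n_bins}")
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    if measurements["image_id"].nunique() > 1:
        raise ValidationError("per-image filter expects measurements of one image")
    icol = ("i_full", "sigma_full") if use_corrected else ("i_partial", "sigma_partial")
    stol2 = measurements["stol2"].to_numpy(dtype=float)
    isig = measurements[icol[0]].to_numpy(dtype=float) / measurements[icol[1]].to_numpy(dtype=float)
    # 1/d^3 = (4*stol2)^(3/2): equal-volume shells are uniform in stol2^(3/2)
    vol = stol2 ** 1.5
    edges = np.linspace(vol.min(), vol.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, vol, side="right") - 1, 0, n_bins - 1)
    cutoff_stol2: float | None = None
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        if float(isig[mask].mean()) < threshold:
            cutoff_stol2 = float(edges[b] ** (2.0 / 3.0))
            break
    if cutoff_stol2 is None:
        return measurements, None
    retained = measurements[stol2 < cutoff_stol2]
    cutoff_d = 1.0 / (2.0 * np.sqrt(cutoff_stol2)) if cutoff_stol2 > 0 else np.inf
    return retained, float(cutoff_d)


def filter_dataset(
    measurements: pd.DataFrame,
    threshold: float = 0.1,
    n_bins: int = 10,
    use_corrected: bool = False,
) -> pd.DataFrame:
    """Apply the per-image resolution filter to every image of a dataset."""
    kept = []
    for _, sub in measurements.groupby("image_id", sort=False):
        retained, _ = per_image_resolution_filter(
            sub, threshold=threshold, n_bins=n_bins, use_corrected=use_corrected
        )
        kept.append(retained)
    return pd.concat(kept, ignore_index=False) if kept else measurements
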