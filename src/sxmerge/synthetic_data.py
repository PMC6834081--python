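"""Synthetic still-diffraction datasets with known ground truth.

The generator emulates the error structure the Ev11 model is meant to
explain, one term at a time:

* true reflection intensities J_h follow Wilson (exponential) statistics for
  acentric reflections in P1;
* each image carries a multiplicative scale G_c, a Wilson B factor B_c and a
  fixed wavelength; each measurement records a partiality fraction P_hj, so
  the expected partial signal is mu = G_c * exp(-2 B_c stol2) * P_hj * J_h
  photons;
* photon counting is Poisson; the detector reports gain_true counts per
  photon, and the analyst divides by gain_assumed — when the two differ by a
  factor g, the reported sigma = sqrt(reported I) is wrong by sqrt(g), which
  is exactly what the s_fac term absorbs;
* an optional Gaussian background term with variance ``background_var``
  photons^2 models the scatter left by background subtraction in the
  integration box; it enters both the noise and the reported sigma
  (sigma^2 = counts + background_var), as integration software does;
* an optional Gaussian instrumental error with standard deviation
  s_add_true * mu is added to the intensity (not the sigma), which is what
  the s_add term absorbs.

Everything is reproducible from the config seed. Zero-count cells receive a
sigma floor of one photon-equivalent so the table never carries sigma <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import ValidationError, write_images, write_measurements

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "make_fixture",
    "PRESETS",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the still-image simulator (defaults: clean Poisson counting)."""

    n_images: int = 200
    reflections_per_image: int = 20
    n_unique: int = 500
    wilson_mean: float = 1000.0          # mean true intensity, photons
    b_range: tuple[float, float] = (0.0, 0.0)   # per-image Wilson B, A^2
    g_range: tuple[float, float] = (1.0, 1.0)   # per-image scale
    partiality_law: str = "ones"         # "ones" | "beta" (Beta(2,1.5) on (0.05, 1])
    gain_true: float = 1.0               # detector units per photon
    gain_assumed: float = 1.0            # gain the analyst divides by
    s_add_true: float = 0.0              # fractional intensity-proportional error
    background_var: float = 0.0          # background variance, photons^2
    resolution_range: tuple[float, float] = (1.8, 20.0)  # d-spacing, A
    cell_a: float = 50.0                 # cubic P1 cell edge, A
    wavelength: float = 1.3              # A
    sigma_floor: float = 1.0             # photon-equivalents
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_images, self.reflections_per_image, self.n_unique) < 1:
            raise ValidationError("all counts must be >= 1")
        if self.gain_true <= 0 or self.gain_assumed <= 0:
            raise ValidationError("gain values must be > 0")
        if self.s_add_true < 0:
            raise ValidationError("s_add_true must be >= 0")
        if self.background_var < 0:
            raise ValidationError("background_var must be >= 0")
        if self.partiality_law not in ("ones", "beta"):
            raise ValidationError(f"unknown partiality law {self.partiality_law!r}")


@dataclass
class SimulatedDataset:
    """Measurement and image tables plus the ground truth that produced them."""

    measurements: pd.DataFrame
    images: pd.DataFrame
    truth_reflections: pd.DataFrame   # h k l j_true (photons)
    truth_measurements: pd.DataFrame  # per-row mu in reported units, partiality
    config: SimulationConfig


def _unique_indices(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Distinct Miller indices whose d-spacing lies in the resolution range."""
    d_min, d_max = config.resolution_range
    hmax = int(np.floor(config.cell_a / d_min))
    grid = np.arange(-hmax, hmax + 1)
    h, k, l = np.meshgrid(grid, grid, grid, indexing="ij")
    hkl = np.column_stack([h.ravel(), k.ravel(), l.ravel()])
    norm2 = (hkl**2).sum(axis=1)
    d = np.full(len(hkl), np.inf)
    nz = norm2 > 0
    d[nz] = config.cell_a / np.sqrt(norm2[nz])
    ok = nz & (d >= d_min) & (d <= d_max)
    hkl = hkl[ok]
    if len(hkl) < config.n_unique:
        raise ValidationError(
            f"only {len(hkl)} indices in the resolution range, "
            f"need {config.n_unique}"
        )
    pick = rng.choice(len(hkl), size=config.n_unique, replace=False)
    return hkl[pick]


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one reproducible unmerged dataset from the config."""
    rng = np.random.default_rng(config.seed)
    hkl = _unique_indices(config, rng)
    stol2_unique = (hkl**2).sum(axis=1) / (4.0 * config.cell_a**2)
    j_true = rng.exponential(config.wilson_mean, size=config.n_unique)

    g_c = rng.uniform(*config.g_range, size=config.n_images)
    b_c = rng.uniform(*config.b_range, size=config.n_images)

    n_ref = config.reflections_per_image
    per_image = min(n_ref, config.n_unique)
    sel = np.empty((config.n_images, per_image), dtype=np.intp)
    for c in range(config.n_images):
        sel[c] = rng.choice(config.n_unique, size=per_image, replace=False)
    sel_flat = sel.ravel()
    image_idx = np.repeat(np.arange(config.n_images), per_image)

    stol2 = stol2_unique[sel_flat]
    if config.partiality_law == "beta":
        p = 0.05 + 0.95 * rng.beta(2.0, 1.5, size=len(sel_flat))
    else:
        p = np.ones(len(sel_flat))

    mu_photons = g_c[image_idx] * np.exp(-2.0 * b_c[image_idx] * stol2) * p * j_true[sel_flat]
    photons = rng.poisson(mu_photons).astype(float)
    if config.background_var > 0:
        photons = photons + rng.normal(
            0.0, np.sqrt(config.background_var), size=len(photons)
        )
    gratio = config.gain_true / config.gain_assumed
    i_rep = gratio * photons
    # counting sigma as integration software estimates it, from the reported
    # (assumed-photon-unit) counts plus the empirically measured background
    # variance: wrong by sqrt(gain ratio) when the gain is wrong
    counts_var = np.maximum(i_rep, 0.0) + gratio**2 * config.background_var
    sigma = np.sqrt(np.maximum(counts_var, gratio * config.sigma_floor))
    mu_rep = gratio * mu_photons
    if config.s_add_true > 0:
        i_rep = i_rep + rng.normal(0.0, config.s_add_true * mu_rep)

    image_ids = np.array([f"img{c:06d}" for c in range(config.n_images)])
    measurements = pd.DataFrame({
        "h": hkl[sel_flat, 0], "k": hkl[sel_flat, 1], "l": hkl[sel_flat, 2],
        "image_id": image_ids[image_idx],
        "i_partial": i_rep, "sigma_partial": sigma,
        "partiality": p, "stol2": stol2,
    })
    images = pd.DataFrame({
        "image_id": image_ids, "scale": g_c, "wilson_b": b_c,
        "wavelength": np.full(config.n_images, config.wavelength),
    })
    truth_reflections = pd.DataFrame({
        "h": hkl[:, 0], "k": hkl[:, 1], "l": hkl[:, 2], "j_true": j_true,
    })
    truth_measurements = pd.DataFrame({
        "mu_reported": mu_rep, "mu_photons": mu_photons, "partiality": p,
    })
    return SimulatedDataset(
        measurements=measurements, images=images,
        truth_reflections=truth_reflections,
        truth_measurements=truth_measurements, config=config,
    )


#: Named study conditions. "gain25" reports intensities in raw detector units
#: (gain 25 misread as 1); "gain25-corrected" is the same experiment with the
#: gain divided out before sigmas are formed.
PRESETS: dict[str, SimulationConfig] = {
    "clean-poisson": SimulationConfig(
        n_images=2000, reflections_per_image=60, n_unique=2000,
        wilson_mean=1000.0,
    ),
    "gain25": SimulationConfig(
        n_images=5000, reflections_per_image=20, n_unique=2000,
        wilson_mean=2000.0, g_range=(0.7, 1.3), b_range=(0.0, 6.0),
        partiality_law="beta", gain_true=25.0, gain_assumed=1.0,
    ),
    "gain25-corrected": SimulationConfig(
        n_images=5000, reflections_per_image=20, n_unique=2000,
        wilson_mean=2000.0, g_range=(0.7, 1.3), b_range=(0.0, 6.0),
        partiality_law="beta", gain_true=25.0, gain_assumed=25.0,
    ),
    "instability": SimulationConfig(
        n_images=5000, reflections_per_image=20, n_unique=2000,
        wilson_mean=200.0, g_range=(0.7, 1.3), b_range=(0.0, 6.0),
        partiality_law="beta", s_add_true=0.5, background_var=25.0,
    ),
    "partiality-heavy": SimulationConfig(
        n_images=1000, reflections_per_image=30, n_unique=1000,
        wilson_mean=1000.0, g_range=(0.5, 2.0), b_range=(0.0, 10.0),
        partiality_law="beta", background_var=25.0,
    ),
    "mini": SimulationConfig(
        n_images=60, reflections_per_image=12, n_unique=120,
        wilson_mean=500.0, g_range=(0.8, 1.2), b_range=(0.0, 4.0),
        partiality_law="beta", background_var=25.0,
    ),
}


def get_preset(name: str, seed: int | None = None) -> SimulationConfig:
    """Look up a preset config, optionally re-seeding it."""
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    config = PRESETS[name]
    if seed is not None:
        config = replace(config, seed=seed)
    return config


def make_fixture(name: str, out_dir: str | Path, seed: int | None = None) -> dict[str, Path]:
    """Simulate a preset and write its tables to ``out_dir``.

    Writes ``measurements.tsv``, ``images.tsv`` and a ``truth.tsv`` sidecar
    with the true per-reflection intensities; returns the written paths.
    """
    config = get_preset(name, seed)
    ds = simulate_dataset(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "measurements": out / "measurements.tsv",
        "images": out / "images.tsv",
        "truth": out / "truth.tsv",
    }
    write_measurements(ds.measurements, paths["measurements"])
    write_images(ds.images, paths["images"])
    ds.truth_reflections.to_csv(paths["truth"], sep="\t", index=False,
                                float_format="%.12g")
    return paths
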