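"""Domain types and reflection-table I/O for still-shot merging.

The central container is a plain :class:`pandas.DataFrame` in the unmerged
reflection-table layout (one row per partial observation); the dataclasses
below are lightweight records for single observations and merge results.
Symmetry handling (mapping Miller indices to a canonical asymmetric-unit
representative) is delegated to gemmi.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Measurement",
    "ImageModel",
    "ReflectionGroup",
    "MergedReflection",
    "FormatError",
    "ValidationError",
    "MEASUREMENT_COLUMNS",
    "IMAGE_COLUMNS",
    "MERGED_COLUMNS",
    "map_to_asu",
    "group_by_miller",
    "iter_groups",
    "read_reflection_table",
    "read_measurements",
    "read_images",
    "write_measurements",
    "write_images",
    "write_merged",
    "merged_to_mtz",
]

#: Required columns of the unmerged measurement table.
MEASUREMENT_COLUMNS = [
    "h", "k", "l", "image_id", "i_partial", "sigma_partial", "partiality", "stol2",
]
#: Required columns of the per-image model table.
IMAGE_COLUMNS = ["image_id", "scale", "wilson_b", "wavelength"]
#: Columns of the merged output table.
MERGED_COLUMNS = ["h", "k", "l", "i_merged", "sigma_merged", "multiplicity"]


class FormatError(ValueError):
    """A table file does not conform to the expected columnar layout."""


class ValidationError(ValueError):
    """A table row violates a physical invariant (e.g. sigma <= 0)."""


@dataclass
class Measurement:
    """One partial observation of a Miller index on one still image.

    ``i_full``/``sigma_full`` hold the full-equivalent values after the
    partiality/scale correction has been applied; both are obtained from the
    partial values by the same multiplicative factor, so I/sigma is preserved.
    """

    hkl: tuple[int, int, int]
    image_id: str
    i_partial: float
    sigma_partial: float
    partiality: float
    stol2: float
    i_full: float | None = None
    sigma_full: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_partial <= 0:
            raise ValidationError(f"sigma_partial must be > 0, got {self.sigma_partial}")
        if not (0.0 < self.partiality <= 1.0):
            raise ValidationError(f"partiality must be in (0, 1], got {self.partiality}")
        if self.stol2 < 0:
            raise ValidationError(f"stol2 must be >= 0, got {self.stol2}")


@dataclass
class ImageModel:
    """Per-image scale factor G_c, Wilson B factor B_c and wavelength."""

    image_id: str
    scale: float
    wilson_b: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValidationError(f"scale must be > 0, got {self.scale}")
        if self.wavelength <= 0:
            raise ValidationError(f"wavelength must be > 0, got {self.wavelength}")


@dataclass
class ReflectionGroup:
    """All n observations of one asymmetric-unit Miller index.

    ``intensities``/``sigmas`` are the corrected (full-equivalent) values used
    by merging and by the error model; ``stol2`` is carried along for
    resolution-binned diagnostics.
    """

    hkl: tuple[int, int, int]
    intensities: np.ndarray
    sigmas: np.ndarray
    stol2: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.intensities)

    @property
    def mean(self) -> float:
        """Plain mean of the corrected measurements, <I_h>."""
        return float(np.mean(self.intensities))


@dataclass
class MergedReflection:
    """Merged intensity and error estimate for one Miller index."""

    hkl: tuple[int, int, int]
    i_merged: float
    sigma_merged: float
    multiplicity: int
    mean_raw: float = field(default=np.nan)
    stol2: float = field(default=np.nan)
    sigma_is_fallback: bool = False


# ---------------------------------------------------------------------------
# symmetry

def map_to_asu(
    hkl: np.ndarray, space_group: str, anomalous: bool = True
) -> np.ndarray:
    """Map Miller indices to canonical asymmetric-unit representatives.

    With ``anomalous=True`` the Friedel sign is preserved: indices whose ASU
    representative is reached through the Friedel flip are negated, so h and
    -h stay distinct and Bijvoet pairs remain separable downstream.

    Parameters
    ----------
    hkl : (n, 3) integer array
    space_group : Hermann-Mauguin symbol, e.g. ``"P 21 21 21"``
    anomalous : keep Friedel mates separate if True
    """
    try:
        sg = gemmi.SpaceGroup(space_group)
    except (ValueError, RuntimeError) as exc:
        raise FormatError(f"unknown space group {space_group!r}") from exc
    asu = gemmi.ReciprocalAsu(sg)
    ops = sg.operations()
    hkl = np.asarray(hkl, dtype=np.int64)
    out = np.empty_like(hkl)
    cache: dict[tuple[int, int, int], tuple[int, int, int]] = {}
    for i, row in enumerate(hkl):
        key = (int(row[0]), int(row[1]), int(row[2]))
        mapped = cache.get(key)
        if mapped is None:
            new_hkl, isym = asu.to_asu(list(key), ops)
            # even isym: reached via Friedel inversion
            if anomalous and isym % 2 == 0:
                mapped = (-new_hkl[0], -new_hkl[1], -new_hkl[2])
            else:
                mapped = (new_hkl[0], new_hkl[1], new_hkl[2])
            cache[key] = mapped
        out[i] = mapped
    return out


def group_by_miller(
    measurements: pd.DataFrame,
    space_group: str = "P1",
    anomalous: bool = True,
    partiality_floor: float | None = None,
) -> pd.DataFrame:
    """Assign each measurement to its asymmetric-unit reflection group.

    Returns a copy of the table with ``h k l`` replaced by the canonical
    ASU representative (Friedel-signed when ``anomalous``). Rows with
    partiality below ``partiality_floor`` (if given) are dropped first.
    The result partitions the input: every surviving row belongs to exactly
    one (h, k, l) group.
    """
    df = measurements
    if partiality_floor is not None:
        df = df[df["partiality"] >= partiality_floor]
    df = df.copy()
    asu = map_to_asu(df[["h", "k", "l"]].to_numpy(), space_group, anomalous)
    df[["h", "k", "l"]] = asu
    return df


def iter_groups(
    grouped: pd.DataFrame, use_corrected: bool = True
) -> Iterator[ReflectionGroup]:
    """Yield :class:`ReflectionGroup` objects from an ASU-mapped table."""
    icol = "i_full" if use_corrected else "i_partial"
    scol = "sigma_full" if use_corrected else "sigma_partial"
    for hkl, sub in grouped.groupby(["h", "k", "l"], sort=True):
        yield ReflectionGroup(
            hkl=tuple(int(x) for x in hkl),
            intensities=sub[icol].to_numpy(dtype=float),
            sigmas=sub[scol].to_numpy(dtype=float),
            stol2=sub["stol2"].to_numpy(dtype=float),
        )


# ---------------------------------------------------------------------------
# table I/O  (tab-separated text, '#' comments, 12-significant-digit floats)

_FLOAT_FMT = "%.12g"


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read an unmerged measurement table, validating physical invariants."""
    df = _read_table(path, MEASUREMENT_COLUMNS)
    for col, bad in [
        ("sigma_partial", df["sigma_partial"].to_numpy() <= 0),
        ("partiality", ~((df["partiality"].to_numpy() > 0) & (df["partiality"].to_numpy() <= 1))),
        ("stol2", df["stol2"].to_numpy() < 0),
    ]:
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1  # 1-based data row
            raise ValidationError(f"{path}: invalid {col} on data row {row}")
    return df


def read_images(path: str | Path) -> pd.DataFrame:
    """Read a per-image model table (deduplicated by image_id)."""
    df = _read_table(path, IMAGE_COLUMNS)
    df = df.drop_duplicates(subset="image_id", keep="first").reset_index(drop=True)
    if (df["scale"].to_numpy() <= 0).any() or (df["wavelength"].to_numpy() <= 0).any():
        raise ValidationError(f"{path}: scale and wavelength must be > 0")
    return df


def read_reflection_table(
    measurements_path: str | Path, images_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the measurement table and its companion per-image table."""
    return read_measurements(measurements_path), read_images(images_path)


def _write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path)


def write_images(df: pd.DataFrame, path: str | Path) -> None:
    _write_table(df, path)


def write_merged(merged: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in merged.columns if c in MERGED_COLUMNS + ["mean_raw", "stol2"]]
    _write_table(merged[cols], path)


def merged_to_mtz(
    merged: pd.DataFrame,
    path: str | Path,
    cell: tuple[float, float, float, float, float, float] = (50, 50, 50, 90, 90, 90),
    space_group: str = "P1",
    anomalous: bool = False,
) -> None:
    """Export a merged table to MTZ (IMEAN/SIGIMEAN, or I(+)/I(-) pairs)."""
    mtz = gemmi.Mtz(with_base=True)
    mtz.spacegroup = gemmi.SpaceGroup(space_group)
    mtz.set_cell_for_all(gemmi.UnitCell(*cell))
    mtz.add_dataset("merged")
    if anomalous:
        df = merged.copy()
        neg = df["h"] < 0  # crude Friedel split on the signed ASU index
        plus = df[~neg]
        minus = df[neg].copy()
        minus[["h", "k", "l"]] = -minus[["h", "k", "l"]]
        both = plus.merge(minus, on=["h", "k", "l"], how="outer", suffixes=("_p", "_m"))
        mtz.add_column("I(+)", "K")
        mtz.add_column("SIGI(+)", "M")
        mtz.add_column("I(-)", "K")
        mtz.add_column("SIGI(-)", "M")
        data = np.column_stack([
            both[["h", "k", "l"]].to_numpy(dtype=float),
            both["i_merged_p"].to_numpy(dtype=float),
            both["sigma_merged_p"].to_numpy(dtype=float),
            both["i_merged_m"].to_numpy(dtype=float),
            both["sigma_merged_m"].to_numpy(dtype=float),
        ])
    else:
        mtz.add_column("IMEAN", "J")
        mtz.add_column("SIGIMEAN", "Q")
        data = np.column_stack([
            merged[["h", "k", "l"]].to_numpy(dtype=float),
            merged["i_merged"].to_numpy(dtype=float),
            merged["sigma_merged"].to_numpy(dtype=float),
        ])
    mtz.set_data(data)
    mtz.write_to_file(str(path))
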