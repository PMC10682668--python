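"""Spectral data model, wavelength grids, wide-CSV I/O, dish averaging and accounting.

The instrument emulated here samples absorbance on a fixed uniform grid of
256 points starting at 1100 nm with a 4.27 nm step.  Note that 256 points at
that step end at 2188.85 nm; the nominal 2200 nm upper bound quoted for such
instruments is treated as a rounding of the true grid end, and the grid is
defined authoritatively by ``(start, step, n)``.

A dataset is a matrix of spectra (rows = measurements) plus a metadata table
carrying the study design coordinates (sample, food type, dish, time step,
measurement point) and any gravimetric columns.  The canonical on-disk format
is a wide CSV: metadata columns first, then one column per wavelength
labelled with the wavelength in nm to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: metadata columns written before the wavelength block, in canonical order
META_COLUMNS = [
    "sample_id",
    "food_type",
    "dish",
    "timestep",
    "point",
    "t_hours",
    "m0",
    "m1",
    "m2",
    "moisture_true",
]

#: subset of metadata that identifies one physical dish at one time step
DISH_KEY = ["sample_id", "timestep", "dish"]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid: lambda_i = start + i * step, i = 0..n-1."""

    start: float = 1100.0
    step: float = 4.27
    n: int = 256

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")
        if self.n < 2:
            raise ValueError(f"grid needs at least 2 points, got n={self.n}")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n)

    @property
    def stop(self) -> float:
        """Last wavelength on the grid (start + (n-1)*step)."""
        return self.start + (self.n - 1) * self.step

    def column_labels(self) -> list[str]:
        return [f"{w:.2f}" for w in self.wavelengths]


def build_grid(start: float = 1100.0, step: float = 4.27, n: int = 256) -> WavelengthGrid:
    """Construct a :class:`WavelengthGrid`; defaults give the 256-point NIR grid."""
    return WavelengthGrid(start=start, step=step, n=n)


@dataclass
class SpectralDataset:
    """A stack of spectra on a common grid with per-row metadata.

    ``absorbance`` has shape ``(n_obs, grid.n)``; ``meta`` has ``n_obs`` rows.
    ``provenance`` records processing stages applied to the data.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    meta: pd.DataFrame
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (n_obs, n_wavelengths)")
        if self.absorbance.shape[1] != self.grid.n:
            raise ValueError(
                f"absorbance has {self.absorbance.shape[1]} columns "
                f"but grid has n={self.grid.n}"
            )
        if len(self.meta) != self.absorbance.shape[0]:
            raise ValueError("metadata row count does not match spectra count")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.absorbance.shape[0]

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            grid=self.grid,
            absorbance=self.absorbance.copy(),
            meta=self.meta.copy(),
            provenance=[dict(p) for p in self.provenance],
        )

    def with_absorbance(self, values: np.ndarray, stage: dict | None = None) -> "SpectralDataset":
        """Return a new dataset with replaced spectra, appending a provenance entry."""
        prov = [dict(p) for p in self.provenance]
        if stage is not None:
            prov.append(dict(stage))
        return SpectralDataset(self.grid, values, self.meta.copy(), prov)

    def subset(self, mask) -> "SpectralDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectralDataset(
            self.grid,
            self.absorbance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            [dict(p) for p in self.provenance],
        )

    def for_food_type(self, food_type: str) -> "SpectralDataset":
        return self.subset((self.meta["food_type"] == food_type).to_numpy())

    @property
    def food_types(self) -> list[str]:
        return list(pd.unique(self.meta["food_type"]))


def average_dish(spectra: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    """Pointwise arithmetic mean of the measurement points of one dish."""
    arr = np.asarray(spectra, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[0] < 1:
        raise ValueError("need at least one spectrum to average")
    return arr.mean(axis=0)


def average_dishes(ds: SpectralDataset) -> SpectralDataset:
    """Average the measurement points of every dish; one spectrum per dish remains.

    Metadata keeps dish identity and drops the point index.  All rows in a
    dish group must share the same grid (guaranteed by the dataset) and the
    same gravimetric values; the first row's values are kept.
    """
    if not set(DISH_KEY) <= set(ds.meta.columns):
        raise ValueError(f"metadata must contain dish key columns {DISH_KEY}")
    groups = ds.meta.groupby(DISH_KEY, sort=True).indices
    rows = []
    specs = np.empty((len(groups), ds.grid.n))
    for i, (key, idx) in enumerate(sorted(groups.items())):
        specs[i] = average_dish(ds.absorbance[np.asarray(idx)])
        rec = ds.meta.iloc[np.asarray(idx)[0]].to_dict()
        rec.pop("point", None)
        rows.append(rec)
    meta = pd.DataFrame(rows)
    prov = [dict(p) for p in ds.provenance] + [{"stage": "average_dish"}]
    return SpectralDataset(ds.grid, specs, meta, prov)


def dataset_accounting(design) -> dict:
    """Combinatorial accounting of a drying study design.

    ``design`` needs the fields of a drying design: ``n_points_per_dish``,
    ``n_dishes_per_timestep``, ``n_timesteps``, ``sample_ids`` (9 IDs grouped
    3 per food type).  Returns the per-dish / per-time-step / per-ID /
    per-food-type / grand-total counts, raw and dish-averaged.
    """
    n_ids = len(design.sample_ids)
    ids_per_food = 3
    n_foods = n_ids // ids_per_food
    per_dish = design.n_points_per_dish
    per_timestep = design.n_dishes_per_timestep
    raw_per_id = per_dish * per_timestep * design.n_timesteps
    avg_per_id = per_timestep * design.n_timesteps
    return {
        "measurements_per_dish": per_dish,
        "dishes_per_timestep": per_timestep,
        "timesteps": design.n_timesteps,
        "raw_per_sample_id": raw_per_id,
        "averaged_per_sample_id": avg_per_id,
        "raw_per_food_type": raw_per_id * ids_per_food,
        "averaged_per_food_type": avg_per_id * ids_per_food,
        "raw_total": raw_per_id * n_ids,
        "averaged_total": avg_per_id * n_ids,
        "n_sample_ids": n_ids,
        "n_food_types": n_foods,
    }


def write_spectra(ds: SpectralDataset, path) -> None:
    """Write a dataset as wide CSV: metadata columns, then wavelength columns."""
    meta_cols = [c for c in META_COLUMNS if c in ds.meta.columns]
    extra = [c for c in ds.meta.columns if c not in meta_cols]
    table = ds.meta[meta_cols + extra].copy()
    wl = ds.grid.column_labels()
    spec = pd.DataFrame(ds.absorbance, columns=wl)
    pd.concat([table, spec], axis=1).to_csv(path, index=False, float_format="%.17g")


def read_spectra(path, grid: WavelengthGrid | None = None) -> SpectralDataset:
    """Read a wide-CSV spectral dataset.

    The wavelength block is identified as the trailing run of columns whose
    labels parse as numbers.  If ``grid`` is given, the block must match its
    size and labels; otherwise a uniform grid is inferred from the labels.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: empty spectral file")
    wl_cols = []
    for c in reversed(df.columns):
        try:
            float(c)
        except ValueError:
            break
        wl_cols.append(c)
    wl_cols.reverse()
    if not wl_cols:
        raise ValueError(f"{path}: no numeric wavelength columns found")
    wavelengths = np.array([float(c) for c in wl_cols])
    if grid is None:
        steps = np.diff(wavelengths)
        if len(wavelengths) < 2 or not np.allclose(steps, steps[0], atol=0.01):
            raise ValueError(f"{path}: wavelength columns are not a uniform grid")
        grid = WavelengthGrid(start=wavelengths[0], step=float(round(steps.mean(), 2)), n=len(wavelengths))
    else:
        if len(wl_cols) != grid.n:
            raise ValueError(
                f"{path}: file has {len(wl_cols)} wavelength columns, expected grid n={grid.n}"
            )
        if not np.allclose(wavelengths, grid.wavelengths, atol=0.01):
            raise ValueError(f"{path}: wavelength header does not match the expected grid")
    values = df[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-numeric or non-finite absorbance values")
    meta = df[[c for c in df.columns if c not in wl_cols]]
    return SpectralDataset(grid, values, meta)
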