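"""Synthetic NIR drying studies.

The measured study this generator emulates dried nine dairy samples (three
chocolate puddings, three vanilla puddings, three yoghurts) in petri dishes
over 8 h, recording at 17 half-hour time steps the masses of three dishes
and five NIR measurement points per dish.  The raw data behind that study
are not publicly archived, so analyses are developed against synthetic
datasets with the same statistical structure:

* moisture follows first-order thin-layer drying kinetics,
  ``M(t) = M_eq + (M_0 - M_eq) exp(-k t)``, nearly linear over the first
  4 h for the rate constants used here;
* spectra are sums of Gaussian absorption bands (water bands near 1300 nm
  and 1700 nm dominating), a cubic baseline drift, a dish-level offset and
  heteroscedastic point noise whose amplitude grows with moisture — fresher
  samples are noisier;
* each dish carries fresh / air-dried / oven-dried masses that are exactly
  consistent with its ground-truth moisture through the gravimetric
  formulas.

Moisture is expressed throughout as remaining water in % of the *fresh*
mass, so the initial value equals the gravimetric initial moisture and the
weight loss at time t equals ``M_0 - M(t)``.

Randomness is split deterministically: every dish draws from
``np.random.SeedSequence(master_seed, spawn_key=(sample_index, timestep,
dish))`` (and sample-level draws from ``spawn_key=(sample_index,)``), so any
dish can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectralDataset, WavelengthGrid

COMPONENTS = ("water", "fat", "sugar", "protein")


@dataclass(frozen=True)
class FoodTypeProfile:
    """Composition and drying behaviour of one food type."""

    name: str
    composition: dict  # % per 100 g for fat, sugar, CHO, protein, salt
    initial_moisture_mean: float  # % of fresh mass
    initial_moisture_spread: float  # SD across sample IDs, % points
    drying_rate: float  # thin-layer rate constant k, 1/h
    equilibrium_moisture: float  # % of fresh mass

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.composition.values()):
            raise ValueError("mass fractions must be non-negative")
        dry = sum(self.composition.values())
        if dry > 100:
            raise ValueError("declared dry matter exceeds 100 g per 100 g")
        if self.initial_moisture_mean + dry > 102:
            raise ValueError("moisture plus declared dry matter exceeds 102")
        if self.drying_rate <= 0:
            raise ValueError("drying rate must be positive")
        if not 0 <= self.equilibrium_moisture < self.initial_moisture_mean:
            raise ValueError("equilibrium moisture must lie in [0, M_0)")

    @property
    def declared_drymatter(self) -> float:
        return sum(self.composition.values())


@dataclass(frozen=True)
class DryingDesign:
    """Counting structure of the measurement campaign."""

    n_points_per_dish: int = 5
    n_dishes_per_timestep: int = 3
    n_timesteps: int = 17
    sample_ids: tuple = ("1", "2", "3", "4", "5", "6", "7", "8", "9")
    timestep_hours: float = 0.5  # 17 steps span 8 h

    def __post_init__(self) -> None:
        if min(self.n_points_per_dish, self.n_dishes_per_timestep, self.n_timesteps) < 1:
            raise ValueError("design counts must be at least 1")
        if len(self.sample_ids) % 3 != 0:
            raise ValueError("sample IDs must group 3 per food type")
        if self.timestep_hours <= 0:
            raise ValueError("timestep duration must be positive")

    @property
    def raw_per_sample_id(self) -> int:
        return self.n_points_per_dish * self.n_dishes_per_timestep * self.n_timesteps

    @property
    def averaged_per_sample_id(self) -> int:
        return self.n_dishes_per_timestep * self.n_timesteps


@dataclass(frozen=True)
class BandModel:
    """Gaussian band-mixing model of the absorbance spectrum.

    ``component_loadings`` maps each component (water, fat, sugar, protein)
    to one amplitude per band, per unit mass fraction of that component.
    ``baseline_coeffs`` are cubic polynomial coefficients (constant first) in
    the reduced coordinate u = (lambda - start)/(stop - start).
    """

    centers: tuple = (1300.0, 1700.0, 1210.0, 1440.0, 2050.0)
    widths: tuple = (60.0, 90.0, 40.0, 50.0, 60.0)
    component_loadings: dict = field(
        default_factory=lambda: {
            "water": (1.0, 0.8, 0.0, 0.0, 0.2),
            "fat": (0.0, 0.0, 0.8, 0.0, 0.1),
            "sugar": (0.0, 0.0, 0.0, 0.6, 0.1),
            "protein": (0.0, 0.0, 0.1, 0.0, 0.7),
        }
    )
    baseline_coeffs: tuple = (0.15, 0.05, 0.03, 0.02)
    noise_base: float = 0.002  # absorbance SD floor
    noise_moisture_slope: float = 0.02  # extra SD per unit moisture fraction
    dish_offset_ratio: float = 1.0  # dish-level offset SD : point noise SD

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.widths):
            raise ValueError("centers and widths must have equal length")
        if any(w <= 0 for w in self.widths):
            raise ValueError("band widths must be positive")
        water = np.asarray(self.component_loadings.get("water", ()), dtype=float)
        centers = np.asarray(self.centers)
        if len(water) != len(centers):
            raise ValueError("water loadings must cover every band")
        active = centers[water > 0]
        if not (np.any(np.abs(active - 1300) < 80) and np.any((active >= 1600) & (active <= 1800))):
            raise ValueError("water bands must include one near 1300 nm and one in 1600-1800 nm")

    def baseline(self, grid: WavelengthGrid) -> np.ndarray:
        u = (grid.wavelengths - grid.start) / (grid.stop - grid.start)
        return np.polynomial.polynomial.polyval(u, np.asarray(self.baseline_coeffs))

    def noise_sd(self, moisture: float) -> float:
        return self.noise_base + self.noise_moisture_slope * moisture / 100.0


def default_profiles() -> dict[str, FoodTypeProfile]:
    """Per-food-type defaults matching the measured study's mass balance.

    Compositions are the means of the three declared samples of each food
    type; initial moistures are the corresponding measured means and their
    across-sample spreads.  Yoghurt dries fastest (largest k), matching its
    stronger late-stage weight loss.
    """
    return {
        "chocolate pudding": FoodTypeProfile(
            name="chocolate pudding",
            composition={"fat": 6.87, "sugar": 13.33, "CHO": 3.20, "protein": 3.27, "salt": 0.14},
            initial_moisture_mean=71.4,
            initial_moisture_spread=5.6,
            drying_rate=0.040,
            equilibrium_moisture=5.0,
        ),
        "vanilla pudding": FoodTypeProfile(
            name="vanilla pudding",
            composition={"fat": 5.07, "sugar": 12.63, "CHO": 2.87, "protein": 3.07, "salt": 0.16},
            initial_moisture_mean=74.6,
            initial_moisture_spread=4.4,
            drying_rate=0.045,
            equilibrium_moisture=5.0,
        ),
        "yoghurt": FoodTypeProfile(
            name="yoghurt",
            composition={"fat": 1.70, "sugar": 4.17, "CHO": 0.0, "protein": 5.07, "salt": 0.13},
            initial_moisture_mean=86.97,
            initial_moisture_spread=1.7,
            drying_rate=0.080,
            equilibrium_moisture=4.0,
        ),
    }


def drying_curve(t: float | np.ndarray, profile: FoodTypeProfile) -> float | np.ndarray:
    """Thin-layer drying: M(t) = M_eq + (M_0 - M_eq) exp(-k t), t in hours."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("drying time must be non-negative")
    m = profile.equilibrium_moisture + (
        profile.initial_moisture_mean - profile.equilibrium_moisture
    ) * np.exp(-profile.drying_rate * t)
    return float(m) if m.ndim == 0 else m


def _drying_curve_from(m0: float, m_eq: float, k: float, t: np.ndarray) -> np.ndarray:
    return m_eq + (m0 - m_eq) * np.exp(-k * np.asarray(t, dtype=float))


def synth_spectrum(
    moisture: float,
    composition: dict,
    band_model: BandModel,
    grid: WavelengthGrid,
    noise_seed=None,
) -> np.ndarray:
    """One synthetic absorbance spectrum at the given moisture.

    Band amplitudes are linear in the component mass fractions (water
    fraction = moisture / 100); the cubic baseline and heteroscedastic
    Gaussian noise (SD ``noise_base + noise_moisture_slope * moisture/100``)
    are added on top.  Deterministic for a fixed ``noise_seed``.
    """
    if not 0 <= moisture <= 100:
        raise ValueError(f"moisture must be in [0, 100], got {moisture}")
    centers = np.asarray(band_model.centers)
    if np.any(centers < grid.start) or np.any(centers > grid.stop):
        raise ValueError("band centers must lie within the wavelength grid span")
    wl = grid.wavelengths
    fractions = {"water": moisture / 100.0}
    for comp in ("fat", "sugar", "protein"):
        fractions[comp] = composition.get(comp, 0.0) / 100.0
    spectrum = band_model.baseline(grid).copy()
    widths = np.asarray(band_model.widths)
    for comp, frac in fractions.items():
        loadings = np.asarray(band_model.component_loadings.get(comp, np.zeros(len(centers))))
        amps = loadings * frac
        for a, c, w in zip(amps, centers, widths):
            if a != 0.0:
                spectrum = spectrum + a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    sd = band_model.noise_sd(moisture)
    if sd > 0:
        rng = np.random.default_rng(noise_seed)
        spectrum = spectrum + rng.normal(0.0, sd, size=grid.n)
    return spectrum


def generate_study(
    design: DryingDesign,
    profiles: dict[str, FoodTypeProfile] | None = None,
    band_model: BandModel | None = None,
    master_seed: int = 0,
    grid: WavelengthGrid | None = None,
) -> SpectralDataset:
    """Generate a full labelled drying study.

    Emits ``n_points_per_dish * n_dishes_per_timestep * n_timesteps`` spectra
    per sample ID.  Each dish carries masses (m0, m1, m2) exactly consistent
    with its ground-truth moisture: ``m2 = m0 (1 - M_init/100)`` and
    ``m1 = m2 + m0 M(t)/100``, so the gravimetric formulas recover
    ``M_init`` and the weight loss ``M_init - M(t)`` from the masses.

    Dish-level variation (shared flat absorbance offset and a small moisture
    offset) is separated from independent point-level noise so that
    averaging the five points of a dish is meaningful.
    """
    profiles = default_profiles() if profiles is None else profiles
    band_model = BandModel() if band_model is None else band_model
    grid = WavelengthGrid() if grid is None else grid
    names = list(profiles)
    if len(design.sample_ids) != 3 * len(names):
        raise ValueError("need exactly 3 sample IDs per food type")

    rows, spectra = [], []
    for i_sample, sid in enumerate(design.sample_ids):
        profile = profiles[names[i_sample // 3]]
        s_rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(i_sample,)))
        m_init_sample = float(
            np.clip(
                profile.initial_moisture_mean
                + s_rng.normal(0.0, profile.initial_moisture_spread),
                profile.equilibrium_moisture + 5.0,
                100.0 - profile.declared_drymatter,
            )
        )
        # the same physical dishes are tracked through every time step
        for i_dish in range(design.n_dishes_per_timestep):
            d_seq = np.random.SeedSequence(master_seed, spawn_key=(i_sample, i_dish))
            d_rng = np.random.default_rng(d_seq)
            m_init = float(
                np.clip(
                    m_init_sample + d_rng.normal(0.0, profile.initial_moisture_spread / 4),
                    profile.equilibrium_moisture + 2.0,
                    100.0 - profile.declared_drymatter,
                )
            )
            m0 = float(d_rng.normal(60.0, 2.0))  # ~60 g of product in a 100 mm dish
            m2 = m0 * (1.0 - m_init / 100.0)
            for i_t in range(design.n_timesteps):
                t_h = i_t * design.timestep_hours
                ss = np.random.SeedSequence(master_seed, spawn_key=(i_sample, i_dish, i_t))
                t_rng = np.random.default_rng(ss)
                moisture = float(
                    _drying_curve_from(m_init, profile.equilibrium_moisture, profile.drying_rate, t_h)
                )
                m1 = m2 + m0 * moisture / 100.0
                dish_offset = t_rng.normal(0.0) * band_model.dish_offset_ratio * band_model.noise_sd(moisture)
                point_seeds = ss.spawn(design.n_points_per_dish)
                for i_pt in range(design.n_points_per_dish):
                    spec = synth_spectrum(
                        moisture, profile.composition, band_model, grid, point_seeds[i_pt]
                    )
                    spectra.append(spec + dish_offset)
                    rows.append(
                        {
                            "sample_id": sid,
                            "food_type": profile.name,
                            "dish": i_dish,
                            "timestep": i_t,
                            "point": i_pt,
                            "t_hours": t_h,
                            "m0": m0,
                            "m1": m1,
                            "m2": m2,
                            "moisture_true": moisture,
                            "moisture_init": m_init,
                            "weight_loss": m_init - moisture,
                        }
                    )
    meta = pd.DataFrame(rows)
    prov = [{"stage": "generate_study", "master_seed": master_seed}]
    return SpectralDataset(grid, np.asarray(spectra), meta, prov)
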