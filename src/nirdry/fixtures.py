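"""Bundled reference tables and a fast synthetic mini-study.

``table1_compositions`` holds the manufacturer nutrition declarations of the
nine study samples (% per 100 g); ``table3_massbalance`` the corresponding
measured water means and spreads.  ``mini_study`` is a tiny seeded synthetic
dataset (2 time steps, 1 dish, 3 points per dish) for fast end-to-end tests.
"""

from __future__ import annotations

import pandas as pd

from .gravimetry import CompositionDeclaration
from .synth import BandModel, DryingDesign, generate_study

#: manufacturer declarations, % per 100 g, sample IDs 1-9
TABLE1_COMPOSITIONS = {
    "1": {"food_type": "chocolate pudding", "fat": 9.3, "sugar": 13.0, "CHO": 3.0, "protein": 3.3, "salt": 0.12},
    "2": {"food_type": "chocolate pudding", "fat": 8.2, "sugar": 13.0, "CHO": 3.0, "protein": 3.3, "salt": 0.18},
    "3": {"food_type": "chocolate pudding", "fat": 3.1, "sugar": 14.0, "CHO": 3.6, "protein": 3.2, "salt": 0.13},
    "4": {"food_type": "vanilla pudding", "fat": 8.8, "sugar": 13.0, "CHO": 2.0, "protein": 3.0, "salt": 0.2},
    "5": {"food_type": "vanilla pudding", "fat": 3.3, "sugar": 12.0, "CHO": 3.0, "protein": 3.2, "salt": 0.14},
    "6": {"food_type": "vanilla pudding", "fat": 3.1, "sugar": 12.9, "CHO": 3.6, "protein": 3.0, "salt": 0.14},
    "7": {"food_type": "yoghurt", "fat": 0.1, "sugar": 4.2, "CHO": 0.0, "protein": 5.4, "salt": 0.13},
    "8": {"food_type": "yoghurt", "fat": 1.5, "sugar": 4.2, "CHO": 0.0, "protein": 5.3, "salt": 0.14},
    "9": {"food_type": "yoghurt", "fat": 3.5, "sugar": 4.1, "CHO": 0.0, "protein": 4.5, "salt": 0.13},
}

#: measured water content per sample, mean and spread (% of fresh mass)
TABLE3_WATER = {
    "1": (64.6, 2.2),
    "2": (71.4, 0.1),
    "3": (78.2, 0.3),
    "4": (68.5, 1.5),
    "5": (77.2, 0.5),
    "6": (78.1, 0.2),
    "7": (89.4, 0.5),
    "8": (85.9, 0.3),
    "9": (85.6, 0.9),
}


def declarations() -> dict[str, CompositionDeclaration]:
    """The nine declarations as :class:`CompositionDeclaration` objects."""
    return {
        sid: CompositionDeclaration(
            fat=row["fat"], sugar=row["sugar"], CHO=row["CHO"],
            protein=row["protein"], salt=row["salt"],
        )
        for sid, row in TABLE1_COMPOSITIONS.items()
    }


def load_fixture(name: str):
    """Load a bundled fixture by name.

    * ``table1_compositions`` — declarations table (DataFrame, one row per
      sample ID);
    * ``table3_massbalance`` — declared dry matter, measured water mean and
      spread per sample ID (DataFrame);
    * ``mini_study`` — small seeded synthetic dataset (9 sample IDs, 2 time
      steps, 1 dish per step, 3 points per dish).
    """
    if name == "table1_compositions":
        rows = [{"sample_id": sid, **row} for sid, row in TABLE1_COMPOSITIONS.items()]
        return pd.DataFrame(rows)
    if name == "table3_massbalance":
        decls = declarations()
        rows = [
            {
                "sample_id": sid,
                "declared_drymatter": decls[sid].total(),
                "water_mean": mean,
                "water_spread": spread,
            }
            for sid, (mean, spread) in TABLE3_WATER.items()
        ]
        return pd.DataFrame(rows)
    if name == "mini_study":
        design = DryingDesign(
            n_points_per_dish=3, n_dishes_per_timestep=1, n_timesteps=2, timestep_hours=2.0
        )
        return generate_study(design, band_model=BandModel(), master_seed=20230)
    raise KeyError(f"unknown fixture {name!r}")
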