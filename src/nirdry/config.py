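"""Run configuration: one serializable object governing a whole experiment.

A :class:`RunConfig` bundles the wavelength grid, the drying-study design,
the food profiles and band model of the generator, preprocessing, the
calibration/validation split, network training and the method list, under a
single master seed.  ``to_yaml`` / ``from_yaml`` round-trip exactly, so a
persisted config reproduces a run seed-for-seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .chemometrics import SplitSpec
from .neural import TrainConfig
from .preprocess import PreprocessConfig
from .spectra import WavelengthGrid
from .synth import BandModel, DryingDesign, FoodTypeProfile, default_profiles


@dataclass
class RunConfig:
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    design: DryingDesign = field(default_factory=DryingDesign)
    profiles: dict = field(default_factory=default_profiles)
    band_model: BandModel = field(default_factory=BandModel)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    methods: tuple = ("pls", "ann", "dnn", "cnn")
    seeds: tuple = (0, 1, 2, 3, 4)
    target: str = "moisture_true"
    output_dir: str = "nirdry_out"
    master_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profiles"] = {k: asdict(v) for k, v in self.profiles.items()}
        return _plain(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        parts = {
            "grid": WavelengthGrid,
            "design": DryingDesign,
            "band_model": BandModel,
            "preprocess": PreprocessConfig,
            "split": SplitSpec,
            "train": TrainConfig,
        }
        kwargs = {}
        for key, typ in parts.items():
            if key in d:
                kwargs[key] = _build(typ, d.pop(key))
        if "profiles" in d:
            kwargs["profiles"] = {
                k: _build(FoodTypeProfile, v) for k, v in d.pop("profiles").items()
            }
        for key in ("methods", "seeds"):
            if key in d:
                d[key] = tuple(d[key])
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _build(typ, d: dict):
    names = {f.name for f in fields(typ)}
    unknown = set(d) - names
    if unknown:
        raise ValueError(f"unknown {typ.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for f in fields(typ):
        if f.name in d:
            v = d[f.name]
            if isinstance(v, list):
                v = tuple(v)
            elif isinstance(v, dict):
                v = {k: tuple(x) if isinstance(x, list) else x for k, x in v.items()}
            kwargs[f.name] = v
    return typ(**kwargs)


def _plain(obj):
    """Recursively convert tuples to lists and numpy scalars to Python ones."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
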