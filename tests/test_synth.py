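"""Synthetic study generator: drying kinetics, band spectra, mass consistency."""

import numpy as np
import pytest

from nirdry.gravimetry import airdry_moisture, initial_moisture
from nirdry.spectra import WavelengthGrid
from nirdry.synth import (
    BandModel,
    DryingDesign,
    FoodTypeProfile,
    default_profiles,
    drying_curve,
    generate_study,
    synth_spectrum,
)


@pytest.fixture(scope="module")
def profile():
    return FoodTypeProfile(
        name="test pudding",
        composition={"fat": 5.0, "sugar": 10.0, "protein": 3.0},
        initial_moisture_mean=70.0,
        initial_moisture_spread=2.0,
        drying_rate=0.05,
        equilibrium_moisture=10.0,
    )


class TestDryingCurve:
    def test_starts_at_initial_moisture(self, profile):
        assert drying_curve(0.0, profile) == profile.initial_moisture_mean

    def test_asymptote(self, profile):
        assert drying_curve(500.0, profile) == pytest.approx(10.0, abs=1e-6)

    def test_closed_form_value(self, profile):
        # direct evaluation: 10 + 60 * exp(-0.05 * 4) = 59.123845...
        assert drying_curve(4.0, profile) == pytest.approx(59.1238451847, abs=1e-6)

    def test_strictly_decreasing(self, profile):
        t = np.linspace(0, 20, 50)
        m = drying_curve(t, profile)
        assert np.all(np.diff(m) < 0)

    def test_negative_time_rejected(self, profile):
        with pytest.raises(ValueError):
            drying_curve(-0.1, profile)


class TestProfileInvariants:
    def test_defaults_are_valid(self):
        for p in default_profiles().values():
            assert p.drying_rate > 0
            assert 0 <= p.equilibrium_moisture < p.initial_moisture_mean
            assert p.initial_moisture_mean + p.declared_drymatter <= 102

    def test_overfull_composition_rejected(self):
        with pytest.raises(ValueError):
            FoodTypeProfile("x", {"fat": 60.0, "sugar": 50.0}, 30.0, 1.0, 0.1, 5.0)

    def test_excess_moisture_rejected(self):
        with pytest.raises(ValueError):
            FoodTypeProfile("x", {"fat": 40.0}, 70.0, 1.0, 0.1, 5.0)


class TestSynthSpectrum:
    def test_baseline_only_when_all_bands_off(self):
        bm = BandModel(
            component_loadings={"water": (1.0, 1.0, 0, 0, 0), "fat": (0,) * 5,
                                "sugar": (0,) * 5, "protein": (0,) * 5},
            noise_base=0.0, noise_moisture_slope=0.0,
        )
        grid = WavelengthGrid()
        spec = synth_spectrum(0.0, {"fat": 10.0}, bm, grid)
        assert np.allclose(spec, bm.baseline(grid), atol=1e-14)

    def test_water_band_amplitude_proportional_to_moisture(self):
        bm = BandModel(noise_base=0.0, noise_moisture_slope=0.0)
        grid = WavelengthGrid()
        base = bm.baseline(grid)
        s1 = synth_spectrum(30.0, {}, bm, grid) - base
        s2 = synth_spectrum(60.0, {}, bm, grid) - base
        centers_idx = [np.argmin(np.abs(grid.wavelengths - c)) for c in (1300, 1700)]
        for i in centers_idx:
            assert s2[i] == pytest.approx(2.0 * s1[i])

    def test_deterministic_given_seed(self):
        bm = BandModel()
        grid = WavelengthGrid()
        a = synth_spectrum(50.0, {"fat": 5.0}, bm, grid, noise_seed=7)
        b = synth_spectrum(50.0, {"fat": 5.0}, bm, grid, noise_seed=7)
        assert np.array_equal(a, b)

    def test_moisture_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            synth_spectrum(101.0, {}, BandModel(), WavelengthGrid())

    def test_band_centers_must_lie_on_grid_span(self):
        bm = BandModel(centers=(1300.0, 1700.0, 3000.0, 1440.0, 2050.0))
        with pytest.raises(ValueError):
            synth_spectrum(50.0, {}, bm, WavelengthGrid())


class TestBandModelInvariants:
    def test_water_band_locations_enforced(self):
        with pytest.raises(ValueError):
            BandModel(
                centers=(1150.0, 2100.0), widths=(50.0, 50.0),
                component_loadings={"water": (1.0, 1.0)},
            )

    def test_width_positivity(self):
        with pytest.raises(ValueError):
            BandModel(centers=(1300.0, 1700.0), widths=(50.0, -1.0),
                      component_loadings={"water": (1.0, 1.0)})


class TestGenerateStudy:
    def test_default_design_counts(self, default_study):
        meta = default_study.meta
        assert len(default_study) == 2295
        per_id = meta.groupby("sample_id").size()
        assert (per_id == 255).all()
        assert meta.groupby("food_type").size().eq(765).all()

    def test_degenerate_design_one_spectrum_per_id(self):
        design = DryingDesign(n_points_per_dish=1, n_dishes_per_timestep=1, n_timesteps=1)
        ds = generate_study(design, master_seed=0)
        assert len(ds) == 9
        assert ds.meta.groupby("sample_id").size().eq(1).all()

    def test_masses_consistent_with_gravimetric_formulas(self, default_study):
        """Eq-style self-consistency: the masses reproduce the stored
        initial moisture and weight loss to 1e-9."""
        meta = default_study.meta.drop_duplicates(subset=["sample_id", "dish", "timestep"])
        for _, row in meta.sample(50, random_state=0).iterrows():
            assert initial_moisture(row.m0, row.m2) == pytest.approx(row.moisture_init, abs=1e-9)
            assert airdry_moisture(row.m0, row.m1) == pytest.approx(row.weight_loss, abs=1e-9)
            assert row.weight_loss == pytest.approx(row.moisture_init - row.moisture_true, abs=1e-9)

    def test_moisture_strictly_decreases_per_dish(self, default_study):
        g = default_study.meta.groupby(["sample_id", "dish"])
        for _, grp in g:
            series = grp.drop_duplicates("timestep").sort_values("timestep")["moisture_true"]
            assert np.all(np.diff(series.to_numpy()) < 0)

    def test_determinism_and_seed_sensitivity(self):
        design = DryingDesign(n_points_per_dish=2, n_dishes_per_timestep=1, n_timesteps=2)
        a = generate_study(design, master_seed=3)
        b = generate_study(design, master_seed=3)
        c = generate_study(design, master_seed=4)
        assert np.array_equal(a.absorbance, b.absorbance)
        assert not np.array_equal(a.absorbance, c.absorbance)

    def test_noise_variance_increases_with_moisture(self):
        """Residual variance about the noiseless twin grows with moisture."""
        design = DryingDesign(n_points_per_dish=5, n_dishes_per_timestep=2, n_timesteps=6,
                              timestep_hours=1.5)
        noisy = generate_study(design, master_seed=11)
        silent_bm = BandModel(noise_base=0.0, noise_moisture_slope=0.0, dish_offset_ratio=0.0)
        clean = generate_study(design, band_model=silent_bm, master_seed=11)
        assert np.allclose(noisy.meta["moisture_true"], clean.meta["moisture_true"])
        resid_var = ((noisy.absorbance - clean.absorbance) ** 2).mean(axis=1)
        m = noisy.meta["moisture_true"].to_numpy()
        order = np.argsort(m)
        n = len(order)
        lo = resid_var[order[: n // 3]].mean()
        hi = resid_var[order[-n // 3 :]].mean()
        assert hi > lo

    def test_dish_offset_shared_within_dish(self):
        """The five points of one dish share one additive offset: the
        between-point differences carry only point-level noise."""
        bm = BandModel(noise_base=0.0, noise_moisture_slope=0.0, dish_offset_ratio=1.0)
        # dish offset is scaled by noise_sd -> zero here, so spectra within a
        # dish and timestep must be identical
        design = DryingDesign(n_points_per_dish=3, n_dishes_per_timestep=1, n_timesteps=1)
        ds = generate_study(design, band_model=bm, master_seed=5)
        for _, grp in ds.meta.groupby(["sample_id", "dish", "timestep"]):
            block = ds.absorbance[grp.index.to_numpy()]
            assert np.allclose(block, block[0])
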