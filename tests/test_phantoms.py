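import numpy as np
import pytest

from patjrec.forward import SensorData
from patjrec.grid import make_grid
from patjrec.phantoms import (
    Disk,
    OpticalMaps,
    add_exogenous_absorbers,
    add_noise,
    build_simple_phantom,
    diffusion_fluence,
    load_chromophore_table,
    p0_from_fluence,
    scaled_twin_spec,
    simple_phantom_spec,
    spectral_mu_a,
    tissue_phantom,
)


def target_grid(n=40, dx=0.5e-3):
    return make_grid(n, dx, 2, 4, 8e-8, 20)


class TestSimplePhantom:
    def test_low_contrast_values(self):
        g = make_grid(100, 0.2e-3, 4, 8, 4e-8, 20)
        med, p0s = build_simple_phantom(simple_phantom_spec("low_contrast"), g)
        c = g.restrict(med.c)
        assert set(np.unique(c)) == {1430.0, 1580.0}
        assert len(p0s) == 4
        for p in p0s:
            assert set(np.unique(p)) == {0.0, 10.0}

    def test_water_bath_layer_present(self):
        g = make_grid(100, 0.2e-3, 4, 8, 4e-8, 20)
        med, _ = build_simple_phantom(simple_phantom_spec("water_bath"), g)
        assert 1482.0 in np.unique(g.restrict(med.c))

    def test_high_contrast_rectangle_present(self):
        g = make_grid(100, 0.2e-3, 4, 8, 4e-8, 20)
        med, _ = build_simple_phantom(simple_phantom_spec("high_contrast"), g)
        assert 2500.0 in np.unique(g.restrict(med.c))

    def test_inclusion_outside_domain_rejected(self):
        g = target_grid()
        spec = scaled_twin_spec()
        spec.c_inclusions.append(Disk(25e-3, 5e-3, 1e-3, 1580.0))
        with pytest.raises(ValueError):
            build_simple_phantom(spec, g)

    def test_rasterised_area_converges_to_circle_area(self):
        r = 2e-3
        areas = []
        for n, dx in [(40, 0.5e-3), (160, 0.125e-3)]:
            g = make_grid(n, dx, 2, 4, 8e-8, 20)
            spec = scaled_twin_spec()
            spec.c_inclusions = [Disk(10e-3, 10e-3, r, 1580.0)]
            spec.p0_disks = [[]]
            med, _ = build_simple_phantom(spec, g)
            areas.append(np.sum(g.restrict(med.c) == 1580.0) * dx**2)
        exact = np.pi * r**2
        assert abs(areas[1] - exact) < abs(areas[0] - exact)
        assert abs(areas[1] - exact) / exact < 0.02


class TestDiffusionFluence:
    def _homog(self, n=40):
        g = target_grid(n)
        mu_a = np.full((n, n), 0.01)
        mu_s = np.full((n, n), 1.0)
        return g, mu_a, mu_s

    def test_positive_and_monotone_decay_from_source(self):
        g, mu_a, mu_s = self._homog()
        phi = diffusion_fluence(mu_a, mu_s, g, sides=("top",))
        assert np.all(phi > 0)
        centre = phi[:, phi.shape[1] // 2]
        assert np.all(np.diff(centre) < 0)  # strictly decreasing with depth

    def test_symmetric_illumination_symmetric_fluence(self):
        g, mu_a, mu_s = self._homog()
        phi = diffusion_fluence(mu_a, mu_s, g, sides=("top", "bottom"))
        assert np.allclose(phi, phi[::-1, :], atol=1e-10 * phi.max())

    def test_centreline_decay_matches_effective_attenuation(self):
        # optics chosen so axial attenuation dominates lateral leakage and
        # the 1D asymptote sqrt(mu_a / kappa) applies on the centreline
        n = 60
        g = target_grid(n)
        mu_a = np.full((n, n), 0.05)
        mu_s = np.full((n, n), 2.0)
        phi = diffusion_fluence(mu_a, mu_s, g, sides=("top",))
        dx_mm = g.dx * 1e3
        kappa = 1.0 / (2.0 * (0.05 + 2.0))
        mu_eff = np.sqrt(0.05 / kappa)  # 1/mm
        centre = phi[:, n // 2]
        # fit decay beyond two transport lengths, away from the far boundary
        i0 = int(2.0 / (2.0 + 0.05) / dx_mm) + 2
        i1 = len(centre) - 10
        slope = np.polyfit(np.arange(i0, i1) * dx_mm, np.log(centre[i0:i1]), 1)[0]
        assert abs(-slope - mu_eff) / mu_eff < 0.10

    def test_invalid_optics_rejected(self):
        g, mu_a, mu_s = self._homog()
        with pytest.raises(ValueError):
            diffusion_fluence(-mu_a, mu_s, g)


class TestPhotoacousticEfficiency:
    def test_p0_product_rule(self):
        mu = np.full((5, 5), 0.2)
        phi = np.full((5, 5), 3.0)
        assert np.allclose(p0_from_fluence(mu, phi, 1.0), 0.6)
        assert np.allclose(p0_from_fluence(mu, phi, 2.0), 1.2)
        assert not p0_from_fluence(mu, np.zeros((5, 5))).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            p0_from_fluence(np.ones((3, 3)), np.ones((4, 4)))


class TestSpectralAbsorption:
    def test_pure_chromophore_recovers_table_value(self):
        table = load_chromophore_table()
        optics = OpticalMaps(
            v_hbo2=np.ones((3, 3)),
            v_hhb=np.zeros((3, 3)),
            v_water=np.zeros((3, 3)),
            v_fat=np.zeros((3, 3)),
            mu_a_baseline=0.0,
        )
        row = table[table.wavelength_nm == 800].iloc[0]
        assert np.allclose(spectral_mu_a(optics, 800.0), row.hbo2)

    def test_zero_fractions_leave_baseline(self):
        optics = OpticalMaps(
            v_hbo2=np.zeros((2, 2)), v_hhb=np.zeros((2, 2)),
            v_water=np.zeros((2, 2)), v_fat=np.zeros((2, 2)),
            mu_a_baseline=1e-3,
        )
        assert np.allclose(spectral_mu_a(optics, 700.0), 1e-3)

    def test_four_wavelengths_give_distinct_maps(self, rng):
        optics = OpticalMaps(
            v_hbo2=rng.random((6, 6)) * 0.1,
            v_hhb=rng.random((6, 6)) * 0.1,
            v_water=rng.random((6, 6)) * 0.5,
            v_fat=rng.random((6, 6)) * 0.3,
        )
        maps = [spectral_mu_a(optics, lam) for lam in (650.0, 750.0, 850.0, 950.0)]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not np.allclose(maps[i], maps[j])

    def test_out_of_range_wavelength_rejected(self):
        optics = OpticalMaps(v_hbo2=np.ones((2, 2)))
        with pytest.raises(ValueError):
            spectral_mu_a(optics, 1500.0)


class TestExogenousAbsorbers:
    def test_empty_list_is_identity(self):
        g = target_grid()
        mu = np.full((40, 40), 0.02)
        assert np.array_equal(add_exogenous_absorbers(mu, [], g), mu)

    def test_override_semantics_and_count(self):
        g = target_grid()
        mu = np.full((40, 40), 0.5)  # tissue more absorbing than the absorber
        mm = 1e-3
        disks = [
            Disk(4 * mm, 4 * mm, 1.5 * mm, 0.3),
            Disk(16 * mm, 4 * mm, 1.5 * mm, 0.3),
            Disk(4 * mm, 16 * mm, 1.5 * mm, 0.3),
            Disk(16 * mm, 16 * mm, 1.5 * mm, 0.3),
        ]
        out = add_exogenous_absorbers(mu, disks, g)
        assert np.sum(out == 0.3) > 0
        from scipy.ndimage import label

        lab, nreg = label(out == 0.3)
        assert nreg == 4

    def test_position_outside_rejected(self):
        g = target_grid()
        with pytest.raises(ValueError):
            add_exogenous_absorbers(np.ones((40, 40)), [Disk(30e-3, 5e-3, 1e-3, 0.3)], g)


class TestAddNoise:
    def _data(self, y):
        return SensorData(y=y, dt=1e-8, dx=1e-4, sensor_positions=np.zeros((y.shape[0], 2)))

    def test_zero_level_identity(self, rng):
        d = self._data(rng.standard_normal((4, 100)))
        assert np.array_equal(add_noise(d, 0.0, 1).y, d.y)

    def test_fixed_seed_reproducible(self, rng):
        d = self._data(rng.standard_normal((4, 100)))
        a = add_noise(d, 0.01, 42)
        b = add_noise(d, 0.01, 42)
        assert np.array_equal(a.y, b.y)
        c = add_noise(d, 0.01, 43)
        assert not np.array_equal(a.y, c.y)

    def test_empirical_std_matches_target(self, rng):
        y = rng.uniform(-5.0, 5.0, size=(1000, 1000))
        y[0, 0], y[0, 1] = -5.0, 5.0
        d = self._data(y)
        noisy = add_noise(d, 0.01, 7)
        std = np.std(noisy.y - y)
        assert abs(std - 0.1) / 0.1 < 0.01


@pytest.fixture(scope="module")
def phantom():
    g = make_grid(48, 0.3e-3, 3, 6, 5e-8, 20)
    optics, c = tissue_phantom(g, seed=0)
    return g, optics, c


class TestTissuePhantom:

    def test_fields_physical(self, phantom):
        g, optics, c = phantom
        for frac in (optics.v_hbo2, optics.v_hhb, optics.v_water, optics.v_fat):
            assert frac.min() >= 0.0 and frac.max() <= 1.0
        assert c.min() >= 1430.0 and c.max() <= 1580.0

    def test_multi_illumination_pressures_distinct(self, phantom):
        from patjrec.experiments import tissue_p0_datasets

        g, optics, _ = phantom
        p0s = tissue_p0_datasets(optics, g, mode="illumination")
        for i in range(4):
            for j in range(i + 1, 4):
                d = np.linalg.norm(p0s[i] - p0s[j]) / max(
                    np.linalg.norm(p0s[i]), np.linalg.norm(p0s[j])
                )
                assert d > 0.10

    def test_multi_wavelength_pressures_similar_in_shape(self, phantom):
        from patjrec.experiments import tissue_p0_datasets

        g, optics, _ = phantom
        p0s = tissue_p0_datasets(optics, g, mode="wavelength")
        for i in range(4):
            for j in range(i + 1, 4):
                a = (p0s[i] - p0s[i].mean()) / p0s[i].std()
                b = (p0s[j] - p0s[j].mean()) / p0s[j].std()
                assert np.mean(a * b) > 0.9

    def test_exogenous_absorber_datasets_differ_from_baseline(self, phantom):
        from patjrec.experiments import tissue_p0_datasets

        g, optics, _ = phantom
        mm = 1e-3
        sets = [
            [Disk(2 * mm, 2 * mm, 1 * mm, 0.3), Disk(12 * mm, 2 * mm, 1 * mm, 0.3)],
            [Disk(2 * mm, 12 * mm, 1 * mm, 0.3), Disk(12 * mm, 12 * mm, 1 * mm, 0.3)],
        ]
        p0s = tissue_p0_datasets(optics, g, mode="absorbers", absorber_sets=sets)
        assert len(p0s) == 3
        for k in (1, 2):
            d = np.linalg.norm(p0s[0] - p0s[k]) / np.linalg.norm(p0s[0])
            assert d > 0.10
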