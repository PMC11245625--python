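"""Phantom generator: geometry, analytic Helmholtz fields, noise, cohorts."""

import numpy as np
import pytest
from scipy.constants import epsilon_0, mu_0

from helmept.phantom import (
    CohortSpec,
    CompartmentSpec,
    FieldModel,
    OrganEffect,
    PhantomGeometry,
    add_noise,
    apply_contrast,
    make_cohort,
    make_dixon,
    make_field,
    make_label_volume,
    wavenumber,
)
from helmept.stats import univariate


def ring_geometry(shape, spacing, widths, height=None):
    return PhantomGeometry(
        shape=shape,
        spacing=spacing,
        outer_diameter_mm=2 * sum(widths),
        ring_widths_mm=tuple(widths),
        height_mm=height,
    )


def comps(sigmas, **kw):
    return [CompartmentSpec(label=i + 1, sigma=s, **kw) for i, s in enumerate(sigmas)]


class TestLabelVolume:
    def test_five_rings_give_five_labels(self):
        geo = ring_geometry((64, 64, 64), (2.0, 2.0, 2.0), [12] * 5)
        labels = make_label_volume(geo, comps([0.2, 0.5, 0.7, 1.0, 1.5]))
        assert set(np.unique(labels.data)) == {0, 1, 2, 3, 4, 5}

    def test_rotational_symmetry_up_to_voxelization(self):
        geo = ring_geometry((32, 32, 8), (2.0, 2.0, 2.0), [10, 6])
        lab = make_label_volume(geo, comps([0.3, 0.6])).data
        # the grid centre sits midway between voxels, so index reversal is a
        # symmetry of the continuous layout
        assert np.array_equal(lab, lab[::-1, :, :])
        assert np.array_equal(lab, lab[:, ::-1, :])
        assert np.array_equal(lab, np.swapaxes(lab, 0, 1))

    def test_default_outer_radius_in_voxels(self):
        # 300 mm outer diameter on 2 mm spacing: outer edge at 75 +/- 1 voxels
        geo = ring_geometry((160, 160, 4), (2.0, 2.0, 2.0), [30] * 5)
        lab = make_label_volume(geo, comps([0.2, 0.5, 0.7, 1.0, 1.5])).data
        sl = lab[:, :, 2]
        xs, ys = np.nonzero(sl)
        r = np.sqrt((xs - 79.5) ** 2 + (ys - 79.5) ** 2)
        assert abs(r.max() - 75.0) <= 1.0

    def test_single_blob_fills_grid(self):
        geo = PhantomGeometry(
            shape=(16, 16, 16),
            spacing=(2.0, 2.0, 2.0),
            layout="blobs",
            blob_centers_mm=((0.0, 0.0, 0.0),),
            blob_radii_mm=(1000.0,),
            fit="clip",
        )
        lab = make_label_volume(geo, comps([0.5])).data
        assert np.all(lab == 1)

    def test_oversized_layout_names_dimension(self):
        geo = ring_geometry((64, 64, 64), (2.0, 2.0, 2.0), [30] * 5)
        with pytest.raises(ValueError, match="dimension"):
            make_label_volume(geo, comps([0.2, 0.5, 0.7, 1.0, 1.5]))

    def test_compartment_count_must_match(self):
        geo = ring_geometry((32, 32, 8), (2.0, 2.0, 2.0), [10, 6])
        with pytest.raises(ValueError, match="compartments"):
            make_label_volume(geo, comps([0.3]))

    def test_invalid_compartment_parameters(self):
        with pytest.raises(ValueError):
            CompartmentSpec(label=0, sigma=0.5)
        with pytest.raises(ValueError):
            CompartmentSpec(label=1, sigma=0.5, eps_r=0.5)
        with pytest.raises(ValueError):
            CompartmentSpec(label=1, sigma=0.5, i0=0.0)
        with pytest.raises(ValueError):
            CompartmentSpec(label=1, sigma=0.5, fvf=1.2)


class TestField:
    def test_lossless_medium_has_unit_magnitude(self):
        geo = ring_geometry((16, 16, 16), (2.0, 2.0, 2.0), [14])
        compartments = comps([0.0], eps_r=1.0)
        labels = make_label_volume(geo, compartments)
        field = make_field(labels, compartments)
        k = wavenumber(0.0, 1.0, FieldModel().omega)
        assert k.imag == pytest.approx(0.0, abs=1e-12)
        fg = labels.foreground()
        np.testing.assert_allclose(np.abs(field.data[fg]), 1.0, rtol=1e-12)

    @pytest.mark.parametrize("sigma,eps_r", [(0.7, 50.0), (0.2, 1.0), (1.5, 80.0)])
    def test_wavenumber_satisfies_helmholtz_dispersion(self, sigma, eps_r):
        omega = FieldModel().omega
        k = wavenumber(sigma, eps_r, omega)
        k2_expected = mu_0 * eps_r * epsilon_0 * omega**2 - 1j * mu_0 * sigma * omega
        assert k**2 == pytest.approx(k2_expected, rel=1e-14)
        # the reconstruction formula applied to the continuum field recovers
        # kappa = sigma + i*omega*eps exactly
        kappa = -(k**2) / (1j * mu_0 * omega)
        assert kappa.real == pytest.approx(sigma, rel=1e-12)
        assert kappa.imag == pytest.approx(omega * eps_r * epsilon_0, rel=1e-12)

    def test_analytic_laplacian_by_finite_differences(self):
        # central differences on the continuum plane wave: Lap(B)/B = -k^2
        omega = FieldModel().omega
        k = wavenumber(0.7, 50.0, omega)
        d = np.array([0.0, 0.0, 1.0])
        f = lambda r: np.exp(-1j * k * (d @ r))
        r0 = np.array([0.003, -0.002, 0.005])
        h = 5e-5
        lap = 0.0
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            lap += (f(r0 + e) - 2 * f(r0) + f(r0 - e)) / h**2
        assert lap / f(r0) == pytest.approx(-(k**2), rel=1e-5)

    def test_two_compartments_piecewise_exact(self, two_ring):
        labels, compartments, model, _ = two_ring
        field = make_field(labels, compartments, model)
        coords = [
            (np.arange(n) - (n - 1) / 2) * s
            for n, s in zip(labels.shape, labels.spacing)
        ]
        zz = np.meshgrid(*coords, indexing="ij")[2] * 1e-3
        for comp in compartments:
            k = wavenumber(comp.sigma, comp.eps_r, model.omega)
            mask = labels.mask(comp.label)
            np.testing.assert_allclose(
                field.data[mask], np.exp(-1j * k * zz[mask]), rtol=1e-12
            )

    def test_missing_spec_lists_labels(self, two_ring):
        labels, compartments, model, _ = two_ring
        with pytest.raises(ValueError, match=r"\[2\]"):
            make_field(labels, compartments[:1], model)

    def test_phase_wrap_guard(self):
        # a long, highly conductive compartment would push arg(S) past pi
        geo = ring_geometry((16, 16, 128), (2.0, 2.0, 2.0), [14])
        compartments = comps([1.5], eps_r=50.0)
        labels = make_label_volume(geo, compartments)
        with pytest.raises(ValueError, match="wrap"):
            make_field(labels, compartments)


class TestContrast:
    def test_unit_contrast_is_squared_field(self, two_ring):
        labels, compartments, model, _ = two_ring
        field = make_field(labels, compartments, model)
        unit = [
            CompartmentSpec(label=c.label, sigma=c.sigma, eps_r=c.eps_r, i0=1.0)
            for c in compartments
        ]
        signal = apply_contrast(field, labels, unit)
        fg = labels.foreground()
        np.testing.assert_array_equal(signal.data[fg], field.data[fg] ** 2)

    def test_doubled_contrast_scales_magnitude_only(self, two_ring):
        labels, compartments, model, signal = two_ring
        doubled = [
            CompartmentSpec(label=c.label, sigma=c.sigma, eps_r=c.eps_r,
                            i0=(2 * c.i0 if c.label == 1 else c.i0))
            for c in compartments
        ]
        field = make_field(labels, compartments, model)
        signal2 = apply_contrast(field, labels, doubled)
        m1 = labels.mask(1)
        np.testing.assert_allclose(np.abs(signal2.data[m1]),
                                   2 * np.abs(signal.data[m1]), rtol=1e-12)
        np.testing.assert_allclose(np.angle(signal2.data[m1]),
                                   np.angle(signal.data[m1]), atol=1e-12)


class TestNoise:
    def _big_signal(self):
        geo = PhantomGeometry(
            shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0), layout="blobs",
            blob_centers_mm=((0.0, 0.0, 0.0),), blob_radii_mm=(1000.0,),
            fit="clip",
        )
        compartments = comps([0.5])
        labels = make_label_volume(geo, compartments)
        data = np.full(labels.shape, 2.0 + 1.0j)
        from helmept.volumes import ComplexVolume
        return ComplexVolume(data, labels.spacing)

    def test_noise_sd_matches_snr_definition(self):
        signal = self._big_signal()
        noisy = add_noise(signal, 30.0, seed=7)
        target_sd = np.mean(np.abs(signal.data)) / 10 ** (30 / 20)
        resid = (noisy.data - signal.data).real.ravel()
        assert resid.size >= 1e5
        assert np.std(resid) == pytest.approx(target_sd, rel=0.02)

    def test_same_seed_bit_identical_different_seed_differs(self):
        signal = self._big_signal()
        a = add_noise(signal, 30.0, seed=3)
        b = add_noise(signal, 30.0, seed=3)
        c = add_noise(signal, 30.0, seed=4)
        np.testing.assert_array_equal(a.data, b.data)
        frac_diff = np.mean(a.data != c.data)
        assert frac_diff > 0.99

    def test_infinite_snr_is_identity(self):
        signal = self._big_signal()
        out = add_noise(signal, np.inf, seed=1)
        np.testing.assert_array_equal(out.data, signal.data)

    def test_empty_foreground_errors(self):
        from helmept.volumes import ComplexVolume
        empty = ComplexVolume(np.zeros((4, 4, 4), complex), (1, 1, 1))
        with pytest.raises(ValueError, match="foreground"):
            add_noise(empty, 30.0, seed=0)


class TestDixon:
    def test_fraction_limits(self, two_ring):
        labels, _, _, _ = two_ring
        lean = comps([0.2, 0.7], fvf=0.0)
        water, fat = make_dixon(labels, lean)
        assert np.all(fat.data == 0)
        half = [CompartmentSpec(label=i + 1, sigma=s, fvf=0.5)
                for i, s in enumerate([0.2, 0.7])]
        water, fat = make_dixon(labels, half)
        fg = labels.foreground()
        np.testing.assert_allclose(
            fat.data[fg] / (water.data[fg] + fat.data[fg]), 0.5, rtol=1e-12
        )

    def test_noisy_roi_mean_within_three_se(self, two_ring):
        labels, _, _, _ = two_ring
        noise_sd = 0.05
        spec = [CompartmentSpec(label=i + 1, sigma=s, fvf=0.3)
                for i, s in enumerate([0.2, 0.7])]
        from helmept.roi import fvf_for_roi
        vals = []
        for seed in range(12):
            water, fat = make_dixon(labels, spec, noise_sd=noise_sd, seed=seed)
            vals.append(fvf_for_roi(water, fat, labels, 1))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        # mean-of-ratios carries a second-order bias s^2 (2f-1) / T^2
        expected = 0.3 + noise_sd**2 * (2 * 0.3 - 1)
        assert abs(vals.mean() - expected) <= 3 * se


class TestCohort:
    def _organs(self, **kw):
        return {"organ": OrganEffect(sigma0=0.6, **kw)}

    def test_zero_slopes_zero_noise_constant_sigma(self):
        spec = CohortSpec(n_subjects=10, organs=self._organs(), seed=1)
        table = make_cohort(spec)
        np.testing.assert_allclose(table["organ_sigma"], 0.6, rtol=1e-14)

    def test_noiseless_slope_recovered_exactly(self):
        spec = CohortSpec(
            n_subjects=12, organs=self._organs(age_slope=0.002), seed=2
        )
        table = make_cohort(spec)
        res = univariate(table["organ_sigma"], table["age"])
        assert res.slope == pytest.approx(0.002, rel=1e-10)
        assert res.r == pytest.approx(1.0, abs=1e-10)

    def test_determinism_under_seed(self):
        spec = CohortSpec(n_subjects=9, organs=self._organs(age_slope=0.001,
                                                            residual_sd=0.02), seed=5)
        a, b = make_cohort(spec), make_cohort(spec)
        assert a.equals(b)

    def test_slope_inside_confidence_interval_across_seeds(self):
        # residual SD 0.05 at n = 15: the 95% CI covers the programmed slope
        # in at least 90% of repeated cohorts
        from scipy import stats as sps
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = CohortSpec(
                n_subjects=15,
                organs=self._organs(age_slope=0.002, residual_sd=0.05),
                seed=seed,
            )
            table = make_cohort(spec)
            res = univariate(table["organ_sigma"], table["age"])
            se = np.sqrt(res.resid_var / res.sxx)
            tq = sps.t.ppf(0.975, res.n - 2)
            if abs(res.slope - 0.002) <= tq * se:
                hits += 1
        assert hits / n_rep >= 0.90

    def test_too_few_subjects_unidentifiable(self):
        with pytest.raises(ValueError, match="identify"):
            CohortSpec(n_subjects=4, organs=self._organs())
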