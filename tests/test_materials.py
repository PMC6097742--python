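"""Material library and biaxial (E, nu) extraction."""

import io

import numpy as np
import pytest

from vpatch.materials import (BiaxialDataset, MaterialError,
                              fit_linear_elastic, get_material,
                              material_library, plane_stress_forward,
                              synth_biaxial)


class TestLibrary:
    @pytest.mark.parametrize("name, nu, e_mpa, t_mm", [
        ("porcine xenopericardium", 0.39, 2.89, 0.4),
        ("human pericardium", 0.40, 3.40, 0.5),
        ("PTFE", 0.31, 1.40, 0.7),
        ("Dacron", 0.42, 1.19, 0.6),
        ("MPA artery 9yr", 0.45, 0.75, 1.0),
    ])
    def test_measured_properties(self, name, nu, e_mpa, t_mm):
        m = material_library()[name]
        assert m.poissons_ratio == pytest.approx(nu)
        assert m.youngs_modulus == pytest.approx(e_mpa * 1e6)
        assert m.thickness == pytest.approx(t_mm * 1e-3)

    def test_unknown_material_raises(self):
        with pytest.raises(MaterialError, match="unknown material"):
            get_material("teflon sponge")

    def test_alias_lookup(self):
        assert get_material("artery").name == "MPA artery 9yr"


class TestPlaneStress:
    def test_equibiaxial_closed_form(self):
        sx, sy = plane_stress_forward(1e6, 0.4, 0.1, 0.1)
        assert sx == pytest.approx(1e6 * 0.1 / (1 - 0.4))  # 166.7 kPa
        assert sy == pytest.approx(sx)

    def test_zero_strain_zero_stress(self):
        assert plane_stress_forward(1e6, 0.3, 0.0, 0.0) == (0.0, 0.0)

    def test_decoupled_axes_at_zero_poisson(self):
        sx, _ = plane_stress_forward(2e6, 0.0, 0.1, 0.3)
        assert sx == pytest.approx(0.1 * 2e6)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError):
            plane_stress_forward(1e6, 0.5, 0.1, 0.1)


class TestSynthBiaxial:
    def test_peak_strain_matches_protocol(self):
        data = synth_biaxial(2.89e6, 0.39, peak_strain=0.20)
        assert data.strain_x.max() == pytest.approx(0.20, rel=1e-6)
        assert data.strain_y.max() == pytest.approx(0.20, rel=1e-3)

    def test_noise_free_data_is_exact_forward_model(self):
        data = synth_biaxial(1.4e6, 0.31)
        sx, sy = plane_stress_forward(1.4e6, 0.31, data.strain_x,
                                      data.strain_y)
        assert np.allclose(data.stress_x, sx)
        assert np.allclose(data.stress_y, sy)

    def test_same_seed_reproduces_dataset(self):
        a = synth_biaxial(1e6, 0.4, noise_level=0.02, seed=7)
        b = synth_biaxial(1e6, 0.4, noise_level=0.02, seed=7)
        assert np.array_equal(a.stress_x, b.stress_x)

    def test_noise_requires_seed(self):
        with pytest.raises(ValueError, match="seed"):
            synth_biaxial(1e6, 0.4, noise_level=0.02)


class TestFit:
    def test_noise_free_recovery_to_a_tenth_percent(self):
        data = synth_biaxial(2.89e6, 0.39)
        fit = fit_linear_elastic(data)
        assert fit.youngs_modulus == pytest.approx(2.89e6, rel=1e-3)
        assert fit.poissons_ratio == pytest.approx(0.39, abs=4e-4)
        assert fit.r2_x > 0.9999 and fit.r2_y > 0.9999

    def test_noisy_recovery_within_three_percent(self):
        data = synth_biaxial(2.89e6, 0.39, n_samples=500,
                             noise_level=0.02, seed=11)
        fit = fit_linear_elastic(data)
        assert abs(fit.youngs_modulus - 2.89e6) / 2.89e6 < 0.03

    def test_round_trip_residual_vanishes(self):
        data = synth_biaxial(1.19e6, 0.42)
        fit = fit_linear_elastic(data)
        assert fit.residual_norm < 1e-6 * np.abs(data.stress_x).max()

    def test_scale_equivariance(self):
        data = synth_biaxial(1e6, 0.35)
        scaled = BiaxialDataset(data.time, data.strain_x, data.strain_y,
                                3.0 * data.stress_x, 3.0 * data.stress_y)
        f1 = fit_linear_elastic(data)
        f2 = fit_linear_elastic(scaled)
        assert f2.youngs_modulus == pytest.approx(3 * f1.youngs_modulus,
                                                  rel=1e-9)
        assert f2.poissons_ratio == pytest.approx(f1.poissons_ratio,
                                                  abs=1e-9)

    def test_recovery_bias_shrinks_with_noise(self):
        errs = []
        for noise in (0.05, 0.005):
            e_hats = []
            for seed in range(5):
                data = synth_biaxial(2e6, 0.4, n_samples=400,
                                     noise_level=noise, seed=100 + seed)
                e_hats.append(fit_linear_elastic(data).youngs_modulus)
            errs.append(abs(np.mean(e_hats) - 2e6))
        assert errs[1] < errs[0]

    def test_equibiaxial_paths_flag_identifiability(self):
        t = np.linspace(0, 1, 60)
        eps = 0.1 * np.sin(np.pi * t) ** 2
        sx, sy = plane_stress_forward(1e6, 0.4, eps, eps)
        data = BiaxialDataset(t, eps, eps, sx, sy)
        with pytest.warns(UserWarning, match="identifiable"):
            fit = fit_linear_elastic(data)
        assert not fit.identifiable
        assert fit.identifiable_modulus == pytest.approx(1e6 / 0.6, rel=1e-6)

    def test_requires_enough_records_in_window(self):
        data = synth_biaxial(1e6, 0.4, n_samples=12)
        with pytest.raises(ValueError, match=">=10"):
            fit_linear_elastic(data, strain_window=(0.19, 0.20))


class TestTableIO:
    def test_tsv_round_trip(self, tmp_path):
        data = synth_biaxial(1.4e6, 0.31, n_samples=50)
        path = tmp_path / "biaxial.tsv"
        data.write_table(path)
        again = BiaxialDataset.read_table(path)
        assert np.allclose(again.stress_x, data.stress_x)
        assert np.allclose(again.strain_y, data.strain_y)
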