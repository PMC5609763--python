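"""Prior-knowledge compilation: the affine constraint map, multiplets,
groups, fixed quantities, unit conversions and the prior file format."""

import math

import numpy as np
import pytest

from amaresfit import ConstraintError, SchemaError, ValidationError
from amaresfit.prior_knowledge import (Multiplet, PeakPrior, apply_constraints,
                                       compile_prior, constraint_jacobian,
                                       dump_priors, load_priors,
                                       peaks_from_free, prior_schema)
from amaresfit.spectral_model import fwhm_to_damping

from conftest import make_meta, two_peak_priors

DEG = math.pi / 180.0


def singlet(name="A", **kw):
    defaults = dict(shift_start=1.0, linewidth_start=10.0,
                    amplitude_start=2.0, amplitude_upper=50.0,
                    phase_start=20.0)
    defaults.update(kw)
    return PeakPrior(name=name, **defaults)


class TestCompile:
    def test_unconstrained_singlet_is_identity(self):
        cmap = compile_prior([singlet()])
        assert cmap.n_free == 4
        assert np.array_equal(cmap.scale, np.eye(4))
        assert np.array_equal(cmap.offset, np.zeros(4))
        assert cmap.labels == ["A_am", "A_ph", "A_lw", "A_cs"]

    def test_doublet_ties_amplitude_and_shift(self):
        p = singlet(multiplet=Multiplet(n_components=2, j_hz=16.0))
        cmap = compile_prior([p])
        assert cmap.n_sinusoids == 2
        assert cmap.n_free == 4  # not 8: components share every free param
        assert cmap.sinusoid_names == ["A1", "A2"]
        np.testing.assert_allclose(cmap.freq_offset_hz, [-8.0, 8.0])

    def test_doublet_amplitude_ratio(self):
        p = singlet(multiplet=Multiplet(n_components=2, j_hz=10.0,
                                        amplitude_ratios=[1.0, 2.0]))
        cmap = compile_prior([p])
        meta = make_meta()
        x = np.array(cmap.free_start, float)
        x[cmap.free_labels.index("A_am")] = 5.0
        full = apply_constraints(cmap, x, meta)
        amps = full[0::4]
        np.testing.assert_allclose(amps, [5.0, 10.0])

    def test_triplet_offsets_are_symmetric(self):
        p = singlet(multiplet=Multiplet(n_components=3, j_hz=16.0,
                                        amplitude_ratios=[1, 2, 1]))
        cmap = compile_prior([p])
        np.testing.assert_allclose(cmap.freq_offset_hz, [-16.0, 0.0, 16.0])

    def test_five_peaks_share_one_phase(self):
        priors = [singlet(name=f"P{i}", shift_start=float(i), group_phase="g")
                  for i in range(5)]
        cmap = compile_prior(priors)
        ph_cols = [j for j, lab in enumerate(cmap.free_labels)
                   if lab.endswith("_ph")]
        assert len(ph_cols) == 1
        col = cmap.scale[:, ph_cols[0]]
        assert np.count_nonzero(col) == 5
        assert set(col[col != 0]) == {1.0}
        # applying a shared 30 deg phase reaches every member
        x = np.array(cmap.free_start, float)
        x[ph_cols[0]] = 30.0 * DEG
        full = cmap.affine(x)
        np.testing.assert_allclose(full[1::4], 30.0 * DEG)

    def test_base_linewidth_is_additive(self):
        p = singlet(base_linewidth=7.0, linewidth_lower=1.0,
                    linewidth_upper=100.0)
        cmap = compile_prior([p])
        j = cmap.free_labels.index("A_lw")
        x = np.array(cmap.free_start, float)
        x[j] = 12.0
        assert cmap.affine(x)[2] == pytest.approx(12.0 + 7.0)

    def test_fixed_quantity_leaves_no_free_parameter(self):
        p = singlet(phase_start=0.0, phase_lower=0.0, phase_upper=0.0)
        cmap = compile_prior([p])
        assert cmap.n_free == 3
        assert not any(lab.endswith("_ph") for lab in cmap.free_labels)
        assert cmap.affine(cmap.free_start)[1] == 0.0

    def test_group_bounds_are_intersected(self):
        a = singlet(name="A", group_linewidth="lw", linewidth_lower=2.0,
                    linewidth_upper=30.0)
        b = singlet(name="B", shift_start=2.0, group_linewidth="lw",
                    linewidth_lower=5.0, linewidth_upper=60.0)
        cmap = compile_prior([a, b])
        j = cmap.free_labels.index("A_lw")
        assert (cmap.free_lower[j], cmap.free_upper[j]) == (5.0, 30.0)

    def test_free_start_within_bounds_for_shipped_prior(self, tmp_path):
        from importlib.resources import files
        priors = load_priors(files("amaresfit") / "priors" / "pk_7t_cardiac.yaml")
        cmap = compile_prior(priors)
        assert np.all(cmap.free_start >= cmap.free_lower)
        assert np.all(cmap.free_start <= cmap.free_upper)
        # compile is idempotent in its dimensions
        again = compile_prior(priors)
        assert again.n_free == cmap.n_free
        assert again.labels == cmap.labels

    @pytest.mark.parametrize("bad, err", [
        ([dict(name="A"), dict(name="A")], ConstraintError),
        ([dict(name="A", amplitude_ratio=2.0)], ConstraintError),
        ([dict(name="A", phase_offset=10.0)], ConstraintError),
    ])
    def test_compile_errors(self, bad, err):
        priors = [singlet(**{k: v for k, v in rec.items() if k != "name"},
                          name=rec["name"]) for rec in bad]
        with pytest.raises(err):
            compile_prior(priors)

    def test_disjoint_group_bounds_rejected(self):
        a = singlet(name="A", group_amplitude="amp", amplitude_start=1.0,
                    amplitude_lower=0.0, amplitude_upper=2.0)
        b = singlet(name="B", shift_start=3.0, group_amplitude="amp",
                    amplitude_start=5.0, amplitude_lower=5.0,
                    amplitude_upper=9.0)
        with pytest.raises(ConstraintError):
            compile_prior([a, b])


class TestApply:
    def test_identity_map_converts_units(self):
        cmap = compile_prior([singlet()])
        meta = make_meta(f0=100.0)
        x = np.array([2.0, 20.0 * DEG, 10.0, 1.0])
        full = apply_constraints(cmap, x, meta)
        np.testing.assert_allclose(
            full, [2.0, 20.0 * DEG, fwhm_to_damping(10.0, 0.0), 100.0])

    def test_length_mismatch_rejected(self):
        cmap = compile_prior([singlet()])
        with pytest.raises(ValidationError):
            apply_constraints(cmap, np.zeros(3), make_meta())

    def test_affine_stage_is_exactly_affine(self, rng):
        cmap = compile_prior(two_peak_priors())
        x = rng.uniform(0.5, 1.0, cmap.n_free)
        delta = rng.normal(scale=0.1, size=cmap.n_free)
        lhs = cmap.affine(x + delta) - cmap.affine(x)
        np.testing.assert_allclose(lhs, cmap.scale @ delta, atol=1e-14)

    def test_reference_shift_moves_frequencies(self):
        cmap = compile_prior([singlet(shift_start=4.7)])
        x = np.array(cmap.free_start, float)
        f_water_ref = apply_constraints(cmap, x, make_meta(f0=123.2,
                                                          reference_shift=4.7))
        assert f_water_ref[3] == pytest.approx(0.0)


class TestJacobian:
    def _fd(self, cmap, x, meta, h=1e-7):
        cols = []
        for j in range(cmap.n_free):
            dx = np.zeros(cmap.n_free)
            dx[j] = h
            cols.append((apply_constraints(cmap, x + dx, meta)
                         - apply_constraints(cmap, x - dx, meta)) / (2 * h))
        return np.stack(cols, axis=1)

    def test_identity_map_gives_conversion_diagonal(self):
        cmap = compile_prior([singlet()])
        meta = make_meta(f0=100.0)
        d = constraint_jacobian(cmap, np.array(cmap.free_start), meta)
        assert d.shape == (4, 4)
        assert d[3, 3] == pytest.approx(100.0)  # ppm -> Hz
        assert d[0, 0] == d[1, 1] == 1.0

    @pytest.mark.parametrize("g", [0.0, 0.35, 1.0])
    def test_matches_finite_differences(self, g, rng):
        priors = two_peak_priors()
        for p in priors:
            p.lineshape_g = g
        priors[0].multiplet = Multiplet(n_components=2, j_hz=12.0,
                                        amplitude_ratios=[1.0, 3.0])
        cmap = compile_prior(priors)
        meta = make_meta()
        x = np.array(cmap.free_start, float) + rng.uniform(0, 0.05, cmap.n_free)
        d = constraint_jacobian(cmap, x, meta)
        fd = self._fd(cmap, x, meta)
        err = np.abs(d - fd).max() / np.abs(d).max()
        assert err < 1e-8

    def test_custom_row_extension_point(self):
        cmap = compile_prior([singlet()])
        meta = make_meta()
        j = cmap.free_labels.index("A_lw")
        row = 2  # linewidth row of the only sinusoid
        cmap.set_custom_row(row, lambda x: x[j] ** 2 / 10.0)
        x = np.array(cmap.free_start, float)
        assert cmap.affine(x)[row] == pytest.approx(x[j] ** 2 / 10.0)
        d = constraint_jacobian(cmap, x, meta)
        fd = self._fd(cmap, x, meta, h=1e-5)
        assert np.abs(d[row] - fd[row]).max() < 1e-5 * max(1, np.abs(d[row]).max())


class TestPriorFiles:
    def test_roundtrip(self, tmp_path):
        path = tmp_path / "prior.yaml"
        dump_priors(two_peak_priors(), path)
        back = load_priors(path)
        assert [p.name for p in back] == ["PCR", "ATP"]
        assert back[0].amplitude_upper == 20.0

    def test_schema_error_names_field(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text(
            "version: 1\npeaks:\n  - name: X\n    shift_start: 0.0\n"
            "    linewidth_start: -5.0\n    linewidth_lower: -5.0\n")
        with pytest.raises(SchemaError, match="linewidth"):
            load_priors(path)

    def test_version_mismatch(self, tmp_path):
        path = tmp_path / "v9.yaml"
        path.write_text("version: 9\npeaks: []\n")
        with pytest.raises(SchemaError, match="version"):
            load_priors(path)

    def test_schema_is_exported(self):
        schema = prior_schema()
        assert "properties" in schema and "name" in schema["properties"]
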