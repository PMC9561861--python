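import numpy as np
import pytest

from iclm import Fmri4D, Mask, assemble_fc_matrix, average_fc, preprocess, seed_fc
from iclm.connectome import R_CLAMP, FCVector


def _fmri(grid, flat_series, tr=2.0, subject="s"):
    """Build an Fmri4D from a (n_voxels_total, t) flat array in canonical order."""
    t = flat_series.shape[1]
    return Fmri4D(grid, flat_series.reshape((*grid.dims, t), order="F"), tr=tr,
                  subject_id=subject)


def _full_mask(grid):
    return Mask(grid, np.ones(grid.dims, dtype=np.uint8))


class TestPreprocess:
    def test_constant_series_becomes_zero(self, grid4):
        flat = np.full((64, 50), 3.7)
        out = preprocess(_fmri(grid4, flat), band=(0.01, 0.08))
        assert np.abs(out.series).max() < 1e-10

    def test_passband_sinusoid_retained(self, grid4):
        # oracle: amplitude read off the discrete Fourier transform
        t = np.arange(600) * 2.0
        sig = np.sin(2 * np.pi * 0.04 * t)
        flat = np.tile(sig, (64, 1))
        out = preprocess(_fmri(grid4, flat), band=(0.01, 0.08))
        spec_in = np.abs(np.fft.rfft(sig))
        spec_out = np.abs(np.fft.rfft(out.series.reshape(-1, 600, order="F")[0]))
        k = np.argmax(spec_in)
        assert spec_out[k] / spec_in[k] == pytest.approx(1.0, abs=0.05)

    def test_stopband_sinusoid_attenuated(self, grid4):
        t = np.arange(600) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        flat = np.tile(sig, (64, 1))
        out = preprocess(_fmri(grid4, flat), band=(0.01, 0.08))
        spec_in = np.abs(np.fft.rfft(sig))
        spec_out = np.abs(np.fft.rfft(out.series.reshape(-1, 600, order="F")[0]))
        k = np.argmax(spec_in)
        assert spec_out[k] / spec_in[k] < 0.1

    def test_confound_regressed_out(self, grid4, rng):
        conf = rng.standard_normal(80)
        flat = np.outer(np.linspace(1, 2, 64), conf)
        out = preprocess(_fmri(grid4, flat), confounds=conf[:, None], band=(0.01, 0.08))
        assert np.abs(out.series).max() < 1e-8

    def test_collinear_confounds_named(self, grid4, rng):
        conf = rng.standard_normal(50)
        flat = rng.standard_normal((64, 50))
        with pytest.raises(ValueError, match="rank-deficient"):
            preprocess(_fmri(grid4, flat), confounds=np.c_[conf, conf], band=(0.01, 0.08))

    def test_bad_band_rejected(self, grid4, rng):
        flat = rng.standard_normal((64, 50))
        with pytest.raises(ValueError, match="Nyquist"):
            preprocess(_fmri(grid4, flat, tr=2.0), band=(0.01, 0.3))


class TestSeedFC:
    def _setup(self, grid, rng, t=80):
        series = rng.standard_normal((64, t))
        lesion_data = np.zeros(grid.dims, dtype=np.uint8)
        lesion_data[0, 0, 0] = 1  # flat position 0
        return series, Mask(grid, lesion_data)

    def test_duplicated_series_hits_clamp(self, grid4, rng):
        series, lesion = self._setup(grid4, rng)
        series[5] = series[0]  # voxel 5 duplicates the seed voxel
        vec = seed_fc(_fmri(grid4, series), lesion, _full_mask(grid4))
        expected = np.arctanh(R_CLAMP)  # = 0.5*ln((2-1e-7)/1e-7)
        assert vec.values[5] == pytest.approx(expected)
        assert expected == pytest.approx(0.5 * np.log((2 - 1e-7) / 1e-7))

    def test_sign_flip_antisymmetry(self, grid4, rng):
        series, lesion = self._setup(grid4, rng)
        flipped = series.copy()
        flipped[7] = -series[7]
        a = seed_fc(_fmri(grid4, series), lesion, _full_mask(grid4))
        b = seed_fc(_fmri(grid4, flipped), lesion, _full_mask(grid4))
        assert b.values[7] == pytest.approx(-a.values[7])

    def test_orthogonal_target_is_zero(self, grid4, rng):
        series, lesion = self._setup(grid4, rng, t=8)
        seed = series[0] - series[0].mean()
        v = rng.standard_normal(8)
        v -= v.mean()
        v -= seed * (v @ seed) / (seed @ seed)  # exactly orthogonal, zero mean
        series[9] = v
        vec = seed_fc(_fmri(grid4, series), lesion, _full_mask(grid4))
        assert vec.values[9] == pytest.approx(0.0, abs=1e-12)

    def test_lesion_entries_zeroed(self, grid4, rng):
        series, lesion = self._setup(grid4, rng)
        vec = seed_fc(_fmri(grid4, series), lesion, _full_mask(grid4))
        assert vec.values[0] == 0.0
        assert vec.lesion_cols[0]

    def test_empty_seed_errors(self, grid4, rng):
        series, _ = self._setup(grid4, rng)
        empty_brain = np.zeros(grid4.dims, dtype=np.uint8)
        empty_brain[3, 3, 3] = 1
        lesion_data = np.zeros(grid4.dims, dtype=np.uint8)
        lesion_data[0, 0, 0] = 1
        with pytest.raises(ValueError, match="does not intersect"):
            seed_fc(_fmri(grid4, series), Mask(grid4, lesion_data),
                    Mask(grid4, empty_brain))


class TestAverageFC:
    def _vec(self, values, subject, lesion_at=0):
        values = np.asarray(values, dtype=float)
        cols = np.zeros(values.size, dtype=bool)
        cols[lesion_at] = True
        values = values.copy()
        values[lesion_at] = 0.0
        return FCVector("p", values, cols, subject_id=subject)

    def test_single_vector_identity(self):
        v = self._vec([0, 1.0, 2.0], "a")
        out = average_fc([v])
        np.testing.assert_array_equal(out.values, v.values)

    def test_opposite_vectors_cancel(self):
        a = self._vec([0, 1.0, 2.0], "a")
        b = self._vec([0, -1.0, -2.0], "b")
        assert np.abs(average_fc([a, b]).values).max() == 0

    def test_two_stage_mean_weights_subjects_equally(self):
        # subject a: sessions 1 and 3 -> 2; subject b: 5 -> mean 3.5
        vecs = [self._vec([0, 1.0, 0], "a"), self._vec([0, 3.0, 0], "a"),
                self._vec([0, 5.0, 0], "b")]
        out = average_fc(vecs)
        assert out.values[1] == pytest.approx(3.5)

    def test_subject_permutation_invariance(self, rng):
        vecs = [self._vec(rng.standard_normal(6), s) for s in "abc"]
        a = average_fc(vecs)
        b = average_fc(vecs[::-1])
        np.testing.assert_allclose(a.values, b.values)

    def test_mismatched_zero_pattern_rejected(self):
        a = self._vec([0, 1.0, 2.0], "a", lesion_at=0)
        b = self._vec([1.0, 0, 2.0], "b", lesion_at=1)
        with pytest.raises(ValueError, match="zero-pattern"):
            average_fc([a, b])


class TestAssemble:
    def _brain(self, n=5):
        grid_dim = 2
        import iclm

        grid = iclm.VolumeGrid((5, 1, 1), np.eye(4))
        return Mask(grid, np.ones((5, 1, 1), dtype=np.uint8))

    def _vec(self, values, pid, lesion_at=None):
        values = np.asarray(values, dtype=float)
        cols = np.zeros(values.size, dtype=bool)
        if lesion_at is not None:
            cols[lesion_at] = True
            values = values.copy()
            values[lesion_at] = 0.0
        return FCVector(pid, values, cols)

    def test_row_standardization(self):
        brain = self._brain()
        fc = assemble_fc_matrix(
            [self._vec([1, 2, 3, 4, 5], "a"), self._vec([2, 2, 3, 4, 9], "b")],
            brain, standardize=True, zscore_scope="row")
        for row in fc.values:
            assert row.mean() == pytest.approx(0.0, abs=1e-12)
            assert row.std() == pytest.approx(1.0)

    def test_lesion_cell_exact_zero_after_standardization(self):
        brain = self._brain()
        fc = assemble_fc_matrix(
            [self._vec([1, 2, 0, 4, 5], "a", lesion_at=2), self._vec([2, 1, 3, 4, 9], "b")],
            brain, standardize=True, zscore_scope="row")
        assert fc.values[0, 2] == 0.0

    def test_no_standardize_is_identity(self):
        brain = self._brain()
        vecs = [self._vec([1, 2, 3, 4, 5], "a"), self._vec([2, 2, 3, 4, 9], "b")]
        fc = assemble_fc_matrix(vecs, brain, standardize=False)
        np.testing.assert_array_equal(fc.values[0], vecs[0].values)

    def test_global_scope_preserves_relative_row_scale(self):
        brain = self._brain()
        strong = self._vec([10, -10, 10, -10, 10.0], "a")
        weak = self._vec([1, -1, 1, -1, 1.0], "b")
        fc = assemble_fc_matrix([strong, weak], brain, standardize=True,
                                zscore_scope="global")
        assert fc.values[0].std() / fc.values[1].std() == pytest.approx(10.0, rel=1e-6)

    def test_zero_variance_row_names_patient(self):
        brain = self._brain()
        with pytest.raises(ValueError, match="pt_bad"):
            assemble_fc_matrix(
                [self._vec([1, 1, 1, 1, 1], "pt_bad"), self._vec([1, 2, 3, 4, 5], "b")],
                brain, standardize=True, zscore_scope="row")

    def test_standardization_idempotent(self):
        brain = self._brain()
        vecs = [self._vec([1, 2, 3, 4, 5], "a"), self._vec([2, 2, 3, 4, 9], "b")]
        once = assemble_fc_matrix(vecs, brain, standardize=True, zscore_scope="row")
        again = assemble_fc_matrix(
            [FCVector(pid, row, cols) for pid, row, cols in
             zip(once.patient_ids, once.values, once.lesion_cols)],
            brain, standardize=True, zscore_scope="row")
        np.testing.assert_allclose(again.values, once.values, atol=1e-12)
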