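import numpy as np
import pytest

from sparsect import phantoms as ph
from sparsect import tomography as tg
from sparsect.encoding import (DoseTarget, ProjectionEncoding, SamplingEncoder,
                               apply_encoding, biased_relu, dose_fraction,
                               equal_interval_encoding, export_fixed_encoding)
from sparsect.nn import Tensor


@pytest.fixture(scope="module")
def sino_batch(small_geo):
    sinos = []
    for i in range(8):
        img, _ = ph.make_random_phantom(32, 4, seed=100 + i)
        sinos.append(tg.radon(img, small_geo))
    return sinos


class TestBiasedRelu:
    @pytest.mark.parametrize("v,lam,expected", [
        (0.5, 0.2, 0.3),
        (-1.0, 0.0, 0.0),
        (0.2, 0.5, 0.0),
    ])
    def test_closed_form(self, v, lam, expected):
        assert biased_relu(np.array([v]), lam)[0] == pytest.approx(expected)

    def test_negative_bias_rejected(self):
        with pytest.raises(ValueError):
            biased_relu(np.zeros(3), -0.1)


class TestDoseFraction:
    def test_full_dose_is_one(self):
        assert dose_fraction(ProjectionEncoding(np.ones(90))) == 1.0

    def test_zero_dose(self):
        assert dose_fraction(ProjectionEncoding(np.zeros(90))) == 0.0

    def test_counting(self):
        e = np.zeros(90)
        e[:30] = 1.0
        assert dose_fraction(ProjectionEncoding(e)) == pytest.approx(1 / 3)


class TestApplyEncoding:
    def test_identity_at_full_dose(self, sino_batch):
        out = apply_encoding(sino_batch[0], ProjectionEncoding(np.ones(30)))
        np.testing.assert_array_equal(out.values, sino_batch[0].values)

    def test_zero_encoding(self, sino_batch):
        out = apply_encoding(sino_batch[0], ProjectionEncoding(np.zeros(30)))
        assert np.all(out.values == 0)

    def test_columnwise_scaling(self, sino_batch):
        e = np.ones(30)
        e[7] = 0.5
        out = apply_encoding(sino_batch[0], ProjectionEncoding(e))
        np.testing.assert_allclose(out.values[:, 7],
                                   0.5 * sino_batch[0].values[:, 7])
        others = [j for j in range(30) if j != 7]
        np.testing.assert_array_equal(out.values[:, others],
                                      sino_batch[0].values[:, others])

    def test_length_mismatch(self, sino_batch):
        with pytest.raises(ValueError):
            apply_encoding(sino_batch[0], ProjectionEncoding(np.ones(29)))


class TestEqualInterval:
    def test_third_of_ninety(self):
        e = equal_interval_encoding(90, DoseTarget(1 / 3))
        assert set(np.flatnonzero(e.e)) == set(range(0, 90, 3))
        assert dose_fraction(e) == pytest.approx(1 / 3)

    def test_full_dose(self):
        e = equal_interval_encoding(90, DoseTarget(1.0))
        assert np.all(e.e == 1.0)

    def test_quarter_of_ten(self):
        e = equal_interval_encoding(10, DoseTarget(0.25))
        assert list(np.flatnonzero(e.e)) == [0, 5]

    def test_zero_kept_angles_rejected(self):
        with pytest.raises(ValueError):
            equal_interval_encoding(10, DoseTarget(0.01))


class TestSamplingEncoder:
    def test_output_contract(self, small_geo, sino_batch):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        codes = enc.encode(sino_batch, mode="train")
        assert len(codes) == 8
        for c in codes:
            assert c.m2 == 30
            assert c.e.min() >= 0.0 and c.e.max() <= 1.0

    def test_large_bias_zeroes_encoding(self, small_geo, sino_batch):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0,
                              lambda_bias=1e6)
        codes = enc.encode(sino_batch, mode="train")
        for c in codes:
            assert np.all(c.e == 0.0)

    def test_eval_mode_deterministic(self, small_geo, sino_batch):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        a = enc.encode(sino_batch[0], mode="eval")[0]
        b = enc.encode(sino_batch[0], mode="eval")[0]
        np.testing.assert_array_equal(a.e, b.e)

    def test_sparsity_monotone_in_bias(self, small_geo, sino_batch):
        """Over a lambda' sweep, the L1 dose never increases and the zero
        count never decreases (direct consequence of thresholding)."""
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        batch = Tensor(np.stack([s.values for s in sino_batch])[:, None])
        doses, zeros = [], []
        for lam in np.linspace(0.0, 3.0, 20):
            enc.lambda_bias = float(lam)
            codes = enc.forward(batch, train=True).data
            doses.append(codes.mean())
            zeros.append(int((codes == 0).sum()))
        assert all(d2 <= d1 + 1e-12 for d1, d2 in zip(doses, doses[1:]))
        assert all(z2 >= z1 for z1, z2 in zip(zeros, zeros[1:]))

    def test_shape_mismatch_rejected(self, small_geo):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        with pytest.raises(ValueError):
            enc.forward(Tensor(np.zeros((2, 1, 10, 30))), train=False)

    def test_gradient_reaches_fcn_weights(self, small_geo, sino_batch):
        """A dose-penalty perturbation propagates to the first FC layer,
        matching finite differences."""
        enc = SamplingEncoder(small_geo.m1, 30, hidden=16, seed=0)
        batch = Tensor(np.stack([s.values for s in sino_batch[:4]])[:, None])

        def loss_val():
            codes = enc.forward(batch, train=True)
            return codes.abs().mean()

        loss = loss_val()
        loss.backward()
        w = enc.fc1.weight
        idx = (100, 3)
        g = w.grad[idx]
        eps = 1e-6
        w.data[idx] += eps
        f1 = float(loss_val().data)
        w.data[idx] -= 2 * eps
        f0 = float(loss_val().data)
        w.data[idx] += eps
        fd = (f1 - f0) / (2 * eps)
        assert g == pytest.approx(fd, abs=1e-6, rel=1e-3)


class TestExportFixedEncoding:
    def test_mean_of_identical_codes(self, small_geo, sino_batch):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        fixed = export_fixed_encoding(enc, [sino_batch[0]] * 3)
        single = enc.encode(sino_batch[0], mode="eval")[0]
        np.testing.assert_allclose(fixed.e, single.e, atol=1e-12)

    def test_binarize_top_k(self, small_geo, sino_batch):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        fixed = export_fixed_encoding(enc, sino_batch, binarize=True,
                                      target=DoseTarget(0.2))
        assert int(fixed.e.sum()) == 6  # round(30 * 0.2)
        assert set(np.unique(fixed.e)) <= {0.0, 1.0}

    def test_deterministic(self, small_geo, sino_batch):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        a = export_fixed_encoding(enc, sino_batch)
        b = export_fixed_encoding(enc, sino_batch)
        np.testing.assert_array_equal(a.e, b.e)

    def test_empty_dataset_rejected(self, small_geo):
        enc = SamplingEncoder(small_geo.m1, 30, hidden=64, seed=0)
        with pytest.raises(ValueError):
            export_fixed_encoding(enc, [])


def test_encoding_validation():
    with pytest.raises(ValueError):
        ProjectionEncoding(np.array([0.5, 1.2]))
    with pytest.raises(ValueError):
        ProjectionEncoding(np.array([-0.1, 0.5]))
    with pytest.raises(ValueError):
        DoseTarget(0.0)
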