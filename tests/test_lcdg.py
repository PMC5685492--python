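"""LCDG intensity model: discrete Gaussians, signed EM fit, class partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

import brainseg as bs
from brainseg.lcdg import (
    DGComponent,
    LCDGError,
    LCDGFitOptions,
    LCDGModel,
    dg_pdf,
    empirical_density,
    fit_lcdg,
    partition_classes,
)


def sample_histogram(means, sigmas, weights, n, seed, Q=256):
    """Draw from a Gaussian mixture, quantize to grey levels, normalize."""
    rng = np.random.default_rng(seed)
    comps = rng.choice(len(means), size=n, p=np.asarray(weights) / np.sum(weights))
    x = rng.normal(np.asarray(means)[comps], np.asarray(sigmas)[comps])
    q = np.clip(np.rint(x), 0, Q - 1).astype(int)
    h = np.bincount(q, minlength=Q).astype(float)
    return h / h.sum()


class TestDGPdf:
    @pytest.mark.parametrize("mu,sigma", [(100.0, 10.0), (0.0, 5.0), (255.0, 30.0), (127.5, 1.0)])
    def test_sums_to_one(self, mu, sigma):
        assert dg_pdf(mu, sigma, 256).sum() == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_about_center(self):
        psi = dg_pdf(127.5, 20.0, 256)
        assert np.allclose(psi, psi[::-1], atol=1e-12)

    def test_center_bin_matches_erf_oracle(self):
        psi = dg_pdf(100.0, 10.0, 256)
        expected = ndtr(0.05) - ndtr(-0.05)
        assert psi[100] == pytest.approx(expected, abs=1e-14)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(LCDGError):
            dg_pdf(10.0, 0.0, 256)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        mu=st.floats(-50, 305),
        sigma=st.floats(0.2, 80),
    )
    def test_valid_density_for_any_parameters(self, mu, sigma):
        """Any DG is a proper non-negative density, unimodal away from the
        tail-absorbing edge bins."""
        psi = dg_pdf(mu, sigma, 256)
        assert psi.min() >= 0.0
        assert psi.sum() == pytest.approx(1.0, abs=1e-9)
        interior = psi[1:-1]
        peak = int(np.argmax(interior))
        assert np.all(np.diff(interior[: peak + 1]) >= -1e-15)
        assert np.all(np.diff(interior[peak:]) <= 1e-15)


class TestEmpiricalDensity:
    def test_constant_volume_is_point_mass(self):
        v = bs.Volume(np.full((6, 6, 6), 42, dtype=np.int16))
        d = empirical_density(v, mask=np.ones((6, 6, 6), dtype=bool))
        assert d[42] == 1.0 and d.sum() == 1.0

    def test_sums_to_one(self, adult_small):
        assert empirical_density(adult_small.grey).sum() == pytest.approx(1.0)

    def test_empty_mask_rejected(self, adult_small):
        with pytest.raises(LCDGError, match="empty"):
            empirical_density(adult_small.grey, mask=np.zeros((32, 32, 32), bool))

    def test_large_sample_close_to_generating_mixture(self):
        means, sigmas, weights = (60, 110, 170), (12, 12, 12), (1 / 3, 1 / 3, 1 / 3)
        h = sample_histogram(means, sigmas, weights, n=200_000, seed=42)
        truth = sum(w * dg_pdf(m, s, 256) for m, s, w in zip(means, sigmas, weights))
        # DKW-style check on the CDFs
        assert np.max(np.abs(np.cumsum(h) - np.cumsum(truth))) < 0.01


class TestFitLCDG:
    def test_single_dg_collapses_to_one_dominant(self):
        f = dg_pdf(120.0, 15.0, 256)
        model = fit_lcdg(f, K=2)
        weights = sorted((c.w for c in model.dominant), reverse=True)
        assert weights[0] >= 0.99
        assert abs(model.dominant[int(np.argmax([c.w for c in model.dominant]))].mu - 120.0) <= 1.0

    def test_signed_weight_constraint(self):
        h = sample_histogram((60, 110, 170), (12, 12, 12), (0.3, 0.4, 0.3), 100_000, 7)
        model = fit_lcdg(h, K=3)
        assert abs(model.signed_weight_sum() - 1.0) <= 1e-6

    def test_three_mode_recovery(self):
        h = sample_histogram((60, 110, 170), (12, 12, 12), (1, 1, 1), 200_000, 0)
        model, trace = fit_lcdg(h, K=3, return_trace=True)
        mus = sorted(c.mu for c in model.dominant)
        for got, want in zip(mus, (60, 110, 170)):
            assert abs(got - want) <= 2.0
        cdf_gap = np.max(np.abs(np.cumsum(model.density() / model.density().sum()) - np.cumsum(h)))
        assert cdf_gap <= 0.01
        # refinement trace is monotone non-increasing (guarded acceptance)
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_unnormalized_density_rejected(self):
        with pytest.raises(LCDGError, match="normalized"):
            fit_lcdg(np.ones(256), K=2)

    def test_k_exceeding_support_rejected(self):
        f = np.zeros(256)
        f[10] = 0.5
        f[20] = 0.5
        with pytest.raises(LCDGError, match="exceeds"):
            fit_lcdg(f, K=3)

    def test_classic_em_agreement_without_subordinates(self):
        """With no subordinate components the fit reduces to classic EM."""
        sklearn = pytest.importorskip("sklearn.mixture")
        means, sigmas, weights = (80, 180), (15, 15), (0.5, 0.5)
        rng = np.random.default_rng(3)
        n = 100_000
        comps = rng.choice(2, size=n, p=weights)
        x = rng.normal(np.asarray(means)[comps], np.asarray(sigmas)[comps])
        q = np.clip(np.rint(x), 0, 255).astype(int)
        h = np.bincount(q, minlength=256).astype(float)
        h /= h.sum()
        model = fit_lcdg(h, K=2, opts=LCDGFitOptions(max_subordinate=0))
        gm = sklearn.GaussianMixture(2, random_state=0, n_init=3).fit(x.reshape(-1, 1))
        order = np.argsort(gm.means_.ravel())
        ours = np.array([[c.mu, c.sigma, c.w] for c in model.dominant])
        theirs = np.column_stack(
            [gm.means_.ravel()[order], np.sqrt(gm.covariances_.ravel()[order]), gm.weights_[order]]
        )
        assert np.abs(ours - theirs).mean() < 0.5


class TestPartitionClasses:
    def test_two_well_separated_modes(self):
        model = LCDGModel(
            dominant=[DGComponent(50.0, 10.0, 0.5), DGComponent(200.0, 10.0, 0.5)],
            Q=256,
        )
        classes = partition_classes(model, 2)
        assert 90 <= classes.thresholds[0] <= 160
        for i, c in enumerate(model.dominant):
            assert np.max(np.abs(classes.densities[i] - c.pdf(256))) < 1e-3

    def test_symmetric_model_symmetric_threshold(self):
        model = LCDGModel(
            dominant=[DGComponent(100.0, 8.0, 0.5), DGComponent(155.0, 8.0, 0.5)],
            Q=256,
        )
        classes = partition_classes(model, 2)
        assert abs(classes.thresholds[0] - 127.5) <= 1.0

    def test_densities_nonnegative_and_normalized(self):
        h = sample_histogram((60, 110, 170), (12, 12, 12), (1, 1, 1), 50_000, 5)
        classes = partition_classes(fit_lcdg(h, K=4), 3)
        assert classes.densities.min() >= 0
        assert np.allclose(classes.densities.sum(axis=1), 1.0, atol=1e-6)
        assert len(classes.thresholds) == 2

    def test_equal_dominant_means_rejected(self):
        model = LCDGModel(
            dominant=[DGComponent(100.0, 8.0, 0.5), DGComponent(100.0, 9.0, 0.5)],
            Q=256,
        )
        model.dominant[1].mu = 100.0
        with pytest.raises(LCDGError, match="separated"):
            partition_classes(model, 2)

    def test_too_many_classes_rejected(self):
        model = LCDGModel(dominant=[DGComponent(100.0, 8.0, 1.0), DGComponent(150.0, 8.0, 0.0)], Q=256)
        with pytest.raises(LCDGError, match="n_classes"):
            partition_classes(model, 3)
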