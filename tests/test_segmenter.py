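"""Initial map, ICM coordinate ascent, fusion, and the full pipeline."""

import numpy as np
import pytest

import brainseg as bs
from brainseg.lcdg import dg_pdf, ClassDensities
from brainseg.mgrf import PotentialTable, enumerate_families, estimate_potentials
from brainseg.segmenter import (
    ICMOptions,
    SegmentationError,
    icm_refine,
    initial_map,
    majority_vote,
)
from brainseg.shape_prior import ShapePriorField


def make_classes(means=(60, 110, 170), sigma=12.0):
    dens = np.stack([dg_pdf(m, sigma, 256) for m in means])
    return ClassDensities(dens, np.full(3, 1 / 3), [85, 140])


def uniform_prior(g):
    probs = np.zeros((*g.shape, 4))
    probs[..., 0] = 1.0
    brain = g.values > 0
    probs[brain] = [0.0, 1 / 3, 1 / 3, 1 / 3]
    return ShapePriorField(probs, g.spacing, g.affine)


def degenerate_prior(g, label):
    probs = np.zeros((*g.shape, 4))
    probs[..., 0] = 1.0
    brain = g.values > 0
    vec = np.zeros(4)
    vec[label] = 1.0
    probs[brain] = vec
    return ShapePriorField(probs, g.spacing, g.affine)


class TestInitialMap:
    def test_uniform_prior_reduces_to_intensity_map(self, adult_noiseless):
        g = adult_noiseless.grey
        m = initial_map(uniform_prior(g), make_classes(), g)
        brain = g.values > 0
        assert np.array_equal(m.values[brain], adult_noiseless.labels.values[brain])
        assert np.all(m.values[~brain] == 0)

    def test_degenerate_prior_overrides_intensity(self, adult_noiseless):
        g = adult_noiseless.grey
        m = initial_map(degenerate_prior(g, 1), make_classes(), g)
        brain = g.values > 0
        # log-floor at 1e-10 cannot overturn certainty: 0 vs about -23
        assert np.all(m.values[brain] == 1)

    def test_exact_prototype_prior_recovers_truth(self, adult_noiseless):
        prior = bs.build_adaptive_prior(
            adult_noiseless.grey, [adult_noiseless], params=bs.PriorSearchParams(tau=0)
        )
        m = initial_map(prior, make_classes(), adult_noiseless.grey)
        brain = adult_noiseless.grey.values > 0
        frac = np.mean(m.values[brain] == adult_noiseless.labels.values[brain])
        assert frac > 0.99

    def test_lattice_mismatch_rejected(self, adult_noiseless):
        g = adult_noiseless.grey
        small = bs.Volume(g.values[:16, :16, :16].copy())
        with pytest.raises(bs.volume_io.VolumeError, match="mismatch"):
            initial_map(uniform_prior(g), make_classes(), small)


class TestICM:
    def test_zero_potentials_fix_initial_map(self, adult_small):
        g = adult_small.grey
        prior = uniform_prior(g)
        classes = make_classes()
        m0 = initial_map(prior, classes, g)
        fams = enumerate_families(4)
        res = icm_refine(g, m0, prior, classes, PotentialTable.zeros(fams), fams)
        assert np.array_equal(res.labels.values, m0.values)
        assert res.changed_fraction[0] == 0.0

    def test_salt_and_pepper_voxel_flipped_back(self):
        # homogeneous 5^3 WM block with one GM voxel; homogeneity-rewarding
        # potentials must restore it in a single sweep
        vals = np.full((5, 5, 5), 170, dtype=np.int16)
        g = bs.Volume(vals)
        labels = np.full((5, 5, 5), 3, dtype=np.int16)
        labels[2, 2, 2] = 2
        m0 = bs.LabelMap(labels)
        prior = uniform_prior(g)
        classes = make_classes(sigma=60.0)  # weak intensity evidence
        fams = enumerate_families(4)
        table = estimate_potentials(m0, fams)
        res = icm_refine(g, m0, prior, classes, table, fams)
        assert res.labels.values[2, 2, 2] == 3
        assert np.all(res.labels.values == 3)

    @pytest.mark.parametrize("seed", range(3))
    def test_objective_non_decreasing(self, seed):
        spec = bs.adult_spec(grid_shape=(24, 24, 24), seed=seed)
        pair = bs.generate_phantom(spec)
        g = pair.grey
        prior = uniform_prior(g)
        classes = make_classes()
        m0 = initial_map(prior, classes, g)
        fams = enumerate_families(4)
        table = estimate_potentials(m0, fams)
        res = icm_refine(g, m0, prior, classes, table, fams)
        trace = res.energy_trace
        assert all(b >= a - 1e-6 for a, b in zip(trace, trace[1:]))

    def test_idempotent_after_convergence(self):
        pair = bs.generate_phantom(bs.adult_spec(grid_shape=(24, 24, 24), seed=50))
        g = pair.grey
        prior = uniform_prior(g)
        classes = make_classes()
        m0 = initial_map(prior, classes, g)
        fams = enumerate_families(4)
        table = estimate_potentials(m0, fams)
        opts = ICMOptions(max_sweeps=30)
        first = icm_refine(g, m0, prior, classes, table, fams, opts)
        assert first.changed_fraction[-1] < opts.stop_fraction
        again = icm_refine(g, first.labels, prior, classes, table, fams, opts)
        assert again.changed_fraction[0] < opts.stop_fraction


class TestMajorityVote:
    def _maps(self, *grids):
        return [bs.LabelMap(np.asarray(v, dtype=np.int16).reshape(1, 1, -1)) for v in grids]

    def test_identical_candidates(self):
        maps = self._maps([1, 2, 3], [1, 2, 3], [1, 2, 3])
        assert np.array_equal(majority_vote(maps).values, maps[0].values)

    def test_two_against_one(self):
        maps = self._maps([1], [1], [2])
        assert majority_vote(maps).values[0, 0, 0] == 1

    def test_three_way_tie_goes_to_best_rank(self):
        maps = self._maps([2], [1], [3])
        assert majority_vote(maps).values[0, 0, 0] == 2
        assert majority_vote(maps, ranks=[1, 0, 2]).values[0, 0, 0] == 1

    def test_never_invents_labels(self, rng):
        maps = [
            bs.LabelMap(rng.integers(0, 4, (4, 4, 4)).astype(np.int16))
            for _ in range(3)
        ]
        fused = majority_vote(maps)
        stack = np.stack([m.values for m in maps])
        assert np.all((fused.values[None] == stack).any(axis=0))

    def test_lattice_mismatch_rejected(self):
        a = bs.LabelMap(np.zeros((2, 2, 2), dtype=np.int16))
        b = bs.LabelMap(np.zeros((3, 3, 3), dtype=np.int16))
        with pytest.raises(bs.volume_io.VolumeError):
            majority_vote([a, b])


class TestPipeline:
    def test_self_segmentation_is_exact(self):
        # 48^3 keeps every shell boundary's curvature radius above the scale
        # where the Gibbs smoothing term can override unanimous data evidence
        spec = bs.PhantomSpec(
            grid_shape=(48, 48, 48),
            class_intensity={1: (60.0, 0.0), 2: (110.0, 0.0), 3: (170.0, 0.0)},
            seed=0,
        )
        pair = bs.generate_phantom(spec)
        params = bs.SegmenterParams(k_prototypes=1)
        fused = bs.segment_subject(pair.grey, [pair], params)
        for lab in (1, 2, 3):
            assert bs.dsc(fused, pair.labels, lab) == 1.0

    def test_noisy_pipeline_beats_095(self, training_small):
        spec = bs.adult_spec(grid_shape=(32, 32, 32), seed=21)
        test = bs.generate_test_subject(spec)
        params = bs.SegmenterParams(k_prototypes=2)
        fused = bs.segment_subject(test.grey, training_small, params)
        for lab in (1, 2, 3):
            assert bs.dsc(fused, test.labels, lab) >= 0.95

    def test_stage_context_in_errors(self, adult_small):
        bad = bs.Volume(np.zeros((8, 8, 8), dtype=np.int16))  # no brain at all
        with pytest.raises(Exception) as exc:
            bs.segment_with_prototype(bad, [adult_small], adult_small)
        assert "stage" in str(exc.value)

    def test_pipeline_deterministic(self, training_small):
        spec = bs.adult_spec(grid_shape=(32, 32, 32), seed=21)
        test = bs.generate_test_subject(spec)
        params = bs.SegmenterParams(k_prototypes=1)
        a = bs.segment_subject(test.grey, training_small[:3], params)
        b = bs.segment_subject(test.grey, training_small[:3], params)
        assert np.array_equal(a.values, b.values)
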