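"""MGRF clique statistics, analytic potentials, and energies vs brute force.

The oracle enumerates every clique with plain nested loops, independently of
the vectorized counting code.
"""

from fractions import Fraction

import numpy as np
import pytest

import brainseg as bs
from brainseg.mgrf import (
    DIRECTIONS_13,
    MGRFError,
    PotentialTable,
    clique_count,
    config_frequencies,
    enumerate_families,
    estimate_potentials,
    local_energy,
    total_energy,
    pack_for_kernel,
)
from tests.conftest import random_labelmap


# ---------------------------------------------------------------- oracle ----

def brute_force_cliques(vals, family, brain_only=True):
    """Yield the label tuple of every in-bounds clique of a family."""
    X, Y, Z = vals.shape
    for shape in family.shapes:
        offsets = [(0, 0, 0), *shape]
        for x in range(X):
            for y in range(Y):
                for z in range(Z):
                    members = [(x + o[0], y + o[1], z + o[2]) for o in offsets]
                    if not all(
                        0 <= m[i] < vals.shape[i] for m in members for i in range(3)
                    ):
                        continue
                    labels = tuple(int(vals[m]) for m in members)
                    if brain_only and 0 in labels:
                        continue
                    yield labels


def brute_force_class_counts(vals, family, brain_only=True):
    counts = np.zeros(3 if family.order == 4 else 2, dtype=np.int64)
    for labels in brute_force_cliques(vals, family, brain_only):
        if family.order == 2:
            counts[0 if labels[0] == labels[1] else 1] += 1
        elif family.order == 3:
            counts[0 if labels[0] == labels[1] == labels[2] else 1] += 1
        else:
            npairs = sum(
                labels[i] == labels[j] for i in range(4) for j in range(i + 1, 4)
            )
            counts[{6: 0, 3: 1}.get(npairs, 2)] += 1
    return counts


def brute_force_total_energy(m, table, families, brain_only=True):
    e = 0.0
    for fam in families:
        c = brute_force_class_counts(m.values, fam, brain_only)
        if fam.order == 2:
            e += (c[0] - c[1]) * table.v2[fam.id]
        elif fam.order == 3:
            e += (c[0] - c[1]) * table.v3[fam.id]
        else:
            e += float(np.dot(c, table.v4[fam.id]))
    return e


# ----------------------------------------------------------------- tests ----

class TestEnumerateFamilies:
    def test_family_census(self):
        fams = enumerate_families(4)
        by_order = {o: [f for f in fams if f.order == o] for o in (2, 3, 4)}
        assert len(fams) == 19
        assert (len(by_order[2]), len(by_order[3]), len(by_order[4])) == (3, 13, 3)
        # pairwise families pool 3 + 6 + 4 undirected offset classes
        assert [len(f.shapes) for f in by_order[2]] == [3, 6, 4]

    def test_second_order_only(self):
        assert len(enumerate_families(2)) == 3

    def test_axis_pair_clique_count(self):
        fams = enumerate_families(2)
        d1 = next(f for f in fams if f.id == "pair_d1")
        X, Y, Z = 5, 6, 7
        # each axis contributes (n_axis - 1) * (product of the others)
        expected = (X - 1) * Y * Z + X * (Y - 1) * Z + X * Y * (Z - 1)
        assert clique_count(d1, (X, Y, Z)) == expected

    def test_counts_match_brute_force_on_4cube(self):
        vals = np.ones((4, 4, 4), dtype=np.int16)
        for fam in enumerate_families(4):
            expected = sum(1 for _ in brute_force_cliques(vals, fam))
            assert clique_count(fam, (4, 4, 4)) == expected, fam.id


class TestConfigFrequencies:
    def test_constant_map_all_equal(self):
        m = bs.LabelMap(np.full((6, 6, 6), 2, dtype=np.int16))
        fr = config_frequencies(m, enumerate_families(4))
        for fid, f in fr.freqs.items():
            assert f[0] == pytest.approx(1.0)
            assert f[1:].sum() == pytest.approx(0.0)

    def test_striped_map_axis_family(self):
        vals = np.zeros((6, 6, 6), dtype=np.int16)
        vals[::2] = 1
        vals[1::2] = 2
        m = bs.LabelMap(vals)
        fams = [f for f in enumerate_families(2) if f.id == "pair_d1"]
        # restrict to the x-direction shape only: every x-pair alternates
        x_only = [
            bs.CliqueFamily("x", 2, (((1, 0, 0),),), "axis x")
        ]
        fr = config_frequencies(m, x_only)
        assert fr.freqs["x"][0] == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_random_maps(self, seed):
        m = random_labelmap((5, 5, 5), seed=seed, background=(seed % 2 == 0))
        fams = enumerate_families(4)
        fr = config_frequencies(m, fams, brain_only=True)
        for fam in fams:
            expected = brute_force_class_counts(m.values, fam, brain_only=True)
            total = expected.sum()
            assert total == fr.counts[fam.id]
            assert np.allclose(fr.freqs[fam.id], expected / total, atol=1e-12)

    def test_zero_clique_family_rejected(self):
        m = bs.LabelMap(np.zeros((4, 4, 4), dtype=np.int16))  # all background
        with pytest.raises(MGRFError, match="zero in-bounds"):
            config_frequencies(m, enumerate_families(2))


class TestEstimatePotentials:
    def test_reference_frequency_gives_zero_potential(self):
        # period-2 double stripes along the last axis, length 9: the 8
        # adjacent pairs alternate eq/ne exactly, so F_eq = 1/2 and V2 = 0
        pattern = np.array([1, 1, 2, 2, 1, 1, 2, 2, 1], dtype=np.int16)
        stripes = np.broadcast_to(pattern, (4, 8, 9)).copy()
        x_only = [bs.CliqueFamily("x", 2, (((0, 0, 1),),), "")]
        m = bs.LabelMap(stripes)
        assert config_frequencies(m, x_only).freqs["x"][0] == pytest.approx(0.5)
        table = estimate_potentials(m, x_only)
        assert table.v2["x"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_map_closed_forms(self):
        m = bs.LabelMap(np.full((6, 6, 6), 3, dtype=np.int16))
        table = estimate_potentials(m, enumerate_families(4))
        for v in table.v2.values():
            assert v == pytest.approx(2.0, abs=1e-12)
        for v in table.v3.values():
            assert v == pytest.approx(4.0, abs=1e-12)
        # independent high-precision evaluation of the lambda* ratio at
        # (F_eq4, F_eq3, F_eq2) = (1, 0, 0), exact rational arithmetic
        num = (Fraction(7, 8) ** 2 + Fraction(1, 2) ** 2 + Fraction(3, 8) ** 2)
        den = (
            Fraction(7, 64) * Fraction(7, 8) ** 2
            + Fraction(1, 4) * Fraction(1, 2) ** 2
            + Fraction(15, 64) * Fraction(3, 8) ** 2
        )
        lam = num / den
        assert lam == Fraction(37, 32) / Fraction(367, 2048)
        assert table.lambda_star == pytest.approx(float(lam), abs=1e-12)
        for v4 in table.v4.values():
            assert v4[0] == pytest.approx(float(lam * Fraction(7, 8)), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_antisymmetry_identities(self, seed):
        m = random_labelmap((6, 6, 6), seed=100 + seed)
        table = estimate_potentials(m, enumerate_families(4))
        fr = config_frequencies(m, enumerate_families(4))
        for fid, v in table.v2.items():
            assert v == pytest.approx(-(-v), abs=1e-9)  # V2:ne = -V2:eq by construction
            assert v == pytest.approx(4 * (fr.freqs[fid][0] - 0.5), abs=1e-9)
        for fid, v in table.v3.items():
            assert v == pytest.approx((16 / 3) * (fr.freqs[fid][0] - 0.25), abs=1e-9)
        for fid, v4 in table.v4.items():
            assert v4[2] == pytest.approx(-(v4[0] + v4[1]), abs=1e-9)

    def test_degenerate_quad_statistics_zero_lambda(self):
        # two labels arranged so every quad family hits its reference freqs is
        # practically impossible; exercise the guard directly instead
        fams = enumerate_families(4)
        table = PotentialTable.zeros(fams)
        assert table.lambda_star == 0.0
        assert all(v == (0.0, 0.0, 0.0) for v in table.v4.values())

    def test_uniform_random_maps_concentrate_near_zero(self):
        # for i.i.d. uniform 2-label maps E[F_eq] = 1/2 so E[V2] = 0
        vals = []
        fams = [f for f in enumerate_families(2) if f.id == "pair_d1"]
        for seed in range(50):
            m = random_labelmap((8, 8, 8), n_labels=2, seed=500 + seed)
            vals.append(estimate_potentials(m, fams).v2["pair_d1"])
        assert abs(np.mean(vals)) < 0.05


class TestEnergies:
    def test_single_voxel_lattice_no_cliques(self):
        m = bs.LabelMap(np.full((1, 1, 1), 2, dtype=np.int16))
        fams = enumerate_families(4)
        table = PotentialTable.zeros(fams)
        for lab in (1, 2, 3):
            assert local_energy(m, (0, 0, 0), lab, table, fams) == 0.0

    def test_out_of_lattice_voxel_rejected(self):
        m = bs.LabelMap(np.full((3, 3, 3), 2, dtype=np.int16))
        fams = enumerate_families(2)
        with pytest.raises(MGRFError, match="outside"):
            local_energy(m, (5, 0, 0), 1, PotentialTable.zeros(fams), fams)

    @pytest.mark.parametrize("seed", range(4))
    def test_local_energy_matches_brute_force_delta(self, seed):
        """Flipping one voxel changes total energy by the local energy difference."""
        m = random_labelmap((5, 5, 5), seed=seed)
        fams = enumerate_families(4)
        table = estimate_potentials(m, fams)
        p = (2, 3, 1)
        old = int(m.values[p])
        new = 1 + (old % 3)
        e_old = brute_force_total_energy(m, table, fams)
        flipped = m.copy()
        flipped.values[p] = new
        e_new = brute_force_total_energy(flipped, table, fams)
        delta_local = local_energy(m, p, new, table, fams) - local_energy(
            m, p, old, table, fams
        )
        assert delta_local == pytest.approx(e_new - e_old, abs=1e-9)

    def test_relabel_permutation_invariance(self):
        m = random_labelmap((5, 5, 5), seed=9)
        fams = enumerate_families(4)
        table = estimate_potentials(m, fams)
        p = (2, 2, 2)
        e = local_energy(m, p, int(m.values[p]), table, fams)
        # swap labels 1 <-> 2 everywhere: equality patterns are unchanged
        swapped = m.values.copy()
        swapped[m.values == 1] = 2
        swapped[m.values == 2] = 1
        ms = bs.LabelMap(swapped)
        lab = int(ms.values[p])
        assert local_energy(ms, p, lab, table, fams) == pytest.approx(e, abs=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_total_energy_matches_brute_force(self, seed):
        m = random_labelmap((5, 5, 5), seed=40 + seed, background=True)
        fams = enumerate_families(4)
        table = estimate_potentials(random_labelmap((5, 5, 5), seed=1), fams)
        assert total_energy(m, table, fams) == pytest.approx(
            brute_force_total_energy(m, table, fams), abs=1e-9
        )

    def test_constant_map_energy_is_count_weighted_sum(self):
        m = bs.LabelMap(np.full((8, 8, 8), 1, dtype=np.int16))
        fams = enumerate_families(4)
        table = estimate_potentials(m, fams)
        expected = 0.0
        for fam in fams:
            n = clique_count(fam, (8, 8, 8))
            if fam.order == 2:
                expected += n * table.v2[fam.id]
            elif fam.order == 3:
                expected += n * table.v3[fam.id]
            else:
                expected += n * table.v4[fam.id][0]
        assert total_energy(m, table, fams) == pytest.approx(expected, abs=1e-9)


class TestKernelConsistency:
    def test_kernel_gibbs_matches_local_energy(self):
        from brainseg._kernels import _gibbs_local

        m = random_labelmap((6, 6, 6), seed=17, background=True)
        fams = enumerate_families(4)
        table = estimate_potentials(m, fams)
        packed = pack_for_kernel(table, fams)
        mv = m.values.astype(np.int64)
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = tuple(int(v) for v in rng.integers(0, 6, 3))
            lab = int(rng.integers(1, 4))
            expected = local_energy(m, p, lab, table, fams)
            got = _gibbs_local(mv, *p, lab, *packed)
            assert got == pytest.approx(expected, abs=1e-9)
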