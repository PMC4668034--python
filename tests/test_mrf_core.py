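"""MRF energy assembly, min s-t cut and alpha-expansion minimisation."""

import numpy as np
import pytest
from scipy.sparse import csr_matrix

from mrfseg import (EntropyStack, LabelMap, PairwiseParams, UnaryField,
                    VoxelSpacing, alpha_expansion, min_st_cut,
                    neighbour_offsets_4, neighbour_offsets_6, pairwise_weight,
                    set_lambdas, total_energy)
from mrfseg.mrf_core import EnergyModel, _shift_pair
from tests._oracles import energy_oracle, min_cut_oracle

SPACING = VoxelSpacing(10.0, 0.5, 0.5)


def random_model(rng, shape=(2, 2, 2), lam=(0.5, 2.0), beta=0.1,
                 anisotropy=2.0):
    u = rng.uniform(0, 3, size=shape + (3,))
    obs = rng.uniform(0, 6, size=shape + (1,))
    params = PairwiseParams(lam[0], lam[1], beta,
                            neighbour_offsets_6(anisotropy))
    sp = VoxelSpacing(anisotropy, 1.0, 1.0)
    return EnergyModel(UnaryField(u), params, EntropyStack(obs, 9, sp))


class TestSetLambdas:
    def test_constant_field(self):
        u = UnaryField(np.full((1, 2, 2, 3), 4.2))
        assert set_lambdas(u) == (pytest.approx(4.2), pytest.approx(0.0))

    def test_known_range(self):
        u = np.full((1, 2, 2, 3), 2.0)
        u[0, 0, 0, 1] = 5.0
        assert set_lambdas(UnaryField(u)) == (2.0, 3.0)

    def test_matches_full_scan(self, rng):
        u = rng.normal(size=(3, 4, 4, 3))
        lam0, lam1 = set_lambdas(UnaryField(u))
        lo = min(u[z, y, x, l] for z in range(3) for y in range(4)
                 for x in range(4) for l in range(3))
        hi = max(u[z, y, x, l] for z in range(3) for y in range(4)
                 for x in range(4) for l in range(3))
        assert lam0 == lo and lam1 == hi - lo


class TestPairwiseWeight:
    PARAMS = PairwiseParams(0.5, 2.0, 0.1, neighbour_offsets_6(20.0))

    def test_identical_observations(self):
        w = pairwise_weight(np.array([1.0, 2.0]), np.array([1.0, 2.0]), 1.0,
                            self.PARAMS)
        assert w == pytest.approx(0.5 + 2.0)

    def test_infinite_contrast_limit(self):
        w = pairwise_weight(np.array([0.0]), np.array([1e6]), 1.0, self.PARAMS)
        assert w == pytest.approx(0.5)

    def test_between_slice_weight_is_scaled_by_anisotropy(self):
        z = np.array([1.5, 2.5])
        in_plane = pairwise_weight(z, z, 1.0, self.PARAMS)
        between = pairwise_weight(z, z, 20.0, self.PARAMS)
        assert between == pytest.approx(in_plane / 20.0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            pairwise_weight(np.array([1.0]), np.array([1.0]), 0.0, self.PARAMS)


class TestTotalEnergy:
    def test_zero_lambdas_reduce_to_unary_sum(self, rng):
        model = random_model(rng, lam=(0.0, 0.0))
        labels = rng.integers(0, 3, size=(2, 2, 2))
        lm = LabelMap(labels, model.observations.spacing)
        expected = sum(model.unary.u[z, y, x, labels[z, y, x]]
                       for z in range(2) for y in range(2) for x in range(2))
        assert total_energy(lm, model) == pytest.approx(expected)

    def test_uniform_labelling_has_no_pairwise_cost(self, rng):
        model = random_model(rng)
        lm = LabelMap(np.full((2, 2, 2), 1), model.observations.spacing)
        assert total_energy(lm, model) == pytest.approx(
            model.unary.u[..., 1].sum())

    def test_matches_term_enumeration_oracle(self, rng):
        for _ in range(5):
            model = random_model(rng, shape=(3, 3, 3))
            labels = rng.integers(0, 3, size=(3, 3, 3))
            lm = LabelMap(labels, model.observations.spacing)

            def weight(i, j, dist):
                return pairwise_weight(model.observations.values[i],
                                       model.observations.values[j], dist,
                                       model.params)

            expected = energy_oracle(labels, model.unary.u,
                                     model.params.neighbour_offsets, weight)
            assert total_energy(lm, model) == pytest.approx(expected,
                                                            abs=1e-9)


class TestMinStCut:
    def test_single_edge(self):
        g = csr_matrix((np.array([5.0]), (np.array([0]), np.array([1]))),
                       shape=(2, 2))
        value, side = min_st_cut(g, 0, 1)
        assert value == pytest.approx(5.0)
        assert side[0] and not side[1]

    def test_disconnected_terminals_zero_cut(self):
        g = csr_matrix((3, 3))
        value, side = min_st_cut(g, 0, 2)
        assert value == 0.0

    def test_random_graphs_match_partition_oracle(self, rng):
        for _ in range(10):
            n = 8
            dense = rng.uniform(0, 5, size=(n, n)) * (rng.random((n, n)) < 0.5)
            np.fill_diagonal(dense, 0.0)
            value, side = min_st_cut(csr_matrix(dense), 0, n - 1)
            expected = min_cut_oracle(dense, 0, n - 1)
            assert value == pytest.approx(expected, abs=1e-6)
            # the returned partition achieves the reported value
            achieved = dense[np.ix_(side, ~side)].sum()
            assert achieved == pytest.approx(value, abs=1e-6)

    def test_negative_capacity_rejected(self):
        g = csr_matrix((np.array([-1.0]), (np.array([0]), np.array([1]))),
                       shape=(2, 2))
        with pytest.raises(ValueError):
            min_st_cut(g, 0, 1)


class TestAlphaExpansion:
    def test_zero_lambdas_give_argmin_unary(self, rng):
        model = random_model(rng, shape=(3, 4, 4), lam=(0.0, 0.0))
        out = alpha_expansion(model)
        np.testing.assert_array_equal(out.labels,
                                      np.argmin(model.unary.u, axis=-1))

    def test_huge_smoothness_gives_constant_labelling(self, rng):
        u = np.zeros((2, 4, 4, 3))
        majority = rng.integers(0, 3, size=(2, 4, 4))
        majority[:, :3, :] = 1            # >50% of voxels prefer label 1
        for lab in range(3):
            u[..., lab] = np.where(majority == lab, 0.0, 1.0)
        obs = np.zeros((2, 4, 4, 1))
        params = PairwiseParams(1000.0, 0.0, 0.1, neighbour_offsets_6(2.0))
        model = EnergyModel(UnaryField(u), params,
                            EntropyStack(obs, 9, VoxelSpacing(2, 1, 1)))
        out = alpha_expansion(model)
        assert np.unique(out.labels).size == 1

    def test_energy_never_increases_from_init(self, rng):
        for _ in range(5):
            model = random_model(rng, shape=(3, 3, 3))
            init = LabelMap(rng.integers(0, 3, size=(3, 3, 3)),
                            model.observations.spacing)
            out = alpha_expansion(model, init=init)
            assert total_energy(out, model) <= total_energy(init, model) + 1e-9

    def test_output_is_expansion_local_optimum(self, rng):
        # the guaranteed contract: no single expansion move improves
        import itertools
        model = random_model(rng)
        out = alpha_expansion(model)
        x = out.labels.ravel()
        e_out = total_energy(out, model)
        sp = model.observations.spacing
        for alpha in range(3):
            for bits in itertools.product([0, 1], repeat=8):
                y = np.where(np.array(bits) == 1, alpha, x).astype(np.uint8)
                e = total_energy(LabelMap(y.reshape(2, 2, 2), sp), model)
                assert e >= e_out - 1e-9

    def test_within_factor_two_of_global_minimum(self, rng):
        import itertools
        labellings = np.array(list(itertools.product(range(3), repeat=8)))
        for _ in range(5):
            model = random_model(rng)
            uf = model.unary.u.reshape(8, 3)
            e = uf[np.arange(8)[None, :], labellings].sum(axis=1)
            idx = np.arange(8).reshape(2, 2, 2)
            for off, dist in model.params.neighbour_offsets:
                w = model.edge_weights(off, dist)
                ii, jj = _shift_pair(idx, off)
                for a, b, wv in zip(ii.ravel(), jj.ravel(), w.ravel()):
                    e = e + wv * (labellings[:, a] != labellings[:, b])
            out = alpha_expansion(model)
            assert total_energy(out, model) <= 2.0 * float(e.min()) + 1e-9

    def test_four_neighbour_mode_ignores_z(self, rng):
        u = rng.uniform(0, 3, size=(2, 4, 4, 3))
        obs = rng.uniform(0, 6, size=(2, 4, 4, 1))
        params = PairwiseParams(0.5, 1.0, 0.1, neighbour_offsets_4())
        model = EnergyModel(UnaryField(u), params,
                            EntropyStack(obs, 9, SPACING))
        out = alpha_expansion(model)
        # slices are independent: solving each slice alone gives the same result
        for z in range(2):
            mz = EnergyModel(UnaryField(u[z:z + 1]), params,
                             EntropyStack(obs[z:z + 1], 9, SPACING))
            out_z = alpha_expansion(mz)
            np.testing.assert_array_equal(out.labels[z], out_z.labels[0])
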