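"""Unit and property tests for the ring Moran model and its exact chain."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptdrift import DriftParams, ParameterError, fixation_probability, simulate_crypt
from cryptdrift.drift_core import (
    ChainPropagator,
    build_clonal_chain,
    clone_size_distribution,
)


def single_cell_labels(n, pos=0):
    labels = np.zeros(n, dtype=np.int64)
    labels[pos] = 1
    return labels


class TestDriftParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"n_stem": 1, "replacement_rate": 0.1},
            {"n_stem": 8, "replacement_rate": 0.0},
            {"n_stem": 8, "replacement_rate": -1.0},
            {"n_stem": 8, "replacement_rate": 0.1, "bias": 1.5},
            {"n_stem": 8, "replacement_rate": 0.1, "border_loss_rate": -0.2},
        ],
    )
    def test_invalid_parameters_are_named(self, kw):
        with pytest.raises(ParameterError):
            DriftParams(**kw)


class TestClonalChain:
    def test_two_cell_ring_is_symmetric_coin_flip(self):
        chain = build_clonal_chain(DriftParams(n_stem=2, replacement_rate=1.0))
        jump = chain.jump_matrix()
        assert jump[1, 0] == pytest.approx(0.5)
        assert jump[1, 2] == pytest.approx(0.5)

    @pytest.mark.parametrize("bias", [0.3, 0.5, 0.8])
    def test_jump_matrix_rows_normalised(self, bias):
        chain = build_clonal_chain(
            DriftParams(n_stem=6, replacement_rate=0.4, bias=bias)
        )
        np.testing.assert_allclose(chain.jump_matrix().sum(axis=1), 1.0)

    def test_long_time_fixation_mass_matches_martingale(self):
        # independent oracle: repeated squaring of the embedded jump chain
        chain = build_clonal_chain(DriftParams(n_stem=5, replacement_rate=1.0))
        jump = chain.jump_matrix()
        power = jump.copy()
        for _ in range(40):
            power = power @ power
        assert power[1, 5] == pytest.approx(1 / 5, abs=1e-12)

    def test_boundary_resolution_rate_convention(self):
        # each of the clone's two boundaries resolves at rate lambda
        chain = build_clonal_chain(
            DriftParams(n_stem=8, replacement_rate=0.3, bias=0.7)
        )
        assert chain.rate_up == pytest.approx(2 * 0.3 * 0.7)
        assert chain.rate_down == pytest.approx(2 * 0.3 * 0.3)


class TestCloneSizeDistribution:
    def test_time_zero_is_point_mass(self, neutral_params):
        chain = build_clonal_chain(neutral_params)
        dist = clone_size_distribution(chain, 3, 0.0)
        assert dist[3] == 1.0 and dist.sum() == 1.0

    @pytest.mark.parametrize("t", [0.5, 3.0, 50.0])
    def test_conservation(self, neutral_params, t):
        chain = build_clonal_chain(neutral_params)
        assert clone_size_distribution(chain, 1, t).sum() == pytest.approx(
            1.0, abs=1e-10
        )

    def test_short_time_matches_first_order_expansion(self):
        # N=4, n0=2: hand-computed one-event probabilities; stepping rate 2*lam
        lam, dt = 0.5, 1e-4
        chain = build_clonal_chain(DriftParams(n_stem=4, replacement_rate=lam))
        dist = clone_size_distribution(chain, 2, dt)
        assert dist[1] == pytest.approx(lam * dt, rel=1e-3)
        assert dist[3] == pytest.approx(lam * dt, rel=1e-3)
        assert dist[2] == pytest.approx(1 - 2 * lam * dt, rel=1e-6)

    def test_n0_out_of_range(self, neutral_params):
        chain = build_clonal_chain(neutral_params)
        with pytest.raises(ParameterError):
            clone_size_distribution(chain, 9, 1.0)

    def test_propagator_agrees_with_expm(self):
        chain = build_clonal_chain(
            DriftParams(n_stem=12, replacement_rate=0.7, bias=0.65)
        )
        prop = ChainPropagator(chain)
        for t in (0.3, 2.0, 15.0):
            p0 = np.zeros(13)
            p0[2] = 1.0
            np.testing.assert_allclose(
                prop.distribution(p0, t),
                clone_size_distribution(chain, 2, t),
                atol=1e-9,
            )


class TestSimulateCrypt:
    def test_monoclonal_start_is_constant(self, neutral_params):
        labels = np.ones(8, dtype=np.int64)
        traj = simulate_crypt(neutral_params, labels, [0.0, 5.0, 20.0], 3)
        assert (traj.labels == 1).all()
        assert traj.absorbed_time == 0.0

    def test_same_seed_is_bit_identical(self, neutral_params):
        labels = single_cell_labels(8)
        a = simulate_crypt(neutral_params, labels, [1.0, 4.0, 9.0], 42)
        b = simulate_crypt(neutral_params, labels, [1.0, 4.0, 9.0], 42)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.events == b.events and a.absorbed_time == b.absorbed_time

    def test_no_label_creation_and_constant_ring(self, neutral_params, rng):
        labels = np.array([0, 1, 1, 2, 0, 3, 0, 0])
        traj = simulate_crypt(neutral_params, labels, [0.0, 2.0, 6.0], rng)
        assert traj.labels.shape[1] == 8
        for row in traj.labels:
            assert set(row).issubset(set(labels))

    def test_empirical_fixation_fraction_one_eighth(self, neutral_params):
        n_rep, fixed = 10_000, 0
        for c in range(n_rep):
            traj = simulate_crypt(
                neutral_params,
                single_cell_labels(8),
                [400.0],
                np.random.default_rng((99, c)),
            )
            fixed += traj.labels[-1, 0] == 1
        se = np.sqrt(0.125 * 0.875 / n_rep)
        assert abs(fixed / n_rep - 0.125) < 3 * se

    def test_input_validation(self, neutral_params):
        with pytest.raises(ParameterError):
            simulate_crypt(neutral_params, np.zeros(5, dtype=int), [1.0], 0)
        with pytest.raises(ParameterError):
            simulate_crypt(neutral_params, np.zeros(8, dtype=int), [], 0)
        with pytest.raises(ParameterError):
            simulate_crypt(neutral_params, np.zeros(8, dtype=int), [3.0, 1.0], 0)

    def test_martingale_mean_clone_size(self, neutral_params):
        # unconditional mean clone size stays at n0 = 1 (neutral drift)
        n_rep = 10_000
        for t in (2.0, 5.0, 10.0):
            sizes = np.empty(n_rep)
            for c in range(n_rep):
                traj = simulate_crypt(
                    neutral_params,
                    single_cell_labels(8, pos=2),
                    [t],
                    np.random.default_rng((7, int(t * 10), c)),
                )
                sizes[c] = (traj.labels[-1] == 1).sum()
            se = sizes.std(ddof=1) / np.sqrt(n_rep)
            assert abs(sizes.mean() - 1.0) < 3 * se

    def test_fraction_fixed_non_increasing_in_n(self):
        # common random numbers across pool sizes at fixed lambda and t
        frac = []
        for n in (4, 8, 16):
            params = DriftParams(n_stem=n, replacement_rate=0.5)
            fixed = sum(
                simulate_crypt(
                    params,
                    single_cell_labels(n),
                    [15.0],
                    np.random.default_rng((17, c)),
                ).labels[-1, 0]
                == 1
                for c in range(3000)
            )
            frac.append(fixed / 3000)
        assert frac[0] >= frac[1] >= frac[2]


class TestFixationProbability:
    def test_certain_and_trivial_cases(self):
        assert fixation_probability(8, 8) == 1.0
        assert fixation_probability(8, 0) == 0.0
        assert fixation_probability(8, 1) == pytest.approx(0.125)

    def test_gamblers_ruin_closed_form(self):
        # bias 2/3 -> rho = 1/2; cross-checked against chain absorption below
        assert fixation_probability(5, 1, bias=2 / 3) == pytest.approx(
            0.5 / (1 - 0.5**5)
        )

    def test_against_brute_force_chain_absorption(self):
        # independent oracle: solve the absorption linear system of the jump chain
        n, bias = 5, 2 / 3
        chain = build_clonal_chain(
            DriftParams(n_stem=n, replacement_rate=1.0, bias=bias)
        )
        jump = chain.jump_matrix()
        interior = np.arange(1, n)
        a = np.eye(n - 1) - jump[np.ix_(interior, interior)]
        b = jump[interior, n]
        absorb = np.linalg.solve(a, b)
        for n0 in interior:
            assert fixation_probability(n, n0, bias) == pytest.approx(
                absorb[n0 - 1], abs=1e-12
            )

    @given(st.floats(0.01, 0.99), st.integers(2, 30))
    @settings(max_examples=60, deadline=None)
    def test_bounded_and_continuous_near_neutral(self, bias, n):
        p = fixation_probability(n, 1, bias)
        assert 0.0 <= p <= 1.0
        near = fixation_probability(n, 1, 0.5 + 1e-10)
        assert near == pytest.approx(1 / n, rel=1e-6)

    @given(st.integers(3, 20))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_in_bias(self, n):
        probs = [fixation_probability(n, 1, b) for b in (0.4, 0.5, 0.6, 0.75)]
        assert all(a < b for a, b in zip(probs, probs[1:]))
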