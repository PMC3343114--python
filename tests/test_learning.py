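"""Perceptron learning rule: updates, convergence, and the certified rate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqcap._kernels import sweep_chunk, sweep_chunk_py
from seqcap.dynamics import NeuronConfig, constraint_margins
from seqcap.learning import LearnerConfig, apply_update, safe_learning_rate, train, updates_bound
from seqcap.markov import AssociationSequence, MarkovSpec, generate_associations
from seqcap.oracle import feasible


class TestApplyUpdate:
    def test_no_error_no_change(self):
        w = np.array([0.1, 0.2])
        np.testing.assert_array_equal(apply_update(w, np.array([1, 1]), 1, 1, 0.5), w)

    def test_ltd_clips_at_zero(self):
        w = apply_update(np.array([0.1]), np.array([1]), y=1, y_t=0, eta=0.5)
        assert w[0] == 0.0

    def test_ltp_from_zero(self):
        w = apply_update(np.array([0.0]), np.array([1]), y=0, y_t=1, eta=0.5)
        assert w[0] == 0.5

    def test_inactive_inputs_untouched(self):
        w = apply_update(np.array([0.1, 0.3]), np.array([0, 1]), y=0, y_t=1, eta=0.5)
        np.testing.assert_allclose(w, [0.1, 0.8])

    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.integers(0, 1), st.floats(0.01, 1.0)),
            min_size=1, max_size=50,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_nonnegativity_under_any_update_stream(self, steps):
        rng = np.random.default_rng(0)
        w = np.zeros(5)
        for y, y_t, eta in steps:
            x = rng.integers(0, 2, size=5)
            w = apply_update(w, x, y, y_t, eta)
            assert (w >= 0).all()


def _feasible_instance(seed, N=20, P=12, delta=0.0):
    neuron = NeuronConfig(N=N, theta=1.0, delta=delta)
    seq = generate_associations(MarkovSpec(0.5, 0.0), MarkovSpec(0.5, 0.2), N=N, P=P, seed=seed)
    ok, witness = feasible(seq, neuron)
    return (seq, neuron, witness) if ok else None


class TestTrain:
    def test_single_pattern_converges(self, small_neuron):
        seq = AssociationSequence(
            inputs=np.ones((1, 20), dtype=np.int8), targets=np.ones(1, dtype=np.int8),
            input_spec=MarkovSpec(0.5, 0), output_spec=MarkovSpec(0.5, 0), seed=0,
        )
        r = train(seq, small_neuron, LearnerConfig(seed=1, max_epochs=200))
        assert r.converged
        assert r.weights.sum() > small_neuron.theta

    def test_contradictory_patterns_never_converge(self, small_neuron):
        x = np.ones((2, 20), dtype=np.int8)
        seq = AssociationSequence(
            inputs=x, targets=np.array([1, 0], dtype=np.int8),
            input_spec=MarkovSpec(0.5, 0), output_spec=MarkovSpec(0.5, 0), seed=0,
        )
        r = train(seq, small_neuron, LearnerConfig(seed=1, max_epochs=50))
        assert not r.converged and r.final_errors > 0

    def test_convergence_certificate(self, small_neuron):
        """Whenever train reports converged, every slack is strictly positive."""
        for seed in range(10):
            seq = generate_associations(
                MarkovSpec(0.5, 0.0), MarkovSpec(0.5, 0.0), N=20, P=10, seed=seed
            )
            r = train(seq, small_neuron, LearnerConfig(seed=seed, max_epochs=2000))
            if r.converged:
                assert (constraint_margins(r.weights, seq, small_neuron) > 0).all()
        assert (r.weights >= 0).all()

    def test_weights_stay_nonnegative_and_deterministic(self, small_neuron):
        seq = generate_associations(MarkovSpec(0.5, 0), MarkovSpec(0.5, 0), N=20, P=15, seed=3)
        r1 = train(seq, small_neuron, LearnerConfig(seed=5, max_epochs=300))
        r2 = train(seq, small_neuron, LearnerConfig(seed=5, max_epochs=300))
        assert (r1.weights >= 0).all()
        np.testing.assert_array_equal(r1.weights, r2.weights)
        assert r1.updates == r2.updates

    def test_unconstrained_mode_allows_negative_weights(self):
        neuron = NeuronConfig(N=10, theta=1.0)
        seq = generate_associations(MarkovSpec(0.5, 0), MarkovSpec(0.5, 0), N=10, P=18, seed=11)
        r = train(seq, neuron, LearnerConfig(seed=2, max_epochs=3000, sign_constrained=False))
        if r.converged:
            assert (r.weights < 0).any()

    def test_bistable_switching_uses_previous_target(self):
        """With a large bistable range, an output sequence with few switches is
        learnable at loads where the standard unit fails."""
        neuron_b = NeuronConfig(N=30, theta=1.0, delta=0.8)
        seq = generate_associations(MarkovSpec(0.5, 0.0), MarkovSpec(0.5, 0.9), N=30, P=60, seed=4)
        r_b = train(seq, neuron_b, LearnerConfig(rule="bistable_switching", seed=1, max_epochs=4000))
        assert r_b.converged

    def test_nss_replay_defines_convergence(self):
        neuron = NeuronConfig(N=20, theta=1.0, delta=0.4)
        seq = generate_associations(MarkovSpec(0.5, 0.0), MarkovSpec(0.5, 0.5), N=20, P=10, seed=6)
        r = train(seq, neuron, LearnerConfig(rule="bistable_nss", seed=1, max_epochs=3000))
        if r.converged:
            # free replay from the down state must reproduce every target
            from seqcap.dynamics import output_bistable, output_standard

            h = seq.inputs @ r.weights
            state = output_standard(h[0], neuron)
            assert state == seq.targets[0]
            for mu in range(1, seq.n_patterns):
                state = output_bistable(h[mu], state, neuron)
                assert state == seq.targets[mu]

    def test_warm_start_resumes(self, small_neuron):
        seq = generate_associations(MarkovSpec(0.5, 0), MarkovSpec(0.5, 0), N=20, P=10, seed=9)
        r1 = train(seq, small_neuron, LearnerConfig(seed=1, max_epochs=500))
        r2 = train(seq, small_neuron, LearnerConfig(seed=2, max_epochs=5), w_init=r1.weights)
        assert r2.converged and r2.epochs == 1 and r2.updates == 0


class TestKernelEquivalence:
    def test_python_and_compiled_paths_agree(self):
        rng = np.random.default_rng(3)
        P, N = 12, 8
        Xf = rng.integers(0, 2, size=(P, N)).astype(np.float64)
        sign = np.where(rng.integers(0, 2, size=P) == 1, 1.0, -1.0)
        theta_eff = np.full(P, 1.0)
        constrained = np.ones(P, dtype=np.bool_)
        orders = rng.integers(0, P, size=(40, P)).astype(np.int64)
        # dyadic learning rate keeps every drive exactly representable, so the
        # compiled and interpreted paths cannot diverge through rounding ties
        for margin in (0.0, 0.3):
            w_a = np.zeros(N)
            w_b = np.zeros(N)
            out_a = sweep_chunk(Xf, sign, theta_eff, constrained, w_a, orders, 0.0625, margin, True)
            out_b = sweep_chunk_py(Xf, sign, theta_eff, constrained, w_b, orders, 0.0625, margin, True)
            assert out_a[0] == out_b[0] and out_a[1] == out_b[1]
            np.testing.assert_array_equal(out_a[2], out_b[2])
            np.testing.assert_allclose(w_a, w_b, rtol=0, atol=1e-12)


class TestSafeLearningRate:
    def test_positive_and_scales_inversely_with_n(self):
        eta1 = safe_learning_rate(NeuronConfig(N=100, theta=1.0), 0.2, 0.6)
        eta2 = safe_learning_rate(NeuronConfig(N=200, theta=1.0), 0.2, 0.6)
        assert eta1 > 0
        assert eta2 <= eta1 / 2 * 1.0001

    def test_requires_margin_above_bistable_range(self):
        with pytest.raises(ValueError):
            safe_learning_rate(NeuronConfig(N=50, theta=1.0, delta=0.3), 0.2, 0.5)

    def test_guaranteed_convergence_and_update_bound_on_feasible_instances(self):
        """On oracle-feasible instances, the certified rate always converges and
        the number of error-driven updates never exceeds the proof bound."""
        checked = 0
        seed = 0
        while checked < 25:
            inst = _feasible_instance(seed, N=20, P=15)
            seed += 1
            if inst is None:
                continue
            seq, neuron, witness = inst
            margin = float(np.min(constraint_margins(witness, seq, neuron)))
            if margin <= 1e-6:
                continue
            frac = float(seq.inputs.sum(axis=1).max()) / neuron.N
            eta = safe_learning_rate(neuron, margin, frac)
            bound = updates_bound(neuron, witness, margin, eta, frac)
            epochs = min(int(bound) + 2, 400_000)
            r = train(seq, neuron, LearnerConfig(eta=eta, seed=seed, max_epochs=epochs,
                                                 presentation="sequential"))
            assert r.converged, f"seed {seed - 1} did not converge"
            assert r.updates <= bound
            checked += 1
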