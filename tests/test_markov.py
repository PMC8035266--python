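import numpy as np
import pandas as pd
import pytest

from pneumotyper.core_io import SampleInfo, ValidationError
from pneumotyper.markov import (
    StateSequence,
    build_sequences,
    chain_properties,
    fit_markov,
    memorylessness_test,
    simulate_chain,
    time_homogeneity_test,
    transition_edge_list,
)


def _seq(pid, states, windows=None):
    windows = windows or list(range(1, len(states) + 1))
    return StateSequence(pid, list(zip(windows, states)))


class TestSimulateChain:
    def test_identity_matrix_is_absorbing(self):
        seq = simulate_chain(np.eye(3), [1, 0, 0], 5, seed=0)
        assert (seq == 0).all()

    def test_absorbing_row_traps_chain(self):
        P = np.array(
            [[0.5, 0.5, 0, 0], [0.25] * 4, [0, 0, 1, 0], [0.25] * 4]
        )
        seq = simulate_chain(P, [0, 0, 1, 0], 10, seed=1)
        assert (seq == 2).all()

    def test_empirical_frequencies_match_rows(self):
        P = np.array([[0.2, 0.8], [0.6, 0.4]])
        seq = simulate_chain(P, [0.5, 0.5], 100_000, seed=2)
        for s in (0, 1):
            nxt = seq[1:][seq[:-1] == s]
            freq = np.bincount(nxt, minlength=2) / len(nxt)
            assert np.abs(freq - P[s]).max() <= 0.01

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValidationError, match="stochastic"):
            simulate_chain(np.array([[0.5, 0.2], [0, 1]]), [1, 0], 3)

    def test_seed_reproducibility(self):
        P = np.full((3, 3), 1 / 3)
        a = simulate_chain(P, np.full(3, 1 / 3), 50, seed=9)
        b = simulate_chain(P, np.full(3, 1 / 3), 50, seed=9)
        assert (a == b).all()


class TestBuildSequences:
    def _info(self, rows):
        return [
            SampleInfo(sid, pid, months, time_window=w)
            for sid, pid, w, months in rows
        ]

    def test_pairing_rule(self):
        info = self._info(
            [("s1", "p1", 1, 1.0), ("s2", "p1", 2, 4.0), ("s3", "p1", 4, 14.0)]
        )
        labels = pd.Series({"s1": "A", "s2": "A", "s3": "B"})
        (seq,) = build_sequences(labels, info)
        assert seq.transitions() == [("A", "A"), ("A", "B")]

    def test_single_sample_patient_retained_without_transitions(self):
        info = self._info([("s1", "p1", 1, 1.0)])
        (seq,) = build_sequences(pd.Series({"s1": "A"}), info)
        assert seq.transitions() == []

    def test_tie_broken_by_sample_id_with_warning(self):
        info = self._info([("s2", "p1", 1, 1.0), ("s1", "p1", 1, 1.0)])
        with pytest.warns(UserWarning, match="tie"):
            (seq,) = build_sequences(pd.Series({"s1": "A", "s2": "B"}), info)
        assert seq.states() == ["A", "B"]

    def test_transition_count_identity(self, processed_cohort):
        truth = processed_cohort["truth"]
        info = processed_cohort["info"]
        labels = truth.labels.reindex([r.sample_id for r in info])
        seqs = build_sequences(labels, info)
        total = sum(len(s.transitions()) for s in seqs)
        per_patient = pd.Series([r.patient_id for r in info]).value_counts()
        assert total == int((per_patient - 1).sum())
        edges = transition_edge_list(seqs)
        assert edges["count"].sum() == total

    def test_new_graft_starts_new_sequence(self):
        info = [
            SampleInfo("s1", "p1", 1.0, time_window=1,
                       clinical_flags={"graft_id": "1"}),
            SampleInfo("s2", "p1", 5.0, time_window=2,
                       clinical_flags={"graft_id": "1"}),
            SampleInfo("s3", "p1", 2.0, time_window=1,
                       clinical_flags={"graft_id": "2"}),
        ]
        labels = pd.Series({"s1": "A", "s2": "B", "s3": "A"})
        seqs = build_sequences(labels, info)
        assert len(seqs) == 2
        assert sum(len(s.transitions()) for s in seqs) == 1


class TestFitMarkov:
    def test_hand_counted_alternating_sequence(self):
        seqs = [_seq("p1", list("ABABA"))]
        with pytest.warns(UserWarning):  # degenerate single-sequence bootstrap
            m = fit_markov(seqs, bootstrap_reps=10, seed=0)
        assert np.allclose(m.P, [[0, 1], [1, 0]])
        props = chain_properties(m.P)
        assert props.irreducible
        assert props.periods == [2]
        assert not props.aperiodic

    def test_absorbing_state_detected(self):
        seqs = [_seq("p1", list("ABBBB")), _seq("p2", list("ABBB"))]
        m = fit_markov(seqs, bootstrap_reps=10, seed=0)
        assert m.P[1, 1] == 1.0
        assert m.properties.absorbing_states == [1]

    def test_zero_outgoing_row_flagged(self):
        seqs = [_seq("p1", list("AAB")), _seq("p2", list("AAB"))]
        with pytest.warns(UserWarning, match="outgoing"):
            m = fit_markov(seqs, bootstrap_reps=10, seed=0)
        assert m.undefined_rows == ["B"]
        assert m.properties is None
        with pytest.raises(ValidationError, match="undefined"):
            chain_properties(m.P)

    def test_recurrence_equals_direct_self_transition_count(self, processed_cohort):
        truth = processed_cohort["truth"]
        info = processed_cohort["info"]
        labels = truth.labels.reindex([r.sample_id for r in info])
        seqs = build_sequences(labels, info)
        m = fit_markov(seqs, bootstrap_reps=10, seed=0)
        trans = [t for s in seqs for t in s.transitions()]
        for i, state in enumerate(m.states):
            outgoing = [t for t in trans if t[0] == state]
            selfs = sum(t[1] == state for t in outgoing)
            assert m.recurrence[state] == pytest.approx(selfs / len(outgoing))

    def test_refit_from_long_simulation_recovers_matrix(self):
        P = np.array([[0.6, 0.3, 0.1], [0.2, 0.5, 0.3], [0.3, 0.3, 0.4]])
        seq = simulate_chain(P, np.full(3, 1 / 3), 100_000, seed=4)
        states = ["a", "b", "c"]
        s = StateSequence("p", [(1, states[i]) for i in seq])
        with pytest.warns(UserWarning):
            m = fit_markov([s], bootstrap_reps=2, seed=0, states=states)
        assert np.abs(m.P - P).max() <= 0.01


class TestChainProperties:
    def test_identity_all_absorbing_reducible(self):
        props = chain_properties(np.eye(3))
        assert not props.irreducible
        assert props.absorbing_states == [0, 1, 2]
        assert len(props.classes) == 3
        assert len(props.recurrent_classes) == 3

    def test_uniform_matrix_stationary_uniform(self):
        props = chain_properties(np.full((4, 4), 0.25))
        assert props.irreducible and props.aperiodic
        assert np.allclose(props.stationary, 0.25, atol=1e-10)

    def test_block_diagonal_two_recurrent_classes(self):
        P = np.zeros((4, 4))
        P[:2, :2] = [[0.5, 0.5], [0.5, 0.5]]
        P[2:, 2:] = [[0.1, 0.9], [0.9, 0.1]]
        props = chain_properties(P)
        assert not props.irreducible
        assert sorted(map(sorted, props.recurrent_classes)) == [[0, 1], [2, 3]]

    def test_stationary_is_left_fixed_point(self, processed_cohort):
        truth = processed_cohort["truth"]
        props = chain_properties(truth.P_true)
        assert props.irreducible and props.aperiodic
        assert np.allclose(props.stationary @ truth.P_true, props.stationary,
                           atol=1e-9)


class TestChiSquareChecks:
    def test_memoryless_degenerate_single_state(self):
        res = memorylessness_test([_seq("p", list("AAAAA"))])
        assert res.note == "no variation in states"
        assert res.p_value == 1.0

    def test_second_order_process_detected(self):
        # next state equals the state two steps back: strongly non-Markov
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            seqs = []
            for p in range(100):
                states = [int(rng.integers(0, 2)), int(rng.integers(0, 2))]
                for _ in range(4):
                    states.append(states[-2])
                seqs.append(_seq(f"p{p}", [str(s) for s in states]))
            res = memorylessness_test(seqs)
            hits += res.p_value < 0.01
        assert hits >= 9

    def test_homogeneity_hand_table(self):
        # 2x2 table (10, 20 / 20, 10): chi2 = 20/3, df 1
        seqs = (
            [_seq(f"a{i}", ["A"], [1]) for i in range(10)]
            + [_seq(f"b{i}", ["A"], [2]) for i in range(20)]
            + [_seq(f"c{i}", ["B"], [1]) for i in range(20)]
            + [_seq(f"d{i}", ["B"], [2]) for i in range(10)]
        )
        res = time_homogeneity_test(seqs)
        assert res.statistic == pytest.approx(20 / 3, rel=1e-12)
        assert res.df == 1

    def test_identical_window_distribution_near_zero(self):
        seqs = []
        for w in (1, 2, 3):
            for i in range(10):
                seqs.append(_seq(f"p{w}{i}a", ["A"], [w]))
            for i in range(5):
                seqs.append(_seq(f"p{w}{i}b", ["B"], [w]))
        res = time_homogeneity_test(seqs)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_planted_drift_detected(self):
        rng = np.random.default_rng(0)
        seqs = []
        for i in range(500):
            w = int(rng.integers(1, 4))
            p_b = {1: 0.2, 2: 0.5, 3: 0.8}[w]
            state = "B" if rng.random() < p_b else "A"
            seqs.append(_seq(f"p{i}", [state], [w]))
        assert time_homogeneity_test(seqs).p_value < 0.01

    def test_single_window_rejected(self):
        with pytest.raises(ValidationError):
            time_homogeneity_test([_seq("p", ["A", "B"], [1, 1])])


class TestEstimatorConsistency:
    def test_error_shrinks_with_sample_size(self):
        P = np.array([[0.7, 0.2, 0.1], [0.3, 0.4, 0.3], [0.2, 0.3, 0.5]])
        states = ["a", "b", "c"]
        medians = []
        for n_patients in (30, 120, 480):
            errs = []
            for rep in range(20):
                rng = np.random.default_rng(1000 + rep)
                seqs = []
                for p in range(n_patients):
                    idx = simulate_chain(P, np.full(3, 1 / 3), 6, rng=rng)
                    seqs.append(
                        StateSequence(f"p{p}", [(t + 1, states[i])
                                                for t, i in enumerate(idx)])
                    )
                m = fit_markov(seqs, bootstrap_reps=2, seed=rep, states=states)
                errs.append(np.abs(m.P - P).max())
            medians.append(np.median(errs))
        assert medians[0] > medians[1] > medians[2]
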