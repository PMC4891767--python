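import itertools

import numpy as np
import pytest

import rankcode as rc
from rankcode.features import ResponseMatrix
from rankcode.pid import JointResponseTable, population_pid_summary


def _table_from_rows(rows):
    """rows of (r1, r2, s), equiprobable."""
    r1, r2, s = (np.array(x) for x in zip(*rows))
    return rc.estimate_joint(r1, r2, s)


def random_table(rng, K=3, A1=3, A2=3):
    joint = rng.dirichlet(np.ones(K * A1 * A2)).reshape(K, A1, A2)
    return JointResponseTable(
        joint=joint,
        alphabet1=np.arange(A1),
        alphabet2=np.arange(A2),
        stimulus_values=np.arange(K),
        n_trials=0,
    )


class TestEstimateJoint:
    def test_deterministic_counts_give_point_masses(self):
        t = _table_from_rows([(0, 5, 0), (1, 3, 1), (2, 7, 2)])
        cond = t.joint / t.p_s[:, None, None]
        assert np.all(np.isin(cond, [0.0, 1.0]))

    def test_normalization_and_bookkeeping(self):
        rng = np.random.default_rng(0)
        s = np.repeat(np.arange(8), 10)
        t = rc.estimate_joint(rng.integers(0, 4, 80), rng.integers(0, 4, 80), s)
        assert t.n_trials == 80
        assert t.joint.sum() == pytest.approx(1.0, abs=1e-12)
        assert t.p_s.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_stimulus_class_rejected(self):
        with pytest.raises(ValueError):
            rc.estimate_joint([], [], [])


class TestPidPair:
    def test_xor_is_pure_synergy(self):
        rows = [(a, b, a ^ b) for a, b in itertools.product([0, 1], [0, 1])]
        res = rc.pid_pair(_table_from_rows(rows))
        assert res.i1 == pytest.approx(0.0, abs=1e-12)
        assert res.i2 == pytest.approx(0.0, abs=1e-12)
        assert res.red == pytest.approx(0.0, abs=1e-12)
        assert res.syn == pytest.approx(1.0, abs=1e-12)

    def test_copies_are_pure_redundancy(self):
        rows = [(0, 0, 0), (1, 1, 1)]
        res = rc.pid_pair(_table_from_rows(rows))
        assert res.red == pytest.approx(1.0, abs=1e-12)
        assert res.unq1 == pytest.approx(0.0, abs=1e-12)
        assert res.syn == pytest.approx(0.0, abs=1e-12)
        assert res.rsi == pytest.approx(-1.0, abs=1e-12)

    def test_split_field_toy(self):
        # ON cell fires to white and split fields, OFF cell to black and
        # split; three equiprobable stimuli
        rows = [(0, 1, 0), (1, 0, 1), (1, 1, 2)]  # black, white, split
        res = rc.pid_pair(_table_from_rows(rows))
        assert res.red == pytest.approx(np.log2(3 / 2), abs=1e-12)
        assert res.unq1 == pytest.approx(1 / 3, abs=1e-12)
        assert res.unq2 == pytest.approx(1 / 3, abs=1e-12)
        assert res.syn == pytest.approx(1 / 3, abs=1e-12)
        assert res.i12 == pytest.approx(np.log2(3), abs=1e-12)
        assert round(100 * res.synergy_fraction) == 21

    def test_direction_selective_toy_has_zero_synergy(self):
        # two DS cells with perpendicular preferred directions; four motions
        rows = [(2, 1, 0), (0, 1, 1), (1, 2, 2), (1, 0, 3)]
        res = rc.pid_pair(_table_from_rows(rows))
        assert res.syn == pytest.approx(0.0, abs=1e-12)
        assert res.red == pytest.approx(1.0, abs=1e-12)
        assert res.unq1 == pytest.approx(0.5, abs=1e-12)

    def test_identities_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            res = rc.pid_pair(random_table(rng))
            assert res.unq1 + res.red == pytest.approx(res.i1, abs=1e-12)
            assert res.unq2 + res.red == pytest.approx(res.i2, abs=1e-12)
            assert res.syn + res.unq1 + res.unq2 + res.red == pytest.approx(
                res.i12, abs=1e-12
            )
            assert res.rsi == pytest.approx(res.syn - res.red, abs=1e-12)
            for comp in (res.red, res.unq1, res.unq2, res.syn):
                assert comp >= -1e-12
            assert res.red <= min(res.i1, res.i2) + 1e-12
            assert res.syn <= res.i12 + 1e-12

    def test_invariant_to_alphabet_relabeling(self):
        rng = np.random.default_rng(5)
        s = np.repeat(np.arange(4), 12)
        r1 = rng.integers(0, 3, s.size)
        r2 = rng.integers(0, 3, s.size)
        a = rc.pid_pair(rc.estimate_joint(r1, r2, s))
        b = rc.pid_pair(rc.estimate_joint(10 - r1 * 3, r2, s))
        for key in ("red", "unq1", "unq2", "syn"):
            assert getattr(a, key) == pytest.approx(getattr(b, key), abs=1e-12)


class TestDeltaIIndependent:
    def test_split_field_toy_loses_nothing(self):
        rows = [(0, 1, 0), (1, 0, 1), (1, 1, 2)]
        assert rc.delta_i_independent(_table_from_rows(rows)) == pytest.approx(0.0, abs=1e-12)

    def test_factorized_table_gives_zero(self):
        rng = np.random.default_rng(1)
        K, A = 3, 2
        p_s = rng.dirichlet(np.ones(K))
        c1 = rng.dirichlet(np.ones(A), size=K)
        c2 = rng.dirichlet(np.ones(A), size=K)
        joint = p_s[:, None, None] * c1[:, :, None] * c2[:, None, :]
        t = JointResponseTable(joint, np.arange(A), np.arange(A), np.arange(K), 0)
        assert rc.delta_i_independent(t) == pytest.approx(0.0, abs=1e-12)

    def test_engineered_noise_correlation_detected(self):
        # s=0: r1=r2 perfectly coupled; s=1: independent uniform
        joint = np.zeros((2, 2, 2))
        joint[0] = np.array([[0.25, 0.0], [0.0, 0.25]])
        joint[1] = np.full((2, 2), 0.125)
        t = JointResponseTable(joint, np.arange(2), np.arange(2), np.arange(2), 0)
        # enumeration oracle with explicit loops
        def mi(p):
            ps = p.sum(axis=(1, 2))
            pr = p.sum(axis=0)
            total = 0.0
            for k in range(2):
                for i in range(2):
                    for j in range(2):
                        if p[k, i, j] > 0:
                            total += p[k, i, j] * np.log2(p[k, i, j] / (ps[k] * pr[i, j]))
            return total
        cond1 = joint.sum(axis=2) / joint.sum(axis=(1, 2))[:, None]
        cond2 = joint.sum(axis=1) / joint.sum(axis=(1, 2))[:, None]
        p_ind = joint.sum(axis=(1, 2))[:, None, None] * cond1[:, :, None] * cond2[:, None, :]
        expected = mi(joint) - mi(p_ind)
        assert expected > 0
        assert rc.delta_i_independent(t) == pytest.approx(expected, abs=1e-12)


class TestBiasCorrect:
    def test_flat_estimator_unchanged(self):
        labels = np.repeat(np.arange(4), 8)
        corrected, diag = rc.bias_correct(lambda idx: 0.7, labels, max_partitions=4, seed=0)
        assert corrected == pytest.approx(0.7, abs=1e-9)
        assert all(v == pytest.approx(0.7) for v in diag.values())

    def test_collinear_points_extrapolate_linearly(self):
        # estimates 0.9, 0.8, 0.7 at k=1,2,3 -> intercept 1.0 exactly
        labels = np.zeros(12, dtype=int)
        fn = lambda idx: 1.0 - 0.1 * (12 / len(idx))
        corrected, diag = rc.bias_correct(fn, labels, max_partitions=3, seed=0)
        assert [diag[k] for k in (1, 2, 3)] == pytest.approx([0.9, 0.8, 0.7])
        assert corrected == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_trials_name_limiting_class(self):
        labels = np.array([0, 0, 0, 1])  # class 1 has one trial
        with pytest.raises(ValueError, match="1"):
            rc.bias_correct(lambda idx: 0.0, labels, max_partitions=3, seed=0)

    def test_corrected_pid_reduces_mi_bias_for_independent_data(self):
        # light version of the Monte-Carlo recovery study
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            s = np.repeat(np.arange(8), 6)
            r1 = rng.integers(0, 2, 48)
            r2 = rng.integers(0, 2, 48)
            res = rc.pid_pair_bias_corrected(r1, r2, s, max_partitions=4, seed=seed + 500)
            if abs(res.corrected["i1"]) < abs(res.i1):
                wins += 1
        assert wins / n_seeds > 0.6


class TestShuffleWithinStimulus:
    def test_marginals_conserved(self):
        rng = np.random.default_rng(3)
        s = np.repeat(np.arange(4), 10)
        r1 = rng.integers(0, 5, 40)
        r2 = rng.integers(0, 5, 40)
        _, r2s = rc.shuffle_within_stimulus(r1, r2, s, seed=1)
        for sv in range(4):
            assert sorted(r2[s == sv]) == sorted(r2s[s == sv])

    def test_single_trial_per_class_is_identity(self):
        s = np.arange(5)
        r1 = np.arange(5)
        r2 = np.arange(5) * 2
        _, r2s = rc.shuffle_within_stimulus(r1, r2, s, seed=1)
        assert np.array_equal(r2, r2s)


def _counts_rm(values):
    values = np.asarray(values, dtype=float)  # (U, S, T)
    return ResponseMatrix(
        values=values,
        censored=np.zeros_like(values, dtype=bool),
        kind="count",
        window=0.5,
        unit_ids=list(range(values.shape[0])),
        stimulus_ids=list(range(values.shape[1])),
    )


class TestPopulationSummary:
    def test_three_units_give_three_pairs(self):
        rng = np.random.default_rng(1)
        rm = _counts_rm(rng.integers(0, 3, (3, 4, 6)))
        per_pair, agg = population_pid_summary(rm)
        assert len(per_pair) == 3
        assert agg["n_pairs"].iloc[0] == 3

    def test_cloned_unit_is_redundant_not_synergistic(self):
        rng = np.random.default_rng(2)
        base = rng.integers(0, 3, (1, 4, 8))
        vals = np.concatenate([base, base], axis=0)  # unit 1 clones unit 0
        per_pair, _ = population_pid_summary(_counts_rm(vals))
        row = per_pair.iloc[0]
        assert row["syn"] == pytest.approx(0.0, abs=1e-12)
        assert row["red"] > 0.1

    def test_xor_engineered_population_is_synergistic(self):
        # two binary units, individually uninformative, whose XOR equals the
        # 2-stimulus label: s=0 -> (0,0)/(1,1); s=1 -> (0,1)/(1,0)
        u1 = np.array([[0, 1], [0, 1]])  # (S=2, T=2)
        u2 = np.array([[0, 1], [1, 0]])
        vals = np.stack([u1, u2])
        per_pair, agg = population_pid_summary(_counts_rm(vals))
        assert agg["syn_mean"].iloc[0] > agg["red_mean"].iloc[0]
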