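import numpy as np
import pytest

import rankcode as rc
from rankcode.decode import (
    DecoderConfig,
    _RankOrderModel,
    fit_decoder,
    run_task,
    sweep_population,
    sweep_window,
)
from rankcode.features import ResponseMatrix, extract_counts, extract_latencies


def _rm(values, kind, censored=None):
    values = np.asarray(values, dtype=float)
    if censored is None:
        censored = np.isnan(values)
    return ResponseMatrix(
        values=values,
        censored=censored,
        kind=kind,
        window=0.5,
        unit_ids=list(range(values.shape[0])),
        stimulus_ids=list(range(values.shape[1])),
    )


def _separable_latency_rm(n_units=12, n_phases=8, n_trials=6):
    """Deterministic latencies with a phase-specific firing order."""
    vals = np.empty((n_units, n_phases, n_trials))
    for u in range(n_units):
        for p in range(n_phases):
            vals[u, p, :] = 0.05 + 0.01 * ((u + p) % n_units)
    return _rm(vals, "latency")


def _separable_count_rm(n_units=12, n_phases=8, n_trials=6):
    vals = np.empty((n_units, n_phases, n_trials))
    for u in range(n_units):
        for p in range(n_phases):
            vals[u, p, :] = (u + 5 * p) % 11
    return _rm(vals, "count")


class TestFitDecoder:
    def test_pair_order_probability_from_training_trials(self):
        # trials (L_i, L_j): (0.10,0.20),(0.12,0.25),(0.30,0.11) -> P(L_i>L_j)=1/3
        x = np.array([[[0.10, 0.12, 0.30]], [[0.20, 0.25, 0.11]]])  # (U=2,P=1,T=3)
        model = fit_decoder(x, DecoderConfig(code="roc_latency", pseudocount=0.0))
        assert model.p_hat[0, 0, 1] == pytest.approx(1 / 3)

    def test_tied_latencies_count_as_not_later(self):
        x = np.array([[[0.1, 0.2]], [[0.1, 0.2]]])
        model = fit_decoder(x, DecoderConfig(code="roc_latency", pseudocount=0.0))
        assert model.p_hat[0, 0, 1] == 0.0

    def test_pseudocount_smoothing_arithmetic(self):
        # alpha=1, T=3, 1 positive trial -> (1+1)/(3+2) = 2/5
        x = np.array([[[0.10, 0.12, 0.30]], [[0.20, 0.25, 0.11]]])
        model = fit_decoder(x, DecoderConfig(code="roc_latency", pseudocount=1.0))
        assert model.p_hat[0, 0, 1] == pytest.approx(2 / 5)

    def test_censored_comparisons(self):
        # censored (inf) vs observed: observed fired earlier -> H=1;
        # censored vs censored: tie -> H=0
        x = np.array([[[np.inf, np.inf]], [[0.2, np.inf]]])
        model = fit_decoder(x, DecoderConfig(code="roc_latency", pseudocount=0.0))
        assert model.p_hat[0, 0, 1] == pytest.approx(1 / 2)

    def test_nan_training_data_rejected(self):
        x = np.array([[[np.nan, 0.1]]])
        with pytest.raises(ValueError, match="NaN"):
            fit_decoder(x, DecoderConfig(code="roc_latency"))


class TestDecodeTrial:
    def test_disjoint_count_alphabets_always_correct(self):
        rm = _separable_count_rm()
        x = rm.values
        model = fit_decoder(x, DecoderConfig(code="count"), alphabet_size=8)
        for p in range(8):
            assert rc.decode_trial(model, x[:, p, 0]) == p

    def test_identical_likelihoods_tie_break_to_lowest_phase(self):
        x = np.tile(np.array([1.0, 2.0, 3.0])[:, None, None], (1, 4, 3))
        model = fit_decoder(x, DecoderConfig(code="count"), alphabet_size=5)
        assert rc.decode_trial(model, np.array([1.0, 2.0, 3.0])) == 0

    def test_poisson_like_counts_prefer_high_mean_phase(self):
        rng = np.random.default_rng(0)
        x = np.stack(
            [np.stack([rng.poisson(1, 30), rng.poisson(10, 30)], axis=0)], axis=0
        ).astype(float)  # (U=1, P=2, T=30)
        model = fit_decoder(x, DecoderConfig(code="count"), alphabet_size=25)
        assert rc.decode_trial(model, np.array([9.0])) == 1


class TestRunTask:
    @pytest.mark.parametrize("code", ["count", "latency", "roc_latency", "roc_count"])
    def test_separable_noise_free_data_decodes_perfectly(self, code):
        rm = (
            _separable_latency_rm()
            if code in ("latency", "roc_latency")
            else _separable_count_rm()
        )
        cm = run_task(rm, DecoderConfig(code=code, n_configurations=5, seed=1))
        assert cm.fraction_correct == 1.0

    @pytest.mark.parametrize("code", ["count", "latency", "roc_latency", "roc_count"])
    def test_label_permutation_gives_chance(self, code, small_dataset):
        rm = (
            extract_latencies(small_dataset)
            if code in ("latency", "roc_latency")
            else extract_counts(small_dataset)
        )
        rng = np.random.default_rng(77)
        # permute (phase, trial) cells across phases, destroying the label
        U, P, T = rm.values.shape
        flat = rm.values.reshape(U, P * T)
        perm = rng.permutation(P * T)
        shuffled = _rm(flat[:, perm].reshape(U, P, T), rm.kind)
        cm = run_task(shuffled, DecoderConfig(code=code, n_configurations=10, seed=3))
        # 99% binomial interval around 1/8, with n = distinct trials
        half_width = 2.576 * np.sqrt(0.125 * 0.875 / (P * T))
        assert abs(cm.fraction_correct - 0.125) < half_width + 0.02

    def test_same_seed_identical_confusions(self, small_dataset):
        rm = extract_latencies(small_dataset)
        cfg = DecoderConfig(code="roc_latency", n_configurations=4, seed=5)
        a = run_task(rm, cfg)
        b = run_task(rm, cfg)
        assert np.array_equal(a.matrix, b.matrix)

    def test_confusion_columns_balanced(self, small_dataset):
        rm = extract_counts(small_dataset)
        cm = run_task(rm, DecoderConfig(code="count", n_configurations=4, seed=5))
        cols = cm.matrix.sum(axis=0)
        assert np.all(cols == cols[0])

    def test_all_but_one_split(self, small_dataset):
        rm = extract_counts(small_dataset)
        cfg = DecoderConfig(code="count", n_configurations=6, split="all-but-one", seed=2)
        cm = run_task(rm, cfg)
        assert cm.matrix.sum() == 6 * 8  # one decoded trial per phase per config

    def test_too_few_trials_rejected(self):
        rm = _rm(np.zeros((3, 8, 1)), "count")
        with pytest.raises(ValueError, match="2 trials"):
            run_task(rm, DecoderConfig(code="count"))

    def test_roc_invariant_to_monotone_latency_transform(self, small_dataset):
        rm = extract_latencies(small_dataset)
        warped = _rm(np.exp(4.0 * rm.values), "latency", censored=rm.censored.copy())
        cfg = DecoderConfig(code="roc_latency", n_configurations=4, seed=8)
        assert np.array_equal(run_task(rm, cfg).matrix, run_task(warped, cfg).matrix)

    def test_count_code_unchanged_by_spike_time_jitter(self, small_dataset):
        # counts over the full trial window are exactly conserved by jitter
        jit = rc.apply_jitter(small_dataset, 0.02, seed=9)
        w = small_dataset.ensemble.trial_duration
        a = extract_counts(small_dataset, window=w)
        b = extract_counts(jit, window=w)
        assert np.array_equal(a.values, b.values)
        cfg = DecoderConfig(code="count", n_configurations=4, seed=8)
        assert np.array_equal(run_task(a, cfg).matrix, run_task(b, cfg).matrix)


class TestSweeps:
    def test_full_population_matches_run_task(self, small_dataset):
        rm = extract_counts(small_dataset)
        cfg = DecoderConfig(code="count", n_configurations=3, seed=4)
        curve = sweep_population(rm, [rm.n_units], n_subsets=1, config=cfg, seed=4)
        derived_seed = int((cfg.seed * 1000003 + rm.n_units * 101) % 2**31)
        from dataclasses import replace

        expected = run_task(rm, replace(cfg, seed=derived_seed)).fraction_correct
        assert curve["fc_mean"].iloc[0] == pytest.approx(expected)

    def test_size_below_two_rejected(self, small_dataset):
        rm = extract_counts(small_dataset)
        with pytest.raises(ValueError):
            sweep_population(rm, [1], n_subsets=1, config=DecoderConfig(code="count"))

    def test_window_half_second_matches_full_task(self, small_dataset):
        stim = list(range(8))
        cfg = DecoderConfig(code="roc_latency", n_configurations=3, seed=6)
        curve = sweep_window(small_dataset, stim, [0.5], config=cfg)
        rm = extract_latencies(small_dataset, window=0.5).select_stimuli(stim)
        assert curve["fraction_correct"].iloc[0] == pytest.approx(
            run_task(rm, cfg).fraction_correct
        )

    def test_window_before_any_latency_is_chance(self):
        # all first spikes at 0.2 s; a 0.05 s window sees nothing
        vals = np.full((6, 8, 4), 0.2)
        rm = _rm(vals, "latency")
        rm.values[:] = np.nan
        rm.censored[:] = True
        rm2 = _rm(rm.values, "latency", censored=rm.censored)
        cm = run_task(rm2, DecoderConfig(code="roc_latency", n_configurations=3, seed=1))
        assert cm.fraction_correct == pytest.approx(0.125)
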