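import numpy as np
import pytest

import rankcode as rc


@pytest.fixture(scope="session")
def single_freq_ensemble():
    """One spatial frequency (800 µm bars), 8 phases, 12 trials."""
    return rc.make_grating_ensemble([800], 30.0, 8, 0.5, 1.0, 12)


@pytest.fixture(scope="session")
def small_dataset(single_freq_ensemble):
    """25 noisy units with shared jitter: the default study conditions at
    desk scale."""
    params = rc.default_population(25, seed=101)
    return rc.simulate_population(params, single_freq_ensemble, seed=102)


@pytest.fixture(scope="session")
def noise_free_dataset(single_freq_ensemble):
    """Deterministic latencies (no noise terms), for exact checks."""
    params = rc.default_population(
        20, seed=103, shared_jitter_sd=0.0, baseline_scale=0.0, latency_sd_individual=0.0
    )
    return rc.simulate_population(params, single_freq_ensemble, seed=104)


def manual_dataset(spike_lists, n_stimuli=1, n_trials=None, flash=0.5, gray=1.0):
    """Build a SpikeDataset from {(unit, stim, trial): [times]}; helper for
    handcrafted fixtures."""
    unit_ids = sorted({k[0] for k in spike_lists})
    if n_trials is None:
        n_trials = max(k[2] for k in spike_lists) + 1
    ens = rc.make_grating_ensemble(
        [400], 30.0, n_stimuli, flash_duration=flash, gray_duration=gray, n_trials=n_trials
    )
    trains = {
        (u, s, t): np.asarray(sorted(spike_lists.get((u, s, t), [])), dtype=float)
        for u in unit_ids
        for s in range(n_stimuli)
        for t in range(n_trials)
    }
    units = [rc.UnitMetadata(unit_id=u, electrode_xy=(42.0 * u, 0.0)) for u in unit_ids]
    return rc.SpikeDataset(ensemble=ens, units=units, trains=trains)
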