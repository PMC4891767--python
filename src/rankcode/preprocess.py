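"""Unit-level preprocessing: duplicate removal, ON/OFF classification,
responsiveness selection.

High-density MEA spike sorting can report the same cell on neighbouring
electrodes.  ``remove_duplicate_units`` detects such duplicates by the
fraction of near-coincident spikes between neighbouring units and
iteratively removes all but the highest-count member of each coincident
group.

``classify_units`` assigns ON / OFF / ON-OFF labels from full-field
alternating white/black responses via the bias index
(ON − OFF) / (ON + OFF) of Gaussian-smoothed peak firing rates, and
``select_responsive_rayleigh`` keeps units whose first-spike latencies are
non-uniform on the circle (Rayleigh test), a responsiveness criterion that
needs no receptive-field mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import ELECTRODE_PITCH_UM, SpikeDataset

__all__ = [
    "remove_duplicate_units",
    "CellClassification",
    "classify_units",
    "rayleigh_test",
    "RayleighSelection",
    "select_responsive_rayleigh",
]

# ±2 acquisition frames at 7.06 kHz
DEFAULT_COINCIDENCE_HALFWIDTH = 2.0 / 7060.0


def _coincident_count(x: np.ndarray, y: np.ndarray, hw: float) -> int:
    """Number of spikes in x having at least one spike of y within ±hw."""
    if x.size == 0 or y.size == 0:
        return 0
    lo = np.searchsorted(y, x - hw, side="left")
    hi = np.searchsorted(y, x + hw, side="right")
    return int(np.count_nonzero(hi > lo))


def _pair_overlap(dataset: SpikeDataset, a: int, b: int, hw: float) -> float:
    """Coincidence fraction for units a, b: coincident spikes of the
    lower-count unit relative to that unit's spike count (symmetric
    subset detection)."""
    n_a = n_b = 0
    coinc = 0
    ens = dataset.ensemble
    # decide the smaller unit first
    for s in range(ens.n_stimuli):
        for t in range(ens.n_trials):
            n_a += dataset.trains[(a, s, t)].size
            n_b += dataset.trains[(b, s, t)].size
    if n_a == 0 or n_b == 0:
        return 0.0
    small, large = (a, b) if n_a <= n_b else (b, a)
    for s in range(ens.n_stimuli):
        for t in range(ens.n_trials):
            coinc += _coincident_count(
                dataset.trains[(small, s, t)], dataset.trains[(large, s, t)], hw
            )
    return coinc / min(n_a, n_b)


def remove_duplicate_units(
    dataset: SpikeDataset,
    coincidence_halfwidth: float = DEFAULT_COINCIDENCE_HALFWIDTH,
    neighbor_radius: float = 1.0,
    threshold: float = 0.05,
    electrode_pitch: float = ELECTRODE_PITCH_UM,
) -> tuple[SpikeDataset, list[int]]:
    """Iteratively remove duplicate units detected on neighbouring electrodes.

    Parameters
    ----------
    coincidence_halfwidth : s
        Spikes of two units closer than this are coincident (default ±2
        frames of a 7.06 kHz acquisition clock).
    neighbor_radius : electrode pitches
        Units whose electrodes are within this Euclidean distance (in
        units of ``electrode_pitch``) are compared; radius 1 covers the
        four closest electrodes and units sharing an electrode.
    threshold : fraction
        Units in a pair whose coincidence fraction exceeds this are
        duplicates; the one with the larger total spike count is retained.

    Removal is iterative and deterministic: the pair with the largest
    overlap is resolved first (ties by unit id), fractions are recomputed
    among the survivors, until no pair exceeds the threshold.
    """
    for u in dataset.units:
        if u.electrode_xy is None:
            raise ValueError(f"unit {u.unit_id} lacks electrode coordinates")

    ids = dataset.unit_ids
    xy = {u.unit_id: np.asarray(u.electrode_xy, dtype=float) for u in dataset.units}
    max_dist = neighbor_radius * electrode_pitch + 1e-9
    neighbor_pairs = [
        (a, b)
        for i, a in enumerate(ids)
        for b in ids[i + 1 :]
        if np.linalg.norm(xy[a] - xy[b]) <= max_dist
    ]
    totals = {
        u: sum(
            dataset.trains[(u, s, t)].size
            for s in range(dataset.ensemble.n_stimuli)
            for t in range(dataset.ensemble.n_trials)
        )
        for u in ids
    }
    overlaps = {
        (a, b): _pair_overlap(dataset, a, b, coincidence_halfwidth)
        for a, b in neighbor_pairs
    }

    removed: list[int] = []
    alive = set(ids)
    while True:
        live_pairs = [
            (p, f) for p, f in overlaps.items() if p[0] in alive and p[1] in alive
        ]
        offending = [(p, f) for p, f in live_pairs if f > threshold]
        if not offending:
            break
        offending.sort(key=lambda item: (-item[1], item[0]))
        (a, b), _ = offending[0]
        # retain the larger spike count; ties resolved by keeping the lower id
        loser = b if (totals[b] < totals[a] or (totals[b] == totals[a] and b > a)) else a
        alive.discard(loser)
        removed.append(loser)

    return dataset.subset_units(sorted(alive)), removed


@dataclass
class CellClassification:
    """ON/OFF polarity classification of one unit from full-field responses."""

    unit_id: int
    bias_index: float  # (ON - OFF)/(ON + OFF), in [-1, 1]; nan if unclassifiable
    cell_class: str  # OFF | ON-OFF | ON | unclassified
    on_amplitude: float  # Hz, peak smoothed rate after light onset
    off_amplitude: float  # Hz, peak smoothed rate after light offset


def _classify_from_bias(bias: float) -> str:
    # boundary values ±0.33 assigned to ON-OFF
    if np.isnan(bias):
        return "unclassified"
    if bias < -0.33:
        return "OFF"
    if bias > 0.33:
        return "ON"
    return "ON-OFF"


def classify_units(
    fullfield: SpikeDataset,
    smoothing_sd: float = 0.025,
    amplitude_window: float = 0.5,
    white_duration: float = 2.0,
    black_duration: float = 2.0,
    grid_dt: float = 0.001,
) -> list[CellClassification]:
    """Classify units as ON / OFF / ON-OFF from alternating full-field epochs.

    ``fullfield`` holds repetitions (trials) of one epoch: white onset at
    t=0 for ``white_duration`` seconds, then black for ``black_duration``.
    The instantaneous rate is the spike train convolved with a Gaussian of
    SD ``smoothing_sd`` (25 ms default), averaged over repetitions.  The ON
    (OFF) amplitude is the peak rate within ``amplitude_window`` after the
    white (black) onset, and the bias index is (ON − OFF)/(ON + OFF).
    Units with zero amplitude in both windows are flagged unclassified.
    """
    n_rep = fullfield.ensemble.n_trials
    epoch = white_duration + black_duration
    grid = np.arange(0.0, epoch, grid_dt)
    inv = 1.0 / (smoothing_sd * np.sqrt(2 * np.pi))
    on_mask = grid < amplitude_window
    off_mask = (grid >= white_duration) & (grid < white_duration + amplitude_window)

    out = []
    for u in fullfield.unit_ids:
        spikes = np.concatenate(
            [fullfield.trains[(u, 0, t)] for t in range(n_rep)]
        )
        if spikes.size:
            d = grid[:, None] - spikes[None, :]
            rate = inv * np.exp(-0.5 * (d / smoothing_sd) ** 2).sum(axis=1) / n_rep
        else:
            rate = np.zeros_like(grid)
        on_amp = float(rate[on_mask].max()) if on_mask.any() else 0.0
        off_amp = float(rate[off_mask].max()) if off_mask.any() else 0.0
        if on_amp + off_amp == 0:
            bias = float("nan")
        else:
            bias = (on_amp - off_amp) / (on_amp + off_amp)
        out.append(
            CellClassification(
                unit_id=u,
                bias_index=bias,
                cell_class=_classify_from_bias(bias),
                on_amplitude=on_amp,
                off_amplitude=off_amp,
            )
        )
    return out


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for non-uniformity of circular data.

    Returns (z, p) with z = n * Rbar² and the standard large-n
    approximation (Zar 1999)
    ``p = exp(sqrt(1 + 4n + 4(n² − R²)) − (1 + 2n))`` where R = n·Rbar.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    C = np.cos(phases).sum()
    S = np.sin(phases).sum()
    R = np.hypot(C, S)
    z = R**2 / n
    p = np.exp(np.sqrt(1 + 4 * n + 4 * (n**2 - R**2)) - (1 + 2 * n))
    return float(z), float(min(p, 1.0))


@dataclass
class RayleighSelection:
    selected_ids: list[int]
    pvalues: dict[int, float]
    excluded_ids: list[int]  # < 2 latencies, untestable
    used_trial_ids: list[int]  # so downstream analyses can exclude these blocks


def select_responsive_rayleigh(
    dataset: SpikeDataset,
    stimulus_ids,
    trial_ids,
    alpha: float = 0.01,
    window: float | None = None,
) -> RayleighSelection:
    """Select responsive units by a Rayleigh test on first-spike latencies.

    Latencies (first spike in (0, window], default the flash duration) of
    the given stimuli/trials are mapped to circular phases as
    ``2π · latency / flash_duration`` and tested for non-uniformity.  Units
    with fewer than 2 latencies are excluded with a warning.  The trial ids
    consumed by the test are reported so their blocks can be excluded from
    subsequent analyses.
    """
    if window is None:
        window = dataset.ensemble.flash_duration
    flash = dataset.ensemble.flash_duration
    selected, pvals, excluded = [], {}, []
    for u in dataset.unit_ids:
        lats = []
        for s in stimulus_ids:
            for t in trial_ids:
                spk = dataset.trains[(u, s, t)]
                in_win = spk[(spk > 0) & (spk <= window)]
                if in_win.size:
                    lats.append(in_win[0])
        if len(lats) < 2:
            warnings.warn(f"unit {u}: fewer than 2 latencies, excluded from Rayleigh test")
            excluded.append(u)
            continue
        phases = 2 * np.pi * np.asarray(lats) / flash
        _, p = rayleigh_test(phases)
        pvals[u] = p
        if p < alpha:
            selected.append(u)
    return RayleighSelection(
        selected_ids=selected,
        pvalues=pvals,
        excluded_ids=excluded,
        used_trial_ids=list(trial_ids),
    )
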