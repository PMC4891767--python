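"""Per-trial response features: first-spike latency and spike count.

A :class:`ResponseMatrix` holds one scalar per (unit, stimulus, trial)
inside an observation window (0, w] after stimulus onset.  Latency trials
with no spike in the window are *censored* (NaN value + mask); counts are
never censored.  Rank transforms convert a population feature vector to
midranks, with censored entries sharing the maximal tied rank — a censored
unit is "slower than everyone", which preserves first-spike ordering
semantics without discarding units.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .simulate import SpikeDataset

__all__ = [
    "ResponseMatrix",
    "extract_latencies",
    "extract_counts",
    "RankVector",
    "rank_transform",
    "VariabilityStats",
    "latency_variability",
]


@dataclass
class ResponseMatrix:
    """Feature values indexed (unit, stimulus, trial).

    ``values`` has shape (n_units, n_stimuli, n_trials); censored entries
    are NaN with ``censored`` True.  ``kind`` is "latency" or "count".
    """

    values: np.ndarray
    censored: np.ndarray
    kind: str
    window: float
    unit_ids: list[int]
    stimulus_ids: list[int]

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    def select_stimuli(self, stimulus_ids) -> "ResponseMatrix":
        idx = [self.stimulus_ids.index(s) for s in stimulus_ids]
        return ResponseMatrix(
            values=self.values[:, idx, :],
            censored=self.censored[:, idx, :],
            kind=self.kind,
            window=self.window,
            unit_ids=list(self.unit_ids),
            stimulus_ids=list(stimulus_ids),
        )

    def select_units(self, unit_ids) -> "ResponseMatrix":
        idx = [self.unit_ids.index(u) for u in unit_ids]
        return ResponseMatrix(
            values=self.values[idx],
            censored=self.censored[idx],
            kind=self.kind,
            window=self.window,
            unit_ids=list(unit_ids),
            stimulus_ids=list(self.stimulus_ids),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: unit, stimulus, trial, value, censored."""
        u, s, t = np.meshgrid(
            self.unit_ids, self.stimulus_ids, np.arange(self.n_trials), indexing="ij"
        )
        return pd.DataFrame(
            {
                "unit": u.ravel(),
                "stimulus": s.ravel(),
                "trial": t.ravel(),
                "value": self.values.ravel(),
                "censored": self.censored.ravel(),
            }
        )


def _check_window(dataset: SpikeDataset, window: float) -> None:
    if not 0 < window <= dataset.ensemble.trial_duration:
        raise ValueError("window must lie in (0, flash + gray]")


def extract_latencies(dataset: SpikeDataset, window: float | None = None) -> ResponseMatrix:
    """First spike time in (0, window]; censored when there is none."""
    if window is None:
        window = dataset.ensemble.flash_duration
    _check_window(dataset, window)
    unit_ids = dataset.unit_ids
    S = dataset.ensemble.n_stimuli
    T = dataset.ensemble.n_trials
    values = np.full((len(unit_ids), S, T), np.nan)
    for ui, u in enumerate(unit_ids):
        for s in range(S):
            for t in range(T):
                spk = dataset.trains[(u, s, t)]
                in_win = spk[(spk > 0) & (spk <= window)]
                if in_win.size:
                    values[ui, s, t] = in_win[0]
    return ResponseMatrix(
        values=values,
        censored=np.isnan(values),
        kind="latency",
        window=window,
        unit_ids=unit_ids,
        stimulus_ids=list(range(S)),
    )


def extract_counts(dataset: SpikeDataset, window: float | None = None) -> ResponseMatrix:
    """Spike count in (0, window]."""
    if window is None:
        window = dataset.ensemble.flash_duration
    _check_window(dataset, window)
    unit_ids = dataset.unit_ids
    S = dataset.ensemble.n_stimuli
    T = dataset.ensemble.n_trials
    values = np.zeros((len(unit_ids), S, T))
    for ui, u in enumerate(unit_ids):
        for s in range(S):
            for t in range(T):
                spk = dataset.trains[(u, s, t)]
                values[ui, s, t] = np.count_nonzero((spk > 0) & (spk <= window))
    return ResponseMatrix(
        values=values,
        censored=np.zeros_like(values, dtype=bool),
        kind="count",
        window=window,
        unit_ids=unit_ids,
        stimulus_ids=list(range(S)),
    )


@dataclass
class RankVector:
    """Midranks of one population feature vector."""

    ranks: np.ndarray

    @property
    def n(self) -> int:
        return self.ranks.size

    @property
    def tie_correction(self) -> float:
        """Σ m(m²−1)/12 over tie groups (the Spearman tie term)."""
        _, counts = np.unique(self.ranks, return_counts=True)
        m = counts[counts > 1].astype(float)
        return float(np.sum(m * (m**2 - 1) / 12.0))


def rank_transform(values, censored=None) -> RankVector:
    """Convert a feature vector to midranks.

    Ties share the average rank; censored entries are ranked as the
    slowest possible value and therefore share the maximal tied rank.
    Raises if everything is censored (no rankable signal).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values to rank")
    if censored is None:
        censored = np.isnan(values)
    else:
        censored = np.asarray(censored, dtype=bool) | np.isnan(values)
    if censored.all():
        raise ValueError("all values censored: no rankable signal")
    work = values.copy()
    work[censored] = np.inf
    return RankVector(ranks=rankdata(work, method="average"))


@dataclass
class VariabilityStats:
    """Latency variability for one stimulus: per-unit and per-pair."""

    stimulus_id: int
    unit_stats: pd.DataFrame  # unit, mean, sd, n_trials, cell_class
    pair_stats: pd.DataFrame  # unit_i, unit_j, sd_diff, n_trials, class_pair

    def sd_distribution(self, cell_class: str | None = None) -> np.ndarray:
        df = self.unit_stats
        if cell_class is not None:
            df = df[df["cell_class"] == cell_class]
        return df["sd"].to_numpy()

    def pair_sd_distribution(self, cell_class: str | None = None) -> np.ndarray:
        df = self.pair_stats
        if cell_class is not None:
            df = df[df["class_pair"] == cell_class]
        return df["sd_diff"].to_numpy()


def latency_variability(
    rm: ResponseMatrix,
    stimulus_id: int,
    classifications: dict[int, str] | None = None,
    min_trials: int = 2,
) -> VariabilityStats:
    """Mean/SD of first-spike latency per unit and SD of pairwise latency
    differences, for one stimulus.

    Pair statistics use complete-case trials only (both latencies
    uncensored); units with fewer than ``min_trials`` uncensored trials are
    omitted with a warning.  ``classifications`` maps unit id to class
    label for stratified distributions; pairs get a class only when both
    members share it.
    """
    if rm.kind != "latency":
        raise ValueError("latency_variability needs a latency ResponseMatrix")
    si = rm.stimulus_ids.index(stimulus_id)
    lat = rm.values[:, si, :]  # (U, T), NaN-censored
    classes = classifications or {}

    rows = []
    kept = []
    for ui, u in enumerate(rm.unit_ids):
        x = lat[ui]
        ok = ~np.isnan(x)
        if ok.sum() < min_trials:
            warnings.warn(f"unit {u}: fewer than {min_trials} uncensored trials, omitted")
            continue
        kept.append(ui)
        rows.append(
            {
                "unit": u,
                "mean": float(np.mean(x[ok])),
                "sd": float(np.std(x[ok], ddof=1)),
                "n_trials": int(ok.sum()),
                "cell_class": classes.get(u, "unclassified"),
            }
        )
    unit_stats = pd.DataFrame(rows)

    pair_rows = []
    for ai, bi in itertools.combinations(kept, 2):
        diff = lat[ai] - lat[bi]
        ok = ~np.isnan(diff)
        if ok.sum() < min_trials:
            continue
        ua, ub = rm.unit_ids[ai], rm.unit_ids[bi]
        ca, cb = classes.get(ua, "unclassified"), classes.get(ub, "unclassified")
        pair_rows.append(
            {
                "unit_i": ua,
                "unit_j": ub,
                "sd_diff": float(np.std(diff[ok], ddof=1)),
                "n_trials": int(ok.sum()),
                "class_pair": ca if ca == cb else "mixed",
            }
        )
    pair_stats = pd.DataFrame(pair_rows)
    return VariabilityStats(stimulus_id=stimulus_id, unit_stats=unit_stats, pair_stats=pair_stats)
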