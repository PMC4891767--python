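"""Spearman rank similarity between waves of first spikes (WFS).

The WFS evoked by one stimulus presentation is the vector of population
first-spike latencies, reduced to ranks.  The similarity between the WFS
of two stimuli is the Spearman rank correlation ρ between the rank vectors
of a pair of trials, averaged over trial pairings: ρ = 1 for identical
firing orders, −1 for exactly opposite orders.

ρ is canonically the Pearson correlation of midranks; the classic
``1 − 6(Σd² + Σcf)/(n(n²−1))`` tie-corrected shortcut is also provided and
agrees exactly whenever there are no ties.

Trial pairings:

* ``matched`` — trial t of stimulus i with trial t of stimulus j (same
  recording block, preserving block-shared noise correlations);
* ``all-pairs`` — every (t, t′) combination;
* ``shuffled`` — a random permutation pairing, which destroys noise
  correlations while preserving the per-stimulus latency statistics.

The trial-shuffling loss statistic (Δ − Δs)/Δ, with
Δ = ρ(0°, 45°) − ρ(0°, 180°), quantifies how much of the phase tuning of
the WFS rests on those correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import RankVector, ResponseMatrix
from .stimuli import StimulusEnsemble

__all__ = [
    "spearman_rho",
    "spearman_rho_tied_formula",
    "SpearmanResult",
    "wfs_distance_matrix",
    "phase_tuning_curve",
    "ShuffleLossResult",
    "shuffle_loss",
]


def _as_ranks(v) -> np.ndarray:
    return v.ranks if isinstance(v, RankVector) else np.asarray(v, dtype=float)


def spearman_rho(a, b) -> float:
    """ρ as the Pearson correlation between two midrank vectors (canonical)."""
    ra, rb = _as_ranks(a), _as_ranks(b)
    if ra.size != rb.size:
        raise ValueError("rank vectors must have equal length")
    if ra.size < 2:
        raise ValueError("need n >= 2")
    if np.ptp(ra) == 0 or np.ptp(rb) == 0:
        raise ValueError("constant rank vector: correlation undefined")
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(np.dot(ra, rb) / np.sqrt(np.dot(ra, ra) * np.dot(rb, rb)))


def spearman_rho_tied_formula(a, b) -> float:
    """ρ via the rank-difference shortcut with tie correction terms.

    ``ρ = 1 − 6(Σ(a_i−b_i)² + Σcf) / (n(n²−1))`` with ``cf = m(m²−1)/12``
    per tie group of either vector.  Equals the Pearson-on-ranks value
    exactly when no ties are present; with ties the two conventions
    differ, and the Pearson form is canonical.
    """
    va = a if isinstance(a, RankVector) else RankVector(_as_ranks(a))
    vb = b if isinstance(b, RankVector) else RankVector(_as_ranks(b))
    n = va.n
    if n != vb.n or n < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d2 = float(np.sum((va.ranks - vb.ranks) ** 2))
    cf = va.tie_correction + vb.tie_correction
    return 1.0 - 6.0 * (d2 + cf) / (n * (n**2 - 1))


@dataclass
class SpearmanResult:
    """Mean ± SEM of ρ for every stimulus pair."""

    mean: np.ndarray  # (S, S)
    sem: np.ndarray  # (S, S)
    stimulus_ids: list[int]
    pairing: str

    def rho(self, i: int, j: int) -> float:
        return float(self.mean[self.stimulus_ids.index(i), self.stimulus_ids.index(j)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.mean, index=self.stimulus_ids, columns=self.stimulus_ids)


def _normalized_rank_tensor(rm: ResponseMatrix) -> np.ndarray:
    """Per (stimulus, trial): midranks over units (censored share the
    maximal tied rank), centered and L2-normalized so that ρ between two
    trials is a plain dot product.  Constant rank vectors become NaN."""
    work = rm.values.copy()
    work[rm.censored] = np.inf
    ranks = rankdata(work, method="average", axis=0).astype(float)  # (U, S, T)
    centered = ranks - ranks.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / norms
    z[:, (norms[0] == 0)] = np.nan
    return z


def wfs_distance_matrix(
    rm: ResponseMatrix,
    pairing: str = "matched",
    seed: int | None = None,
) -> SpearmanResult:
    """Mean Spearman ρ between the WFS of every stimulus pair.

    Diagonal entries (identical stimuli) use distinct trial pairs only and
    measure response reliability.  ``shuffled`` pairing requires a seed.
    Trial pairs whose rank vector is constant (e.g. fully censored) are
    skipped with a warning.
    """
    if pairing not in ("matched", "all-pairs", "shuffled"):
        raise ValueError(f"unknown pairing {pairing!r}")
    if pairing == "shuffled" and seed is None:
        raise ValueError("shuffled pairing requires a seed")
    if rm.n_trials < 2:
        raise ValueError("need at least 2 trials per stimulus")

    z = _normalized_rank_tensor(rm)  # (U, S, T)
    S, T = z.shape[1], z.shape[2]
    rng = np.random.default_rng(seed) if pairing == "shuffled" else None
    mean = np.full((S, S), np.nan)
    sem = np.full((S, S), np.nan)
    n_bad = 0
    for i in range(S):
        for j in range(i, S):
            M = z[:, i, :].T @ z[:, j, :]  # (T, T) trial-pair rho
            if pairing == "matched":
                vals = np.diag(M) if i != j else M[np.triu_indices(T, k=1)]
            elif pairing == "all-pairs":
                vals = M.ravel() if i != j else M[~np.eye(T, dtype=bool)]
            else:  # shuffled
                perm = rng.permutation(T)
                keep = np.ones(T, dtype=bool) if i != j else perm != np.arange(T)
                vals = M[np.arange(T)[keep], perm[keep]]
            ok = ~np.isnan(vals)
            n_bad += int((~ok).sum())
            if ok.sum():
                mean[i, j] = mean[j, i] = vals[ok].mean()
                if ok.sum() > 1:
                    sem[i, j] = sem[j, i] = vals[ok].std(ddof=1) / np.sqrt(ok.sum())
    if n_bad:
        warnings.warn(f"{n_bad} trial pairs with constant rank vectors were skipped")
    return SpearmanResult(mean=mean, sem=sem, stimulus_ids=list(rm.stimulus_ids), pairing=pairing)


def phase_tuning_curve(
    result: SpearmanResult,
    ensemble: StimulusEnsemble,
    reference_phase: float = 0.0,
) -> pd.DataFrame:
    """ρ(reference phase, φ) per spatial frequency, for the other phases.

    Returns a tidy frame (frequency, phase_deg, rho_mean, rho_sem).
    """
    rows = []
    phases = ensemble.phases_deg
    for fi, freq in enumerate(ensemble.frequencies):
        stim_ids = ensemble.stimuli_for_frequency(fi)
        if not all(s in result.stimulus_ids for s in stim_ids):
            continue
        ref = stim_ids[phases.index(reference_phase)]
        for ph, sid in zip(phases, stim_ids):
            if ph == reference_phase:
                continue
            ii = result.stimulus_ids.index(ref)
            jj = result.stimulus_ids.index(sid)
            rows.append(
                {
                    "frequency": freq,
                    "phase_deg": ph,
                    "rho_mean": result.mean[ii, jj],
                    "rho_sem": result.sem[ii, jj],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ShuffleLossResult:
    """Per-frequency trial-shuffling loss of WFS phase tuning.

    Δ = mean ρ(0°, 45°) − mean ρ(0°, 180°) under matched pairing;
    Δs is the same quantity under random trial re-pairing; the relative
    loss is (Δ − Δs)/Δ, NaN (flagged undefined) when Δ = 0.
    """

    table: pd.DataFrame  # frequency, delta, delta_shuffled, delta_shuffled_sem,
    # relative_loss, undefined

    def relative_loss(self, frequency: float) -> float:
        row = self.table[self.table["frequency"] == frequency]
        return float(row["relative_loss"].iloc[0])


def shuffle_loss(
    rm: ResponseMatrix,
    ensemble: StimulusEnsemble,
    seed: int,
    n_shuffles: int = 100,
    probe_phase: float = 45.0,
    anti_phase: float = 180.0,
) -> ShuffleLossResult:
    """Quantify the tuning loss caused by destroying trial pairing.

    For each spatial frequency, Δ contrasts the WFS similarity between
    nearby phases (0° vs ``probe_phase``) against opposite phases (0° vs
    ``anti_phase``); Δs recomputes it after randomly re-pairing trials
    within each stimulus, averaged over ``n_shuffles`` permutations.
    """
    z = _normalized_rank_tensor(rm)
    T = z.shape[2]
    phases = list(ensemble.phases_deg)
    rng = np.random.default_rng(seed)
    rows = []
    for fi, freq in enumerate(ensemble.frequencies):
        stim_ids = ensemble.stimuli_for_frequency(fi)
        if not all(s in rm.stimulus_ids for s in stim_ids):
            continue
        loc = {ph: rm.stimulus_ids.index(stim_ids[phases.index(ph)]) for ph in (0.0, probe_phase, anti_phase)}
        M_probe = z[:, loc[0.0], :].T @ z[:, loc[probe_phase], :]
        M_anti = z[:, loc[0.0], :].T @ z[:, loc[anti_phase], :]
        diag = np.arange(T)
        delta = float(np.nanmean(np.diag(M_probe)) - np.nanmean(np.diag(M_anti)))
        ds = np.empty(n_shuffles)
        for k in range(n_shuffles):
            p1, p2 = rng.permutation(T), rng.permutation(T)
            ds[k] = np.nanmean(M_probe[diag, p1]) - np.nanmean(M_anti[diag, p2])
        delta_s = float(ds.mean())
        undefined = delta == 0
        rows.append(
            {
                "frequency": freq,
                "delta": delta,
                "delta_shuffled": delta_s,
                "delta_shuffled_sem": float(ds.std(ddof=1) / np.sqrt(n_shuffles))
                if n_shuffles > 1
                else np.nan,
                "relative_loss": np.nan if undefined else (delta - delta_s) / delta,
                "undefined": undefined,
            }
        )
    return ShuffleLossResult(table=pd.DataFrame(rows))
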