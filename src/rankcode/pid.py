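"""Two-variable partial information decomposition (PID) of spike counts.

The Williams–Beer PID splits the mutual information that a pair of
responses (R1, R2) carries about a stimulus S into four non-negative
parts:

* redundancy — the expectation over p(s) of the *minimum* specific
  information min_i I(S=s; R_i), where the specific information is the
  Kullback–Leibler divergence D_KL( R_i | S=s ‖ R_i );
* unique information of each variable, Unq_i = I(S;R_i) − Red;
* synergy, Syn = I(S;R1,R2) − Unq1 − Unq2 − Red.

The redundancy–synergy index RSI = I(S;R1,R2) − I(S;R1) − I(S;R2) equals
Syn − Red.  All quantities are in bits (log base 2) with 0·log 0 ≡ 0.

Plug-in estimates from finite trial counts are biased upward; the
subsampling correction re-estimates each underlying quantity (every
D_KL(R_i|S=s ‖ R_i), I(S;R_i) and I(S;R1,R2)) on random partitions of the
trials into k = 1, 2, … subsets, fits a second-degree polynomial in k, and
takes the k → 0 intercept as the infinite-data extrapolation; the PID is
then recomposed from the corrected quantities.  Corrected components may
violate non-negativity and are flagged rather than clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .features import ResponseMatrix
from .stimuli import StimulusEnsemble

__all__ = [
    "JointResponseTable",
    "estimate_joint",
    "PIDResult",
    "pid_pair",
    "delta_i_independent",
    "bias_correct",
    "pid_pair_bias_corrected",
    "shuffle_within_stimulus",
    "population_pid_summary",
]


def _xlogy2(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """p * log2(q) with the 0·log0 = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    mask = p > 0
    out[mask] = p[mask] * np.log2(q[mask])
    return out


@dataclass
class JointResponseTable:
    """Empirical joint distribution p(s, r1, r2) for one unit pair.

    ``joint`` has shape (n_stimuli, len(alphabet1), len(alphabet2)) and
    sums to 1.
    """

    joint: np.ndarray
    alphabet1: np.ndarray
    alphabet2: np.ndarray
    stimulus_values: np.ndarray
    n_trials: int

    @property
    def p_s(self) -> np.ndarray:
        return self.joint.sum(axis=(1, 2))

    @property
    def p_r1(self) -> np.ndarray:
        return self.joint.sum(axis=(0, 2))

    @property
    def p_r2(self) -> np.ndarray:
        return self.joint.sum(axis=(0, 1))

    def validate(self, atol: float = 1e-12) -> None:
        if abs(self.joint.sum() - 1.0) > atol:
            raise ValueError("joint distribution does not sum to 1")
        if (self.joint < 0).any():
            raise ValueError("negative probability")


def estimate_joint(r1, r2, s, max_value: int | None = None) -> JointResponseTable:
    """Plug-in joint response table from per-trial counts and stimulus labels.

    ``max_value`` optionally caps the response alphabets (counts above the
    cap are clipped), bounding the table size for high-rate units.
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    s = np.asarray(s)
    if not (r1.shape == r2.shape == s.shape):
        raise ValueError("r1, r2, s must be aligned 1-D arrays")
    if s.size == 0:
        raise ValueError("empty stimulus class: no trials")
    if max_value is not None:
        r1 = np.minimum(r1, max_value)
        r2 = np.minimum(r2, max_value)
    svals, sidx = np.unique(s, return_inverse=True)
    a1, i1 = np.unique(r1, return_inverse=True)
    a2, i2 = np.unique(r2, return_inverse=True)
    counts = np.zeros((svals.size, a1.size, a2.size))
    np.add.at(counts, (sidx, i1, i2), 1.0)
    class_n = counts.sum(axis=(1, 2))
    if (class_n == 0).any():
        raise ValueError("empty stimulus class")
    return JointResponseTable(
        joint=counts / counts.sum(),
        alphabet1=a1,
        alphabet2=a2,
        stimulus_values=svals,
        n_trials=int(r1.size),
    )


def _mutual_information(p_xy: np.ndarray) -> float:
    """I(X;Y) in bits from a joint table p(x, y) (first axis = X)."""
    px = p_xy.sum(axis=1, keepdims=True)
    py = p_xy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(p_xy > 0, p_xy / (px * py), 1.0)
    return float(np.sum(_xlogy2(p_xy, ratio)))


def _components(table: JointResponseTable):
    """(specific (K,2), I1, I2, I12) plug-in values in bits."""
    P = table.joint
    p_s = table.p_s
    p_sr1 = P.sum(axis=2)  # (K, A1)
    p_sr2 = P.sum(axis=1)  # (K, A2)
    i1 = _mutual_information(p_sr1)
    i2 = _mutual_information(p_sr2)
    i12 = _mutual_information(P.reshape(P.shape[0], -1))

    K = p_s.size
    specific = np.zeros((K, 2))
    p_r1 = table.p_r1
    p_r2 = table.p_r2
    for k in range(K):
        for vi, (p_sr, p_r) in enumerate(((p_sr1, p_r1), (p_sr2, p_r2))):
            cond = p_sr[k] / p_s[k]
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(cond > 0, cond / p_r, 1.0)
            specific[k, vi] = np.sum(_xlogy2(cond, ratio))
    return specific, i1, i2, i12


def _recompose(p_s, specific, i1, i2, i12) -> dict:
    red = float(np.sum(p_s * specific.min(axis=1)))
    unq1 = i1 - red
    unq2 = i2 - red
    syn = i12 - unq1 - unq2 - red
    return {
        "i1": i1,
        "i2": i2,
        "i12": i12,
        "red": red,
        "unq1": unq1,
        "unq2": unq2,
        "syn": syn,
        "rsi": i12 - i1 - i2,
    }


@dataclass
class PIDResult:
    """Plug-in (and optionally bias-corrected) PID for one pair, in bits."""

    i1: float
    i2: float
    i12: float
    specific: np.ndarray  # (n_stimuli, 2) specific informations
    red: float
    unq1: float
    unq2: float
    syn: float
    rsi: float
    corrected: dict | None = None  # same keys as the raw components
    diagnostics: dict = field(default_factory=dict)  # k -> per-quantity estimates

    @property
    def corrected_has_negative(self) -> bool:
        if self.corrected is None:
            return False
        return any(self.corrected[k] < 0 for k in ("red", "unq1", "unq2", "syn"))

    @property
    def synergy_fraction(self) -> float:
        """Syn / I(S;R1,R2): share of the pair information that is synergistic."""
        return self.syn / self.i12 if self.i12 > 0 else float("nan")


def pid_pair(table: JointResponseTable) -> PIDResult:
    """Williams–Beer PID of one joint response table (plug-in)."""
    table.validate()
    specific, i1, i2, i12 = _components(table)
    parts = _recompose(table.p_s, specific, i1, i2, i12)
    return PIDResult(specific=specific, **parts)


def delta_i_independent(table: JointResponseTable) -> float:
    """Information lost by ignoring within-stimulus correlations, in bits.

    I(S;R1,R2) minus the same mutual information recomputed after
    replacing p(r1, r2 | s) with p(r1|s)·p(r2|s) (marginals preserved).
    Zero whenever responses are conditionally independent; may take either
    sign in general.
    """
    table.validate()
    p_s = table.p_s
    p_sr1 = table.joint.sum(axis=2)
    p_sr2 = table.joint.sum(axis=1)
    cond1 = p_sr1 / p_s[:, None]
    cond2 = p_sr2 / p_s[:, None]
    p_ind = p_s[:, None, None] * cond1[:, :, None] * cond2[:, None, :]
    i12 = _mutual_information(table.joint.reshape(p_s.size, -1))
    i_ind = _mutual_information(p_ind.reshape(p_s.size, -1))
    return i12 - i_ind


def _stratified_partitions(labels: np.ndarray, k: int, rng: np.random.Generator):
    """Split trial indices into k disjoint subsets, each containing ≥1
    trial of every stimulus class."""
    svals, counts = np.unique(labels, return_counts=True)
    short = svals[counts < k]
    if short.size:
        raise ValueError(
            f"stimulus class {short[0]!r} has fewer than {k} trials; "
            "cannot partition"
        )
    parts: list[list[int]] = [[] for _ in range(k)]
    for sv in svals:
        idx = np.flatnonzero(labels == sv)
        idx = rng.permutation(idx)
        for j, chunk in enumerate(np.array_split(idx, k)):
            parts[j].extend(chunk.tolist())
    return [np.asarray(sorted(p)) for p in parts]


def bias_correct(
    estimate_fn,
    labels,
    max_partitions: int = 4,
    seed: int | None = None,
    n_repeats: int = 10,
) -> tuple[float, dict[int, float]]:
    """Subsampling-extrapolation bias correction of one scalar estimator.

    ``estimate_fn(indices)`` must return the plug-in estimate computed on
    the given trial subset.  The estimate is computed on the full data
    (k=1) and, for k = 2..max_partitions, averaged over the k disjoint
    stratified random partitions of ``n_repeats`` independent random
    partitionings (the partition assignment is auxiliary randomness;
    averaging over repeats removes its contribution to the estimator
    variance).  A degree-2 polynomial in k is least-squares fit; its value
    at k = 0 is the corrected estimate.
    Returns (corrected, {k: mean estimate}).
    """
    if max_partitions < 2:
        raise ValueError("max_partitions must be >= 2")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    ks = np.arange(1, max_partitions + 1)
    means = {}
    for k in ks:
        if k == 1:
            means[1] = float(estimate_fn(np.arange(labels.size)))
        else:
            ests = []
            for _ in range(n_repeats):
                parts = _stratified_partitions(labels, int(k), rng)
                ests.append(np.mean([estimate_fn(p) for p in parts]))
            means[int(k)] = float(np.mean(ests))
    y = np.array([means[int(k)] for k in ks])
    deg = min(2, ks.size - 1)
    coef = np.polyfit(ks, y, deg)
    return float(np.polyval(coef, 0.0)), means


def pid_pair_bias_corrected(
    r1,
    r2,
    s,
    max_partitions: int = 4,
    seed: int | None = None,
    max_value: int | None = None,
    n_repeats: int = 10,
) -> PIDResult:
    """PID with subsampling bias correction of every underlying quantity.

    Each specific information D_KL(R_i|S=s ‖ R_i), I(S;R_i) and
    I(S;R1,R2) is extrapolated separately (sharing the same random
    partitions, averaged over ``n_repeats`` random partitionings per k),
    then the decomposition is recomposed from the corrected quantities
    using the full-data p(s).
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    s = np.asarray(s)
    full = estimate_joint(r1, r2, s, max_value=max_value)
    raw = pid_pair(full)
    K = full.stimulus_values.size

    def all_quantities(idx) -> np.ndarray:
        tab = estimate_joint(r1[idx], r2[idx], s[idx], max_value=max_value)
        if tab.stimulus_values.size != K:
            raise ValueError("subset lost a stimulus class")
        spec, i1, i2, i12 = _components(tab)
        return np.concatenate([spec.ravel(), [i1, i2, i12]])

    rng = np.random.default_rng(seed)
    ks = np.arange(1, max_partitions + 1)
    means = {}
    for k in ks:
        if k == 1:
            means[1] = all_quantities(np.arange(s.size))
        else:
            ests = []
            for _ in range(n_repeats):
                parts = _stratified_partitions(s, int(k), rng)
                ests.append(np.mean([all_quantities(p) for p in parts], axis=0))
            means[int(k)] = np.mean(ests, axis=0)
    Y = np.stack([means[int(k)] for k in ks])  # (n_k, n_quantities)
    deg = min(2, ks.size - 1)
    coef = np.polyfit(ks, Y, deg)  # per-column fits
    corrected_q = np.polyval(coef, 0.0)
    spec_c = corrected_q[: 2 * K].reshape(K, 2)
    i1_c, i2_c, i12_c = corrected_q[2 * K :]
    parts_c = _recompose(full.p_s, spec_c, float(i1_c), float(i2_c), float(i12_c))
    parts_c["specific"] = spec_c
    raw.corrected = parts_c
    raw.diagnostics = {k: v for k, v in means.items()}
    return raw


def shuffle_within_stimulus(r1, r2, s, seed: int):
    """Permute the second variable's trials independently within each
    stimulus class, destroying noise correlations while preserving all
    per-stimulus marginals.  Returns (r1, r2_shuffled)."""
    r1 = np.asarray(r1)
    r2 = np.asarray(r2).copy()
    s = np.asarray(s)
    rng = np.random.default_rng(seed)
    for sv in np.unique(s):
        idx = np.flatnonzero(s == sv)
        r2[idx] = r2[rng.permutation(idx)]
    return r1, r2


def population_pid_summary(
    counts: ResponseMatrix,
    ensemble: StimulusEnsemble | None = None,
    pairs=None,
    bias_correction: bool = False,
    max_partitions: int = 4,
    seed: int | None = None,
    max_value: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PID for every unit pair (unique up to ordering), per spatial frequency.

    Returns (per-pair tidy frame, per-frequency aggregate with mean and
    SEM over pairs of redundancy / unique / synergy).
    """
    if counts.kind != "count":
        raise ValueError("population_pid_summary needs a count ResponseMatrix")
    if ensemble is not None:
        groups = [
            (freq, ensemble.stimuli_for_frequency(fi))
            for fi, freq in enumerate(ensemble.frequencies)
            if all(sid in counts.stimulus_ids for sid in ensemble.stimuli_for_frequency(fi))
        ]
    else:
        groups = [(np.nan, list(counts.stimulus_ids))]
    if pairs is None:
        pairs = list(combinations(range(counts.n_units), 2))

    rows = []
    for freq, stim_ids in groups:
        cols = [counts.stimulus_ids.index(sid) for sid in stim_ids]
        vals = counts.values[:, cols, :]  # (U, S, T)
        T = vals.shape[2]
        labels = np.repeat(np.arange(len(cols)), T)
        for i, j in pairs:
            x1 = vals[i].ravel()
            x2 = vals[j].ravel()
            if bias_correction:
                res = pid_pair_bias_corrected(
                    x1, x2, labels, max_partitions=max_partitions, seed=seed, max_value=max_value
                )
            else:
                res = pid_pair(estimate_joint(x1, x2, labels, max_value=max_value))
            row = {
                "unit_i": counts.unit_ids[i],
                "unit_j": counts.unit_ids[j],
                "frequency": freq,
                "i1": res.i1,
                "i2": res.i2,
                "i12": res.i12,
                "red": res.red,
                "unq1": res.unq1,
                "unq2": res.unq2,
                "syn": res.syn,
                "rsi": res.rsi,
                "n_trials": x1.size,
            }
            if res.corrected is not None:
                for key in ("red", "unq1", "unq2", "syn", "rsi", "i12"):
                    row[f"{key}_bc"] = res.corrected[key]
            rows.append(row)
    per_pair = pd.DataFrame(rows)

    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    agg = per_pair.groupby("frequency", dropna=False).agg(
        red_mean=("red", "mean"),
        red_sem=("red", sem),
        unq1_mean=("unq1", "mean"),
        unq2_mean=("unq2", "mean"),
        syn_mean=("syn", "mean"),
        syn_sem=("syn", sem),
        rsi_mean=("rsi", "mean"),
        n_pairs=("red", "size"),
    )
    return per_pair, agg.reset_index()
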