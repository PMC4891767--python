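"""Configuration-driven orchestration of the full analysis.

A single YAML config describes one reproducible run: simulate (or load) a
spike dataset, extract features, then any of the rank-similarity, PID and
decoding analyses.  All outputs are tidy CSV/TSV tables plus a
``manifest.json`` recording the config, per-stage seeds and SHA-256
checksums of every file written.  The manifest is written last: outputs
without a manifest are stale (a failed or interrupted run).

Per-stage seeds are derived from the global seed as
``(seed XOR crc32(stage_name)) mod 2^31`` so a stage rerun in isolation
reproduces its part of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import decode as _decode
from . import io as _io
from .features import extract_counts, extract_latencies
from .pid import population_pid_summary
from .ranksim import phase_tuning_curve, shuffle_loss, wfs_distance_matrix
from .simulate import default_population, simulate_population
from .stimuli import make_grating_ensemble

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "PipelineError"]

logger = logging.getLogger("rankcode")

DEFAULT_STAGES = ["simulate", "features", "rankdist", "pid", "decode"]


class PipelineError(RuntimeError):
    pass


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % 2**31


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    seed: int = 0
    output_dir: str = "rankcode_out"
    stages: list = field(default_factory=lambda: list(DEFAULT_STAGES))
    input_spikes: str | None = None  # skip simulation, load this table instead
    ensemble: dict = field(default_factory=dict)
    population: dict = field(default_factory=lambda: {"n_units": 50})
    rankdist: dict = field(default_factory=dict)
    pid: dict = field(default_factory=dict)
    decode: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": self.output_dir,
            "stages": list(self.stages),
            "input_spikes": self.input_spikes,
            "ensemble": dict(self.ensemble),
            "population": dict(self.population),
            "rankdist": dict(self.rankdist),
            "pid": dict(self.pid),
            "decode": dict(self.decode),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest dict.  A stage failure aborts with the failing
    stage named; in that case no manifest is written, marking any partial
    outputs as stale.
    """
    out = Path(config.output_dir)
    if config.input_spikes is not None and not Path(config.input_spikes).exists():
        raise FileNotFoundError(f"input_spikes path does not exist: {config.input_spikes}")
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest_path.unlink()  # absence of a manifest marks outputs stale

    written: list[Path] = []
    seeds = {stage: stage_seed(config.seed, stage) for stage in config.stages}
    state: dict = {}

    def _write_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    stage_fns = {
        "simulate": _stage_simulate,
        "features": _stage_features,
        "rankdist": _stage_rankdist,
        "pid": _stage_pid,
        "decode": _stage_decode,
    }
    for stage in config.stages:
        if stage not in stage_fns:
            raise PipelineError(f"unknown stage {stage!r}")
        logger.info("running stage %s (seed %d)", stage, seeds[stage])
        try:
            stage_fns[stage](config, seeds[stage], out, state, written, _write_df)
        except Exception as e:  # noqa: BLE001 - reported with stage context
            raise PipelineError(f"stage {stage!r} failed: {e}") from e

    manifest = {
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in written},
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _get_dataset(config: RunConfig, out: Path, state: dict):
    if "dataset" not in state:
        if config.input_spikes is not None:
            state["dataset"] = _io.read_spike_table(config.input_spikes)
        else:
            path = out / "spikes.tsv"
            if not path.exists():
                raise PipelineError("no dataset: run the simulate stage or set input_spikes")
            state["dataset"] = _io.read_spike_table(path)
    return state["dataset"]


def _stage_simulate(config, seed, out, state, written, _write_df):
    ens = make_grating_ensemble(
        bar_widths=config.ensemble.get("bar_widths", [1600, 800, 400, 200]),
        microns_per_degree=config.ensemble.get("microns_per_degree", 30.0),
        n_phases=config.ensemble.get("n_phases", 8),
        flash_duration=config.ensemble.get("flash_duration", 0.5),
        gray_duration=config.ensemble.get("gray_duration", 1.0),
        n_trials=config.ensemble.get("n_trials", 30),
    )
    pop = dict(config.population)
    n_units = pop.pop("n_units", 50)
    params = default_population(n_units, seed=seed, **pop)
    ds = simulate_population(params, ens, seed=seed)
    path = out / "spikes.tsv"
    _io.write_spike_table(ds, path)
    written.append(path)
    state["dataset"] = ds


def _stage_features(config, seed, out, state, written, _write_df):
    ds = _get_dataset(config, out, state)
    state["latency"] = extract_latencies(ds)
    state["counts"] = extract_counts(ds)
    _write_df(state["latency"].to_frame(), "latency.csv")
    _write_df(state["counts"].to_frame(), "counts.csv")


def _stage_rankdist(config, seed, out, state, written, _write_df):
    ds = _get_dataset(config, out, state)
    rm = state.get("latency") or extract_latencies(ds)
    opts = config.rankdist
    result = wfs_distance_matrix(rm, pairing=opts.get("pairing", "matched"), seed=seed)
    _write_df(result.to_frame().reset_index(names="stimulus"), "rho_matrix.csv")
    _write_df(phase_tuning_curve(result, ds.ensemble), "tuning_curve.csv")
    loss = shuffle_loss(rm, ds.ensemble, seed=seed, n_shuffles=opts.get("n_shuffles", 100))
    _write_df(loss.table, "shuffle_loss.csv")


def _stage_pid(config, seed, out, state, written, _write_df):
    ds = _get_dataset(config, out, state)
    counts = state.get("counts") or extract_counts(ds)
    opts = config.pid
    max_units = opts.get("max_units")
    if max_units is not None and counts.n_units > max_units:
        counts = counts.select_units(counts.unit_ids[:max_units])
    per_pair, summary = population_pid_summary(
        counts,
        ensemble=ds.ensemble,
        bias_correction=opts.get("bias_correction", False),
        max_partitions=opts.get("max_partitions", 4),
        seed=seed,
        max_value=opts.get("max_value"),
    )
    _write_df(per_pair, "pid_pairs.csv")
    _write_df(summary, "pid_summary.csv")


def _stage_decode(config, seed, out, state, written, _write_df):
    ds = _get_dataset(config, out, state)
    opts = config.decode
    freq_index = opts.get("frequency_index", 1)
    stim_ids = ds.ensemble.stimuli_for_frequency(freq_index)
    codes = opts.get("codes", list(_decode.CODES))
    rows = []
    for code in codes:
        cfg = _decode.DecoderConfig(
            code=code,
            window=opts.get("window", 0.5),
            n_configurations=opts.get("n_configurations", 20),
            split=opts.get("split", "half"),
            seed=seed,
        )
        rm = state.get("latency") if code in ("latency", "roc_latency") else state.get("counts")
        if rm is None:
            rm = (
                extract_latencies(ds)
                if code in ("latency", "roc_latency")
                else extract_counts(ds)
            )
        cm = _decode.run_task(rm.select_stimuli(stim_ids), cfg)
        _write_df(cm.to_frame().reset_index(names="decoded"), f"confusion_{code}.csv")
        rows.append({"code": code, "fraction_correct": cm.fraction_correct})
    _write_df(pd.DataFrame(rows), "decode_summary.csv")
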