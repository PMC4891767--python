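"""Reading and writing spike datasets.

Two equivalent on-disk layouts:

* a tab-separated text table ``unit_id  stimulus_id  trial_id  spike_time_s``
  with ``#``-prefixed header lines carrying the ensemble and unit metadata
  as JSON, and
* an HDF5 mirror with one dataset per trial under
  ``/spikes/u{unit}/s{stimulus}/t{trial}``.

Both round-trip losslessly: empty trials are materialized as empty arrays
on read (every (unit, stimulus, trial) key exists), unknown header keys and
extra columns are preserved as dataset metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .simulate import SpikeDataset, UnitMetadata
from .stimuli import StimulusEnsemble

__all__ = ["read_spike_table", "write_spike_table", "read_hdf5", "write_hdf5"]

_MAGIC = "rankcode-spike-table v1"
_COLUMNS = ["unit_id", "stimulus_id", "trial_id", "spike_time_s"]


class SpikeTableParseError(ValueError):
    """Malformed spike table; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def write_spike_table(dataset: SpikeDataset, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# {_MAGIC}\n")
        fh.write(f"# ensemble={json.dumps(dataset.ensemble.to_dict())}\n")
        fh.write(f"# units={json.dumps([u.to_dict() for u in dataset.units])}\n")
        extra = getattr(dataset, "metadata", None)
        if extra:
            for k, v in extra.items():
                fh.write(f"# {k}={json.dumps(v)}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for key in sorted(dataset.trains):
            u, s, t = key
            for time in dataset.trains[key]:
                fh.write(f"{u}\t{s}\t{t}\t{float(time)!r}\n")


def read_spike_table(path) -> SpikeDataset:
    path = Path(path)
    ensemble = None
    units = None
    metadata: dict = {}
    rows: list[tuple[int, int, int, float]] = []
    extra_columns: dict[str, list] = {}
    header_cols: list[str] | None = None

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body == _MAGIC:
                    continue
                if "=" in body:
                    key, _, val = body.partition("=")
                    key = key.strip()
                    try:
                        parsed = json.loads(val)
                    except json.JSONDecodeError as e:
                        raise SpikeTableParseError(f"bad JSON in header key {key!r}: {e}", lineno)
                    if key == "ensemble":
                        ensemble = StimulusEnsemble.from_dict(parsed)
                    elif key == "units":
                        units = [UnitMetadata.from_dict(d) for d in parsed]
                    else:
                        metadata[key] = parsed
                continue
            if header_cols is None:
                header_cols = line.split("\t")
                if header_cols[:4] != _COLUMNS:
                    raise SpikeTableParseError(
                        f"expected columns {_COLUMNS}, got {header_cols[:4]}", lineno
                    )
                for name in header_cols[4:]:
                    extra_columns[name] = []
                continue
            parts = line.split("\t")
            if len(parts) != len(header_cols):
                raise SpikeTableParseError(
                    f"expected {len(header_cols)} fields, got {len(parts)}", lineno
                )
            try:
                u, s, t = int(parts[0]), int(parts[1]), int(parts[2])
                time = float(parts[3])
            except ValueError as e:
                raise SpikeTableParseError(str(e), lineno)
            if time < 0:
                raise SpikeTableParseError(f"negative spike time {time}", lineno)
            rows.append((u, s, t, time))
            for name, val in zip(header_cols[4:], parts[4:]):
                extra_columns[name].append(val)

    if ensemble is None or units is None:
        raise SpikeTableParseError("missing ensemble/units header metadata", 0)
    if extra_columns:
        metadata["extra_columns"] = extra_columns

    trains: dict[tuple[int, int, int], list] = {
        (u.unit_id, s, t): []
        for u in units
        for s in range(ensemble.n_stimuli)
        for t in range(ensemble.n_trials)
    }
    for u, s, t, time in rows:
        key = (u, s, t)
        if key not in trains:
            raise SpikeTableParseError(f"row references unknown key {key}", 0)
        trains[key].append(time)
    arrays = {k: np.asarray(sorted(v), dtype=float) for k, v in trains.items()}
    ds = SpikeDataset(ensemble=ensemble, units=units, trains=arrays)
    ds.metadata = metadata  # type: ignore[attr-defined]
    return ds


def write_hdf5(dataset: SpikeDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _MAGIC
        f.attrs["ensemble"] = json.dumps(dataset.ensemble.to_dict())
        f.attrs["units"] = json.dumps([u.to_dict() for u in dataset.units])
        extra = getattr(dataset, "metadata", None)
        if extra:
            f.attrs["metadata"] = json.dumps(extra)
        grp = f.create_group("spikes")
        for (u, s, t), arr in dataset.trains.items():
            grp.create_dataset(f"u{u}/s{s}/t{t}", data=arr)


def read_hdf5(path) -> SpikeDataset:
    with h5py.File(path, "r") as f:
        ensemble = StimulusEnsemble.from_dict(json.loads(f.attrs["ensemble"]))
        units = [UnitMetadata.from_dict(d) for d in json.loads(f.attrs["units"])]
        metadata = json.loads(f.attrs["metadata"]) if "metadata" in f.attrs else {}
        trains = {}
        grp = f["spikes"]
        for u in units:
            for s in range(ensemble.n_stimuli):
                for t in range(ensemble.n_trials):
                    key = f"u{u.unit_id}/s{s}/t{t}"
                    trains[(u.unit_id, s, t)] = (
                        np.asarray(grp[key][...], dtype=float)
                        if key in grp
                        else np.empty(0)
                    )
    ds = SpikeDataset(ensemble=ensemble, units=units, trains=trains)
    ds.metadata = metadata  # type: ignore[attr-defined]
    return ds
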