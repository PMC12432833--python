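"""Readers and writers for recordings, configuration, and result tables.

Recordings use the standard SNIRF (HDF5) container as the canonical on-disk
form, with a plain delimited fallback (``.csv`` intensity matrix plus a
``.events.tsv`` sidecar) for dependency-light, text-only round trips.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import (
    EventBlock,
    Montage,
    RunRecording,
    SearchSpace,
    ValidationError,
)

__all__ = [
    "load_recording",
    "write_recording",
    "load_montage",
    "write_montage",
    "load_search_spaces",
    "adult_search_spaces",
    "toddler_search_spaces",
    "write_table",
    "read_table",
    "BLOCK_TABLE_COLUMNS",
]

#: Documented column order of the block-response table (see blocks module).
BLOCK_TABLE_COLUMNS = (
    "subject_id",
    "task_id",
    "run_index",
    "channel_id",
    "block_index",
    "condition",
    "mean_hbo",
    "mean_hbr",
)


class FormatError(ValueError):
    """Raised when an on-disk artifact cannot be interpreted."""


# ---------------------------------------------------------------------------
# SNIRF
# ---------------------------------------------------------------------------

def _write_snirf(rec: RunRecording, path: Path) -> None:
    m = rec.montage
    nt, nc, nw = rec.intensity.shape
    flat = rec.intensity.reshape(nt, nc * nw)  # channel-major, wavelength fastest
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=str(rec.subject_id))
        meta.create_dataset("MeasurementDate", data="unknown")
        meta.create_dataset("MeasurementTime", data="unknown")
        meta.create_dataset("LengthUnit", data="mm")
        meta.create_dataset("TimeUnit", data="s")
        meta.create_dataset("FrequencyUnit", data="Hz")
        meta.create_dataset("TaskID", data=str(rec.task_id))
        meta.create_dataset("RunIndex", data=int(rec.run_index))
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times)
        for i in range(nc * nw):
            ch, wl = divmod(i, nw)
            s, d = m.channels[ch]
            ml = data.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=s + 1)
            ml.create_dataset("detectorIndex", data=d + 1)
            ml.create_dataset("wavelengthIndex", data=wl + 1)
            ml.create_dataset("dataType", data=1)
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(m.wavelengths_nm))
        probe.create_dataset("sourcePos3D", data=m.source_positions)
        probe.create_dataset("detectorPos3D", data=m.detector_positions)
        probe.create_dataset("channelIds", data=np.asarray(m.channel_ids))
        conditions = sorted({ev.condition for ev in rec.events})
        for j, cond in enumerate(conditions):
            rows = [[ev.onset_s, ev.duration_s, 1.0] for ev in rec.events if ev.condition == cond]
            stim = nirs.create_group(f"stim{j + 1}")
            stim.create_dataset("name", data=cond)
            stim.create_dataset("data", data=np.asarray(rows, dtype=float))


def _read_str(ds) -> str:
    v = ds[()]
    if isinstance(v, bytes):
        return v.decode()
    return str(v)


def _read_snirf(path: Path, montage: Montage) -> RunRecording:
    with h5py.File(path, "r") as f:
        nirs = f["nirs"]
        data = nirs["data1"]
        flat = np.asarray(data["dataTimeSeries"])
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe"]["wavelengths"]))
        if wavelengths != montage.wavelengths_nm:
            raise FormatError(
                f"file wavelengths {wavelengths} do not match montage {montage.wavelengths_nm}"
            )
        nc, nw = montage.n_channels, montage.n_wavelengths
        if flat.shape[1] != nc * nw:
            raise FormatError(
                f"{flat.shape[1]} measurements inconsistent with montage ({nc} x {nw})"
            )
        # Verify the measurement list matches the montage's channel order.
        for i in range(nc * nw):
            ml = data[f"measurementList{i + 1}"]
            ch, wl = divmod(i, nw)
            s, d = montage.channels[ch]
            if int(ml["sourceIndex"][()]) != s + 1 or int(ml["detectorIndex"][()]) != d + 1:
                raise FormatError(f"measurementList{i + 1} optodes disagree with montage")
            if int(ml["wavelengthIndex"][()]) != wl + 1:
                raise FormatError(f"measurementList{i + 1} wavelength index disagrees with montage")
        events = []
        j = 1
        while f"stim{j}" in nirs:
            stim = nirs[f"stim{j}"]
            name = _read_str(stim["name"])
            for onset, dur, _amp in np.atleast_2d(np.asarray(stim["data"], dtype=float)):
                events.append(EventBlock(name, float(onset), float(dur)))
            j += 1
        events.sort(key=lambda ev: ev.onset_s)
        meta = nirs["metaDataTags"]
        subject = _read_str(meta["SubjectID"]) if "SubjectID" in meta else "unknown"
        task = _read_str(meta["TaskID"]) if "TaskID" in meta else "unknown"
        run = int(meta["RunIndex"][()]) if "RunIndex" in meta else 1
    intensity = flat.reshape(flat.shape[0], nc, nw)
    return RunRecording(subject, task, run, intensity, events, montage)


# ---------------------------------------------------------------------------
# Delimited fallback
# ---------------------------------------------------------------------------

def _events_sidecar(path: Path) -> Path:
    return path.with_suffix(".events.tsv")


def _write_csv(rec: RunRecording, path: Path) -> None:
    m = rec.montage
    nt, nc, nw = rec.intensity.shape
    cols = [
        f"ch{m.channel_ids[c]}_wl{m.wavelengths_nm[w]:g}" for c in range(nc) for w in range(nw)
    ]
    df = pd.DataFrame(rec.intensity.reshape(nt, nc * nw), columns=cols)
    df.insert(0, "time_s", rec.times)
    header = (
        f"# subject_id={rec.subject_id} task_id={rec.task_id} run_index={rec.run_index} "
        f"fs_hz={m.sampling_rate_hz!r}\n"
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)
    ev = pd.DataFrame(
        [(e.condition, e.onset_s, e.duration_s) for e in rec.events],
        columns=["condition", "onset_s", "duration_s"],
    )
    ev.to_csv(_events_sidecar(path), sep="\t", index=False)


def _read_csv(path: Path, montage: Montage) -> RunRecording:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path} is missing its metadata header line")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh, float_precision="round_trip")
    nc, nw = montage.n_channels, montage.n_wavelengths
    expected = [
        f"ch{montage.channel_ids[c]}_wl{montage.wavelengths_nm[w]:g}"
        for c in range(nc)
        for w in range(nw)
    ]
    if list(df.columns[1:]) != expected:
        raise FormatError(f"{path}: column layout does not match the montage")
    intensity = df[expected].to_numpy().reshape(len(df), nc, nw)
    ev = pd.read_csv(_events_sidecar(path), sep="\t")
    events = [
        EventBlock(str(r.condition), float(r.onset_s), float(r.duration_s))
        for r in ev.itertuples()
    ]
    return RunRecording(
        meta["subject_id"], meta["task_id"], int(meta["run_index"]), intensity, events, montage
    )


# ---------------------------------------------------------------------------
# Public recording API
# ---------------------------------------------------------------------------

def write_recording(rec: RunRecording, path) -> Path:
    """Serialize a recording; format chosen by extension (.snirf or .csv)."""
    path = Path(path)
    if path.suffix == ".snirf":
        _write_snirf(rec, path)
    elif path.suffix == ".csv":
        _write_csv(rec, path)
    else:
        raise FormatError(f"unsupported recording extension {path.suffix!r}")
    return path


def load_recording(path, montage: Montage) -> RunRecording:
    """Load and validate a recording; events must fall inside the run span."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".snirf":
        return _read_snirf(path, montage)
    if path.suffix == ".csv":
        return _read_csv(path, montage)
    raise FormatError(f"unsupported recording extension {path.suffix!r}")


# ---------------------------------------------------------------------------
# Montage config
# ---------------------------------------------------------------------------

def montage_to_dict(montage: Montage) -> dict:
    return {
        "wavelengths_nm": list(montage.wavelengths_nm),
        "sampling_rate_hz": montage.sampling_rate_hz,
        "source_positions": montage.source_positions.tolist(),
        "detector_positions": montage.detector_positions.tolist(),
        "channels": [list(c) for c in montage.channels],
        "channel_ids": list(montage.channel_ids),
    }


def load_montage(config) -> Montage:
    """Build a validated montage from a YAML/JSON file path or a mapping."""
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    return Montage(
        wavelengths_nm=tuple(config["wavelengths_nm"]),
        source_positions=np.asarray(config["source_positions"], dtype=float),
        detector_positions=np.asarray(config["detector_positions"], dtype=float),
        channels=tuple(tuple(c) for c in config["channels"]),
        sampling_rate_hz=float(config["sampling_rate_hz"]),
        channel_ids=tuple(config.get("channel_ids", ())),
    )


def write_montage(montage: Montage, path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(montage_to_dict(montage), fh, sort_keys=False)
    return path


# ---------------------------------------------------------------------------
# Search spaces
# ---------------------------------------------------------------------------

def load_search_spaces(config, montage: Montage) -> list[SearchSpace]:
    """Read ``{name: [channel ids]}`` YAML and validate against the montage."""
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = config
    if not isinstance(raw, dict) or not raw:
        raise ValidationError("search-space config must be a non-empty mapping")
    spaces = []
    for name, members in raw.items():
        if not members:
            raise ValidationError(f"search space {name!r} is empty")
        spaces.append(SearchSpace(str(name), frozenset(members)).validate_against(montage))
    by_name = {s.name: s for s in spaces}
    if "LIFG" in by_name and "RIFG" in by_name:
        if by_name["LIFG"].member_channels & by_name["RIFG"].member_channels:
            raise ValidationError("LIFG and RIFG must be disjoint")
    return spaces


def _packaged_spaces(filename: str, montage: Montage | None) -> list[SearchSpace]:
    ref = importlib.resources.files("fcoi_nirs.data") / filename
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    if montage is None:
        return [SearchSpace(str(k), frozenset(v)) for k, v in raw.items()]
    return load_search_spaces(raw, montage)


def adult_search_spaces(montage: Montage | None = None) -> list[SearchSpace]:
    return _packaged_spaces("adult_search_spaces.yaml", montage)


def toddler_search_spaces(montage: Montage | None = None) -> list[SearchSpace]:
    return _packaged_spaces("toddler_search_spaces.yaml", montage)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path) -> Path:
    """Write a result table as UTF-8 CSV with a loss-free numeric round trip.

    Floats are serialized with ``repr`` semantics (shortest string that
    round-trips to the same 64-bit value).
    """
    if table is None or len(table) == 0:
        raise ValidationError("refusing to write an empty table")
    path = Path(path)
    table.to_csv(path, index=False, encoding="utf-8")
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
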