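"""File formats: spine CSV interchange, ISI TIFF stacks, JSON sidecars.

The spine interchange format is a plain UTF-8 CSV (comma separator, "."
decimal, mandatory header) with one row per spine x session and columns
``dendrite_id, spine_id, position_um, day, present, spine_intensity,
shaft_intensity, background_intensity, true_size, true_change`` plus the
optional ``dendrite_length_um`` (segment length, needed for density).  The
same schema is accepted for real annotation exports; the ground-truth columns
are simply empty there.  A JSON sidecar (``<name>.json``) carries the
generating configuration and the baseline-session labels.

ISI recordings travel as multi-frame TIFFs (one frame per time bin) with a
JSON sidecar holding frame rate, stimulus frequency and the names of the
ground-truth map TIFFs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .isi import ISIRecording
from .spines import SpineDataset

__all__ = [
    "SPINE_CSV_COLUMNS",
    "write_spine_csv",
    "read_spine_csv",
    "write_isi_recording",
    "read_isi_recording",
    "write_mask_tiff",
    "file_checksum",
    "config_to_dict",
]

SPINE_CSV_COLUMNS = [
    "dendrite_id",
    "spine_id",
    "position_um",
    "day",
    "present",
    "spine_intensity",
    "shaft_intensity",
    "background_intensity",
    "true_size",
    "true_change",
    "dendrite_length_um",
]

_REQUIRED_COLUMNS = SPINE_CSV_COLUMNS[:8]


def config_to_dict(config) -> dict:
    """Dataclass config to a JSON-serializable dict (arrays to lists)."""
    out = {}
    for field in dataclasses.fields(config):
        value = getattr(config, field.name)
        if isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, tuple):
            value = list(value)
        out[field.name] = value
    return out


def file_checksum(path) -> str:
    """SHA-256 hex digest of a file."""
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_spine_csv(dataset: SpineDataset, path, config=None) -> Path:
    """Write a dataset to the CSV interchange format with a JSON sidecar."""
    path = Path(path)
    df = dataset.to_dataframe()
    df.to_csv(path, index=False)
    sidecar = {
        "sessions": list(dataset.sessions),
        "baseline_sessions": list(dataset.baseline_sessions),
    }
    if config is not None:
        sidecar["config"] = (
            config_to_dict(config)
            if dataclasses.is_dataclass(config)
            else dict(config)
        )
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_spine_csv(
    path, baseline_sessions=None, allow_readdition: bool = False
) -> SpineDataset:
    """Read the CSV interchange format back into a dataset.

    ``baseline_sessions`` defaults to the value stored in the JSON sidecar.
    Unknown columns warn; missing required columns or malformed values raise
    with the file, row and column named.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    unknown = set(df.columns) - set(SPINE_CSV_COLUMNS)
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown columns {sorted(unknown)}",
            stacklevel=2,
        )
    as_float = pd.to_numeric(df["day"], errors="coerce")
    bad = as_float.isna() | (as_float != as_float.round())
    if bad.any():
        row = int(df.index[bad][0]) + 2  # header + 1-based line number
        raise ValueError(
            f"{path}, line {row}, column 'day': non-integer value "
            f"{df['day'].iloc[row - 2]!r}"
        )
    df["day"] = as_float.astype(int)
    if baseline_sessions is None:
        sidecar_path = path.with_suffix(".json")
        if not sidecar_path.exists():
            raise ValueError(
                f"{path}: baseline_sessions not given and sidecar "
                f"{sidecar_path.name} not found"
            )
        sidecar = json.loads(sidecar_path.read_text())
        baseline_sessions = sidecar["baseline_sessions"]
    try:
        return SpineDataset.from_dataframe(
            df, baseline_sessions, allow_readdition=allow_readdition
        )
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from None


def write_isi_recording(recording: ISIRecording, directory, stem=None) -> Path:
    """Write an ISI recording: stack TIFF, truth-map TIFFs, JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or f"isi_{recording.eye}"
    stack_path = directory / f"{stem}.tif"
    tifffile.imwrite(stack_path, recording.frames.astype(np.float32))
    meta = {
        "frame_rate": recording.frame_rate,
        "stim_freq": recording.stim_freq,
        "eye": recording.eye,
        "n_frames": recording.n_frames,
    }
    for name in ("truth_amplitude", "truth_phase"):
        array = getattr(recording, name)
        if array is not None:
            map_path = directory / f"{stem}_{name}.tif"
            tifffile.imwrite(map_path, array.astype(np.float32))
            meta[name] = map_path.name
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=2))
    return stack_path


def read_isi_recording(stack_path, meta_path=None) -> ISIRecording:
    """Read a recording written by :func:`write_isi_recording`."""
    stack_path = Path(stack_path)
    if meta_path is None:
        meta_path = stack_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    frames = tifffile.imread(stack_path).astype(float)
    truth = {}
    for name in ("truth_amplitude", "truth_phase"):
        if name in meta:
            truth[name] = tifffile.imread(
                stack_path.parent / meta[name]
            ).astype(float)
    return ISIRecording(
        frames=frames,
        frame_rate=meta["frame_rate"],
        stim_freq=meta["stim_freq"],
        eye=meta.get("eye", "contra"),
        truth_amplitude=truth.get("truth_amplitude"),
        truth_phase=truth.get("truth_phase"),
    )


def write_mask_tiff(mask, path) -> Path:
    """Serialize a boolean mask as a single-frame 0/1 TIFF."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8))
    return path
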