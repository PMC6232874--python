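"""Plain-text readers and writers for recordings, matrices, and tables.

Formats are deliberately simple: tab-separated text with channel labels, plus
JSON sidecars for parameters that do not fit a rectangular table.  EDF input
is supported through MNE when it is installed (``pip install neuroxent[edf]``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .coupling import CouplingMatrix
from .entropy import EntropyParams
from .preprocessing import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording",
    "write_matrix",
    "read_matrix",
    "write_json",
]


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as TSV: one row per channel, first column the label."""
    path = Path(path)
    df = pd.DataFrame(recording.data, index=list(recording.channels))
    df.to_csv(path, sep="\t", header=False, float_format="%.6g")
    sidecar = {
        "subject_id": recording.subject_id,
        "fs": recording.fs,
        "group": recording.group,
        "channels": list(recording.channels),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_recording(
    path: str | Path,
    fs: float | None = None,
    subject_id: str | None = None,
    group: str | None = None,
) -> Recording:
    """Read a recording from TSV/CSV (rows = channels) or EDF.

    For delimited text the sampling rate comes from the JSON sidecar written
    by :func:`write_recording`, or from ``fs``.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("EDF input requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        rec = Recording(
            subject_id=subject_id or path.stem,
            fs=float(raw.info["sfreq"]),
            channels=tuple(raw.ch_names),
            data=raw.get_data(),
            group=group,
        )
    else:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep, header=None, index_col=0)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
        rate = fs or meta.get("fs")
        if rate is None:
            raise ValueError("sampling rate not given and no sidecar found")
        rec = Recording(
            subject_id=subject_id or meta.get("subject_id", path.stem),
            fs=float(rate),
            channels=tuple(str(c) for c in df.index),
            data=df.to_numpy(),
            group=group if group is not None else meta.get("group"),
        )
    logger.info(
        "read %s: fs=%g, %d channels, %d samples",
        path.name, rec.fs, rec.n_channels, rec.n_samples,
    )
    return rec


def write_matrix(matrix: CouplingMatrix, path: str | Path) -> None:
    """Write a coupling matrix as labeled TSV plus a JSON params sidecar."""
    path = Path(path)
    df = pd.DataFrame(matrix.values, index=list(matrix.channels), columns=list(matrix.channels))
    df.to_csv(path, sep="\t", float_format="%.12g")
    sidecar = {
        "subject_id": matrix.subject_id,
        "band": matrix.band,
        "params": dataclasses.asdict(matrix.params),
        "n_epochs_averaged": matrix.n_epochs_averaged,
        "symmetric": matrix.symmetric,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_matrix(path: str | Path) -> CouplingMatrix:
    """Read a coupling matrix written by :func:`write_matrix`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return CouplingMatrix(
        subject_id=meta["subject_id"],
        band=meta["band"],
        params=EntropyParams(**meta["params"]),
        channels=tuple(df.index),
        values=df.to_numpy(),
        n_epochs_averaged=meta["n_epochs_averaged"],
        symmetric=meta["symmetric"],
    )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=1, default=_jsonable) + "\n")
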