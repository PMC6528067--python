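"""File formats: simulator binary+JSON EEG, TSV events/series, NIfTI maps.

Real recordings in BrainVision or EDF format are read through MNE when
it is installed (optional dependency); everything the pipeline itself
writes uses plain formats — float32 raw + JSON sidecar for EEG, TSV for
events, weights and time series, NIfTI for BOLD and statistical maps,
JSON for reports and provenance.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Recording
from .simulate import BoldDataset, TrialSchedule


# --- EEG ------------------------------------------------------------------

def write_recording(rec: Recording, stem: Path) -> list[Path]:
    """Write channels x samples float32 raw data plus a JSON sidecar."""
    stem = Path(stem)
    bin_path = stem.with_suffix(".bin")
    json_path = stem.with_suffix(".json")
    rec.data.astype(np.float32).tofile(bin_path)
    sidecar = {
        "fs": rec.fs,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "channel_labels": rec.channel_labels,
        "events": [[int(s), p] for s, p in rec.events],
        "dtype": "float32",
        "order": "C",
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return [bin_path, json_path]


def read_recording(stem: Path) -> Recording:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype=meta["dtype"])
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return Recording(
        data=data, fs=meta["fs"], channel_labels=meta["channel_labels"],
        events=[(int(s), p) for s, p in meta["events"]],
    )


def read_brainvision(vhdr_path: Path) -> Recording:
    """Read a BrainVision recording (requires mne)."""
    return _from_mne_raw(_mne().io.read_raw_brainvision(vhdr_path, preload=True))


def read_edf(path: Path) -> Recording:
    """Read an EDF recording (requires mne)."""
    return _from_mne_raw(_mne().io.read_raw_edf(path, preload=True))


def _mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading BrainVision/EDF requires the 'mne' package") from exc
    return mne


def _from_mne_raw(raw) -> Recording:
    events = []
    ann = getattr(raw, "annotations", None)
    if ann is not None:
        events = [(int(round(on * raw.info["sfreq"])), desc)
                  for on, desc in zip(ann.onset, ann.description)]
    return Recording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        events=events,
    )


# --- events and series ----------------------------------------------------

def write_events_tsv(schedule: TrialSchedule, path: Path) -> Path:
    df = pd.DataFrame({
        "onset": schedule.onsets,
        "duration": schedule.stim_duration,
        "phase": schedule.phase_id,
    })
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_events_tsv(path: Path) -> TrialSchedule:
    df = pd.read_csv(path, sep="\t")
    return TrialSchedule(
        phase_id=str(df["phase"].iloc[0]),
        onsets=df["onset"].to_numpy(float),
        stim_duration=float(df["duration"].iloc[0]),
        reversal_interval=0.1,
    )


def write_series_tsv(values: np.ndarray, path: Path, fs: float | None = None,
                     column: str = "value") -> Path:
    df = pd.DataFrame({column: np.asarray(values)})
    if fs is not None:
        df.insert(0, "time", np.arange(len(df)) / fs)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_series_tsv(path: Path, column: str = "value") -> np.ndarray:
    return pd.read_csv(path, sep="\t")[column].to_numpy(float)


def write_weights_tsv(weights: np.ndarray, labels: list[str] | None,
                      path: Path) -> Path:
    labels = labels or [f"CH{i:02d}" for i in range(len(weights))]
    pd.DataFrame({"channel": labels, "weight": weights}).to_csv(
        path, sep="\t", index=False)
    return Path(path)


# --- NIfTI ----------------------------------------------------------------

def _nib():
    import nibabel as nib
    return nib


def write_bold_nifti(bold: BoldDataset, path: Path, mask_path: Path | None = None):
    """BOLD as 4-D float32 NIfTI (grid layout, or n x 1 x 1 if flat)."""
    nib = _nib()
    shape = bold.grid_shape or (bold.n_voxels, 1, 1)
    vol = bold.series.reshape(*shape, bold.n_scans).astype(np.float32)
    affine = np.eye(4)
    img = nib.Nifti1Image(vol, affine)
    img.header["pixdim"][4] = bold.tr
    nib.save(img, str(path))
    if mask_path is not None:
        m = bold.mask.reshape(shape).astype(np.int16)
        nib.save(nib.Nifti1Image(m, affine), str(mask_path))


def read_bold_nifti(path: Path, mask_path: Path | None = None,
                    tr: float | None = None) -> BoldDataset:
    nib = _nib()
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    grid_shape = vol.shape[:3]
    series = vol.reshape(-1, vol.shape[-1])
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj).reshape(-1) > 0
    else:
        mask = np.ones(series.shape[0], dtype=bool)
    tr = tr or float(img.header["pixdim"][4]) or 1.98
    return BoldDataset(
        series=series, tr=tr, mask=mask,
        scan_onsets=np.arange(series.shape[1]) * tr,
        grid_shape=tuple(int(s) for s in grid_shape),
    )


def write_map_nifti(values: np.ndarray, grid_shape, path: Path,
                    dtype=np.float32) -> Path:
    nib = _nib()
    shape = grid_shape or (len(values), 1, 1)
    vol = np.asarray(values).reshape(shape).astype(dtype)
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    return Path(path)


# --- JSON / manifest ------------------------------------------------------

def write_json(obj, path: Path) -> Path:
    Path(path).write_text(json.dumps(obj, indent=1, default=_json_default))
    return Path(path)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: list[Path], out: Path) -> Path:
    root = Path(out).parent
    entries = {str(Path(p).relative_to(root)): sha256_of(p) for p in paths}
    return write_json(entries, out)
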