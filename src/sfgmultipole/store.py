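"""HDF5 container for profiles/spectra and CSV export of 1-D spectra."""

from __future__ import annotations

import hashlib

import h5py
import numpy as np
import pandas as pd


def save_datasets(path, datasets: dict, attrs: dict | None = None):
    """Write a flat mapping name → ndarray (axes stored as named datasets
    alongside the data) into an HDF5 file."""
    with h5py.File(path, "w") as fh:
        for name, arr in datasets.items():
            fh.create_dataset(name, data=np.asarray(arr))
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v


def load_datasets(path) -> tuple[dict, dict]:
    out, attrs = {}, {}
    with h5py.File(path, "r") as fh:
        for name in fh:
            out[name] = fh[name][...]
        attrs.update(fh.attrs)
    return out, attrs


def export_spectrum_csv(path, frequencies: np.ndarray, values: np.ndarray):
    """CSV of a complex 1-D spectrum: columns nu_cm, re, im, abs."""
    vals = np.asarray(values)
    pd.DataFrame({
        "nu_cm": np.asarray(frequencies),
        "re": vals.real,
        "im": vals.imag,
        "abs": np.abs(vals),
    }).to_csv(path, index=False)


def export_profile_csv(path, z: np.ndarray, columns: dict):
    df = pd.DataFrame({"z": np.asarray(z)})
    for name, col in columns.items():
        df[name] = np.asarray(col)
    df.to_csv(path, index=False)


def dataset_hash(datasets: dict) -> str:
    """Deterministic content hash of a name → array mapping."""
    h = hashlib.sha256()
    for name in sorted(datasets):
        h.update(name.encode())
        h.update(np.ascontiguousarray(datasets[name]).tobytes())
    return h.hexdigest()
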