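"""HDF5 epoch container and the optional GDF reader.

Layout: ``/data`` (trials x channels x samples), ``/labels``; attributes
``fs``, ``subject``, ``session``, optional ``channel_names`` and a
``synthetic`` flag for generated sets.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .preprocess import EpochSet, RawRecording


def save_epochs(path, epochs: EpochSet, synthetic: bool = False):
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("labels", data=epochs.labels)
        f.attrs["fs"] = epochs.fs
        f.attrs["subject"] = epochs.subject_id
        f.attrs["session"] = epochs.session_id
        f.attrs["synthetic"] = synthetic
        if epochs.channel_names is not None:
            f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        names = f.attrs.get("channel_names")
        return EpochSet(
            data=f["data"][...],
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            subject_id=str(f.attrs.get("subject", "")),
            session_id=str(f.attrs.get("session", "")),
            channel_names=list(names) if names is not None else None,
        )


def save_filter_stack(path, stack):
    """Persist a band x class CSP filter stack with per-column provenance."""
    with h5py.File(path, "w") as f:
        f.create_dataset("columns", data=stack.columns())
        f.create_dataset("provenance", data=np.asarray(stack.column_index(),
                                                       dtype=int))
        f.create_dataset("eigenvalues", data=np.concatenate(
            [sf.eigenvalues for band in stack.subfilters for sf in band]))
        f.attrs["m"] = stack.m
        f.attrs["classes"] = np.asarray(stack.classes)


def load_filter_stack(path):
    from .cspselect import BandFilterStack, CSPSubFilter
    with h5py.File(path, "r") as f:
        cols = f["columns"][...]
        prov = f["provenance"][...]
        evals = f["eigenvalues"][...]
        m = int(f.attrs["m"])
        classes = np.asarray(f.attrs["classes"])
    n_bands = int(prov[:, 0].max()) + 1
    subfilters = []
    j = 0
    for b in range(n_bands):
        band_list = []
        for c in classes:
            band_list.append(CSPSubFilter(
                band_index=b, target_class=int(c), W=cols[:, j:j + m],
                eigenvalues=evals[j:j + m], m=m))
            j += m
        subfilters.append(band_list)
    return BandFilterStack(subfilters=subfilters, classes=classes, m=m)


def save_sparse_filter(path, sparse_filter):
    """Persist a sparse spatial filter (matrix + per-column provenance)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=sparse_filter.W)
        f.create_dataset("band_of_column", data=sparse_filter.band_of_column)
        f.create_dataset("provenance", data=np.asarray(sparse_filter.provenance,
                                                       dtype=int))


def load_sparse_filter(path):
    from .cspselect import SparseSpatialFilter
    with h5py.File(path, "r") as f:
        return SparseSpatialFilter(
            W=f["W"][...],
            provenance=[tuple(row) for row in f["provenance"][...]],
            band_of_column=f["band_of_column"][...],
        )


def read_gdf(path, eeg_channels: int = 22) -> RawRecording:
    """Read a GDF recording (the BCI IV 2a native format) via mne.

    Requires the optional ``mne`` dependency (install extra ``[gdf]``).
    Returns the continuous EEG with cue onsets/labels from the annotations.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError("reading GDF files requires the 'mne' package "
                          "(pip install mieeg[gdf])") from err
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    picks = list(range(min(eeg_channels, len(raw.ch_names))))
    data = raw.get_data(picks=picks) * 1e6          # volts -> microvolts
    fs = float(raw.info["sfreq"])
    cue_codes = {"769": 1, "770": 2, "771": 3, "772": 4}
    onsets, labels = [], []
    for ann in raw.annotations:
        code = str(ann["description"])
        if code in cue_codes:
            onsets.append(int(round(ann["onset"] * fs)))
            labels.append(cue_codes[code])
    return RawRecording(data=data, fs=fs,
                        channel_names=[raw.ch_names[i] for i in picks],
                        cue_onsets=np.asarray(onsets),
                        labels=np.asarray(labels))
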