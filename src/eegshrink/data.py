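"""Epoch containers and readers for public deposits and synthetic archives.

The in-memory container is :class:`EpochSet`: a flat collection of
single-channel EEG epochs (384 samples = 3 s at 128 Hz) with binary
labels (0 = alert, 1 = drowsy) and integer subject identifiers.
Synthetic sets additionally carry ground-truth event annotations.

Two on-disk dialects are supported:

* the preprocessed sustained-attention driving deposits, distributed as
  MATLAB matrix containers (v5 via :mod:`scipy.io`, v7.3/HDF5 via
  :mod:`h5py`), read by :func:`load_deposit` with a configurable field
  map and channel index;
* the package's own compressed archives (``.npz`` + a delimited event
  sidecar), written by :meth:`EpochSet.save` and read bit-identically by
  :func:`load_archive`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import scipy.io

EPOCH_LEN = 384

#: Default array names inside the public preprocessed deposits.
DEFAULT_FIELD_MAP = {
    "signals": "EEGsample",
    "labels": "substate",
    "subjects": "subindex",
}


class LoadError(ValueError):
    """A deposit or archive failed validation on load."""


@dataclass
class Event:
    """One annotated oscillatory event inside an epoch (sample indices)."""

    start: int
    end: int
    kind: str  # theta_delta | alpha_spindle | beta | blink


@dataclass
class EpochSet:
    """Labeled single-channel EEG epochs with subject identifiers.

    ``signals`` is ``(n, 384)`` float64 (channel already selected),
    ``labels`` ``(n,)`` int in {0, 1}, ``subject_ids`` ``(n,)`` int.
    ``events`` (synthetic data only) is one list of :class:`Event` per
    epoch.
    """

    signals: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    provenance: str = "synthetic"
    events: list[list[Event]] | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=int)
        n = len(self.signals)
        if self.signals.ndim != 2:
            raise LoadError("signals must be (n_epochs, epoch_len)")
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise LoadError("signals, labels and subject_ids must align")
        if n and not np.isin(self.labels, [0, 1]).all():
            raise LoadError("labels must be 0 (alert) or 1 (drowsy)")
        if self.events is not None and len(self.events) != n:
            raise LoadError("events must align with epochs")

    def __len__(self) -> int:
        return len(self.signals)

    @property
    def subjects(self) -> np.ndarray:
        """Sorted unique subject identifiers."""
        return np.unique(self.subject_ids)

    def subset(self, index) -> "EpochSet":
        """Epochs selected by a boolean mask or integer index array."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        events = [self.events[i] for i in index] if self.events is not None else None
        return EpochSet(self.signals[index], self.labels[index],
                        self.subject_ids[index], self.provenance, events)

    def for_subject(self, subject_id: int) -> "EpochSet":
        return self.subset(self.subject_ids == subject_id)

    def without_subject(self, subject_id: int) -> "EpochSet":
        return self.subset(self.subject_ids != subject_id)

    def class_counts(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in (0, 1)}

    def per_subject_counts(self):
        """(subject_id, n_alert, n_drowsy) rows, one per subject."""
        rows = []
        for sid in self.subjects:
            lab = self.labels[self.subject_ids == sid]
            rows.append((int(sid), int((lab == 0).sum()), int((lab == 1).sum())))
        return rows

    # -- archives ----------------------------------------------------------

    def save(self, path) -> None:
        """Write a compressed archive (+ delimited event sidecar if present)."""
        path = Path(path)
        np.savez_compressed(
            path,
            signals=self.signals[:, None, :],   # (n, 1, 384) on disk
            labels=self.labels,
            subject_ids=self.subject_ids,
            provenance=np.array(self.provenance),
        )
        if self.events is not None:
            with open(_sidecar(path), "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["epoch", "start", "end", "kind"])
                for i, evs in enumerate(self.events):
                    for ev in evs:
                        w.writerow([i, ev.start, ev.end, ev.kind])


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".events.csv")


def load_archive(path) -> EpochSet:
    """Read an archive written by :meth:`EpochSet.save`."""
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        signals = npz["signals"][:, 0, :]
        labels = npz["labels"]
        subject_ids = npz["subject_ids"]
        provenance = str(npz["provenance"])
    events = None
    side = _sidecar(path)
    if side.exists():
        events = [[] for _ in range(len(signals))]
        with open(side, newline="") as fh:
            for row in csv.DictReader(fh):
                events[int(row["epoch"])].append(
                    Event(int(row["start"]), int(row["end"]), row["kind"])
                )
    return EpochSet(signals, labels, subject_ids, provenance, events)


# ---------------------------------------------------------------------------
# public deposits (MATLAB containers)
# ---------------------------------------------------------------------------

def _read_matrix_container(path: Path, names: list[str]) -> dict[str, np.ndarray]:
    """Read named arrays from a MAT v5 or v7.3 (HDF5) container."""
    try:
        mat = scipy.io.loadmat(path)
        return {n: np.asarray(mat[n]) for n in names if n in mat}
    except (NotImplementedError, ValueError):
        # v7.3 (or plain-HDF5) containers are not readable by scipy.io
        with h5py.File(path, "r") as f:
            # MATLAB HDF5 stores arrays transposed relative to v5
            return {n: np.asarray(f[n]).T for n in names if n in f}


def load_deposit(path, field_map: dict | None = None,
                 channel_index: int = 0) -> EpochSet:
    """Load a preprocessed deposit of labeled single-channel epochs.

    Parameters
    ----------
    path : file path
        MAT v5 or v7.3 container holding a sample array (``n`` epochs by
        one-or-more channels by 384 samples), a label vector and a
        subject-index vector.
    field_map : dict, optional
        Maps the logical names ``signals``/``labels``/``subjects`` to the
        array names inside the file; defaults to the public deposits'
        conventional names (``EEGsample``/``substate``/``subindex``).
    channel_index : int
        Channel to keep when the sample array is multi-channel (the
        occipital Oz electrode in the public deposits; its index depends
        on the deposit's channel list and is deliberately a caller
        argument).
    """
    path = Path(path)
    if not path.exists():
        raise LoadError(f"no such file: {path}")
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    arrays = _read_matrix_container(path, list(fmap.values()))
    for logical, name in fmap.items():
        if name not in arrays:
            raise LoadError(
                f"deposit {path.name} is missing the {logical} array {name!r}"
            )
    sig = np.asarray(arrays[fmap["signals"]], dtype=float)
    if sig.ndim == 2:
        sig = sig[:, None, :]
    if sig.ndim != 3:
        raise LoadError(f"sample array must be 2-D or 3-D, got shape {sig.shape}")
    if not 0 <= channel_index < sig.shape[1]:
        raise LoadError(
            f"channel_index {channel_index} out of range for "
            f"{sig.shape[1]}-channel deposit"
        )
    sig = sig[:, channel_index, :]
    if sig.shape[1] != EPOCH_LEN:
        raise LoadError(
            f"epochs have {sig.shape[1]} samples, expected {EPOCH_LEN}"
        )
    labels = np.asarray(arrays[fmap["labels"]]).ravel().astype(int)
    subjects = np.asarray(arrays[fmap["subjects"]]).ravel().astype(int)
    if not np.isin(labels, [0, 1]).all():
        raise LoadError("labels outside {0, 1}")
    return EpochSet(sig, labels, subjects, provenance="deposit")
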