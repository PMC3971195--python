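"""In-memory containers for multi-channel EEG: Recording and EpochArray."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import SCALP_LABELS, canonical_label


@dataclass
class Recording:
    """A multi-channel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    labels : tuple of str
        Ordered channel names (canonical 10-20, possibly plus bipolar names).
    reference : str
        Free-text reference descriptor, e.g. ``"bi-auricular"``.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    reference: str = "bi-auricular"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(f"{len(self.labels)} labels for "
                             f"{self.data.shape[0]} data rows")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal of a named channel."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]

    def pick(self, labels) -> "Recording":
        """Sub-recording restricted to `labels`, in the given order."""
        idx = [self.labels.index(l) for l in labels]
        return replace(self, data=self.data[idx].copy(), labels=tuple(labels))

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())

    def with_data(self, data: np.ndarray) -> "Recording":
        return replace(self, data=np.asarray(data, dtype=np.float64))


def standard_recording(data: np.ndarray, fs: float,
                       reference: str = "bi-auricular") -> Recording:
    """Build a Recording on the canonical 20-channel scalp montage."""
    return Recording(data=data, fs=fs, labels=SCALP_LABELS, reference=reference)


def normalize_montage(rec: Recording) -> Recording:
    """Resolve label synonyms/case and reorder channels canonically.

    Channels that are not scalp labels (e.g. bipolar names) are left at the
    end in their original order.
    """
    canon = []
    for lbl in rec.labels:
        try:
            canon.append(canonical_label(lbl))
        except ValueError:
            canon.append(lbl)
    order = [canon.index(l) for l in SCALP_LABELS if l in canon]
    extra = [i for i, l in enumerate(canon) if l not in SCALP_LABELS]
    idx = order + extra
    return Recording(data=rec.data[idx].copy(), fs=rec.fs,
                     labels=tuple(canon[i] for i in idx), reference=rec.reference)


@dataclass
class EpochArray:
    """Fixed-length epoch stack cut from a Recording.

    `data` has shape (n_epochs, n_channels, n_samples_per_epoch) and
    `valid_mask` marks epochs that survived screening.
    """

    data: np.ndarray
    fs: float
    labels: tuple[str, ...]
    epoch_length: float
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        expected = int(round(self.fs * self.epoch_length))
        if self.data.shape[2] != expected:
            raise ValueError(f"samples per epoch {self.data.shape[2]} != "
                             f"fs*epoch_length = {expected}")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[1]:
            raise ValueError("label count does not match channel axis")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.data.shape[0],):
                raise ValueError("valid_mask length must equal number of epochs")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def select(self, mask) -> "EpochArray":
        mask = np.asarray(mask, dtype=bool)
        return EpochArray(data=self.data[mask].copy(), fs=self.fs,
                          labels=self.labels, epoch_length=self.epoch_length,
                          valid_mask=np.ones(int(mask.sum()), dtype=bool))

    def concatenate(self) -> Recording:
        """Stitch epochs back into a continuous Recording."""
        flat = np.concatenate(list(self.data), axis=1) if self.n_epochs else \
            np.empty((self.n_channels, 0))
        return Recording(data=flat, fs=self.fs, labels=self.labels)
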