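"""Reading, writing and preprocessing of multichannel EEG recordings.

Conventions used throughout the package:

* data matrices are channels x samples, float64, in microvolts (µV);
* the time of sample ``i`` is ``i / fs`` seconds (0-based index);
* "average reference" means the cross-channel mean has been subtracted
  from every sample, so each column of the data matrix sums to zero.

Supported on-disk formats are EDF (read only, via :mod:`mne`), delimited
text matrices, and a raw little-endian float64 binary matrix with a JSON
sidecar describing shape, sampling rate and channel labels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "EEGRecording",
    "read_recording",
    "write_recording",
    "preprocess",
    "write_table",
    "read_table",
]


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (C, N)
        Potentials in µV, channels x samples.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel.
    reference : {"as-recorded", "average"}
        Whether a common average reference has been applied.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    reference: str = "as-recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        c, n = self.data.shape
        if c < 2:
            raise ValueError(f"need at least 2 channels, got {c}")
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(c)]
        if len(self.channel_labels) != c:
            raise ValueError("channel_labels length does not match channel count")
        if self.reference not in ("as-recorded", "average"):
            raise ValueError(f"unknown reference {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def average_reference(self) -> "EEGRecording":
        """Return a copy with the common average subtracted per sample."""
        centred = self.data - self.data.mean(axis=0, keepdims=True)
        return replace(self, data=centred, reference="average")

    def pick(self, labels: Sequence[str]) -> "EEGRecording":
        """Subset and reorder channels by label."""
        index = {lab: i for i, lab in enumerate(self.channel_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise KeyError(f"unknown channel label(s): {missing}")
        rows = [index[lab] for lab in labels]
        return replace(self, data=self.data[rows], channel_labels=list(labels))


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".edf":
        return "edf"
    if suffix in (".txt", ".csv", ".tsv", ".dat"):
        return "matrix-text"
    if suffix in (".bin", ".f64", ".raw"):
        return "matrix-binary"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs: float | None = None,
    labels: Sequence[str] | None = None,
) -> EEGRecording:
    """Load an EEG recording from disk.

    ``format`` is one of ``"edf"``, ``"matrix-text"``, ``"matrix-binary"``
    (inferred from the suffix when omitted).  Matrix formats are channels x
    samples and require ``fs``; EDF carries its own sampling rate and labels.
    EDF potentials are converted from the reader's volts to µV.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # mne returns SI volts
        return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names))

    if fmt == "matrix-text":
        if fs is None:
            raise ValueError("fs must be supplied for matrix formats")
        text = path.read_text()
        delimiter = "," if "," in text.splitlines()[0] else None
        data = np.loadtxt(path, delimiter=delimiter, ndmin=2)
        return EEGRecording(data, float(fs), list(labels) if labels else [])

    if fmt == "matrix-binary":
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            c, n = int(meta["channels"]), int(meta["samples"])
            fs = float(meta.get("fs", fs or 0)) or fs
            labels = labels or meta.get("labels")
        else:
            raise FileNotFoundError(f"missing sidecar {sidecar} for binary matrix")
        if fs is None:
            raise ValueError("fs must be supplied for matrix formats")
        data = np.fromfile(path, dtype="<f8").reshape(c, n)
        return EEGRecording(data, float(fs), list(labels) if labels else [])

    raise ValueError(f"unknown format {fmt!r}")


def write_recording(rec: EEGRecording, path: str | Path, format: str | None = None) -> None:
    """Persist a recording as a text or binary matrix (EDF writing is out of scope)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "matrix-text":
        np.savetxt(path, rec.data, fmt="%.17g")
    elif fmt == "matrix-binary":
        rec.data.astype("<f8").tofile(path)
        meta = {
            "channels": rec.n_channels,
            "samples": rec.n_samples,
            "fs": rec.fs,
            "labels": rec.channel_labels,
        }
        _sidecar_path(path).write_text(json.dumps(meta))
    else:
        raise ValueError(f"cannot write format {fmt!r}")


def _design_bandpass(lowcut: float, highcut: float, fs: float, n_samples: int) -> np.ndarray:
    """Windowed-sinc FIR taps for a zero-phase band-pass.

    Transition width is 25% of the low edge with a 1 Hz floor; the tap count
    is capped so forward-backward filtering stays well-posed on short inputs.
    """
    nyq = fs / 2.0
    if not (0 <= lowcut < highcut < nyq):
        raise ValueError(
            f"band edges ({lowcut}, {highcut}) must satisfy 0 <= low < high < fs/2={nyq}"
        )
    trans = max(1.0, 0.25 * max(lowcut, 1.0))
    numtaps = int(round(3.3 * fs / trans))
    numtaps = min(numtaps, max(9, (n_samples - 2) // 3))
    numtaps |= 1  # odd length -> type-I linear phase
    if lowcut <= 0:
        return sps.firwin(numtaps, highcut, window="hamming", fs=fs)
    return sps.firwin(numtaps, [lowcut, highcut], pass_zero=False, window="hamming", fs=fs)


def filtfilt_fir(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply FIR taps forward and backward along the last axis (zero phase)."""
    padlen = min(3 * (len(taps) - 1), data.shape[-1] - 2)
    return sps.filtfilt(taps, [1.0], data, axis=-1, padlen=padlen)


def preprocess(
    rec: EEGRecording,
    lowcut: float = 0.1,
    highcut: float = 40.0,
    keep_channels: Sequence[str] | None = None,
    rereference: bool = True,
) -> EEGRecording:
    """Standard preprocessing: band-pass filter, channel subset, average reference.

    The band-pass is a zero-phase (forward-backward) windowed-sinc FIR.
    Channel subsetting happens before re-referencing so the average is taken
    over the retained montage only.
    """
    out = rec
    if keep_channels is not None:
        out = out.pick(keep_channels)
    taps = _design_bandpass(lowcut, highcut, rec.fs, rec.n_samples)
    out = replace(out, data=filtfilt_fir(out.data, taps))
    if rereference:
        out = out.average_reference()
    return out


def write_table(rows: Sequence[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write records as CSV with full numeric precision (>= 10 significant digits)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
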