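"""Shared fixtures: small recordings, tone generators, and an EDF writer.

The EDF writer emits a minimal but standard-conforming file (ASCII header,
16-bit little-endian samples, physical scaling in µV) so EDF read support
can be exercised without shipping any binary fixture.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from hhtmicrostate import EEGRecording, SyntheticSpec, simulate_microstate_eeg

FS = 250.0


def tone(freq: float, duration: float, fs: float = FS, amp: float = 1.0,
         phase: float = 0.0) -> np.ndarray:
    t = np.arange(int(round(duration * fs))) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


def central(x: np.ndarray, fraction: float = 0.8) -> slice:
    """Slice selecting the central ``fraction`` of samples (edge effects excluded)."""
    margin = int(round(len(x) * (1 - fraction) / 2))
    return slice(margin, len(x) - margin)


def write_minimal_edf(path: Path, data: np.ndarray, fs: float,
                      labels: list[str], phys_range: float = 1000.0) -> None:
    """Write a channels x samples µV matrix as a minimal EDF file."""
    n_sig, n_samp = data.shape
    spr = int(round(fs))  # one-second data records
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "duration must be a whole number of seconds"

    def pad(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("synthetic subject", 80), pad("synthetic recording", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 * (n_sig + 1)), 8), pad("", 44),
        pad(str(n_rec), 8), pad("1", 8), pad(str(n_sig), 4),
    ])
    fields = [
        ("label", 16, labels),
        ("transducer", 80, [""] * n_sig),
        ("dim", 8, ["uV"] * n_sig),
        ("pmin", 8, [f"{-phys_range:g}"] * n_sig),
        ("pmax", 8, [f"{phys_range:g}"] * n_sig),
        ("dmin", 8, ["-32768"] * n_sig),
        ("dmax", 8, ["32767"] * n_sig),
        ("prefilter", 80, [""] * n_sig),
        ("spr", 8, [str(spr)] * n_sig),
        ("reserved", 32, [""] * n_sig),
    ]
    for _, width, values in fields:
        header += b"".join(pad(v, width) for v in values)

    scale = 65535.0 / (2 * phys_range)
    digital = np.clip(np.round(data * scale), -32768, 32767).astype("<i2")
    records = b"".join(
        digital[sig, r * spr:(r + 1) * spr].tobytes()
        for r in range(n_rec) for sig in range(n_sig)
    )
    path.write_bytes(header + records)


@pytest.fixture
def small_recording() -> EEGRecording:
    """8-channel, 4 s deterministic recording with oscillatory structure."""
    rng = np.random.default_rng(1234)
    n = int(4 * FS)
    t = np.arange(n) / FS
    data = np.vstack([
        np.sin(2 * np.pi * (5 + i) * t + rng.uniform(0, 2 * np.pi))
        for i in range(8)
    ]) + 0.1 * rng.standard_normal((8, n))
    return EEGRecording(data, FS)


@pytest.fixture
def planted_eeg():
    """Synthetic microstate EEG (12 channels, 20 s, K=3) with ground truth."""
    spec = SyntheticSpec(C=12, fs=FS, duration=20.0, K=3, seed=99,
                         amplitude=10.0, noise_sigma=0.5)
    return simulate_microstate_eeg(spec)
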