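"""Multi-channel extracellular recordings and their on-disk format.

A :class:`Recording` holds per-channel voltage traces in microvolts together
with the sampling rate, the role of each channel (which claustrum, which Imc,
or the shared synchronization square wave) and the time origin.  On disk a
recording is a flat little-endian ``int16`` file with channel-interleaved
samples plus a JSON sidecar carrying the scaling and channel metadata, so it
can be read back without guessing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# Canonical channel roles.
CLA_L = "claustrum-L"
CLA_R = "claustrum-R"
IMC_L = "Imc-L"
IMC_R = "Imc-R"
SYNC = "sync"

_DATA_FILE = "recording.int16.bin"
_SIDECAR_FILE = "recording.json"


@dataclass
class Recording:
    """Multi-channel voltage time series in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts (already scaled; no raw integers leak
        downstream).
    rate_hz : float
        Sampling rate in samples per second.
    channel_roles : list of str
        One role label per channel (see module constants).
    t0 : float
        Time of the first sample, in seconds.
    """

    data: np.ndarray
    rate_hz: float
    channel_roles: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data))
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_roles)} roles for {self.data.shape[0]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate_hz

    def channel(self, role: str) -> np.ndarray:
        """Return the voltage trace (microvolts) for a channel role."""
        try:
            i = self.channel_roles.index(role)
        except ValueError:
            raise KeyError(
                f"channel role {role!r} not in {self.channel_roles}"
            ) from None
        return self.data[i]

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles

    # ------------------------------------------------------------------ I/O
    def to_dir(self, path: str | Path) -> Path:
        """Write the interleaved int16 binary + JSON sidecar into ``path``."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        peak = float(np.max(np.abs(self.data))) if self.data.size else 1.0
        uv_per_bit = max(peak, 1e-9) / 32000.0
        quant = np.round(self.data / uv_per_bit).astype("<i2")
        # channel-interleaved: sample-major on disk
        quant.T.tofile(path / _DATA_FILE)
        sidecar = {
            "rate_hz": self.rate_hz,
            "n_channels": int(self.data.shape[0]),
            "channel_roles": list(self.channel_roles),
            "uv_per_bit": uv_per_bit,
            "t0": self.t0,
            "dtype": "<i2",
            "order": "interleaved",
        }
        (path / _SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1))
        return path

    @classmethod
    def from_dir(cls, path: str | Path) -> "Recording":
        path = Path(path)
        sidecar = json.loads((path / _SIDECAR_FILE).read_text())
        raw = np.fromfile(path / _DATA_FILE, dtype=sidecar["dtype"])
        n_ch = sidecar["n_channels"]
        data = raw.reshape(-1, n_ch).T.astype(np.float64) * sidecar["uv_per_bit"]
        return cls(
            data=data,
            rate_hz=sidecar["rate_hz"],
            channel_roles=list(sidecar["channel_roles"]),
            t0=sidecar["t0"],
        )
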