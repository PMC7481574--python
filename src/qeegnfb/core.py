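"""Shared containers for EEG recordings, spectra and QEEG features.

Conventions used throughout the package:

* signals are stored channel x time in microvolts (μV) at a nominal
  sampling rate of 500 Hz;
* power spectra are channel x frequency in μV² on a uniform grid starting
  at 0 Hz with 0.5 Hz steps (2000 ms analysis epochs);
* frequency bands are half-open intervals [lo, hi).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 26-label 10–20 montage subset used by the recording convention.
MONTAGE_26 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC3", "FCz", "FC4", "T3", "C3", "Cz", "C4", "T4",
    "CP3", "CPz", "CP4", "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

#: Channels the downstream feature extraction requires.
REQUIRED_CHANNELS = ("Fz", "FCz", "Cz", "Pz", "Oz", "C3", "C4")


@dataclass(frozen=True)
class Band:
    """Half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi})")

    def contains(self, f: float) -> bool:
        return self.lo <= f < self.hi


#: Default band table. Theta/beta edges and the spindle search range are
#: package conventions; SMR (12–15 Hz) and the EMG inhibit (55–100 Hz)
#: follow the protocol definitions.
BANDS = {
    "delta": Band("delta", 1.0, 4.0),
    "theta": Band("theta", 4.0, 8.0),
    "alpha": Band("alpha", 8.0, 13.0),
    "smr": Band("smr", 12.0, 15.0),
    "beta": Band("beta", 13.0, 21.0),
    "spindle_search": Band("spindle_search", 13.0, 30.0),
    "emg": Band("emg", 55.0, 100.0),
    "mu": Band("mu", 11.0, 13.0),
}

THETA_SUBBANDS = {
    "4-6": Band("theta_low", 4.0, 6.0),
    "5-8": Band("theta_high", 5.0, 8.0),
    "default": Band("theta", 4.0, 8.0),
}


@dataclass
class EEGRecording:
    """Multichannel EEG segment for one task condition.

    ``events`` holds (onset_sample, type) pairs for the oddball task;
    type is ``"target"`` or ``"standard"``.
    """

    channel_labels: list[str]
    fs: float
    samples: np.ndarray  # channel x time, μV
    condition: str  # "EO" | "EC" | "oddball"
    events: list[tuple[int, str]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be channel x time")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel label count does not match samples")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the signal for one channel label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(
                f"channel {label!r} not in recording "
                f"(have {', '.join(self.channel_labels)})"
            ) from None
        return self.samples[idx]


@dataclass
class PowerSpectrum:
    """Averaged power spectrum, channel x frequency in μV².

    The grid is uniform, starts at 0 Hz, and has 0.5 Hz steps for the
    default 2000 ms epochs. Differences of spectra reuse this container
    and may hold negative values.
    """

    freqs: np.ndarray
    power: np.ndarray  # channel x frequency
    channel_labels: list[str]
    n_epochs: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.power.shape != (len(self.channel_labels), self.freqs.size):
            raise ValueError("power must be channel x frequency")
        df = np.diff(self.freqs)
        if self.freqs.size > 1 and not np.allclose(df, df[0]):
            raise ValueError("frequency grid must be uniform")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 0.0

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"site {label!r} not in spectrum") from None
        return self.power[idx]


#: Sites at which the iAPF is scored.
IAPF_SITES = ("Fz", "FCz", "Pz", "Oz")
#: Sites at which the theta/beta ratio is scored.
TBR_SITES = ("Fz", "Cz")


@dataclass
class QEEGFeatures:
    """Per-subject resting-state feature set feeding the protocol engine."""

    iapf: dict[str, float]  # site -> Hz (NaN when undefined)
    iapf_edge_flag: dict[str, bool]
    band_power: dict[tuple[str, str], float]  # (site, band name) -> μV²
    tbr: dict[str, float]  # site -> ratio (NaN when beta power is zero)
    theta_subband: str  # "4-6" | "5-8" | "default"
    theta_no_peak: bool = False
    excess_slowing: bool = False
    frontal_alpha_excess: bool = False
    beta_spindles: bool = False
    beta_spindle_center_hz: float = float("nan")
    beta_spindle_site: str | None = None
    low_voltage: bool = False
    mu_excess: bool = False
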