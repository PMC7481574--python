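"""Target-locked ERP extraction and N200/P300 scoring from the auditory oddball.

Epochs span [−300, 700) ms around each target tone (500 samples at
500 Hz), are 25 Hz zero-phase low-pass filtered, baselined to the 300 ms
pre-stimulus window and averaged; peaks are scored as the signed extremum
inside a component-specific latency window (N200: most negative value in
150–300 ms; P300: most positive value in 250–500 ms). The scoring windows
are package conventions — common oddball practice — and configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import EEGRecording

EPOCH_START_MS = -300.0
EPOCH_STOP_MS = 700.0

#: Default component scoring windows (ms, half-open [lo, hi)).
COMPONENT_WINDOWS = {
    "N200": (150.0, 300.0),
    "P300": (250.0, 500.0),
}
#: Scoring polarity: +1 → maximum, −1 → minimum.
COMPONENT_SIGN = {"N200": -1, "P300": +1}

ERP_SITES = ("Fz", "Cz", "Pz")


@dataclass
class EpochSet:
    """Stimulus-locked epochs: trial x channel x time (μV)."""

    epochs: np.ndarray
    times_ms: np.ndarray
    fs: float
    channel_labels: list[str]
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trial x channel x time")
        if self.epochs.shape[2] != self.times_ms.size:
            raise ValueError("time axis does not match epoch length")

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    def copy_with(self, epochs: np.ndarray) -> "EpochSet":
        return EpochSet(
            epochs=epochs,
            times_ms=self.times_ms.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            n_dropped=self.n_dropped,
            meta=dict(self.meta),
        )


def epoch_targets(
    rec: EEGRecording,
    start_ms: float = EPOCH_START_MS,
    stop_ms: float = EPOCH_STOP_MS,
) -> EpochSet:
    """Cut one [start, stop) ms epoch per target event.

    Targets whose window would leave the recording are dropped and
    counted in ``n_dropped``.
    """
    if not rec.events:
        raise ValueError("recording carries no events")
    i0 = int(round(start_ms / 1000.0 * rec.fs))
    i1 = int(round(stop_ms / 1000.0 * rec.fs))
    n_t = i1 - i0
    times = (np.arange(i0, i1) / rec.fs) * 1000.0
    epochs, dropped = [], 0
    for onset, kind in rec.events:
        if kind != "target":
            continue
        a, b = onset + i0, onset + i1
        if a < 0 or b > rec.n_samples:
            dropped += 1
            continue
        epochs.append(rec.samples[:, a:b])
    if not epochs:
        raise ValueError("no target event with a full epoch inside the recording")
    arr = np.stack(epochs)
    assert arr.shape[2] == n_t
    return EpochSet(
        epochs=arr,
        times_ms=times,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        n_dropped=dropped,
    )


def lowpass_filter(epochs: EpochSet, cutoff_hz: float = 25.0) -> EpochSet:
    """Zero-phase FIR low-pass (forward-backward) per epoch and channel.

    Zero-phase filtering keeps peak latencies unshifted, which matters
    because latency is a scored outcome.
    """
    nyq = epochs.fs / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist {nyq} Hz")
    numtaps = 101  # ~0.2 s FIR at 500 Hz: steep enough for 25 Hz with flat passband
    taps = sps.firwin(numtaps, cutoff_hz, fs=epochs.fs)
    out = sps.filtfilt(taps, [1.0], epochs.epochs, axis=-1, padlen=3 * numtaps)
    return epochs.copy_with(out)


def baseline_correct(epochs: EpochSet, base_ms: tuple[float, float] = (-300.0, 0.0)) -> EpochSet:
    """Subtract the mean over the pre-stimulus window per epoch and channel."""
    mask = (epochs.times_ms >= base_ms[0]) & (epochs.times_ms < base_ms[1])
    if not mask.any():
        raise ValueError("baseline window outside the epoch")
    base = epochs.epochs[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.copy_with(epochs.epochs - base)


def average_erp(epochs: EpochSet) -> np.ndarray:
    """Pointwise mean across trials → channel x time waveform (μV)."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one epoch")
    return epochs.epochs.mean(axis=0)


def score_peak(
    waveform: np.ndarray,
    times_ms: np.ndarray,
    component: str,
    window_ms: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Score one component on a single-channel waveform.

    Returns (amplitude μV, latency ms) of the signed extremum inside the
    component window; ties resolve to the earliest latency.
    """
    if component not in COMPONENT_WINDOWS:
        raise ValueError(f"unknown component {component!r}")
    lo, hi = window_ms if window_ms is not None else COMPONENT_WINDOWS[component]
    mask = (times_ms >= lo) & (times_ms < hi)
    if not mask.any() or lo < times_ms[0] or hi > times_ms[-1] + (times_ms[1] - times_ms[0]):
        raise ValueError(f"scoring window [{lo}, {hi}) ms outside waveform span")
    w = waveform[mask] * COMPONENT_SIGN[component]
    i = int(np.argmax(w))  # first index → earliest latency on ties
    return float(waveform[mask][i]), float(times_ms[mask][i])


def score_components(
    rec: EEGRecording,
    sites: tuple[str, ...] = ERP_SITES,
    cutoff_hz: float = 25.0,
    windows: dict | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Full oddball scoring for one recording.

    Epoch → low-pass → baseline → average → peak-score N200 and P300 at
    each site. Returns {(site, component): (amplitude, latency)}.
    """
    eps = baseline_correct(lowpass_filter(epoch_targets(rec), cutoff_hz))
    avg = average_erp(eps)
    out = {}
    for site in sites:
        ch = eps.channel_labels.index(site)
        for comp in ("N200", "P300"):
            win = (windows or {}).get(comp)
            out[(site, comp)] = score_peak(avg[ch], eps.times_ms, comp, win)
    return out
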