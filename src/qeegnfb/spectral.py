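"""Resting-state spectral analysis.

Implements the segmented-FFT power spectrum (2000 ms epochs, 0.5 Hz
resolution), the eyes-closed minus eyes-open difference spectrum used to
isolate the alpha rhythm by its suppression with open eyes, individual
alpha peak frequency (iAPF) detection in 6–13 Hz, band powers on
half-open bands, the theta/beta ratio, theta sub-band individualization,
and the QEEG deviation flags that drive protocol assignment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import signal as sps

from .core import (
    BANDS,
    IAPF_SITES,
    TBR_SITES,
    Band,
    EEGRecording,
    PowerSpectrum,
    QEEGFeatures,
)

#: Epochs whose absolute amplitude exceeds this value (μV) are excluded
#: from spectral averaging.
ARTIFACT_UV = 100.0

#: Default z threshold for "excess" deviation flags.
Z_CRIT = 1.5

#: EC broadband (1–30 Hz) RMS amplitude below this (μV) flags low-voltage EEG.
LOW_VOLTAGE_RMS_UV = 4.0


def compute_spectrum(
    rec: EEGRecording,
    epoch_ms: float = 2000.0,
    artifact_uv: float | None = ARTIFACT_UV,
) -> PowerSpectrum:
    """Average non-overlapping Hann-windowed periodograms.

    The recording is cut into non-overlapping ``epoch_ms`` epochs (2000 ms
    gives 0.5 Hz resolution at 500 Hz); each epoch is mean-detrended,
    Hann-windowed and transformed; bin powers are scaled so that their sum
    approximates the signal variance (μV²). Epochs in which any channel
    exceeds ``artifact_uv`` in absolute amplitude are excluded.
    """
    nper = int(round(rec.fs * epoch_ms / 1000.0))
    if rec.n_samples < nper:
        raise ValueError(
            f"recording too short for one {epoch_ms:g} ms epoch "
            f"({rec.n_samples} < {nper} samples)"
        )
    n_epochs = rec.n_samples // nper
    x = rec.samples[:, : n_epochs * nper].reshape(rec.samples.shape[0], n_epochs, nper)
    keep = np.ones(n_epochs, dtype=bool)
    if artifact_uv is not None:
        keep = np.abs(x).max(axis=(0, 2)) <= artifact_uv
        if not keep.any():
            warnings.warn("all epochs exceeded the artifact threshold; keeping all")
            keep[:] = True
    x = x[:, keep, :]
    freqs, pxx = sps.periodogram(
        x, fs=rec.fs, window="hann", detrend="constant", scaling="density", axis=-1
    )
    df = freqs[1] - freqs[0]
    power = pxx.mean(axis=1) * df  # per-bin power in μV²
    return PowerSpectrum(
        freqs=freqs,
        power=power,
        channel_labels=list(rec.channel_labels),
        n_epochs=int(keep.sum()),
    )


def difference_spectrum(ec: PowerSpectrum, eo: PowerSpectrum) -> PowerSpectrum:
    """Elementwise EC − EO spectrum (may be negative)."""
    if ec.freqs.shape != eo.freqs.shape or not np.allclose(ec.freqs, eo.freqs):
        raise ValueError("frequency grids do not match")
    if ec.channel_labels != eo.channel_labels:
        raise ValueError("channel sets do not match")
    return PowerSpectrum(
        freqs=ec.freqs.copy(),
        power=ec.power - eo.power,
        channel_labels=list(ec.channel_labels),
        n_epochs=min(ec.n_epochs, eo.n_epochs),
    )


def detect_iapf(
    diff: PowerSpectrum, site: str, lo: float = 6.0, hi: float = 13.0
) -> tuple[float, bool]:
    """Individual alpha peak frequency on the EC−EO difference spectrum.

    Returns the frequency of the maximum difference in [lo, hi] (both
    edges inclusive) and an edge flag, set when the maximum sits on an
    edge of the search range or is not positive. Ties resolve to the
    lowest frequency.
    """
    p = diff.channel(site)
    mask = (diff.freqs >= lo) & (diff.freqs <= hi)
    if not mask.any():
        raise ValueError(f"grid does not cover [{lo}, {hi}] Hz")
    f = diff.freqs[mask]
    v = p[mask]
    i = int(np.argmax(v))  # argmax takes the first (lowest-frequency) maximum
    iapf = float(f[i])
    edge = i == 0 or i == f.size - 1 or v[i] <= 0
    return iapf, bool(edge)


def band_power(spec: PowerSpectrum, site: str, band: Band) -> float:
    """Sum of bin power over [band.lo, band.hi) at one site, μV²."""
    if band.lo < spec.freqs[0] or band.hi > spec.freqs[-1] + spec.df:
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}) outside grid")
    p = spec.channel(site)
    mask = (spec.freqs >= band.lo) & (spec.freqs < band.hi)
    return float(p[mask].sum())


def theta_beta_ratio(
    spec: PowerSpectrum,
    site: str,
    theta: Band = BANDS["theta"],
    beta: Band = BANDS["beta"],
) -> float:
    """Theta (4–8 Hz) over beta (13–21 Hz) power ratio; NaN when beta is zero."""
    tp = band_power(spec, site, theta)
    bp = band_power(spec, site, beta)
    if bp <= 0:
        warnings.warn(f"zero beta power at {site}; theta/beta ratio undefined")
        return float("nan")
    return tp / bp


def individualize_theta_band(spec: PowerSpectrum, site: str) -> tuple[str, bool]:
    """Choose the theta sub-band to inhibit: "4-6", "5-8" or "default".

    A local spectral peak with frequency in [4, 8) Hz selects the
    sub-band containing it (below 6 Hz → 4–6, otherwise 5–8). Without a
    local theta peak (e.g. a pure 1/f background is monotone) the full
    4–8 Hz band is kept and flagged.
    """
    p = spec.channel(site)
    # search slightly beyond the band so edge peaks register as local maxima
    mask = (spec.freqs >= 3.0) & (spec.freqs <= 9.0)
    idx = np.flatnonzero(mask)
    peaks, props = sps.find_peaks(p[idx], prominence=0)
    cand = [
        (props["prominences"][j], spec.freqs[idx[k]])
        for j, k in enumerate(peaks)
        if 4.0 <= spec.freqs[idx[k]] < 8.0
    ]
    if not cand:
        return "default", True
    _, f_peak = max(cand)
    return ("4-6" if f_peak < 6.0 else "5-8"), False


# ---------------------------------------------------------------------------
# QEEG deviation flags
# ---------------------------------------------------------------------------

SLOWING_SITES = ("Fz", "FCz", "Cz")
FRONTAL_SITES = ("Fz", "FCz")
SPINDLE_SITES = ("Fz", "FCz", "Cz", "C3", "C4")


def _ref_lookup(reference: pd.DataFrame, band: str, site: str) -> tuple[float, float]:
    need = {"band", "site", "mean", "sd"}
    if not need.issubset(reference.columns):
        raise ValueError(
            f"normative reference must have columns {sorted(need)}, "
            f"got {sorted(reference.columns)}"
        )
    row = reference[(reference["band"] == band) & (reference["site"] == site)]
    if row.empty:
        raise ValueError(f"normative reference lacks band={band!r}, site={site!r}")
    return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])


def detect_beta_spindles(
    rec: EEGRecording,
    sites: tuple[str, ...] = SPINDLE_SITES,
    k_median: float = 2.0,
    min_dur_s: float = 0.25,
    min_rate_per_min: float = 2.0,
    band: Band = BANDS["spindle_search"],
) -> tuple[bool, float, str | None]:
    """Time-domain beta-spindle burst detector.

    The signal is band-passed to the 13–30 Hz search range; samples whose
    Hilbert envelope exceeds ``k_median`` times the channel's median
    envelope for at least ``min_dur_s`` form a burst. A channel with at
    least ``min_rate_per_min`` bursts per minute flags spindling beta;
    the centre frequency is the periodogram maximum of the concatenated
    burst segments. Returns (present, centre Hz, site).
    """
    nyq = rec.fs / 2.0
    sos = sps.butter(4, [band.lo / nyq, band.hi / nyq], btype="band", output="sos")
    best: tuple[float, float, str] | None = None  # (rate, center, site)
    min_len = int(round(min_dur_s * rec.fs))
    for site in sites:
        if site not in rec.channel_labels:
            continue
        xb = sps.sosfiltfilt(sos, rec.channel(site))
        env = np.abs(sps.hilbert(xb))
        thr = k_median * np.median(env)
        above = env > thr
        # run-length encode the supra-threshold mask
        runs = []
        i0 = 0 if above[0] else None
        for j in np.flatnonzero(np.diff(above.astype(np.int8)) != 0):
            if above[j + 1]:
                i0 = j + 1
            elif i0 is not None:
                runs.append((i0, j + 1))
                i0 = None
        if i0 is not None and above[-1]:
            runs.append((i0, above.size))
        bursts = [(a, b) for a, b in runs if b - a >= min_len]
        rate = len(bursts) / (rec.duration / 60.0)
        if rate >= min_rate_per_min:
            # zero-padded per-burst periodograms: sub-bin peak location
            nfft = 4096
            acc = None
            for a, b in bursts:
                seg = xb[a:b] * np.hanning(b - a)
                px = np.abs(np.fft.rfft(seg, n=nfft)) ** 2
                acc = px if acc is None else acc + px
            f = np.fft.rfftfreq(nfft, d=1.0 / rec.fs)
            sel = (f >= band.lo) & (f < band.hi)
            center = float(f[sel][np.argmax(acc[sel])])
            if best is None or rate > best[0]:
                best = (rate, center, site)
    if best is None:
        return False, float("nan"), None
    return True, best[1], best[2]


def compute_qeeg_flags(
    eo_spec: PowerSpectrum,
    ec_spec: PowerSpectrum,
    rec_ec: EEGRecording,
    reference: pd.DataFrame,
    z_crit: float = Z_CRIT,
    low_voltage_rms_uv: float = LOW_VOLTAGE_RMS_UV,
) -> dict:
    """Deviation flags against a normative band-power reference.

    ``reference`` rows carry columns ``band, site, mean, sd`` with means
    and SDs of band power (μV²) in neurotypical resting EEG; EC rows are
    used for theta, EO rows for alpha. Flags:

    * ``excess_slowing`` — fronto-central (Fz/FCz/Cz) EC theta z ≥ z_crit;
    * ``frontal_alpha_excess`` — frontal EO alpha z ≥ z_crit;
    * ``low_voltage`` — EC broadband (1–30 Hz) RMS amplitude below
      ``low_voltage_rms_uv`` averaged over channels;
    * ``beta_spindles`` — time-domain burst detection (see
      :func:`detect_beta_spindles`), with centre frequency and site;
    * ``mu_excess`` — EO 11–13 Hz peak at C3/C4 at least as large as the
      occipital (Oz) 8–13 Hz alpha peak.
    """
    theta_z = max(
        (band_power(ec_spec, s, BANDS["theta"]) - _ref_lookup(reference, "theta", s)[0])
        / _ref_lookup(reference, "theta", s)[1]
        for s in SLOWING_SITES
    )
    alpha_z = max(
        (band_power(eo_spec, s, BANDS["alpha"]) - _ref_lookup(reference, "alpha", s)[0])
        / _ref_lookup(reference, "alpha", s)[1]
        for s in FRONTAL_SITES
    )
    broad = Band("broad", 1.0, 30.0)
    rms = np.sqrt(
        np.mean([band_power(ec_spec, s, broad) for s in ec_spec.channel_labels])
    )
    spindles, center, spindle_site = detect_beta_spindles(rec_ec)
    mu_peak = max(
        _peak_in(eo_spec, s, BANDS["mu"]) for s in ("C3", "C4")
        if s in eo_spec.channel_labels
    )
    occ_peak = _peak_in(eo_spec, "Oz", BANDS["alpha"])
    return {
        "excess_slowing": bool(theta_z >= z_crit),
        "frontal_alpha_excess": bool(alpha_z >= z_crit),
        "low_voltage": bool(rms < low_voltage_rms_uv),
        "beta_spindles": bool(spindles),
        "beta_spindle_center_hz": center,
        "beta_spindle_site": spindle_site,
        "mu_excess": bool(mu_peak >= occ_peak),
    }


def _peak_in(spec: PowerSpectrum, site: str, band: Band) -> float:
    p = spec.channel(site)
    mask = (spec.freqs >= band.lo) & (spec.freqs < band.hi)
    return float(p[mask].max())


def extract_features(
    eo_rec: EEGRecording,
    ec_rec: EEGRecording,
    reference: pd.DataFrame,
    z_crit: float = Z_CRIT,
) -> QEEGFeatures:
    """Full resting-state feature set for one subject.

    Computes EO/EC spectra, the EC−EO difference, per-site iAPF, band
    powers, theta/beta ratios at Fz and Cz, the individualized theta
    sub-band (at the fronto-central site of maximal theta power), and
    the deviation flags.
    """
    eo_spec = compute_spectrum(eo_rec)
    ec_spec = compute_spectrum(ec_rec)
    diff = difference_spectrum(ec_spec, eo_spec)
    iapf, edge = {}, {}
    for site in IAPF_SITES:
        iapf[site], edge[site] = detect_iapf(diff, site)
    bp = {}
    sites = list(dict.fromkeys((*IAPF_SITES, *TBR_SITES, *SLOWING_SITES)))
    for site in sites:
        for bname in ("theta", "alpha", "beta", "smr"):
            bp[(site, bname)] = band_power(ec_spec, site, BANDS[bname])
    tbr = {site: theta_beta_ratio(ec_spec, site) for site in TBR_SITES}
    theta_site = max(SLOWING_SITES, key=lambda s: bp[(s, "theta")])
    sub, no_peak = individualize_theta_band(ec_spec, theta_site)
    flags = compute_qeeg_flags(eo_spec, ec_spec, ec_rec, reference, z_crit=z_crit)
    return QEEGFeatures(
        iapf=iapf,
        iapf_edge_flag=edge,
        band_power=bp,
        tbr=tbr,
        theta_subband=sub,
        theta_no_peak=no_peak,
        excess_slowing=flags["excess_slowing"],
        frontal_alpha_excess=flags["frontal_alpha_excess"],
        beta_spindles=flags["beta_spindles"],
        beta_spindle_center_hz=flags["beta_spindle_center_hz"],
        beta_spindle_site=flags["beta_spindle_site"],
        low_voltage=flags["low_voltage"],
        mu_excess=flags["mu_excess"],
    )
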