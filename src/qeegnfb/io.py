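"""File I/O: EDF recordings, event/cohort CSVs, pipeline configuration.

EEG interchange uses plain EDF (16-bit, 1-second data records, signals
in μV); reading goes through MNE's EDF reader, writing through a minimal
writer in this module (fixed physical range ±500 μV and a fixed header
date so that outputs are bit-reproducible). Events travel in a sidecar
CSV (``onset_s,type``) next to each oddball EDF. All tabular outputs are
comma-separated UTF-8 with '.' decimals and carry a JSON metadata
sidecar (version, seed, config hash).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EEGRecording
from .outcomes import SubjectRecord

EDF_PHYS_UV = 500.0  # physical range ±500 μV
EDF_DIG = 32767


def write_eeg(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as plain EDF (int16, 1-s records, μV).

    The signal is clipped to ±500 μV; events, when present, go to a
    ``<stem>_events.csv`` sidecar.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record per signal
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one 1-s EDF record")
    if n_rec * spr < rec.n_samples:
        warnings.warn("recording truncated to whole 1-s EDF records")
    nch = len(rec.channel_labels)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    hdr = b"".join([
        pad("0", 8),
        pad(f"X X X {rec.meta.get('subject_id', 'X')}", 80),
        pad(f"Startdate 01-JAN-2000 X X X condition_{rec.condition}", 80),
        pad("01.01.00", 8),
        pad("00.00.00", 8),
        pad(str(256 * (1 + nch)), 8),
        pad("", 44),
        pad(str(n_rec), 8),
        pad("1", 8),
        pad(str(nch), 4),
    ])
    fields = [
        ("".join([l.ljust(16) for l in rec.channel_labels]), None),
        ("".join(["".ljust(80)] * nch), None),
        ("".join(["uV".ljust(8)] * nch), None),
        ("".join([f"{-EDF_PHYS_UV:g}".ljust(8)] * nch), None),
        ("".join([f"{EDF_PHYS_UV:g}".ljust(8)] * nch), None),
        ("".join([f"{-EDF_DIG}".ljust(8)] * nch), None),
        ("".join([f"{EDF_DIG}".ljust(8)] * nch), None),
        ("".join(["".ljust(80)] * nch), None),
        ("".join([str(spr).ljust(8)] * nch), None),
        ("".join(["".ljust(32)] * nch), None),
    ]
    sig_hdr = "".join(f for f, _ in fields).encode("ascii")

    scale = EDF_DIG / EDF_PHYS_UV
    x = np.clip(rec.samples[:, : n_rec * spr], -EDF_PHYS_UV, EDF_PHYS_UV)
    dig = np.round(x * scale).astype("<i2")
    # interleave: record-major, signal-major within record
    blocks = dig.reshape(nch, n_rec, spr).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(hdr)
        fh.write(sig_hdr)
        fh.write(blocks.tobytes())
    if rec.events:
        ev = pd.DataFrame(
            [(onset / rec.fs, kind) for onset, kind in rec.events],
            columns=["onset_s", "type"],
        )
        ev.to_csv(path.with_name(path.stem + "_events.csv"), index=False)
    return path


def read_eeg(path: str | Path, require_channels: tuple[str, ...] = ()) -> EEGRecording:
    """Read an EDF recording (via MNE) and merge any event sidecar CSV."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EEG file not found: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise ValueError(f"unreadable EDF {path.name}: {exc}") from exc
    data = raw.get_data(units="uV")
    labels = list(raw.ch_names)
    for ch in require_channels:
        if ch not in labels:
            raise ValueError(f"{path.name}: required channel {ch!r} missing")
    condition = "unknown"
    for tag in ("EO", "EC", "oddball"):
        if path.stem.endswith(tag):
            condition = tag
    events = None
    ev_path = path.with_name(path.stem + "_events.csv")
    if ev_path.exists():
        fs = float(raw.info["sfreq"])
        ev = pd.read_csv(ev_path)
        n = data.shape[1]
        events = []
        n_bad = 0
        for _, row in ev.iterrows():
            onset = int(round(float(row["onset_s"]) * fs))
            if 0 <= onset < n:
                events.append((onset, str(row["type"])))
            else:
                n_bad += 1
        if n_bad:
            warnings.warn(f"{ev_path.name}: dropped {n_bad} out-of-range events")
    return EEGRecording(
        channel_labels=labels,
        fs=float(raw.info["sfreq"]),
        samples=data,
        condition=condition,
        events=events,
        meta={"path": str(path)},
    )


# ---------------------------------------------------------------------------
# subject records <-> CSV
# ---------------------------------------------------------------------------

def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Long-format table: one row per subject x assessment."""
    rows = []
    for r in records:
        for j in range(r.adhd_items.shape[0]):
            row = dict(
                subject_id=r.subject_id, age=r.age, sex=r.sex,
                session=r.assessment_sessions[j], sessions_taken=r.sessions_taken,
                psqi_total=r.psqi_total, protocol=r.protocol or "",
            )
            row.update({f"hsdq_{k}": v for k, v in r.hsdq.items()})
            row.update({f"item_{i + 1}": r.adhd_items[j, i] for i in range(18)})
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    out = []
    item_cols = [f"item_{i + 1}" for i in range(18)]
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("session")
        hsdq = {
            c[len("hsdq_"):]: float(g[c].iloc[0])
            for c in df.columns if c.startswith("hsdq_")
        }
        out.append(
            SubjectRecord(
                subject_id=str(sid),
                age=float(g["age"].iloc[0]),
                sex=str(g["sex"].iloc[0]),
                adhd_items=g[item_cols].to_numpy(),
                assessment_sessions=[int(s) for s in g["session"]],
                sessions_taken=int(g["sessions_taken"].iloc[0]),
                psqi_total=float(g["psqi_total"].iloc[0]),
                hsdq=hsdq,
                protocol=str(g["protocol"].iloc[0]) or None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str = "qeegnfb_run"
    n_subjects: int = 24
    seed: int = 0
    resting_duration_s: float = 60.0
    n_targets: int = 40
    oddball_noise_rms_uv: float = 1.0
    epoch_ms: float = 2000.0
    z_crit: float = 1.5
    erp_windows: dict = field(
        default_factory=lambda: {"N200": (150.0, 300.0), "P300": (250.0, 500.0)}
    )
    do_session_cutoff: int = 20
    remission_item_mean: float = 1.00
    psqi_sleep_cutoff: float = 5.0
    alpha: float = 0.05

    def config_hash(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig(**raw)
    if "N200" in cfg.erp_windows:
        cfg.erp_windows = {k: tuple(v) for k, v in cfg.erp_windows.items()}
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["erp_windows"] = {k: list(v) for k, v in d["erp_windows"].items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def write_csv_with_sidecar(
    df: pd.DataFrame, path: str | Path, cfg: PipelineConfig
) -> None:
    path = Path(path)
    df.to_csv(path, index=False)
    meta = {
        "version": "0.1.0",
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "rows": int(df.shape[0]),
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
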