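"""End-to-end pipeline: simulate → features → erp → assign → outcomes → predict.

Each stage reads the previous stage's on-disk artifacts and writes CSVs
(with metadata sidecars) plus a run log, so a run is reproducible from
its output directory and seed alone.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import spectral, stats
from .io import (
    PipelineConfig,
    frame_to_records,
    read_eeg,
    records_to_frame,
    save_config,
    write_csv_with_sidecar,
    write_eeg,
)
from .outcomes import classify_outcome
from .protocol import assign_protocol, build_session_config
from .synthetic import (
    CohortSpec,
    make_clinical_cohort,
    make_normative_reference,
    make_oddball_recording,
    make_resting_eeg,
)

STAGES = ("simulate", "features", "erp", "assign", "outcomes", "predict")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _log(lines: list[str], msg: str) -> None:
    lines.append(msg)


def stage_simulate(cfg: PipelineConfig, out: Path, log: list[str]):
    spec = CohortSpec(n=cfg.n_subjects, seed=cfg.seed)
    cohort = make_clinical_cohort(spec)
    eeg_dir = out / "eeg"
    eeg_dir.mkdir(parents=True, exist_ok=True)
    seed_seq = np.random.SeedSequence(cfg.seed)
    child_seeds = seed_seq.spawn(len(cohort.params))
    for p, cs in zip(cohort.params, child_seeds):
        s = int(cs.generate_state(1)[0] % (2**31))
        for cond, offset in (("EO", 1), ("EC", 2)):
            rec = make_resting_eeg(p, cond, cfg.resting_duration_s, seed=s + offset)
            write_eeg(rec, eeg_dir / f"{p.subject_id}_{cond}.edf")
        odd = make_oddball_recording(
            p, n_targets=cfg.n_targets, noise_rms_uv=cfg.oddball_noise_rms_uv,
            seed=s + 3,
        )
        write_eeg(odd, eeg_dir / f"{p.subject_id}_oddball.edf")
    write_csv_with_sidecar(cohort.table, out / "cohort.csv", cfg)
    write_csv_with_sidecar(records_to_frame(cohort.records), out / "records.csv", cfg)
    _log(log, f"simulate: {len(cohort.params)} subjects, EEG in {eeg_dir}")
    return cohort


def stage_features(cfg: PipelineConfig, out: Path, log: list[str]) -> pd.DataFrame:
    eeg_dir = out / "eeg"
    if not eeg_dir.exists():
        raise FileNotFoundError(f"EEG directory missing: {eeg_dir}")
    reference = make_normative_reference()
    reference.to_csv(out / "normative_reference.csv", index=False)
    cohort = pd.read_csv(out / "cohort.csv")
    rows = []
    for sid in cohort["subject_id"]:
        eo = read_eeg(eeg_dir / f"{sid}_EO.edf", require_channels=("Fz", "Oz"))
        ec = read_eeg(eeg_dir / f"{sid}_EC.edf", require_channels=("Fz", "Oz"))
        feats = spectral.extract_features(eo, ec, reference, z_crit=cfg.z_crit)
        row = {"subject_id": sid}
        for site, v in feats.iapf.items():
            row[f"iapf_{site}"] = v
            row[f"iapf_edge_{site}"] = feats.iapf_edge_flag[site]
        for site, v in feats.tbr.items():
            row[f"tbr_{site}"] = v
        row.update(
            theta_subband=feats.theta_subband,
            excess_slowing=feats.excess_slowing,
            frontal_alpha_excess=feats.frontal_alpha_excess,
            beta_spindles=feats.beta_spindles,
            beta_spindle_center_hz=feats.beta_spindle_center_hz,
            beta_spindle_site=feats.beta_spindle_site or "",
            low_voltage=feats.low_voltage,
            mu_excess=feats.mu_excess,
        )
        for (site, band), v in feats.band_power.items():
            row[f"bp_{site}_{band}"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    write_csv_with_sidecar(df, out / "features.csv", cfg)
    _log(log, f"features: {df.shape[0]} subjects")
    return df


def stage_erp(cfg: PipelineConfig, out: Path, log: list[str]) -> pd.DataFrame:
    eeg_dir = out / "eeg"
    cohort = pd.read_csv(out / "cohort.csv")
    rows = []
    for sid in cohort["subject_id"]:
        rec = read_eeg(eeg_dir / f"{sid}_oddball.edf")
        comps = erp_mod.score_components(rec, windows=cfg.erp_windows)
        row = {"subject_id": sid}
        for (site, comp), (amp, lat) in comps.items():
            row[f"{comp.lower()}_amp_{site}"] = amp
            row[f"{comp.lower()}_lat_{site}"] = lat
        rows.append(row)
    df = pd.DataFrame(rows)
    write_csv_with_sidecar(df, out / "erp.csv", cfg)
    _log(log, f"erp: {df.shape[0]} subjects scored")
    return df


def stage_assign(cfg: PipelineConfig, out: Path, log: list[str]) -> pd.DataFrame:
    feats = pd.read_csv(out / "features.csv")
    cohort = pd.read_csv(out / "cohort.csv")
    psqi = dict(zip(cohort["subject_id"], cohort["psqi"]))
    rows = []
    for _, r in feats.iterrows():
        q = _features_from_row(r)
        sleep = psqi.get(r["subject_id"], 0.0) > cfg.psqi_sleep_cutoff
        dec = assign_protocol(q, sleep_problems=bool(sleep))
        sc = build_session_config(dec)
        rows.append(
            dict(
                subject_id=r["subject_id"],
                protocol=dec.primary_protocol,
                sites="|".join(dec.sites),
                reward_band=(
                    f"{dec.reward_band.lo:g}-{dec.reward_band.hi:g}"
                    if dec.reward_band else ""
                ),
                inhibit_bands="|".join(f"{b.lo:g}-{b.hi:g}" for b in dec.inhibit_bands),
                adjunct="|".join(dec.adjunct),
                emg_inhibit=f"{sc.emg_inhibit_band.lo:g}-{sc.emg_inhibit_band.hi:g}",
                emg_threshold_uv=sc.emg_threshold_uv,
                rationale="; ".join(dec.rationale),
            )
        )
        _log(log, f"assign {r['subject_id']}: {dec.primary_protocol} "
                  f"[{'; '.join(dec.rationale)}]")
    df = pd.DataFrame(rows)
    write_csv_with_sidecar(df, out / "protocols.csv", cfg)
    return df


def _features_from_row(r: pd.Series):
    from .core import IAPF_SITES, QEEGFeatures, TBR_SITES

    bp = {}
    for col in r.index:
        if col.startswith("bp_"):
            _, site, band = col.split("_", 2)
            bp[(site, band)] = float(r[col])
    return QEEGFeatures(
        iapf={s: float(r[f"iapf_{s}"]) for s in IAPF_SITES},
        iapf_edge_flag={s: bool(r[f"iapf_edge_{s}"]) for s in IAPF_SITES},
        band_power=bp,
        tbr={s: float(r[f"tbr_{s}"]) for s in TBR_SITES},
        theta_subband=str(r["theta_subband"]),
        excess_slowing=bool(r["excess_slowing"]),
        frontal_alpha_excess=bool(r["frontal_alpha_excess"]),
        beta_spindles=bool(r["beta_spindles"]),
        beta_spindle_center_hz=float(r["beta_spindle_center_hz"]),
        beta_spindle_site=str(r["beta_spindle_site"]) or None,
        low_voltage=bool(r["low_voltage"]),
        mu_excess=bool(r["mu_excess"]),
    )


def stage_outcomes(cfg: PipelineConfig, out: Path, log: list[str]) -> pd.DataFrame:
    records = frame_to_records(pd.read_csv(out / "records.csv"))
    rows = []
    for rec in records:
        lab = classify_outcome(
            rec,
            do_session_cutoff=cfg.do_session_cutoff,
            remission_item_mean=cfg.remission_item_mean,
        )
        rows.append(
            dict(
                subject_id=rec.subject_id,
                endpoint_source=lab.endpoint_source,
                att_reduction_pct=lab.att_reduction_pct,
                hyp_reduction_pct=lab.hyp_reduction_pct,
                item_mean=lab.item_mean,
                remission=lab.remission, r50=lab.r50, r25=lab.r25,
                nr=lab.nr, do=lab.do,
            )
        )
        if lab.do:
            _log(log, f"outcomes {rec.subject_id}: drop-out, excluded from analyses")
    df = pd.DataFrame(rows)
    write_csv_with_sidecar(df, out / "outcomes.csv", cfg)
    kept = df[~df["do"]]
    summary = pd.DataFrame(
        {
            "label": ["remission", "r50", "r25", "nr", "do"],
            "rate_pct": [
                round(100 * kept[c].mean(), 1) if len(kept) else float("nan")
                for c in ("remission", "r50", "r25", "nr")
            ] + [round(100 * df["do"].mean(), 1)],
        }
    )
    write_csv_with_sidecar(summary, out / "outcome_summary.csv", cfg)
    _log(log, f"outcomes: {len(kept)}/{len(df)} analyzable")
    return df


def build_analysis_frame(out: Path) -> pd.DataFrame:
    """Merge cohort, features, ERP and outcome tables; DO rows excluded."""
    cohort = pd.read_csv(out / "cohort.csv")
    feats = pd.read_csv(out / "features.csv")
    erp = pd.read_csv(out / "erp.csv")
    outc = pd.read_csv(out / "outcomes.csv")
    prot = pd.read_csv(out / "protocols.csv")
    df = cohort.merge(feats, on="subject_id").merge(erp, on="subject_id")
    df = df.merge(outc, on="subject_id").merge(
        prot[["subject_id", "protocol"]], on="subject_id"
    )
    df = df[~df["do"]].reset_index(drop=True)
    df["remission"] = df["remission"].astype(bool)
    df["protocol3"] = df["protocol"].where(
        df["protocol"].isin(["SMR", "TBR"]), "other"
    )
    return df


def stage_predict(cfg: PipelineConfig, out: Path, log: list[str]) -> pd.DataFrame:
    df = build_analysis_frame(out)
    results = []
    report = []

    def note(name, fn):
        try:
            sr = fn()
        except Exception as exc:
            _log(log, f"predict: {name} skipped ({exc})")
            return
        results.append(
            dict(effect=name, statistic=sr.statistic, df=str(sr.df), p=sr.p,
                 **{k: v for k, v in sr.extra.items() if np.isscalar(v)})
        )

    if df["remission"].nunique() == 2:
        try:
            tab = stats.glm_screen(df, "hyp_baseline", covariate="age",
                                   factors=("sex",), group="remission")
            for _, r in tab.iterrows():
                results.append(dict(effect=f"glm_hyp[{r['effect']}]",
                                    statistic=r["F"], df=f"({r['df1']},{r['df2']})",
                                    p=r["p"]))
        except Exception as exc:
            _log(log, f"predict: glm screen skipped ({exc})")
        note("wilks_hyp",
             lambda: stats.lda_wilks(df["hyp_baseline"], df["remission"]))
        note("auc_hyp_nonremission",
             lambda: stats.roc_auc(df["hyp_baseline"], ~df["remission"], orient=True))
        if df["p300_lat_Fz"].notna().all():
            note("wilks_p300lat_Fz",
                 lambda: stats.lda_wilks(df["p300_lat_Fz"], df["remission"]))
    kids = df[df["age"] < 18]
    if len(kids) >= 5 and kids["sbd"].std() > 0:
        note("spearman_hyp_sbd",
             lambda: stats.correlate(kids["hyp_baseline"], kids["sbd"], "spearman"))
        note("pearson_logsbd_hypchange",
             lambda: stats.correlate(stats.log_scores(kids["sbd"]),
                                     kids["hyp_reduction_pct"], "pearson"))
    res = pd.DataFrame(results)
    write_csv_with_sidecar(res, out / "predictors.csv", cfg)
    report.append("Predictor screen (remission):")
    for r in results:
        report.append(f"  {r['effect']}: stat={r['statistic']:.4g} p={r['p']:.4g}")
    (out / "report.txt").write_text("\n".join(report) + "\n")
    _log(log, f"predict: {len(results)} statistics")
    return res


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; any failure aborts naming the stage and cause."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    log: list[str] = [f"seed={cfg.seed} config_hash={cfg.config_hash()}"]
    stage_fns = {
        "simulate": stage_simulate,
        "features": stage_features,
        "erp": stage_erp,
        "assign": stage_assign,
        "outcomes": stage_outcomes,
        "predict": stage_predict,
    }
    for stage in STAGES:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stage_fns[stage](cfg, out, log)
        except Exception as exc:
            (out / "run_log.txt").write_text("\n".join(log) + f"\nFAILED {stage}: {exc}\n")
            raise StageError(stage, exc) from exc
    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    return out
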