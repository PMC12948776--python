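"""End-to-end study analysis: colorimetry -> pipeline -> agreement -> model.

`analyze_study` drives the full validation workflow on in-memory tables and
returns a :class:`StudyResult` bundle; `write_bundle` serializes the bundle
to CSV/JSON artifacts and `render_report` turns a written bundle into a
human-readable summary without computing any new numbers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, colorimetry, error_model, hr_pipeline
from .protocol import ProtocolConfig

log = logging.getLogger("pulseval")


@dataclass
class AnalysisConfig:
    """All tunable constants of the analysis, with reference defaults."""

    epoch_s: float = 30.0
    hr_low: float = hr_pipeline.HR_PLAUSIBLE_LOW
    hr_high: float = hr_pipeline.HR_PLAUSIBLE_HIGH
    outlier_k: float = hr_pipeline.OUTLIER_K
    grade_thresholds: tuple[float, float] = agreement.GRADE_THRESHOLDS
    dark_threshold: float = colorimetry.DARK_ITA_THRESHOLD
    alpha: float = 0.05
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def __post_init__(self):
        if min(self.epoch_s, self.outlier_k, *self.grade_thresholds) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class StudyResult:
    """Machine-readable artifacts of one analysis run."""

    pigmentation: pd.DataFrame
    pigmentation_summary: pd.DataFrame
    matched: pd.DataFrame
    agreement_table: pd.DataFrame
    ba_plot_data: pd.DataFrame
    mae_table: pd.DataFrame
    intensity_anova: pd.DataFrame
    quality: dict
    model_summary: pd.DataFrame
    selection_traces: pd.DataFrame


def _match_all(hr, profiles, cfg) -> tuple[pd.DataFrame, dict]:
    """Screen, epoch and match every subject x device stream."""
    quality: dict = {"devices": {}}
    matched_frames = []
    epoch_frames: dict[str, list] = {}
    device_ids = [
        d for d in hr["device_id"].unique() if d != "criterion"
    ]
    removed_by_device = dict.fromkeys(list(device_ids) + ["criterion"], 0)
    for subj, sub_df in hr.groupby("subject_id", sort=True):
        crit_raw = sub_df[sub_df["device_id"] == "criterion"]
        if crit_raw.empty:
            log.warning("subject %s has no criterion stream; skipped", subj)
            continue
        origin = crit_raw["timestamp"].min()
        crit, n_rm = hr_pipeline.plausibility_filter(crit_raw, cfg.hr_low, cfg.hr_high)
        removed_by_device["criterion"] += n_rm
        crit_ep = hr_pipeline.epoch_average(crit, origin, cfg.epoch_s)
        for dev in device_ids:
            dev_raw = sub_df[sub_df["device_id"] == dev]
            if dev_raw.empty:
                continue
            dev_f, n_rm = hr_pipeline.plausibility_filter(
                dev_raw, cfg.hr_low, cfg.hr_high
            )
            removed_by_device[dev] += n_rm
            if dev_f.empty:
                continue
            dev_ep = hr_pipeline.epoch_average(dev_f, origin, cfg.epoch_s)
            epoch_frames.setdefault(dev, []).append(dev_ep)
            m, n_excl = hr_pipeline.match_epochs(
                crit_ep, dev_ep, cfg.protocol, cfg.epoch_s
            )
            log.info(
                "subject %s device %s: %d matched epochs, %d excluded",
                subj, dev, len(m), n_excl,
            )
            matched_frames.append(m)
    matched = (
        pd.concat(matched_frames, ignore_index=True)
        if matched_frames
        else pd.DataFrame(
            columns=["subject_id", "device_id", "epoch_index", "criterion_hr",
                     "device_hr", "error", "abs_error", "intensity", "outlier"]
        )
    )
    # outlier flagging: pooled per device, one pass
    dark_by_subject = profiles["category"].eq("dark")
    expected = cfg.protocol.expected_epochs(cfg.epoch_s)
    for dev in device_ids:
        mask = matched["device_id"] == dev
        if mask.sum() >= 3:
            flags = hr_pipeline.flag_outliers(
                matched.loc[mask, "error"], cfg.outlier_k
            )
            matched.loc[mask, "outlier"] = flags
        dq: dict = {"removed_implausible_count": removed_by_device.get(dev, 0)}
        if dev in epoch_frames:
            rep = hr_pipeline.missing_accounting(
                pd.concat(epoch_frames[dev], ignore_index=True),
                expected,
                dark_by_subject,
            )
            dq.update(
                missing_epoch_count=rep.missing_count,
                expected_epoch_count=rep.expected_count,
                missing_rate=rep.missing_rate,
                missing_dark_attribution=rep.dark_attribution,
            )
        n_out = int(matched.loc[mask, "outlier"].sum())
        n_match = int(mask.sum())
        dark_out = int(
            matched.loc[
                mask & matched["outlier"],
                "subject_id",
            ].map(dark_by_subject).sum()
        )
        dq.update(
            outlier_count=n_out,
            outlier_rate=n_out / n_match if n_match else None,
            outlier_dark_attribution=dark_out / n_out if n_out else None,
        )
        quality["devices"][dev] = dq
    quality["criterion_removed_implausible"] = removed_by_device["criterion"]
    return matched, quality


def _agreement_tables(matched, cfg) -> tuple[pd.DataFrame, pd.DataFrame]:
    rows = []
    plot_frames = []
    for dev, grp in matched.groupby("device_id", sort=True):
        clean = grp[~grp["outlier"]]
        row = {"device_id": dev, "n_epochs": len(clean),
               "n_subjects": clean["subject_id"].nunique()}
        if len(clean) < 2 or clean["subject_id"].nunique() < 2:
            row.update(estimable=False)
            rows.append(row)
            continue
        ba = agreement.bland_altman_rm(clean["error"], clean["subject_id"])
        r, p = agreement.proportional_bias(clean["criterion_hr"], clean["error"])
        rm = agreement.rmcorr(
            clean["criterion_hr"], clean["device_hr"], clean["subject_id"]
        )
        row.update(
            estimable=True,
            bias=ba.bias,
            sd=ba.sd_total,
            loa_lower=ba.loa_lower,
            loa_upper=ba.loa_upper,
            trend_r=r,
            trend_p=p,
            r_rm=rm.r_rm,
            r_rm_p=rm.p,
            grade=agreement.classify_agreement(
                ba.loa_lower, ba.loa_upper, cfg.grade_thresholds
            ),
        )
        rows.append(row)
        plot_frames.append(
            clean[["device_id", "subject_id", "criterion_hr", "error"]].assign(
                bias=ba.bias, loa_lower=ba.loa_lower, loa_upper=ba.loa_upper
            )
        )
    table = pd.DataFrame(rows)
    plot = (
        pd.concat(plot_frames, ignore_index=True)
        if plot_frames
        else pd.DataFrame()
    )
    return table, plot


def _intensity_tables(matched, cfg) -> tuple[pd.DataFrame, pd.DataFrame]:
    clean = matched[~matched["outlier"]]
    mae = agreement.mae_by_intensity(clean) if len(clean) else pd.DataFrame()
    anova_rows = []
    for dev, grp in clean.groupby("device_id", sort=True):
        per_subj = grp.pivot_table(
            index="subject_id", columns="intensity", values="abs_error",
            aggfunc="mean",
        )
        complete = per_subj.dropna()
        n_dropped = len(per_subj) - len(complete)
        if n_dropped:
            log.info(
                "device %s: %d subject(s) dropped from the intensity ANOVA "
                "(incomplete cells)", dev, n_dropped,
            )
        if len(complete) < 3 or complete.shape[1] < 2:
            continue
        res = agreement.rm_anova(complete.to_numpy())
        anova_rows.append(
            {
                "device_id": dev,
                "f": res.f,
                "df1": res.df1,
                "df2": res.df2,
                "p": res.p,
                "epsilon_gg": res.epsilon_gg,
                "df1_gg": res.df1_gg,
                "df2_gg": res.df2_gg,
                "p_gg": res.p_gg,
                "n_subjects": res.n_subjects,
                "n_dropped_subjects": n_dropped,
            }
        )
    return mae, pd.DataFrame(anova_rows)


def _error_models(matched, profiles, cfg) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per device: forward-entry mixed model of the absolute epoch error."""
    rows = []
    traces = []
    clean = matched[~matched["outlier"]]
    for dev, grp in clean.groupby("device_id", sort=True):
        ita = grp["subject_id"].map(profiles["mean_device_ita"])
        data = pd.DataFrame(
            {
                "abs_error": grp["abs_error"].to_numpy(),
                "ita": ita.to_numpy(),
                "criterion_hr": grp["criterion_hr"].to_numpy(),
                "subject_id": grp["subject_id"].to_numpy(),
            }
        ).dropna()
        if data["subject_id"].nunique() < 3 or len(data) < 10:
            log.warning("device %s: too little data for the error model", dev)
            continue
        y = data["abs_error"].to_numpy()
        candidates = data[["ita", "criterion_hr"]]
        fit, trace = error_model.forward_entry(
            y, candidates, data["subject_id"], alpha=cfg.alpha
        )
        trace.insert(0, "device_id", dev)
        traces.append(trace)
        kept = [n for n in fit.fe_names if n != error_model.INTERCEPT]
        sr2 = (
            error_model.semipartial_sr2(y, candidates, kept, data["subject_id"])
            if kept
            else {}
        )
        vifs = error_model.vif(candidates[kept]) if len(kept) >= 2 else None
        row = {
            "device_id": dev,
            "icc": error_model.icc_from_null(y, data["subject_id"]),
            "constant": fit.beta[error_model.INTERCEPT],
            "marginal_r2": error_model.marginal_r2(fit),
            "sigma2_b": fit.sigma2_b,
            "sigma2_e": fit.sigma2_e,
            "loglik": fit.loglik,
            "n_obs": fit.n_obs,
            "n_subjects": fit.n_subjects,
        }
        for name in candidates.columns:
            row[f"beta_{name}"] = fit.beta.get(name, np.nan)
            row[f"se_{name}"] = fit.beta_se.get(name, np.nan)
            row[f"sr2_{name}"] = sr2.get(name, np.nan)
            row[f"vif_{name}"] = (
                vifs[name] if vifs is not None and name in vifs else np.nan
            )
        rows.append(row)
    return (
        pd.DataFrame(rows),
        pd.concat(traces, ignore_index=True) if traces else pd.DataFrame(),
    )


def analyze_study(
    hr_samples: pd.DataFrame,
    colorimeter: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> StudyResult:
    """Run the full validation analysis on long-format input tables.

    ``hr_samples`` has columns subject_id, device_id, timestamp, hr (one
    device_id must be ``criterion``); ``colorimeter`` has subject_id, site,
    replicate, L, a, b.
    """
    cfg = config or AnalysisConfig()
    profiles = colorimetry.pigmentation_profiles(
        colorimeter, dark_threshold=cfg.dark_threshold
    )
    matched, quality = _match_all(hr_samples, profiles, cfg)
    agreement_table, ba_plot = _agreement_tables(matched, cfg)
    mae_table, anova_table = _intensity_tables(matched, cfg)
    model_summary, traces = _error_models(matched, profiles, cfg)
    return StudyResult(
        pigmentation=profiles,
        pigmentation_summary=colorimetry.site_summary(profiles),
        matched=matched,
        agreement_table=agreement_table,
        ba_plot_data=ba_plot,
        mae_table=mae_table,
        intensity_anova=anova_table,
        quality=quality,
        model_summary=model_summary,
        selection_traces=traces,
    )


BUNDLE_FILES = {
    "pigmentation": "pigmentation_profiles.csv",
    "pigmentation_summary": "pigmentation_summary.csv",
    "matched": "matched_epochs.csv",
    "agreement_table": "agreement_table.csv",
    "ba_plot_data": "bland_altman_plot_data.csv",
    "mae_table": "mae_by_intensity.csv",
    "intensity_anova": "intensity_anova.csv",
    "model_summary": "model_summary.csv",
    "selection_traces": "selection_trace.csv",
}


def write_bundle(result: StudyResult, outdir) -> Path:
    """Serialize every artifact of an analysis run to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in BUNDLE_FILES.items():
        df = getattr(result, attr)
        df.to_csv(out / fname, index=attr in ("pigmentation", "pigmentation_summary"))
    with open(out / "data_quality.json", "w") as fh:
        json.dump(result.quality, fh, indent=1)
    return out


def render_report(bundle_dir) -> str:
    """Human-readable summary assembled from a written bundle.

    Every number shown is read back from the machine-readable artifacts;
    nothing is recomputed at render time.
    """
    out = Path(bundle_dir)
    if not out.is_dir():
        raise FileNotFoundError(f"bundle directory not found: {bundle_dir}")
    agr_path = out / BUNDLE_FILES["agreement_table"]
    if not agr_path.exists():
        raise FileNotFoundError(f"incomplete bundle: missing {agr_path.name}")
    lines = ["Device validation summary", "=" * 25, ""]
    agr = pd.read_csv(agr_path)
    lines.append("Agreement vs criterion (bias / 95% LoA, bpm):")
    for _, r in agr.iterrows():
        if not r.get("estimable", True):
            lines.append(f"  {r['device_id']}: not estimable")
            continue
        lines.append(
            f"  {r['device_id']}: bias {r['bias']:+.1f}, SD {r['sd']:.1f}, "
            f"LoA [{r['loa_lower']:.1f}, {r['loa_upper']:.1f}], "
            f"trend r {r['trend_r']:.2f}, grade {r['grade']}"
        )
    mae_path = out / BUNDLE_FILES["mae_table"]
    if mae_path.exists():
        mae = pd.read_csv(mae_path)
        lines.append("")
        lines.append("MAE by intensity (bpm):")
        wide = mae.pivot(index="device_id", columns="intensity", values="mae")
        lines.append(wide.round(2).to_string())
    dq_path = out / "data_quality.json"
    if dq_path.exists():
        with open(dq_path) as fh:
            dq = json.load(fh)
        lines.append("")
        lines.append("Data quality:")
        for dev, d in dq.get("devices", {}).items():
            rate = d.get("missing_rate")
            attr = d.get("missing_dark_attribution")
            lines.append(
                f"  {dev}: missing rate "
                f"{rate:.1%}" + (
                    f" (dark-skin share {attr:.0%})" if attr is not None else ""
                ) + f", outliers {d.get('outlier_count', 0)}"
            )
    model_path = out / BUNDLE_FILES["model_summary"]
    if model_path.exists() and model_path.stat().st_size > 1:
        model = pd.read_csv(model_path)
        if len(model):
            lines.append("")
            lines.append("Mixed-effects error models (MAE_HR ~ pigmentation + HR):")
            for _, r in model.iterrows():
                terms = [f"constant {r['constant']:.2f}"]
                for cand in ("ita", "criterion_hr"):
                    b = r.get(f"beta_{cand}")
                    if pd.notna(b):
                        terms.append(f"{cand} {b:+.4f}")
                lines.append(
                    f"  {r['device_id']}: " + ", ".join(terms)
                    + f"; ICC {r['icc']:.3f}, marginal R2 {r['marginal_r2']:.3f}"
                )
        else:
            lines.append("")
            lines.append("Mixed-effects error model: skipped (insufficient data)")
    else:
        lines.append("")
        lines.append("Mixed-effects error model: skipped (no output present)")
    return "\n".join(lines)
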