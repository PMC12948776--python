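"""Heart-rate stream ingestion, screening, epoch harmonization and QC.

Raw streams arrive at heterogeneous sampling intervals (the chest-strap
criterion at ~1 s; wearables at 2-15 s).  The pipeline screens physiologically
implausible values, averages each stream into half-open 30-s epochs anchored
at the session origin, matches device epochs to criterion epochs by epoch
index, labels each matched epoch with its protocol stage, accounts for
missing epochs, and flags outlying signed errors at ``k`` standard deviations
from the per-device mean error (k = 3.29 by default, the two-sided 0.1%
normal point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .protocol import ProtocolConfig

SAMPLE_COLUMNS = ["subject_id", "device_id", "timestamp", "hr"]

#: plausibility screen bounds, bpm (inclusive retention)
HR_PLAUSIBLE_LOW = 50.0
HR_PLAUSIBLE_HIGH = 200.0

#: outlier rule multiplier on the SD of the signed error
OUTLIER_K = 3.29

DEFAULT_EPOCH_S = 30.0


def read_hr_stream(path, dialect: str = "long") -> tuple[pd.DataFrame, int]:
    """Read an HR sample CSV; returns ``(samples, n_malformed)``.

    The ``long`` dialect has columns ``subject_id, device_id, timestamp,
    hr_bpm`` with ISO-8601 timestamps.  Malformed rows (unparseable timestamp
    or heart rate, or hr <= 0) are counted and reported via a warning, not
    silently dropped from the count.  Non-monotone timestamps within a
    (subject, device) stream raise, naming the first offending row.
    """
    if dialect != "long":
        raise ValueError(f"unknown HR stream dialect: {dialect!r}")
    raw = pd.read_csv(path, dtype=str)
    if len(raw) == 0:
        raise ValueError(f"empty HR stream file: {path}")
    need = ["subject_id", "device_id", "timestamp", "hr_bpm"]
    missing = [c for c in need if c not in raw.columns]
    if missing:
        raise ValueError(f"HR stream file {path} lacks columns {missing}")
    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    hr = pd.to_numeric(raw["hr_bpm"], errors="coerce")
    bad = ts.isna() | hr.isna() | (hr <= 0)
    n_malformed = int(bad.sum())
    if n_malformed:
        warnings.warn(
            f"{path}: dropped {n_malformed} malformed HR row(s)", stacklevel=2
        )
    df = pd.DataFrame(
        {
            "subject_id": raw.loc[~bad, "subject_id"],
            "device_id": raw.loc[~bad, "device_id"],
            "timestamp": ts[~bad],
            "hr": hr[~bad],
        }
    ).reset_index(drop=True)
    for (subj, dev), grp in df.groupby(["subject_id", "device_id"], sort=False):
        diffs = grp["timestamp"].diff()
        off = diffs < pd.Timedelta(0)
        if off.any():
            row = int(off.idxmax())
            raise ValueError(
                f"{path}: timestamps out of order for {subj}/{dev} "
                f"at row index {row}"
            )
    return df, n_malformed


def plausibility_filter(
    samples: pd.DataFrame,
    low: float = HR_PLAUSIBLE_LOW,
    high: float = HR_PLAUSIBLE_HIGH,
) -> tuple[pd.DataFrame, int]:
    """Drop samples with hr < low or hr > high; bounds themselves are kept.

    Returns the filtered frame and the number of removed samples.
    """
    if low >= high:
        raise ValueError("plausibility bounds inverted")
    keep = (samples["hr"] >= low) & (samples["hr"] <= high)
    return samples[keep].reset_index(drop=True), int((~keep).sum())


def epoch_average(
    samples: pd.DataFrame,
    origin: pd.Timestamp,
    epoch_s: float = DEFAULT_EPOCH_S,
) -> pd.DataFrame:
    """Average one stream into fixed epochs from the session origin.

    Epoch ``i`` covers the half-open window ``[origin + i*epoch_s,
    origin + (i+1)*epoch_s)``.  The returned series is contiguous from epoch
    0 through the epoch of the last sample; windows without samples appear
    with ``mean_hr`` NaN and ``n_samples`` 0.

    ``samples`` must be a single (subject, device) stream and ``origin`` must
    not postdate its first sample.
    """
    if epoch_s <= 0:
        raise ValueError("epoch length must be positive")
    if samples["subject_id"].nunique() != 1 or samples["device_id"].nunique() != 1:
        raise ValueError("epoch_average expects a single subject/device stream")
    subj = samples["subject_id"].iloc[0]
    dev = samples["device_id"].iloc[0]
    sec = (samples["timestamp"] - origin).dt.total_seconds().to_numpy()
    if sec.min() < 0:
        raise ValueError("origin postdates the first sample")
    idx = np.floor(sec / epoch_s).astype(int)
    n_epochs = int(idx.max()) + 1
    sums = np.bincount(idx, weights=samples["hr"].to_numpy(), minlength=n_epochs)
    counts = np.bincount(idx, minlength=n_epochs)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    epochs = np.arange(n_epochs)
    return pd.DataFrame(
        {
            "subject_id": subj,
            "device_id": dev,
            "epoch_index": epochs,
            "epoch_start": origin + pd.to_timedelta(epochs * epoch_s, unit="s"),
            "mean_hr": means,
            "n_samples": counts.astype(int),
        }
    )


def match_epochs(
    criterion: pd.DataFrame,
    device: pd.DataFrame,
    protocol: ProtocolConfig | None = None,
    epoch_s: float = DEFAULT_EPOCH_S,
) -> tuple[pd.DataFrame, int]:
    """Pair device and criterion epoch means by epoch index.

    Both inputs are epoch series from :func:`epoch_average` for the same
    subject and session origin.  The inner join keeps epochs with a mean on
    both sides; the second return value counts candidate epochs excluded
    because either side was missing.  When ``protocol`` is given, each
    matched epoch is labelled with the stage covering its start time.
    """
    if criterion["subject_id"].iloc[0] != device["subject_id"].iloc[0]:
        raise ValueError("criterion and device epochs are from different subjects")
    o_c = criterion["epoch_start"].iloc[0] - pd.to_timedelta(
        criterion["epoch_index"].iloc[0] * epoch_s, unit="s"
    )
    o_d = device["epoch_start"].iloc[0] - pd.to_timedelta(
        device["epoch_index"].iloc[0] * epoch_s, unit="s"
    )
    if o_c != o_d:
        raise ValueError("criterion and device epoch series have different origins")
    merged = criterion.merge(
        device[["epoch_index", "mean_hr"]],
        on="epoch_index",
        how="outer",
        suffixes=("_criterion", "_device"),
    )
    ok = merged["mean_hr_criterion"].notna() & merged["mean_hr_device"].notna()
    n_excluded = int((~ok).sum())
    out = merged[ok].reset_index(drop=True)
    matched = pd.DataFrame(
        {
            "subject_id": criterion["subject_id"].iloc[0],
            "device_id": device["device_id"].iloc[0],
            "epoch_index": out["epoch_index"].astype(int),
            "criterion_hr": out["mean_hr_criterion"],
            "device_hr": out["mean_hr_device"],
        }
    )
    matched["error"] = matched["device_hr"] - matched["criterion_hr"]
    matched["abs_error"] = matched["error"].abs()
    if protocol is not None:
        offsets = matched["epoch_index"].to_numpy() * epoch_s
        matched["intensity"] = [protocol.intensity_at(t) for t in offsets]
    matched["outlier"] = False
    return matched, n_excluded


def flag_outliers(errors, k: float = OUTLIER_K) -> np.ndarray:
    """Boolean mask of errors more than ``k`` SDs from the mean error.

    Computed in one pass on the pooled per-device signed errors (no
    re-estimation after removal).  A zero SD yields no flags.
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 3:
        raise ValueError("need at least 3 errors to flag outliers")
    sd = e.std(ddof=1)
    if sd == 0:
        return np.zeros(e.size, dtype=bool)
    return np.abs(e - e.mean()) > k * sd


@dataclass
class MissingReport:
    """Missing-epoch accounting for one device."""

    missing_count: int
    expected_count: int
    missing_rate: float
    dark_attribution: float | None  # None when nothing is missing


def missing_accounting(
    epoch_series: pd.DataFrame,
    expected_epoch_count: int,
    dark_by_subject: dict[str, bool] | pd.Series,
) -> MissingReport:
    """Count missing epochs against the protocol-expected total.

    ``epoch_series`` concatenates one device's epoch series over subjects.
    An epoch is missing if it was never produced (stream ended early) or was
    produced with no samples.  ``expected_epoch_count`` is per subject;
    ``dark_by_subject`` maps subject id to the dark-skin label used for the
    attribution fraction (share of all missing epochs belonging to
    dark-skinned subjects).
    """
    if expected_epoch_count <= 0:
        raise ValueError("expected_epoch_count must be positive")
    dark = pd.Series(dark_by_subject)
    subjects = epoch_series["subject_id"].unique()
    expected_total = expected_epoch_count * len(subjects)
    missing_total = 0
    missing_dark = 0
    for subj, grp in epoch_series.groupby("subject_id", sort=False):
        present = int(grp["mean_hr"].notna().sum())
        n_miss = expected_epoch_count - min(present, expected_epoch_count)
        missing_total += n_miss
        if bool(dark.get(subj, False)):
            missing_dark += n_miss
    rate = missing_total / expected_total
    attribution = missing_dark / missing_total if missing_total else None
    return MissingReport(missing_total, expected_total, rate, attribution)
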