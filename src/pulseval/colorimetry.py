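"""Skin-pigmentation quantification from CIELAB colorimetry.

Skin pigmentation is summarized by the Individual Typology Angle (ITA),

    ITA (deg) = arctan((L* - 50) / b*) * 180 / pi,

computed from the CIELAB luminance ``L*`` and yellow-blue component ``b*``
of a tri-stimulus colorimeter reading.  Lower ITA indicates darker (more
melanized) skin.  Readings are taken in replicate per anatomical site; the
channel means are averaged first and ITA is computed from the averaged
channels, never as the mean of per-replicate angles.

Subjects are classified as dark-skinned when the mean ITA over the device
placement sites (both wrists and the lateral upper arm; the volar arm is a
standardization site and excluded) falls below a threshold, 10 degrees by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sites where a wearable device sits; these enter the dark-skin classifier
DEVICE_SITES = ("wrist_dominant", "wrist_nondominant", "lateral_upper_arm")
#: sun-protected standardization site, reported separately
VOLAR_SITE = "volar_arm"
ALL_SITES = (VOLAR_SITE,) + DEVICE_SITES

#: ITA below this (degrees) classifies a subject as dark-skinned
DARK_ITA_THRESHOLD = 10.0

READING_COLUMNS = ["subject_id", "site", "replicate", "L", "a", "b"]


def ita_degrees(L_star, b_star):
    """Individual Typology Angle in degrees from CIELAB L* and b*.

    Parameters
    ----------
    L_star : float or array-like
        Luminance, in [0, 100].
    b_star : float or array-like
        Yellow-blue component.  Must be nonzero; negative values are
        physically unusual for skin and trigger a warning (the angle's
        sign flips).

    Returns
    -------
    float or ndarray
        Angle in degrees, in (-90, 90) for positive ``b_star``.
    """
    L = np.asarray(L_star, dtype=float)
    b = np.asarray(b_star, dtype=float)
    if not (np.all(np.isfinite(L)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite colorimeter channel value")
    if np.any(L < 0.0) or np.any(L > 100.0):
        raise ValueError("L* outside [0, 100]")
    if np.any(b == 0.0):
        raise ValueError(
            "b* = 0 gives an undefined typology angle (degenerate colorimetry)"
        )
    if np.any(b < 0.0):
        warnings.warn(
            "negative b* is physically unusual for skin; ITA sign flips",
            stacklevel=2,
        )
    out = np.degrees(np.arctan((L - 50.0) / b))
    if out.ndim == 0:
        return float(out)
    return out


def average_site(readings: pd.DataFrame) -> pd.Series:
    """Average replicate readings for one subject and site, per channel.

    ``readings`` must contain columns ``subject_id, site, L, a, b`` and hold
    at least one row, all from the same subject and site.  Returns a Series
    with the mean ``L``, ``a`` and ``b``; downstream ITA is computed from
    these averaged channels.
    """
    if len(readings) == 0:
        raise ValueError("no readings to average")
    if readings["subject_id"].nunique() != 1 or readings["site"].nunique() != 1:
        raise ValueError("readings mix subjects or sites")
    return readings[["L", "a", "b"]].mean()


@dataclass
class PigmentationProfile:
    """Per-subject pigmentation summary derived from colorimetry."""

    subject_id: str
    ita_by_site: dict[str, float]
    mean_device_ita: float
    category: str  # "dark" | "non_dark"
    dark_threshold: float = field(default=DARK_ITA_THRESHOLD, repr=False)


def classify_pigmentation(
    mean_device_ita: float, dark_threshold: float = DARK_ITA_THRESHOLD
) -> str:
    """Classify skin pigmentation from the device-site mean ITA.

    Dark iff ``mean_device_ita < dark_threshold`` (strict inequality, so the
    boundary value itself is non-dark).
    """
    if not np.isfinite(mean_device_ita):
        raise ValueError("no device-site ITA available for classification")
    return "dark" if mean_device_ita < dark_threshold else "non_dark"


def pigmentation_profiles(
    readings: pd.DataFrame,
    dark_threshold: float = DARK_ITA_THRESHOLD,
    device_sites: tuple[str, ...] = DEVICE_SITES,
) -> pd.DataFrame:
    """Build per-subject pigmentation profiles from replicate readings.

    Channels are averaged per (subject, site) first; ITA is computed from
    the averaged L*/b*.  ``mean_device_ita`` averages ITA over the device
    placement sites present for the subject (the volar arm never enters).

    Returns a DataFrame indexed by ``subject_id`` with one ``ita_<site>``
    column per observed site plus ``mean_device_ita`` and ``category``.
    """
    missing = [c for c in ("subject_id", "site", "L", "b") if c not in readings]
    if missing:
        raise ValueError(f"colorimeter table lacks columns {missing}")
    means = readings.groupby(["subject_id", "site"], sort=True)[["L", "b"]].mean()
    ita = pd.Series(
        ita_degrees(means["L"].to_numpy(), means["b"].to_numpy()),
        index=means.index,
        name="ita",
    )
    wide = ita.unstack("site")
    device_cols = [s for s in device_sites if s in wide.columns]
    if not device_cols:
        raise ValueError("no device-site readings; cannot classify pigmentation")
    out = wide.add_prefix("ita_")
    out["mean_device_ita"] = wide[device_cols].mean(axis=1)
    out["category"] = [
        classify_pigmentation(v, dark_threshold) for v in out["mean_device_ita"]
    ]
    out.columns.name = None
    return out


def read_colorimeter_csv(path) -> pd.DataFrame:
    """Read a colorimeter CSV with columns subject_id, site, replicate, L, a, b."""
    df = pd.read_csv(path, dtype={"subject_id": str, "site": str})
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"colorimeter file {path} lacks columns {missing}")
    unknown = set(df["site"]) - set(ALL_SITES)
    if unknown:
        raise ValueError(f"unknown anatomical sites in {path}: {sorted(unknown)}")
    return df[READING_COLUMNS]


def site_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Cohort ITA summary per site: mean, SD, min, max, n.

    Mirrors the usual descriptive table of per-site pigmentation including
    the device-site mean used for classification.
    """
    cols = [c for c in profiles.columns if c.startswith("ita_")] + ["mean_device_ita"]
    rows = []
    for c in cols:
        vals = profiles[c].dropna()
        rows.append(
            {
                "site": c.removeprefix("ita_"),
                "n": int(len(vals)),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "min": vals.min(),
                "max": vals.max(),
            }
        )
    return pd.DataFrame(rows).set_index("site")
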