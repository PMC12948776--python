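"""Synthetic study generator with known ground truth.

Emulates a laboratory criterion-validity session: a bimodal-pigmentation
cohort, a 1-Hz criterion heart-rate trace over a rest / graded-cycling /
recovery protocol, and wearable-device streams derived from the criterion
with configurable constant bias, proportional bias, between-subject error
heterogeneity, pigmentation-dependent extra noise, epoch-level missingness
(optionally inflated for dark-skinned subjects) and sporadic outliers.

Because every generating parameter is known, pipeline and statistical
routines can be validated end to end: estimated bias should recover the
configured bias, the proportional-bias trend should be positive when the
configured slope is, the fitted pigmentation coefficient should be negative
when pigmentation-linked noise is present, and dark-skin attribution of
missing epochs should exceed the dark fraction when the missingness
multiplier exceeds one.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .colorimetry import DEVICE_SITES, VOLAR_SITE, ita_degrees
from .protocol import ProtocolConfig

DEFAULT_ORIGIN = pd.Timestamp("2023-06-01 08:00:00")
CRITERION_ID = "criterion"

#: device -> anatomical placement site
DEVICE_PLACEMENT = {
    "watch_a": "wrist_dominant",
    "watch_b": "wrist_nondominant",
    "armband": "lateral_upper_arm",
}

#: margin (degrees) between the dark threshold and either mixture component,
#: keeping site-level noise from flipping a subject's intended label
_LABEL_MARGIN_DEG = 2.0


def hr_max_age_predicted(age) -> float:
    """Age-predicted maximal heart rate, 208 - 0.7 x age (bpm)."""
    return 208.0 - 0.7 * np.asarray(age, dtype=float)


def _child_seed(seed: int, i: int, j: int = 0) -> int:
    """Deterministic per-subject/per-device seed expansion."""
    return (seed * 1_000_003 + 7919 * i + j) % (2**31)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort composition and pigmentation mixture.

    The ITA mixture has a dark component (mean -36.8, SD 16.3 degrees) with
    weight ``dark_fraction`` and a non-dark component whose parameters are
    set so the pooled device-site ITA lands near mean 11.9, SD 39.2.
    """

    n_subjects: int = 28
    dark_fraction: float = 10 / 28
    dark_ita_mean: float = -36.8
    dark_ita_sd: float = 16.3
    nondark_ita_mean: float = 38.9
    nondark_ita_sd: float = 13.9
    site_ita_sd: float = 3.0
    volar_ita_shift: float = 19.5
    age_mean: float = 25.0
    age_sd: float = 5.0
    age_range: tuple[float, float] = (18.0, 59.0)
    resting_hr_mean: float = 69.0
    resting_hr_sd: float = 12.0


@dataclass(frozen=True)
class DeviceErrorConfig:
    """Error structure of one simulated wearable device.

    ``sampling_interval_s`` is either a fixed interval or a ``(lo, hi)``
    range of uniformly drawn gaps.  Device HR at a sample is

        criterion + bias + slope * (criterion - 120) + subject_intercept
                  + N(0, noise_sd + ita_noise_slope * max(0, 10 - ITA)),

    with probability ``outlier_prob`` of an added spike of
    ``+/- outlier_magnitude_bpm``.  Whole 30-s epochs are dropped with
    probability ``base_missing_prob`` (times ``dark_missing_multiplier``
    for dark-skinned subjects).
    """

    sampling_interval_s: float | tuple[float, float] = 5.0
    bias_bpm: float = 0.0
    proportional_slope: float = 0.0
    proportional_ref_bpm: float = 120.0
    noise_sd_bpm: float = 0.0
    subject_intercept_sd_bpm: float = 0.0
    ita_noise_slope: float = 0.0
    ita_noise_ref_deg: float = 10.0
    base_missing_prob: float = 0.0
    dark_missing_multiplier: float = 1.0
    outlier_prob: float = 0.0
    outlier_magnitude_bpm: float = 25.0

    def __post_init__(self):
        for name in (
            "noise_sd_bpm",
            "subject_intercept_sd_bpm",
            "ita_noise_slope",
            "base_missing_prob",
            "outlier_prob",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.base_missing_prob > 1 or self.outlier_prob > 1:
            raise ValueError("probabilities must be <= 1")


def default_device_configs() -> dict[str, DeviceErrorConfig]:
    """Three wearables spanning the error profiles seen in practice.

    ``watch_a`` is an accurate 5-s wrist watch, ``watch_b`` a noisier
    irregular-interval wrist watch, and ``armband`` a 10-s upper-arm band
    with the largest noise, a clear proportional bias, pigmentation-linked
    extra noise, and heavy missingness concentrated in dark-skinned
    subjects.
    """
    return {
        "watch_a": DeviceErrorConfig(
            sampling_interval_s=5.0,
            bias_bpm=0.0,
            proportional_slope=0.004,
            noise_sd_bpm=2.7,
            subject_intercept_sd_bpm=0.3,
            base_missing_prob=0.055,
            dark_missing_multiplier=1.8,
            outlier_prob=0.002,
        ),
        "watch_b": DeviceErrorConfig(
            sampling_interval_s=(2.0, 15.0),
            bias_bpm=0.4,
            proportional_slope=0.003,
            noise_sd_bpm=3.7,
            subject_intercept_sd_bpm=0.5,
            base_missing_prob=0.20,
            dark_missing_multiplier=1.0,
            outlier_prob=0.004,
        ),
        "armband": DeviceErrorConfig(
            sampling_interval_s=10.0,
            bias_bpm=0.7,
            proportional_slope=0.027,
            noise_sd_bpm=6.0,
            subject_intercept_sd_bpm=0.8,
            ita_noise_slope=0.024,
            base_missing_prob=0.047,
            dark_missing_multiplier=10.0,
            outlier_prob=0.006,
        ),
    }


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Rejection-sampled truncated normal (bounds are far from the mean
    in every use here, so rejection is cheap)."""
    out = np.empty(size)
    need = np.ones(size, dtype=bool)
    while need.any():
        draw = rng.normal(mean, sd, size=int(need.sum()))
        ok = (draw > lo) & (draw < hi)
        idx = np.flatnonzero(need)[ok]
        out[idx] = draw[ok]
        need[idx] = False
    return out


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Generate the participant table with latent pigmentation and HR traits.

    Columns: subject_id, dark (intended mixture label), per-site ITA,
    ita_device_mean, age, hr_max (age-predicted), resting_hr.
    Deterministic given ``seed``.
    """
    cfg = config or CohortConfig()
    if cfg.n_subjects < 2:
        raise ValueError("need >= 2 subjects")
    rng = np.random.default_rng(_child_seed(seed, 0))
    n = cfg.n_subjects
    n_dark = int(round(cfg.dark_fraction * n))
    dark = np.zeros(n, dtype=bool)
    dark[:n_dark] = True
    threshold = 10.0
    ita_subject = np.empty(n)
    ita_subject[dark] = _truncated_normal(
        rng, cfg.dark_ita_mean, cfg.dark_ita_sd, -89.0, threshold - _LABEL_MARGIN_DEG,
        n_dark,
    )
    ita_subject[~dark] = _truncated_normal(
        rng, cfg.nondark_ita_mean, cfg.nondark_ita_sd,
        threshold + _LABEL_MARGIN_DEG, 89.0, n - n_dark,
    )
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), *cfg.age_range)
    resting = np.clip(rng.normal(cfg.resting_hr_mean, cfg.resting_hr_sd, n), 45, 100)
    rows = {
        "subject_id": [f"S{i + 1:03d}" for i in range(n)],
        "dark": dark,
        "ita_subject": ita_subject,
        "age": age,
        "hr_max": hr_max_age_predicted(age),
        "resting_hr": resting,
    }
    for site in DEVICE_SITES:
        rows[f"ita_{site}"] = np.clip(
            ita_subject + rng.normal(0.0, cfg.site_ita_sd, n), -89.0, 89.0
        )
    rows[f"ita_{VOLAR_SITE}"] = np.clip(
        ita_subject + cfg.volar_ita_shift + rng.normal(0.0, cfg.site_ita_sd, n),
        -89.0, 89.0,
    )
    cohort = pd.DataFrame(rows)
    cohort["ita_device_mean"] = cohort[[f"ita_{s}" for s in DEVICE_SITES]].mean(axis=1)
    return cohort


def generate_criterion_trace(
    participant: pd.Series,
    protocol: ProtocolConfig | None = None,
    seed: int = 0,
    noise_sd: float = 2.0,
    ar_rho: float = 0.9,
    origin: pd.Timestamp = DEFAULT_ORIGIN,
) -> pd.DataFrame:
    """1-Hz criterion heart-rate trace over the full session.

    Rest holds the resting HR; each exercise stage ramps linearly over the
    protocol ramp time to its target fraction of HRmax and holds; recovery
    decays exponentially toward resting + 30 bpm.  AR(1) fluctuation
    (stationary SD ``noise_sd``, lag-1 correlation ``ar_rho``) is added
    throughout and the result clipped to [40, HRmax + 5].
    """
    proto = protocol or ProtocolConfig()
    rng = np.random.default_rng(seed)
    hr_max = float(participant["hr_max"])
    resting = float(participant["resting_hr"])
    n = int(proto.total_s)
    t = np.arange(n, dtype=float)
    target = np.full(n, resting)
    prev = resting
    t0 = proto.rest_s
    for frac in proto.stage_fractions:
        level = frac * hr_max
        in_stage = (t >= t0) & (t < t0 + proto.stage_s)
        rel = t[in_stage] - t0
        ramp = np.minimum(rel / proto.ramp_s, 1.0)
        target[in_stage] = prev + ramp * (level - prev)
        prev = level
        t0 += proto.stage_s
    rec = t >= t0
    asymptote = resting + 30.0
    tau = 150.0
    target[rec] = asymptote + (prev - asymptote) * np.exp(-(t[rec] - t0) / tau)
    if noise_sd > 0:
        eps = rng.normal(0.0, noise_sd * np.sqrt(1 - ar_rho**2), n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, noise_sd)
        for i in range(1, n):
            noise[i] = ar_rho * noise[i - 1] + eps[i]
        target = target + noise
    hr = np.clip(target, 40.0, hr_max + 5.0)
    return pd.DataFrame(
        {
            "subject_id": participant["subject_id"],
            "device_id": CRITERION_ID,
            "timestamp": origin + pd.to_timedelta(t, unit="s"),
            "hr": hr,
        }
    )


def generate_device_stream(
    criterion_trace: pd.DataFrame,
    device_cfg: DeviceErrorConfig,
    participant: pd.Series,
    seed: int = 0,
    device_id: str = "device",
    epoch_s: float = 30.0,
) -> pd.DataFrame:
    """Derive a wearable stream from a criterion trace with injected error."""
    rng = np.random.default_rng(seed)
    origin = criterion_trace["timestamp"].iloc[0]
    sec = (criterion_trace["timestamp"] - origin).dt.total_seconds().to_numpy()
    crit = criterion_trace["hr"].to_numpy()
    total = sec[-1]
    interval = device_cfg.sampling_interval_s
    if isinstance(interval, (tuple, list)):
        gaps = rng.uniform(interval[0], interval[1], size=int(total) + 1)
        times = np.cumsum(gaps)
        times = times[times <= total]
        times = np.concatenate([[0.0], times])
    else:
        times = np.arange(0.0, total + 1e-9, float(interval))
    base = np.interp(times, sec, crit)

    subject_intercept = rng.normal(0.0, device_cfg.subject_intercept_sd_bpm)
    ita = float(participant["ita_device_mean"])
    extra_sd = device_cfg.ita_noise_slope * max(
        0.0, device_cfg.ita_noise_ref_deg - ita
    )
    sd = device_cfg.noise_sd_bpm + extra_sd
    hr = (
        base
        + device_cfg.bias_bpm
        + device_cfg.proportional_slope * (base - device_cfg.proportional_ref_bpm)
        + subject_intercept
    )
    if sd > 0:
        hr = hr + rng.normal(0.0, sd, size=hr.size)
    if device_cfg.outlier_prob > 0:
        spikes = rng.random(hr.size) < device_cfg.outlier_prob
        signs = rng.choice([-1.0, 1.0], size=hr.size)
        hr = hr + spikes * signs * device_cfg.outlier_magnitude_bpm
    # epoch-granular missingness
    p_miss = device_cfg.base_missing_prob
    if bool(participant.get("dark", False)):
        p_miss = min(1.0, p_miss * device_cfg.dark_missing_multiplier)
    if p_miss > 0:
        n_epochs = int(np.floor(total / epoch_s)) + 1
        dropped = rng.random(n_epochs) < p_miss
        keep = ~dropped[np.floor(times / epoch_s).astype(int)]
        times, hr = times[keep], hr[keep]
    hr = np.maximum(hr, 1.0)
    return pd.DataFrame(
        {
            "subject_id": participant["subject_id"],
            "device_id": device_id,
            "timestamp": origin + pd.to_timedelta(times, unit="s"),
            "hr": hr,
        }
    )


def generate_colorimeter_readings(
    cohort: pd.DataFrame,
    seed: int = 0,
    replicate_sd: float = 0.5,
    b_range: tuple[float, float] = (10.0, 22.0),
) -> pd.DataFrame:
    """Triplicate CIELAB readings per subject and site.

    For each (subject, site) a yellow-blue value b* is drawn in ``b_range``
    (shrunk when the target angle is extreme, keeping L* within [0, 100])
    and L* set to invert the target ITA; replicates add channel noise of SD
    ``replicate_sd``.
    """
    rng = np.random.default_rng(_child_seed(seed, 3))
    sites = (VOLAR_SITE,) + DEVICE_SITES
    rows = []
    for _, subj in cohort.iterrows():
        for site in sites:
            ita = float(subj[f"ita_{site}"])
            tan = np.tan(np.radians(ita))
            b_hi = b_range[1]
            if abs(tan) > 1e-9:
                b_hi = min(b_hi, 49.0 / abs(tan))
            b_lo = min(b_range[0], b_hi)
            b_star = rng.uniform(b_lo, b_hi)
            L_star = 50.0 + b_star * tan
            a_star = rng.normal(12.0, 2.0)
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "subject_id": subj["subject_id"],
                        "site": site,
                        "replicate": rep,
                        "L": np.clip(L_star + rng.normal(0, replicate_sd), 0.0, 100.0),
                        "a": a_star + rng.normal(0, replicate_sd),
                        "b": max(0.5, b_star + rng.normal(0, replicate_sd)),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class StudyData:
    """One complete synthetic study with its generating ground truth."""

    cohort: pd.DataFrame
    hr_samples: pd.DataFrame
    colorimeter: pd.DataFrame
    protocol: ProtocolConfig
    device_configs: dict[str, DeviceErrorConfig]
    seed: int

    def ground_truth(self) -> dict:
        """All generating parameters and latent per-subject values."""
        return {
            "seed": self.seed,
            "protocol": asdict(self.protocol),
            "devices": {k: asdict(v) for k, v in self.device_configs.items()},
            "subjects": json.loads(self.cohort.to_json(orient="records")),
        }


def generate_study(
    cohort_config: CohortConfig | None = None,
    protocol: ProtocolConfig | None = None,
    device_configs: dict[str, DeviceErrorConfig] | None = None,
    seed: int = 0,
    criterion_noise_sd: float = 2.0,
    origin: pd.Timestamp = DEFAULT_ORIGIN,
) -> StudyData:
    """Generate a full study: cohort, criterion and device streams, colorimetry.

    A single seed expands deterministically to per-subject and per-device
    child seeds, so any subset regenerates identically.
    """
    proto = protocol or ProtocolConfig()
    devices = device_configs if device_configs is not None else default_device_configs()
    cohort = generate_cohort(cohort_config, seed)
    frames = []
    for i, (_, subj) in enumerate(cohort.iterrows()):
        crit = generate_criterion_trace(
            subj, proto, seed=_child_seed(seed, 1 + i), noise_sd=criterion_noise_sd,
            origin=origin,
        )
        frames.append(crit)
        for j, (dev_id, cfg) in enumerate(devices.items()):
            frames.append(
                generate_device_stream(
                    crit, cfg, subj,
                    seed=_child_seed(seed, 1000 + i, j + 1),
                    device_id=dev_id,
                )
            )
    hr = pd.concat(frames, ignore_index=True)
    colorimeter = generate_colorimeter_readings(cohort, seed)
    return StudyData(cohort, hr, colorimeter, proto, devices, seed)


def write_study(study: StudyData, outdir) -> dict[str, str]:
    """Write the canonical CSV/JSON artifacts consumed by the pipeline."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    hr = study.hr_samples.copy()
    hr["timestamp"] = hr["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    hr = hr.rename(columns={"hr": "hr_bpm"})
    hr["hr_bpm"] = hr["hr_bpm"].round(1)
    paths = {
        "hr_streams": str(out / "hr_streams.csv"),
        "colorimeter": str(out / "colorimeter.csv"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    hr.to_csv(paths["hr_streams"], index=False)
    col = study.colorimeter.copy()
    col[["L", "a", "b"]] = col[["L", "a", "b"]].round(3)
    col.to_csv(paths["colorimeter"], index=False)
    with open(paths["ground_truth"], "w") as fh:
        json.dump(study.ground_truth(), fh, indent=1, default=str)
    return paths
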