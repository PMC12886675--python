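"""Synthetic biomarker cohorts for the chronic-diet and acute-intervention studies.

Chronic arm: three diet groups — CON (standard chow), HFFD (high-fat
high-fructose) and HFFSD (HFFD plus 8% w/w salt) — measured weekly for four
weeks after a pre-diet baseline visit. Each animal contributes a six-analyte
panel (glucose mM, uric acid μM, cholesterol mM, Na+ mM, K+ mM, pH) per
visit, plus a continuous *health degree* in [0, 1] expressing metabolic
deviation from the healthy reference group: 0 for CON, ramping linearly with
time on diet for the experimental groups (HFFSD ≥ HFFD at equal week).

The generator encodes the statistical structure the downstream analysis
assumes: group-specific mean shifts that switch on with the diet, a shared
latent factor correlating glucose and cholesterol, animal-level random
intercepts for repeated measures, Gaussian biological noise, and clipping to
the sensor-operable span (mirroring physical saturation) with a logged clip
count.

Acute arm: hour-long intervention time courses on naive animals — a glucose
bolus (HG) producing a smooth pulse peaking near 20 min with a ~30 min
return, a urate precursor + uricase-inhibitor treatment (HUA) producing a
sigmoidal rise from ~160.2 to a ~1015 μM plateau, and a saline control
(NORM) in which every channel is stationary noise about baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

CHRONIC_GROUPS = ("CON", "HFFD", "HFFSD")
ACUTE_GROUPS = ("NORM", "HG", "HUA")

ANALYTE_COLUMNS = ("glucose_mM", "ua_uM", "cholesterol_mM", "na_mM", "k_mM", "ph")
PANEL_COLUMNS = ("sample_id", "group", "week", "time_min") + ANALYTE_COLUMNS + ("degree",)

#: operable span of each channel used for panel validity and clipping. The
#: UA upper bound extends slightly past the calibrated 1000 μM ladder so the
#: device-observed hyperuricemic plateau (~1015 μM) is representable.
PANEL_RANGES = {
    "glucose_mM": (0.0, 20.0),
    "ua_uM": (0.0, 1100.0),
    "cholesterol_mM": (0.0, 10.0),
    "na_mM": (5.0, 160.0),
    "k_mM": (1.0, 32.0),
    "ph": (3.0, 8.0),
}

# Healthy reference levels (means inside the physiological windows
# 4.4-6.6 mM glucose, 130-460 μM UA, 2.9-5.2 mM cholesterol, 135-145 mM Na+,
# 3.5-5 mM K+, pH 6.6-7.6) and between-animal biological SDs.
DEFAULT_BASELINE_MEANS = {
    "glucose_mM": 5.5, "ua_uM": 295.0, "cholesterol_mM": 4.0,
    "na_mM": 140.0, "k_mM": 4.2, "ph": 7.1,
}
DEFAULT_BASELINE_SDS = {
    "glucose_mM": 0.25, "ua_uM": 20.0, "cholesterol_mM": 0.2,
    "na_mM": 1.0, "k_mM": 0.2, "ph": 0.07,
}

# Full-progression (week-4) mean shifts per diet group. HFFD raises glucose,
# cholesterol and UA; HFFSD shows a stronger glycaemic response and
# additionally perturbs Na+ and pH through the salt load. K+ is deliberately
# untouched in both groups, providing a null channel for attribution checks.
DEFAULT_MAX_EFFECTS = {
    "CON": {c: 0.0 for c in ANALYTE_COLUMNS},
    "HFFD": {
        "glucose_mM": 6.0, "ua_uM": 180.0, "cholesterol_mM": 3.2,
        "na_mM": 0.0, "k_mM": 0.0, "ph": 0.0,
    },
    "HFFSD": {
        "glucose_mM": 10.0, "ua_uM": 200.0, "cholesterol_mM": 3.6,
        "na_mM": 6.0, "k_mM": 0.0, "ph": -0.3,
    },
}

# Fraction of the full shift expressed at each weekly visit (index = week).
# Rapid onset then progressive saturation; the degree *label* stays a linear
# ramp (see `severity`), the two need not share a time course.
DEFAULT_WEEK_FRACTIONS = (0.0, 0.55, 0.70, 0.85, 1.00)

DEFAULT_SEVERITY_MAX = {"CON": 0.0, "HFFD": 0.8, "HFFSD": 1.0}


def default_effect_matrix(
    weeks: int = 4,
    max_effects: Mapping[str, Mapping[str, float]] | None = None,
    week_fractions: tuple[float, ...] | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Per-group per-channel mean-shift trajectories over weeks 0..weeks."""
    max_effects = max_effects or DEFAULT_MAX_EFFECTS
    if week_fractions is None:
        if weeks == 4:
            week_fractions = DEFAULT_WEEK_FRACTIONS
        else:  # fall back to the same shape stretched over the study span
            w = np.arange(weeks + 1) / max(weeks, 1)
            week_fractions = tuple(np.interp(w, [0, 0.25, 0.5, 0.75, 1.0],
                                             DEFAULT_WEEK_FRACTIONS))
    frac = np.asarray(week_fractions, dtype=float)
    if frac.size != weeks + 1:
        raise ValueError("week_fractions must have weeks+1 entries")
    return {
        g: {c: max_effects[g][c] * frac for c in ANALYTE_COLUMNS}
        for g in CHRONIC_GROUPS
    }


@dataclass
class CohortConfig:
    """Design of the chronic cohort simulation."""

    n_per_group: int = 125
    weeks: int = 4
    baseline_means: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_MEANS))
    baseline_sds: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_SDS))
    effect_matrix: dict | None = None  # group -> channel -> (weeks+1,) shifts
    glucose_cholesterol_rho: float = 0.6
    degree_noise_sd: float = 0.02
    animal_sd_frac: float = 0.5  # random-intercept SD as a fraction of baseline SD
    severity_max: dict = field(default_factory=lambda: dict(DEFAULT_SEVERITY_MAX))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        if abs(self.glucose_cholesterol_rho) > 1:
            raise ValueError("|glucose_cholesterol_rho| must be <= 1")
        for c in ANALYTE_COLUMNS:
            lo, hi = PANEL_RANGES[c]
            if not lo <= self.baseline_means[c] <= hi:
                raise ValueError(f"baseline mean for {c} outside sensor range")
        if self.effect_matrix is None:
            self.effect_matrix = default_effect_matrix(self.weeks)

    def to_jsonable(self) -> dict:
        d = {
            "n_per_group": self.n_per_group,
            "weeks": self.weeks,
            "baseline_means": self.baseline_means,
            "baseline_sds": self.baseline_sds,
            "glucose_cholesterol_rho": self.glucose_cholesterol_rho,
            "degree_noise_sd": self.degree_noise_sd,
            "animal_sd_frac": self.animal_sd_frac,
            "severity_max": self.severity_max,
            "seed": self.seed,
            "effect_matrix": {
                g: {c: list(np.asarray(v, float)) for c, v in chans.items()}
                for g, chans in self.effect_matrix.items()
            },
        }
        return d


def zero_effect_config(**kwargs) -> CohortConfig:
    """Cohort config with all diet effects removed (exchangeable groups)."""
    kwargs.setdefault("weeks", 4)
    cfg = CohortConfig(**kwargs)
    cfg.effect_matrix = {
        g: {c: np.zeros(cfg.weeks + 1) for c in ANALYTE_COLUMNS}
        for g in CHRONIC_GROUPS
    }
    return cfg


def severity(group: str, week: int, config: CohortConfig) -> float:
    """Ground-truth health degree: a linear ramp from 0 to the group ceiling.

    CON is the healthy reference and stays at 0; the experimental groups
    follow s = s_max · week / weeks, so HFFSD (s_max 1.0) ≥ HFFD (0.8) at
    every visit.
    """
    if group not in CHRONIC_GROUPS:
        raise ValueError(f"unknown chronic group {group!r}; expected one of {CHRONIC_GROUPS}")
    if not 0 <= week <= config.weeks:
        raise ValueError(f"week {week} outside 0..{config.weeks}")
    return float(config.severity_max.get(group, 0.0) * week / config.weeks)


def _validate_group_means(config: CohortConfig) -> None:
    for g in CHRONIC_GROUPS:
        for c in ANALYTE_COLUMNS:
            lo, hi = PANEL_RANGES[c]
            shifts = np.asarray(config.effect_matrix[g][c], dtype=float)
            means = config.baseline_means[c] + shifts
            if means.min() < lo or means.max() > hi:
                raise ValueError(
                    f"effect shift pushes group {g} mean for channel {c} "
                    f"outside the sensor range {PANEL_RANGES[c]}"
                )


def simulate_chronic(config: CohortConfig) -> pd.DataFrame:
    """Draw the weekly chronic-cohort biomarker panels.

    Returns a panel table with ``n_per_group × 3 × (weeks+1)`` rows and a
    ``clip_count`` entry in ``df.attrs`` recording how many values hit the
    sensor-operable span. Bit-identical for identical config + seed.
    """
    _validate_group_means(config)
    rng = np.random.default_rng(config.seed)
    rho = config.glucose_cholesterol_rho
    # Cholesky factor of the 2x2 glucose/cholesterol correlation
    l21, l22 = rho, np.sqrt(max(1.0 - rho**2, 0.0))

    rows = []
    clip_count = 0
    for g in CHRONIC_GROUPS:
        for animal in range(config.n_per_group):
            sid = f"{g}-{animal:03d}"
            intercept = {
                c: rng.normal(0.0, config.animal_sd_frac * config.baseline_sds[c])
                for c in ANALYTE_COLUMNS
            }
            for week in range(config.weeks + 1):
                z = rng.standard_normal(6)
                z[2] = l21 * z[0] + l22 * z[2]  # couple cholesterol to glucose
                values = {}
                for i, c in enumerate(ANALYTE_COLUMNS):
                    mean = (
                        config.baseline_means[c]
                        + float(np.asarray(config.effect_matrix[g][c])[week])
                        + intercept[c]
                    )
                    v = mean + config.baseline_sds[c] * z[i]
                    lo, hi = PANEL_RANGES[c]
                    if v < lo or v > hi:
                        clip_count += 1
                        v = min(max(v, lo), hi)
                    values[c] = v
                deg = severity(g, week, config) + rng.normal(0.0, config.degree_noise_sd)
                rows.append(
                    {
                        "sample_id": f"{sid}-w{week}",
                        "group": g,
                        "week": week,
                        "time_min": np.nan,
                        **values,
                        "degree": float(np.clip(deg, 0.0, 1.0)),
                    }
                )
    df = pd.DataFrame(rows, columns=list(PANEL_COLUMNS))
    df.attrs["clip_count"] = clip_count
    df.attrs["config"] = config.to_jsonable()
    return df


@dataclass
class InterventionProtocol:
    """Shape parameters of one acute intervention time course."""

    kind: str  # NORM | HG | HUA
    baseline_level: float = np.nan
    peak_level: float = np.nan
    onset_min: float = np.nan
    peak_time_min: float = np.nan
    return_time_min: float = np.nan
    duration_min: float = 60.0
    dt_s: float = 10.0
    pulse_shape: float = 6.0  # HG gamma-pulse sharpness
    rise_tau_min: float = 1.5  # HUA logistic time constant
    noise_frac: float = 0.015  # channel noise SD as a fraction of the healthy mean

    def __post_init__(self) -> None:
        if self.kind not in ACUTE_GROUPS:
            raise ValueError(f"unknown intervention {self.kind!r}")
        if self.dt_s <= 0:
            raise ValueError("dt_s must be > 0")
        if self.kind == "HG":
            if np.isnan(self.baseline_level):
                self.baseline_level = 4.5
            if np.isnan(self.peak_level):
                self.peak_level = 12.0
            if np.isnan(self.onset_min):
                self.onset_min = 2.0
            if np.isnan(self.peak_time_min):
                self.peak_time_min = 20.0
            if np.isnan(self.return_time_min):
                self.return_time_min = 30.0
            if self.duration_min < self.return_time_min:
                raise ValueError("HG duration must cover the return to baseline")
        elif self.kind == "HUA":
            if np.isnan(self.baseline_level):
                self.baseline_level = 160.2
            if np.isnan(self.peak_level):
                self.peak_level = 1015.0
            if np.isnan(self.onset_min):
                self.onset_min = 15.0
            if np.isnan(self.peak_time_min):
                self.peak_time_min = 25.0
            if np.isnan(self.return_time_min):
                self.return_time_min = np.inf  # plateau persists
        if not np.isnan(self.onset_min) and not np.isnan(self.peak_time_min):
            if not self.onset_min < self.peak_time_min:
                raise ValueError("onset must precede the peak")


def _hg_pulse(t_min: np.ndarray, p: InterventionProtocol) -> np.ndarray:
    """Gamma-like bolus pulse: baseline until onset, maximum exactly at
    peak_time, decayed to <2% of the excursion within return_time after it."""
    y = np.full_like(t_min, p.baseline_level)
    u = (t_min - p.onset_min) / (p.peak_time_min - p.onset_min)
    rising = u > 0
    a = p.pulse_shape
    y[rising] += (p.peak_level - p.baseline_level) * (
        u[rising] ** a * np.exp(a * (1.0 - u[rising]))
    )
    return y


def _hua_rise(t_min: np.ndarray, p: InterventionProtocol) -> np.ndarray:
    """Logistic rise centred between onset and plateau start."""
    mid = 0.5 * (p.onset_min + p.peak_time_min)
    return p.baseline_level + (p.peak_level - p.baseline_level) / (
        1.0 + np.exp(-(t_min - mid) / p.rise_tau_min)
    )


def simulate_acute(protocol: InterventionProtocol, seed: int = 0) -> pd.DataFrame:
    """Time-indexed panel table for one acute intervention.

    The targeted channel follows the protocol trajectory; every other
    channel is stationary noise about its healthy baseline. Values are true
    concentrations — sensor saturation is applied downstream by the forward
    models, so the hyperuricemic plateau may sit above the calibrated UA
    ladder.
    """
    rng = np.random.default_rng(seed)
    n = int(round(protocol.duration_min * 60.0 / protocol.dt_s))
    if n < 2:
        raise ValueError("duration too short for the sampling interval")
    t_min = np.arange(n) * protocol.dt_s / 60.0

    traj = {c: np.full(n, DEFAULT_BASELINE_MEANS[c]) for c in ANALYTE_COLUMNS}
    if protocol.kind == "HG":
        traj["glucose_mM"] = _hg_pulse(t_min, protocol)
    elif protocol.kind == "HUA":
        traj["ua_uM"] = _hua_rise(t_min, protocol)

    df = pd.DataFrame({"time_min": t_min})
    df["sample_id"] = [f"{protocol.kind}-{i:05d}" for i in range(n)]
    df["group"] = protocol.kind
    df["week"] = np.nan
    for c in ANALYTE_COLUMNS:
        noise_sd = protocol.noise_frac * DEFAULT_BASELINE_MEANS[c]
        y = traj[c] + rng.normal(0.0, noise_sd, size=n)
        lo, hi = PANEL_RANGES[c]
        df[c] = np.clip(y, lo, hi)
    df["degree"] = 0.0
    df = df[list(PANEL_COLUMNS)]
    df.attrs["protocol"] = protocol.kind
    return df


# ---------------------------------------------------------------------------
# panel table I/O

def write_panels(df: pd.DataFrame, path: str | Path,
                 config: CohortConfig | None = None, seed: int | None = None) -> None:
    """Write a panel CSV plus a JSON manifest recording config and seed."""
    path = Path(path)
    df.to_csv(path, index=False)
    manifest = {
        "rows": int(len(df)),
        "columns": list(df.columns),
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": config.to_jsonable() if config else df.attrs.get("config"),
        "clip_count": df.attrs.get("clip_count"),
    }
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))


def read_panels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel CSV missing columns: {sorted(missing)}")
    return df


def validate_panels(df: pd.DataFrame) -> None:
    """Assert every emitted panel satisfies the range and label invariants."""
    for c in ANALYTE_COLUMNS:
        lo, hi = PANEL_RANGES[c]
        v = df[c].to_numpy(dtype=float)
        if np.any(v < lo - 1e-9) or np.any(v > hi + 1e-9):
            raise AssertionError(f"channel {c} outside operable span {PANEL_RANGES[c]}")
    d = df["degree"].to_numpy(dtype=float)
    if np.any(d < -1e-12) or np.any(d > 1 + 1e-12):
        raise AssertionError("degree outside [0, 1]")
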