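"""Inverse sensor models and analytical figures of merit.

Calibration curves are ordinary least-squares fits of the steady-state
readout against concentration (amperometric channels), against
log10(concentration) (ion-selective channels) or against pH (pH channel).
The reported ``r`` is the Pearson correlation of the fit, ``sigma`` the
residual SD with ddof=2 (two fitted parameters), and the detection limit
follows LOD = 3.3·σ/S with σ the baseline-noise SD and S the slope.

Also implemented here: the bench reliability statistics used to qualify a
sensor — per-addition selectivity drift, long-session signal retention, and
relative standard deviation — and the biomarker Pearson correlation matrix.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sensors import (
    AMPEROMETRIC,
    CHANNELS,
    PH,
    POTENTIOMETRIC,
    SensorTrace,
)


@dataclass
class CalibrationCurve:
    """A fitted inverse model for one channel."""

    channel: str
    modality: str
    slope: float
    intercept: float
    r: float
    sigma: float
    lod: float
    range: tuple[float, float]
    ref_conc: float = 1.0
    ph_sign: int = -1

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("calibration slope must be nonzero")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS slope/intercept plus Pearson r and residual SD (ddof=2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired calibration points")
    if np.unique(x).size < 2:
        raise ValueError("all concentrations identical; cannot fit a line")
    res = stats.linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    sigma = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    return float(res.slope), float(res.intercept), float(res.rvalue), sigma


def compute_lod(sigma: float, slope: float) -> float:
    """Detection limit LOD = 3.3·σ/S in analyte units."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 3.3 * sigma / slope


def fit_amperometric(
    conc: Sequence[float],
    readout: Sequence[float],
    channel: str = "glucose",
    baseline_sigma: float | None = None,
) -> CalibrationCurve:
    """OLS calibration of current density on concentration.

    The LOD uses the baseline-noise SD when supplied, else the fit's
    residual SD.
    """
    slope, intercept, r, sigma = _ols(np.asarray(conc, float), readout)
    sig_for_lod = sigma if baseline_sigma is None else baseline_sigma
    lod = compute_lod(sig_for_lod, slope) if slope > 0 else np.inf
    c = np.asarray(conc, float)
    return CalibrationCurve(
        channel=channel, modality=AMPEROMETRIC, slope=slope,
        intercept=intercept, r=r, sigma=sigma, lod=lod,
        range=(float(c.min()), float(c.max())),
    )


def fit_potentiometric(
    conc: Sequence[float],
    potential: Sequence[float],
    modality: str = POTENTIOMETRIC,
    channel: str = "na",
    ref_conc: float = 1.0,
    baseline_sigma: float | None = None,
) -> CalibrationCurve:
    """OLS calibration of OCP on log10(conc) (ions) or on pH.

    For ion channels the returned slope is mV per decade; for the pH channel
    the fitted slope keeps its sign (the device convention is negative) and
    callers wanting the calibrated sensitivity take ``abs(slope)``.
    """
    c = np.asarray(conc, dtype=float)
    if modality == POTENTIOMETRIC:
        if np.any(c <= 0):
            raise ValueError("ion concentrations must be > 0")
        x = np.log10(c / ref_conc)
    elif modality == PH:
        x = c
    else:
        raise ValueError(f"unsupported modality {modality!r}")
    slope, intercept, r, sigma = _ols(x, potential)
    sig_for_lod = sigma if baseline_sigma is None else baseline_sigma
    lod = compute_lod(sig_for_lod, abs(slope)) if slope != 0 else np.inf
    curve = CalibrationCurve(
        channel=channel, modality=modality, slope=slope, intercept=intercept,
        r=r, sigma=sigma, lod=lod, range=(float(c.min()), float(c.max())),
        ref_conc=ref_conc, ph_sign=-1 if slope < 0 else 1,
    )
    return curve


class OutOfRangeReadout(float):
    """A concentration estimate outside the calibrated range (flagged, not clamped)."""

    out_of_range = True


def inverse_concentration(curve: CalibrationCurve, readout: float) -> float:
    """Exact algebraic inverse of the fitted calibration model.

    Estimates outside the calibrated range are returned as
    :class:`OutOfRangeReadout` (a float subclass flagged with
    ``out_of_range``) rather than silently clamped.
    """
    if curve.modality == AMPEROMETRIC:
        conc = (readout - curve.intercept) / curve.slope
    elif curve.modality == POTENTIOMETRIC:
        conc = curve.ref_conc * 10.0 ** ((readout - curve.intercept) / curve.slope)
    elif curve.modality == PH:
        conc = (readout - curve.intercept) / curve.slope
    else:
        raise ValueError(f"unsupported modality {curve.modality!r}")
    lo, hi = curve.range
    if not lo <= conc <= hi:
        return OutOfRangeReadout(conc)
    return float(conc)


def selectivity_drift(
    trace: SensorTrace,
    event_times: Sequence[float],
    window_s: float = 30.0,
    guard_s: float = 5.0,
) -> np.ndarray:
    """Per-addition signal drift in percent of the pre-event level.

    For each event the pre window is the ``window_s`` seconds ending
    ``guard_s`` before the event and the post window the ``window_s``
    seconds starting ``guard_s`` after it; the guard keeps mixing
    transients out of both means.
    """
    out = []
    for te in event_times:
        if te < trace.t[0] or te > trace.t[-1]:
            raise ValueError(f"event at {te} s outside the trace span")
        pre = trace.y[(trace.t >= te - guard_s - window_s) & (trace.t < te - guard_s)]
        post = trace.y[(trace.t > te + guard_s) & (trace.t <= te + guard_s + window_s)]
        if pre.size == 0 or post.size == 0:
            raise ValueError(f"event at {te} s leaves an empty window")
        pre_mean = pre.mean()
        if pre_mean == 0:
            raise ValueError("pre-event mean is zero; relative drift undefined")
        out.append(100.0 * (post.mean() - pre_mean) / pre_mean)
    return np.asarray(out)


def signal_retention(trace: SensorTrace, window_s: float = 60.0) -> float:
    """Final-window mean as a percentage of the initial-window mean."""
    if 2 * window_s > trace.duration_s:
        raise ValueError("trace too short for two disjoint windows")
    first = trace.y[trace.t <= trace.t[0] + window_s]
    last = trace.y[trace.t >= trace.t[-1] - window_s]
    if first.mean() == 0:
        raise ValueError("initial-window mean is zero; retention undefined")
    return float(100.0 * last.mean() / first.mean())


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation, 100·SD(ddof=1)/mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("mean is zero; RSD undefined")
    return float(100.0 * v.std(ddof=1) / m)


def pearson_matrix(panels: pd.DataFrame) -> pd.DataFrame:
    """6×6 Pearson correlation matrix of the biomarker channels."""
    from .cohort import ANALYTE_COLUMNS  # local import to avoid a cycle

    cols = [c for c in ANALYTE_COLUMNS if c in panels.columns]
    if len(cols) != 6:
        missing = set(ANALYTE_COLUMNS) - set(panels.columns)
        raise ValueError(f"panels table missing analyte columns: {sorted(missing)}")
    if len(panels) < 3:
        raise ValueError("need >= 3 panels")
    for c in cols:
        if np.isclose(panels[c].std(ddof=0), 0.0):
            raise ValueError(f"channel {c} is constant; correlation undefined")
    return panels[cols].corr(method="pearson")


def curve_to_dict(curve: CalibrationCurve) -> dict:
    return {
        "channel": curve.channel,
        "modality": curve.modality,
        "slope": curve.slope,
        "intercept": curve.intercept,
        "r": curve.r,
        "sigma": curve.sigma,
        "lod": curve.lod,
        "range": list(curve.range),
        "ref_conc": curve.ref_conc,
        "ph_sign": curve.ph_sign,
    }


def curves_to_json(
    curves: dict[str, CalibrationCurve], path: str | Path,
    input_hash: str | None = None,
) -> None:
    doc = {ch: curve_to_dict(c) for ch, c in curves.items()}
    doc["_meta"] = {
        "fit_time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "input_hash": input_hash,
        "channels": list(curves),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def curves_from_json(path: str | Path) -> dict[str, CalibrationCurve]:
    doc = json.loads(Path(path).read_text())
    out = {}
    for ch, d in doc.items():
        if ch == "_meta":
            continue
        out[ch] = CalibrationCurve(
            channel=d["channel"], modality=d["modality"], slope=d["slope"],
            intercept=d["intercept"], r=d["r"], sigma=d["sigma"],
            lod=d["lod"], range=tuple(d["range"]), ref_conc=d["ref_conc"],
            ph_sign=d["ph_sign"],
        )
    return out


def table_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(
        pd.util.hash_pandas_object(df, index=True).values.tobytes()
    ).hexdigest()[:16]


def calibrate_all(
    params: dict, n_points: int = 11, readout_window_s: float = 10.0,
    seed: int | None = None,
) -> dict[str, CalibrationCurve]:
    """Run a full concentration-ladder calibration through the forward models.

    Amperometric ladders are evenly spaced across the linear range;
    ion ladders use doubling steps (5→160 mM Na+, 1→32 mM K+) and the pH
    ladder unit steps, mirroring the bench protocol.
    """
    from . import sensors

    rng = np.random.default_rng(seed)
    curves: dict[str, CalibrationCurve] = {}
    for ch in CHANNELS:
        p = params[ch]
        lo, hi = p.linear_range
        if p.modality == AMPEROMETRIC:
            ladder = np.linspace(lo, hi, n_points)
        elif p.modality == POTENTIOMETRIC:
            n_doublings = int(round(np.log2(hi / lo)))
            ladder = lo * 2.0 ** np.arange(n_doublings + 1)
        else:
            ladder = np.arange(lo, hi + 0.5)
        readouts = []
        for c in ladder:
            tr = sensors.channel_forward(
                float(c), p, duration_s=60.0,
                seed=int(rng.integers(2**31 - 1)),
            )
            readouts.append(sensors.steady_state(tr, readout_window_s))
        if p.modality == AMPEROMETRIC:
            curves[ch] = fit_amperometric(
                ladder, readouts, channel=ch, baseline_sigma=p.noise_sd or None
            )
        else:
            curves[ch] = fit_potentiometric(
                ladder, readouts, modality=p.modality, channel=ch,
                ref_conc=p.ref_conc, baseline_sigma=p.noise_sd or None,
            )
    return curves
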