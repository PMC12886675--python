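"""Forward electrochemical models for the six-channel microneedle patch.

The patch carries three enzymatic channels read out by chronoamperometry
(glucose, uric acid, cholesterol; steady-state current density linear in
concentration) and three potentiometric channels read out as open-circuit
potential (Na+, K+ with a near-Nernstian log-linear response; pH with a
linear mV-per-pH response). This module is the *forward* direction: given a
true analyte concentration and per-channel parameters it synthesises the raw
sensor trace, including Gaussian noise, slow drift, additive interference
from co-present species, and motion-artifact bursts. The inverse direction
(calibration fitting, readout-to-concentration) lives in
:mod:`empatch.calibration`.

Units are carried explicitly: current density in μA·cm⁻² (sensitivities are
per cm², so no electrode area is ever needed) and potential in mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

CHANNELS = ("glucose", "ua", "cholesterol", "na", "k", "ph")

#: analyte units per channel, used in column names and serialized params
CHANNEL_UNITS = {
    "glucose": "mM",
    "ua": "uM",
    "cholesterol": "mM",
    "na": "mM",
    "k": "mM",
    "ph": "pH",
}

AMPEROMETRIC = "amperometric"
POTENTIOMETRIC = "potentiometric"
PH = "ph"


@dataclass
class ChannelParams:
    """Forward-model parameters of one sensing channel.

    slope units depend on modality: μA·cm⁻²·mM⁻¹ or μA·cm⁻²·μM⁻¹ for
    amperometric channels, mV per decade for ion-selective channels and
    mV per pH unit for the pH channel. ``ref_conc`` anchors the decade law
    (E = intercept + slope·log10(conc/ref_conc)); it only shifts the
    intercept and defaults to 1 mM. ``ph_sign`` encodes the convention that
    the PANI electrode potential falls as pH rises (E = intercept +
    ph_sign·slope·pH, default -1); it is configurable because only the
    slope magnitude is physically calibrated.
    """

    channel: str
    modality: str
    slope: float
    intercept: float = 0.0
    ref_conc: float = 1.0
    noise_sd: float = 0.0
    drift_rate: float = 0.0  # signal units per minute
    interference_coeffs: dict[str, float] = field(default_factory=dict)
    linear_range: tuple[float, float] = (0.0, 1.0)
    settle_s: float = 30.0  # chronoamperometric transient is gone after this
    ph_sign: int = -1

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"{self.channel}: slope must be > 0")
        if self.noise_sd < 0:
            raise ValueError(f"{self.channel}: noise_sd must be >= 0")
        lo, hi = self.linear_range
        if not lo < hi:
            raise ValueError(f"{self.channel}: linear_range must satisfy lo < hi")

    @property
    def signal_unit(self) -> str:
        return "uA_cm2" if self.modality == AMPEROMETRIC else "mV"


@dataclass
class SensorTrace:
    """A uniformly sampled raw signal record for one channel."""

    channel: str
    t: np.ndarray  # seconds, strictly increasing, uniform
    y: np.ndarray
    sample_rate_hz: float
    unit: str
    saturated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape or self.t.size < 2:
            raise ValueError("t and y must be equal-length with >= 2 samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0) or np.max(np.abs(dt - dt[0])) > 1e-9:
            raise ValueError("t must be strictly increasing and uniform")

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "channel": self.channel,
                "t_s": self.t,
                "y": self.y,
                "unit": self.unit,
                "saturated": self.saturated,
            }
        )


# Printed device calibrations: sensitivities and calibrated linear ranges of
# the six channels, plus baseline-noise SDs chosen so that 3.3·σ/S equals the
# device's detection limits (0.39 mM glucose, 2.7 μM UA, 0.52 mM cholesterol).
_DEVICE_SENSITIVITY = {
    "glucose": 0.1122,  # μA cm-2 mM-1
    "ua": 0.001395,  # μA cm-2 μM-1
    "cholesterol": 0.1637,  # μA cm-2 mM-1
    "na": 52.87,  # mV per decade
    "k": 58.46,  # mV per decade
    "ph": 57.61,  # mV per pH
}
_DEVICE_LOD = {"glucose": 0.39, "ua": 2.7, "cholesterol": 0.52}
_LINEAR_RANGE = {
    "glucose": (0.0, 20.0),
    "ua": (0.0, 1000.0),
    "cholesterol": (0.0, 10.0),
    "na": (5.0, 160.0),
    "k": (1.0, 32.0),
    "ph": (3.0, 8.0),
}

# Default additive interference coefficients (signal units per interferent
# concentration unit, units embedded in key names). Magnitudes are set so
# each single addition from the bench interferent panel perturbs the signal
# at the physiological operating point by ~0.5-2.5%, comfortably inside the
# 6% selectivity budget.
_INTERFERENCE = {
    "glucose": {
        "ua_uM": 2e-5, "aa_uM": 2e-5, "acetaminophen_uM": 4e-5,
        "aspirin_uM": 2e-5, "histidine_uM": 2e-6, "tryptophan_uM": 2e-6,
        "lactate_mM": 8e-4, "nacl_mM": 2e-4, "kcl_mM": 2e-4,
        "cholesterol_mM": 1e-3,
    },
    "ua": {
        "aa_uM": 2e-5, "glucose_mM": 1e-3, "cholesterol_mM": 1e-3,
        "acetaminophen_uM": 3e-5, "aspirin_uM": 1e-5, "histidine_uM": 2e-6,
        "tryptophan_uM": 2e-6, "lactate_mM": 5e-4, "nacl_mM": 2e-4,
        "kcl_mM": 2e-4,
    },
    "cholesterol": {
        "ua_uM": 3e-5, "aa_uM": 4e-5, "glucose_mM": 2e-3,
        "acetaminophen_uM": 8e-5, "aspirin_uM": 3e-5, "histidine_uM": 3e-6,
        "tryptophan_uM": 3e-6, "lactate_mM": 1.2e-3, "nacl_mM": 3e-4,
        "kcl_mM": 3e-4,
    },
    "na": {
        "kcl_mM": 0.3, "mgcl2_mM": 0.4, "cacl2_mM": 0.3, "glucose_mM": 0.1,
        "ua_uM": 0.002, "cholesterol_mM": 0.1,
    },
    "k": {
        "nacl_mM": 0.25, "mgcl2_mM": 0.4, "cacl2_mM": 0.35, "glucose_mM": 0.1,
        "ua_uM": 0.002, "cholesterol_mM": 0.1,
    },
    "ph": {
        "nacl_mM": 0.2, "kcl_mM": 0.2, "mgcl2_mM": 0.3, "cacl2_mM": 0.3,
        "glucose_mM": 0.1, "ua_uM": 0.0015, "cholesterol_mM": 0.1,
    },
}

# Bench interferent panels (concentration steps added during selectivity
# characterisation) at the stated concentrations.
ENZYMATIC_INTERFERENT_PANEL = {
    "ua_uM": 300.0, "aa_uM": 300.0, "nacl_mM": 5.0, "kcl_mM": 5.0,
    "histidine_uM": 500.0, "tryptophan_uM": 500.0, "aspirin_uM": 100.0,
    "acetaminophen_uM": 100.0, "lactate_mM": 5.0,
}
ION_INTERFERENT_PANEL = {
    "nacl_mM": 5.0, "kcl_mM": 5.0, "mgcl2_mM": 2.0, "cacl2_mM": 4.0,
    "glucose_mM": 5.0, "ua_uM": 300.0, "cholesterol_mM": 5.0,
}

# Slow sensor drift defaults (signal units / min), a bench-scenario parameter
# representing gradual fouling; magnitudes correspond to ~0.04%/min of the
# physiological operating-point signal so a 120-min session retains >88%.
_DRIFT_PER_MIN = {
    "glucose": -2.2e-4,
    "ua": -1.6e-4,
    "cholesterol": -3.2e-4,
    "na": -0.04,
    "k": -0.08,
    "ph": -0.08,
}

_E0 = {"na": -13.46, "k": 180.0, "ph": 600.0}  # mV, anchor intercepts


def device_channel_params() -> dict[str, ChannelParams]:
    """Per-channel forward-model parameters from the device's printed calibrations."""
    params: dict[str, ChannelParams] = {}
    for ch in ("glucose", "ua", "cholesterol"):
        sigma = _DEVICE_LOD[ch] * _DEVICE_SENSITIVITY[ch] / 3.3
        params[ch] = ChannelParams(
            channel=ch,
            modality=AMPEROMETRIC,
            slope=_DEVICE_SENSITIVITY[ch],
            intercept=0.0,
            noise_sd=sigma,
            drift_rate=_DRIFT_PER_MIN[ch],
            interference_coeffs=dict(_INTERFERENCE[ch]),
            linear_range=_LINEAR_RANGE[ch],
        )
    for ch in ("na", "k"):
        params[ch] = ChannelParams(
            channel=ch,
            modality=POTENTIOMETRIC,
            slope=_DEVICE_SENSITIVITY[ch],
            intercept=_E0[ch],
            ref_conc=1.0,
            noise_sd=0.5,
            drift_rate=_DRIFT_PER_MIN[ch],
            interference_coeffs=dict(_INTERFERENCE[ch]),
            linear_range=_LINEAR_RANGE[ch],
        )
    params["ph"] = ChannelParams(
        channel="ph",
        modality=PH,
        slope=_DEVICE_SENSITIVITY["ph"],
        intercept=_E0["ph"],
        noise_sd=0.5,
        drift_rate=_DRIFT_PER_MIN["ph"],
        interference_coeffs=dict(_INTERFERENCE["ph"]),
        linear_range=_LINEAR_RANGE["ph"],
    )
    return params


def noiseless(params: ChannelParams) -> ChannelParams:
    """Copy of ``params`` with noise and drift switched off."""
    return replace(params, noise_sd=0.0, drift_rate=0.0)


def _time_axis(duration_s: float, dt_s: float) -> np.ndarray:
    n = int(round(duration_s / dt_s))
    if n < 2:
        raise ValueError("duration too short for the requested sampling interval")
    return np.arange(n) * dt_s


def steady_value(conc: float, params: ChannelParams) -> float:
    """Noiseless steady-state signal for a concentration (no saturation check)."""
    if params.modality == AMPEROMETRIC:
        return params.intercept + params.slope * conc
    if params.modality == POTENTIOMETRIC:
        if conc <= 0:
            raise ValueError(f"{params.channel}: ion concentration must be > 0")
        return params.intercept + params.slope * np.log10(conc / params.ref_conc)
    if params.modality == PH:
        return params.intercept + params.ph_sign * params.slope * conc
    raise ValueError(f"unknown modality {params.modality!r}")


def amperometric_forward(
    conc: float,
    params: ChannelParams,
    duration_s: float = 60.0,
    seed: int | None = None,
    dt_s: float = 1.0,
    transient_amp: float = 0.0,
) -> SensorTrace:
    """Synthesise a chronoamperometric trace at a fixed concentration.

    Out-of-range concentrations saturate: the emitted signal corresponds to
    the nearest edge of the calibrated linear range and the trace is flagged.
    The optional initial exponential transient (amplitude ``transient_amp``
    above steady state) decays to <1% within ``params.settle_s``.
    """
    if params.modality != AMPEROMETRIC:
        raise ValueError(f"{params.channel} is not an amperometric channel")
    lo, hi = params.linear_range
    saturated = not (lo <= conc <= hi)
    conc_eff = float(np.clip(conc, lo, hi))
    t = _time_axis(duration_s, dt_s)
    y = np.full_like(t, params.intercept + params.slope * conc_eff)
    if transient_amp:
        tau = params.settle_s / 5.0  # exp(-5) < 1% remaining at settle_s
        y = y + transient_amp * np.exp(-t / tau)
    y = y + params.drift_rate * t / 60.0
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd, size=t.size)
    return SensorTrace(
        channel=params.channel, t=t, y=y, sample_rate_hz=1.0 / dt_s,
        unit=params.signal_unit, saturated=saturated,
        meta={"seed": seed, "conc": conc},
    )


def potentiometric_forward(
    conc: float,
    params: ChannelParams,
    duration_s: float = 60.0,
    seed: int | None = None,
    dt_s: float = 1.0,
) -> SensorTrace:
    """Synthesise an open-circuit-potential trace (ion or pH channel).

    Ion channels follow E = intercept + slope·log10(conc/ref_conc), so a
    tenfold concentration step moves the potential by exactly one slope.
    The pH channel is linear in pH with the configured sign convention.
    """
    if params.modality not in (POTENTIOMETRIC, PH):
        raise ValueError(f"{params.channel} is not a potentiometric channel")
    if params.modality == POTENTIOMETRIC and conc <= 0:
        raise ValueError(f"{params.channel}: ion concentration must be > 0")
    lo, hi = params.linear_range
    # the log-linear law extends beyond the calibrated window; out-of-range
    # readings are flagged rather than clamped
    saturated = not (lo <= conc <= hi)
    t = _time_axis(duration_s, dt_s)
    y = np.full_like(t, steady_value(conc, params))
    y = y + params.drift_rate * t / 60.0
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, params.noise_sd, size=t.size)
    return SensorTrace(
        channel=params.channel, t=t, y=y, sample_rate_hz=1.0 / dt_s,
        unit="mV", saturated=saturated, meta={"seed": seed, "conc": conc},
    )


def channel_forward(
    conc: float, params: ChannelParams, duration_s: float = 60.0,
    seed: int | None = None, dt_s: float = 1.0,
) -> SensorTrace:
    """Dispatch to the modality-appropriate forward model."""
    if params.modality == AMPEROMETRIC:
        return amperometric_forward(conc, params, duration_s, seed, dt_s)
    return potentiometric_forward(conc, params, duration_s, seed, dt_s)


def apply_interference(
    conc_target: float,
    interferents: Mapping[str, float],
    params: ChannelParams,
) -> float:
    """Additive signal offset Δy = Σ_j α_j·C_j from co-present species.

    Raises ``KeyError`` listing the channel's known interferents when an
    unknown name is supplied; negative concentrations are rejected.
    """
    delta = 0.0
    for name, c in interferents.items():
        if c < 0:
            raise ValueError(f"negative interferent concentration for {name}")
        if name not in params.interference_coeffs:
            known = sorted(params.interference_coeffs)
            raise KeyError(
                f"unknown interferent {name!r} for channel {params.channel}; "
                f"known: {known}"
            )
        delta += params.interference_coeffs[name] * c
    return delta


def add_artifacts(
    trace: SensorTrace,
    drift_rate: float = 0.0,
    motion: Mapping | None = None,
    seed: int | None = None,
) -> SensorTrace:
    """Pure transform adding linear drift and motion-artifact bursts.

    ``motion`` is a mapping with ``amplitude`` (signal units) and ``times``
    (burst onsets, s); each burst is a damped 8 Hz oscillation lasting ~1 s.
    The substrate-comparison scenario uses a 4:1 amplitude ratio between the
    stiff-backing and elastomer-backing variants.
    """
    y = trace.y + drift_rate * trace.t / 60.0
    if motion:
        amp = float(motion["amplitude"])
        rng = np.random.default_rng(seed)
        for t0 in np.atleast_1d(np.asarray(motion["times"], dtype=float)):
            mask = trace.t >= t0
            dt = trace.t[mask] - t0
            jitter = 1.0 + 0.02 * rng.standard_normal()
            y = y.copy()
            y[mask] = y[mask] + amp * jitter * np.exp(-dt / 0.4) * np.sin(
                2 * np.pi * 8.0 * dt
            )
    return SensorTrace(
        channel=trace.channel, t=trace.t.copy(), y=y,
        sample_rate_hz=trace.sample_rate_hz, unit=trace.unit,
        saturated=trace.saturated, meta=dict(trace.meta),
    )


def steady_state(trace: SensorTrace, window_s: float) -> float:
    """Mean signal over the trailing window — the calibrated readout."""
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if window_s > trace.duration_s + 1.0 / trace.sample_rate_hz:
        raise ValueError("readout window longer than the trace")
    mask = trace.t >= trace.t[-1] - window_s + 0.5 / trace.sample_rate_hz
    return float(trace.y[mask].mean())


# ---------------------------------------------------------------------------
# serialisation

def traces_to_csv(traces: Sequence[SensorTrace], path: str | Path) -> None:
    pd.concat([tr.to_frame() for tr in traces], ignore_index=True).to_csv(
        path, index=False
    )


def params_to_yaml(params: Mapping[str, ChannelParams], path: str | Path) -> None:
    doc = {}
    for ch, p in params.items():
        doc[ch] = {
            "modality": p.modality,
            "slope": float(p.slope),
            "intercept": float(p.intercept),
            "ref_conc_mM": float(p.ref_conc),
            "noise_sd": float(p.noise_sd),
            "drift_rate_per_min": float(p.drift_rate),
            "interference_coeffs": {k: float(v) for k, v in p.interference_coeffs.items()},
            "linear_range": [float(p.linear_range[0]), float(p.linear_range[1])],
            "settle_s": float(p.settle_s),
            "ph_sign": int(p.ph_sign),
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def params_from_yaml(path: str | Path) -> dict[str, ChannelParams]:
    doc = yaml.safe_load(Path(path).read_text())
    out = {}
    for ch, d in doc.items():
        out[ch] = ChannelParams(
            channel=ch,
            modality=d["modality"],
            slope=d["slope"],
            intercept=d["intercept"],
            ref_conc=d["ref_conc_mM"],
            noise_sd=d["noise_sd"],
            drift_rate=d["drift_rate_per_min"],
            interference_coeffs=dict(d["interference_coeffs"]),
            linear_range=tuple(d["linear_range"]),
            settle_s=d["settle_s"],
            ph_sign=d["ph_sign"],
        )
    return out
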