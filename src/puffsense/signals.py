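"""Raw-signal processing into the four network predictors.

Pipeline per puff: per-band attenuation from the baseline intensities,
inhalation pressure from the trailing baseline, resampling onto the common
optical time grid, detection of the effective window where the red-channel
attenuation exceeds 1/10 of its maximum, then the three attenuation AUCs and
the mean inhalation pressure over that window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import RawPuffSignals

__all__ = [
    "AttenuationTraces",
    "EffectiveWindow",
    "FeatureVector",
    "NoPuffDetectedError",
    "compute_attenuation",
    "compute_inhalation_pressure",
    "resample_common_grid",
    "detect_effective_window",
    "extract_features",
    "process_puff",
    "features_to_frame",
]

logger = logging.getLogger(__name__)

BASELINE_SECONDS = 2.0
INTENSITY_FLOOR_REL = 1e-6  # floor, as a fraction of I0, applied before the log


class NoPuffDetectedError(RuntimeError):
    """The red-channel attenuation never rises above the noise floor."""


@dataclass(frozen=True)
class AttenuationTraces:
    """Per-band base-10 attenuation and inhalation pressure on a common grid."""

    time: np.ndarray
    a_uv: np.ndarray
    a_r: np.ndarray
    a_ir: np.ndarray
    delta_p: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.time).size
        for name in ("a_uv", "a_r", "a_ir", "delta_p"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.size != n or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and match the time grid")

    def channel(self, label: str) -> np.ndarray:
        return {"uv": self.a_uv, "r": self.a_r, "ir": self.a_ir}[label.lower()]


@dataclass(frozen=True)
class EffectiveWindow:
    t0: float
    t1: float

    def __post_init__(self) -> None:
        if not (self.t0 < self.t1):
            raise ValueError("window requires t0 < t1")


@dataclass(frozen=True)
class FeatureVector:
    """The four predictors: attenuation AUCs (attenuation*s) and mean dP (Pa)."""

    auc_uv: float
    auc_r: float
    auc_ir: float
    mean_dp: float

    def as_array(self) -> np.ndarray:
        return np.array([self.auc_uv, self.auc_r, self.auc_ir, self.mean_dp])


def _baseline_mean(time: np.ndarray, values: np.ndarray, seconds: float, tail: bool):
    if time[-1] - time[0] < 2 * seconds:
        raise ValueError("trace too short for leading and trailing baseline windows")
    mask = time >= time[-1] - seconds if tail else time <= time[0] + seconds
    return float(np.mean(values[mask]))


def compute_attenuation(
    raw: RawPuffSignals, baseline_seconds: float = BASELINE_SECONDS
) -> dict:
    """A_j(t) = -log10(I_j(t)/I0_j); I0_j is the mean over the first 2 s.

    Intensities are floored at ``1e-6 * I0`` before the log so noise-driven
    negative samples cannot produce non-finite attenuation.
    """
    t = raw.optical_time
    out = {}
    for label, sig in (
        ("uv", raw.intensity_uv),
        ("r", raw.intensity_r),
        ("ir", raw.intensity_ir),
    ):
        i0 = _baseline_mean(t, sig, baseline_seconds, tail=False)
        if i0 <= 0:
            raise ValueError(f"non-positive baseline intensity for band {label!r}")
        floored = np.maximum(sig, INTENSITY_FLOOR_REL * i0)
        out[label] = -np.log10(floored / i0)
    return out


def compute_inhalation_pressure(
    raw: RawPuffSignals, baseline_seconds: float = BASELINE_SECONDS
) -> np.ndarray:
    """dP(t) = P_amb - P(t), with P_amb the mean over the final 2 s."""
    p_amb = _baseline_mean(raw.pressure_time, raw.pressure_abs, baseline_seconds, tail=True)
    return p_amb - raw.pressure_abs


def resample_common_grid(raw: RawPuffSignals, baseline_seconds: float = BASELINE_SECONDS
                         ) -> AttenuationTraces:
    """Attenuation and pressure on the optical grid (pressure linearly
    interpolated; no extrapolation beyond the recorded pressure span)."""
    atten = compute_attenuation(raw, baseline_seconds)
    dp = compute_inhalation_pressure(raw, baseline_seconds)
    t_opt, t_pre = raw.optical_time, raw.pressure_time
    lo, hi = max(t_opt[0], t_pre[0]), min(t_opt[-1], t_pre[-1])
    if lo >= hi:
        raise ValueError("optical and pressure traces do not overlap in time")
    mask = (t_opt >= lo) & (t_opt <= hi)
    t = t_opt[mask]
    dp_resampled = np.interp(t, t_pre, dp)
    return AttenuationTraces(
        t, atten["uv"][mask], atten["r"][mask], atten["ir"][mask], dp_resampled
    )


def _crossings(t: np.ndarray, a: np.ndarray, level: float) -> list:
    """All threshold crossing times, located by linear interpolation."""
    above = a >= level
    idx = np.nonzero(above[1:] != above[:-1])[0]
    times = []
    for i in idx:
        frac = (level - a[i]) / (a[i + 1] - a[i])
        times.append(t[i] + frac * (t[i + 1] - t[i]))
    return times


def detect_effective_window(
    traces: AttenuationTraces,
    channel: str = "r",
    threshold_fraction: float = 0.1,
    noise_floor: float = 0.02,
) -> EffectiveWindow:
    """Window [t0, t1] where the chosen channel exceeds 1/10 of its maximum.

    t0 is the first upward crossing and t1 the last downward crossing; extra
    crossings from noisy shoulders are logged and subsumed by the
    first-rise / last-fall convention.
    """
    a = traces.channel(channel)
    peak = float(np.max(a))
    if peak <= noise_floor:
        raise NoPuffDetectedError(
            f"max attenuation {peak:.4g} below noise floor {noise_floor}"
        )
    level = threshold_fraction * peak
    times = _crossings(traces.time, a, level)
    if len(times) < 2:
        # pulse may touch a trace edge; fall back to the sampled support
        above = np.nonzero(a >= level)[0]
        return EffectiveWindow(traces.time[above[0]], traces.time[above[-1]])
    if len(times) > 2:
        logger.warning(
            "window detection found %d threshold crossings; using first rise "
            "and last fall", len(times),
        )
    return EffectiveWindow(times[0], times[-1])


def _window_integral(t: np.ndarray, a: np.ndarray, window: EffectiveWindow) -> float:
    """Trapezoidal integral over [t0, t1] with interpolated endpoints."""
    inside = (t > window.t0) & (t < window.t1)
    tt = np.concatenate(([window.t0], t[inside], [window.t1]))
    aa = np.concatenate(
        ([np.interp(window.t0, t, a)], a[inside], [np.interp(window.t1, t, a)])
    )
    return float(np.trapezoid(aa, tt))


def extract_features(traces: AttenuationTraces, window: EffectiveWindow) -> FeatureVector:
    """AUC of each band over the window; arithmetic mean of dP over the
    samples inside the window."""
    t = traces.time
    if window.t0 < t[0] or window.t1 > t[-1]:
        raise ValueError("window lies outside the trace span")
    in_win = (t >= window.t0) & (t <= window.t1)
    if not np.any(in_win):
        raise ValueError("window contains no samples")
    return FeatureVector(
        auc_uv=_window_integral(t, traces.a_uv, window),
        auc_r=_window_integral(t, traces.a_r, window),
        auc_ir=_window_integral(t, traces.a_ir, window),
        mean_dp=float(np.mean(traces.delta_p[in_win])),
    )


def process_puff(raw: RawPuffSignals, **window_kwargs) -> FeatureVector:
    """Raw record -> FeatureVector (the full per-puff processing chain)."""
    traces = resample_common_grid(raw)
    window = detect_effective_window(traces, **window_kwargs)
    return extract_features(traces, window)


def features_to_frame(features, puff_ids=None) -> pd.DataFrame:
    """Tabulate FeatureVectors as (puff_id, auc_uv, auc_r, auc_ir, mean_dp_pa)."""
    ids = puff_ids if puff_ids is not None else range(len(features))
    return pd.DataFrame(
        [
            {
                "puff_id": i,
                "auc_uv": f.auc_uv,
                "auc_r": f.auc_r,
                "auc_ir": f.auc_ir,
                "mean_dp_pa": f.mean_dp,
            }
            for i, f in zip(ids, features)
        ]
    )
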