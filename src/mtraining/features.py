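"""Steady-state feature extraction from raw gas-sensor response curves.

A sampling experiment exposes the metal-oxide sensor array (TGS2620,
TGS2602 and the two-output TGS2201) to clean air for a baseline phase,
then to the target gas, then to clean air again for recovery, sampled at
1 Hz.  The feature used downstream is, per channel, the maximum response
during the steady-state (exposure) window — four numbers per experiment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Sample

logger = logging.getLogger(__name__)

#: Fixed gas-channel order of the feature vector.  TGS2201 has two outputs.
GAS_CHANNELS = ("TGS2620", "TGS2602", "TGS2201A", "TGS2201B")

__all__ = ["GAS_CHANNELS", "ResponseCurve", "extract_steady_state_max",
           "curves_to_sample", "read_curve_csv"]


@dataclass
class ResponseCurve:
    """Multi-channel sensor time series on a uniform 1 Hz grid.

    Parameters
    ----------
    channel_names : ordered channel identifiers.
    times : seconds from experiment start, strictly increasing, uniform.
    values : array (n_times, n_channels) of sensor responses.
    baseline_end, exposure_end, recovery_end : phase boundaries in seconds
        (clean air / gas exposure / clean-air recovery).
    """

    channel_names: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    baseline_end: float
    exposure_end: float
    recovery_end: float

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (len(self.times), len(self.channel_names)):
            raise ValueError("values must have shape (n_times, n_channels)")
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if not (0 < self.baseline_end < self.exposure_end < self.recovery_end <= self.times[-1] + 1e-9):
            raise ValueError("phase marks must satisfy 0 < baseline_end < exposure_end "
                             "< recovery_end <= last time")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.channel_names.index(name)]


def extract_steady_state_max(curve: ResponseCurve,
                             window: tuple[float, float] | None = None,
                             subtract_baseline_mean: bool = False) -> np.ndarray:
    """Per-channel maximum response within the steady-state window.

    The default window is the gas-exposure phase
    ``[baseline_end, exposure_end]``.  With ``subtract_baseline_mean`` the
    per-channel mean over ``[0, baseline_end]`` is subtracted first (off
    by default: the raw maximum is the canonical feature).
    """
    if window is None:
        window = (curve.baseline_end, curve.exposure_end)
    lo, hi = window
    if lo < curve.times[0] - 1e-9 or hi > curve.times[-1] + 1e-9:
        raise ValueError("window lies outside the recorded times")
    mask = (curve.times >= lo) & (curve.times <= hi)
    if not mask.any():
        raise ValueError("window contains no grid points")
    vals = curve.values[mask]
    if np.isnan(vals).any():
        raise ValueError("NaN response inside the extraction window")
    feats = vals.max(axis=0)
    if subtract_baseline_mean:
        base_mask = curve.times <= curve.baseline_end
        feats = feats - curve.values[base_mask].mean(axis=0)
    return feats


def curves_to_sample(curve: ResponseCurve, sample_id: str,
                     label: str | None = None,
                     concentration: float | None = None,
                     window: tuple[float, float] | None = None,
                     subtract_baseline_mean: bool = False) -> Sample:
    """Reduce one experiment's curve to a 4-feature :class:`Sample`.

    Only the four gas channels in :data:`GAS_CHANNELS` enter the feature
    vector, in that fixed order; extra channels (temperature, humidity)
    are dropped.  A missing gas channel is an error.
    """
    missing = [c for c in GAS_CHANNELS if c not in curve.channel_names]
    if missing:
        raise ValueError(f"curve missing gas channel(s): {', '.join(missing)}")
    extra = [c for c in curve.channel_names if c not in GAS_CHANNELS]
    if extra:
        logger.info("curves_to_sample: dropping non-gas channel(s) %s", extra)
    feats = extract_steady_state_max(curve, window=window,
                                     subtract_baseline_mean=subtract_baseline_mean)
    order = [curve.channel_names.index(c) for c in GAS_CHANNELS]
    return Sample(sample_id, tuple(feats[order]), label, concentration)


def read_curve_csv(source, baseline_end: float = 120.0, exposure_end: float = 360.0,
                   recovery_end: float = 900.0) -> ResponseCurve:
    """Read a raw curve CSV with header ``time_s,<channel>,...``."""
    df = pd.read_csv(source)
    if "time_s" not in df.columns:
        raise ValueError("curve file missing 'time_s' column")
    channels = tuple(c for c in df.columns if c != "time_s")
    return ResponseCurve(
        channel_names=channels,
        times=df["time_s"].to_numpy(dtype=float),
        values=df[list(channels)].to_numpy(dtype=float),
        baseline_end=baseline_end,
        exposure_end=exposure_end,
        recovery_end=recovery_end,
    )
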