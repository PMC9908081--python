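"""Photoresponse and EPSC quantification for light-evoked recordings.

Voltage-clamp currents are in pA with inward currents negative;
current-clamp potentials are in mV.  Event metrics follow the standard
workflow for light-evoked EPSCs at hair-cell ribbon synapses:

* the baseline mean/SD are taken from a pre-stimulus window;
* EPSC onset is the first sustained excursion beyond baseline ±k·SD
  after light onset (k = 4 by default), latency is onset − light onset;
* amplitude and charge are measured from the light-pulse onset to the
  end of release (sustained re-entry into the baseline band after the
  peak); the return to baseline is EPSC offset − EPSC onset;
* Q20/Q50 are the charge integrals truncated 20/50 ms after light onset.

Charge is the trapezoidal integral of the baseline-subtracted current,
reported in pC (pA·ms / 1000), on possibly irregular time grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import InsufficientBaseline, NoEvent

__all__ = [
    "EphysTrace",
    "LightPulse",
    "EpscMetrics",
    "baseline_stats",
    "detect_event_onset",
    "epsc_metrics",
    "photoresponse",
    "qc_filter",
]

# Recording-quality limits: cells are excluded when leak current exceeds
# the limit (more negative) or series resistance is strictly above it.
QC_LIMITS = {
    "IHC": {"leak_pA": -50.0, "rs_MOhm": 30.0},
    "bouton": {"leak_pA": -100.0, "rs_MOhm": 80.0},
}


@dataclass
class EphysTrace:
    """One recorded sweep plus acquisition metadata."""

    time_ms: np.ndarray
    values: np.ndarray
    mode: Literal["voltage_clamp", "current_clamp"] = "voltage_clamp"
    holding_mV: float | None = None
    leak_pA: float | None = None
    series_resistance_MOhm: float | None = None
    cell_type: Literal["IHC", "bouton"] = "bouton"
    trace_id: str = ""
    series_index: int | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_ms.shape != self.values.shape:
            raise ValueError("time_ms and values must have the same shape")
        if self.time_ms.size and np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time_ms must be strictly increasing")


@dataclass(frozen=True)
class LightPulse:
    onset_ms: float
    duration_ms: float
    irradiance_mW_mm2: float | None = None

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration_ms must be > 0")


@dataclass
class EpscMetrics:
    baseline_mean_pA: float
    baseline_sd_pA: float
    onset_ms: float
    latency_ms: float
    amplitude_pA: float
    peak_time_ms: float
    offset_ms: float
    return_to_baseline_ms: float
    charge_pC: float
    Q20_pC: float
    Q50_pC: float
    truncated: bool = False

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def baseline_stats(
    trace: EphysTrace, light: LightPulse, window_ms: float = 50.0
) -> tuple[float, float]:
    """Mean and sample SD over the pre-stimulus window ending at light onset."""
    t = trace.time_ms
    mask = (t >= light.onset_ms - window_ms) & (t < light.onset_ms)
    n = int(mask.sum())
    if n < 10:
        raise InsufficientBaseline(
            f"only {n} samples in the {window_ms} ms pre-stimulus window"
        )
    vals = trace.values[mask]
    return float(vals.mean()), float(vals.std(ddof=1))


def detect_event_onset(
    trace: EphysTrace,
    light: LightPulse,
    baseline: tuple[float, float] | None = None,
    k: float = 4.0,
    m: int = 3,
) -> float:
    """First sustained excursion beyond baseline ±k·SD after light onset.

    The signal must stay outside the band for ``m`` consecutive samples
    (the ±k·SD rule alone is sample-rate dependent); pre-stimulus
    excursions are ignored.  Raises :class:`NoEvent` if no crossing.
    """
    if baseline is None:
        baseline = baseline_stats(trace, light)
    mean, sd = baseline
    t, v = trace.time_ms, trace.values
    start = int(np.searchsorted(t, light.onset_ms))
    out = np.abs(v[start:] - mean) > k * sd
    if m > 1 and out.size >= m:
        # sustained: sample i qualifies iff i..i+m-1 are all out of band
        windows = np.lib.stride_tricks.sliding_window_view(out, m)
        sustained = windows.all(axis=1)
        idx = np.flatnonzero(sustained)
    else:
        idx = np.flatnonzero(out)
    if idx.size == 0:
        raise NoEvent("no sustained excursion beyond the baseline band")
    return float(t[start + idx[0]])


def _moving_average(values: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return values
    pad = n // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, np.ones(n) / n, mode="same")[pad : pad + values.size]


def _trapz_between(t: np.ndarray, y: np.ndarray, t0: float, t1: float) -> float:
    """Trapezoidal integral of y dt over [t0, t1] (pA·ms)."""
    if t1 <= t0:
        return 0.0
    i0, i1 = np.searchsorted(t, [t0, t1])
    # sample points inside plus interpolated endpoints
    ts = np.concatenate(([t0], t[i0:i1], [t1]))
    ys = np.concatenate(
        ([np.interp(t0, t, y)], y[i0:i1], [np.interp(t1, t, y)])
    )
    keep = np.concatenate(([True], np.diff(ts) > 0))
    return float(np.trapezoid(ys[keep], ts[keep]))


def epsc_metrics(
    trace: EphysTrace,
    light: LightPulse,
    baseline: tuple[float, float] | None = None,
    k: float = 4.0,
    m: int = 3,
    offset_sustain_ms: float = 2.0,
    offset_smooth_ms: float = 1.0,
) -> EpscMetrics:
    """Quantify one light-evoked EPSC.

    The end of release (EPSC offset) is the first time after the peak at
    which the signal re-enters the ±k·SD band and stays within it for at
    least ``offset_sustain_ms``; for robustness the re-entry test runs on
    a lightly smoothed copy (``offset_smooth_ms`` moving average).  When
    the band is never re-entered the metrics are truncated at trace end
    and flagged.
    """
    if baseline is None:
        baseline = baseline_stats(trace, light)
    mean, sd = baseline
    onset = detect_event_onset(trace, light, baseline, k=k, m=m)

    t, v = trace.time_ms, trace.values
    dev = v - mean
    i_light = int(np.searchsorted(t, light.onset_ms))

    # peak: extremal signed deviation after light onset
    seg = dev[i_light:]
    i_peak = i_light + int(np.argmax(np.abs(seg)))
    amplitude = float(dev[i_peak])
    peak_time = float(t[i_peak])

    # offset: sustained re-entry into the band after the peak
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    n_smooth = max(1, int(round(offset_smooth_ms / dt)))
    smoothed_dev = _moving_average(v, n_smooth) - mean
    inside = np.abs(smoothed_dev) <= k * sd
    w = max(1, int(round(offset_sustain_ms / dt)))
    truncated = True
    offset = float(t[-1])
    post = inside[i_peak:]
    if post.size >= w:
        windows = np.lib.stride_tricks.sliding_window_view(post, w)
        hits = np.flatnonzero(windows.all(axis=1))
        if hits.size:
            offset = float(t[i_peak + hits[0]])
            truncated = False

    charge = _trapz_between(t, dev, light.onset_ms, offset) / 1000.0
    q20 = _trapz_between(t, dev, light.onset_ms, min(offset, light.onset_ms + 20.0)) / 1000.0
    q50 = _trapz_between(t, dev, light.onset_ms, min(offset, light.onset_ms + 50.0)) / 1000.0

    return EpscMetrics(
        baseline_mean_pA=mean,
        baseline_sd_pA=sd,
        onset_ms=onset,
        latency_ms=onset - light.onset_ms,
        amplitude_pA=amplitude,
        peak_time_ms=peak_time,
        offset_ms=offset,
        return_to_baseline_ms=offset - onset,
        charge_pC=charge,
        Q20_pC=q20,
        Q50_pC=q50,
        truncated=truncated,
    )


def photoresponse(
    trace: EphysTrace, light: LightPulse, baseline_window_ms: float = 50.0
) -> tuple[float, float]:
    """Peak photoresponse and time-to-peak.

    Peak is the extremal deviation from the pre-stimulus mean within
    [light onset, trace end]; works for photodepolarizations (mV,
    positive-going) and photocurrents (pA, negative-going) alike — the
    extremum of largest magnitude is reported, signed.  Ties break to the
    earliest sample.
    """
    try:
        mean, _ = baseline_stats(trace, light, baseline_window_ms)
    except InsufficientBaseline:
        pre = trace.values[trace.time_ms < light.onset_ms]
        mean = float(pre.mean()) if pre.size else 0.0
    t, v = trace.time_ms, trace.values
    i0 = int(np.searchsorted(t, light.onset_ms))
    dev = v[i0:] - mean
    if dev.size == 0:
        raise NoEvent("trace does not span the light pulse")
    i_peak = int(np.argmax(np.abs(dev)))  # argmax returns the first maximum
    return float(dev[i_peak]), float(t[i0 + i_peak] - light.onset_ms)


def qc_filter(recordings) -> tuple[list, list]:
    """Apply the recording-quality exclusion rules.

    IHCs are excluded with leak currents exceeding −50 pA (at −84 mV) or
    series resistance above 30 MΩ; boutons with leak exceeding −100 pA
    (at −94 mV) or Rs above 80 MΩ.  "Exceeding"/"above" are strict, so
    boundary values are kept.  Traces with missing metadata are excluded
    with reason ``MissingQC``.

    Returns ``(kept, excluded)`` where ``excluded`` is a list of
    ``(trace, reason)`` pairs.
    """
    kept: list = []
    excluded: list = []
    for rec in recordings:
        limits = QC_LIMITS.get(rec.cell_type)
        if limits is None:
            excluded.append((rec, f"UnknownCellType:{rec.cell_type}"))
            continue
        if rec.leak_pA is None or rec.series_resistance_MOhm is None:
            excluded.append((rec, "MissingQC"))
            continue
        if rec.leak_pA < limits["leak_pA"]:
            excluded.append((rec, f"LeakExceeds:{rec.leak_pA}pA"))
        elif rec.series_resistance_MOhm > limits["rs_MOhm"]:
            excluded.append((rec, f"RsExceeds:{rec.series_resistance_MOhm}MOhm"))
        else:
            kept.append(rec)
    return kept, excluded


def first_series_only(recordings) -> list:
    """Keep only each cell's first stimulus series when series metadata exists.

    Channelrhodopsin inactivates over repeated stimulation, so only the
    first series of evoked responses per cell is analyzed.
    """
    best: dict[str, EphysTrace] = {}
    order: list[str] = []
    for rec in recordings:
        key = rec.trace_id or id(rec)
        if key not in best:
            best[key] = rec
            order.append(key)
        elif (
            rec.series_index is not None
            and best[key].series_index is not None
            and rec.series_index < best[key].series_index
        ):
            best[key] = rec
    return [best[k] for k in order]
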