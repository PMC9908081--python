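"""Freezing and stimulation timing for opto-HPF shots.

A high-pressure-freezing machine (HPM) shot is instrumented with an
external pneumatic-pressure sensor (absolute clock starting at HPM START)
and internal chamber pressure/temperature sensors (relative clock that
only starts once chamber pressure reaches 65 bar).  The quantities of
interest per shot are

* ``T_HPM_delay = T_N2_pressurized + T_mechanics + T_specimen_at_0`` —
  the absolute time from pressing START until the specimen reaches 0 °C;
* ``stim_duration = T_HPM_delay − stim_start`` — how long the optogenetic
  light pulse overlapped the live specimen before freezing.

``T_mechanics`` is read off the pneumatic trace: the needle valve opening
produces a small dip in pneumatic pressure just before the final steady
build-up and sudden drop; the dip time minus the nominal LN2
pressurization time (~400 ms) is the per-shot mechanical delay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InsufficientShots,
    InvalidConstants,
    MissingChannel,
    NegativeMechanicsDelay,
    NoValveEvent,
)

__all__ = [
    "TimingConstants",
    "SensorShot",
    "ShotTiming",
    "specimen_freeze_offset",
    "chamber_cooling_from_shots",
    "detect_valve_opening",
    "align_internal_curves",
    "shot_timing",
]

#: StimStart values (ms after HPM START) used for the two stimulation
#: paradigms; a 100 ms pulse starting at 425 ms gives the short overlap,
#: at 390 ms the long overlap.
STIM_START_SHORT_MS = 425.0
STIM_START_LONG_MS = 390.0


@dataclass(frozen=True)
class TimingConstants:
    """Fixed delay components of the freeze-time equation (all ms).

    Defaults are the instrument-specific values for the HPM100:
    ~400 ms to pressurize the LN2, 5.41 ms for the chamber to reach 0 °C
    (mean of rise time + p/T shift over test shots), 0.01 ms for the
    sapphire disc and 1.1 ms for the sample center to follow.
    """

    T_N2_pressurized: float = 400.0
    T_chamber_at_0: float = 5.41
    T_sapphire_at_0: float = 0.01
    T_sample_center_at_0: float = 1.1
    T_chamber_at_0_sd: float = 0.26

    def __post_init__(self) -> None:
        for name in (
            "T_N2_pressurized",
            "T_chamber_at_0",
            "T_sapphire_at_0",
            "T_sample_center_at_0",
        ):
            if getattr(self, name) < 0:
                raise InvalidConstants(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class SensorShot:
    """Time series recorded during one freezing shot.

    ``pneumatic`` uses absolute time (ms from HPM START, starting at 0);
    the internal channels use a relative clock that starts when the
    chamber pressure reaches 65 bar.
    """

    shot_id: str
    pneumatic: np.ndarray  # (n, 2): time_ms, pressure_bar
    internal_pressure: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    internal_temperature: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    stim_start_ms: float = 0.0

    def __post_init__(self) -> None:
        self.pneumatic = np.asarray(self.pneumatic, dtype=float)
        self.internal_pressure = np.asarray(self.internal_pressure, dtype=float)
        self.internal_temperature = np.asarray(self.internal_temperature, dtype=float)
        if self.stim_start_ms < 0:
            raise ValueError("stim_start_ms must be >= 0")
        for name in ("pneumatic", "internal_pressure", "internal_temperature"):
            arr = getattr(self, name)
            if arr.size and np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"{name} time vector must be strictly increasing")


@dataclass
class ShotTiming:
    """Per-shot timing result."""

    shot_id: str
    t_valve_open_ms: float
    T_mechanics_ms: float
    T_specimen_at_0_ms: float
    T_HPM_delay_ms: float
    stim_start_ms: float
    stim_duration_ms: float
    condition_label: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def specimen_freeze_offset(constants: TimingConstants = TimingConstants()) -> float:
    """Time (ms) for the specimen to reach 0 °C after chamber filling starts.

    Sum of chamber, sapphire-disc and sample-center cooling delays;
    ~6.52 ms with the default constants.
    """
    return (
        constants.T_chamber_at_0
        + constants.T_sapphire_at_0
        + constants.T_sample_center_at_0
    )


def chamber_cooling_from_shots(shots) -> tuple[float, float]:
    """Estimate T_chamber_at_0 from test shots.

    Each shot contributes ``rise_time + shift``: the time for chamber
    pressure to reach 2100 bar plus the pressure/temperature shift until
    the chamber drops below 0 °C.  Returns (sample mean, sample SD with
    n−1 denominator).
    """
    shots = list(shots)
    if len(shots) < 2:
        raise InsufficientShots("need at least 2 test shots for mean and SD")
    vals = np.array([rise + shift for rise, shift in shots], dtype=float)
    return float(vals.mean()), float(vals.std(ddof=1))


def _moving_average(values: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return values
    kernel = np.ones(n) / n
    # reflect-pad so the average stays centered at the edges
    pad = n // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + values.size]
    return out


def detect_valve_opening(
    pneumatic: np.ndarray,
    smooth_ms: float = 1.0,
    refine_ms: float = 2.0,
    min_dip_rel: float = 0.02,
) -> float:
    """Locate the valve-opening dip in the pneumatic pressure trace.

    The needle valve opening shows as a small pressure dip immediately
    before the final steady increase and sudden drop.  Procedure: smooth
    with a centered moving average (``smooth_ms`` wide), find the sudden
    drop (largest negative first difference), take the global maximum
    before it, then walk back down the rise tracking the running
    minimum; the walk stops once the signal climbs a significant
    tolerance above that minimum (``min_dip_rel`` of the signal range,
    or above the noise floor, whichever is larger), which marks a local
    minimum of real depth — the dip.  The result is refined by an argmin
    over a ±``refine_ms`` window and reported on the absolute (HPM
    START) axis.

    Raises :class:`NoValveEvent` if the trace is flat, has no drop, or
    has no dip of sufficient depth before the final rise.
    """
    arr = np.asarray(pneumatic, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 5:
        raise NoValveEvent("pneumatic trace too short")
    t, p = arr[:, 0], arr[:, 1]
    rng = p.max() - p.min()
    if rng <= 0:
        raise NoValveEvent("flat pneumatic trace")

    dt = float(np.median(np.diff(t)))
    n_smooth = max(1, int(round(smooth_ms / dt)))
    s = _moving_average(p, n_smooth)

    d = np.diff(s)
    drop_idx = int(np.argmin(d))
    if d[drop_idx] >= 0:
        raise NoValveEvent("no pressure drop found")
    # require the drop to be sudden relative to the overall range
    if -d[drop_idx] < 0.01 * rng:
        raise NoValveEvent("no sudden pressure drop found")

    peak_idx = int(np.argmax(s[: drop_idx + 1]))
    if peak_idx == 0:
        raise NoValveEvent("no rise phase before the drop")

    # noise floor of the smoothed trace, from robust raw-sample diffs
    mad = float(np.median(np.abs(np.diff(p) - np.median(np.diff(p)))))
    tol = max(min_dip_rel * rng, 6.0 * 1.4826 * mad / np.sqrt(2.0 * n_smooth))

    # walk back from the peak; stop once the signal rises `tol` above
    # the running minimum — that minimum is the dip bottom
    run_min = s[peak_idx]
    run_idx = peak_idx
    found = False
    for i in range(peak_idx, -1, -1):
        if s[i] < run_min:
            run_min = s[i]
            run_idx = i
        elif s[i] - run_min > tol and run_idx < peak_idx:
            found = True
            break
    if not found:
        raise NoValveEvent("no dip preceding the final rise")

    # refine: local minimum of the smoothed signal around the stop
    w = max(1, int(round(refine_ms / dt)))
    lo, hi = max(0, run_idx - w), min(peak_idx, run_idx + w) + 1
    dip_idx = lo + int(np.argmin(s[lo:hi]))
    return float(t[dip_idx])


def align_internal_curves(
    shot: SensorShot, t_valve_open_ms: float, delta_ms: float = 0.0
) -> dict[str, np.ndarray]:
    """Map the internal sensors' relative clocks onto the absolute axis.

    The start of the internal pressure build-up is anchored to
    ``t_valve_open + delta``; both internal series are shifted by the
    same amount so pressure and temperature stay mutually aligned.
    """
    if shot.internal_pressure.size == 0:
        raise MissingChannel("internal_pressure series is empty")
    shift = t_valve_open_ms + delta_ms - shot.internal_pressure[0, 0]
    out: dict[str, np.ndarray] = {}
    for name in ("internal_pressure", "internal_temperature"):
        arr = getattr(shot, name)
        if arr.size == 0:
            out[name] = arr.copy()
            continue
        shifted = arr.copy()
        shifted[:, 0] = shifted[:, 0] + shift
        out[name] = shifted
    return out


def _condition_label(stim_start_ms: float, stim_duration_ms: float) -> str:
    if stim_duration_ms <= 0:
        return "NotStimulated"
    if stim_start_ms == STIM_START_SHORT_MS:
        return "ShortStim"
    if stim_start_ms == STIM_START_LONG_MS:
        return "LongStim"
    return "Custom"


def shot_timing(
    shot: SensorShot,
    constants: TimingConstants = TimingConstants(),
    t_valve_open_ms: float | None = None,
    on_negative_mechanics: str = "clamp",
    **detect_kwargs,
) -> ShotTiming:
    """Compute the full per-shot timing result.

    ``t_valve_open_ms`` may be passed explicitly (e.g. read manually from
    the trace); otherwise it is detected from ``shot.pneumatic``.
    ``on_negative_mechanics`` is ``"clamp"`` (warn and clamp to 0) or
    ``"raise"``.
    """
    if t_valve_open_ms is None:
        t_valve_open_ms = detect_valve_opening(shot.pneumatic, **detect_kwargs)

    T_mech = t_valve_open_ms - constants.T_N2_pressurized
    if T_mech < 0:
        msg = (
            f"valve opening at {t_valve_open_ms:.2f} ms precedes the nominal "
            f"T_N2_pressurized = {constants.T_N2_pressurized:.2f} ms"
        )
        if on_negative_mechanics == "raise":
            raise NegativeMechanicsDelay(msg)
        warnings.warn(msg + "; clamping T_mechanics to 0", stacklevel=2)
        T_mech = 0.0

    T_spec = specimen_freeze_offset(constants)
    T_delay = constants.T_N2_pressurized + T_mech + T_spec
    stim_duration = max(0.0, T_delay - shot.stim_start_ms)
    return ShotTiming(
        shot_id=shot.shot_id,
        t_valve_open_ms=float(t_valve_open_ms),
        T_mechanics_ms=float(T_mech),
        T_specimen_at_0_ms=float(T_spec),
        T_HPM_delay_ms=float(T_delay),
        stim_start_ms=float(shot.stim_start_ms),
        stim_duration_ms=float(stim_duration),
        condition_label=_condition_label(shot.stim_start_ms, stim_duration),
    )
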