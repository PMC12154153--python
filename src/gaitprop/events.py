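"""Gait event detection and per-trial outcome measures.

Two detectors are provided, matching the two definitions used in treadmill
gait analysis:

* kinetic — foot-strike when the vertical ground reaction force reaches
  100 N, toe-off when it drops below 100 N (sub-sample localization by
  linear interpolation, with a debounce against threshold chatter);
* kinematic — foot-strike at the most anterior and toe-off at the most
  posterior fore-aft position of the lateral malleolus marker.

Step length is the fore-aft distance between the two malleoli at foot-strike,
attributed to the striking (leading) limb; peak AGRF is the maximum anterior
force between each foot-strike and the following toe-off. Per-trial outcomes
are the averages over all steps in the analysis window, and step length
asymmetry is (paretic - nonparetic) / (paretic + nonparetic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

FORCE_THRESHOLD_N = 100.0

__all__ = [
    "GaitEvents",
    "StepRecord",
    "TrialMetrics",
    "NoEventsError",
    "detect_events_kinetic",
    "detect_events_kinematic",
    "step_length_at_fs",
    "peak_agrf",
    "sla",
    "summarize_trial",
]


class NoEventsError(RuntimeError):
    """No gait events could be detected in the window."""


@dataclass
class GaitEvents:
    """Foot-strike / toe-off times (s) for one limb, FS->TO alternating."""

    fs_times: np.ndarray
    to_times: np.ndarray
    method: str  # 'kinetic' | 'kinematic'

    def __post_init__(self) -> None:
        fs, to = np.asarray(self.fs_times, float), np.asarray(self.to_times, float)
        if fs.size != to.size:
            raise ValueError("foot-strike and toe-off counts differ")
        if fs.size and (np.any(np.diff(fs) <= 0) or np.any(np.diff(to) <= 0)):
            raise ValueError("event times must be strictly increasing")
        if np.any(to <= fs):
            raise ValueError("each toe-off must follow its foot-strike")
        self.fs_times, self.to_times = fs, to


@dataclass
class StepRecord:
    striking_limb: str
    fs_time: float
    step_length: float
    stance_peak_agrf: float | None = None
    agrf_nonpositive: bool = False


@dataclass
class TrialMetrics:
    """Per-trial averaged outcomes for one walking trial."""

    mean_step_length_paretic: float
    mean_step_length_nonparetic: float
    mean_agrf_paretic: float
    mean_agrf_nonparetic: float
    sla: float
    speed: float
    n_steps_paretic: int
    n_steps_nonparetic: int
    participant_id: str = ""
    speed_condition: str = ""
    extras: dict = field(default_factory=dict)


def _crossings(t: np.ndarray, x: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated up- and down-crossing times of ``threshold``."""
    above = x >= threshold
    up = np.flatnonzero(~above[:-1] & above[1:])
    dn = np.flatnonzero(above[:-1] & ~above[1:])

    def interp(idx: np.ndarray) -> np.ndarray:
        x0, x1 = x[idx], x[idx + 1]
        frac = (threshold - x0) / (x1 - x0)
        return t[idx] + frac * (t[idx + 1] - t[idx])

    return interp(up), interp(dn)


def detect_events_kinetic(
    time: np.ndarray,
    vgrf: np.ndarray,
    threshold: float = FORCE_THRESHOLD_N,
    debounce: float = 0.05,
) -> GaitEvents:
    """Stance events for one belt from the vertical force threshold.

    Analysis starts at the first complete stance (first upward crossing);
    a trailing stance without a toe-off inside the window is dropped.
    Above- or below-threshold excursions shorter than ``debounce`` seconds
    are treated as noise and merged away.
    """
    time = np.asarray(time, float)
    vgrf = np.asarray(vgrf, float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    up, dn = _crossings(time, vgrf, threshold)
    if up.size == 0 or dn.size == 0:
        raise NoEventsError("vertical force never crosses the threshold in both directions")
    fs_arr, to_arr = _pair_debounced(up, dn, debounce)
    if fs_arr.size == 0:
        raise NoEventsError("no complete stance in window")
    return GaitEvents(fs_arr, to_arr, method="kinetic")


def _pair_debounced(up: np.ndarray, dn: np.ndarray, debounce: float) -> tuple[np.ndarray, np.ndarray]:
    """Pair upward/downward crossings into stances, merging brief excursions."""
    merged: list[list[float]] = []  # [fs, to] stance intervals
    i = j = 0
    dn = dn[dn > (up[0] if up.size else np.inf)]
    while i < up.size and j < dn.size:
        fs = up[i]
        # find the matching downward crossing after fs
        while j < dn.size and dn[j] <= fs:
            j += 1
        if j >= dn.size:
            break
        to = dn[j]
        merged.append([fs, to])
        i += 1
        while i < up.size and up[i] <= to:
            i += 1
        j += 1
    if not merged:
        return np.array([]), np.array([])
    # merge stances separated by a sub-debounce dip, drop sub-debounce blips
    out: list[list[float]] = [merged[0]]
    for fs, to in merged[1:]:
        if fs - out[-1][1] < debounce:
            out[-1][1] = to
        else:
            out.append([fs, to])
    out = [iv for iv in out if iv[1] - iv[0] >= debounce]
    if not out:
        return np.array([]), np.array([])
    arr = np.array(out)
    return arr[:, 0], arr[:, 1]


def detect_events_kinematic(
    time: np.ndarray,
    malleolus_ap: np.ndarray,
    expected_stride_time: float | None = None,
    min_separation_fraction: float = 0.5,
) -> GaitEvents:
    """Stance events for one side from the malleolus fore-aft extrema.

    Foot-strikes are the local maxima (most anterior) and toe-offs the local
    minima (most posterior) of the marker path, with a minimum peak
    separation of ``min_separation_fraction`` of the expected stride time.
    When ``expected_stride_time`` is None it is estimated from the dominant
    frequency of the (detrended) signal.
    """
    time = np.asarray(time, float)
    x = np.asarray(malleolus_ap, float)
    if x.size < 3 or np.ptp(x) < 1e-9:
        raise NoEventsError("marker channel has no extrema")
    dt = float(np.median(np.diff(time)))
    if expected_stride_time is None:
        xd = x - x.mean()
        freqs = np.fft.rfftfreq(x.size, dt)
        power = np.abs(np.fft.rfft(xd)) ** 2
        k = int(np.argmax(power[1:]) + 1)
        if freqs[k] <= 0:
            raise NoEventsError("cannot estimate stride frequency")
        expected_stride_time = 1.0 / freqs[k]
    distance = max(1, int(round(min_separation_fraction * expected_stride_time / dt)))
    fs_idx, _ = signal.find_peaks(x, distance=distance)
    to_idx, _ = signal.find_peaks(-x, distance=distance)
    if fs_idx.size == 0 or to_idx.size == 0:
        raise NoEventsError("no alternating extrema found")
    fs_t, to_t = time[fs_idx], time[to_idx]
    # keep complete FS->TO pairs: each TO is the first minimum after its FS
    fs_keep: list[float] = []
    to_keep: list[float] = []
    j = 0
    for ft in fs_t:
        while j < to_t.size and to_t[j] <= ft:
            j += 1
        if j >= to_t.size:
            break
        fs_keep.append(ft)
        to_keep.append(to_t[j])
        j += 1
    if not fs_keep:
        raise NoEventsError("no complete foot-strike/toe-off pair")
    return GaitEvents(np.array(fs_keep), np.array(to_keep), method="kinematic")


def step_length_at_fs(
    kinematic_time: np.ndarray,
    malleolus_ap_left: np.ndarray,
    malleolus_ap_right: np.ndarray,
    fs_time: float,
    striking_side: str,
) -> float:
    """Fore-aft malleolus separation at a foot-strike (leading - trailing)."""
    kinematic_time = np.asarray(kinematic_time, float)
    if not kinematic_time[0] <= fs_time <= kinematic_time[-1]:
        raise ValueError("foot-strike time outside the marker time span")
    i = int(np.argmin(np.abs(kinematic_time - fs_time)))
    xl, xr = malleolus_ap_left[i], malleolus_ap_right[i]
    if striking_side == "left":
        return float(xl - xr)
    if striking_side == "right":
        return float(xr - xl)
    raise ValueError("striking_side must be 'left' or 'right'")


def peak_agrf(
    kinetic_time: np.ndarray,
    apgrf: np.ndarray,
    fs_time: float,
    to_time: float,
) -> tuple[float, bool]:
    """Maximum anterior force in [fs, to]; flags a stance that never goes
    anterior (returns the non-positive maximum with ``flagged=True``)."""
    if to_time <= fs_time:
        raise ValueError("toe-off must follow foot-strike")
    sel = (kinetic_time >= fs_time) & (kinetic_time <= to_time)
    if not sel.any():
        raise ValueError("empty stance interval")
    peak = float(np.max(np.asarray(apgrf, float)[sel]))
    return peak, peak <= 0.0


def sla(mean_sl_paretic: float, mean_sl_nonparetic: float) -> float:
    """Step length asymmetry: (P - NP) / (P + NP); positive means longer
    paretic steps."""
    total = mean_sl_paretic + mean_sl_nonparetic
    if total <= 0:
        raise ValueError("step length sum must be > 0")
    return (mean_sl_paretic - mean_sl_nonparetic) / total


def summarize_trial(
    trial,
    paretic_side: str = "left",
    threshold: float = FORCE_THRESHOLD_N,
    expected_stride_time: float | None = None,
) -> TrialMetrics:
    """Full per-trial outcome computation on a windowed, filtered trial.

    Step lengths come from kinematic (marker-extrema) events and AGRF from
    kinetic (force-threshold) events, each metric bound to the event source
    defined for it. Returns per-limb means over all steps in the window.
    """
    other = {"left": "right", "right": "left"}
    sides = {"paretic": paretic_side, "nonparetic": other[paretic_side]}
    markers = {"left": trial.malleolus_ap_left, "right": trial.malleolus_ap_right}
    vgrf = {"left": trial.vgrf_left, "right": trial.vgrf_right}
    apgrf = {"left": trial.apgrf_left, "right": trial.apgrf_right}

    mean_sl: dict[str, float] = {}
    mean_agrf: dict[str, float] = {}
    n_steps: dict[str, int] = {}
    kin_events: dict[str, GaitEvents] = {}
    kit_events: dict[str, GaitEvents] = {}
    for limb, side in sides.items():
        ev_kin = detect_events_kinematic(
            trial.kinematic_time, markers[side], expected_stride_time=expected_stride_time
        )
        ev_kit = detect_events_kinetic(trial.kinetic_time, vgrf[side], threshold=threshold)
        kin_events[limb], kit_events[limb] = ev_kin, ev_kit
        sls = [
            step_length_at_fs(
                trial.kinematic_time, trial.malleolus_ap_left, trial.malleolus_ap_right, ft, side
            )
            for ft in ev_kin.fs_times
        ]
        peaks = [
            peak_agrf(trial.kinetic_time, apgrf[side], a, b)[0]
            for a, b in zip(ev_kit.fs_times, ev_kit.to_times)
        ]
        if not sls or not peaks:
            raise NoEventsError(f"no steps detected for the {limb} limb")
        mean_sl[limb] = float(np.mean(sls))
        mean_agrf[limb] = float(np.mean(peaks))
        n_steps[limb] = len(sls)

    return TrialMetrics(
        mean_step_length_paretic=mean_sl["paretic"],
        mean_step_length_nonparetic=mean_sl["nonparetic"],
        mean_agrf_paretic=mean_agrf["paretic"],
        mean_agrf_nonparetic=mean_agrf["nonparetic"],
        sla=sla(mean_sl["paretic"], mean_sl["nonparetic"]),
        speed=trial.belt_speed,
        n_steps_paretic=n_steps["paretic"],
        n_steps_nonparetic=n_steps["nonparetic"],
        participant_id=getattr(trial, "participant_id", ""),
        speed_condition=getattr(trial, "speed_condition", ""),
        extras={"kinematic_events": kin_events, "kinetic_events": kit_events},
    )
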