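"""Channel filtering and analysis-window selection.

Raw channels are zero-phase lowpass filtered (6 Hz kinematic, 20 Hz kinetic
by default) and the 90-120 s window of each trial is extracted for analysis.
If the force data in that window show the two belts loaded simultaneously for
longer than normal double support allows — the signature of a foot landing on
both plates — the window is shifted back to 60-90 s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synth import SyntheticTrial

KINEMATIC_CUTOFF_HZ = 6.0
KINETIC_CUTOFF_HZ = 20.0
PRIMARY_WINDOW = (90.0, 120.0)
FALLBACK_WINDOW = (60.0, 90.0)
FORCE_THRESHOLD_N = 100.0

__all__ = [
    "lowpass",
    "select_window",
    "detect_contamination",
    "filter_trial",
    "WindowSelection",
    "UnusableTrialError",
    "PRIMARY_WINDOW",
    "FALLBACK_WINDOW",
]


class UnusableTrialError(RuntimeError):
    """Both candidate analysis windows are contaminated or out of range."""


def lowpass(x: np.ndarray, cutoff: float, sample_rate: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth lowpass (dual-pass, cutoff-corrected).

    A Butterworth filter of the given order is applied forward and backward
    (``filtfilt``), doubling the effective order and cancelling phase lag.
    The design cutoff is raised by 1/(2^(1/2)-1)^(1/(2*order)) so the overall
    dual-pass response is -3 dB at the requested ``cutoff`` (Winter's
    correction). Default order 2 gives a 4th-order zero-lag filter.
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 < cutoff < sample_rate / 2.0:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    correction = (2.0 ** 0.5 - 1.0) ** (1.0 / (2.0 * order))
    wn = cutoff / correction / (sample_rate / 2.0)
    if wn >= 1.0:
        raise ValueError("corrected cutoff reaches Nyquist; lower the cutoff")
    sos = signal.butter(order, wn, btype="low", output="sos")
    padlen = 6 * (2 * order + 1)
    if x.size <= padlen:
        raise ValueError(f"series too short for stable filtering (need > {padlen} samples)")
    return signal.sosfiltfilt(sos, x)


def filter_trial(
    trial: SyntheticTrial,
    kinematic_cutoff: float = KINEMATIC_CUTOFF_HZ,
    kinetic_cutoff: float = KINETIC_CUTOFF_HZ,
) -> SyntheticTrial:
    """Lowpass every kinematic channel at 6 Hz and every kinetic one at 20 Hz."""
    fs_kin = 1.0 / np.median(np.diff(trial.kinematic_time))
    fs_kit = 1.0 / np.median(np.diff(trial.kinetic_time))
    return replace(
        trial,
        malleolus_ap_left=lowpass(trial.malleolus_ap_left, kinematic_cutoff, fs_kin),
        malleolus_ap_right=lowpass(trial.malleolus_ap_right, kinematic_cutoff, fs_kin),
        malleolus_vert_right=lowpass(trial.malleolus_vert_right, kinematic_cutoff, fs_kin),
        trochanter_vert_right=lowpass(trial.trochanter_vert_right, kinematic_cutoff, fs_kin),
        vgrf_left=lowpass(trial.vgrf_left, kinetic_cutoff, fs_kit),
        vgrf_right=lowpass(trial.vgrf_right, kinetic_cutoff, fs_kit),
        apgrf_left=lowpass(trial.apgrf_left, kinetic_cutoff, fs_kit),
        apgrf_right=lowpass(trial.apgrf_right, kinetic_cutoff, fs_kit),
    )


def _crop(trial: SyntheticTrial, window: tuple[float, float]) -> SyntheticTrial:
    a, b = window
    kin = (trial.kinematic_time >= a) & (trial.kinematic_time < b)
    kit = (trial.kinetic_time >= a) & (trial.kinetic_time < b)
    return replace(
        trial,
        kinematic_time=trial.kinematic_time[kin],
        malleolus_ap_left=trial.malleolus_ap_left[kin],
        malleolus_ap_right=trial.malleolus_ap_right[kin],
        malleolus_vert_right=trial.malleolus_vert_right[kin],
        trochanter_vert_right=trial.trochanter_vert_right[kin],
        kinetic_time=trial.kinetic_time[kit],
        vgrf_left=trial.vgrf_left[kit],
        vgrf_right=trial.vgrf_right[kit],
        apgrf_left=trial.apgrf_left[kit],
        apgrf_right=trial.apgrf_right[kit],
    )


def detect_contamination(
    vgrf_left: np.ndarray,
    vgrf_right: np.ndarray,
    time: np.ndarray,
    threshold: float = FORCE_THRESHOLD_N,
    max_double_support_fraction: float = 0.4,
) -> bool:
    """Flag windows where both belts are loaded simultaneously for too long.

    Normal double support occupies roughly 20-30% of a stride; a both-belts
    epoch longer than ``max_double_support_fraction`` of the local stride
    duration indicates a foot landed on the wrong plate. Returns False for
    empty or unloaded windows.
    """
    if len(time) == 0:
        return False
    both = (np.asarray(vgrf_left) > threshold) & (np.asarray(vgrf_right) > threshold)
    if not both.any():
        return False
    # stride duration from one belt's loading onsets
    above = np.asarray(vgrf_left) > threshold
    onsets = np.flatnonzero(~above[:-1] & above[1:])
    dt = float(np.median(np.diff(time)))
    if onsets.size >= 2:
        stride = float(np.median(np.diff(time[onsets])))
    else:
        stride = 1.2  # plausible default when one belt never cycles
    # longest contiguous both-loaded run
    padded = np.concatenate(([False], both, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    run_lengths = edges[1::2] - edges[0::2]
    longest = run_lengths.max() * dt
    return bool(longest > max_double_support_fraction * stride)


@dataclass
class WindowSelection:
    trial: SyntheticTrial
    window_used: tuple[float, float]
    fallback_used: bool


def select_window(
    trial: SyntheticTrial,
    primary: tuple[float, float] = PRIMARY_WINDOW,
    fallback: tuple[float, float] = FALLBACK_WINDOW,
    threshold: float = FORCE_THRESHOLD_N,
    max_double_support_fraction: float = 0.4,
) -> WindowSelection:
    """Crop the trial to the primary window, falling back if contaminated.

    The fallback is used only when the contamination detector flags the
    primary window; a trial too short for the primary window is an error
    (the shift-back rule exists for dirty force data, not short records).
    """
    duration = float(trial.kinetic_time[-1]) if len(trial.kinetic_time) else 0.0
    if duration < primary[1] - 1e-9:
        raise ValueError(
            f"trial duration {duration:.1f} s does not cover the primary window "
            f"[{primary[0]:.0f}, {primary[1]:.0f}] s"
        )
    cropped = _crop(trial, primary)
    if not detect_contamination(
        cropped.vgrf_left, cropped.vgrf_right, cropped.kinetic_time,
        threshold, max_double_support_fraction,
    ):
        return WindowSelection(cropped, primary, False)
    cropped = _crop(trial, fallback)
    if detect_contamination(
        cropped.vgrf_left, cropped.vgrf_right, cropped.kinetic_time,
        threshold, max_double_support_fraction,
    ):
        raise UnusableTrialError("both candidate windows show force-plate crossover")
    return WindowSelection(cropped, fallback, True)
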