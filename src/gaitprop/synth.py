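"""Synthetic treadmill gait trials with known ground truth.

Generates marker and force-plate time series that mimic split-belt treadmill
walking: sawtooth-like fore-aft malleolus trajectories (backward at belt speed
during stance, smooth forward return during swing), stance-only vertical
ground reaction forces that cross the 100 N detection threshold at the true
foot-strike and toe-off instants, and a braking-then-propulsion
anterior-posterior force whose anterior maximum equals a commanded peak.

On a treadmill at steady state the two step lengths and the stride time are
linked to belt speed by the identity

    step_length_paretic + step_length_nonparetic = belt_speed * stride_time

up to a small slip term from the post-contact velocity blend (below), so
``stride_time`` is derived from the commanded step lengths and belt speed
rather than commanded independently.

Two realism/testability choices shape the signals. First, the marker path is
C1: after foot-strike the malleolus blends from zero fore-aft velocity to the
belt speed over a short window instead of turning a sharp corner, which keeps
its spectral content low enough that the analysis lowpass filter leaves the
foot-strike position essentially untouched. Second, stride timing is
quantized to the sample grids (stride on the 100 Hz grid, stance on multiples
of 4 ms of the 1000 Hz grid) so that true foot-strikes coincide with samples
and commanded step lengths and propulsive peaks are recovered exactly in the
noiseless case; the realized belt speed is adjusted (by < 1%) to honour the
commanded step lengths under the quantized timing and is reported on the
generated trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

KINEMATIC_RATE = 100.0  # Hz
KINETIC_RATE = 1000.0  # Hz
GRAVITY = 9.81  # m/s^2
BLEND_TIME = 0.08  # s, post-contact fore-aft velocity blend

__all__ = [
    "GaitParams",
    "GroundTruth",
    "SyntheticTrial",
    "generate_trial",
    "generate_cohort",
    "CohortEffects",
]


@dataclass
class GaitParams:
    """Parameters controlling one synthetic walking trial.

    ``paretic_side`` fixes which belt/marker set carries the paretic limb.
    Step lengths are commanded per limb; with ``noise_sd_* = 0`` the pipeline
    recovers them exactly. ``crossover_times`` lists (start, end) epochs in
    seconds during which the right belt's vertical force is duplicated onto
    the left belt, emulating a participant stepping on both plates at once.
    """

    belt_speed: float = 0.8  # m/s
    step_length_paretic: float = 0.48  # m
    step_length_nonparetic: float = 0.52  # m
    agrf_peak_paretic: float = 60.0  # N
    agrf_peak_nonparetic: float = 90.0  # N
    duty_factor: float = 0.62  # stance fraction of the stride
    body_mass: float = 75.0  # kg
    leg_length: float = 0.90  # m, trochanter-to-malleolus
    trochanter_height: float = 0.95  # m above the belt
    paretic_side: str = "left"
    noise_sd_marker: float = 0.0  # m
    noise_sd_force: float = 0.0  # N
    crossover_times: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0

    @property
    def stride_time(self) -> float:
        """Nominal stride time implied by the commanded step lengths."""
        total = self.step_length_paretic + self.step_length_nonparetic
        return total / self.belt_speed + BLEND_TIME

    def validate(self) -> None:
        if not math.isfinite(self.belt_speed) or self.belt_speed <= 0:
            raise ValueError("belt_speed must be finite and > 0")
        for name in ("step_length_paretic", "step_length_nonparetic"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0")
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must lie in (0, 1)")
        for name in ("agrf_peak_paretic", "agrf_peak_nonparetic"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("noise_sd_marker", "noise_sd_force"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.paretic_side not in ("left", "right"):
            raise ValueError("paretic_side must be 'left' or 'right'")
        if self.body_mass <= 0 or self.leg_length <= 0:
            raise ValueError("body_mass and leg_length must be > 0")


@dataclass
class GroundTruth:
    """True event times and outcome values for a generated trial."""

    fs_times: dict[str, np.ndarray]  # limb -> foot-strike times (s)
    to_times: dict[str, np.ndarray]  # limb -> toe-off times (s)
    step_lengths: dict[str, float]  # limb -> commanded step length (m)
    agrf_peaks: dict[str, float]  # limb -> commanded anterior peak (N)
    leg_length: float
    paretic_side: str

    def limb_of_side(self, side: str) -> str:
        if side == self.paretic_side:
            return "paretic"
        return "nonparetic"


@dataclass
class SyntheticTrial:
    """Raw channels of one generated trial (pre-filtering)."""

    kinematic_time: np.ndarray
    malleolus_ap_left: np.ndarray
    malleolus_ap_right: np.ndarray
    malleolus_vert_right: np.ndarray
    trochanter_vert_right: np.ndarray
    kinetic_time: np.ndarray
    vgrf_left: np.ndarray
    vgrf_right: np.ndarray
    apgrf_left: np.ndarray
    apgrf_right: np.ndarray
    belt_speed: float
    participant_id: str = "synthetic"
    speed_condition: str = "self-selected"


def _side_of_limb(limb: str, paretic_side: str) -> str:
    if limb == "paretic":
        return paretic_side
    return "right" if paretic_side == "left" else "left"


@dataclass(frozen=True)
class _Timing:
    """Grid-quantized stride timing (all values in seconds)."""

    stride: float  # multiple of 20 ms -> strikes hit both sample grids
    stance: float  # multiple of 4 ms -> propulsion peak hits a 1 kHz sample
    t0: float  # first left foot-strike, multiple of 20 ms
    speed: float  # realized belt speed honouring the commanded step lengths
    blend: float


def _effective_timing(params: GaitParams) -> _Timing:
    total = params.step_length_paretic + params.step_length_nonparetic
    stride_ms = 20 * max(round(1000.0 * params.stride_time / 20.0), int(BLEND_TIME * 1000 / 20) + 2)
    speed = total / (stride_ms / 1000.0 - BLEND_TIME)
    stance_ms = 4 * round(stride_ms * params.duty_factor / 4.0)
    stance_ms = min(max(stance_ms, int(BLEND_TIME * 1000) + 4), stride_ms - 40)
    t0_ms = 20 * max(round(0.35 * stride_ms / 20.0), 1)
    return _Timing(stride_ms / 1000.0, stance_ms / 1000.0, t0_ms / 1000.0, speed, BLEND_TIME)


def _event_schedule(tm: _Timing, duration: float) -> dict[str, dict[str, np.ndarray]]:
    """Foot-strike and toe-off times per side over [0, duration].

    Left strikes at t0 + k*T, right half a stride later; toe-off follows each
    strike by the stance duration. Times are assembled in integer
    milliseconds so they coincide exactly with kinetic (and, for strikes,
    kinematic) sample instants.
    """
    stride_ms = round(tm.stride * 1000)
    stance_ms = round(tm.stance * 1000)
    t0_ms = round(tm.t0 * 1000)
    dur_ms = int(duration * 1000)
    out: dict[str, dict[str, np.ndarray]] = {}
    for side, off_ms in (("left", 0), ("right", stride_ms // 2)):
        fs_ms = np.arange(t0_ms + off_ms, dur_ms, stride_ms)
        to_ms = fs_ms + stance_ms
        keep = to_ms < dur_ms
        out[side] = {"fs": fs_ms[keep] / 1000.0, "to": to_ms[keep] / 1000.0}
    return out


def _fs_positions(params: GaitParams, tm: _Timing) -> dict[str, float]:
    """Fore-aft malleolus position of each side at its own foot-strikes.

    At a left foot-strike the right foot struck half a stride earlier and has
    been carried backward by speed * (T/2 - blend/2) (the blend halves the
    travel over its window), so
    step_length(left) = x_fs_left - x_fs_right + speed * (T/2 - blend/2).
    """
    carry = tm.speed * (tm.stride / 2.0 - tm.blend / 2.0)
    sl_left = params.step_length_paretic if params.paretic_side == "left" else params.step_length_nonparetic
    dx = sl_left - carry  # x_fs_left - x_fs_right
    return {"left": dx / 2.0, "right": -dx / 2.0}


def _marker_trajectory(t: np.ndarray, first_fs: float, x_fs: float, tm: _Timing) -> np.ndarray:
    """Piecewise fore-aft malleolus path.

    Quadratic blend from zero fore-aft velocity to -speed just after contact,
    linear backward translation for the rest of stance, cosine forward return
    in swing. The path is C1 with its local maximum exactly at each
    foot-strike and local minimum exactly at each toe-off."""
    x = np.empty_like(t)
    x_to = x_fs - tm.speed * (tm.stance - tm.blend / 2.0)
    swing_len = tm.stride - tm.stance
    phase = np.mod(t - first_fs, tm.stride)
    blend = phase < tm.blend
    stance = (phase >= tm.blend) & (phase < tm.stance)
    swing = ~blend & ~stance
    x[blend] = x_fs - tm.speed * phase[blend] ** 2 / (2.0 * tm.blend)
    x[stance] = x_fs - tm.speed * (phase[stance] - tm.blend / 2.0)
    s = (phase[swing] - tm.stance) / swing_len
    x[swing] = x_to + (x_fs - x_to) * 0.5 * (1.0 - np.cos(np.pi * s))
    return x


def _stance_forces(
    t: np.ndarray,
    fs: np.ndarray,
    to: np.ndarray,
    body_mass: float,
    agrf_peak: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vertical and anterior-posterior force for one belt.

    The vertical profile steps to 200 N at the stance edges and rises as a
    raised cosine to ~1.1 body weight in between: the 100 N threshold is
    crossed at the edge itself (and stays there under symmetric zero-phase
    smoothing, since 100 N is half the edge step). The AP profile is a
    braking half-sine followed by a propulsion half-sine whose maximum is
    exactly ``agrf_peak``.
    """
    vgrf = np.zeros_like(t)
    apgrf = np.zeros_like(t)
    edge = 200.0
    plateau = 1.1 * body_mass * GRAVITY
    braking = max(0.8 * agrf_peak, 1.0)
    for a, b in zip(fs, to):
        sel = (t >= a) & (t < b)
        s = (t[sel] - a) / (b - a)
        vgrf[sel] = edge + (plateau - edge) * 0.5 * (1.0 - np.cos(2.0 * np.pi * s))
        first = s < 0.5
        ap = np.empty_like(s)
        ap[first] = -braking * np.sin(np.pi * s[first] / 0.5)
        ap[~first] = agrf_peak * np.sin(np.pi * (s[~first] - 0.5) / 0.5)
        apgrf[sel] = ap
    return vgrf, apgrf


def generate_trial(params: GaitParams, duration: float = 150.0) -> tuple[SyntheticTrial, GroundTruth]:
    """Generate one synthetic treadmill trial plus its ground truth.

    Parameters
    ----------
    params
        Gait parameters; see :class:`GaitParams`.
    duration
        Trial length in seconds; must cover at least two strides.
    """
    params.validate()
    tm = _effective_timing(params)
    if not math.isfinite(duration) or duration < 2.0 * tm.stride:
        raise ValueError(f"duration must be >= 2 stride times ({2 * tm.stride:.2f} s)")

    rng = np.random.default_rng(params.seed)
    t_kin = np.arange(round(duration * KINEMATIC_RATE)) / KINEMATIC_RATE
    t_kit = np.arange(round(duration * KINETIC_RATE)) / KINETIC_RATE

    sched = _event_schedule(tm, duration)
    x_fs = _fs_positions(params, tm)

    markers: dict[str, np.ndarray] = {}
    vgrf: dict[str, np.ndarray] = {}
    apgrf: dict[str, np.ndarray] = {}
    for side in ("left", "right"):
        limb = "paretic" if side == params.paretic_side else "nonparetic"
        peak = params.agrf_peak_paretic if limb == "paretic" else params.agrf_peak_nonparetic
        markers[side] = _marker_trajectory(t_kin, sched[side]["fs"][0], x_fs[side], tm)
        vgrf[side], apgrf[side] = _stance_forces(
            t_kit, sched[side]["fs"], sched[side]["to"], params.body_mass, peak
        )

    # crossover contamination: right belt's load duplicated onto the left
    for a, b in params.crossover_times:
        sel = (t_kit >= a) & (t_kit < b)
        vgrf["left"][sel] = np.maximum(vgrf["left"][sel], vgrf["right"][sel])

    # vertical channels for leg-length estimation (right side only is consumed)
    troch = np.full_like(t_kin, params.trochanter_height)
    mall_vert = np.full_like(t_kin, params.trochanter_height - params.leg_length)
    # lift the foot a little during swing so the channel is not constant
    phase = np.mod(t_kin - sched["right"]["fs"][0], tm.stride)
    swing = phase >= tm.stance
    s = (phase[swing] - tm.stance) / (tm.stride - tm.stance)
    mall_vert[swing] += 0.05 * np.sin(np.pi * s)

    if params.noise_sd_marker > 0:
        for side in ("left", "right"):
            markers[side] = markers[side] + rng.normal(0.0, params.noise_sd_marker, t_kin.size)
        mall_vert = mall_vert + rng.normal(0.0, params.noise_sd_marker, t_kin.size)
        troch = troch + rng.normal(0.0, params.noise_sd_marker, t_kin.size)
    if params.noise_sd_force > 0:
        for side in ("left", "right"):
            vgrf[side] = vgrf[side] + rng.normal(0.0, params.noise_sd_force, t_kit.size)
            apgrf[side] = apgrf[side] + rng.normal(0.0, params.noise_sd_force, t_kit.size)

    trial = SyntheticTrial(
        kinematic_time=t_kin,
        malleolus_ap_left=markers["left"],
        malleolus_ap_right=markers["right"],
        malleolus_vert_right=mall_vert,
        trochanter_vert_right=troch,
        kinetic_time=t_kit,
        vgrf_left=vgrf["left"],
        vgrf_right=vgrf["right"],
        apgrf_left=apgrf["left"],
        apgrf_right=apgrf["right"],
        belt_speed=tm.speed,  # realized speed after grid quantization
    )

    def by_limb(key: str) -> dict[str, np.ndarray]:
        return {
            "paretic": sched[_side_of_limb("paretic", params.paretic_side)][key].copy(),
            "nonparetic": sched[_side_of_limb("nonparetic", params.paretic_side)][key].copy(),
        }

    truth = GroundTruth(
        fs_times=by_limb("fs"),
        to_times=by_limb("to"),
        step_lengths={
            "paretic": params.step_length_paretic,
            "nonparetic": params.step_length_nonparetic,
        },
        agrf_peaks={
            "paretic": params.agrf_peak_paretic,
            "nonparetic": params.agrf_peak_nonparetic,
        },
        leg_length=params.leg_length,
        paretic_side=params.paretic_side,
    )
    return trial, truth


@dataclass
class CohortEffects:
    """Fixed effects of the generative mixed model for cohort simulation.

    The outcome for limb level L at centered speed c is

        intercept + offset[L] + (slope + slope_offset[L]) * c + b_i + e,

    with ``b_i ~ N(0, sd_intercept^2)`` per participant and
    ``e ~ N(0, sd_resid^2)`` per row. Offsets are relative to the
    'predicted' reference level, matching the model the analysis fits.
    """

    intercept: float
    slope: float
    offset_paretic: float
    offset_nonparetic: float
    slope_offset_paretic: float
    slope_offset_nonparetic: float

    def mean(self, limb: str, cspeed: float) -> float:
        off = {"predicted": 0.0, "paretic": self.offset_paretic, "nonparetic": self.offset_nonparetic}[limb]
        soff = {
            "predicted": 0.0,
            "paretic": self.slope_offset_paretic,
            "nonparetic": self.slope_offset_nonparetic,
        }[limb]
        return self.intercept + off + (self.slope + soff) * cspeed


# Conditions mirroring the study cohort: ~32 participants, slow speed set to
# 50% of self-selected, fast ~1.3x self-selected.
DEFAULT_SPEED_RATIOS = (0.5, 1.0, 1.3)


def generate_cohort(
    n_participants: int,
    effects: CohortEffects,
    sd_intercept: float,
    sd_resid: float,
    seed: int,
    speeds: dict[str, list[float]] | None = None,
    mean_ss_speed: float = 0.8,
    sd_ss_speed: float = 0.2,
) -> pd.DataFrame:
    """Simulate a long-format limb-level cohort from the mixed model.

    Returns a DataFrame with columns participant_id, speed, limb, outcome —
    one row per (trial, limb level). Speeds per participant default to
    (0.5, 1.0, 1.3) x a lognormal-ish self-selected speed; pass ``speeds``
    to command them explicitly (participant_id -> list of speeds).
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if sd_intercept < 0 or sd_resid < 0:
        raise ValueError("variance components must be >= 0")
    rng = np.random.default_rng(seed)

    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        if speeds is not None:
            spd = list(speeds[pid])
        else:
            ss = max(0.4, rng.normal(mean_ss_speed, sd_ss_speed))
            spd = [r * ss for r in DEFAULT_SPEED_RATIOS]
        if len(spd) < 2:
            raise ValueError(f"participant {pid} needs >= 2 speeds")
        b_i = rng.normal(0.0, sd_intercept) if sd_intercept > 0 else 0.0
        for v in spd:
            for limb in ("predicted", "paretic", "nonparetic"):
                rows.append({"participant_id": pid, "speed": v, "limb": limb, "_b": b_i})
    df = pd.DataFrame(rows)
    grand_mean = df["speed"].mean()
    cs = df["speed"] - grand_mean
    mu = np.array([effects.mean(l, c) for l, c in zip(df["limb"], cs)])
    eps = rng.normal(0.0, sd_resid, len(df)) if sd_resid > 0 else np.zeros(len(df))
    df["outcome"] = mu + df.pop("_b").to_numpy() + eps
    return df
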