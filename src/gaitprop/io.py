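"""Trial file formats, run configuration, and pipeline orchestration.

Canonical interchange is plain CSV + JSON: per trial one kinematic file
(time_s, malleolus_ap_L, malleolus_ap_R, malleolus_vert_R, trochanter_vert_R;
100 Hz) and one kinetic file (time_s, vgrf_L, vgrf_R, apgrf_L, apgrf_R;
1000 Hz), all SI units with +anterior fore-aft convention, plus an optional
ground-truth JSON sidecar for synthetic trials. A run manifest (JSON) lists
participants and trials; ``run_pipeline`` executes
filter -> window -> events -> metrics -> predict -> domain filter ->
assemble -> mixed-model fits (+ robust, bootstrap, subgroups) and writes
tidy CSV outputs plus a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import predict as pred
from . import preprocess as pp
from . import stats as st
from .synth import GroundTruth, SyntheticTrial, KINEMATIC_RATE, KINETIC_RATE

KINEMATIC_COLUMNS = ["time_s", "malleolus_ap_L", "malleolus_ap_R", "malleolus_vert_R", "trochanter_vert_R"]
KINETIC_COLUMNS = ["time_s", "vgrf_L", "vgrf_R", "apgrf_L", "apgrf_R"]
RATE_TOLERANCE = 0.01  # relative tolerance on inferred sampling rate

__all__ = [
    "RunConfig",
    "read_trial_csv",
    "write_trial_csv",
    "write_ground_truth",
    "read_manifest",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Configuration of one end-to-end analysis run (defaults = stated rules)."""

    manifest: str = "manifest.json"
    output_dir: str = "results"
    window_primary: tuple[float, float] = pp.PRIMARY_WINDOW
    window_fallback: tuple[float, float] = pp.FALLBACK_WINDOW
    kinematic_cutoff_hz: float = pp.KINEMATIC_CUTOFF_HZ
    kinetic_cutoff_hz: float = pp.KINETIC_CUTOFF_HZ
    force_threshold_n: float = pp.FORCE_THRESHOLD_N
    max_double_support_fraction: float = 0.4
    prediction_spec: str | None = None  # None -> bundled synthetic demo spec
    sla_threshold: float = 0.02
    bootstrap_iters: int = 1000
    seed: int = 0
    subgroups: bool = True
    robust_agrf: bool = True
    step_length_event_source: str = "kinematic"
    agrf_event_source: str = "kinetic"

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["window_primary"] = list(self.window_primary)
        d["window_fallback"] = list(self.window_fallback)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["window_primary"] = tuple(d["window_primary"])
        d["window_fallback"] = tuple(d["window_fallback"])
        return cls(**d)


def _check_time(t: np.ndarray, declared_rate: float, label: str) -> None:
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{label}: non-monotone time column")
    rate = 1.0 / float(np.median(np.diff(t)))
    if abs(rate - declared_rate) / declared_rate > RATE_TOLERANCE:
        raise ValueError(
            f"{label}: measured sampling rate {rate:.1f} Hz does not match declared {declared_rate:.0f} Hz"
        )


def read_trial_csv(
    kinematic_path: str | Path,
    kinetic_path: str | Path,
    belt_speed: float,
    participant_id: str = "",
    speed_condition: str = "",
) -> SyntheticTrial:
    """Read and validate one trial's kinematic and kinetic CSV files."""
    kin = pd.read_csv(kinematic_path, float_precision="round_trip")
    kit = pd.read_csv(kinetic_path, float_precision="round_trip")
    for df, cols, label in ((kin, KINEMATIC_COLUMNS, "kinematic"), (kit, KINETIC_COLUMNS, "kinetic")):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{label} file missing columns: {sorted(missing)}")
        if df[cols].isna().any().any() or not np.isfinite(df[cols].to_numpy()).all():
            raise ValueError(f"{label} file contains non-finite values")
    t_kin = kin["time_s"].to_numpy(float)
    t_kit = kit["time_s"].to_numpy(float)
    _check_time(t_kin, KINEMATIC_RATE, "kinematic")
    _check_time(t_kit, KINETIC_RATE, "kinetic")
    if t_kin[0] > t_kit[-1] or t_kit[0] > t_kin[-1]:
        raise ValueError("kinematic and kinetic time spans do not overlap")
    return SyntheticTrial(
        kinematic_time=t_kin,
        malleolus_ap_left=kin["malleolus_ap_L"].to_numpy(float),
        malleolus_ap_right=kin["malleolus_ap_R"].to_numpy(float),
        malleolus_vert_right=kin["malleolus_vert_R"].to_numpy(float),
        trochanter_vert_right=kin["trochanter_vert_R"].to_numpy(float),
        kinetic_time=t_kit,
        vgrf_left=kit["vgrf_L"].to_numpy(float),
        vgrf_right=kit["vgrf_R"].to_numpy(float),
        apgrf_left=kit["apgrf_L"].to_numpy(float),
        apgrf_right=kit["apgrf_R"].to_numpy(float),
        belt_speed=float(belt_speed),
        participant_id=participant_id,
        speed_condition=speed_condition,
    )


def write_trial_csv(trial: SyntheticTrial, kinematic_path: str | Path, kinetic_path: str | Path) -> None:
    kin = pd.DataFrame(
        {
            "time_s": trial.kinematic_time,
            "malleolus_ap_L": trial.malleolus_ap_left,
            "malleolus_ap_R": trial.malleolus_ap_right,
            "malleolus_vert_R": trial.malleolus_vert_right,
            "trochanter_vert_R": trial.trochanter_vert_right,
        }
    )
    kit = pd.DataFrame(
        {
            "time_s": trial.kinetic_time,
            "vgrf_L": trial.vgrf_left,
            "vgrf_R": trial.vgrf_right,
            "apgrf_L": trial.apgrf_left,
            "apgrf_R": trial.apgrf_right,
        }
    )
    # default float repr = shortest round-trip: lossless write/read
    kin.to_csv(kinematic_path, index=False)
    kit.to_csv(kinetic_path, index=False)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    d = {
        "fs_times": {k: list(map(float, v)) for k, v in truth.fs_times.items()},
        "to_times": {k: list(map(float, v)) for k, v in truth.to_times.items()},
        "step_lengths": truth.step_lengths,
        "agrf_peaks": truth.agrf_peaks,
        "leg_length": truth.leg_length,
        "paretic_side": truth.paretic_side,
    }
    Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    m = json.loads(Path(path).read_text())
    for key in ("participants", "trials"):
        if key not in m:
            raise ValueError(f"manifest missing '{key}'")
    return m


def simulate_cohort_files(
    outdir: str | Path,
    n_participants: int = 20,
    seed: int = 0,
    duration: float = 150.0,
    mean_ss_speed: float = 0.78,
    sd_ss_speed: float = 0.20,
    mean_sla: float = 0.0,
    sd_sla: float = 0.05,
    noise_sd_marker: float = 0.002,
    noise_sd_force: float = 2.0,
) -> Path:
    """Generate a synthetic cohort on disk and return the manifest path.

    Each participant walks at slow (50% of self-selected), self-selected and
    fast (~130%) belt speeds; step-length asymmetry is a persistent
    per-participant trait, step lengths and propulsive peaks grow with speed.
    Ground-truth JSON sidecars accompany every trial.
    """
    from .synth import GaitParams, generate_trial

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants = []
    trials = []
    for i in range(n_participants):
        pid = f"P{i + 1:03d}"
        sex = "F" if rng.random() < 0.35 else "M"
        age = float(rng.uniform(30, 80))
        mass = float(np.clip(rng.normal(78, 14), 50, 120))
        leg = float(np.clip(rng.normal(0.90, 0.05), 0.75, 1.05))
        side = "left" if rng.random() < 0.5 else "right"
        ss = float(np.clip(rng.normal(mean_ss_speed, sd_ss_speed), 0.45, 1.3))
        sla_trait = float(np.clip(rng.normal(mean_sla, sd_sla), -0.25, 0.25))
        stride_time = float(np.clip(rng.normal(1.25, 0.08), 1.0, 1.5))
        participants.append(
            {"id": pid, "sex": sex, "age": age, "mass": mass, "paretic_side": side, "dataset": 1}
        )
        for cond, speed in (("slow", 0.5 * ss), ("self-selected", ss), ("fast", 1.3 * ss)):
            total_sl = speed * stride_time
            params = GaitParams(
                belt_speed=speed,
                step_length_paretic=total_sl * (1 + sla_trait) / 2,
                step_length_nonparetic=total_sl * (1 - sla_trait) / 2,
                agrf_peak_paretic=max(20.0, 25.0 + 55.0 * speed + rng.normal(0, 3)),
                agrf_peak_nonparetic=max(25.0, 45.0 + 75.0 * speed + rng.normal(0, 3)),
                body_mass=mass,
                leg_length=leg,
                paretic_side=side,
                noise_sd_marker=noise_sd_marker,
                noise_sd_force=noise_sd_force,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trial, truth = generate_trial(params, duration)
            trial.participant_id, trial.speed_condition = pid, cond
            speed = trial.belt_speed  # realized speed after grid quantization
            stem = f"{pid}_{cond.replace('self-selected', 'ss')}"
            kin_p = outdir / f"{stem}_kinematic.csv"
            kit_p = outdir / f"{stem}_kinetic.csv"
            write_trial_csv(trial, kin_p, kit_p)
            write_ground_truth(truth, outdir / f"{stem}_truth.json")
            trials.append(
                {
                    "participant_id": pid,
                    "speed_condition": cond,
                    "belt_speed": speed,
                    "kinematic_csv": str(kin_p),
                    "kinetic_csv": str(kit_p),
                }
            )
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps({"participants": participants, "trials": trials}, indent=1))
    return manifest_path


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    exclusions: pd.DataFrame
    fits: dict[str, st.LMMFit]
    slope_tables: dict[str, pd.DataFrame]
    subgroup_labels: list[st.SubgroupLabel] = field(default_factory=list)
    trial_log: list[dict] = field(default_factory=list)


def _analyze_one_trial(trial: SyntheticTrial, participant: dict, cfg: RunConfig):
    filtered = pp.filter_trial(trial, cfg.kinematic_cutoff_hz, cfg.kinetic_cutoff_hz)
    sel = pp.select_window(
        filtered, cfg.window_primary, cfg.window_fallback,
        cfg.force_threshold_n, cfg.max_double_support_fraction,
    )
    metrics = ev.summarize_trial(
        sel.trial, paretic_side=participant["paretic_side"], threshold=cfg.force_threshold_n
    )
    # leg length from the right limb's stances (vertical marker channels)
    right_vgrf = sel.trial.vgrf_right
    right_ev = ev.detect_events_kinetic(sel.trial.kinetic_time, right_vgrf, cfg.force_threshold_n)
    ll, implausible = pred.leg_length(
        sel.trial.kinematic_time,
        sel.trial.trochanter_vert_right,
        sel.trial.malleolus_vert_right,
        list(zip(right_ev.fs_times, right_ev.to_times)),
    )
    return metrics, ll, sel.fallback_used, implausible


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``; see module docs."""
    manifest = read_manifest(config.manifest)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    specs = pred.load_prediction_specs(config.prediction_spec)

    participants = {p["id"]: p for p in manifest["participants"]}
    rows: list[dict] = []
    exclusions: list[dict] = []
    log: list[dict] = []

    for tr in manifest["trials"]:
        pid = tr["participant_id"]
        part = participants[pid]
        entry = {"participant_id": pid, "speed_condition": tr.get("speed_condition", "")}
        try:
            trial = read_trial_csv(
                tr["kinematic_csv"], tr["kinetic_csv"], tr["belt_speed"],
                participant_id=pid, speed_condition=tr.get("speed_condition", ""),
            )
            metrics, ll, fallback_used, ll_implausible = _analyze_one_trial(trial, part, config)
        except (ValueError, RuntimeError) as exc:
            exclusions.append({**entry, "reasons": f"error:{exc}"})
            log.append({**entry, "status": "error", "detail": str(exc)})
            continue
        entry["window_fallback_used"] = fallback_used
        record = pred.ParticipantRecord(
            id=pid, sex=part["sex"], age=part["age"], mass=part["mass"],
            leg_length=ll, paretic_side=part["paretic_side"], dataset=part.get("dataset", 1),
        )
        decision = pred.applicability_filter(metrics, specs["step_length"])
        if not decision.keep:
            exclusions.append({**entry, "reasons": "+".join(decision.reasons)})
            log.append({**entry, "status": "excluded", "detail": "+".join(decision.reasons)})
            continue
        row = {
            **entry,
            "speed": metrics.speed,
            "mean_step_length_paretic": metrics.mean_step_length_paretic,
            "mean_step_length_nonparetic": metrics.mean_step_length_nonparetic,
            "mean_agrf_paretic": metrics.mean_agrf_paretic,
            "mean_agrf_nonparetic": metrics.mean_agrf_nonparetic,
            "sla": metrics.sla,
            "n_steps_paretic": metrics.n_steps_paretic,
            "n_steps_nonparetic": metrics.n_steps_nonparetic,
            "leg_length": ll,
            "leg_length_implausible": ll_implausible,
            "predicted_step_length": pred.predict_value(specs["step_length"], metrics.speed, record),
            "predicted_agrf": pred.predict_value(specs["agrf"], metrics.speed, record),
        }
        rows.append(row)
        log.append({**entry, "status": "ok", "detail": ""})

    metrics_df = pd.DataFrame(rows)
    exclusions_df = pd.DataFrame(exclusions, columns=["participant_id", "speed_condition", "window_fallback_used", "reasons"])
    if metrics_df.empty or metrics_df["participant_id"].nunique() < 2:
        raise RuntimeError("fewer than 2 participants survive the exclusion filters")

    fits: dict[str, st.LMMFit] = {}
    slope_tables: dict[str, pd.DataFrame] = {}
    rng_seed = config.seed

    ds_sl = st.assemble(metrics_df, "step_length")
    fits["step_length"] = st.fit_lmm(ds_sl)
    slope_tables["step_length"] = st.slope_contrasts(fits["step_length"])

    ds_agrf = st.assemble(metrics_df, "agrf")
    fitter = st.fit_robust_lmm if config.robust_agrf else st.fit_lmm
    fits["agrf"] = fitter(ds_agrf)
    slope_tables["agrf"] = st.slope_contrasts(fits["agrf"])
    if config.bootstrap_iters > 0 and metrics_df["participant_id"].nunique() >= 5:
        fits["agrf"].bootstrap_ci = st.cluster_bootstrap(
            ds_agrf, fitter, B=config.bootstrap_iters, seed=rng_seed
        )

    labels: list[st.SubgroupLabel] = []
    if config.subgroups:
        ss = metrics_df[metrics_df["speed_condition"] == "self-selected"]
        ss_sla = dict(zip(ss["participant_id"], ss["sla"]))
        have_ss = set(ss_sla)
        for outcome, ds in (("step_length", ds_sl), ("agrf", ds_agrf)):
            usable = ds.data[ds.data["participant_id"].isin(have_ss)]
            ds_use = st.LimbLevelDataset(usable.reset_index(drop=True), ds.grand_mean_speed, outcome)
            labels, subs = st.subgroup_split(ds_use, ss_sla, config.sla_threshold)
            sub_fitter = fitter if outcome == "agrf" else st.fit_lmm
            for direction, sub in subs.items():
                if sub.data["participant_id"].nunique() < 2:
                    continue
                key = f"{outcome}:{direction}"
                fits[key] = sub_fitter(sub)
                slope_tables[key] = st.slope_contrasts(fits[key])

    # ---- write outputs
    metrics_df.to_csv(outdir / "metrics.csv", index=False, float_format="%.9g")
    exclusions_df.to_csv(outdir / "exclusions.csv", index=False)
    model_rows = []
    for name, fit in fits.items():
        t = fit.tidy()
        t.insert(0, "analysis_id", name)
        model_rows.append(t)
    pd.concat(model_rows, ignore_index=True).to_csv(outdir / "models.csv", index=False, float_format="%.9g")
    slope_rows = []
    for name, t in slope_tables.items():
        t = t.copy()
        t.insert(0, "analysis_id", name)
        slope_rows.append(t)
    pd.concat(slope_rows, ignore_index=True).to_csv(outdir / "slopes.csv", index=False, float_format="%.9g")
    run_manifest = {
        "seed": config.seed,
        "bootstrap_iters": config.bootstrap_iters,
        "grand_mean_speed": {k: fits[k].grand_mean_speed for k in ("step_length", "agrf")},
        "n_trials_included": int(len(metrics_df)),
        "n_trials_excluded": int(len(exclusions_df)),
        "n_participants": int(metrics_df["participant_id"].nunique()),
        "estimators": {k: v.estimator for k, v in fits.items()},
        "subgroup_labels": [dataclasses.asdict(l) for l in labels],
    }
    (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1, sort_keys=True))
    pd.DataFrame(log).to_csv(outdir / "trial_log.csv", index=False)

    return PipelineResult(metrics_df, exclusions_df, fits, slope_tables, labels, log)
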