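"""Limb-level mixed-effects inference.

The analysis dataset is long-format: one row per (participant, trial speed,
limb level), where the limb factor has three levels — paretic, non-paretic,
and the predicted individualized value — and gait speed is centered on the
analysis sample's grand mean so the limb coefficients are interpreted at the
average speed. The model is

    outcome ~ centered_speed * limb + (1 | participant)

with 'predicted' as the reference level, so the limb dummies estimate
limb-minus-predicted offsets at the mean speed and the interaction terms
estimate limb-minus-predicted slope differences.

The random-intercept model is fit by profiled REML: for a given variance
ratio psi = sigma_b^2 / sigma_e^2 the per-cluster covariance inverts in
closed form (Sherman-Morrison), beta is the GLS solution, and sigma_e^2 is
profiled out; a one-dimensional search over log(psi) completes the fit. This
keeps a single fit fast enough for dense bootstrap and coverage simulation.
A Huber-weighted variant handles heavy-tailed residuals, and cluster
(participant-level) bootstrap percentile intervals provide confidence limits
that respect within-participant correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

LIMB_LEVELS = ("predicted", "paretic", "nonparetic")
HUBER_K = 1.345

__all__ = [
    "LimbLevelDataset",
    "LMMFit",
    "SubgroupLabel",
    "assemble",
    "fit_lmm",
    "fit_robust_lmm",
    "slope_contrasts",
    "cluster_bootstrap",
    "subgroup_split",
]


@dataclass
class LimbLevelDataset:
    """Long-format modelling table plus the centering constant."""

    data: pd.DataFrame  # participant_id, speed, centered_speed, limb, outcome
    grand_mean_speed: float
    outcome_name: str = "outcome"

    def __post_init__(self) -> None:
        need = {"participant_id", "speed", "centered_speed", "limb", "outcome"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset missing columns: {sorted(missing)}")
        bad = set(self.data["limb"]) - set(LIMB_LEVELS)
        if bad:
            raise ValueError(f"unknown limb levels: {sorted(bad)}")


def assemble(
    metrics: pd.DataFrame,
    outcome: str,
    prediction_col: str | None = None,
) -> LimbLevelDataset:
    """Build the limb-level dataset from per-trial metrics + predictions.

    ``metrics`` must contain participant_id, speed, the per-limb outcome
    columns (``mean_step_length_paretic``/... or ``mean_agrf_paretic``/...)
    and a prediction column (default ``predicted_<outcome>``). Each trial
    contributes exactly three rows; centered speed uses the grand mean over
    all included rows.
    """
    if outcome not in ("step_length", "agrf"):
        raise ValueError("outcome must be 'step_length' or 'agrf'")
    pcol = prediction_col or f"predicted_{outcome}"
    col = {"step_length": "mean_step_length", "agrf": "mean_agrf"}[outcome]
    need = {f"{col}_paretic", f"{col}_nonparetic", pcol, "participant_id", "speed"}
    missing = need - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    counts = metrics.groupby("participant_id")["speed"].nunique()
    singles = counts[counts < 2].index.tolist()
    if singles:
        import warnings

        warnings.warn(f"participants with a single speed retained: {singles}", stacklevel=2)

    rows = []
    for _, r in metrics.iterrows():
        for limb, v in (
            ("predicted", r[pcol]),
            ("paretic", r[f"{col}_paretic"]),
            ("nonparetic", r[f"{col}_nonparetic"]),
        ):
            rows.append(
                {
                    "participant_id": r["participant_id"],
                    "speed": float(r["speed"]),
                    "limb": limb,
                    "outcome": float(v),
                }
            )
    df = pd.DataFrame(rows)
    grand_mean = float(df["speed"].mean())
    df["centered_speed"] = df["speed"] - grand_mean
    return LimbLevelDataset(df, grand_mean, outcome_name=outcome)


# ---------------------------------------------------------------------------
# random-intercept REML machinery


def design_matrix(df: pd.DataFrame, reference: str = "predicted") -> tuple[np.ndarray, list[str]]:
    """Treatment-coded fixed-effects design for centered_speed * limb."""
    others = [l for l in LIMB_LEVELS if l != reference]
    cs = df["centered_speed"].to_numpy(float)
    cols = [np.ones(len(df)), cs]
    names = ["intercept", "centered_speed"]
    for lv in others:
        d = (df["limb"] == lv).to_numpy(float)
        cols.append(d)
        names.append(f"limb[{lv}]")
    for lv in others:
        d = (df["limb"] == lv).to_numpy(float)
        cols.append(cs * d)
        names.append(f"centered_speed:limb[{lv}]")
    return np.column_stack(cols), names


def _cluster_slices(groups: np.ndarray) -> list[np.ndarray]:
    idx: dict = {}
    for i, g in enumerate(groups):
        idx.setdefault(g, []).append(i)
    return [np.array(v) for v in idx.values()]


class _Blocks:
    """Per-cluster views of the design, precomputed once per fit."""

    def __init__(self, X: np.ndarray, y: np.ndarray, clusters: list[np.ndarray]):
        self.Xc = [X[ix] for ix in clusters]
        self.yc = [y[ix] for ix in clusters]
        self.idx = clusters
        self.n = len(y)
        self.p = X.shape[1]

    def weights_of(self, w: np.ndarray) -> list[np.ndarray]:
        return [w[ix] for ix in self.idx]


def _profiled_reml(blocks: _Blocks, wc: list[np.ndarray], log_psi: float):
    """GLS + profiled sigma_e^2 at a fixed variance ratio psi.

    V_i = sigma_e^2 (W_i^-1 + psi 1 1'); Sherman-Morrison gives
    Vtilde_i^-1 = W_i - psi (W_i 1)(W_i 1)' / (1 + psi s_i), s_i = sum w.
    Returns (REML criterion, beta, unscaled information A, sigma_e2).
    """
    psi = np.exp(log_psi)
    n, p = blocks.n, blocks.p
    A = np.zeros((p, p))
    c = np.zeros(p)
    logdet_v = 0.0
    cache = []
    for Xi, yi, wi in zip(blocks.Xc, blocks.yc, wc):
        s = wi.sum()
        denom = 1.0 + psi * s
        WX = Xi * wi[:, None]
        u_x = WX.sum(axis=0)
        u_y = float(wi @ yi)
        A += Xi.T @ WX - (psi / denom) * np.outer(u_x, u_x)
        c += WX.T @ yi - (psi / denom) * u_x * u_y
        logdet_v += np.log(denom) - np.log(wi).sum()
        cache.append(denom)
    beta = np.linalg.solve(A, c)
    rss = 0.0
    for Xi, yi, wi, denom in zip(blocks.Xc, blocks.yc, wc, cache):
        ri = yi - Xi @ beta
        wri = ri * wi
        rss += float(ri @ wri) - (psi / denom) * float(wri.sum()) ** 2
    rss = max(rss, 1e-300)
    sigma_e2 = rss / (n - p)
    _, logdet_a = np.linalg.slogdet(A)
    crit = (n - p) * np.log(sigma_e2) + logdet_v + logdet_a
    return crit, beta, A, sigma_e2


@dataclass
class LMMFit:
    """Fitted random-intercept mixed model."""

    params: pd.Series
    cov_params: pd.DataFrame
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    pvalues: pd.Series
    sigma_b2: float
    sigma_e2: float
    estimator: str  # 'reml' | 'robust'
    reference: str
    n_obs: int
    n_groups: int
    converged: bool = True
    n_iter: int = 0
    weights: np.ndarray | None = None
    bootstrap_ci: pd.DataFrame | None = None
    grand_mean_speed: float = float("nan")

    def tidy(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "term": self.params.index,
                "estimate": self.params.values,
                "se": self.se.values,
                "ci_low": self.ci_low.values,
                "ci_high": self.ci_high.values,
                "p": self.pvalues.values,
                "estimator": self.estimator,
            }
        )
        if self.bootstrap_ci is not None:
            out = out.merge(
                self.bootstrap_ci.rename(
                    columns={"ci_low": "boot_ci_low", "ci_high": "boot_ci_high"}
                ),
                on="term",
                how="left",
            )
        return out


def _finalize_fit(
    beta, A, sigma_e2, psi, names, n, g, estimator, reference,
    converged=True, n_iter=0, weights=None, grand_mean_speed=float("nan"),
) -> LMMFit:
    cov = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = sps.norm.ppf(0.975)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta + (beta == 0)))
    pvals = 2.0 * sps.norm.sf(np.abs(zstat))
    idx = pd.Index(names, name="term")
    return LMMFit(
        params=pd.Series(beta, index=idx),
        cov_params=pd.DataFrame(cov, index=idx, columns=idx),
        se=pd.Series(se, index=idx),
        ci_low=pd.Series(beta - z * se, index=idx),
        ci_high=pd.Series(beta + z * se, index=idx),
        pvalues=pd.Series(pvals, index=idx),
        sigma_b2=float(psi * sigma_e2),
        sigma_e2=float(sigma_e2),
        estimator=estimator,
        reference=reference,
        n_obs=n,
        n_groups=g,
        converged=converged,
        n_iter=n_iter,
        weights=weights,
        grand_mean_speed=grand_mean_speed,
    )


def _fit_weighted_reml(blocks: _Blocks, weights: np.ndarray):
    """Profiled REML over log(psi); returns (beta, A, sigma_e2, psi)."""
    n, p = blocks.n, blocks.p
    if n <= p:
        raise ValueError("singular design: more parameters than observations")
    X = np.vstack(blocks.Xc)
    y = np.concatenate(blocks.yc)
    # degenerate noiseless data: fall back to exact least squares
    beta_ols, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError("singular fixed-effects design")
    resid = y - X @ beta_ols
    scale = max(np.abs(y).max(), 1.0)
    if np.max(np.abs(resid)) < 1e-10 * scale:
        A = X.T @ (X * np.ones(n)[:, None])
        return beta_ols, A, 0.0, 0.0

    wc = blocks.weights_of(weights)

    def crit(lp: float) -> float:
        return _profiled_reml(blocks, wc, lp)[0]

    res_opt = optimize.minimize_scalar(
        crit, bounds=(-15.0, 15.0), method="bounded", options={"xatol": 1e-4}
    )
    log_psi = float(res_opt.x)
    # check the psi -> 0 boundary (no between-cluster variance)
    if crit(-30.0) <= res_opt.fun + 1e-10:
        log_psi = -30.0
    _, beta, A, sigma_e2 = _profiled_reml(blocks, wc, log_psi)
    psi = np.exp(log_psi) if log_psi > -29.0 else 0.0
    return beta, A, sigma_e2, psi


def _blocks_from(dataset: LimbLevelDataset, reference: str) -> tuple[_Blocks, list[str]]:
    df = dataset.data
    X, names = design_matrix(df, reference)
    y = df["outcome"].to_numpy(float)
    clusters = _cluster_slices(df["participant_id"].to_numpy())
    if len(clusters) < 2:
        raise ValueError("need at least 2 participants")
    return _Blocks(X, y, clusters), names


def fit_lmm(dataset: LimbLevelDataset, reference: str = "predicted") -> LMMFit:
    """REML fit of outcome ~ centered_speed * limb + (1 | participant)."""
    blocks, names = _blocks_from(dataset, reference)
    beta, A, sigma_e2, psi = _fit_weighted_reml(blocks, np.ones(blocks.n))
    return _finalize_fit(
        beta, A, sigma_e2, psi, names, blocks.n, len(blocks.idx), "reml", reference,
        grand_mean_speed=dataset.grand_mean_speed,
    )


def _blup_intercepts(blocks: _Blocks, weights: np.ndarray, beta: np.ndarray, psi: float) -> np.ndarray:
    """Empirical-Bayes random intercepts at the current fit."""
    b = np.zeros(len(blocks.idx))
    for kk, (Xi, yi, wi) in enumerate(zip(blocks.Xc, blocks.yc, blocks.weights_of(weights))):
        ri = yi - Xi @ beta
        b[kk] = psi * float(wi @ ri) / (1.0 + psi * wi.sum())
    return b


def _robust_core(
    blocks: _Blocks,
    k: float = HUBER_K,
    tol: float = 1e-8,
    max_iter: int = 100,
    w0: np.ndarray | None = None,
):
    """Huber-weighted IRLS around the profiled-REML fit."""
    w = np.ones(blocks.n) if w0 is None else np.asarray(w0, float).copy()
    beta_prev = None
    beta = A = None
    sigma_e2 = psi = 0.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta, A, sigma_e2, psi = _fit_weighted_reml(blocks, w)
        if sigma_e2 <= 0:
            converged = True
            break
        b = _blup_intercepts(blocks, w, beta, psi)
        sigma_e = np.sqrt(sigma_e2)
        sigma_b = np.sqrt(psi * sigma_e2)
        w_new = np.empty(blocks.n)
        for kk, (Xi, yi, ix) in enumerate(zip(blocks.Xc, blocks.yc, blocks.idx)):
            r = (yi - Xi @ beta - b[kk]) / sigma_e
            w_obs = np.minimum(1.0, k / np.maximum(np.abs(r), 1e-12))
            if sigma_b > 0:
                w_clu = min(1.0, k / max(abs(b[kk]) / sigma_b, 1e-12))
            else:
                w_clu = 1.0
            w_new[ix] = w_obs * w_clu
        w = w_new
        if beta_prev is not None and np.max(np.abs(beta - beta_prev)) < tol:
            converged = True
            break
        beta_prev = beta.copy()
    return beta, A, sigma_e2, psi, w, converged, it


def fit_robust_lmm(
    dataset: LimbLevelDataset,
    reference: str = "predicted",
    k: float = HUBER_K,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LMMFit:
    """Huber-weighted iteratively reweighted REML fit.

    Observations are downweighted by the Huber function (tuning constant
    ``k`` = 1.345) of their standardized conditional residuals, and whole
    clusters by the Huber function of their standardized predicted random
    intercepts, so gross outliers influence neither the fixed effects nor the
    variance components. Iteration stops when the fixed effects change by
    less than ``tol`` or after ``max_iter`` sweeps. In the Gaussian,
    outlier-free limit all weights stay ~1 and the fit matches plain REML up
    to the estimator's efficiency loss.
    """
    blocks, names = _blocks_from(dataset, reference)
    beta, A, sigma_e2, psi, w, converged, it = _robust_core(blocks, k, tol, max_iter)
    return _finalize_fit(
        beta, A, sigma_e2, psi, names, blocks.n, len(blocks.idx), "robust", reference,
        converged=converged, n_iter=it, weights=w,
        grand_mean_speed=dataset.grand_mean_speed,
    )


def slope_contrasts(fit: LMMFit) -> pd.DataFrame:
    """Per-level speed slopes and pairwise slope differences (Wald).

    slope(level) = beta_centered_speed + beta_centered_speed:limb[level]
    (zero interaction for the reference level); differences and their tests
    propagate the fixed-effects covariance.
    """
    names = list(fit.params.index)
    if "centered_speed" not in names:
        raise ValueError("fit has no speed term")
    p = len(names)
    vecs: dict[str, np.ndarray] = {}
    for lv in LIMB_LEVELS:
        v = np.zeros(p)
        v[names.index("centered_speed")] = 1.0
        inter = f"centered_speed:limb[{lv}]"
        if lv != fit.reference:
            if inter not in names:
                raise ValueError(f"missing interaction term for level {lv}")
            v[names.index(inter)] = 1.0
        vecs[lv] = v

    beta = fit.params.to_numpy()
    cov = fit.cov_params.to_numpy()
    rows = []
    for lv, v in vecs.items():
        est = float(v @ beta)
        se = float(np.sqrt(max(v @ cov @ v, 0.0)))
        rows.append({"contrast": f"slope[{lv}]", "estimate": est, "se": se})
    pairs = [("paretic", "predicted"), ("nonparetic", "predicted"), ("paretic", "nonparetic")]
    for a, b in pairs:
        v = vecs[a] - vecs[b]
        est = float(v @ beta)
        se = float(np.sqrt(max(v @ cov @ v, 0.0)))
        rows.append({"contrast": f"slope[{a}]-slope[{b}]", "estimate": est, "se": se})
    out = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(out["se"] > 0, out["estimate"] / out["se"], 0.0)
    out["p"] = np.where(out["se"] > 0, 2.0 * sps.norm.sf(np.abs(z)), np.where(out["estimate"] == 0, 1.0, 0.0))
    return out


def cluster_bootstrap(
    dataset: LimbLevelDataset,
    fitter=fit_lmm,
    B: int = 1000,
    seed: int = 0,
    max_failure_fraction: float = 0.10,
) -> pd.DataFrame:
    """Participant-level bootstrap percentile 95% CIs for the fixed effects.

    Participants (clusters) are resampled with replacement, relabelled so
    repeated draws stay distinct clusters, and the model refit per replicate;
    per-term 2.5/97.5 percentiles are reported. Failed refits are logged and
    excluded; more than ``max_failure_fraction`` failures aborts.
    """
    if fitter not in (fit_lmm, fit_robust_lmm):
        raise ValueError("fitter must be fit_lmm or fit_robust_lmm")
    parent = fitter(dataset)
    blocks, _ = _blocks_from(dataset, parent.reference)
    n_clusters = len(blocks.idx)
    if n_clusters < 5:
        raise ValueError("need at least 5 participants for the cluster bootstrap")
    rng = np.random.default_rng(seed)
    robust = fitter is fit_robust_lmm
    w_parent = parent.weights

    draws: list[np.ndarray] = []
    failures = 0
    for _ in range(B):
        pick = rng.integers(0, n_clusters, size=n_clusters)
        bb = _Blocks.__new__(_Blocks)
        bb.Xc = [blocks.Xc[j] for j in pick]
        bb.yc = [blocks.yc[j] for j in pick]
        # re-index rows consecutively: repeated draws become distinct clusters
        sizes = [len(v) for v in bb.yc]
        offsets = np.concatenate(([0], np.cumsum(sizes)))
        bb.idx = [np.arange(offsets[i], offsets[i + 1]) for i in range(n_clusters)]
        bb.n = int(offsets[-1])
        bb.p = blocks.p
        try:
            if robust:
                w0 = np.concatenate([w_parent[blocks.idx[j]] for j in pick]) if w_parent is not None else None
                beta = _robust_core(bb, w0=w0)[0]
            else:
                beta = _fit_weighted_reml(bb, np.ones(bb.n))[0]
            draws.append(beta)
        except Exception:
            failures += 1
    if failures > max_failure_fraction * B:
        raise RuntimeError(f"cluster bootstrap: {failures}/{B} replicate fits failed")
    arr = np.array(draws)
    lo = np.percentile(arr, 2.5, axis=0)
    hi = np.percentile(arr, 97.5, axis=0)
    return pd.DataFrame(
        {"term": parent.params.index, "ci_low": lo, "ci_high": hi,
         "n_success": len(draws), "n_failed": failures}
    )


@dataclass
class SubgroupLabel:
    participant_id: str
    direction: str  # 'longer_paretic' | 'longer_nonparetic' | 'excluded_symmetric'
    ss_sla: float


def subgroup_split(
    dataset: LimbLevelDataset,
    ss_sla_by_participant: dict[str, float],
    sla_threshold: float = 0.02,
) -> tuple[list[SubgroupLabel], dict[str, LimbLevelDataset]]:
    """Split participants by step-length-asymmetry direction at self-selected
    speed; |SLA| <= threshold is excluded from the sub-analyses. Each
    subgroup dataset is re-centered on its own grand-mean speed."""
    labels: list[SubgroupLabel] = []
    assign: dict[str, str] = {}
    for pid in pd.unique(dataset.data["participant_id"]):
        if pid not in ss_sla_by_participant:
            raise ValueError(f"missing self-selected SLA for participant {pid}")
        v = float(ss_sla_by_participant[pid])
        if abs(v) <= sla_threshold:
            direction = "excluded_symmetric"
        elif v > 0:
            direction = "longer_paretic"
        else:
            direction = "longer_nonparetic"
        labels.append(SubgroupLabel(pid, direction, v))
        assign[pid] = direction

    out: dict[str, LimbLevelDataset] = {}
    for direction in ("longer_paretic", "longer_nonparetic"):
        keep = [pid for pid, d in assign.items() if d == direction]
        sub = dataset.data[dataset.data["participant_id"].isin(keep)].copy()
        if len(sub) == 0:
            continue
        gm = float(sub["speed"].mean())
        sub["centered_speed"] = sub["speed"] - gm
        out[direction] = LimbLevelDataset(sub.reset_index(drop=True), gm, dataset.outcome_name)
    return labels, out
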