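"""Internal model validation: CWRES diagnostics, bootstrap, pcVPC, and NPDE.

All four diagnostics are simulation- or resampling-based re-evaluations of a
converged fit on its own dataset design and are seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import Dataset
from .nlme_fit import FitResult, ModelSpec, _Design, _FoceEngine, fit

__all__ = [
    "cwres",
    "bootstrap",
    "BootstrapResult",
    "pcvpc",
    "VPCResult",
    "npde",
    "NPDEResult",
]


def _engine_at_fit(fit_result: FitResult, ds: Dataset):
    """Rebuild the FOCE engine and evaluate it at the fitted estimates."""
    design = _Design(ds)
    engine = _FoceEngine(design, fit_result.spec)
    thetas_j = [
        fit_result.covariate_thetas[e.label] for e in fit_result.spec.covariate_effects
    ]
    omega = np.array([fit_result.omega[p] for p in fit_result.spec.iiv_parameters])
    sigma_add = fit_result.sigma_add if fit_result.sigma_add > 0 else 1e-12
    x = engine.enc.encode(
        fit_result.theta.as_array(), thetas_j, omega, fit_result.sigma_prop, sigma_add
    )
    return design, engine, x, omega


# ---------------------------------------------------------------------------
# residual diagnostics


def cwres(fit_result: FitResult, ds: Dataset) -> pd.DataFrame:
    """Population/individual predictions and conditional weighted residuals.

    PRED is the population prediction (eta = 0), IPRED the prediction at the
    empirical Bayes estimates, and CWRES decorrelates the residual about the
    FOCE linearization: ``CWRES_i = C_i^{-1/2} (y_i - f_i(eta_hat) + G_i eta_hat)``
    with ``C_i = G_i Omega G_i' + V_i``.  Under a correct model CWRES is
    approximately standard normal.
    """
    design, engine, x, omega = _engine_at_fit(fit_result, ds)
    ofv, eta, f, J, v = engine.ofv(x, tight=True)
    theta4, thetas_j, _, _, _ = engine.enc.decode(x)
    from .nlme_fit import _multipliers
    mult = _multipliers(design, fit_result.spec.covariate_effects, thetas_j,
                        engine.cov_values)
    pred = engine._pred(theta4, mult, np.zeros_like(eta))
    om2 = omega * omega
    n_eta = engine.enc.n_eta
    out_cwres = np.empty(design.n_obs)
    for i in range(design.n_subjects):
        lo, hi = design.obs_offsets[i], design.obs_offsets[i + 1]
        vi = v[lo:hi]
        resid = design.y[lo:hi] - f[lo:hi]
        if n_eta:
            Gi = J[lo:hi]
            Ci = Gi @ np.diag(om2) @ Gi.T + np.diag(vi)
            ri = resid + Gi @ eta[i]
        else:
            Ci = np.diag(vi)
            ri = resid
        w, V = np.linalg.eigh(Ci)
        if np.any(w <= 0):
            raise np.linalg.LinAlgError(
                f"singular conditional covariance for subject {design.subjects[i].subject_id}"
            )
        inv_sqrt = V @ np.diag(1.0 / np.sqrt(w)) @ V.T
        out_cwres[lo:hi] = inv_sqrt @ ri
    tad = np.empty(design.n_obs)
    sid = np.empty(design.n_obs, dtype=int)
    for i, s in enumerate(design.subjects):
        lo, hi = design.obs_offsets[i], design.obs_offsets[i + 1]
        tad[lo:hi] = design.t[lo:hi] - s.regimen.end_time
        sid[lo:hi] = s.subject_id
    return pd.DataFrame(
        {"ID": sid, "TIME": design.t, "TAD": tad, "DV": design.y,
         "PRED": pred, "IPRED": f, "CWRES": out_cwres}
    )


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapResult:
    """Percentile summaries of subject-resampled refits."""

    estimates: pd.DataFrame      # one row per converged replicate
    summary: pd.DataFrame        # median / 2.5% / 97.5% per parameter
    n_requested: int
    n_converged: int

    @property
    def convergence_rate(self) -> float:
        return self.n_converged / self.n_requested


def bootstrap(ds: Dataset, spec: ModelSpec, n_reps: int = 1000, seed=None,
              init_fit: FitResult | None = None, maxfun: int = 600) -> BootstrapResult:
    """Nonparametric bootstrap: resample subjects (not rows) with replacement, refit.

    Replicate fits start from the original estimates when available (stability
    and speed); non-converged replicates are excluded and counted.  More than
    50% non-convergence is a hard failure.
    """
    if ds.n_subjects < 2:
        raise ValueError("bootstrap requires at least 2 subjects")
    rng = np.random.default_rng(seed)
    ids = ds.subject_ids
    if init_fit is None:
        init_fit = fit(ds, spec, compute_rse=False)
    rows = []
    n_converged = 0
    for rep in range(n_reps):
        draw = rng.choice(ids, size=len(ids), replace=True)
        rep_ds = ds.subset(draw, renumber=True)
        try:
            res = fit(
                rep_ds, spec,
                init=init_fit.theta,
                init_omega=float(np.mean(list(init_fit.omega.values()))) or 0.3,
                init_sigma_prop=init_fit.sigma_prop,
                init_cov_thetas=dict(init_fit.covariate_thetas),
                compute_rse=False, maxfun=maxfun,
                seed=int(rng.integers(2**31)),
            )
        except Exception:
            continue
        if not res.converged:
            continue
        n_converged += 1
        row = {"replicate": rep, "OFV": res.ofv,
               "CL": res.theta.cl, "V1": res.theta.v1,
               "Q": res.theta.q, "V2": res.theta.v2,
               "sigma_prop": res.sigma_prop}
        for p, w in res.omega.items():
            row[f"omega_{p}"] = w
        for lbl, v in res.covariate_thetas.items():
            row[lbl] = v
        rows.append(row)
    if n_converged < 0.5 * n_reps:
        raise RuntimeError(
            f"bootstrap failed: only {n_converged}/{n_reps} replicates converged"
        )
    est = pd.DataFrame(rows)
    params = [c for c in est.columns if c != "replicate"]
    summary = pd.DataFrame(
        {
            "median": est[params].median(),
            "ci_lower": est[params].quantile(0.025),
            "ci_upper": est[params].quantile(0.975),
        }
    )
    return BootstrapResult(
        estimates=est, summary=summary, n_requested=n_reps, n_converged=n_converged
    )


# ---------------------------------------------------------------------------
# simulation under the fitted model (shared by pcVPC and NPDE)


def _simulate_matrix(fit_result: FitResult, design, engine, n_sim: int, rng):
    """(n_sim, n_obs) observation matrix simulated under the fitted model."""
    from .nlme_fit import _multipliers
    thetas_j = [
        fit_result.covariate_thetas[e.label] for e in fit_result.spec.covariate_effects
    ]
    mult = _multipliers(design, fit_result.spec.covariate_effects, thetas_j,
                        engine.cov_values)
    theta4 = fit_result.theta.as_array()
    omega = np.array([fit_result.omega[p] for p in fit_result.spec.iiv_parameters])
    sims = np.empty((n_sim, design.n_obs))
    for k in range(n_sim):
        eta = rng.normal(0.0, 1.0, size=(design.n_subjects, engine.enc.n_eta)) * omega
        f = engine._pred(theta4, mult, eta)
        y = f * (1.0 + rng.normal(0.0, fit_result.sigma_prop, size=design.n_obs))
        if fit_result.sigma_add > 0:
            y = y + rng.normal(0.0, fit_result.sigma_add, size=design.n_obs)
        sims[k] = np.maximum(y, 0.0)
    return sims


# ---------------------------------------------------------------------------
# prediction-corrected visual predictive check


@dataclass
class VPCResult:
    """Binned observed percentiles, simulated confidence bands, and PI coverage."""

    bins: pd.DataFrame
    coverage_90: float           # fraction of observations inside the 90% PI
    n_sim: int
    observed: pd.DataFrame       # per-observation bin and pc-corrected value


def pcvpc(fit_result: FitResult, ds: Dataset, n_sim: int = 1000, bins=None,
          seed=None) -> VPCResult:
    """Prediction-corrected VPC on the observed design.

    Each observed and simulated value is scaled by median(PRED in bin)/PRED
    before percentiles are computed; bins default to the protocol's nominal
    post-cessation sampling times (observations are assigned to the nearest
    nominal time, and empty bins simply drop out).
    """
    from .cohort_sim import POST_STOP_MINUTES
    from .nlme_fit import _multipliers

    design, engine, x, omega = _engine_at_fit(fit_result, ds)
    theta4, thetas_j, _, _, _ = engine.enc.decode(x)
    mult = _multipliers(design, fit_result.spec.covariate_effects, thetas_j,
                        engine.cov_values)
    pred = engine._pred(theta4, mult, np.zeros((design.n_subjects, engine.enc.n_eta)))

    tad = np.empty(design.n_obs)
    for i, s in enumerate(design.subjects):
        lo, hi = design.obs_offsets[i], design.obs_offsets[i + 1]
        tad[lo:hi] = design.t[lo:hi] - s.regimen.end_time
    nominal = np.asarray(bins if bins is not None else POST_STOP_MINUTES, float)
    bin_idx = np.argmin(np.abs(tad[:, None] * 60.0 - nominal[None, :]), axis=1)

    rng = np.random.default_rng(seed)
    sims = _simulate_matrix(fit_result, design, engine, n_sim, rng)

    rows = []
    inside = 0
    obs_rows = []
    for b, minutes in enumerate(nominal):
        mask = bin_idx == b
        if not mask.any():
            continue
        factor = np.median(pred[mask]) / np.maximum(pred[mask], 1e-12)
        pc_obs = design.y[mask] * factor
        pc_sim = sims[:, mask] * factor[None, :]
        lo_pi, hi_pi = np.percentile(pc_sim, [5.0, 95.0])
        inside += int(np.sum((pc_obs >= lo_pi) & (pc_obs <= hi_pi)))
        sim_pct = np.percentile(pc_sim, [5.0, 50.0, 95.0], axis=1)  # (3, n_sim)
        band = np.percentile(sim_pct, [2.5, 97.5], axis=1)
        obs_pct = np.percentile(pc_obs, [5.0, 50.0, 95.0])
        rows.append(
            {"bin_minutes": minutes, "n": int(mask.sum()),
             "obs_p5": obs_pct[0], "obs_p50": obs_pct[1], "obs_p95": obs_pct[2],
             "sim_p5_lo": band[0, 0], "sim_p5_hi": band[1, 0],
             "sim_p50_lo": band[0, 1], "sim_p50_hi": band[1, 1],
             "sim_p95_lo": band[0, 2], "sim_p95_hi": band[1, 2],
             "pi90_lo": lo_pi, "pi90_hi": hi_pi}
        )
        obs_rows.append(pd.DataFrame(
            {"bin_minutes": minutes, "pc_dv": pc_obs, "tad_h": tad[mask]}
        ))
    return VPCResult(
        bins=pd.DataFrame(rows),
        coverage_90=inside / design.n_obs,
        n_sim=n_sim,
        observed=pd.concat(obs_rows, ignore_index=True),
    )


# ---------------------------------------------------------------------------
# normalized prediction distribution errors


@dataclass
class NPDEResult:
    """Per-observation NPDE values, summary moments, and the three tests."""

    table: pd.DataFrame
    mean: float
    variance: float
    p_wilcoxon: float        # location: mean 0
    p_variance: float        # scale: variance 1 (chi-square scale test)
    p_shapiro: float         # shape: normality
    p_global: float          # Bonferroni of the three

    @property
    def npde(self) -> np.ndarray:
        return self.table["NPDE"].to_numpy()


def _npde_from_sims(y, sims, ridge: float = 1e-8):
    """NPDE values for one subject from an (K, n) simulation matrix.

    Decorrelates observed and simulated vectors with the mean and Cholesky
    factor of the empirical simulation covariance, takes the fraction of
    decorrelated simulations below the decorrelated observation (ties count
    half), clips to [1/2K, 1 - 1/2K], and maps through the normal quantile.
    """
    y = np.asarray(y, float)
    K, n = sims.shape
    m = sims.mean(axis=0)
    cov = np.cov(sims, rowvar=False, ddof=1).reshape(n, n)
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        L = np.linalg.cholesky(cov + ridge * np.mean(np.diag(cov)) * np.eye(n))
    y_star = np.linalg.solve(L, y - m)
    sims_star = np.linalg.solve(L, (sims - m).T).T
    below = (sims_star < y_star[None, :]).sum(axis=0)
    ties = (sims_star == y_star[None, :]).sum(axis=0)
    pde = (below + 0.5 * ties) / K
    pde = np.clip(pde, 1.0 / (2 * K), 1.0 - 1.0 / (2 * K))
    return stats.norm.ppf(pde)


def npde(fit_result: FitResult, ds: Dataset, n_sim: int = 1000, seed=None) -> NPDEResult:
    """Normalized prediction distribution errors with the three adequacy tests.

    Location is tested by the Wilcoxon signed-rank test (mean 0), scale by a
    chi-square test of sum(npde^2) against its chi-square(n) reference
    (variance 1), and shape by Shapiro-Wilk; the global test is the Bonferroni
    combination of the three.
    """
    design, engine, x, _ = _engine_at_fit(fit_result, ds)
    rng = np.random.default_rng(seed)
    sims = _simulate_matrix(fit_result, design, engine, n_sim, rng)
    values = np.empty(design.n_obs)
    for i in range(design.n_subjects):
        lo, hi = design.obs_offsets[i], design.obs_offsets[i + 1]
        values[lo:hi] = _npde_from_sims(design.y[lo:hi], sims[:, lo:hi])
    sid = np.concatenate(
        [np.full(len(s.times), s.subject_id) for s in design.subjects]
    )
    table = pd.DataFrame({"ID": sid, "TIME": design.t, "DV": design.y, "NPDE": values})

    mean = float(values.mean())
    variance = float(values.var(ddof=1))
    p_w = float(stats.wilcoxon(values, zero_method="wilcox").pvalue) \
        if np.any(values != 0) else 1.0
    n = len(values)
    t_stat = float(np.sum(values ** 2))
    p_v = float(2.0 * min(stats.chi2.cdf(t_stat, n), stats.chi2.sf(t_stat, n)))
    p_s = float(stats.shapiro(values).pvalue)
    p_global = float(min(1.0, 3.0 * min(p_w, p_v, p_s)))
    return NPDEResult(
        table=table, mean=mean, variance=variance,
        p_wilcoxon=p_w, p_variance=p_v, p_shapiro=p_s, p_global=p_global,
    )
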