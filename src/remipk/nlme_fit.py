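"""Nonlinear mixed-effects estimation of the population PK model (FOCE-I).

Model
-----
For subject i with individual parameters ``P_i = theta_tv * m_i(cov) * exp(eta_i)``
(log-normal inter-individual variability ``eta_i ~ N(0, diag(omega^2))``,
multiplicative covariate terms ``m_i``), the observed concentration is

    y_ij = f_ij(P_i) * (1 + eps_prop,ij) + eps_add,ij

so the residual variance is ``v_ij = sigma_prop^2 f_ij^2 + sigma_add^2``.

The marginal likelihood has no closed form; it is approximated by first-order
conditional estimation with interaction (FOCE-I): for each subject the
conditional mode ``eta_hat_i`` of the joint density of (y_i, eta) is found,
the model is linearized there with gradient ``G_i = df/deta |eta_hat``, the
residual variance is evaluated at the mode (the "interaction"), and the
subject's contribution to the objective function value (OFV, -2 log-likelihood
up to the 2*pi constant, NONMEM convention) is

    log|C_i| + r_i' C_i^{-1} r_i,   C_i = G_i Omega G_i' + V_i,
    r_i = y_i - f_i(eta_hat) + G_i eta_hat.

Implementation notes: the inner eta-optimization is a damped Gauss-Newton
solve vectorized across all subjects at once (model gradients by central
finite differences of the closed-form profile), warm-started from the previous
outer iteration's empirical Bayes estimates; the outer problem runs on
log-transformed population parameters under L-BFGS-B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .dataset_io import Dataset
from .pkcore import PKParameters, _segment_concentration

__all__ = [
    "PARAM_ORDER",
    "CovariateEffect",
    "ModelSpec",
    "FitResult",
    "individual_parameters",
    "chi2_threshold",
    "foce_objective",
    "foce_subject_contribution",
    "fit",
    "default_candidates",
    "forward_selection",
    "backward_elimination",
]

PARAM_ORDER = ("CL", "V1", "Q", "V2")

_V_FLOOR = 1e-12        # residual-variance floor, (ng/mL)^2
_FD_ETA = 1e-5          # central-difference step for df/deta
_INNER_TOL = 3e-4       # gradient tolerance of the inner eta solve
_INNER_MAXIT = 60
_INNER_STALL = 1e-9     # stop when no subject improves by more than this


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate term on a structural parameter.

    ``continuous_power``:   multiplier = (COV / reference) ** theta_j
    ``categorical_exponent``: multiplier = theta_j ** COV,  COV in {0, 1}
    """

    parameter: str
    covariate: str
    form: str
    theta_j: float = 1.0
    reference: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_ORDER:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("continuous_power", "categorical_exponent"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "continuous_power" and self.reference is None:
            raise ValueError("continuous_power effect requires a reference (median)")
        if self.form == "categorical_exponent" and self.theta_j <= 0:
            raise ValueError("categorical_exponent theta_j must be > 0")

    @property
    def label(self) -> str:
        return f"{self.covariate}~{self.parameter}"

    def multiplier(self, value: float) -> float:
        if self.form == "continuous_power":
            if value <= 0:
                raise ValueError(
                    f"non-positive covariate {self.covariate}={value!r} in power model"
                )
            return (value / self.reference) ** self.theta_j
        return self.theta_j ** value


@dataclass(frozen=True)
class ModelSpec:
    """Structural + random-effects + covariate specification (diagonal Omega)."""

    error_model: str = "proportional"           # "proportional" | "combined"
    iiv_parameters: tuple = PARAM_ORDER
    covariate_effects: tuple = ()

    def __post_init__(self) -> None:
        if self.error_model not in ("proportional", "combined"):
            raise ValueError(f"unknown error model {self.error_model!r}")
        iiv = tuple(p for p in PARAM_ORDER if p in self.iiv_parameters)
        if len(iiv) != len(self.iiv_parameters):
            unknown = set(self.iiv_parameters) - set(PARAM_ORDER)
            raise ValueError(f"unknown IIV parameter(s): {sorted(unknown)}")
        object.__setattr__(self, "iiv_parameters", iiv)
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + (effect,))

    def without_effect(self, label: str) -> "ModelSpec":
        kept = tuple(e for e in self.covariate_effects if e.label != label)
        return replace(self, covariate_effects=kept)


@dataclass
class FitResult:
    """Population estimates, OFV, empirical Bayes estimates, and uncertainty."""

    spec: ModelSpec
    theta: PKParameters
    covariate_thetas: dict
    omega: dict                 # per-IIV-parameter SD on the log scale
    sigma_prop: float
    sigma_add: float
    ofv: float
    ebes: pd.DataFrame          # one row per subject, one column per eta
    converged: bool
    n_obs: int
    n_subjects: int
    rse: dict = field(default_factory=dict)        # % relative standard errors
    shrinkage: dict = field(default_factory=dict)  # per-eta %, 100*(1 - SD(ebe)/omega)
    n_function_evals: int = 0
    message: str = ""

    @property
    def iiv_percent(self) -> dict:
        """IIV magnitudes reported as 100*sqrt(omega^2), the usual CV% convention."""
        return {p: 100.0 * w for p, w in self.omega.items()}

    def estimates_table(self) -> pd.DataFrame:
        """Long-format estimates table (parameter, estimate, RSE%, shrinkage%)."""
        rows = []
        for p, v in zip(PARAM_ORDER, self.theta.as_array()):
            rows.append(("theta", p, v, self.rse.get(p, np.nan), np.nan))
        for lbl, v in self.covariate_thetas.items():
            rows.append(("covariate", lbl, v, self.rse.get(lbl, np.nan), np.nan))
        for p, w in self.omega.items():
            rows.append(
                ("IIV (%)", f"IIV-{p}", 100.0 * w,
                 self.rse.get(f"omega_{p}", np.nan), self.shrinkage.get(p, np.nan))
            )
        rows.append(
            ("residual", "proportional error (%)", 100.0 * self.sigma_prop,
             self.rse.get("sigma_prop", np.nan), np.nan)
        )
        if self.spec.error_model == "combined":
            rows.append(
                ("residual", "additive error (ng/mL)", self.sigma_add,
                 self.rse.get("sigma_add", np.nan), np.nan)
            )
        return pd.DataFrame(
            rows, columns=["block", "parameter", "estimate", "rse_percent", "shrinkage_percent"]
        )


# ---------------------------------------------------------------------------
# covariate machinery


def _cov_value(cov, name: str) -> float:
    if hasattr(cov, "get"):
        return float(cov.get(name))
    return float(getattr(cov, name.lower()))


def individual_parameters(
    theta: PKParameters,
    effects,
    cov,
    eta,
    iiv_parameters: tuple = PARAM_ORDER,
) -> PKParameters:
    """Individual parameters: typical value x covariate multipliers x exp(eta).

    ``eta`` has one entry per IIV parameter (in CL, V1, Q, V2 order restricted
    to ``iiv_parameters``); parameters without IIV use eta = 0.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (len(iiv_parameters),):
        raise ValueError(
            f"eta must have length {len(iiv_parameters)}, got shape {eta.shape}"
        )
    values = dict(zip(PARAM_ORDER, theta.as_array()))
    for eff in effects:
        values[eff.parameter] *= eff.multiplier(_cov_value(cov, eff.covariate))
    for p, e in zip(iiv_parameters, eta):
        values[p] *= math.exp(e)
    return PKParameters(values["CL"], values["V1"], values["Q"], values["V2"])


def chi2_threshold(alpha: float, df: int) -> float:
    """Upper-alpha quantile of chi-square(df): the dOFV cut-off of a level-alpha LRT."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df!r}")
    return float(stats.chi2.ppf(1.0 - alpha, df))


# ---------------------------------------------------------------------------
# design: the dataset flattened into engine-ready arrays


class _Design:
    """Flat observation/segment arrays with subject indexing for batched evaluation."""

    def __init__(self, ds: Dataset):
        subjects = [s for s in ds.subjects(drop_blq=True) if len(s.times) > 0]
        if not subjects:
            raise ValueError("dataset has no quantifiable observations")
        self.subjects = subjects
        self.n_subjects = len(subjects)
        y, t, obs_subj = [], [], []
        seg_subj, seg_start, seg_rate, seg_dur = [], [], [], []
        pair_obs, pair_seg = [], []
        for i, s in enumerate(subjects):
            base_obs = len(y)
            y.extend(s.dv)
            t.extend(s.times)
            obs_subj.extend([i] * len(s.times))
            seg_ids = []
            for ev in s.regimen.events:
                if ev.rate == 0.0:
                    continue
                seg_ids.append(len(seg_subj))
                seg_subj.append(i)
                seg_start.append(ev.start)
                seg_rate.append(ev.rate)
                seg_dur.append(ev.duration)
            for j in range(len(s.times)):
                for sg in seg_ids:
                    pair_obs.append(base_obs + j)
                    pair_seg.append(sg)
        self.y = np.asarray(y, float)
        self.t = np.asarray(t, float)
        self.obs_subj = np.asarray(obs_subj, int)
        self.n_obs = len(self.y)
        self.seg_start = np.asarray(seg_start, float)
        self.seg_rate = np.asarray(seg_rate, float)
        self.seg_dur = np.asarray(seg_dur, float)
        self.pair_obs = np.asarray(pair_obs, int)
        self.pair_subj = np.asarray(seg_subj, int)[np.asarray(pair_seg, int)]
        self.pair_seg = np.asarray(pair_seg, int)
        self.pair_t = self.t[self.pair_obs]
        # per-subject observation slices (subjects are contiguous in y)
        counts = np.bincount(self.obs_subj, minlength=self.n_subjects)
        self.obs_offsets = np.concatenate([[0], np.cumsum(counts)])
        self._multi_cache: dict = {}

    def covariate_values(self, effects) -> np.ndarray:
        """(n_subjects, n_effects) raw covariate values for the active effects."""
        out = np.empty((self.n_subjects, len(effects)))
        for j, eff in enumerate(effects):
            for i, s in enumerate(self.subjects):
                out[i, j] = _cov_value(s.covariates, eff.covariate)
        return out

    def predict(self, p_ind: np.ndarray) -> np.ndarray:
        """Concentrations (ng/mL) at every observation for per-subject parameters.

        ``p_ind`` is (n_subjects, 4) in CL, V1, Q, V2 order.
        """
        p = p_ind[self.pair_subj]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            contrib = _segment_concentration(
                p[:, 0], p[:, 1], p[:, 2], p[:, 3],
                self.seg_start[self.pair_seg],
                self.seg_rate[self.pair_seg],
                self.seg_dur[self.pair_seg],
                self.pair_t,
            )
        f = np.bincount(self.pair_obs, weights=contrib, minlength=self.n_obs)
        return f * 1000.0

    def predict_multi(self, p_stack: np.ndarray) -> np.ndarray:
        """Predictions for m parameter sets at once: (m, n_subjects, 4) -> (m, n_obs).

        One flattened evaluation replaces m separate :meth:`predict` calls;
        the inner Jacobian and line searches are built on this.
        """
        m = p_stack.shape[0]
        cache = self._multi_cache.get(m)
        if cache is None:
            offs_subj = np.arange(m)[:, None] * self.n_subjects
            offs_obs = np.arange(m)[:, None] * self.n_obs
            cache = (
                (offs_subj + self.pair_subj[None, :]).ravel(),
                np.tile(self.pair_seg, m),
                (offs_obs + self.pair_obs[None, :]).ravel(),
                np.tile(self.pair_t, m),
            )
            self._multi_cache[m] = cache
        pair_subj, pair_seg, pair_obs, pair_t = cache
        p = p_stack.reshape(-1, 4)[pair_subj]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            contrib = _segment_concentration(
                p[:, 0], p[:, 1], p[:, 2], p[:, 3],
                self.seg_start[pair_seg], self.seg_rate[pair_seg],
                self.seg_dur[pair_seg], pair_t,
            )
        f = np.bincount(pair_obs, weights=contrib, minlength=m * self.n_obs)
        return f.reshape(m, self.n_obs) * 1000.0


# ---------------------------------------------------------------------------
# parameter vector encoding


class _Encoding:
    """Bijection between the population parameters and the flat outer vector x.

    Structural parameters, omegas and sigmas are log-encoded (positivity by
    construction); categorical covariate factors are log-encoded; continuous
    power exponents are raw (sign free).
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.iiv_idx = [PARAM_ORDER.index(p) for p in spec.iiv_parameters]
        self.n_eta = len(self.iiv_idx)
        self.n_eff = len(spec.covariate_effects)
        self.n_sigma = 2 if spec.error_model == "combined" else 1
        self.size = 4 + self.n_eff + self.n_eta + self.n_sigma
        self.names = list(PARAM_ORDER)
        self.names += [e.label for e in spec.covariate_effects]
        self.names += [f"omega_{p}" for p in spec.iiv_parameters]
        self.names += ["sigma_prop"] + (["sigma_add"] if self.n_sigma == 2 else [])
        self.log_scaled = (
            [True] * 4
            + [e.form == "categorical_exponent" for e in spec.covariate_effects]
            + [True] * (self.n_eta + self.n_sigma)
        )

    def encode(self, theta4, thetas_j, omega, sigma_prop, sigma_add) -> np.ndarray:
        x = np.empty(self.size)
        x[:4] = np.log(theta4)
        for j, (eff, tj) in enumerate(zip(self.spec.covariate_effects, thetas_j)):
            x[4 + j] = math.log(tj) if eff.form == "categorical_exponent" else tj
        base = 4 + self.n_eff
        x[base:base + self.n_eta] = np.log(omega)
        x[base + self.n_eta] = math.log(sigma_prop)
        if self.n_sigma == 2:
            x[base + self.n_eta + 1] = math.log(sigma_add)
        return x

    def decode(self, x):
        theta4 = np.exp(x[:4])
        thetas_j = [
            math.exp(x[4 + j]) if eff.form == "categorical_exponent" else x[4 + j]
            for j, eff in enumerate(self.spec.covariate_effects)
        ]
        base = 4 + self.n_eff
        omega = np.exp(x[base:base + self.n_eta])
        sigma_prop = math.exp(x[base + self.n_eta])
        sigma_add = math.exp(x[base + self.n_eta + 1]) if self.n_sigma == 2 else 0.0
        return theta4, thetas_j, omega, sigma_prop, sigma_add


def _multipliers(design: _Design, effects, thetas_j, cov_values) -> np.ndarray:
    """(n_subjects, 4) covariate multiplier matrix for the current theta_j values."""
    mult = np.ones((design.n_subjects, 4))
    for j, eff in enumerate(effects):
        col = PARAM_ORDER.index(eff.parameter)
        vals = cov_values[:, j]
        if eff.form == "continuous_power":
            if np.any(vals <= 0):
                raise ValueError(
                    f"non-positive covariate {eff.covariate} in power model"
                )
            mult[:, col] *= (vals / eff.reference) ** thetas_j[j]
        else:
            mult[:, col] *= thetas_j[j] ** vals
    return mult


# ---------------------------------------------------------------------------
# FOCE-I engine


class _FoceEngine:
    """Stateful evaluator: OFV(x) with warm-started empirical Bayes modes."""

    def __init__(self, design: _Design, spec: ModelSpec):
        self.design = design
        self.spec = spec
        self.enc = _Encoding(spec)
        self.cov_values = design.covariate_values(spec.covariate_effects)
        # warm-start snapshot for the inner solve: updated only when a new
        # best OFV is seen, so ofv(x) stays a deterministic function of x
        # (finite-difference probes must not perturb it)
        self.eta_warm = np.zeros((design.n_subjects, self.enc.n_eta))
        self.best_ofv = np.inf
        self.n_evals = 0

    # -- batched model evaluation ------------------------------------------

    def _p_ind(self, theta4, mult, eta) -> np.ndarray:
        eta_full = np.zeros((self.design.n_subjects, 4))
        if self.enc.n_eta:
            eta_full[:, self.enc.iiv_idx] = np.clip(eta, -40.0, 40.0)
        return theta4[None, :] * mult * np.exp(eta_full)

    def _pred(self, theta4, mult, eta) -> np.ndarray:
        return self.design.predict(self._p_ind(theta4, mult, eta))

    def _pred_multi(self, theta4, mult, eta_stack) -> np.ndarray:
        """(m, S, k) eta stack -> (m, N) predictions in one flattened call."""
        m, S, k = eta_stack.shape
        eta_full = np.zeros((m, S, 4))
        if k:
            eta_full[:, :, self.enc.iiv_idx] = np.clip(eta_stack, -40.0, 40.0)
        p_stack = theta4[None, None, :] * mult[None, :, :] * np.exp(eta_full)
        return self.design.predict_multi(p_stack)

    def _jacobian(self, theta4, mult, eta):
        """f and df/deta by central differences; one batched model evaluation."""
        d = self.design
        k = self.enc.n_eta
        stack = np.empty((2 * k + 1, d.n_subjects, k))
        stack[0] = eta
        for a in range(k):
            stack[1 + 2 * a] = eta
            stack[1 + 2 * a][:, a] += _FD_ETA
            stack[2 + 2 * a] = eta
            stack[2 + 2 * a][:, a] -= _FD_ETA
        preds = self._pred_multi(theta4, mult, stack)
        f = preds[0]
        J = np.empty((d.n_obs, k))
        for a in range(k):
            J[:, a] = (preds[1 + 2 * a] - preds[2 + 2 * a]) / (2.0 * _FD_ETA)
        return f, J

    def _eta_penalized(self, theta4, mult, eta, omega, sp, sa):
        """Per-subject penalized conditional objective l_i(eta)."""
        d = self.design
        f = self._pred(theta4, mult, eta)
        v = np.maximum(sp * sp * f * f + sa * sa, _V_FLOOR)
        r = d.y - f
        term = np.log(v) + r * r / v
        per_sub = np.bincount(d.obs_subj, weights=term, minlength=d.n_subjects)
        if self.enc.n_eta:
            per_sub = per_sub + np.sum(eta * eta / (omega * omega)[None, :], axis=1)
        return per_sub

    def _solve_inner(self, theta4, mult, omega, sp, sa, eta0):
        """Damped Gauss-Newton for all subjects' conditional modes at once."""
        d = self.design
        if self.enc.n_eta == 0:
            return np.zeros((d.n_subjects, 0))
        k = self.enc.n_eta
        eta = eta0.copy()
        inv_om2 = 1.0 / (omega * omega)
        l_cur = self._eta_penalized(theta4, mult, eta, omega, sp, sa)
        active = np.ones(d.n_subjects, dtype=bool)
        for _ in range(_INNER_MAXIT):
            f, J = self._jacobian(theta4, mult, eta)
            v = np.maximum(sp * sp * f * f + sa * sa, _V_FLOOR)
            r = d.y - f
            dv = 2.0 * sp * sp * f[:, None] * J             # (N, k)
            coeff = (1.0 / v - r * r / (v * v))[:, None]
            g_obs = coeff * dv - (2.0 * r / v)[:, None] * J
            grad = np.empty((d.n_subjects, k))
            # observed second derivative of the per-observation deviance wrt f
            # (clamped at a fraction of the expected information to stay PD)
            A = 2.0 * sp * sp * f
            w_obs = (
                2.0 * sp * sp / v - A * A / (v * v)
                + 4.0 * r * A / (v * v)
                - 2.0 * sp * sp * r * r / (v * v)
                + 2.0 * A * A * r * r / (v * v * v)
                + 2.0 / v
            )
            w = np.maximum(w_obs, 0.2 / v)
            H = np.empty((d.n_subjects, k, k))
            for a in range(k):
                grad[:, a] = np.bincount(
                    d.obs_subj, weights=g_obs[:, a], minlength=d.n_subjects
                )
                for b in range(a, k):
                    Hab = np.bincount(
                        d.obs_subj, weights=w * J[:, a] * J[:, b],
                        minlength=d.n_subjects,
                    )
                    H[:, a, b] = Hab
                    H[:, b, a] = Hab
            grad += 2.0 * eta * inv_om2[None, :]
            H += (2.0 * np.diag(inv_om2))[None, :, :]
            H += (1e-8 * (1.0 + np.trace(H, axis1=1, axis2=2)))[:, None, None] \
                * np.eye(k)[None, :, :]
            active &= np.abs(grad).max(axis=1) >= _INNER_TOL
            if not active.any():
                break
            try:
                step = -np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            except np.linalg.LinAlgError:
                step = -np.linalg.solve(
                    H + 1e-6 * np.eye(k)[None, :, :], grad[:, :, None]
                )[:, :, 0]
            # trust-region style cap on the per-subject Newton step
            norms = np.linalg.norm(step, axis=1)
            big = norms > 4.0
            step[big] *= (4.0 / norms[big])[:, None]
            step[~active] = 0.0
            # per-subject backtracking line search over the active set
            alpha = np.ones(d.n_subjects)
            pending = active.copy()
            gain = np.zeros(d.n_subjects)
            for _bt in range(30):
                trial = eta + (alpha * pending)[:, None] * step
                l_trial = self._eta_penalized(theta4, mult, trial, omega, sp, sa)
                better = pending & (l_trial < l_cur - 1e-13)
                gain[better] = l_cur[better] - l_trial[better]
                eta[better] = trial[better]
                l_cur[better] = l_trial[better]
                pending &= ~better
                if not pending.any():
                    break
                alpha[pending] *= 0.5
            # subjects whose line search stalled are as converged as they get
            active &= ~pending
            if not active.any() or gain.max() < _INNER_STALL:
                break
        return eta

    def ofv(self, x, tight: bool = False):
        """OFV and conditional modes at the population vector x."""
        self.n_evals += 1
        d = self.design
        theta4, thetas_j, omega, sp, sa = self.enc.decode(x)
        mult = _multipliers(d, self.spec.covariate_effects, thetas_j, self.cov_values)
        eta = self._solve_inner(theta4, mult, omega, sp, sa, self.eta_warm)
        if self.enc.n_eta:
            f, J = self._jacobian(theta4, mult, eta)
        else:
            f = self._pred(theta4, mult, eta)
            J = np.zeros((d.n_obs, 0))
        v = np.maximum(sp * sp * f * f + sa * sa, _V_FLOOR)
        r = d.y - f
        om2 = omega * omega
        total = 0.0
        for i in range(d.n_subjects):
            lo, hi = d.obs_offsets[i], d.obs_offsets[i + 1]
            vi = v[lo:hi]
            if self.enc.n_eta:
                Gi = J[lo:hi]
                Ci = Gi @ np.diag(om2) @ Gi.T + np.diag(vi)
                ri = r[lo:hi] + Gi @ eta[i]
                try:
                    cf = cho_factor(Ci, lower=True)
                except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
                    raise FloatingPointError(
                        f"singular conditional covariance for subject index {i}"
                    ) from exc
                logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
                total += logdet + float(ri @ cho_solve(cf, ri))
            else:
                ri = r[lo:hi]
                total += float(np.sum(np.log(vi) + ri * ri / vi))
        if not np.isfinite(total):
            raise FloatingPointError("non-finite OFV")
        if total < self.best_ofv:
            self.best_ofv = total
            self.eta_warm = eta.copy()
        return total, eta, f, J, v


# ---------------------------------------------------------------------------
# public objective / reference per-subject implementation


def foce_objective(ds: Dataset, spec: ModelSpec, theta, omega, sigma):
    """FOCE-I objective for given population parameters; returns (OFV, EBEs).

    Parameters
    ----------
    theta : PKParameters or (PKParameters, dict of covariate theta_j by label)
    omega : sequence of per-IIV-parameter SDs (log scale), in spec order
    sigma : float (proportional SD) or (sigma_prop, sigma_add)
    """
    if isinstance(theta, tuple):
        theta, cov_thetas = theta
    else:
        cov_thetas = {}
    sp, sa = (sigma, 0.0) if np.isscalar(sigma) else (sigma[0], sigma[1])
    design = _Design(ds)
    engine = _FoceEngine(design, spec)
    thetas_j = [cov_thetas.get(e.label, e.theta_j) for e in spec.covariate_effects]
    x = engine.enc.encode(theta.as_array(), thetas_j, np.asarray(omega, float), sp, sa)
    ofv, eta, *_ = engine.ofv(x)
    ebes = pd.DataFrame(
        eta,
        index=[s.subject_id for s in design.subjects],
        columns=[f"eta_{p}" for p in spec.iiv_parameters],
    )
    return ofv, ebes


def foce_subject_contribution(y, f_of_eta, omega, sigma_prop, sigma_add=0.0,
                              n_eta=1, eta0=None):
    """Single-subject FOCE-I contribution for an arbitrary model function.

    Reference implementation used for cross-checks: ``f_of_eta`` maps an eta
    vector to the prediction vector; the conditional mode is found with a
    general-purpose quasi-Newton optimizer and the contribution is assembled
    from the same linearization formula as the production engine.
    """
    y = np.asarray(y, float)
    omega = np.atleast_1d(np.asarray(omega, float))
    inv_om2 = 1.0 / (omega * omega)

    def pen(eta):
        f = np.asarray(f_of_eta(eta), float)
        v = np.maximum(sigma_prop ** 2 * f * f + sigma_add ** 2, _V_FLOOR)
        r = y - f
        return float(np.sum(np.log(v) + r * r / v) + np.sum(eta * eta * inv_om2))

    eta0 = np.zeros(n_eta) if eta0 is None else np.asarray(eta0, float)
    res = optimize.minimize(pen, eta0, method="BFGS",
                            options={"gtol": 1e-12, "maxiter": 500})
    eta_hat = res.x
    f = np.asarray(f_of_eta(eta_hat), float)
    J = np.empty((len(y), n_eta))
    for k in range(n_eta):
        step = np.zeros(n_eta)
        step[k] = _FD_ETA
        J[:, k] = (np.asarray(f_of_eta(eta_hat + step), float)
                   - np.asarray(f_of_eta(eta_hat - step), float)) / (2 * _FD_ETA)
    v = np.maximum(sigma_prop ** 2 * f * f + sigma_add ** 2, _V_FLOOR)
    C = J @ np.diag(omega ** 2) @ J.T + np.diag(v)
    r = y - f + J @ eta_hat
    sign, logdet = np.linalg.slogdet(C)
    return float(logdet + r @ np.linalg.solve(C, r)), eta_hat


# ---------------------------------------------------------------------------
# fitting


def _default_init(design: _Design) -> PKParameters:
    """Crude steady-state initializer from each subject's first post-cessation sample.

    After several terminal half-lives of infusion C ~ rate/CL, so
    CL ~ 1000 * rate / C; volumes/Q are seeded at fixed fractions of CL.
    """
    ratios = []
    for s in design.subjects:
        if not len(s.times) or not len(s.regimen.events):
            continue
        c0 = s.dv[np.argmin(s.times)]
        rate = s.regimen.events[-1].rate
        if c0 > 0 and rate > 0:
            ratios.append(1000.0 * rate / c0)
    cl = float(np.median(ratios)) if ratios else 50.0
    cl = min(max(cl, 1.0), 500.0)
    return PKParameters(cl, 0.5 * cl, cl / 3.0, 0.75 * cl)


def _fd_hessian(fun, x, h=1e-3):
    """Central-difference Hessian (symmetrized)."""
    n = len(x)
    H = np.empty((n, n))
    f0 = fun(x)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h
            ej = np.zeros(n); ej[j] = h
            if i == j:
                fpp = fun(x + 2 * ei)
                fmm = fun(x - 2 * ei)
                H[i, i] = (fpp - 2 * f0 + fmm) / (4 * h * h)
            else:
                fpp = fun(x + ei + ej)
                fpm = fun(x + ei - ej)
                fmp = fun(x - ei + ej)
                fmm = fun(x - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    return H


def fit(
    ds: Dataset,
    spec: ModelSpec | None = None,
    init: PKParameters | None = None,
    seed: int = 0,
    init_omega: float = 0.3,
    init_sigma_prop: float = 0.2,
    init_sigma_add: float = 1.0,
    init_cov_thetas: dict | None = None,
    compute_rse: bool = True,
    maxfun: int = 1500,
) -> FitResult:
    """Estimate the population model by FOCE-I.

    Optimizes the OFV over transformed population parameters in three
    stages (bounded quasi-Newton, simplex polish, quasi-Newton certificate);
    a result that fails every stage's stopping rule is flagged
    non-converged, never silently returned.  ``seed`` is reserved for
    stochastic search strategies and keeps replicate calls reproducible.
    """
    spec = spec or ModelSpec()
    design = _Design(ds)
    engine = _FoceEngine(design, spec)
    enc = engine.enc
    if init is None:
        init = _default_init(design)
    init_cov_thetas = init_cov_thetas or {}
    thetas_j0 = [
        init_cov_thetas.get(
            e.label, 1.0 if e.form == "categorical_exponent" else 0.0
        )
        for e in spec.covariate_effects
    ]
    x0 = enc.encode(
        init.as_array(), thetas_j0,
        np.full(enc.n_eta, init_omega), init_sigma_prop, init_sigma_add,
    )

    # box bounds keep every component in a physically sensible range
    bounds = []
    for name, logged in zip(enc.names, enc.log_scaled):
        if name in PARAM_ORDER:
            bounds.append((math.log(1e-2), math.log(1e4)))
        elif name.startswith("omega_") or name.startswith("sigma"):
            bounds.append((math.log(1e-3), math.log(10.0)))
        elif logged:                       # categorical factor
            bounds.append((math.log(1e-2), math.log(1e2)))
        else:                              # power exponent
            bounds.append((-10.0, 10.0))

    def objective(x):
        try:
            return engine.ofv(x)[0]
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    # three-stage outer search: quasi-Newton descent, a derivative-free
    # simplex polish (finite-difference gradients stall in the flat, curved
    # omega valleys typical of sparse designs), then a short quasi-Newton
    # run that certifies convergence at the polished point
    ofv0 = objective(x0)
    res = optimize.minimize(
        objective, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxfun": maxfun, "eps": 1e-5, "ftol": 1e-11, "gtol": 1e-6},
    )
    best_f, best_x = float(res.fun), res.x.copy()
    res_nm = optimize.minimize(
        objective, best_x, method="Nelder-Mead",
        options={"maxfev": maxfun, "xatol": 1e-4, "fatol": 1e-4, "adaptive": True},
    )
    if res_nm.fun < best_f:
        best_f, best_x = float(res_nm.fun), res_nm.x.copy()
    res = optimize.minimize(
        objective, best_x, method="L-BFGS-B", bounds=bounds,
        options={"maxfun": max(maxfun // 3, 200), "eps": 1e-5,
                 "ftol": 1e-11, "gtol": 1e-6},
    )
    final_gain = best_f - float(res.fun)
    if res.fun < best_f:
        best_f, best_x = float(res.fun), res.x.copy()
    # the final stage certifies stationarity: either optimizer's own success
    # flag, or a final quasi-Newton pass that found essentially no further
    # descent from the simplex point (the FD-noise floor of the surface)
    stationary = bool(res.success) or bool(res_nm.success) or final_gain < 0.05
    converged = stationary and best_f <= ofv0 + 1e-8
    message = "" if converged else str(res.message)

    x_hat = best_x
    ofv, eta, f, J, v = engine.ofv(x_hat, tight=True)
    theta4, thetas_j, omega, sp, sa = enc.decode(x_hat)

    shrinkage = {}
    for k, p in enumerate(spec.iiv_parameters):
        sd_ebe = float(np.std(eta[:, k], ddof=1)) if design.n_subjects > 1 else 0.0
        shrinkage[p] = 100.0 * (1.0 - sd_ebe / omega[k]) if omega[k] > 0 else np.nan

    rse = {}
    if compute_rse:
        try:
            H = _fd_hessian(objective, x_hat)
            cov_x = 2.0 * np.linalg.pinv(H)
            se_x = np.sqrt(np.maximum(np.diag(cov_x), 0.0))
            for name, logged, se, val in zip(
                enc.names, enc.log_scaled, se_x, x_hat
            ):
                if logged:
                    rse[name] = 100.0 * se          # delta method on log scale
                else:
                    est = val
                    rse[name] = 100.0 * se / abs(est) if est != 0 else np.inf
        except np.linalg.LinAlgError:  # pragma: no cover - defensive
            message = message or "RSE Hessian not invertible"

    ebes = pd.DataFrame(
        eta,
        index=[s.subject_id for s in design.subjects],
        columns=[f"eta_{p}" for p in spec.iiv_parameters],
    )
    return FitResult(
        spec=spec,
        theta=PKParameters.from_array(theta4),
        covariate_thetas={
            e.label: tj for e, tj in zip(spec.covariate_effects, thetas_j)
        },
        omega=dict(zip(spec.iiv_parameters, omega)),
        sigma_prop=sp,
        sigma_add=sa,
        ofv=float(ofv),
        ebes=ebes,
        converged=converged,
        n_obs=design.n_obs,
        n_subjects=design.n_subjects,
        rse=rse,
        shrinkage=shrinkage,
        n_function_evals=engine.n_evals,
        message=message if not converged else "",
    )


# ---------------------------------------------------------------------------
# stepwise covariate screening


_DEFAULT_COVARIATES = (
    ("AGE", "continuous_power"),
    ("WT", "continuous_power"),
    ("SEX", "categorical_exponent"),
    ("ALT", "continuous_power"),
    ("SCR", "continuous_power"),
    ("CRCL", "continuous_power"),
    ("EGFR", "continuous_power"),
    ("ECMO", "categorical_exponent"),
    ("CRRT", "categorical_exponent"),
)


def default_candidates(ds: Dataset, parameters=PARAM_ORDER, covariates=None) -> list:
    """All parameter x covariate candidate effects, medians taken from the data."""
    if covariates is None:
        covariates = _DEFAULT_COVARIATES
    out = []
    for cov_name, form in covariates:
        ref = ds.covariate_median(cov_name) if form == "continuous_power" else None
        for p in parameters:
            out.append(
                CovariateEffect(parameter=p, covariate=cov_name, form=form,
                                theta_j=1.0 if form == "categorical_exponent" else 0.0,
                                reference=ref)
            )
    return out


def _refit(ds, spec, base_fit, **fit_kw):
    return fit(
        ds, spec,
        init=base_fit.theta if base_fit is not None else None,
        init_omega=float(np.mean(list(base_fit.omega.values()))) if base_fit and base_fit.omega else 0.3,
        init_sigma_prop=base_fit.sigma_prop if base_fit else 0.2,
        init_cov_thetas=dict(base_fit.covariate_thetas) if base_fit else None,
        compute_rse=False,
        **fit_kw,
    )


def forward_selection(ds: Dataset, base: ModelSpec, candidates,
                      threshold: float = 3.84, **fit_kw):
    """Stepwise forward inclusion by the largest OFV drop >= threshold.

    Ties are broken toward the lexicographically first effect label
    (each candidate adds exactly one parameter, so parsimony never breaks a
    tie here).  Returns the selected ModelSpec, the trace DataFrame of every
    tested delta-OFV, and the final fit.
    """
    current = base
    current_fit = fit(ds, current, compute_rse=False, **fit_kw)
    trace = []
    step = 0
    remaining = list(candidates)
    while remaining:
        step += 1
        results = []
        for cand in remaining:
            trial = current.with_effect(cand)
            try:
                trial_fit = _refit(ds, trial, current_fit, **fit_kw)
                dofv = current_fit.ofv - trial_fit.ofv
                results.append((cand, trial_fit, dofv, ""))
            except Exception as exc:  # candidate failures are recorded, not fatal
                results.append((cand, None, np.nan, f"fit failed: {exc}"))
        for cand, trial_fit, dofv, note in results:
            trace.append(
                {"step": step, "direction": "forward", "effect": cand.label,
                 "delta_ofv": dofv, "selected": False, "note": note}
            )
        ok = [(c, fres, d) for c, fres, d in
              [(c, fr, d) for c, fr, d, _ in results] if fres is not None]
        ok = [t for t in ok if t[2] >= threshold]
        if not ok:
            break
        ok.sort(key=lambda t: (-t[2], t[0].label))
        chosen, chosen_fit, chosen_dofv = ok[0]
        for row in trace:
            if row["step"] == step and row["effect"] == chosen.label:
                row["selected"] = True
        current = current.with_effect(chosen)
        current_fit = chosen_fit
        remaining = [c for c in remaining if c.label != chosen.label]
    return current, pd.DataFrame(trace), current_fit


def backward_elimination(ds: Dataset, full: ModelSpec,
                         threshold: float = 10.82, **fit_kw):
    """Stepwise backward removal: drop the cheapest effect while its cost < threshold.

    An effect survives only if removing it would raise the OFV by at least
    ``threshold`` (default: the printed chi-square(1) 0.001 cut-off, 10.82).
    """
    current = full
    current_fit = fit(ds, current, compute_rse=False, **fit_kw)
    trace = []
    step = 0
    while current.covariate_effects:
        step += 1
        results = []
        for eff in current.covariate_effects:
            trial = current.without_effect(eff.label)
            try:
                trial_fit = _refit(ds, trial, current_fit, **fit_kw)
                dofv = trial_fit.ofv - current_fit.ofv   # cost of removal
                results.append((eff, trial_fit, dofv, ""))
            except Exception as exc:
                results.append((eff, None, np.nan, f"fit failed: {exc}"))
        for eff, trial_fit, dofv, note in results:
            trace.append(
                {"step": step, "direction": "backward", "effect": eff.label,
                 "delta_ofv": dofv, "removed": False, "note": note}
            )
        ok = [(e, fr, d) for e, fr, d, _ in results if fr is not None and d < threshold]
        if not ok:
            break
        ok.sort(key=lambda t: (t[2], t[0].label))
        dropped, dropped_fit, _ = ok[0]
        for row in trace:
            if row["step"] == step and row["effect"] == dropped.label:
                row["removed"] = True
        current = current.without_effect(dropped.label)
        current_fit = dropped_fit
    return current, pd.DataFrame(trace), current_fit
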