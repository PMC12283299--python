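"""Synthetic cohort generator emulating the ICU remimazolam study design.

Produces datasets with the same design as the clinical study this package
models: 32 critically ill adults on continuous remimazolam infusion
(2-17.28 mg/h, median 6), arterial samples drawn at dose cessation and 10,
20, 30, 60, 90, 120 and 240 min after the stop, log-normal inter-individual
variability on all four disposition parameters, proportional residual error,
and an assay quantification floor of 1.0 ng/mL.  Covariate marginals target
the study's demographic table (medians and observed ranges); covariates are
sampled independently of one another and of the PK parameters unless an
explicit covariate effect is supplied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataset_io import COVARIATE_COLUMNS, Dataset
from .nlme_fit import PARAM_ORDER, individual_parameters
from .pkcore import PKParameters, Regimen, concentration

__all__ = [
    "CovariateProfile",
    "PopulationModel",
    "FINAL_MODEL_PK",
    "FINAL_MODEL_IIV",
    "default_population",
    "sample_covariates",
    "derive_renal",
    "sample_regimens",
    "simulate_cohort",
    "POST_STOP_MINUTES",
]

#: Nominal sampling protocol: minutes after infusion stop (0 = at cessation).
POST_STOP_MINUTES = (0.0, 10.0, 20.0, 30.0, 60.0, 90.0, 120.0, 240.0)

#: Final-model typical disposition values (CL L/h, V1 L, Q L/h, V2 L).
FINAL_MODEL_PK = PKParameters(cl=58.2, v1=25.5, q=20.0, v2=34.5)

#: Final-model IIV standard deviations on the log scale, per parameter
#: (the conventional CV% reading of 50.3 / 16.5 / 65.7 / 61.2 percent).
FINAL_MODEL_IIV = {"CL": 0.503, "V1": 0.165, "Q": 0.657, "V2": 0.612}

#: Assay lower limit of quantification, ng/mL.
LLOQ_DEFAULT = 1.0

#: Sample-loss probability reproducing the study's attrition
#: (256 nominal draws -> ~236 analysable samples).
DROPOUT_DEFAULT = 0.08


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline covariates of one simulated patient (units in field docs)."""

    age: float        # years
    weight: float     # kg
    sex: int          # 0 male, 1 female
    alt: float        # U/L
    scr: float        # umol/L
    tp: float         # g/L
    alb: float        # g/L
    ecmo: int         # 0/1
    crrt: int         # 0/1
    crcl: float = 0.0     # mL/min, Cockcroft-Gault (derived)
    egfr: float = 0.0     # mL/min/1.73m2, CKD-EPI 2009 (derived)

    def get(self, name: str) -> float:
        return float(getattr(self, name.lower() if name != "WT" else "weight"))

    def as_row(self) -> dict:
        return {
            "AGE": self.age, "WT": self.weight, "SEX": self.sex, "ALT": self.alt,
            "SCR": self.scr, "TP": self.tp, "ALB": self.alb, "ECMO": self.ecmo,
            "CRRT": self.crrt, "CRCL": self.crcl, "EGFR": self.egfr,
        }


@dataclass(frozen=True)
class PopulationModel:
    """Generating population model: typical values, IIV, residual error, covariates.

    The default residual model is proportional-only (sigma_prop = 0.25), the
    structure of the final clinical model; a combined model is obtained by
    setting ``sigma_add`` > 0.
    """

    theta: PKParameters = FINAL_MODEL_PK
    omega: dict = field(default_factory=lambda: dict(FINAL_MODEL_IIV))
    sigma_prop: float = 0.25
    sigma_add: float = 0.0
    covariate_effects: tuple = ()

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.omega.values()):
            raise ValueError("omega entries must be >= 0")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual SDs must be >= 0")
        unknown = set(self.omega) - set(PARAM_ORDER)
        if unknown:
            raise ValueError(f"unknown omega parameter(s): {sorted(unknown)}")

    @property
    def omega_vector(self) -> np.ndarray:
        return np.array([self.omega.get(p, 0.0) for p in PARAM_ORDER])


def default_population(**overrides) -> PopulationModel:
    """The final-model generating population (typical values + IIV + 25% error)."""
    return PopulationModel(**overrides)


# ---------------------------------------------------------------------------
# covariates


def _truncated_normal(rng, loc, scale, low, high, size):
    a, b = (low - loc) / scale, (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _truncated_lognormal(rng, median, log_sd, low, high, size):
    mu = math.log(median)
    a = (math.log(low) - mu) / log_sd
    b = (math.log(high) - mu) / log_sd
    return np.exp(
        stats.truncnorm.rvs(a, b, loc=mu, scale=log_sd, size=size, random_state=rng)
    )


def derive_renal(age: float, weight: float, sex: int, scr: float):
    """Cockcroft-Gault CrCL (mL/min) and CKD-EPI 2009 eGFR (mL/min/1.73 m2).

    ``scr`` is serum creatinine in umol/L (divided by 88.4 to mg/dL inside);
    the CKD-EPI equation is used without the race coefficient.
    """
    if scr <= 0:
        raise ValueError(f"SCR must be > 0, got {scr!r}")
    if age <= 0 or weight <= 0:
        raise ValueError("age and weight must be > 0")
    scr_mgdl = scr / 88.4
    crcl = (140.0 - age) * weight / (72.0 * scr_mgdl)
    if sex == 1:
        crcl *= 0.85
    kappa = 0.7 if sex == 1 else 0.9
    alpha = -0.329 if sex == 1 else -0.411
    ratio = scr_mgdl / kappa
    egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993 ** age
    if sex == 1:
        egfr *= 1.018
    return float(crcl), float(egfr)


def sample_covariates(n: int, seed=None) -> list:
    """Draw baseline covariate profiles matching the study's Table-1 marginals.

    Age and weight are truncated normals on the printed median/SD/range;
    skewed labs (ALT, SCR) are truncated log-normals centred on the printed
    medians; sex is 3:1 male:female; ECMO and CRRT use the observed 18/32 and
    14/32 prevalences.  Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    age = _truncated_normal(rng, 62.0, 13.22, 26.0, 79.0, n)
    weight = _truncated_normal(rng, 63.0, 19.0, 47.0, 98.0, n)
    sex = (rng.random(n) < 0.25).astype(int)             # 1 = female
    alt = _truncated_lognormal(rng, 34.85, 0.85, 7.8, 549.2, n)
    scr = _truncated_lognormal(rng, 75.75, 0.60, 42.1, 911.77, n)
    tp = _truncated_normal(rng, 55.4, 8.57, 26.82, 85.29, n)
    alb = _truncated_normal(rng, 30.4, 4.87, 15.97, 51.7, n)
    ecmo = (rng.random(n) < 18.0 / 32.0).astype(int)
    crrt = (rng.random(n) < 14.0 / 32.0).astype(int)
    out = []
    for i in range(n):
        crcl, egfr = derive_renal(age[i], weight[i], int(sex[i]), scr[i])
        out.append(
            CovariateProfile(
                age=float(age[i]), weight=float(weight[i]), sex=int(sex[i]),
                alt=float(alt[i]), scr=float(scr[i]), tp=float(tp[i]),
                alb=float(alb[i]), ecmo=int(ecmo[i]), crrt=int(crrt[i]),
                crcl=crcl, egfr=egfr,
            )
        )
    return out


# ---------------------------------------------------------------------------
# regimens


def sample_regimens(n: int, seed=None) -> list:
    """Constant-rate infusion regimens matching the study's dosing table.

    Rates: truncated log-normal, median 6 mg/h, bounded to the observed
    [2, 17.28] mg/h.  Durations: the observed distribution has half its mass
    within ~2 h of its 6.15-h minimum yet a 294.9-h maximum, so durations are
    drawn as 6.15 h plus a log-normal excess whose median lands the total at
    8.33 h, truncated at the observed maximum.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n!r}")
    rng = np.random.default_rng(seed)
    rates = _truncated_lognormal(rng, 6.0, 0.5, 2.0, 17.28, n)
    excess = _truncated_lognormal(rng, 8.33 - 6.15, 1.5, 1e-6, 294.9 - 6.15, n)
    durations = 6.15 + excess
    return [Regimen.constant_infusion(float(r), float(d)) for r, d in zip(rates, durations)]


# ---------------------------------------------------------------------------
# cohort simulation


def draw_individual_parameters(pop: PopulationModel, covs, rng) -> list:
    """Per-subject disposition parameters: typical x covariate terms x exp(eta)."""
    omega = pop.omega_vector
    params = []
    for cov in covs:
        eta = rng.normal(0.0, 1.0, size=4) * omega
        params.append(
            individual_parameters(
                pop.theta, pop.covariate_effects, cov, eta, iiv_parameters=PARAM_ORDER
            )
        )
    return params


def simulate_cohort(
    pop: PopulationModel | None = None,
    n: int = 32,
    seed=None,
    lloq: float = LLOQ_DEFAULT,
    dropout: float = DROPOUT_DEFAULT,
    return_truth: bool = False,
):
    """Simulate one study-design cohort and return it as a Dataset.

    Per subject: covariates and a constant-rate regimen are drawn, individual
    parameters include log-normal IIV and any covariate effects, observations
    are placed at dose cessation plus the protocol's post-stop minutes, and
    measurements apply ``y = f*(1+eps_prop) + eps_add`` with fresh errors per
    sample (negative draws redrawn).  Samples are independently lost with
    probability ``dropout`` (at least one observation per subject is always
    retained); values below ``lloq`` are kept but flagged BLQ.

    With ``return_truth=True`` also returns a per-subject frame of the true
    individual parameters (used by calibration tests).
    """
    pop = pop or default_population()
    if not 0.0 <= dropout < 1.0:
        raise ValueError(f"dropout must lie in [0, 1), got {dropout!r}")
    rng = np.random.default_rng(seed)
    covs = sample_covariates(n, seed=rng.integers(2**31))
    regimens = sample_regimens(n, seed=rng.integers(2**31))
    params = draw_individual_parameters(pop, covs, rng)

    rows = []
    truth = []
    for sid, (cov, regimen, p) in enumerate(zip(covs, regimens, params), start=1):
        cov_row = cov.as_row()
        for ev in regimen.events:
            rows.append(
                {"ID": sid, "TIME": ev.start, "AMT": ev.amount, "RATE": ev.rate,
                 "EVID": 1, "DV": np.nan, "MDV": 1, "BLQ": 0, **cov_row}
            )
        stop = regimen.end_time
        times = stop + np.asarray(POST_STOP_MINUTES) / 60.0
        f = concentration(p, regimen, times)
        keep = rng.random(len(times)) >= dropout
        if not keep.any():
            keep[rng.integers(len(times))] = True
        for tj, fj, kj in zip(times, f, keep):
            if not kj:
                continue
            for _ in range(100):
                y = fj * (1.0 + rng.normal(0.0, pop.sigma_prop)) \
                    + rng.normal(0.0, pop.sigma_add)
                if y >= 0.0 or (pop.sigma_prop == 0.0 and pop.sigma_add == 0.0):
                    break
            y = max(y, 0.0)
            rows.append(
                {"ID": sid, "TIME": tj, "AMT": 0.0, "RATE": 0.0, "EVID": 0,
                 "DV": y, "MDV": 0, "BLQ": int(y < lloq), **cov_row}
            )
        truth.append(
            {"ID": sid, "CL": p.cl, "V1": p.v1, "Q": p.q, "V2": p.v2,
             "SEX": cov.sex, "rate": regimen.events[-1].rate, "duration": stop}
        )
    frame = pd.DataFrame(rows, columns=["ID", "TIME", "AMT", "RATE", "EVID", "DV",
                                        "MDV", "BLQ"] + COVARIATE_COLUMNS)
    ds = Dataset(frame)
    if return_truth:
        return ds, pd.DataFrame(truth)
    return ds
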