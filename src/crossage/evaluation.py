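"""Evaluation surfaces: truth recovery, age RMSE, Cox association, moments.

Two ways of judging an aging-divergence prediction are implemented:

* against simulated truth (:func:`eval_delta_recovery`), available only in
  synthetic cohorts;
* against prospective mortality (:func:`fit_cox_delta`): a Cox proportional
  hazards model on the chronological-age timescale with delayed entry at the
  baseline age, the z-scored prediction and sex as covariates.

:func:`observational_equivalence` checks that two (marker, age) pairs share
all observable first and second moments — the empirical shadow of the
untestability of the identical-association assumption.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .predictors import DeltaPrediction
from .synthgen import CohortData

__all__ = [
    "RecoveryMetrics",
    "CoxDeltaResult",
    "RandomWeightSummary",
    "MomentReport",
    "eval_delta_recovery",
    "rmse_age",
    "fit_cox_delta",
    "observational_equivalence",
    "summarize_random_coefs",
]


@dataclass
class RecoveryMetrics:
    """Agreement between predicted and true aging divergence."""

    pearson_r: float
    rmse: float
    slope: float  # of truth on prediction; detects attenuation
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r out of range")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")


@dataclass
class CoxDeltaResult:
    """Log hazard ratio per SD of the aging-divergence prediction."""

    method: str
    loghr_per_sd: float
    se: float
    n_subjects: int
    n_events: int
    draw_index: int | None = None
    degenerate: bool = False
    converged: bool = True


@dataclass
class RandomWeightSummary:
    """Distribution of random-weight Cox coefficients vs reference methods."""

    coefficients: np.ndarray
    median: float
    exceedance: dict[str, float] = field(default_factory=dict)  # strict
    ties: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, frac in self.exceedance.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"exceedance fraction for {name!r} out of [0, 1]")


# ---------------------------------------------------------------------------
# truth recovery
# ---------------------------------------------------------------------------


def eval_delta_recovery(pred: DeltaPrediction, truth: np.ndarray) -> RecoveryMetrics:
    """Pearson r, RMSE (years) and the slope of truth on prediction."""
    truth = np.asarray(truth, dtype=float)
    d = pred.delta_hat
    if truth.shape != d.shape:
        raise ValueError("truth and prediction lengths differ")
    rmse = float(np.sqrt(np.mean((d - truth) ** 2)))
    if np.std(d) == 0:
        warnings.warn("zero-variance prediction: correlation undefined", stacklevel=2)
        return RecoveryMetrics(pearson_r=0.0, rmse=rmse, slope=0.0, degenerate=True)
    r = float(np.corrcoef(d, truth)[0, 1])
    slope = float(np.cov(truth, d, ddof=1)[0, 1] / np.var(d, ddof=1))
    return RecoveryMetrics(pearson_r=r, rmse=rmse, slope=slope)


def rmse_age(proxy: np.ndarray, age: np.ndarray) -> float:
    """Root-mean-square error of an age proxy against chronological age."""
    proxy = np.asarray(proxy, dtype=float)
    age = np.asarray(age, dtype=float)
    if proxy.shape != age.shape:
        raise ValueError("proxy and age lengths differ")
    return float(np.sqrt(np.mean((proxy - age) ** 2)))


# ---------------------------------------------------------------------------
# survival association
# ---------------------------------------------------------------------------


def fit_cox_delta(pred: DeltaPrediction, data: CohortData) -> CoxDeltaResult:
    """Cox PH fit of mortality on the scaled prediction, age timescale.

    Entry at baseline age (left truncation), exit at death or censoring,
    adjusted for sex when present; Efron handling of ties.  The prediction is
    z-scored before inclusion so the coefficient reads per SD.
    """
    from lifelines import CoxPHFitter

    if not data.has_survival():
        raise ValueError("cohort has no survival columns")
    n_events = int(data.event.sum())
    if n_events < 1:
        raise ValueError("no events in cohort")

    d = pred.delta_hat
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("constant delta prediction: coefficient degenerate", stacklevel=2)
        return CoxDeltaResult(
            method=pred.method,
            loghr_per_sd=0.0,
            se=float("nan"),
            n_subjects=data.n,
            n_events=n_events,
            draw_index=pred.draw_index,
            degenerate=True,
            converged=False,
        )

    frame = pd.DataFrame(
        {
            "entry_age": data.entry_age,
            "exit_age": data.exit_age,
            "event": data.event,
            "delta_scaled": (d - d.mean()) / sd,
        }
    )
    covariates = ["delta_scaled"]
    if data.sex is not None:
        frame["sex"] = data.sex
        covariates.append("sex")

    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(
                frame,
                duration_col="exit_age",
                event_col="event",
                entry_col="entry_age",
                fit_options={"precision": 1e-12, "max_steps": 500},
            )
    except Exception:
        return CoxDeltaResult(
            method=pred.method,
            loghr_per_sd=float("nan"),
            se=float("nan"),
            n_subjects=data.n,
            n_events=n_events,
            draw_index=pred.draw_index,
            converged=False,
        )
    return CoxDeltaResult(
        method=pred.method,
        loghr_per_sd=float(fitter.params_["delta_scaled"]),
        se=float(fitter.standard_errors_["delta_scaled"]),
        n_subjects=data.n,
        n_events=n_events,
        draw_index=pred.draw_index,
    )


# ---------------------------------------------------------------------------
# observational equivalence
# ---------------------------------------------------------------------------


@dataclass
class MomentReport:
    """Moment-by-moment comparison of two (marker, age) pairs."""

    differences: pd.DataFrame  # one row per moment: value_a, value_b, diff, se
    ks_statistic: float
    ks_pvalue: float
    indistinguishable: bool


def _var_se(x: np.ndarray) -> float:
    # SE of the sample variance under approximate normality
    return float(np.var(x, ddof=1) * np.sqrt(2.0 / (x.size - 1)))


def observational_equivalence(
    pair_a: tuple[np.ndarray, np.ndarray],
    pair_b: tuple[np.ndarray, np.ndarray],
    n_se: float = 4.0,
    ks_level: float = 0.01,
) -> MomentReport:
    """Compare the observable moments of two (marker, age) samples.

    All first moments, variances and the marker-age covariance must agree
    within ``n_se`` Monte-Carlo standard errors, and a two-sample
    Kolmogorov-Smirnov test on the marker columns must not reject at
    ``ks_level``, for the pairs to be flagged indistinguishable.
    """
    xa, ca = (np.asarray(v, dtype=float) for v in pair_a)
    xb, cb = (np.asarray(v, dtype=float) for v in pair_b)
    if xa.size != xb.size:
        raise ValueError("samples must have equal size")
    n = xa.size

    def mean_se(u, v):
        return float(np.sqrt(u.var(ddof=1) / u.size + v.var(ddof=1) / v.size))

    def cov_xc(x, c):
        return float(np.cov(x, c, ddof=1)[0, 1])

    def cov_se(x, c):
        # large-sample SE of the sample covariance
        return float(
            np.sqrt(
                (x.var(ddof=1) * c.var(ddof=1) + cov_xc(x, c) ** 2) / x.size
            )
        )

    rows = [
        ("mean_marker", xa.mean(), xb.mean(), mean_se(xa, xb)),
        ("mean_age", ca.mean(), cb.mean(), mean_se(ca, cb)),
        (
            "var_marker",
            xa.var(ddof=1),
            xb.var(ddof=1),
            float(np.hypot(_var_se(xa), _var_se(xb))),
        ),
        (
            "var_age",
            ca.var(ddof=1),
            cb.var(ddof=1),
            float(np.hypot(_var_se(ca), _var_se(cb))),
        ),
        (
            "cov_marker_age",
            cov_xc(xa, ca),
            cov_xc(xb, cb),
            float(np.hypot(cov_se(xa, ca), cov_se(xb, cb))),
        ),
    ]
    table = pd.DataFrame(rows, columns=["moment", "value_a", "value_b", "se"])
    table["diff"] = table["value_a"] - table["value_b"]
    identical = bool(np.array_equal(xa, xb) and np.array_equal(ca, cb))
    table["within_tol"] = identical | (table["diff"].abs() <= n_se * table["se"])

    ks_stat, ks_p = stats.ks_2samp(xa, xb)
    flag = bool(table["within_tol"].all() and (identical or ks_p > ks_level))
    return MomentReport(
        differences=table,
        ks_statistic=float(ks_stat),
        ks_pvalue=float(ks_p),
        indistinguishable=flag,
    )


# ---------------------------------------------------------------------------
# random-weight summaries
# ---------------------------------------------------------------------------


def summarize_random_coefs(
    results: list[CoxDeltaResult],
    references: dict[str, float] | None = None,
) -> RandomWeightSummary:
    """Median and strict exceedance fractions of random-weight coefficients."""
    if not results:
        raise ValueError("need at least one result")
    coefs = np.array([r.loghr_per_sd for r in results], dtype=float)
    references = references or {}
    exceedance = {
        name: float(np.mean(coefs > ref)) for name, ref in references.items()
    }
    ties = {name: int(np.sum(coefs == ref)) for name, ref in references.items()}
    return RandomWeightSummary(
        coefficients=coefs,
        median=float(np.median(coefs)),
        exceedance=exceedance,
        ties=ties,
    )
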